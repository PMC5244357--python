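"""The three-stage error-rate cascade on variant-free plasma.

Simulates a healthy (variant-free) sample and three negative controls at
the raw-read error regime (2.8e-3 substitutions per base), then shows how
each correction stage lowers the per-base non-reference call rate:
raw single reads -> paired-end consensus with discordant bases masked ->
per-base noise filtering against the worst control.
"""

from plasmacall import (
    ErrorModel,
    SimulationParams,
    assign_reads,
    base_noise_filter,
    build_pileup,
    make_panel,
    merge_read_set,
    nonref_rate_profile,
    simulate_controls,
    simulate_reads,
)

panel, _ = make_panel(4, insert_length_range=(60, 100), seed=11)
err = ErrorModel(substitution_rate=2.8e-3)
params = SimulationParams(depth_per_amplicon=4000, ctdna_fraction=0.0, seed=12)

sample = simulate_reads(panel, params, err)
controls = simulate_controls(panel, err, n_controls=3, seed=13, params=params)

# stage 0: raw mate-1 reads
raw_piles = []
for amp in panel:
    reads = [r1 for name, r1, _ in sample.pairs if name.startswith(amp.id + "|")]
    raw_piles.append(build_pileup(reads, amp))
raw = nonref_rate_profile(raw_piles)

# stage 1: merged consensus reads
merged = merge_read_set(sample).merged
groups, _ = assign_reads(merged, panel)
merged_piles = {amp.id: build_pileup(groups[amp.id], amp) for amp in panel}
consensus = nonref_rate_profile(list(merged_piles.values()))

# stage 2: noise filtering against the worst same-run control
control_piles = {amp.id: [] for amp in panel}
for ctl in controls:
    ctl_merged = merge_read_set(ctl).merged
    ctl_groups, _ = assign_reads(ctl_merged, panel)
    for amp in panel:
        control_piles[amp.id].append(build_pileup(ctl_groups[amp.id], amp))
filtered_piles = [
    base_noise_filter(merged_piles[amp.id], control_piles[amp.id]).filtered for amp in panel
]
filtered = nonref_rate_profile(filtered_piles)

print(f"raw reads:           {raw.mean_rate:.3e} non-reference calls per base")
print(f"merged consensus:    {consensus.mean_rate:.3e}")
print(f"noise-filtered:      {filtered.mean_rate:.3e}")
print(f"zero-error bases after filtering: {filtered.zero_error_fraction:.2%}")

# With independent mate errors, masking is nearly total (a substitution
# must hit both mates identically to survive, probability ~e^2/3). Real
# libraries gain closer to tenfold because a fraction of error events is
# shared between mates; the correlated mode reproduces that floor.
corr = ErrorModel(
    substitution_rate=2.8e-3, mate_error_mode="correlated", mate_error_correlation=0.1
)
corr_sample = simulate_reads(panel, params, corr)
corr_groups, _ = assign_reads(merge_read_set(corr_sample).merged, panel)
corr_profile = nonref_rate_profile(
    [build_pileup(corr_groups[amp.id], amp) for amp in panel]
)
print(f"\nmerged consensus with 10% correlated mate errors: {corr_profile.mean_rate:.3e}")
print(
    "\nIndependent-error masking would be almost perfect; shared error events\n"
    "set the realistic ~10x post-merge floor, and the per-base exact test\n"
    "against the worst control then removes nearly all residual noise."
)
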