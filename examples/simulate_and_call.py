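"""Simulate a patient plasma sample and call its panel variants.

Builds a 10-amplicon personalised panel, simulates a plasma library at a
0.5% ctDNA fraction plus three same-run negative controls, then runs the
full caller: pair merging with N-masking, primer-anchored assignment,
target counting, and the exact conditional Poisson rate-ratio test against
the worst control at the 0.01 cutoff.
"""

from plasmacall import (
    ErrorModel,
    SimulationParams,
    call_read_sets,
    call_sample,
    make_panel,
    results_table,
    simulate_controls,
    simulate_reads,
)

panel, _ = make_panel(10, seed=1)
err = ErrorModel()  # 2.8e-3 per-base substitution rate, independent mates
params = SimulationParams(
    genome_equivalents=3000, depth_per_amplicon=3000, ctdna_fraction=0.005, seed=2
)

sample = simulate_reads(panel, params, err)
controls = simulate_controls(panel, err, n_controls=3, seed=3, params=params)
res = call_read_sets(panel, sample, controls)

print(results_table(res.results).to_string(index=False))
sc = call_sample(res.results, sample_id="PT01-preop")
print(f"\nsample positive: {sc.positive}; reported ctDNA fraction: {sc.fraction_display}")
print(
    "Each row is one amplicon: k variant reads of n informative depth, the\n"
    "one-sided exact-test p-value against the highest-proportion control,\n"
    "and whether p < 0.01 calls the variant. The sample is positive when\n"
    "any amplicon is called; its fraction is the highest called VAF."
)
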