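"""Serial-dilution linearity: observed vs expected variant frequency.

Simulates a tumour-into-normal dilution series over the nine standard part
ratios (1:10 ... 1:2560), runs the counting pipeline at each ratio and
measures per-amplicon Pearson correlation between expected and observed
frequencies plus the pooled regression slope.
"""

import numpy as np
import pandas as pd

from plasmacall import (
    SimulationParams,
    counts_for_read_set,
    dilution_linearity,
    make_panel,
    simulate_dilution_series,
)

panel, _ = make_panel(6, seed=21)
tumour_vafs = dict(zip((a.id for a in panel), np.geomspace(0.02, 0.11, 6)))
normal_vafs = {a.id: 0.0 for a in panel}
params = SimulationParams(genome_equivalents=50000, depth_per_amplicon=3000)

series = simulate_dilution_series(panel, tumour_vafs, normal_vafs, params=params, seed=22)
rows = []
for ratio, read_set in series.read_sets.items():
    counts = counts_for_read_set(read_set, panel)
    for amp in panel:
        ef = series.expected.query("amplicon_id == @amp.id and ratio == @ratio")[
            "expected_frequency"
        ].item()
        c = counts[amp.id]
        rows.append(
            {
                "amplicon_id": amp.id,
                "ratio": ratio,
                "expected_frequency": ef,
                "variant_reads": c.variant_reads,
                "depth": c.depth,
            }
        )

res = dilution_linearity(pd.DataFrame(rows), min_depth=1000, r_threshold=0.95)
print(res.per_amplicon.to_string(index=False))
print(f"\nfraction of amplicons with r > 0.95: {res.fraction_above_threshold:.0%}")
print(f"pooled slope: {res.slope:.3f} (1.0 = unbiased recovery)")
print(f"aggregate r^2: {res.aggregate_r2:.3f}")
print(
    "\nHigh per-amplicon correlations and a slope near one mean the assay\n"
    "reports allele frequency linearly across three orders of magnitude;\n"
    "the lowest dilutions scatter because few mutant templates remain."
)
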