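"""Designing a panel: variant ranking, tissue QC and primer-dimer screening.

Ranks candidate tumour variants by the design priority scheme (previously
validated site > cancer-gene list > missense/indel > splice > synonymous >
UTR/intron), applies the tumour-vs-normal tissue VAF filter, and flags
primers whose dimers consume more than 20% of sequencing reads.
"""

from plasmacall import (
    CandidateVariant,
    make_panel,
    qc_amplicons_by_tissue_vaf,
    rank_variants,
    revcomp,
    scan_primer_dimers,
)

candidates = [
    CandidateVariant("17", 7577538, "C", "T", gene="TP53", consequence="missense"),
    CandidateVariant("5", 112175240, "G", "A", gene="APC", consequence="synonymous"),
    CandidateVariant("12", 25398284, "C", "A", gene="KRAS", consequence="missense"),
    CandidateVariant("3", 178936091, "G", "A", gene="PIK3CA", consequence="utr"),
    CandidateVariant("1", 115256529, "T", "C", gene="NRAS", consequence="splice"),
]
ranked = rank_variants(
    candidates,
    prior_primer_sites={("12", 25398284)},  # KRAS hotspot: validated primers exist
    cancer_genes={"APC", "TP53"},
)
print("design priority order:")
for cand, cls in ranked:
    print(f"  class {cls}: {cand.gene} {cand.chrom}:{cand.pos} {cand.ref}>{cand.alt}")

decisions = qc_amplicons_by_tissue_vaf(
    tumour_counts={"AMP01": (120, 400), "AMP02": (0, 500), "AMP03": (12, 600)},
    normal_counts={"AMP01": (1, 400), "AMP02": (0, 500), "AMP03": (8, 600)},
)
print("\ntissue QC (tumour vs normal VAF, 2-fold rule):")
for amp, decision in decisions.items():
    print(f"  {amp}: {decision}")

panel, _ = make_panel(3, seed=31)
p1 = panel.amplicons[0].fwd_primer
dimers = [p1 + revcomp(p1)] * 30  # 30% of reads are self-dimers of primer 1
report = scan_primer_dimers(dimers, panel, total_reads=100)
print(f"\nflagged primers (>20% dimer reads): {report.flagged}")
print(
    "\nA hotspot with validated primers outranks everything; amplicons whose\n"
    "tumour VAF is zero or <2-fold the matched normal are dropped; primers\n"
    "feeding >20% of reads into dimers are removed from the multiplex."
)
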