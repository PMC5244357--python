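"""Patient-specific assay panels.

A panel is the definition of one patient's personalised multiplex amplicon
assay: up to 15 amplicons, each with a forward/reverse primer pair, a short
insert (60-150 bp) and exactly one target somatic variant strictly inside
the insert. Variants carry a priority class reflecting how candidates are
ranked when a panel is designed from tumour sequencing, and an optional
origin label (e.g. ``primary`` / ``metastasis``) used for multi-origin
reporting.

Internal coordinates are 0-based half-open; the TSV interchange format is
1-based inclusive, converted on read/write.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

PRIORITY_CLASSES = ("a", "b", "c", "d", "e", "f")

#: consequence annotation -> priority class when no higher rule applies
_CONSEQUENCE_CLASS = {
    "missense": "c",
    "inframe_indel": "c",
    "frameshift": "c",
    "indel": "c",
    "splice": "d",
    "splice_site": "d",
    "synonymous": "e",
    "utr": "f",
    "intron": "f",
    "intergenic": "f",
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class PanelError(ValueError):
    """Raised for malformed panel definitions or panel files."""


@dataclass(frozen=True)
class PanelVariant:
    """A single target somatic variant (SNV or short indel).

    ``pos`` is the 1-based reference coordinate of the first affected base,
    VCF-style: for indels, ``ref`` and ``alt`` share their first base.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    priority_class: str = "c"
    origin_label: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise PanelError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise PanelError(f"ref and alt alleles are identical at {self.chrom}:{self.pos}")
        if self.priority_class not in PRIORITY_CLASSES:
            raise PanelError(f"unknown priority class {self.priority_class!r}")
        for allele in (self.ref, self.alt):
            if not allele or set(allele) - set("ACGT"):
                raise PanelError(f"bad allele {allele!r} at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class Amplicon:
    """One amplicon of a panel.

    The reference contig holds the full PCR product; the insert interval
    (0-based half-open, in contig coordinates) excludes the primer binding
    sites. The single target variant must lie strictly inside the insert.
    """

    id: str
    chrom: str
    insert_start: int
    insert_end: int
    fwd_primer: str
    rev_primer: str
    insert_seq: str
    variant: PanelVariant

    def __post_init__(self) -> None:
        length = self.insert_end - self.insert_start
        if not 60 <= length <= 150:
            raise PanelError(
                f"amplicon {self.id}: insert length {length} outside [60, 150]"
            )
        if len(self.insert_seq) != length:
            raise PanelError(f"amplicon {self.id}: insert sequence/interval length mismatch")
        pos0 = self.variant.pos - 1
        if not (self.insert_start < pos0 < self.insert_end - max(1, len(self.variant.ref))):
            raise PanelError(
                f"amplicon {self.id}: variant at {self.variant.pos} not strictly inside insert"
            )
        if self.variant.chrom != self.chrom:
            raise PanelError(f"amplicon {self.id}: variant contig differs from amplicon contig")

    @property
    def insert_length(self) -> int:
        return self.insert_end - self.insert_start

    @property
    def variant_offset(self) -> int:
        """0-based offset of the variant within the insert."""
        return self.variant.pos - 1 - self.insert_start

    @property
    def product_seq(self) -> str:
        """Full PCR product: forward primer + insert + revcomp(reverse primer)."""
        return self.fwd_primer + self.insert_seq + revcomp(self.rev_primer)

    @property
    def variant_product_offset(self) -> int:
        """0-based offset of the variant within the PCR product."""
        return len(self.fwd_primer) + self.variant_offset

    def alt_product_seq(self) -> str:
        """PCR product carrying the alt allele (may differ in length for indels)."""
        p = self.product_seq
        off = self.variant_product_offset
        return p[:off] + self.variant.alt + p[off + len(self.variant.ref):]


@dataclass
class Panel:
    """A patient's assay: 1-15 uniquely identified amplicons."""

    patient_id: str
    amplicons: list[Amplicon]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= len(self.amplicons) <= 15:
            raise PanelError(
                f"panel {self.patient_id}: {len(self.amplicons)} amplicons outside [1, 15]"
            )
        ids = [a.id for a in self.amplicons]
        if len(set(ids)) != len(ids):
            raise PanelError(f"panel {self.patient_id}: duplicate amplicon ids")
        keys = [a.variant.key for a in self.amplicons]
        if len(set(keys)) != len(keys):
            raise PanelError(f"panel {self.patient_id}: duplicate target variants")

    def __len__(self) -> int:
        return len(self.amplicons)

    def __iter__(self):
        return iter(self.amplicons)

    def get(self, amplicon_id: str) -> Amplicon:
        for a in self.amplicons:
            if a.id == amplicon_id:
                return a
        raise KeyError(amplicon_id)


# ---------------------------------------------------------------------------
# variant ranking


@dataclass(frozen=True)
class CandidateVariant:
    """A tumour-derived candidate variant annotated for panel design."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: str = "missense"
    origin_label: str = ""


def classify_priority(
    candidate: CandidateVariant,
    prior_primer_sites: Iterable[tuple[str, int]] = (),
    cancer_genes: Iterable[str] = (),
) -> str:
    """Priority class of a candidate under the design ranking rules.

    Class ``a`` (a previously validated primer pair covers the site)
    dominates; then ``b`` (gene on the supplied cancer-gene list); classes
    ``c``-``f`` follow from the consequence annotation (missense/indel,
    splice, synonymous, UTR/intronic).
    """
    if (candidate.chrom, candidate.pos) in set(prior_primer_sites):
        return "a"
    if candidate.gene and candidate.gene in set(cancer_genes):
        return "b"
    return _CONSEQUENCE_CLASS.get(candidate.consequence, "f")


def rank_variants(
    candidates: Sequence[CandidateVariant],
    prior_primer_sites: Iterable[tuple[str, int]] = (),
    cancer_genes: Iterable[str] = (),
    max_n: int = 15,
) -> list[tuple[CandidateVariant, str]]:
    """Rank candidates by priority class a->f and truncate at ``max_n``.

    The sort is stable: ties within a class keep input order. Returns
    (candidate, assigned_class) pairs. The cancer-gene list is configuration
    supplied by the user, not a built-in.
    """
    prior = set(prior_primer_sites)
    genes = set(cancer_genes)
    classed = [(c, classify_priority(c, prior, genes)) for c in candidates]
    ranked = sorted(classed, key=lambda cc: PRIORITY_CLASSES.index(cc[1]))
    return ranked[:max_n]


# ---------------------------------------------------------------------------
# tissue-VAF amplicon QC


def qc_amplicons_by_tissue_vaf(
    tumour_counts: Mapping[str, tuple[int, int]],
    normal_counts: Mapping[str, tuple[int, int]],
    fold_threshold: float = 2.0,
    min_depth: int = 100,
) -> dict[str, str]:
    """Keep/drop decisions from tumour vs matched-normal tissue VAFs.

    An amplicon is dropped when the tumour VAF is 0, or when it is less
    than ``fold_threshold`` times the normal-tissue VAF (the variant does
    not discriminate tumour from germline/noise). Amplicons with depth below
    ``min_depth`` (default 100X, the tissue-verification threshold) in
    either tissue are ``unevaluable`` rather than silently dropped.

    Counts are (variant_reads, depth) pairs per amplicon id. Decisions are
    invariant to scaling both tissues' counts by a common factor.
    """
    decisions: dict[str, str] = {}
    for amp_id, (tk, tn) in tumour_counts.items():
        if amp_id not in normal_counts:
            decisions[amp_id] = "unevaluable"
            continue
        nk, nn = normal_counts[amp_id]
        if tn < min_depth or nn < min_depth or tn == 0 or nn == 0:
            decisions[amp_id] = "unevaluable"
            continue
        tvaf = tk / tn
        nvaf = nk / nn
        if tvaf == 0:
            decisions[amp_id] = "drop"
        elif nvaf > 0 and tvaf < fold_threshold * nvaf:
            decisions[amp_id] = "drop"
        else:
            decisions[amp_id] = "keep"
    return decisions


# ---------------------------------------------------------------------------
# TSV / BED / VCF interchange

_TSV_COLUMNS = [
    "patient_id",
    "amplicon_id",
    "chrom",
    "insert_start",
    "insert_end",
    "fwd_primer",
    "rev_primer",
    "insert_seq",
    "variant_pos",
    "ref",
    "alt",
    "gene",
    "priority_class",
    "origin_label",
]


def write_panel(panel: Panel, path) -> None:
    """Write a panel to TSV (1-based inclusive insert coordinates)."""
    rows = []
    for a in panel:
        rows.append(
            {
                "patient_id": panel.patient_id,
                "amplicon_id": a.id,
                "chrom": a.chrom,
                "insert_start": a.insert_start + 1,
                "insert_end": a.insert_end,
                "fwd_primer": a.fwd_primer,
                "rev_primer": a.rev_primer,
                "insert_seq": a.insert_seq,
                "variant_pos": a.variant.pos,
                "ref": a.variant.ref,
                "alt": a.variant.alt,
                "gene": a.variant.gene,
                "priority_class": a.variant.priority_class,
                "origin_label": a.variant.origin_label,
            }
        )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_panel(path) -> Panel:
    """Read a panel TSV written by :func:`write_panel`.

    1-based inclusive coordinates are converted to the 0-based half-open
    internal convention. Malformed rows raise :class:`PanelError` with the
    offending line number; duplicate variants are rejected by the
    :class:`Panel` invariants.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise PanelError(f"panel file missing columns: {sorted(missing)}")
    amplicons = []
    patient_id = ""
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            variant = PanelVariant(
                chrom=row["chrom"],
                pos=int(row["variant_pos"]),
                ref=row["ref"],
                alt=row["alt"],
                gene=row["gene"],
                priority_class=row["priority_class"] or "c",
                origin_label=row["origin_label"],
            )
            amplicons.append(
                Amplicon(
                    id=row["amplicon_id"],
                    chrom=row["chrom"],
                    insert_start=int(row["insert_start"]) - 1,
                    insert_end=int(row["insert_end"]),
                    fwd_primer=row["fwd_primer"],
                    rev_primer=row["rev_primer"],
                    insert_seq=row["insert_seq"],
                    variant=variant,
                )
            )
            patient_id = row["patient_id"]
        except (PanelError, ValueError) as exc:
            raise PanelError(f"{path}, line {line_no}: {exc}") from exc
    return Panel(patient_id=patient_id, amplicons=amplicons)


def write_bed(panel: Panel, path) -> None:
    """Export insert intervals as BED (0-based half-open, as BED requires)."""
    with open(path, "w") as fh:
        for a in panel:
            fh.write(f"{a.chrom}\t{a.insert_start}\t{a.insert_end}\t{a.id}\n")


def write_vcf(panel: Panel, path, contig_lengths: Mapping[str, int] | None = None) -> None:
    """Export target variants as a minimal VCF 4.2 file."""
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write(f"##source=plasmacall panel {panel.patient_id}\n")
    if contig_lengths:
        for name, length in contig_lengths.items():
            buf.write(f"##contig=<ID={name},length={length}>\n")
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for a in panel:
        v = a.variant
        info = f"AMPLICON={a.id}"
        if v.gene:
            info += f";GENE={v.gene}"
        buf.write(f"{v.chrom}\t{v.pos}\t{a.id}\t{v.ref}\t{v.alt}\t.\t.\t{info}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
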