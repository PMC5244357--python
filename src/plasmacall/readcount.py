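"""Amplicon assignment, pileups, and variant-supporting read counts.

Merged consensus reads are anchored to their amplicon by the forward primer
at the 5' end (the multiplex PCR product structure makes an aligner
unnecessary for synthetic or well-behaved data; a SAM ingestion path exists
for pre-aligned reads). Per-target counts distinguish variant-supporting,
reference, other-substitution and N-masked reads: an N at the target
position is uninformative and is excluded from the depth denominator, so
the exact-test exposures equal informative depth.

Internal coordinates are 0-based half-open; interchange stays 1-based.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import Amplicon, Panel
from .readprep import MergedRead

logger = logging.getLogger(__name__)

_ROW = {b: i for i, b in enumerate("ACGTN")}


@dataclass
class AmpliconCount:
    """Variant-supporting and total informative counts at one target.

    ``depth`` (n) counts reads informative at the target position:
    variant + reference + other-substitution reads. N-masked reads are
    excluded; they support neither allele.
    """

    amplicon_id: str
    variant_reads: int
    depth: int
    reference_reads: int
    other_reads: int = 0
    n_masked_reads: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.variant_reads <= self.depth:
            raise ValueError(
                f"{self.amplicon_id}: variant reads {self.variant_reads} "
                f"outside [0, depth={self.depth}]"
            )

    @property
    def vaf(self) -> float:
        return self.variant_reads / self.depth if self.depth else 0.0


@dataclass
class ControlCounts:
    """Counts at one target for up to three same-run negative controls."""

    entries: list  # (variant_reads, depth) per control

    def __post_init__(self) -> None:
        if not 1 <= len(self.entries) <= 3:
            raise ValueError(f"expected 1-3 controls, got {len(self.entries)}")
        for k, n in self.entries:
            if not 0 <= k <= n:
                raise ValueError(f"control counts ({k}, {n}) violate 0 <= k <= n")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class Pileup:
    """Base counts over one amplicon's insert positions.

    ``base_counts`` is a (5, L) matrix with rows A, C, G, T, N; ``del_counts``
    counts reads whose gapped placement deletes the position, and
    ``ins_counts`` counts reads with an insertion starting at the position.
    Coverage at a position is the column sum plus deletions.
    """

    amplicon_id: str
    chrom: str
    insert_start: int
    ref_insert: str
    base_counts: np.ndarray
    del_counts: np.ndarray
    ins_counts: np.ndarray

    @classmethod
    def empty(cls, amplicon: Amplicon) -> "Pileup":
        length = amplicon.insert_length
        return cls(
            amplicon_id=amplicon.id,
            chrom=amplicon.chrom,
            insert_start=amplicon.insert_start,
            ref_insert=amplicon.insert_seq,
            base_counts=np.zeros((5, length), dtype=np.int64),
            del_counts=np.zeros(length, dtype=np.int64),
            ins_counts=np.zeros(length, dtype=np.int64),
        )

    def coverage(self) -> np.ndarray:
        return self.base_counts.sum(axis=0) + self.del_counts

    def nonref_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(non-reference non-N calls, total non-N calls) per position.

        Deleted bases count as non-reference calls; N calls are excluded
        from both numerator and denominator.
        """
        acgt = self.base_counts[:4].sum(axis=0)
        ref_idx = np.array([_ROW[b] for b in self.ref_insert])
        ref_counts = self.base_counts[ref_idx, np.arange(len(self.ref_insert))]
        total = acgt + self.del_counts
        nonref = total - ref_counts
        return nonref, total


# ---------------------------------------------------------------------------
# read -> amplicon assignment


def _prefix_mismatches(seq: str, primer: str) -> int:
    if len(seq) < len(primer):
        return len(primer)  # cannot anchor
    return sum(a != b for a, b in zip(seq, primer))


def assign_reads(
    merged_reads: Iterable,
    panel: Panel,
    max_primer_mismatches: int = 2,
) -> tuple[dict, list]:
    """Group merged reads by amplicon via forward-primer anchoring.

    A read is assigned to the unique amplicon whose forward primer matches
    its 5' end within ``max_primer_mismatches``; reads matching zero or
    several amplicons are left unassigned (ambiguity rule).
    """
    groups: dict[str, list] = {a.id: [] for a in panel}
    unassigned: list = []
    primers = [(a.id, a.fwd_primer) for a in panel]
    # Exact-prefix lookup is a safe shortcut when primers are pairwise more
    # than 2*max_primer_mismatches apart: an exact hit then excludes any
    # near-hit on another primer, so no ambiguity check is needed.
    separated = all(
        sum(x != y for x, y in zip(p, q)) > 2 * max_primer_mismatches
        for i, (_, p) in enumerate(primers)
        for (_, q) in primers[i + 1 :]
    )
    exact = {p: amp_id for amp_id, p in primers}
    lengths = sorted({len(p) for _, p in primers})
    for read in merged_reads:
        seq = read.sequence if hasattr(read, "sequence") else read
        if separated:
            hit = None
            for length in lengths:
                hit = exact.get(seq[:length])
                if hit is not None:
                    break
            if hit is not None:
                groups[hit].append(read)
                continue
        hits = [
            amp_id
            for amp_id, primer in primers
            if _prefix_mismatches(seq, primer) <= max_primer_mismatches
        ]
        if len(hits) == 1:
            groups[hits[0]].append(read)
        else:
            unassigned.append(read)
    return groups, unassigned


# ---------------------------------------------------------------------------
# read classification at the target


def classify_read(seq: str, amplicon: Amplicon) -> str:
    """Classify one product-anchored read at the target position.

    Returns ``alt``, ``ref``, ``other`` (covers the position with a third
    allele), ``n`` (N at the discriminating position — uninformative) or
    ``noncovering``. SNVs compare the single aligned base; indels require
    the read suffix from the variant position to reproduce the alt (or ref)
    haplotype exactly, ignoring N positions.
    """
    v = amplicon.variant
    p = amplicon.variant_product_offset
    if v.is_snv:
        if len(seq) <= p:
            return "noncovering"
        c = seq[p]
        if c == "N":
            return "n"
        if c == v.alt:
            return "alt"
        if c == v.ref:
            return "ref"
        return "other"
    # indel: match suffixes against the two haplotypes
    if len(seq) < p + max(len(v.ref), len(v.alt)) + 1:
        return "noncovering"
    seg = seq[p:]
    ref_seg = amplicon.product_seq[p : p + len(seg)]
    alt_seg = amplicon.alt_product_seq()[p : p + len(seg)]
    matches_ref = all(c == "N" or c == r for c, r in zip(seg, ref_seg))
    matches_alt = all(c == "N" or c == r for c, r in zip(seg, alt_seg))
    if matches_ref and matches_alt:
        return "n"  # Ns (or truncation) prevent discrimination
    if matches_alt:
        return "alt"
    if matches_ref:
        return "ref"
    return "other"


def count_variant_reads(read_group: Sequence, amplicon: Amplicon) -> AmpliconCount:
    """Count variant-supporting and reference reads at an amplicon's target.

    The depth n is informative coverage (alt + ref + other); N-masked reads
    are excluded from n entirely. No reads covering the position yields
    k = 0, n = 0.
    """
    tallies = {"alt": 0, "ref": 0, "other": 0, "n": 0, "noncovering": 0}
    for read in read_group:
        seq = read.sequence if hasattr(read, "sequence") else read
        tallies[classify_read(seq, amplicon)] += 1
    return AmpliconCount(
        amplicon_id=amplicon.id,
        variant_reads=tallies["alt"],
        depth=tallies["alt"] + tallies["ref"] + tallies["other"],
        reference_reads=tallies["ref"],
        other_reads=tallies["other"],
        n_masked_reads=tallies["n"],
    )


def apply_depth_filter(count: AmpliconCount, min_depth: int = 1000) -> str:
    """Depth gate: ``evaluable`` at n >= min_depth (default 1000X), else
    ``not_called`` — excluded from positivity and metric denominators."""
    return "evaluable" if count.depth >= min_depth else "not_called"


# ---------------------------------------------------------------------------
# pileups


def build_pileup(read_group: Sequence, amplicon: Amplicon) -> Pileup:
    """Pileup of product-anchored reads over the amplicon insert.

    Reads classified as supporting an indel alt are placed with the gap:
    deleted reference positions receive deletion counts and positions after
    the event are shifted back into reference coordinates; insertion reads
    increment the insertion-start counter at the anchor position.
    """
    pile = Pileup.empty(amplicon)
    v = amplicon.variant
    fwd_len = len(amplicon.fwd_primer)
    length = amplicon.insert_length
    indel = not v.is_snv
    event_off = amplicon.variant_offset  # insert coordinate of the anchor base
    dlen = len(v.ref) - len(v.alt)  # >0 deletion, <0 insertion
    for read in read_group:
        seq = read.sequence if hasattr(read, "sequence") else read
        gapped = indel and classify_read(seq, amplicon) == "alt"
        if not gapped:
            start = fwd_len
            seg = seq[start : start + length]
            for j, c in enumerate(seg):
                pile.base_counts[_ROW.get(c, 4), j] += 1
        else:
            if dlen > 0:  # deletion
                for j in range(length):
                    if event_off < j <= event_off + dlen:
                        pile.del_counts[j] += 1
                        continue
                    q = fwd_len + (j if j <= event_off else j - dlen)
                    if q < len(seq):
                        pile.base_counts[_ROW.get(seq[q], 4), j] += 1
            else:  # insertion of -dlen bases after the anchor
                ilen = -dlen
                pile.ins_counts[event_off] += 1
                for j in range(length):
                    q = fwd_len + (j if j <= event_off else j + ilen)
                    if q < len(seq):
                        pile.base_counts[_ROW.get(seq[q], 4), j] += 1
    return pile


def pileups_for_sample(
    merged_reads: Iterable, panel: Panel, max_primer_mismatches: int = 2
) -> dict:
    """Assign reads and build one pileup per amplicon."""
    groups, _ = assign_reads(merged_reads, panel, max_primer_mismatches)
    return {amp.id: build_pileup(groups[amp.id], amp) for amp in panel}


# ---------------------------------------------------------------------------
# error-rate profiling


@dataclass
class ErrorProfile:
    per_position: pd.DataFrame  # amplicon_id, chrom, pos (1-based), nonref, total, proportion
    mean_rate: float
    zero_error_fraction: float
    n_positions: int


def nonref_rate_profile(
    pileups: Sequence[Pileup],
    exclude_sites: Iterable[tuple[str, int]] = (),
) -> ErrorProfile:
    """Per-position non-reference proportions over a set of pileups.

    ``exclude_sites`` lists (chrom, 1-based position) sites to remove —
    typically common population variants and the panel's own targets.
    Reports the mean non-reference proportion over included covered
    positions and the fraction of those positions with zero non-reference
    calls (the "clean base" fraction).
    """
    excluded = set(exclude_sites)
    rows = []
    for pile in pileups:
        nonref, total = pile.nonref_counts()
        for j in range(len(pile.ref_insert)):
            pos1 = pile.insert_start + j + 1
            if (pile.chrom, pos1) in excluded:
                continue
            if total[j] == 0:
                continue
            rows.append(
                {
                    "amplicon_id": pile.amplicon_id,
                    "chrom": pile.chrom,
                    "pos": pos1,
                    "nonref": int(nonref[j]),
                    "total": int(total[j]),
                    "proportion": nonref[j] / total[j],
                }
            )
    df = pd.DataFrame(rows, columns=["amplicon_id", "chrom", "pos", "nonref", "total", "proportion"])
    if df.empty:
        warnings.warn("all positions excluded or uncovered; empty error profile")
        return ErrorProfile(df, float("nan"), float("nan"), 0)
    return ErrorProfile(
        per_position=df,
        mean_rate=float(df["proportion"].mean()),
        zero_error_fraction=float((df["nonref"] == 0).mean()),
        n_positions=len(df),
    )


# ---------------------------------------------------------------------------
# SAM ingestion (pre-aligned reads)


def sam_variant_counts(sam_path, panel: Panel) -> dict:
    """Per-amplicon target counts from a SAM/BAM of pre-aligned reads.

    Reads must be aligned to the panel's reference contigs (one PCR product
    per amplicon). Base identity at the target comes from the query sequence
    through the aligned pairs, so files with extended CIGAR (=/X) or plain M
    operations both work; indel targets are matched through the gap
    structure. Unmapped and off-target records are ignored.
    """
    import pysam

    by_chrom = {a.chrom: a for a in panel}
    tallies = {a.id: {"alt": 0, "ref": 0, "other": 0, "n": 0} for a in panel}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped or rec.reference_name not in by_chrom:
                continue
            amp = by_chrom[rec.reference_name]
            v = amp.variant
            pos0 = v.pos - 1
            pairs = rec.get_aligned_pairs()
            if v.is_snv:
                q = next((qp for qp, rp in pairs if rp == pos0), None)
                if q is None:
                    if any(rp == pos0 for _, rp in pairs):
                        tallies[amp.id]["other"] += 1  # deleted at target
                    continue
                base = rec.query_sequence[q]
                cls = (
                    "n"
                    if base == "N"
                    else "alt"
                    if base == v.alt
                    else "ref"
                    if base == v.ref
                    else "other"
                )
                tallies[amp.id][cls] += 1
            else:
                cls = _classify_sam_indel(rec, pairs, v, pos0)
                if cls is not None:
                    tallies[amp.id][cls] += 1
    out = {}
    for amp in panel:
        t = tallies[amp.id]
        out[amp.id] = AmpliconCount(
            amplicon_id=amp.id,
            variant_reads=t["alt"],
            depth=t["alt"] + t["ref"] + t["other"],
            reference_reads=t["ref"],
            other_reads=t["other"],
            n_masked_reads=t["n"],
        )
    return out


def _classify_sam_indel(rec, pairs, v, pos0: int):
    """Classify an aligned read at an indel target (None = noncovering)."""
    covered = [rp for _, rp in pairs if rp is not None]
    if not covered or pos0 < covered[0] or pos0 >= covered[-1]:
        return None
    dlen = len(v.ref) - len(v.alt)
    if dlen > 0:  # deletion of dlen bases after the anchor
        deleted = [rp for qp, rp in pairs if qp is None and rp is not None]
        want = set(range(pos0 + 1, pos0 + 1 + dlen))
        if want <= set(deleted):
            return "alt"
        return "ref" if not (want & set(deleted)) else "other"
    # insertion after the anchor: query positions with no reference position
    ins_len = -dlen
    ins_here = 0
    seen_anchor = False
    for qp, rp in pairs:
        if rp == pos0:
            seen_anchor = True
            continue
        if seen_anchor and rp is None and qp is not None:
            ins_here += 1
            continue
        if seen_anchor and rp is not None:
            break
    if ins_here == ins_len:
        return "alt"
    return "ref" if ins_here == 0 else "other"
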