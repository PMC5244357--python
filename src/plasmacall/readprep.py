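"""Paired-end consensus merging and read screening.

This is the first error-correction stage of the pipeline: overlapping mates
of an amplicon read pair are merged into a single consensus read, and any
position where the two mates disagree is masked to N rather than resolved.
Because a substitution error must hit the same position on both mates (and
produce the same wrong base) to survive, masking drops the per-base error
rate at double-covered positions from e to roughly e^2/3.

Also here: the short-read filter (<40 nt) and the primer-dimer scan that
attributes short artefactual reads to the primer pairs that formed them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .panel import Panel, revcomp

logger = logging.getLogger(__name__)

_ORD_N = ord("N")


@dataclass(frozen=True)
class ReadPair:
    """A mate pair as sequenced (mate2 on the reverse strand)."""

    id: str
    mate1: str
    mate2: str

    def __post_init__(self) -> None:
        for seq in (self.mate1, self.mate2):
            if not seq or set(seq) - set("ACGTN"):
                raise ValueError(f"read pair {self.id}: bad sequence")


@dataclass(frozen=True)
class MergedRead:
    id: str
    sequence: str
    overlap_length: int
    n_masked: int = 0


@dataclass
class MergeStats:
    merged: int = 0
    unmerged: int = 0
    skipped: int = 0
    masked_positions: int = 0


@dataclass
class MergeResult:
    merged: list
    unmerged: list
    stats: MergeStats


@dataclass
class DimerReport:
    """Per-primer dimer read fractions over total sequencing reads."""

    fractions: dict  # primer id -> fraction of total reads
    flagged: list  # primer ids with fraction > threshold
    dimer_reads: int = 0
    total_reads: int = 0


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _best_overlap(
    a: np.ndarray, b: np.ndarray, min_overlap: int, max_mismatch_fraction: float
):
    """Best admissible overlap placement of b (revcomp mate2) against a.

    Offsets s place b[0] at position s of a's coordinate system; all s with
    >= min_overlap overlapping positions are scored. Matches per offset come
    from four per-base cross-correlations (one C call each); positions where
    either base is N are excluded from both match and mismatch counts.
    Score = concordant matches; ties broken by longer overlap, then smaller
    (leftmost) offset. Returns (offset, overlap_len, n_mismatch) or None.
    """
    la, lb = len(a), len(b)
    match = np.zeros(la + lb - 1)
    for c in b"ACGT":
        match += np.correlate((a == c).astype(np.float64), (b == c).astype(np.float64), "full")
    comparable = np.correlate(
        (a != _ORD_N).astype(np.float64), (b != _ORD_N).astype(np.float64), "full"
    )
    match = np.rint(match)
    comparable = np.rint(comparable)
    s_all = np.arange(la + lb - 1) - (lb - 1)
    ov_all = np.minimum(la, s_all + lb) - np.maximum(0, s_all)
    mismatch = comparable - match
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(comparable > 0, mismatch / np.maximum(comparable, 1), 0.0)
    admissible = (ov_all >= min_overlap) & (frac <= max_mismatch_fraction)
    if not admissible.any():
        return None
    # lexicographic argmax: score, then overlap length, then leftmost offset
    tot = la + lb
    score = match * tot * tot + ov_all * tot + (lb - 1 - s_all)
    score[~admissible] = -1
    idx = int(np.argmax(score))
    s = int(s_all[idx])
    return s, int(ov_all[idx]), int(mismatch[idx])


def merge_pair(
    pair: ReadPair, min_overlap: int = 10, max_mismatch_fraction: float = 0.25
) -> MergedRead | None:
    """Merge one pair into a consensus read, or None if no admissible overlap.

    At overlap positions, concordant bases are kept, a discordant pair of
    called bases becomes N, and an N on one mate defers to the other mate's
    call. Non-overlapping overhangs are kept unmasked from whichever mate
    covers them.
    """
    a = _encode(pair.mate1)
    b = _encode(revcomp(pair.mate2))
    placement = _best_overlap(a, b, min_overlap, max_mismatch_fraction)
    if placement is None:
        return None
    s, ov, _ = placement
    lo = max(0, s)
    hi = min(len(a), s + len(b))
    out = []
    if s > 0:
        out.append(a[:s])
    elif s < 0:
        out.append(b[:-s])
    ov_a = a[lo:hi].copy()
    ov_b = b[lo - s : hi - s]
    discord = (ov_a != ov_b) & (ov_a != _ORD_N) & (ov_b != _ORD_N)
    a_is_n = ov_a == _ORD_N
    consensus = ov_a
    consensus[a_is_n] = ov_b[a_is_n]  # one-sided N defers to the called mate
    consensus[discord] = _ORD_N
    out.append(consensus)
    if s + len(b) > len(a):
        out.append(b[len(a) - s :])
    else:
        out.append(a[s + len(b) :])
    seq = np.concatenate([o for o in out if len(o)]).tobytes().decode()
    return MergedRead(
        id=pair.id, sequence=seq, overlap_length=ov, n_masked=int(discord.sum())
    )


def merge_pairs(
    pairs: Iterable[ReadPair],
    min_overlap: int = 10,
    max_mismatch_fraction: float = 0.25,
) -> MergeResult:
    """Merge a stream of read pairs; inadmissible pairs are kept as unmerged.

    Malformed records (constructed lazily from raw tuples) are counted and
    skipped with a log entry rather than aborting the stream.
    """
    result = MergeResult(merged=[], unmerged=[], stats=MergeStats())
    for item in pairs:
        try:
            pair = item if isinstance(item, ReadPair) else ReadPair(*item)
        except (ValueError, TypeError) as exc:
            result.stats.skipped += 1
            logger.warning("skipping malformed read record: %s", exc)
            continue
        merged = merge_pair(pair, min_overlap, max_mismatch_fraction)
        if merged is None:
            result.unmerged.append(pair)
            result.stats.unmerged += 1
        else:
            result.merged.append(merged)
            result.stats.merged += 1
            result.stats.masked_positions += merged.n_masked
    return result


def filter_short(reads: Sequence, min_length: int = 40) -> tuple[list, list]:
    """Split reads into (kept, discarded) by the minimum-length rule.

    Reads shorter than ``min_length`` (default 40 nt) are typically primer
    artefacts rather than genuine amplicon molecules. Accepts MergedRead
    objects or plain strings; conserves reads: |kept| + |discarded| = input.
    """
    kept, discarded = [], []
    for r in reads:
        seq = r.sequence if hasattr(r, "sequence") else r
        (kept if len(seq) >= min_length else discarded).append(r)
    return kept, discarded


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def scan_primer_dimers(
    discarded_reads: Sequence,
    panel: Panel,
    total_reads: int,
    max_mismatches: int = 2,
    flag_fraction: float = 0.20,
    min_partner_overlap: int = 4,
) -> DimerReport:
    """Attribute discarded short reads to primer-dimer products.

    A read is a dimer of primers (p, q) if it matches the concatenation
    p + revcomp(q) within ``max_mismatches`` mismatches (reads shorter than
    the concatenation are compared against its prefix but must extend at
    least ``min_partner_overlap`` nt into q to credit q). Each dimer read
    credits both contributing primers once; fractions are over total
    sequencing reads, and primers above ``flag_fraction`` are flagged for
    removal from the multiplex.
    """
    if len(panel.amplicons) == 0:
        raise ValueError("empty panel")
    primers: list[tuple[str, str]] = []
    for amp in panel:
        primers.append((f"{amp.id}_F", amp.fwd_primer))
        primers.append((f"{amp.id}_R", amp.rev_primer))
    credits = {name: 0 for name, _ in primers}
    dimer_reads = 0
    for r in discarded_reads:
        seq = r.sequence if hasattr(r, "sequence") else r
        best: tuple[int, str, str] | None = None
        for p_name, p_seq in primers:
            if len(seq) < len(p_seq) + min_partner_overlap:
                continue
            for q_name, q_seq in primers:
                concat = p_seq + revcomp(q_seq)
                if len(seq) > len(concat):
                    continue
                mism = _hamming(seq, concat[: len(seq)])
                if mism <= max_mismatches and (best is None or mism < best[0]):
                    best = (mism, p_name, q_name)
        if best is not None:
            dimer_reads += 1
            credits[best[1]] += 1
            if best[2] != best[1]:
                credits[best[2]] += 1
            else:
                credits[best[1]] += 0  # self-dimer credits the primer once
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    fractions = {name: c / total_reads for name, c in credits.items()}
    flagged = [name for name, frac in fractions.items() if frac > flag_fraction]
    return DimerReport(
        fractions=fractions,
        flagged=flagged,
        dimer_reads=dimer_reads,
        total_reads=total_reads,
    )


def merge_fastq(
    r1_path, r2_path, out_path=None, min_overlap: int = 10, max_mismatch_fraction: float = 0.25
) -> MergeResult:
    """Merge paired FASTQ files; optionally write the merged reads as FASTQ."""
    from .fastqio import read_fastq, write_fastq

    pairs = (
        ReadPair(id=n1, mate1=s1, mate2=s2)
        for (n1, s1), (_, s2) in zip(read_fastq(r1_path), read_fastq(r2_path))
    )
    result = merge_pairs(pairs, min_overlap, max_mismatch_fraction)
    if out_path is not None:
        write_fastq(((m.id, m.sequence) for m in result.merged), out_path)
    return result
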