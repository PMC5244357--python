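"""End-to-end glue: merged reads -> counts -> calls for a sample and its controls.

Thin plumbing over the readprep / readcount / stats modules so that
examples, the CLI and tests can run the whole caller in a few lines on
either in-memory simulated read sets or FASTQ files.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .panel import Panel
from .readcount import AmpliconCount, ControlCounts, assign_reads, count_variant_reads
from .readprep import MergeResult, ReadPair, merge_pairs
from .stats import CallParameters, DetectionResult, call_amplicon


def merge_read_set(read_set, min_overlap: int = 10, max_mismatch_fraction: float = 0.25) -> MergeResult:
    """Merge a simulated read set's pairs into consensus reads."""
    pairs = (ReadPair(id=n, mate1=r1, mate2=r2) for n, r1, r2 in read_set.pairs)
    return merge_pairs(pairs, min_overlap, max_mismatch_fraction)


def counts_for_read_set(read_set, panel: Panel) -> dict[str, AmpliconCount]:
    """Merge, assign and count one library; returns per-amplicon counts."""
    merged = merge_read_set(read_set).merged
    groups, _ = assign_reads(merged, panel)
    return {amp.id: count_variant_reads(groups[amp.id], amp) for amp in panel}


@dataclass
class SampleResults:
    counts: dict  # amplicon id -> AmpliconCount
    control_counts: dict  # amplicon id -> ControlCounts
    results: list  # DetectionResult per amplicon


def call_read_sets(
    panel: Panel,
    sample_read_set,
    control_read_sets: Sequence,
    params: CallParameters = CallParameters(),
) -> SampleResults:
    """Run the full caller on a simulated sample plus its negative controls."""
    counts = counts_for_read_set(sample_read_set, panel)
    per_control = [counts_for_read_set(c, panel) for c in control_read_sets]
    control_counts = {
        amp.id: ControlCounts(
            entries=[(pc[amp.id].variant_reads, pc[amp.id].depth) for pc in per_control]
        )
        for amp in panel
    }
    results = [call_amplicon(counts[amp.id], control_counts[amp.id], params) for amp in panel]
    return SampleResults(counts=counts, control_counts=control_counts, results=results)


def results_table(results: Sequence[DetectionResult]) -> pd.DataFrame:
    """Flat per-amplicon results for TSV/JSON export."""
    return pd.DataFrame(
        [
            {
                "amplicon_id": r.amplicon_id,
                "variant_reads": r.variant_reads,
                "depth": r.depth,
                "vaf": r.vaf,
                "p_value": r.p_value,
                "called": r.called,
                "status": r.status,
                "control_index": r.control_index,
            }
            for r in results
        ]
    )
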