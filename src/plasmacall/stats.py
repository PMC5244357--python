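"""Exact conditional Poisson rate-ratio testing and cutoff calibration.

The caller asks, per amplicon: is the rate of variant-supporting reads in
the plasma sample significantly higher than in the worst (highest-
proportion) same-run negative control? With counts k1 (sample) and k2
(control) over exposures n1 and n2 read depths, and both counts modelled as
Poisson, conditioning on the total m = k1 + k2 makes the sample count
Binomial(m, p0) with p0 = n1/(n1+n2) under a rate ratio of 1. The one-sided
p-value is the inclusive upper tail P(X >= k1 | m, p0).

Using the maximum-proportion control (rather than pooling the three
controls) is a deliberate guard against overdispersion: three controls are
too few to fit an overdispersed count model, but testing against the worst
of them bounds the background from above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .readcount import AmpliconCount, ControlCounts, Pileup, apply_depth_filter


@dataclass(frozen=True)
class CallParameters:
    """Operating parameters of the caller.

    alpha is the significance cutoff on the exact-test p-value (default
    0.01, the calibrated operating point); min_depth is the evaluability
    gate (default 1000X); n_controls_required bounds how many same-run
    controls must be present.
    """

    alpha: float = 0.01
    min_depth: int = 1000
    n_controls_required: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_depth < 0:
            raise ValueError("min_depth must be non-negative")
        if not 1 <= self.n_controls_required <= 3:
            raise ValueError("n_controls_required must be in [1, 3]")


@dataclass
class DetectionResult:
    """Per-amplicon outcome: p-value, call status and the control used."""

    amplicon_id: str
    p_value: float | None
    called: bool
    vaf: float
    status: str  # "evaluable" | "not_called"
    control_index: int | None = None
    variant_reads: int = 0
    depth: int = 0

    def __post_init__(self) -> None:
        if self.status == "not_called" and self.p_value is not None:
            raise ValueError("not_called results carry no p-value")
        if self.called and self.status != "evaluable":
            raise ValueError("called results must be evaluable")


def poisson_rate_ratio_test(k1: int, n1: float, k2: int, n2: float) -> float:
    """One-tailed exact conditional test that rate k1/n1 exceeds k2/n2.

    Conditional on m = k1 + k2 the sample count is Binomial(m, p0) with
    p0 = n1/(n1+n2) under the null; returns the inclusive upper tail
    P(X >= k1 | m, p0). Evaluated through the regularised incomplete beta
    (scipy's binomial survival function), stable for m well beyond 1e6.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("exposures must be positive")
    if k1 < 0 or k2 < 0:
        raise ValueError("counts must be non-negative")
    if k1 > n1 or k2 > n2:
        raise ValueError("count exceeds exposure")
    if k1 == 0:
        return 1.0
    m = k1 + k2
    p0 = n1 / (n1 + n2)
    return float(_sps.binom.sf(k1 - 1, m, p0))


def select_reference_control(controls: ControlCounts) -> tuple[int, int, int]:
    """The control with the highest variant-read proportion.

    Returns (k2, n2, index). Ties on proportion are broken by the smallest
    depth — the more conservative exposure, since a smaller n2 gives a
    larger p0 and hence larger p-values.
    """
    best = None
    for i, (k, n) in enumerate(controls):
        if n <= 0:
            continue
        key = (-(k / n), n, i)
        if best is None or key < best[0]:
            best = (key, (k, n, i))
    if best is None:
        raise ValueError("all controls have zero depth")
    return best[1]


def call_amplicon(
    count: AmpliconCount,
    controls: ControlCounts,
    params: CallParameters = CallParameters(),
) -> DetectionResult:
    """Call one amplicon: depth gate, then exact test against the worst control.

    Below ``min_depth`` the amplicon is ``not_called`` (no p-value); above
    it, the variant is called iff the exact conditional p-value against the
    maximum-proportion control is strictly below alpha.
    """
    if len(controls) < params.n_controls_required:
        raise ValueError(
            f"{len(controls)} controls present, {params.n_controls_required} required"
        )
    if apply_depth_filter(count, params.min_depth) == "not_called":
        return DetectionResult(
            amplicon_id=count.amplicon_id,
            p_value=None,
            called=False,
            vaf=count.vaf,
            status="not_called",
            variant_reads=count.variant_reads,
            depth=count.depth,
        )
    k2, n2, idx = select_reference_control(controls)
    p = poisson_rate_ratio_test(count.variant_reads, count.depth, k2, n2)
    return DetectionResult(
        amplicon_id=count.amplicon_id,
        p_value=p,
        called=p < params.alpha,
        vaf=count.vaf,
        status="evaluable",
        control_index=idx,
        variant_reads=count.variant_reads,
        depth=count.depth,
    )


# ---------------------------------------------------------------------------
# per-base noise filtering


@dataclass
class NoiseFilterResult:
    filtered: Pileup
    pre_mean_rate: float
    post_mean_rate: float
    n_tested: int
    n_retained: int


def base_noise_filter(
    sample_pileup: Pileup,
    control_pileups: Sequence[Pileup],
    params: CallParameters = CallParameters(),
) -> NoiseFilterResult:
    """Zero out per-base non-reference calls indistinguishable from noise.

    At every insert position and every non-reference base, the sample count
    is tested against the same base's count in the control with the highest
    proportion at that position; the call set is retained iff p < alpha.
    Positions absent (uncovered) in all controls are tested against count 0
    at the smallest control depth observed anywhere, and logged.

    Returns a filtered copy of the pileup plus the pre/post mean
    non-reference rates — on synthetic data this reproduces the
    raw -> merged -> noise-filtered error-rate cascade.
    """
    import logging

    logger = logging.getLogger(__name__)
    if any(len(c.ref_insert) != len(sample_pileup.ref_insert) for c in control_pileups):
        raise ValueError("control pileups must cover the same positions as the sample")
    filtered = Pileup(
        amplicon_id=sample_pileup.amplicon_id,
        chrom=sample_pileup.chrom,
        insert_start=sample_pileup.insert_start,
        ref_insert=sample_pileup.ref_insert,
        base_counts=sample_pileup.base_counts.copy(),
        del_counts=sample_pileup.del_counts.copy(),
        ins_counts=sample_pileup.ins_counts.copy(),
    )
    nonref_pre, total_pre = sample_pileup.nonref_counts()
    ctl_totals = [c.base_counts[:4].sum(axis=0) + c.del_counts for c in control_pileups]
    covered = [t[t > 0] for t in ctl_totals if (t > 0).any()]
    # smallest observed control depth; with no control coverage at all, fall
    # back to the sample's own depth (0 events over an equal exposure)
    fallback_depth = int(np.concatenate(covered).min()) if covered else None
    n_tested = 0
    n_retained = 0
    rows = {b: i for i, b in enumerate("ACGT")}
    for j, ref_base in enumerate(sample_pileup.ref_insert):
        n1 = int(sample_pileup.base_counts[:4, j].sum() + sample_pileup.del_counts[j])
        if n1 == 0:
            continue
        for base, i in rows.items():
            if base == ref_base:
                continue
            k1 = int(sample_pileup.base_counts[i, j])
            if k1 == 0:
                continue
            n_tested += 1
            best = None
            for c, tot in zip(control_pileups, ctl_totals):
                n2 = int(tot[j])
                if n2 == 0:
                    continue
                k2 = int(c.base_counts[i, j])
                key = (-(k2 / n2), n2)
                if best is None or key < best[0]:
                    best = (key, (k2, n2))
            if best is None:
                k2, n2 = 0, fallback_depth if fallback_depth is not None else n1
                logger.info(
                    "position %s:%d uncovered in controls; using 0/%d",
                    sample_pileup.chrom,
                    sample_pileup.insert_start + j + 1,
                    n2,
                )
            else:
                k2, n2 = best[1]
            p = poisson_rate_ratio_test(k1, n1, k2, n2)
            if p < params.alpha:
                n_retained += 1
            else:
                filtered.base_counts[i, j] = 0
    nonref_post, total_post = filtered.nonref_counts()
    pre = _mean_rate(nonref_pre, total_pre)
    post = _mean_rate(nonref_post, total_post)
    return NoiseFilterResult(
        filtered=filtered,
        pre_mean_rate=pre,
        post_mean_rate=post,
        n_tested=n_tested,
        n_retained=n_retained,
    )


def _mean_rate(nonref: np.ndarray, total: np.ndarray) -> float:
    cov = total > 0
    if not cov.any():
        return float("nan")
    return float((nonref[cov] / total[cov]).mean())


def simulate_null_false_call_rate(
    n_replicates: int = 10000,
    depth: int = 5000,
    error_rate: float = 1e-3,
    n_controls: int = 3,
    params: CallParameters = CallParameters(),
    seed: int = 0,
) -> float:
    """Empirical false-call rate of the caller under the null.

    Simulates replicate amplicons in which the plasma sample and all
    controls draw variant-supporting reads from the same per-base error
    rate at equal depth, runs the full caller (max-proportion control
    selection + exact conditional test) and returns the fraction of
    evaluable amplicons called. Exact conditional tests are conservative,
    so this should come out at or below alpha.
    """
    rng = np.random.default_rng(seed)
    draws = rng.binomial(depth, error_rate, size=(n_replicates, 1 + n_controls))
    called = 0
    evaluable = 0
    for row in draws:
        count = AmpliconCount(
            amplicon_id="null",
            variant_reads=int(row[0]),
            depth=depth,
            reference_reads=depth - int(row[0]),
        )
        controls = ControlCounts(entries=[(int(k), depth) for k in row[1:]])
        result = call_amplicon(count, controls, params)
        if result.status == "evaluable":
            evaluable += 1
            called += result.called
    if evaluable == 0:
        raise ValueError("no evaluable replicates")
    return called / evaluable


# ---------------------------------------------------------------------------
# significance-cutoff calibration


@dataclass
class RocCurve:
    """Threshold sweep over observed p-values with accuracy bookkeeping."""

    table: pd.DataFrame  # threshold, tp, fp, tn, fn, accuracy
    max_accuracy_threshold: float
    next_threshold: float | None
    recommended_cutoff: float


def calibrate_cutoff(labelled: Sequence[tuple[float, bool]]) -> RocCurve:
    """ROC-style sweep to choose an operating significance cutoff.

    ``labelled`` pairs each amplicon's exact-test p-value with its truth
    label (True = expected positive). Candidate thresholds are the distinct
    observed p-values; at threshold t an amplicon is called iff p < t.
    Reports accuracy per threshold, the first maximum-accuracy threshold,
    the next larger candidate, and a recommended cutoff at their geometric
    midpoint — the operating default remains user-controlled (0.01).
    """
    labelled = list(labelled)
    if not labelled:
        raise ValueError("no labelled p-values")
    labels = {lab for _, lab in labelled}
    if labels != {True, False}:
        raise ValueError("need at least one positive and one negative label")
    ps = np.array([p for p, _ in labelled], dtype=float)
    truth = np.array([bool(t) for _, t in labelled])
    thresholds = np.unique(ps)
    rows = []
    for t in thresholds:
        called = ps < t
        tp = int((called & truth).sum())
        fp = int((called & ~truth).sum())
        fn = int((~called & truth).sum())
        tn = int((~called & ~truth).sum())
        rows.append(
            {
                "threshold": t,
                "tp": tp,
                "fp": fp,
                "tn": tn,
                "fn": fn,
                "accuracy": (tp + tn) / len(labelled),
            }
        )
    table = pd.DataFrame(rows)
    best_i = int(table["accuracy"].idxmax())  # first maximum
    best_t = float(table.loc[best_i, "threshold"])
    if best_i + 1 < len(table):
        next_t = float(table.loc[best_i + 1, "threshold"])
        recommended = float(np.sqrt(best_t * next_t))
    else:
        next_t = None
        recommended = best_t
    return RocCurve(
        table=table,
        max_accuracy_threshold=best_t,
        next_threshold=next_t,
        recommended_cutoff=recommended,
    )
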