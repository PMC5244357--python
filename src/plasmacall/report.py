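"""Sample-level calling, dilution linearity, detection curves and cohort metrics.

A plasma sample is positive when at least one of its evaluable amplicons is
called; its reported ctDNA fraction is by default the maximum VAF among
called amplicons ("ND" — not detected — when negative). The dilution
analysis quantifies assay linearity (per-amplicon Pearson correlation of
expected vs observed frequency across a serial dilution) and the
template-bottleneck detection curve, and cohort metrics summarise
sensitivity/specificity with exact binomial confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.proportion import proportion_confint

from .panel import Panel
from .stats import DetectionResult
from .synthdata import expected_detection_probability


@dataclass
class SampleCall:
    """Sample-level outcome aggregated over amplicons."""

    sample_id: str
    timepoint: float | None
    results: list  # DetectionResult
    status: str  # "evaluable" | "unevaluable"
    positive: bool
    ctdna_fraction: float | None  # None <=> "ND"
    origin_fractions: dict = field(default_factory=dict)

    @property
    def fraction_display(self) -> str:
        return "ND" if self.ctdna_fraction is None else f"{self.ctdna_fraction:.4g}"


def panel_sensitivity(per_amplicon_rate: float, n_amplicons: int) -> float:
    """Panel-level detection probability from a per-amplicon rate.

    Assuming independent detection across amplicons, a panel of n amplicons
    each detected with probability r misses only with probability (1-r)^n;
    e.g. 10 amplicons at r = 0.76 give >99.99% panel sensitivity.
    """
    if not 0.0 <= per_amplicon_rate <= 1.0:
        raise ValueError("per-amplicon rate must be in [0, 1]")
    if n_amplicons < 1:
        raise ValueError("n_amplicons must be >= 1")
    return float(-np.expm1(n_amplicons * np.log1p(-per_amplicon_rate)))


def call_sample(
    results: Sequence[DetectionResult],
    sample_id: str = "",
    timepoint: float | None = None,
    fraction_rule: str = "max",
    panel: Panel | None = None,
) -> SampleCall:
    """Aggregate per-amplicon results into a sample call.

    Positive iff any evaluable amplicon is called. The sample ctDNA fraction
    is the ``max`` (default) or ``mean`` of called-amplicon VAFs; negative
    samples report None, displayed as "ND". With a panel supplied, fractions
    are additionally broken down by the variants' origin labels (e.g.
    primary vs second-primary tumours).
    """
    if not results:
        raise ValueError("no amplicon results")
    if fraction_rule not in ("max", "mean"):
        raise ValueError(f"unknown fraction_rule {fraction_rule!r}")
    evaluable = [r for r in results if r.status == "evaluable"]
    if not evaluable:
        return SampleCall(
            sample_id=sample_id,
            timepoint=timepoint,
            results=list(results),
            status="unevaluable",
            positive=False,
            ctdna_fraction=None,
        )
    called = [r for r in evaluable if r.called]
    agg = max if fraction_rule == "max" else (lambda v: sum(v) / len(v))
    fraction = agg([r.vaf for r in called]) if called else None
    origin_fractions: dict[str, float | None] = {}
    if panel is not None:
        by_label: dict[str, list] = {}
        for r in evaluable:
            label = panel.get(r.amplicon_id).variant.origin_label
            by_label.setdefault(label, []).append(r)
        for label, rs in by_label.items():
            called_l = [r.vaf for r in rs if r.called]
            origin_fractions[label] = agg(called_l) if called_l else None
    return SampleCall(
        sample_id=sample_id,
        timepoint=timepoint,
        results=list(results),
        status="evaluable",
        positive=bool(called),
        ctdna_fraction=fraction,
        origin_fractions=origin_fractions,
    )


# ---------------------------------------------------------------------------
# dilution linearity


@dataclass
class DilutionResult:
    per_amplicon: pd.DataFrame  # amplicon_id, r, n_points, passes
    fraction_above_threshold: float
    aggregate_r2: float
    slope: float
    n_amplicons: int
    n_excluded_depth: int


def dilution_linearity(
    table: pd.DataFrame,
    min_depth: int = 1000,
    r_threshold: float = 0.95,
) -> DilutionResult:
    """Linearity of observed vs expected frequency over a dilution series.

    ``table`` needs columns amplicon_id, ratio, expected_frequency,
    variant_reads, depth. Amplicons failing the ``min_depth`` filter at any
    point of the series are excluded entirely; survivors need >=3 points.
    Per amplicon the Pearson correlation of expected vs observed VAF is
    computed; a constant observed series has no defined correlation and is
    reported as NA but still counts against the >r_threshold fraction (so
    flat, undetectable amplicons cannot inflate the linearity claim).
    The aggregate r^2 and regression slope pool all retained points.
    """
    required = {"amplicon_id", "ratio", "expected_frequency", "variant_reads", "depth"}
    if missing := required - set(table.columns):
        raise ValueError(f"dilution table missing columns {sorted(missing)}")
    work = table.copy()
    work["observed"] = work["variant_reads"] / work["depth"].where(work["depth"] > 0)
    depth_ok = work.groupby("amplicon_id")["depth"].transform("min") >= min_depth
    n_excluded = work.loc[~depth_ok, "amplicon_id"].nunique()
    work = work[depth_ok]
    rows = []
    for amp_id, grp in work.groupby("amplicon_id"):
        if len(grp) < 3:
            continue
        x = grp["expected_frequency"].to_numpy(float)
        y = grp["observed"].to_numpy(float)
        if np.ptp(y) == 0 or np.ptp(x) == 0:
            r = np.nan
        else:
            r = float(_sps.pearsonr(x, y)[0])
        rows.append(
            {
                "amplicon_id": amp_id,
                "r": r,
                "n_points": len(grp),
                "passes": bool(r > r_threshold) if np.isfinite(r) else False,
            }
        )
    per_amp = pd.DataFrame(rows, columns=["amplicon_id", "r", "n_points", "passes"])
    if per_amp.empty:
        raise ValueError("no amplicon passes the depth filter with >=3 dilution points")
    x_all = work["expected_frequency"].to_numpy(float)
    y_all = work["observed"].to_numpy(float)
    slope, intercept = np.polyfit(x_all, y_all, 1)
    r_all = float(np.corrcoef(x_all, y_all)[0, 1])
    return DilutionResult(
        per_amplicon=per_amp,
        fraction_above_threshold=float(per_amp["passes"].mean()),
        aggregate_r2=r_all**2,
        slope=float(slope),
        n_amplicons=len(per_amp),
        n_excluded_depth=int(n_excluded),
    )


# ---------------------------------------------------------------------------
# detection-by-frequency binning


def detection_by_frequency_bins(
    results: pd.DataFrame,
    bin_edges: Sequence[float],
    genome_equivalents: int = 3000,
) -> pd.DataFrame:
    """Observed detection proportion per expected-frequency bin, with the
    template-sampling expectation band.

    ``results`` needs columns expected_frequency, detected (bool) and
    optionally status (not_called rows are dropped). The band per bin is
    [1-(1-f_min)^G, 1-(1-f_max)^G] over the member frequencies actually in
    the bin — the probability that at least one mutant template is sampled
    among G genome equivalents. Cumulative detection proportions at-or-above
    and below each bin's lower edge are included.
    """
    work = results.copy()
    if "status" in work.columns:
        work = work[work["status"] == "evaluable"]
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be increasing with >= 2 entries")
    f = work["expected_frequency"].to_numpy(float)
    det = work["detected"].to_numpy(bool)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (f >= lo) & (f < hi)
        n = int(in_bin.sum())
        if n == 0:
            rows.append(
                {
                    "bin_low": lo,
                    "bin_high": hi,
                    "n": 0,
                    "detected_fraction": np.nan,
                    "band_low": np.nan,
                    "band_high": np.nan,
                    "cum_at_or_above": np.nan,
                    "cum_below": np.nan,
                }
            )
            continue
        fmin, fmax = f[in_bin].min(), f[in_bin].max()
        above = f >= lo
        below = f < lo
        rows.append(
            {
                "bin_low": lo,
                "bin_high": hi,
                "n": n,
                "detected_fraction": float(det[in_bin].mean()),
                "band_low": expected_detection_probability(fmin, genome_equivalents),
                "band_high": expected_detection_probability(fmax, genome_equivalents),
                "cum_at_or_above": float(det[above].mean()) if above.any() else np.nan,
                "cum_below": float(det[below].mean()) if below.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort sensitivity / specificity


def _rate_ci(successes: int, total: int) -> tuple[float, float, float]:
    if total == 0:
        return (np.nan, np.nan, np.nan)
    lo, hi = proportion_confint(successes, total, alpha=0.05, method="beta")
    return (successes / total, float(lo), float(hi))


def cohort_metrics(calls: pd.DataFrame) -> dict:
    """Sensitivity and specificity at amplicon and sample granularity.

    ``calls`` needs columns sample_id, amplicon_id, expected_positive,
    called, status. not_called amplicons are excluded from denominators. A
    sample is expected-positive if any of its amplicons is, and called if
    any evaluable amplicon is called; samples with no evaluable amplicon are
    excluded. Confidence intervals are exact (Clopper-Pearson) at 95%.
    """
    required = {"sample_id", "amplicon_id", "expected_positive", "called", "status"}
    if missing := required - set(calls.columns):
        raise ValueError(f"calls table missing columns {sorted(missing)}")
    ev = calls[calls["status"] == "evaluable"]
    out: dict = {}
    pos = ev[ev["expected_positive"].astype(bool)]
    neg = ev[~ev["expected_positive"].astype(bool)]
    tp = int(pos["called"].sum())
    tn = int((~neg["called"].astype(bool)).sum())
    sens, sens_lo, sens_hi = _rate_ci(tp, len(pos))
    spec, spec_lo, spec_hi = _rate_ci(tn, len(neg))
    out["amplicon"] = {
        "sensitivity": sens,
        "sensitivity_ci": (sens_lo, sens_hi),
        "specificity": spec,
        "specificity_ci": (spec_lo, spec_hi),
        "tp": tp,
        "fn": len(pos) - tp,
        "tn": tn,
        "fp": len(neg) - tn,
    }
    by_sample = ev.groupby("sample_id").agg(
        expected=("expected_positive", "any"), called=("called", "any")
    )
    s_pos = by_sample[by_sample["expected"]]
    s_neg = by_sample[~by_sample["expected"]]
    s_tp = int(s_pos["called"].sum())
    s_tn = int((~s_neg["called"]).sum())
    sens, sens_lo, sens_hi = _rate_ci(s_tp, len(s_pos))
    spec, spec_lo, spec_hi = _rate_ci(s_tn, len(s_neg))
    out["sample"] = {
        "sensitivity": sens,
        "sensitivity_ci": (sens_lo, sens_hi),
        "specificity": spec,
        "specificity_ci": (spec_lo, spec_hi),
        "tp": s_tp,
        "fn": len(s_pos) - s_tp,
        "tn": s_tn,
        "fp": len(s_neg) - s_tn,
    }
    return out


# ---------------------------------------------------------------------------
# longitudinal reporting


def longitudinal_report(
    sample_calls: Sequence[SampleCall],
    events: Mapping[str, float] | None = None,
    external_columns: Mapping[str, Mapping[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-patient time series of detection status and ctDNA fraction.

    ``sample_calls`` carry timepoints in days relative to surgery; ``events``
    optionally maps sample (patient) id to a clinical event day, and the
    lead time is the gap between the first positive sample and that event.
    ``external_columns`` (e.g. a serum-marker series) are passed through by
    timepoint without interpretation. Duplicate timepoints are flagged.
    """
    rows = []
    by_patient: dict[str, list] = {}
    for sc in sample_calls:
        by_patient.setdefault(sc.sample_id, []).append(sc)
    for patient, calls in by_patient.items():
        calls = sorted(calls, key=lambda c: (c.timepoint is None, c.timepoint))
        seen: set = set()
        first_positive = None
        for sc in calls:
            dup = sc.timepoint in seen
            if dup:
                warnings.warn(f"duplicate timepoint {sc.timepoint} for {patient}")
            seen.add(sc.timepoint)
            if sc.positive and first_positive is None:
                first_positive = sc.timepoint
            row = {
                "sample_id": patient,
                "timepoint": sc.timepoint,
                "status": sc.status,
                "positive": sc.positive,
                "ctdna_fraction": sc.fraction_display,
                "duplicate_timepoint": dup,
            }
            for label, frac in sc.origin_fractions.items():
                row[f"fraction_{label or 'unlabelled'}"] = (
                    "ND" if frac is None else f"{frac:.4g}"
                )
            if external_columns:
                for name, series in external_columns.items():
                    row[name] = series.get(sc.timepoint, np.nan)
            rows.append(row)
        if events and patient in events:
            event_day = events[patient]
            lead = event_day - first_positive if first_positive is not None else np.nan
            for row in rows:
                if row["sample_id"] == patient:
                    row["event_day"] = event_day
                    row["lead_time_days"] = lead
    return pd.DataFrame(rows)
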