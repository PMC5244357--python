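"""Sample-level calls, dilution linearity, detection curves, cohort metrics
and longitudinal reporting."""

import numpy as np
import pandas as pd
import pytest

from plasmacall import (
    DetectionResult,
    call_sample,
    cohort_metrics,
    detection_by_frequency_bins,
    dilution_linearity,
    longitudinal_report,
    make_panel,
    panel_sensitivity,
)
from plasmacall.synthdata import sample_mutant_templates


def _result(amp="A1", p=0.5, called=False, vaf=0.0, status="evaluable"):
    return DetectionResult(
        amplicon_id=amp,
        p_value=None if status == "not_called" else p,
        called=called,
        vaf=vaf,
        status=status,
    )


class TestCallSample:
    def test_no_call_is_negative_nd(self):
        sc = call_sample([_result("A1"), _result("A2")], sample_id="s")
        assert not sc.positive
        assert sc.ctdna_fraction is None
        assert sc.fraction_display == "ND"

    def test_single_call_reports_its_vaf(self):
        sc = call_sample([_result("A1", p=1e-4, called=True, vaf=0.0022), _result("A2")])
        assert sc.positive
        assert sc.ctdna_fraction == pytest.approx(0.0022)

    def test_max_rule_over_called_amplicons(self):
        results = [
            _result("A1", p=1e-3, called=True, vaf=0.004),
            _result("A2", p=1e-5, called=True, vaf=0.011),
            _result("A3", vaf=0.5),  # not called: excluded from the fraction
        ]
        assert call_sample(results).ctdna_fraction == pytest.approx(0.011)
        assert call_sample(results, fraction_rule="mean").ctdna_fraction == pytest.approx(0.0075)

    def test_all_not_called_is_unevaluable(self):
        sc = call_sample([_result(status="not_called")])
        assert sc.status == "unevaluable"
        assert not sc.positive

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            call_sample([])

    def test_positivity_is_monotone_in_calls(self):
        base = [_result("A1", p=1e-4, called=True, vaf=0.01)]
        extra = base + [_result("A2", p=1e-6, called=True, vaf=0.002)]
        assert call_sample(base).positive
        assert call_sample(extra).positive

    def test_origin_label_breakdown_is_partitioned(self):
        panel, _ = make_panel(4, seed=157)
        # relabel: two amplicons from the primary, two from a second primary
        import dataclasses

        amps = []
        for i, a in enumerate(panel.amplicons):
            v = dataclasses.replace(a.variant, origin_label="primary" if i < 2 else "second")
            amps.append(dataclasses.replace(a, variant=v))
        panel = dataclasses.replace(panel, amplicons=amps)
        results = [
            _result(amps[0].id, p=1e-4, called=True, vaf=0.02),
            _result(amps[1].id),
            _result(amps[2].id),
            _result(amps[3].id),
        ]
        sc = call_sample(results, panel=panel)
        assert sc.origin_fractions["primary"] == pytest.approx(0.02)
        assert sc.origin_fractions["second"] is None


class TestPanelSensitivity:
    def test_independent_combination(self):
        assert panel_sensitivity(0.76, 10) == pytest.approx(1 - 0.24**10, rel=1e-12)

    def test_single_amplicon_is_identity(self):
        assert panel_sensitivity(0.3, 1) == pytest.approx(0.3)


def _dilution_table(expected_map, observed_fn, depth=5000):
    rows = []
    for amp, efs in expected_map.items():
        for ef in efs:
            obs = observed_fn(ef)
            rows.append(
                {
                    "amplicon_id": amp,
                    "ratio": 1 / ef if ef else 0,
                    "expected_frequency": ef,
                    "variant_reads": int(round(obs * depth)),
                    "depth": depth,
                }
            )
    return pd.DataFrame(rows)


class TestDilutionLinearity:
    EFS = [0.01 / 2**i for i in range(9)]

    def test_identity_series_is_perfectly_linear(self):
        table = _dilution_table({"A": self.EFS, "B": self.EFS}, lambda f: f, depth=10**6)
        res = dilution_linearity(table)
        assert res.fraction_above_threshold == 1.0
        assert res.aggregate_r2 == pytest.approx(1.0, abs=1e-6)

    def test_scaling_preserves_correlation_not_identity(self):
        table = _dilution_table({"A": self.EFS}, lambda f: 2 * f, depth=10**6)
        res = dilution_linearity(table)
        assert res.per_amplicon["r"].iloc[0] == pytest.approx(1.0, abs=1e-6)
        assert res.slope == pytest.approx(2.0, rel=0.01)

    def test_constant_observed_counts_against_threshold(self):
        table = pd.concat(
            [
                _dilution_table({"A": self.EFS}, lambda f: f, depth=10**6),
                _dilution_table({"B": self.EFS}, lambda f: 0.0),
            ]
        )
        res = dilution_linearity(table)
        b = res.per_amplicon.set_index("amplicon_id").loc["B"]
        assert np.isnan(b["r"])
        assert not b["passes"]
        assert res.fraction_above_threshold == pytest.approx(0.5)

    def test_depth_failure_excludes_whole_amplicon(self):
        table = _dilution_table({"A": self.EFS, "B": self.EFS}, lambda f: f)
        table.loc[(table.amplicon_id == "B") & (table.expected_frequency < 1e-3), "depth"] = 500
        res = dilution_linearity(table)
        assert res.n_amplicons == 1
        assert res.n_excluded_depth == 1

    def test_all_amplicons_below_depth_rejected(self):
        table = _dilution_table({"A": self.EFS}, lambda f: f, depth=100)
        with pytest.raises(ValueError):
            dilution_linearity(table)


class TestDetectionBins:
    def test_band_edges_from_bin_members(self):
        df = pd.DataFrame(
            {
                "expected_frequency": [0.001, 0.005, 0.01, 0.02],
                "detected": [True, True, True, True],
                "status": ["evaluable"] * 4,
            }
        )
        out = detection_by_frequency_bins(df, [0.001, 0.01, 0.1], genome_equivalents=3000)
        assert out.loc[0, "band_low"] == pytest.approx(0.9503, abs=1e-3)
        assert out.loc[0, "n"] == 2

    def test_zero_frequency_gives_zero_band(self):
        df = pd.DataFrame(
            {"expected_frequency": [0.0], "detected": [False], "status": ["evaluable"]}
        )
        out = detection_by_frequency_bins(df, [0.0, 0.1])
        assert out.loc[0, "band_low"] == 0.0

    def test_empty_bin_is_na(self):
        df = pd.DataFrame(
            {"expected_frequency": [0.5], "detected": [True], "status": ["evaluable"]}
        )
        out = detection_by_frequency_bins(df, [0.0, 0.1, 1.0])
        assert np.isnan(out.loc[0, "detected_fraction"])

    def test_template_limited_detection_matches_closed_form(self):
        # deep sequencing of G=3000 templates at f=0.1%: detection is
        # limited by template sampling, ~95%
        counts = sample_mutant_templates(1e-3, 3000, 10000, seed=163)
        df = pd.DataFrame(
            {
                "expected_frequency": np.full(10000, 1e-3),
                "detected": counts > 0,
                "status": ["evaluable"] * 10000,
            }
        )
        out = detection_by_frequency_bins(df, [5e-4, 5e-3], genome_equivalents=3000)
        assert out.loc[0, "detected_fraction"] == pytest.approx(0.9503, abs=0.01)
        assert out.loc[0, "band_low"] <= out.loc[0, "detected_fraction"] <= out.loc[0, "band_high"] + 0.01


class TestCohortMetrics:
    def _table(self, tp, fn, tn, fp):
        rows = []
        i = 0
        for called, expected, n in [(True, True, tp), (False, True, fn), (False, False, tn), (True, False, fp)]:
            for _ in range(n):
                rows.append(
                    {
                        "sample_id": f"s{i}",
                        "amplicon_id": f"a{i}",
                        "expected_positive": expected,
                        "called": called,
                        "status": "evaluable",
                    }
                )
                i += 1
        return pd.DataFrame(rows)

    def test_published_style_rates(self):
        # 32 of 48 expected positives detected; 1 of 554 negatives called
        m = cohort_metrics(self._table(tp=32, fn=16, tn=553, fp=1))
        assert m["amplicon"]["sensitivity"] == pytest.approx(32 / 48, abs=1e-9)
        assert m["amplicon"]["specificity"] == pytest.approx(553 / 554, abs=1e-9)
        assert m["amplicon"]["specificity"] > 0.99

    def test_perfect_calls(self):
        m = cohort_metrics(self._table(tp=5, fn=0, tn=5, fp=0))
        assert m["amplicon"]["sensitivity"] == 1.0
        assert m["amplicon"]["specificity"] == 1.0

    def test_not_called_excluded_from_denominators(self):
        df = self._table(tp=3, fn=1, tn=4, fp=0)
        extra = df.iloc[[0]].assign(status="not_called", amplicon_id="x", sample_id="sx")
        m = cohort_metrics(pd.concat([df, extra]))
        assert m["amplicon"]["tp"] + m["amplicon"]["fn"] == 4

    def test_sample_level_any_rule(self):
        rows = [
            {"sample_id": "p1", "amplicon_id": "a", "expected_positive": True, "called": False, "status": "evaluable"},
            {"sample_id": "p1", "amplicon_id": "b", "expected_positive": True, "called": True, "status": "evaluable"},
            {"sample_id": "p2", "amplicon_id": "c", "expected_positive": False, "called": False, "status": "evaluable"},
        ]
        m = cohort_metrics(pd.DataFrame(rows))
        assert m["sample"]["sensitivity"] == 1.0
        assert m["sample"]["specificity"] == 1.0

    def test_zero_denominator_is_na(self):
        m = cohort_metrics(self._table(tp=2, fn=0, tn=0, fp=0))
        assert np.isnan(m["amplicon"]["specificity"])


class TestLongitudinal:
    def _call(self, sample_id, timepoint, positive, fraction=None):
        from plasmacall.report import SampleCall

        return SampleCall(
            sample_id=sample_id,
            timepoint=timepoint,
            results=[],
            status="evaluable",
            positive=positive,
            ctdna_fraction=fraction,
        )

    def test_single_negative_timepoint(self):
        df = longitudinal_report([self._call("p1", 30, False)])
        assert len(df) == 1
        assert df.loc[0, "ctdna_fraction"] == "ND"

    def test_lead_time_to_event(self):
        calls = [
            self._call("p1", -400, False),
            self._call("p1", -255, True, 0.003),
            self._call("p1", -100, True, 0.01),
        ]
        df = longitudinal_report(calls, events={"p1": 0})
        assert (df["lead_time_days"] == 255).all()

    def test_duplicate_timepoints_flagged(self):
        calls = [self._call("p1", 10, False), self._call("p1", 10, False)]
        with pytest.warns(UserWarning):
            df = longitudinal_report(calls)
        assert df["duplicate_timepoint"].sum() == 1

    def test_external_column_passthrough(self):
        df = longitudinal_report(
            [self._call("p1", 5, True, 0.01)],
            external_columns={"cea_ng_ml": {5: 7.2}},
        )
        assert df.loc[0, "cea_ng_ml"] == pytest.approx(7.2)
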