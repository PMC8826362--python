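"""Scale reversal and copy-mean imputation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qolnet.cohort import ScaleDefinition
from qolnet.preprocess import (
    ReversalRule,
    impute_copy_mean,
    missing_summary,
    reverse_scales,
)

from conftest import make_table


class TestReversal:
    def test_reflects_about_pivot(self):
        tab = make_table({"depression": {("A", "M0"): 0.0, ("A", "M12"): 39.0}},
                         [ScaleDefinition("depression", "continuous", (0, 39),
                                          direction="higher-is-worse")])
        out = reverse_scales(tab, [ReversalRule("depression", 39.0)])
        assert out.data.loc[("A", "M0"), "depression"] == 39.0
        assert out.data.loc[("A", "M12"), "depression"] == 0.0
        assert out.scale_defs["depression"].direction == "higher-is-better"

    def test_symptom_score_example(self):
        tab = make_table({"pain": {("A", "M0"): 16.67}})
        out = reverse_scales(tab, [ReversalRule("pain", 100.0)])
        assert out.data.loc[("A", "M0"), "pain"] == pytest.approx(83.33)

    def test_double_application_is_identity(self, small_cohort):
        rules = [ReversalRule("fatigue", 100.0)]
        twice = reverse_scales(reverse_scales(small_cohort, rules), rules)
        pd.testing.assert_frame_equal(twice.data, small_cohort.data)

    def test_missing_cells_stay_missing(self):
        tab = make_table({"pain": {("A", "M0"): 10.0, ("A", "M12"): np.nan}})
        out = reverse_scales(tab, [ReversalRule("pain", 100.0)])
        assert np.isnan(out.data.loc[("A", "M12"), "pain"])

    def test_unknown_scale_raises(self, small_cohort):
        with pytest.raises(ValueError, match="unknown scale"):
            reverse_scales(small_cohort, [ReversalRule("nope", 100.0)])

    def test_reversal_flips_spearman_sign_not_magnitude(self):
        rng = np.random.default_rng(0)
        x = rng.normal(50, 10, 40)
        y = x + rng.normal(0, 5, 40)
        vals = {
            "x": {(f"S{i}", "M0"): x[i] for i in range(40)},
            "y": {(f"S{i}", "M0"): y[i] for i in range(40)},
        }
        tab = make_table(vals, timepoints=("M0",))
        out = reverse_scales(tab, [ReversalRule("y", 100.0)])
        r0 = stats.spearmanr(x, tab.data["y"]).statistic
        r1 = stats.spearmanr(x, out.data["y"]).statistic
        assert r1 == pytest.approx(-r0, abs=1e-12)


class TestCopyMean:
    def test_fully_observed_table_unchanged(self, small_cohort):
        out = impute_copy_mean(small_cohort)
        pd.testing.assert_frame_equal(out.data, small_cohort.data)

    def test_trailing_copy_rule(self):
        """Observed 10 at M0, missing at M12; popmeans 20 / 24 -> 14."""
        vals = {"s": {
            ("A", "M0"): 10.0, ("A", "M12"): np.nan,
            ("B", "M0"): 30.0, ("B", "M12"): 24.0,
            ("C", "M0"): 20.0, ("C", "M12"): 24.0,
        }}
        out = impute_copy_mean(make_table(vals))
        assert out.data.loc[("A", "M12"), "s"] == pytest.approx(14.0)

    def test_interior_gap_rule_three_timepoints(self):
        """(10, ., 20) with popmeans (20, 26, 24) -> 15 + (26-22) = 19."""
        tps = ("T0", "T1", "T2")
        vals = {"s": {
            ("A", "T0"): 10.0, ("A", "T1"): np.nan, ("A", "T2"): 20.0,
            ("B", "T0"): 30.0, ("B", "T1"): 26.0, ("B", "T2"): 28.0,
        }}
        out = impute_copy_mean(make_table(vals, timepoints=tps))
        assert out.data.loc[("A", "T1"), "s"] == pytest.approx(19.0)

    def test_idempotent(self):
        vals = {"s": {
            ("A", "M0"): 10.0, ("A", "M12"): np.nan,
            ("B", "M0"): 30.0, ("B", "M12"): 24.0,
            ("C", "M0"): 20.0, ("C", "M12"): 24.0,
        }}
        once = impute_copy_mean(make_table(vals))
        twice = impute_copy_mean(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_shared_trajectory_closed_form(self):
        """Same mean shape for everyone: imputed = observed + pop shift."""
        rng = np.random.default_rng(1)
        shift = 5.0
        vals = {"s": {}}
        for i in range(20):
            base = float(rng.uniform(20, 60))
            vals["s"][(f"S{i}", "M0")] = base
            vals["s"][(f"S{i}", "M12")] = np.nan if i == 0 else base + shift
        tab = make_table(vals)
        pm0 = np.mean([v for (s, tp), v in vals["s"].items() if tp == "M0"])
        pm12 = np.nanmean([v for (s, tp), v in vals["s"].items() if tp == "M12"])
        out = impute_copy_mean(tab)
        expected = vals["s"][("S0", "M0")] + (pm12 - pm0)
        assert out.data.loc[("S0", "M12"), "s"] == pytest.approx(expected)

    def test_imputed_values_clipped_to_range(self):
        vals = {"s": {
            ("A", "M0"): 99.0, ("A", "M12"): np.nan,
            ("B", "M0"): 50.0, ("B", "M12"): 90.0,
        }}
        defs = [ScaleDefinition("s", "continuous", (0, 100))]
        out = impute_copy_mean(make_table(vals, defs))
        assert out.data.loc[("A", "M12"), "s"] == 100.0
        unclipped = impute_copy_mean(make_table(vals, defs), clip=False)
        assert unclipped.data.loc[("A", "M12"), "s"] == pytest.approx(
            99.0 + (90.0 - 74.5)
        )

    def test_scale_fully_missing_at_timepoint_raises(self):
        vals = {"s": {
            ("A", "M0"): 10.0, ("A", "M12"): np.nan,
            ("B", "M0"): 20.0, ("B", "M12"): np.nan,
        }}
        with pytest.raises(ValueError, match="no observed values"):
            impute_copy_mean(make_table(vals))

    def test_subject_all_missing_gets_population_mean(self):
        vals = {"s": {
            ("A", "M0"): np.nan, ("A", "M12"): np.nan,
            ("B", "M0"): 20.0, ("B", "M12"): 30.0,
            ("C", "M0"): 40.0, ("C", "M12"): 50.0,
        }}
        out, log = impute_copy_mean(make_table(vals), return_log=True)
        assert out.data.loc[("A", "M0"), "s"] == pytest.approx(30.0)
        assert out.data.loc[("A", "M12"), "s"] == pytest.approx(40.0)
        assert set(log.loc[log["subject_id"] == "A", "rule"]) == {"population-mean"}
        with pytest.raises(ValueError, match="no observations"):
            impute_copy_mean(make_table(vals), on_all_missing="error")


class TestMissingSummary:
    def test_fully_observed(self, small_cohort):
        rep = missing_summary(small_cohort)
        assert (rep["missing_fraction"] == 0).all()
        assert (rep["subjects_all_missing"] == 0).all()

    def test_counts_all_missing_subjects(self):
        vals = {
            "a": {("A", "M0"): 1.0, ("A", "M12"): np.nan,
                  ("B", "M0"): 2.0, ("B", "M12"): 3.0},
            "b": {("A", "M0"): 1.0, ("A", "M12"): np.nan,
                  ("B", "M0"): 2.0, ("B", "M12"): 3.0},
        }
        rep = missing_summary(make_table(vals))
        assert rep.loc["M12", "subjects_all_missing"] == 1
        assert rep.loc["M12", "missing_fraction"] == pytest.approx(0.5)

    def test_binomial_rate_recovery(self, continuous_defs_15):
        from qolnet.simulate import generate_cohort, make_precision_spec

        spec = make_precision_spec(15, 0.2, seed=0)
        tab = generate_cohort(spec, continuous_defs_15, n=487,
                              missing_rate=0.04, seed=6)
        rep = missing_summary(tab)
        for tp in ("M0", "M12"):
            assert abs(rep.loc[tp, "missing_fraction"] - 0.04) < 0.01
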