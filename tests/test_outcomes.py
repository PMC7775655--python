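"""Clinical rules, group comparisons, and survival statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from pituradiomics import (CohortSpec, classify_resection, compare_groups,
                           cox_fit, generate_cohort, km_logrank,
                           label_progression)


class TestLabelProgression:
    def test_ten_mm_growth_is_progression(self):
        # residual tumor 38 mm growing to 48 mm
        assert label_progression([38.0, 20.0, 20.0], [48.0, 20.0, 20.0]) is True

    def test_identical_dimensions_no_progression(self):
        assert label_progression([30.0, 25.0, 20.0], [30.0, 25.0, 20.0]) is False

    def test_exactly_two_mm_is_not_progression(self):
        # the rule is strictly more than 2 mm
        assert label_progression([30.0, 25.0, 20.0], [32.0, 25.0, 20.0]) is False
        assert label_progression([30.0, 25.0, 20.0], [32.01, 25.0, 20.0]) is True

    def test_negative_dimension_rejected(self):
        with pytest.raises(ValueError):
            label_progression([-1.0, 10.0], [5.0, 10.0])

    def test_axis_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            label_progression([10.0, 10.0], [10.0])


class TestClassifyResection:
    def test_zero_residual_is_gtr(self):
        assert classify_resection(10.0, 0.0) == "GTR"

    def test_nine_percent_is_gtr(self):
        assert classify_resection(10.0, 0.9) == "GTR"

    def test_fifteen_percent_is_str(self):
        assert classify_resection(10.0, 1.5) == "STR"

    def test_exactly_ten_percent_is_str(self):
        assert classify_resection(10.0, 1.0) == "STR"

    def test_residual_exceeding_original_rejected(self):
        with pytest.raises(ValueError):
            classify_resection(5.0, 6.0)


def _records_df(**cols):
    n = len(next(iter(cols.values())))
    base = {"pr_event": [True] * n, "time_months": [10.0] * n}
    base.update(cols)
    return pd.DataFrame(base)


class TestCompareGroups:
    def test_visual_disturbance_fisher(self):
        # 26/28 vs 13/22 affected: expected count < 5 switches to Fisher
        event = [True] * 28 + [False] * 22
        vis = [True] * 26 + [False] * 2 + [True] * 13 + [False] * 9
        df = _records_df(pr_event=event, visual=vis)
        test, _, p, _ = compare_groups(df, "visual")
        assert test == "fisher"
        assert p == pytest.approx(0.006, abs=0.002)

    def test_identical_degenerate_table_p_one(self):
        df = _records_df(pr_event=[True] * 4 + [False] * 4,
                         flag=[True, True, False, False] * 2)
        test, _, p, _ = compare_groups(df, "flag")
        assert test == "fisher" and p == 1.0

    def test_continuous_uses_mannwhitney(self):
        rng = np.random.default_rng(0)
        df = _records_df(pr_event=[True] * 30 + [False] * 30,
                         height=list(rng.normal(30, 5, 30)) + list(rng.normal(20, 5, 30)))
        test, _, p, summary = compare_groups(df, "height")
        assert test == "mann-whitney"
        assert p < 0.001
        assert "(" in summary["event"]  # median (IQR) formatting

    def test_mannwhitney_null_pvalues_uniform(self):
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(200):
            a, b = rng.normal(size=500), rng.normal(size=500)
            df = _records_df(pr_event=[True] * 500 + [False] * 500,
                             x=list(a) + list(b))
            pvals.append(compare_groups(df, "x")[2])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_variable_rejected(self):
        df = _records_df(pr_event=[True, True, False, False], c=[1, 1, 1, 1])
        with pytest.raises(ValueError, match="constant"):
            compare_groups(df, "c")


class TestKmLogrank:
    def test_km_no_censoring_equals_empirical_survival(self):
        times = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0]
        df = pd.DataFrame({"time_months": times * 2,
                           "pr_event": [True] * 12,
                           "grp": [True] * 6 + [False] * 6})
        curves, _, _ = km_logrank(df, "grp")
        sf = curves["high"].iloc[:, 0]
        t = np.asarray(times)
        for time_point in sorted(set(times)):
            empirical = (t > time_point).mean()
            assert sf.loc[time_point] == pytest.approx(empirical, abs=1e-12)

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"time_months": [1.0, 2.0], "pr_event": [True, True],
                           "grp": [True, True]})
        with pytest.raises(ValueError):
            km_logrank(df, "grp")


class TestCoxFit:
    @staticmethod
    def _sim(n=300, hr=2.0, seed=0):
        rng = np.random.default_rng(seed)
        grp = rng.integers(0, 2, n)
        lam = 0.02 * hr**grp
        t = rng.exponential(1 / lam)
        event = t <= 60
        return pd.DataFrame({"time_months": np.minimum(t, 60),
                             "pr_event": event, "grp": grp.astype(float)})

    def test_recovers_binary_hazard_ratio(self):
        df = self._sim(n=500, hr=2.0, seed=5)
        res = cox_fit(df, ["grp"], "univariate")
        assert 1.5 < res.table.loc["grp", "hr"] < 2.6
        assert res.table.loc["grp", "ci_low"] < 2.0 < res.table.loc["grp", "ci_high"]

    def test_promotion_rule_takes_only_significant(self):
        rng = np.random.default_rng(2)
        df = self._sim(n=400, hr=3.0, seed=1)
        df["strong"] = df["grp"]
        df["noise_a"] = rng.normal(size=len(df))
        df["noise_b"] = rng.normal(size=len(df))
        covs = ["strong", "noise_a", "noise_b"]
        uni = cox_fit(df, covs, "univariate")
        multi = cox_fit(df, covs, "multivariate")
        expected = [c for c in covs if uni.table.loc[c, "p"] < 0.05]
        assert multi.variables == expected
        assert "strong" in multi.variables

    def test_logrank_and_cox_agree_in_direction(self):
        df = self._sim(n=400, hr=3.0, seed=3)
        res = cox_fit(df, ["grp"], "univariate")
        _, _, p_lr = km_logrank(df, lambda r: r["grp"] > 0.5)
        assert res.table.loc["grp", "hr"] > 1.0
        assert p_lr < 0.01 and res.table.loc["grp", "p"] < 0.01

    def test_progression_labels_from_generator_agree(self):
        cases = generate_cohort(CohortSpec(n_cases=12, grid_shape=(40, 40, 16),
                                           rng_seed=3))
        for c in cases:
            assert label_progression(c.record.baseline_dims_mm,
                                     c.record.followup_dims_mm) == c.record.pr_event
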