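"""Descriptive statistics, nonparametric tests and report rendering."""

import itertools
import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ttgsim import (
    StatResult,
    bonferroni,
    flexion_effect_tests,
    friedman_test,
    read_summary,
    render_report,
    rotation_tests_by_flexion,
    shapiro_wilk,
    summarize,
    wilcoxon_signed_rank,
)


def _long(values: dict[tuple[str, float, float], float]) -> pd.DataFrame:
    rows = [{"specimen_id": s, "flexion_deg": f, "rotation_deg": r, "tttg_mm": v}
            for (s, f, r), v in values.items()]
    return pd.DataFrame(rows)


class TestSummarize:
    def test_two_specimen_hand_arithmetic(self):
        df = _long({("a", 0, 0): 10.0, ("b", 0, 0): 18.0})
        s = summarize(df).loc[(0.0, 0.0)]
        assert s["mean"] == pytest.approx(14.0)
        assert s["sd"] == pytest.approx(8 / np.sqrt(2), abs=1e-12)  # 5.657
        assert s["n"] == 2

    def test_identical_specimens_have_zero_width_ci(self):
        df = _long({("a", 0, 0): 12.0, ("b", 0, 0): 12.0, ("c", 0, 0): 12.0})
        s = summarize(df).loc[(0.0, 0.0)]
        assert s["sd"] == 0
        assert s["ci95_low"] == s["ci95_high"] == 12.0

    def test_t_ci_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(14, 4, 56)
        df = _long({(f"s{i}", 0, 0): v for i, v in enumerate(vals)})
        s = summarize(df).loc[(0.0, 0.0)]
        half = sps.t.ppf(0.975, 55) * vals.std(ddof=1) / np.sqrt(56)
        assert s["ci95_low"] == pytest.approx(vals.mean() - half, abs=1e-12)
        assert s["ci95_high"] == pytest.approx(vals.mean() + half, abs=1e-12)
        assert s["ci95_low"] <= s["mean"] <= s["ci95_high"]

    def test_normal_ci_is_narrower(self):
        rng = np.random.default_rng(1)
        df = _long({(f"s{i}", 0, 0): v for i, v in enumerate(rng.normal(0, 1, 10))})
        t_ci = summarize(df, ci_method="t").loc[(0.0, 0.0)]
        n_ci = summarize(df, ci_method="normal").loc[(0.0, 0.0)]
        assert (n_ci["ci95_high"] - n_ci["ci95_low"]) < (t_ci["ci95_high"] - t_ci["ci95_low"])

    def test_single_specimen_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            summarize(_long({("a", 0, 0): 10.0}))


class TestShapiroWilk:
    def test_rejects_uniform_at_n500(self):
        rng = np.random.default_rng(2)
        res = shapiro_wilk(rng.uniform(0, 1, 500))
        assert res.p_value < 0.05

    def test_type_one_error_near_nominal(self):
        rejections = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            if shapiro_wilk(rng.normal(0, 1, 50)).p_value < 0.05:
                rejections += 1
        assert 0.05 - 0.03 <= rejections / 200 <= 0.05 + 0.03

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="constant"):
            shapiro_wilk(np.full(10, 3.0))


class TestFriedman:
    def test_identical_conditions_give_zero_statistic(self):
        X = np.tile([[4.0], [7.0], [1.0]], (1, 4))
        res = friedman_test(X)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_small_matrix_against_brute_force_rank_formula(self):
        X = np.array([[1.0, 3.0, 2.0], [2.0, 3.0, 1.0], [1.0, 2.0, 3.0]])
        ranks = np.array([sps.rankdata(row) for row in X])
        n, k = X.shape
        stat_bf = (12.0 / (n * k * (k + 1))) * np.sum(ranks.sum(axis=0) ** 2) - 3 * n * (k + 1)
        res = friedman_test(X)
        assert res.statistic == pytest.approx(stat_bf, abs=1e-12)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_scipy_on_tie_free_data(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 5))
        res = friedman_test(X)
        ref_stat, ref_p = sps.friedmanchisquare(*X.T)
        assert res.statistic == pytest.approx(ref_stat, abs=1e-10)
        assert res.p_value == pytest.approx(ref_p, abs=1e-10)

    def test_invariant_under_per_specimen_monotone_transform(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 4))
        transforms = [np.exp, np.tanh, lambda v: 3 * v + 1]
        Y = np.array([transforms[i % 3](row) for i, row in enumerate(X)])
        assert friedman_test(Y).statistic == pytest.approx(
            friedman_test(X).statistic, abs=1e-12)

    def test_null_type_one_error(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            friedman_test(rng.normal(size=(8, 4))).p_value < 0.05 for _ in range(1000))
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_missing_cells_rejected(self):
        X = np.array([[1.0, 2.0], [np.nan, 1.0]])
        with pytest.raises(ValueError, match="complete"):
            friedman_test(X)


class TestWilcoxon:
    def test_shift_detected_at_n56(self):
        rng = np.random.default_rng(8)
        a = rng.normal(14, 4, 56)
        res = wilcoxon_signed_rank(a, a + 2.0 + rng.normal(0, 0.3, 56))
        assert res.p_value < 0.01

    def test_all_zero_differences_error(self):
        a = np.arange(10, dtype=float)
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(a, a)

    def test_too_few_nonzero_differences_error(self):
        a = np.zeros(8)
        b = np.array([0, 0, 0, 0, 1.0, 2.0, -1.0, 0.5])
        with pytest.raises(ValueError, match="at least 5"):
            wilcoxon_signed_rank(a, b)

    def test_exact_p_equals_exhaustive_sign_enumeration(self):
        """For n = 10 untied pairs, the exact two-sided p must equal direct
        enumeration over all 2^10 sign assignments of the rank sum."""
        d = np.array([1.2, -0.7, 2.3, 0.4, -1.9, 3.1, 0.9, -0.2, 1.5, 2.8])
        res = wilcoxon_signed_rank(np.zeros(10), d)
        ranks = sps.rankdata(np.abs(d))
        total = ranks.sum()
        tplus = ranks[d > 0].sum()
        tmin = min(tplus, total - tplus)
        dist = np.array([
            sum(r for keep, r in zip(signs, ranks) if keep)
            for signs in itertools.product([0, 1], repeat=10)
        ])
        p_enum = np.mean(dist <= tmin) + np.mean(dist >= total - tmin)
        assert res.statistic == pytest.approx(tmin)
        assert res.p_value == pytest.approx(p_enum, abs=1e-12)

    def test_null_type_one_error(self):
        rng = np.random.default_rng(9)
        rejections = 0
        for _ in range(1000):
            d = rng.normal(size=20)
            if wilcoxon_signed_rank(np.zeros(20), d).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / 1000 <= 0.07


class TestBonferroni:
    def test_examples_and_cap(self):
        np.testing.assert_allclose(bonferroni([0.01], 10), [0.1])
        np.testing.assert_allclose(bonferroni([0.5], 4), [1.0])
        p = np.array([0.001, 0.2, 0.9])
        assert (bonferroni(p) >= p).all()

    def test_family_smaller_than_pvalues_rejected(self):
        with pytest.raises(ValueError, match="family"):
            bonferroni([0.1, 0.2, 0.3], m=2)


class TestStatResult:
    def test_adjusted_defaults_and_validation(self):
        r = StatResult("t", 1.0, 0.04)
        assert r.p_adjusted == 0.04
        with pytest.raises(ValueError):
            StatResult("t", 1.0, 1.5)
        with pytest.raises(ValueError):
            StatResult("t", 1.0, 0.5, p_adjusted=0.2)


class TestFamilies:
    @pytest.fixture()
    def small_long(self):
        rng = np.random.default_rng(10)
        rows = []
        for i in range(12):
            base = rng.normal(14, 4)
            for f in (0.0, 10.0, 20.0):
                for r in (0.0, 5.0, 10.0):
                    if f == 0 and r > 0:
                        continue
                    rows.append({"specimen_id": f"s{i}", "flexion_deg": f,
                                 "rotation_deg": r,
                                 "tttg_mm": base - 0.5 * r + rng.normal(0, 0.1)})
        return pd.DataFrame(rows)

    def test_rotation_families_sizes(self, small_long):
        fried, pairwise = rotation_tests_by_flexion(small_long)
        assert len(fried) == 2  # flexion 10 and 20 have >1 rotation level
        assert len(pairwise) == 2 * 3  # C(3,2) per flexion
        assert all(r.p_adjusted >= r.p_value for r in pairwise)

    def test_flexion_family(self, small_long):
        fried, per_flexion = flexion_effect_tests(small_long)
        assert fried.comparison.startswith("flexion effect")
        assert len(per_flexion) == 2


class TestRenderReport:
    def test_minimal_report_files(self, tmp_path):
        rng = np.random.default_rng(11)
        rows = []
        for i in range(2):
            for f in (0.0, 10.0):
                for r in (0.0, 5.0):
                    if f == 0 and r > 0:
                        continue
                    rows.append({"specimen_id": f"s{i}", "flexion_deg": f,
                                 "rotation_deg": r,
                                 "tttg_mm": 14 + i - 0.5 * r + 0.01 * rng.normal()})
        long_df = pd.DataFrame(rows)
        paths = render_report(long_df, tmp_path / "out", seed=1)
        for key in ("summary", "table1", "table2", "table3", "figure", "stats",
                    "manifest"):
            assert paths[key].exists(), key
        # tidy summary round-trips
        back = read_summary(paths["summary"])
        pd.testing.assert_frame_equal(back, summarize(long_df), check_exact=False)
        # the 0-degree flexion row shows "–" for rotated poses
        table2 = pd.read_csv(paths["table2"], index_col=0)
        assert table2.loc["0° flexion", "5° rotation"] == "–"
        assert json.loads(paths["manifest"].read_text())["seed"] == 1
        assert isinstance(json.loads(paths["stats"].read_text()), list)
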