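"""Correlation, regression, and screening statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from figground import (
    compare_independent_correlations,
    hierarchical_regression,
    noise_ceiling,
    paired_t_dz,
    partial_correlation,
    pearson,
    screen_audiogram,
    stepwise_forward,
    variance_explained_percent,
)
from figground.stats import DegenerateDataError, fisher_confidence_interval


class TestScreenAudiogram:
    def test_constant_thresholds_included(self):
        include, hf = screen_audiogram([10] * 6, [10] * 6)
        assert include and hf == 10

    def test_borderline_ear_excluded(self):
        include, _ = screen_audiogram([20] * 6, [0] * 6)
        assert not include  # six-frequency average of 20 >= 20 dB HL

    def test_hand_worked_high_frequency_average(self):
        include, hf = screen_audiogram([0, 0, 0, 0, 10, 20], [0, 0, 0, 0, 20, 30])
        assert include  # ear means 5 and ~8.3
        assert hf == pytest.approx((10 + 20 + 20 + 30) / 4)

    def test_wrong_frequency_count_raises(self):
        with pytest.raises(ValueError):
            screen_audiogram([0] * 5, [0] * 6)


class TestPearson:
    @pytest.mark.parametrize(
        "r,n,lo,hi",
        [(0.39, 97, 0.21, 0.55), (0.32, 97, 0.13, 0.49)],
    )
    def test_fisher_ci_reproduces_printed_intervals(self, r, n, lo, hi):
        ci = fisher_confidence_interval(r, n)
        assert round(ci[0], 2) == lo
        assert round(ci[1], 2) == hi

    def test_fisher_ci_noise_ceiling_interval(self):
        # the test-retest ceiling CI for r = 0.69, n = 97 (the printed lower
        # bound reflects an unrounded r, hence the one-digit slack there)
        lo, hi = fisher_confidence_interval(0.69, 97)
        assert lo == pytest.approx(0.56, abs=0.01)
        assert round(hi, 2) == 0.78

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_direct_formula_oracle_on_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        x, y = rng.standard_normal((2, n))
        res = pearson(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-9)

    def test_perfect_correlation_degenerate_ci(self):
        x = np.arange(10.0)
        res = pearson(x, x)
        assert res.r == 1.0 and res.ci95 == (1.0, 1.0) and res.degenerate

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateDataError):
            pearson(np.ones(10), np.arange(10.0))


class TestVarianceExplained:
    @pytest.mark.parametrize("r,pct", [(0.39, 15), (0.48, 23), (0.0, 0), (1.0, 100)])
    def test_known_percentages(self, r, pct):
        assert variance_explained_percent(r) == pct


class TestNoiseCeiling:
    def test_identical_blocks_hit_ceiling_of_one(self):
        x = np.random.default_rng(0).standard_normal(50)
        assert noise_ceiling(x, x)["correlation"].r == pytest.approx(1.0)

    def test_recovers_generating_reliability(self):
        rng = np.random.default_rng(42)
        latent = rng.standard_normal(5000)
        # two blocks correlated at 0.7 by shared-latent construction
        lam = np.sqrt(0.7)
        b1 = lam * latent + np.sqrt(1 - 0.7) * rng.standard_normal(5000)
        b2 = lam * latent + np.sqrt(1 - 0.7) * rng.standard_normal(5000)
        nc = noise_ceiling(b1, b2)
        lo, hi = nc["correlation"].ci95
        assert lo < 0.7 < hi

    def test_independent_blocks_give_near_zero_ceiling(self):
        rng = np.random.default_rng(43)
        nc = noise_ceiling(rng.standard_normal(5000), rng.standard_normal(5000))
        assert abs(nc["correlation"].r) < 0.05


class TestHierarchicalRegression:
    def test_single_predictor_r_equals_pearson(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(200)
        y = 0.5 * x + rng.standard_normal(200)
        step = hierarchical_regression(y, [(("x",), x)])[0]
        assert step.r == pytest.approx(abs(pearson(x, y).r), abs=1e-12)

    def test_r2_change_matches_brute_force_two_model_comparison(self):
        rng = np.random.default_rng(2)
        n = 5000
        x1, x2 = rng.standard_normal((2, n))
        y = 0.5 * x1 + 0.3 * x2 + rng.standard_normal(n)
        steps = hierarchical_regression(y, [(("x1",), x1), (("x2",), x2)])

        def brute_r2(X):
            d = np.column_stack([np.ones(n)] + X)
            resid = y - d @ np.linalg.lstsq(d, y, rcond=None)[0]
            return 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))

        assert steps[1].r2_change == pytest.approx(
            brute_r2([x1, x2]) - brute_r2([x1]), abs=1e-12
        )
        assert steps[1].r2 >= steps[0].r2  # monotone along the path

    def test_duplicate_predictor_changes_nothing_and_warns(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(100)
        y = x + rng.standard_normal(100)
        with pytest.warns(UserWarning, match="collinear"):
            steps = hierarchical_regression(y, [(("x",), x), (("x_copy",), x)])
        assert steps[1].r2_change == 0.0
        assert steps[1].p_change == 1.0

    def test_r2_change_telescopes_to_total(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((300, 3))
        y = X @ [0.4, 0.2, 0.1] + rng.standard_normal(300)
        steps = hierarchical_regression(
            y, [(("a",), X[:, 0]), (("b",), X[:, 1]), (("c",), X[:, 2])]
        )
        total = sum(s.r2_change for s in steps)
        assert total == pytest.approx(steps[-1].r2, abs=1e-12)


class TestStepwise:
    def test_selects_exactly_the_informative_predictor(self):
        rng = np.random.default_rng(5)
        n = 5000
        strong = rng.standard_normal(n)
        y = 0.6 * strong + rng.standard_normal(n)
        cands = {"strong": strong}
        cands |= {f"noise{i}": rng.standard_normal(n) for i in range(3)}
        # strict entry criterion: the informative predictor enters with
        # p ~ 0 while pure-noise candidates clear p < 0.001 only ~0.3% of
        # the time each
        sel = stepwise_forward(y, cands, entry_p=0.001)
        assert [s.variables[-1] for s in sel["path"]] == ["strong"]
        assert sorted(sel["excluded"]) == ["noise0", "noise1", "noise2"]

    def test_pure_noise_usually_selects_nothing(self):
        rng = np.random.default_rng(6)
        n = 5000
        y = rng.standard_normal(n)
        cands = {f"n{i}": rng.standard_normal(n) for i in range(4)}
        sel = stepwise_forward(y, cands, entry_p=0.01)
        assert len(sel["path"]) <= 1  # at most a false positive

    def test_entry_p_one_enters_everything_by_incremental_fit(self):
        rng = np.random.default_rng(7)
        n = 500
        cands = {f"x{i}": rng.standard_normal(n) for i in range(3)}
        y = 0.5 * cands["x0"] + 0.2 * cands["x1"] + rng.standard_normal(n)
        sel = stepwise_forward(y, cands, entry_p=1.0)
        assert len(sel["path"]) == 3 and sel["excluded"] == []
        assert sel["path"][0].variables[-1] == "x0"


class TestPartialCorrelation:
    def test_independent_covariate_leaves_r_unchanged(self):
        rng = np.random.default_rng(8)
        n = 5000
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        z = rng.standard_normal(n)
        raw = pearson(x, y).r
        part = partial_correlation(x, y, z).r
        assert part == pytest.approx(raw, abs=0.02)

    def test_shared_confound_is_removed(self):
        rng = np.random.default_rng(9)
        n = 5000
        z = rng.standard_normal(n)
        x = 0.7 * z + rng.standard_normal(n)
        y = 0.7 * z + rng.standard_normal(n)
        assert pearson(x, y).r > 0.2
        assert abs(partial_correlation(x, y, z).r) < 0.05

    def test_degenerate_residual_returns_zero_with_flag(self):
        rng = np.random.default_rng(10)
        z = rng.standard_normal(100)
        x = rng.standard_normal(100)
        with pytest.warns(UserWarning, match="zero-variance residual"):
            res = partial_correlation(x, z.copy(), z)
        assert res.r == 0.0 and res.degenerate

    def test_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(11)
        n = 200
        z = rng.standard_normal(n)
        x = 0.4 * z + rng.standard_normal(n)
        y = 0.3 * z + 0.3 * x + rng.standard_normal(n)
        res = partial_correlation(x, y, z)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z")
        p_col = "p_val" if "p_val" in ref.columns else "p-val"
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref[p_col].iloc[0]), rel=1e-6)


class TestCompareCorrelations:
    def test_reproduces_printed_subsample_comparison(self):
        z, p = compare_independent_correlations(0.39, 97, 0.25, 89)
        assert z == pytest.approx(1.05, abs=0.005)
        assert p == pytest.approx(0.29, abs=0.005)

    def test_equal_correlations_give_zero(self):
        z, p = compare_independent_correlations(0.3, 50, 0.3, 80)
        assert z == 0.0 and p == 1.0

    def test_closed_form_example(self):
        z, _ = compare_independent_correlations(0.5, 103, 0.0, 103)
        assert z == pytest.approx(np.arctanh(0.5) / np.sqrt(2 / 100), rel=1e-9)


class TestPairedT:
    def test_constant_shift_is_degenerate(self):
        a = np.arange(10.0)
        with pytest.raises(DegenerateDataError):
            paired_t_dz(a + 2, a)

    def test_identical_columns_are_degenerate(self):
        a = np.arange(10.0)
        with pytest.raises(DegenerateDataError):
            paired_t_dz(a, a)

    def test_dz_recovers_standardised_effect(self):
        rng = np.random.default_rng(12)
        b = rng.standard_normal(97)
        a = b + rng.normal(1.0, 1.0, 97)
        res = paired_t_dz(a, b)
        assert res["df"] == 96
        assert res["dz"] == pytest.approx(1.0, abs=0.35)
        assert res["t"] == pytest.approx(res["dz"] * np.sqrt(97), rel=1e-9)
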