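"""Unit and oracle-equivalence tests for the ten vQTL detection methods.

Closed-form tests are checked to 1e-10 against independent evaluations of
their defining formulas (explicit sums / rank tables / scipy's reference
implementations of the classical homogeneity tests); regression-based tests
are checked against inline closed-form simple-regression algebra.
"""

import numpy as np
import pytest
from scipy import stats

from vqtlbench.methods import (
    METHOD_NAMES,
    bartlett_test,
    center_distance_anova,
    cls_test,
    dglm_test,
    drm_test,
    fligner_killeen_test,
    quail_test,
    run_method,
    svlm_test,
    zscore_test,
)
from vqtlbench.preprocess import PreprocessPlan

Y12 = np.array([1.2, 3.4, 2.2, 5.1, 0.3, 4.4, 7.8, 2.5, 6.1, 9.0, 3.3, 1.1])
G12 = np.repeat([0, 1, 2], 4)


def _simple_slope_t(x, y):
    """Closed-form simple regression slope and Wald t (independent oracle)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sxx = ((x - x.mean()) ** 2).sum()
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    s2 = (resid**2).sum() / (n - 2)
    t = slope / np.sqrt(s2 / sxx)
    p = 2 * stats.t.sf(abs(t), n - 2)
    return slope, t, p


class TestClassicalHomogeneityTests:
    """Levene / BF / Bartlett / FK against scipy's reference implementations."""

    def test_levene_matches_reference(self):
        res = center_distance_anova(Y12, G12, center="mean")
        ref = stats.levene(*[Y12[G12 == k] for k in range(3)], center="mean")
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_bf_matches_reference(self):
        res = center_distance_anova(Y12, G12, center="median")
        ref = stats.levene(*[Y12[G12 == k] for k in range(3)], center="median")
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_bartlett_matches_reference(self):
        res = bartlett_test(Y12, G12)
        ref = stats.bartlett(*[Y12[G12 == k] for k in range(3)])
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_fk_matches_reference(self):
        res = fligner_killeen_test(Y12, G12)
        ref = stats.fligner(*[Y12[G12 == k] for k in range(3)])
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_bf_hand_computed_distance_anova(self):
        # medians 2 and 4 -> distances [1,0,1] and [4,0,4]; ANOVA gives F = 36/17
        res = center_distance_anova(
            np.array([1.0, 2, 3, 0, 4, 8]), np.array([0, 0, 0, 1, 1, 1]), center="median"
        )
        assert res.statistic == pytest.approx(36.0 / 17.0, abs=1e-12)
        assert res.p_value == pytest.approx(stats.f.sf(36.0 / 17.0, 1, 4), abs=1e-12)

    @pytest.mark.parametrize("center", ["mean", "median"])
    def test_equal_within_group_spread_gives_null(self, center):
        res = center_distance_anova(np.array([1.0, 3, 1, 3]), np.array([0, 0, 1, 1]), center)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 genotype groups"):
            center_distance_anova(np.arange(4.0), np.zeros(4))

    def test_bartlett_equal_variances_gives_null(self):
        res = bartlett_test(np.array([1.0, 2, 3, 4, 5, 6]), np.repeat([0, 1], 3))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_bartlett_rejects_size_one_group(self):
        with pytest.raises(ValueError):
            bartlett_test(np.array([1.0, 2, 3, 4]), np.array([0, 0, 0, 1]))

    def test_fk_symmetric_construction_gives_null(self):
        res = fligner_killeen_test(np.array([1.0, 3, 2, 4, 6, 5]), np.repeat([0, 1], 3))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_fk_all_distances_tied_degenerates_to_p_one(self):
        res = fligner_killeen_test(np.array([1.0, 3, 1, 3]), np.array([0, 0, 1, 1]))
        assert res.p_value == 1.0 and "tied" in res.note


class TestRegressionBasedTests:
    def test_svlm_two_stage_matches_closed_form(self):
        g = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2], float)
        y = np.array([0.1, -0.2, 0.05, 0.9, -1.1, 0.3, 2.5, -2.0, 0.7])
        slope1, _, _ = _simple_slope_t(g, y)
        r2 = (y - (y.mean() - slope1 * g.mean()) - slope1 * g) ** 2
        slope2, t2, p2 = _simple_slope_t(g, r2)
        res = svlm_test(y, g)
        assert res.effect_size == pytest.approx(slope2, abs=1e-10)
        assert res.statistic == pytest.approx(t2, abs=1e-10)
        assert res.p_value == pytest.approx(p2, abs=1e-10)
        assert res.effect_size > 0  # variance increases with g by construction

    def test_svlm_perfect_fit_degenerates_to_p_one(self):
        g = np.array([0, 1, 2, 0, 1, 2], float)
        res = svlm_test(3.0 * g + 1.0, g)
        assert res.p_value == 1.0 and res.effect_size == 0.0

    def test_svlm_duplicated_genotype_covariate_rejected(self):
        g = np.array([0, 1, 2, 0, 1, 2], float)
        with pytest.raises(ValueError, match="collinear"):
            svlm_test(np.random.default_rng(0).normal(size=6), g, covariates=g[:, None])

    def test_cls_perfect_monotone_agreement_under_average_ranks(self):
        # squared residuals [1,1,2,2,3,3] against g: tied ranks align exactly
        from vqtlbench.methods import _spearman_t

        g = np.array([0, 0, 1, 1, 2, 2], float)
        res = _spearman_t(np.array([1.0, 1, 2, 2, 3, 3]), g)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == 0.0

    def test_cls_anti_monotone(self):
        from vqtlbench.methods import _spearman_t

        g = np.array([0, 0, 1, 1, 2, 2], float)
        res = _spearman_t(np.array([3.0, 3, 2, 2, 1, 1]), g)
        assert res.statistic == pytest.approx(-1.0, abs=1e-12)

    def test_cls_untied_fixture_matches_rank_formula(self):
        # continuous "dosage" g, y orthogonal to [1, g] with distinct squares
        g = np.array([0.5, 1.2, 2.0, 2.7, 3.1, 3.9, 4.4, 5.0])
        rng = np.random.default_rng(5)
        y = rng.normal(size=8)
        from vqtlbench.preprocess import adjust_covariates

        y = adjust_covariates(y, g)  # now stage-1 residuals == y exactly
        r2 = y**2
        d = stats.rankdata(r2) - stats.rankdata(g)
        rho = 1.0 - 6.0 * (d**2).sum() / (8 * 63)
        t = rho * np.sqrt(6 / (1 - rho**2))
        p = 2 * stats.t.sf(abs(t), 6)
        res = cls_test(y, g)
        assert res.statistic == pytest.approx(rho, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_drm_slope_from_covariance_formula(self):
        y = np.array([1.0, 2, 3, 0, 4, 8])
        g = np.array([0, 0, 0, 2, 2, 2], float)
        # distances [1,0,1,4,0,4]; slope = cov(d,g)/var(g) = 1.0 exactly
        res = drm_test(y, g)
        d = np.array([1.0, 0, 1, 4, 0, 4])
        slope, t, p = _simple_slope_t(g, d)
        assert slope == pytest.approx(1.0, abs=1e-12)
        assert res.effect_size == pytest.approx(slope, abs=1e-12)
        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_drm_identical_distance_multisets_give_null(self):
        res = drm_test(np.array([1.0, 3, 11, 13]), np.array([0, 0, 1, 1], float))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_drm_scale_equivariance(self):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 3, 200).astype(float)
        y = rng.normal(size=200) * (1 + 0.3 * g)
        a, b = drm_test(y, g), drm_test(5.0 * y, g)
        assert b.effect_size == pytest.approx(5.0 * a.effect_size, rel=1e-10)
        assert b.p_value == pytest.approx(a.p_value, abs=1e-10)

    def test_zscore_matches_explicit_score_table(self):
        g = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2], float)
        y = np.array([0.3, -1.2, 0.8, 2.1, -0.6, 1.4, -2.2, 3.0, 0.1])
        ranks = stats.rankdata(y)
        z2 = stats.norm.ppf((ranks - 0.5) / 9.0) ** 2
        slope, t, p = _simple_slope_t(g, z2)
        res = zscore_test(np.concatenate([y, [5.0]]), np.concatenate([g, [1.0]]))  # n >= 10
        # recompute oracle at n = 10
        y10 = np.concatenate([y, [5.0]])
        g10 = np.concatenate([g, [1.0]])
        z2 = stats.norm.ppf((stats.rankdata(y10) - 0.5) / 10.0) ** 2
        slope, t, p = _simple_slope_t(g10, z2)
        assert res.effect_size == pytest.approx(slope, abs=1e-10)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_zscore_permutation_of_sample_order_is_invariant(self):
        rng = np.random.default_rng(7)
        g = rng.integers(0, 3, 100).astype(float)
        y = rng.normal(size=100)
        perm = rng.permutation(100)
        a, b = zscore_test(y, g), zscore_test(y[perm], g[perm])
        assert a.statistic == pytest.approx(b.statistic, abs=1e-10)

    def test_zscore_rejects_tiny_or_constant_input(self):
        with pytest.raises(ValueError):
            zscore_test(np.arange(5.0), np.array([0, 0, 1, 1, 1]))
        with pytest.raises(ValueError):
            zscore_test(np.ones(20), np.tile([0, 1], 10))


class TestQuail:
    def test_null_effect_near_zero(self):
        rng = np.random.default_rng(8)
        g = rng.integers(0, 3, 5000).astype(float)
        for seed in range(3):
            y = np.random.default_rng(seed).normal(size=5000)
            res = quail_test(y, g)
            assert abs(res.statistic) < 4.0  # Wald t within a null band

    def test_scale_model_detected(self):
        # y = g * u with u ~ uniform(-1, 1): variance rises with genotype
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            g = rng.integers(0, 3, 5000).astype(float)
            y = g * rng.uniform(-1, 1, 5000)
            res = quail_test(y, g)
            hits += res.effect_size > 0 and res.p_value < 0.05
        assert hits >= 9

    def test_permutation_inference_agrees_on_strong_signal(self):
        rng = np.random.default_rng(9)
        g = rng.integers(0, 3, 2000).astype(float)
        y = rng.normal(size=2000) * (1 + g)
        a = quail_test(y, g)
        b = quail_test(y, g, inference="permutation", n_perm=99, seed=1)
        assert a.p_value < 0.01 and b.p_value <= 0.02
        assert a.effect_size == b.effect_size

    @pytest.mark.parametrize("nq", [0, -2, 5])
    def test_invalid_quantile_grid(self, nq):
        with pytest.raises(ValueError):
            quail_test(np.random.default_rng(0).normal(size=500),
                       np.zeros(500), n_quantiles=nq)


class TestDglm:
    def test_dispersion_parameter_recovery(self):
        # var(y | g) = exp(0.5 g): the dispersion-model genotype coefficient is 0.5
        rng = np.random.default_rng(10)
        g = rng.integers(0, 3, 20_000).astype(float)
        y = rng.normal(0.0, np.exp(0.25 * g))
        res = dglm_test(y, g)
        assert res.converged
        assert res.effect_size == pytest.approx(0.5, rel=0.10)
        assert res.p_value < 1e-10

    def test_iteration_cap_zero_returns_nonconverged(self):
        res = dglm_test(np.random.default_rng(0).normal(size=100),
                        np.tile([0.0, 1, 2], 34)[:100], max_iter=0)
        assert not res.converged and res.p_value is None

    def test_scale_invariance_of_dispersion_coefficient(self):
        rng = np.random.default_rng(11)
        g = rng.integers(0, 3, 3000).astype(float)
        y = rng.normal(0.0, 1 + 0.2 * g)
        a, b = dglm_test(y, g), dglm_test(7.0 * y, g)
        assert a.effect_size == pytest.approx(b.effect_size, abs=1e-6)


class TestInvarianceProperties:
    @pytest.fixture
    def heteroscedastic(self):
        # odd group sizes: each group median is a data point, so the median-
        # distance tests have no constructed exact ties that a shift could break
        rng = np.random.default_rng(12)
        g = np.repeat([0.0, 1.0, 2.0], [135, 133, 133])
        rng.shuffle(g)
        return rng.normal(size=401) * (1 + 0.2 * g), g

    def test_location_invariance_of_distance_tests(self, heteroscedastic):
        y, g = heteroscedastic
        for fn in (
            lambda a, b: center_distance_anova(a, b, "mean"),
            lambda a, b: center_distance_anova(a, b, "median"),
            bartlett_test,
            fligner_killeen_test,
            drm_test,
        ):
            assert fn(y + 17.3, g).statistic == pytest.approx(fn(y, g).statistic, abs=1e-10)

    @pytest.mark.parametrize("name", [m for m in METHOD_NAMES if m != "dglm"])
    def test_scale_invariance_of_p_values(self, name, heteroscedastic):
        y, g = heteroscedastic
        a = run_method(name, y, g)
        b = run_method(name, 3.7 * y, g)
        assert b.p_value == pytest.approx(a.p_value, abs=1e-10)


class TestDispatch:
    def test_bf_routes_to_median_centered_anova(self):
        rng = np.random.default_rng(13)
        g = rng.integers(0, 3, 200).astype(float)
        y = rng.normal(size=200)
        assert run_method("bf", y, g).statistic == pytest.approx(
            center_distance_anova(y, g, "median").statistic, abs=1e-12
        )

    def test_svlm_stage1_absorbs_exposure_covariate(self):
        rng = np.random.default_rng(14)
        g = rng.integers(0, 3, 300).astype(float)
        e = rng.normal(size=300)
        y = 0.5 * e + rng.normal(size=300) * (1 + 0.2 * g)
        routed = run_method("svlm", y, g, e[:, None], plan=PreprocessPlan())
        direct = svlm_test(y, g, covariates=e[:, None])
        assert routed.statistic == pytest.approx(direct.statistic, abs=1e-12)

    def test_unobserved_exposure_route_uses_raw_trait(self):
        rng = np.random.default_rng(15)
        g = rng.integers(0, 3, 300).astype(float)
        e = rng.normal(size=300)
        y = 0.5 * e + rng.normal(size=300)
        raw = run_method("levene", y, g, e[:, None], plan=PreprocessPlan(adjust_exposure=False))
        assert raw.statistic == pytest.approx(
            center_distance_anova(y, g, "mean").statistic, abs=1e-12
        )

    def test_unknown_method_lists_valid_ids(self):
        with pytest.raises(ValueError, match="levene"):
            run_method("foo", np.zeros(10), np.zeros(10))
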