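"""The ten variance-QTL detection methods.

Each method maps (trait vector, genotype vector coded 0/1/2, optional
covariates) to a :class:`TestResult`.  Variance-only tests: Levene,
Brown-Forsythe (BF), Bartlett, Fligner-Killeen (FK, modified
median-centered variant), SVLM, CLS, DRM, the squared-Z-score regression,
and QUAIL.  The double generalized linear model (DGLM) is the
mean-variance joint test.  All p-values are two-sided.

Degenerate inputs (zero-variance stages, tied distances) resolve to p = 1
with a note rather than raising, so Monte-Carlo loops can count them as
non-discoveries; genuinely invalid inputs (a single genotype group, a
constant trait where ordering is required) raise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .preprocess import PreprocessPlan, adjust_covariates, build_design, _check_full_rank, rank_int

__all__ = [
    "TestResult",
    "METHOD_NAMES",
    "center_distance_anova",
    "bartlett_test",
    "fligner_killeen_test",
    "svlm_test",
    "cls_test",
    "drm_test",
    "zscore_test",
    "quail_test",
    "dglm_test",
    "run_method",
    "batch_run",
]

METHOD_NAMES = ("levene", "bf", "bartlett", "fk", "svlm", "cls", "drm", "zscore", "quail", "dglm")

#: methods whose TestResult carries an effect size (genotype-term coefficient)
EFFECT_SIZE_METHODS = frozenset({"dglm", "svlm", "drm", "quail", "zscore"})


@dataclass
class TestResult:
    """One method's output on one dataset."""

    method: str
    statistic: float
    p_value: float | None
    effect_size: float | None = None
    df: float | tuple[float, float] | None = None
    converged: bool = True
    note: str = ""


def _split_groups(y: np.ndarray, g: np.ndarray, min_size: int = 2):
    y = np.asarray(y, dtype=float)
    g = np.asarray(g)
    levels = np.unique(g)
    if levels.size < 2:
        raise ValueError("variance tests require at least 2 genotype groups")
    groups = [y[g == lev] for lev in levels]
    if any(grp.size < min_size for grp in groups):
        raise ValueError(f"every genotype group needs >= {min_size} samples")
    return levels, groups


def _ols_slope(X: np.ndarray, y: np.ndarray, idx: int):
    """Coefficient, Wald t and two-sided p for one column of an OLS fit."""
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - k
    s2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(s2 * xtx_inv[idx, idx])
    if se == 0.0 or not np.isfinite(se):
        return float(beta[idx]), 0.0, 1.0, dof
    t = float(beta[idx]) / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(beta[idx]), t, float(p), dof


def center_distance_anova(
    y: np.ndarray, g: np.ndarray, center: Literal["mean", "median"] = "mean"
) -> TestResult:
    """Levene (center='mean') / Brown-Forsythe (center='median') test.

    Distances z_gi = |y_gi - center(group g)| enter a one-way ANOVA with
    (G-1, N-G) degrees of freedom.
    """
    levels, groups = _split_groups(y, g)
    centre = np.median if center == "median" else np.mean
    z = [np.abs(grp - centre(grp)) for grp in groups]
    n = sum(grp.size for grp in groups)
    G = len(groups)
    zbar = np.concatenate(z).mean()
    ss_between = sum(grp.size * (grp.mean() - zbar) ** 2 for grp in z)
    ss_within = sum(((grp - grp.mean()) ** 2).sum() for grp in z)
    df = (G - 1, n - G)
    if ss_within <= 0.0:
        if ss_between <= 0.0:
            return TestResult("levene" if center == "mean" else "bf", 0.0, 1.0, df=df,
                              note="all distances equal")
        return TestResult("levene" if center == "mean" else "bf", np.inf, 0.0, df=df)
    F = (ss_between / df[0]) / (ss_within / df[1])
    p = stats.f.sf(F, *df)
    return TestResult("levene" if center == "mean" else "bf", float(F), float(p), df=df)


def bartlett_test(y: np.ndarray, g: np.ndarray) -> TestResult:
    """Bartlett's homogeneity-of-variance test (chi-squared, G-1 df)."""
    levels, groups = _split_groups(y, g)
    n = sum(grp.size for grp in groups)
    G = len(groups)
    vars_ = np.array([grp.var(ddof=1) for grp in groups])
    if np.any(vars_ <= 0.0):
        raise ValueError("Bartlett's test undefined for a zero-variance genotype group")
    sizes = np.array([grp.size for grp in groups])
    sp2 = np.sum((sizes - 1) * vars_) / (n - G)
    num = (n - G) * np.log(sp2) - np.sum((sizes - 1) * np.log(vars_))
    corr = 1.0 + (np.sum(1.0 / (sizes - 1)) - 1.0 / (n - G)) / (3.0 * (G - 1))
    stat = num / corr
    p = stats.chi2.sf(stat, G - 1)
    return TestResult("bartlett", float(stat), float(p), df=G - 1)


def fligner_killeen_test(y: np.ndarray, g: np.ndarray) -> TestResult:
    """Modified Fligner-Killeen test on median-centered distances.

    Distances |y - median(group)| are ranked across all samples (average
    ranks for ties) and mapped through Phi^{-1}(1/2 + r/(2(N+1))); the
    statistic compares group means of these normal scores against their
    overall variance, chi-squared with G-1 df.
    """
    levels, groups = _split_groups(y, g)
    z = np.concatenate([np.abs(grp - np.median(grp)) for grp in groups])
    sizes = np.array([grp.size for grp in groups])
    n = z.size
    ranks = stats.rankdata(z, method="average")
    scores = stats.norm.ppf(0.5 + ranks / (2.0 * (n + 1.0)))
    sigma2 = scores.var(ddof=1)
    if sigma2 <= 0.0:
        return TestResult("fk", 0.0, 1.0, df=len(groups) - 1, note="all normal scores tied")
    abar = scores.mean()
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    group_means = np.array([scores[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
    stat = np.sum(sizes * (group_means - abar) ** 2) / sigma2
    p = stats.chi2.sf(stat, len(groups) - 1)
    return TestResult("fk", float(stat), float(p), df=len(groups) - 1)


def _stage1_squared_residuals(y, g, covariates):
    y = np.asarray(y, dtype=float)
    X1 = build_design(len(y), covariates, g)
    _check_full_rank(X1)
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    return resid**2


def svlm_test(y: np.ndarray, g: np.ndarray, covariates: np.ndarray | None = None) -> TestResult:
    """Squared residual value linear model.

    Stage 1 regresses the trait on intercept + genotype (+ covariates) to
    strip the mean genetic effect; stage 2 regresses the squared stage-1
    residuals on genotype.  The genotype slope of stage 2 is the effect
    size; its Wald t gives the p-value.
    """
    r2 = _stage1_squared_residuals(y, g, covariates)
    if np.allclose(r2, 0.0):
        return TestResult("svlm", 0.0, 1.0, effect_size=0.0, note="zero stage-1 residual variance")
    X2 = build_design(len(r2), None, g)
    slope, t, p, dof = _ols_slope(X2, r2, idx=1)
    return TestResult("svlm", t, p, effect_size=slope, df=dof)


def _spearman_t(values: np.ndarray, g: np.ndarray) -> TestResult:
    """Spearman rho (average ranks for ties) with the t-approximation p-value."""
    values = np.asarray(values, dtype=float)
    g = np.asarray(g, dtype=float)
    n = values.size
    if np.allclose(values, values[0]) or np.allclose(g, g[0]):
        return TestResult("cls", 0.0, 1.0, note="constant input, correlation undefined")
    rho = float(stats.spearmanr(values, g).statistic)
    if abs(rho) >= 1.0:
        return TestResult("cls", rho, 0.0, df=n - 2)
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return TestResult("cls", rho, float(p), df=n - 2)


def cls_test(y: np.ndarray, g: np.ndarray, covariates: np.ndarray | None = None) -> TestResult:
    """Spearman rank correlation between squared stage-1 residuals and genotype.

    p-value from the t approximation t = rho * sqrt((n-2)/(1-rho^2)).
    """
    r2 = _stage1_squared_residuals(y, g, covariates)
    return _spearman_t(r2, g)


def drm_test(y: np.ndarray, g: np.ndarray) -> TestResult:
    """Deviation regression model: |y - median(group)| regressed on genotype."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    levels, groups = _split_groups(y, g, min_size=1)
    d = np.empty_like(y)
    for lev in levels:
        mask = g == lev
        d[mask] = np.abs(y[mask] - np.median(y[mask]))
    if np.ptp(d) == 0.0 or np.allclose(d, d[0], rtol=0.0, atol=1e-12 * max(1.0, np.abs(d).max())):
        return TestResult("drm", 0.0, 1.0, effect_size=0.0, note="no spread difference")
    X = build_design(len(y), None, g)
    slope, t, p, dof = _ols_slope(X, d, idx=1)
    return TestResult("drm", t, p, effect_size=slope, df=dof)


def zscore_test(y: np.ndarray, g: np.ndarray) -> TestResult:
    """Squared inverse-normal-score regression: Phi^{-1}(rank(y))^2 ~ g."""
    y = np.asarray(y, dtype=float)
    if y.size < 10:
        raise ValueError("zscore test requires n >= 10")
    z2 = rank_int(y) ** 2
    X = build_design(len(y), None, g)
    slope, t, p, dof = _ols_slope(X, z2, idx=1)
    return TestResult("zscore", t, p, effect_size=slope, df=dof)


def quail_test(
    y: np.ndarray,
    g: np.ndarray,
    covariates: np.ndarray | None = None,
    n_quantiles: int = 100,
    inference: Literal["rank_score", "permutation"] = "rank_score",
    n_perm: int = 200,
    seed: int | None = None,
) -> TestResult:
    """Quantile integral linear model.

    For tau_k = k/(K+1) the quantile rank score of sample i at level tau is
    a_tau(i) = tau - 1{y_i <= Q_tau}, with Q_tau the null conditional
    quantile (empirical quantile without covariates, quantile regression on
    the covariates otherwise).  The per-sample integrated score

        s_i = mean over tau < 0.5 of ( a_{1-tau}(i) - a_tau(i) )

    is large for samples in either tail and negative in the middle, i.e. a
    dispersion outlyingness score; the integrated quantile effect of
    genotype is estimated by regressing s on genotype, whose Wald t supplies
    the p-value (a Riemann approximation of the integral of
    beta_{1-tau} - beta_tau over tau in (0, 0.5)).  ``inference='permutation'``
    replaces the t-test with a genotype-permutation p-value.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    n = y.size
    if n_quantiles <= 0:
        raise ValueError("n_quantiles must be a positive even integer")
    if n_quantiles % 2:
        raise ValueError("n_quantiles must be even so tau levels pair across 0.5")
    n_regressors = 2 + (0 if covariates is None else np.atleast_2d(covariates).shape[-1])
    if n < 50 * n_regressors:
        raise ValueError(f"quail requires n >= {50 * n_regressors} for {n_regressors} regressors")
    taus = np.arange(1, n_quantiles + 1) / (n_quantiles + 1.0)
    lower = taus[taus < 0.5]

    if covariates is None or not np.size(covariates):
        q_lo = np.quantile(y, lower)
        q_hi = np.quantile(y, 1.0 - lower)
        qhat_lo = np.broadcast_to(q_lo[:, None], (lower.size, n))
        qhat_hi = np.broadcast_to(q_hi[:, None], (lower.size, n))
    else:
        from statsmodels.regression.quantile_regression import QuantReg

        X0 = build_design(n, covariates)
        qhat_lo = np.empty((lower.size, n))
        qhat_hi = np.empty((lower.size, n))
        for j, tau in enumerate(lower):
            for tgt, level in ((qhat_lo, tau), (qhat_hi, 1.0 - tau)):
                try:
                    fit = QuantReg(y, X0).fit(q=level)
                except Exception:
                    return TestResult("quail", np.nan, None, converged=False,
                                      note=f"quantile fit failed at tau={level:.4g}")
                tgt[j] = fit.predict(X0)

    a_lo = lower[:, None] - (y[None, :] <= qhat_lo)
    a_hi = (1.0 - lower)[:, None] - (y[None, :] <= qhat_hi)
    s = (a_hi - a_lo).mean(axis=0)

    X = build_design(n, covariates, g)
    idx = X.shape[1] - 1
    slope, t, p, dof = _ols_slope(X, s, idx=idx)
    if inference == "permutation":
        rng = np.random.default_rng(seed)
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        hits = 0
        for _ in range(n_perm):
            Xp = X.copy()
            Xp[:, idx] = rng.permutation(X[:, idx])
            perm_slope, *_ = _ols_slope(Xp, s, idx=idx)
            if abs(perm_slope) >= abs(slope):
                hits += 1
        p = (1.0 + hits) / (n_perm + 1.0)
    return TestResult("quail", t, p, effect_size=slope, df=dof)


def dglm_test(
    y: np.ndarray,
    g: np.ndarray,
    covariates: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> TestResult:
    """Double generalized linear model (mean-variance joint test).

    Alternates (a) weighted least squares for the mean submodel
    y ~ 1 + g + covariates with weights 1/phi_i, and (b) a gamma-family
    log-link GLM for the dispersion submodel: leverage-corrected squared
    mean-model residuals e_i^2/(1-h_i) regressed on 1 + g with prior weights
    (1-h_i)/2, following the standard double-GLM construction.  Iterates
    until the dispersion-model deviance changes by less than ``tol``.  The
    reported test is the Wald test of the genotype coefficient in the
    dispersion submodel (gamma dispersion fixed at its asymptotic value 2,
    already folded into the prior weights); that coefficient is the effect
    size.  Non-convergence yields converged=False with p absent.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    n = y.size
    Xm = build_design(n, covariates, g)
    _check_full_rank(Xm)
    Xd = build_design(n, None, g)
    k = Xm.shape[1]
    if n <= 2 * (k + 2):
        raise ValueError("dglm requires n > 2 * (regressors + 2)")
    if max_iter == 0:
        return TestResult("dglm", np.nan, None, converged=False, note="max_iter=0")

    phi = np.ones(n)
    dev_old = np.inf
    gamma_fit = None
    converged = False
    for _ in range(max_iter):
        w = 1.0 / phi
        WX = Xm * w[:, None]
        xtwx = Xm.T @ WX
        beta = np.linalg.solve(xtwx, WX.T @ y)
        resid = y - Xm @ beta
        # leverages of the weighted hat matrix
        M = np.linalg.solve(xtwx, Xm.T)
        h = w * np.einsum("ij,ji->i", Xm, M)
        h = np.clip(h, 0.0, 1.0 - 1e-8)
        d = resid**2 / (1.0 - h)
        if np.allclose(d, 0.0):
            return TestResult("dglm", 0.0, 1.0, effect_size=0.0, note="deterministic trait")
        d = np.maximum(d, 1e-12 * d.mean())
        prior_w = (1.0 - h) / 2.0
        model = sm.GLM(d, Xd, family=sm.families.Gamma(link=sm.families.links.Log()),
                       var_weights=prior_w)
        try:
            gamma_fit = model.fit(scale=1.0)
        except Exception as exc:  # numerical failure inside IRLS
            return TestResult("dglm", np.nan, None, converged=False, note=f"dispersion fit failed: {exc}")
        phi = np.asarray(gamma_fit.mu)
        dev = float(gamma_fit.deviance)
        if abs(dev - dev_old) < tol * (1.0 + abs(dev)):
            converged = True
            break
        dev_old = dev
    if not converged or gamma_fit is None:
        return TestResult("dglm", np.nan, None, converged=False, note="iteration cap reached")
    coef = float(gamma_fit.params[-1])
    se = float(gamma_fit.bse[-1])
    if se == 0.0 or not np.isfinite(se):
        return TestResult("dglm", 0.0, 1.0, effect_size=coef, note="degenerate dispersion fit")
    z = coef / se
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult("dglm", float(z), float(p), effect_size=coef, df=1)


_DISPATCH = {
    "levene": lambda y, g, cov, kw: center_distance_anova(y, g, center="mean"),
    "bf": lambda y, g, cov, kw: center_distance_anova(y, g, center="median"),
    "bartlett": lambda y, g, cov, kw: bartlett_test(y, g),
    "fk": lambda y, g, cov, kw: fligner_killeen_test(y, g),
    "svlm": lambda y, g, cov, kw: svlm_test(y, g, cov),
    "cls": lambda y, g, cov, kw: cls_test(y, g, cov),
    "drm": lambda y, g, cov, kw: drm_test(y, g),
    "zscore": lambda y, g, cov, kw: zscore_test(y, g),
    "quail": lambda y, g, cov, kw: quail_test(y, g, cov, **kw),
    "dglm": lambda y, g, cov, kw: dglm_test(y, g, cov, **kw),
}


def run_method(
    name: str,
    y: np.ndarray,
    g: np.ndarray,
    covariates: np.ndarray | None = None,
    plan: PreprocessPlan | None = None,
    **kwargs,
) -> TestResult:
    """Preprocess per plan, then dispatch to the named method.

    With ``plan.adjust_exposure`` the exposure covariates are regressed out
    of the trait before testing — except for SVLM and CLS, whose own
    first-stage regression absorbs both genotype and exposure, so the
    covariates are forwarded into the test instead.  ``plan.apply_int``
    additionally rank-INT-transforms the residuals for every method except
    the Z-score test (which transforms internally).
    """
    if name not in _DISPATCH:
        raise ValueError(f"unknown method {name!r}; valid ids: {', '.join(METHOD_NAMES)}")
    if plan is None:
        plan = PreprocessPlan()
    y = np.asarray(y, dtype=float)
    cov = covariates
    if plan.adjust_exposure and cov is not None and np.size(cov):
        if name in ("svlm", "cls"):
            pass  # exposure joins the test's own stage-1 design: y ~ 1 + g + E
        else:
            y = adjust_covariates(y, cov, g=g if plan.adjust_genotype else None)
            cov = None
    else:
        cov = None
    if plan.apply_int and name != "zscore":
        y = rank_int(y)
    result = _DISPATCH[name](y, g, cov, kwargs)
    result.method = name
    return result


def batch_run(triplets, methods, plan: PreprocessPlan | None = None):
    """Run several methods over (y, g, covariates) triplets.

    Returns a pandas DataFrame with one row per (triplet, method):
    columns method, statistic, p_value, effect_size, converged.
    """
    import pandas as pd

    rows = []
    for i, (y, g, cov) in enumerate(triplets):
        for m in methods:
            res = run_method(m, y, g, cov, plan=plan)
            rows.append(
                {
                    "triplet": i,
                    "method": res.method,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "effect_size": res.effect_size,
                    "converged": res.converged,
                }
            )
    return pd.DataFrame(rows)
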