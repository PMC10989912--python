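"""Covariate adjustment and normalization applied before variance testing.

Two preprocessing routes feed the tests: residualize the trait on the
exposure (most methods), or hand the exposure to the test's own first-stage
regression together with genotype (SVLM/CLS).  A rank-based inverse normal
transform (INT) of the residuals is available to reproduce the
normalization-inflation experiment; it is never combined with the Z-score
test, which already transforms internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

__all__ = ["PreprocessPlan", "adjust_covariates", "rank_int", "build_design"]


@dataclass(frozen=True)
class PreprocessPlan:
    """Which preprocessing route to apply before a test.

    adjust_exposure: residualize on the exposure (or include it in the
        test's first stage for SVLM/CLS); False models the unobserved-exposure
        setting where the raw trait enters the tests.
    adjust_genotype: include genotype among the adjustment covariates
        (the SVLM/CLS first-stage route).
    apply_int: rank-inverse-normal transform the residuals (all methods
        except the Z-score test).
    """

    adjust_exposure: bool = True
    adjust_genotype: bool = False
    apply_int: bool = False


def build_design(
    n: int,
    covariates: np.ndarray | None = None,
    g: np.ndarray | None = None,
) -> np.ndarray:
    """Stack an intercept, optional covariate columns, and optional genotype."""
    cols = [np.ones(n)]
    if covariates is not None and np.size(covariates):
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError(f"covariate rows ({cov.shape[0]}) do not match y ({n})")
        cols.extend(cov.T)
    if g is not None:
        cols.append(np.asarray(g, dtype=float))
    return np.column_stack(cols)


def _check_full_rank(X: np.ndarray) -> None:
    # QR diagonal exposes which column is linearly dependent on its predecessors
    r_diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
    tol = X.shape[0] * np.finfo(float).eps * max(r_diag.max(), 1.0)
    bad = np.nonzero(r_diag <= tol)[0]
    if bad.size:
        raise ValueError(
            f"design matrix is rank-deficient: column {bad[0]} is collinear with earlier columns"
        )


def adjust_covariates(
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    g: np.ndarray | None = None,
) -> np.ndarray:
    """OLS residuals of y on an intercept plus covariates (plus genotype).

    With no covariates this is mean-centering.  Residuals are exactly
    orthogonal to every regressor; re-adjusting them on the same design is a
    no-op.  A rank-deficient design raises, naming the collinear column.
    """
    y = np.asarray(y, dtype=float)
    X = build_design(len(y), covariates, g)
    _check_full_rank(X)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def rank_int(y: np.ndarray, offset: Literal["half", "blom"] = "half") -> np.ndarray:
    """Rank-based inverse normal transform.

    Maps average-tied ranks r through the standard normal quantile function:
    ``half`` uses (r - 0.5)/n, ``blom`` uses (r - 3/8)/(n + 1/4).  Strictly
    monotone on untied inputs, antisymmetric (rank_int(-y) == -rank_int(y)),
    and zero-mean by symmetry of the offsets.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("rank_int requires at least 3 observations")
    if np.all(y == y[0]):
        raise ValueError("rank_int undefined for a constant vector (no ordering information)")
    r = stats.rankdata(y, method="average")
    n = y.size
    if offset == "half":
        q = (r - 0.5) / n
    elif offset == "blom":
        q = (r - 3.0 / 8.0) / (n + 0.25)
    else:
        raise ValueError(f"unknown INT offset {offset!r}")
    return stats.norm.ppf(q)
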