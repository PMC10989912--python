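"""Cohort simulation under a single-locus gene-by-environment trait model.

A quantitative trait is generated as a convex combination of four component
terms, each min-max normalized to [0, 1] before weighting::

    y = a_mean * G  +  a_env * E  +  a_var * (G x E)  +  a_error * error

``G`` is the additive genotype code at one biallelic locus (0/1/2 copies of
the minor allele, Hardy-Weinberg group sizes), ``E`` an environmental
exposure (binary, uniform(20, 70) or normal(25, 3)), ``G x E`` the
elementwise product of the raw genotype and exposure codes, and ``error`` a
noise draw (normal, chi-squared or gamma).  The four weights sum to one.

A variant with ``a_var > 0`` is a true variance QTL: the interaction spreads
the trait differently across genotype groups.  For binary exposures the
exposed/unexposed categories can be encoded so that the *expected* trait
mean is identical in every genotype group ("variance-only" design): with an
exposed fraction f the codes are ((1 - f)/f, -1), e.g. (9, -1) at f = 0.1,
which zeroes the exposure-weighted mean of the interaction term.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "ExposureSpec",
    "ErrorSpec",
    "SimulationScenario",
    "SimulatedCohort",
    "minmax",
    "binary_exposure_encoding",
    "simulate_genotypes",
    "simulate_exposure",
    "simulate_trait",
    "export_cohort",
]


def minmax(v: np.ndarray) -> np.ndarray:
    """Rescale a vector to [0, 1] by its realized extremes.

    A constant vector maps to all zeros rather than raising: scenarios with
    a zero weight on a term (e.g. ``a_mean = 0``) may legitimately produce
    constant components and must degrade gracefully.  The map is invariant
    under positive affine transforms: ``minmax(a*v + b) == minmax(v)`` for
    ``a > 0``.
    """
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("minmax: empty vector")
    lo = v.min()
    hi = v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def binary_exposure_encoding(f_exposed: float) -> tuple[float, float]:
    """Exposure codes for the variance-only binary design.

    The unexposed category is fixed at -1 and the exposed category at
    ``(1 - f)/f``, so the exposure-weighted mean ``f*x_exp + (1-f)*x_unexp``
    is zero and the expected genotype-group means of the interaction term
    coincide.  At f = 0.1 this is the (9, -1) encoding; at f = 0.5 it is
    (1, -1).
    """
    if not 0.0 < f_exposed < 1.0:
        raise ValueError(f"exposed fraction must be in (0, 1), got {f_exposed}")
    return (1.0 - f_exposed) / f_exposed, -1.0


@dataclass(frozen=True)
class ExposureSpec:
    """Distribution of the environmental exposure E.

    kind 'binary' uses ``f_exposed`` (and the variance-only encoding when
    ``encode_variance_only``); 'uniform' uses [low, high]; 'normal' uses
    (mu, sd).  Defaults follow the study conditions: uniform(20, 70),
    normal(25, 3).
    """

    kind: Literal["binary", "uniform", "normal"]
    f_exposed: float = 0.1
    low: float = 20.0
    high: float = 70.0
    mu: float = 25.0
    sd: float = 3.0
    encode_variance_only: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "uniform", "normal"):
            raise ValueError(f"unknown exposure kind {self.kind!r}")
        if self.kind == "binary" and not 0.0 < self.f_exposed < 1.0:
            raise ValueError("binary exposure requires 0 < f_exposed < 1")
        if self.kind == "uniform" and not self.low < self.high:
            raise ValueError("uniform exposure requires low < high")
        if self.kind == "normal" and not self.sd > 0:
            raise ValueError("normal exposure requires sd > 0")
        if self.encode_variance_only and self.kind != "binary":
            raise ValueError("variance-only encoding applies to binary exposures only")


@dataclass(frozen=True)
class ErrorSpec:
    """Distribution of the error term: normal, chi-squared(df) or gamma.

    Gamma parameters are shape/rate as in R's rgamma; defaults (2, 0.5).
    The scale of the draw is irrelevant downstream because every component
    is min-max normalized before weighting.
    """

    kind: Literal["normal", "chisq", "gamma"] = "normal"
    df: float = 1.0
    shape: float = 2.0
    rate: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "chisq", "gamma"):
            raise ValueError(f"unknown error kind {self.kind!r}")
        if self.kind == "chisq" and not self.df > 0:
            raise ValueError("chisq error requires df > 0")
        if self.kind == "gamma" and not (self.shape > 0 and self.rate > 0):
            raise ValueError("gamma error requires shape > 0 and rate > 0")


@dataclass(frozen=True)
class SimulationScenario:
    """Full parameterization of one generative setting.

    ``a_env`` is implicit: weights satisfy a_mean + a_env + a_var + a_error = 1,
    so ``a_env = 1 - a_mean - a_var - a_error`` and must be nonnegative.
    ``genetic_exposure`` switches to the genetically associated exposure
    E1 = E + a_mean * G (raw scales).  ``interact_flipped`` interacts with the
    complementary allele count (2 - g) instead of g; min-max normalization
    absorbs affine relabelings of G itself, so only the interaction term is
    affected.
    """

    n: int
    maf: float
    a_mean: float
    a_var: float
    a_error: float = 0.2
    exposure: ExposureSpec = field(default_factory=lambda: ExposureSpec(kind="binary"))
    error: ErrorSpec = field(default_factory=ErrorSpec)
    genetic_exposure: bool = False
    interact_flipped: bool = False
    min_group: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3 * self.min_group:
            raise ValueError(f"n={self.n} cannot host three genotype groups of >= {self.min_group}")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")
        for name in ("a_mean", "a_var", "a_error"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.a_env < -1e-12:
            raise ValueError(
                "weights must sum to <= 1: a_mean + a_var + a_error = "
                f"{self.a_mean + self.a_var + self.a_error:.6g} > 1"
            )

    @property
    def a_env(self) -> float:
        return 1.0 - self.a_mean - self.a_var - self.a_error


@dataclass
class SimulatedCohort:
    """One realized dataset plus its four normalized component terms."""

    y: np.ndarray
    g: np.ndarray
    e_raw: np.ndarray
    terms: dict[str, np.ndarray]  # keys: genotype, exposure, interaction, error
    scenario: SimulationScenario


def _hwe_proportions(maf: float) -> np.ndarray:
    # index = minor allele count
    return np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])


def _expected_counts(n: int, maf: float, min_group: int) -> np.ndarray:
    """Largest-remainder rounding of Hardy-Weinberg group sizes, floored at min_group.

    The floor is taken from the largest class so the total stays n.
    """
    raw = n * _hwe_proportions(maf)
    counts = np.floor(raw).astype(int)
    frac = raw - counts
    for i in np.argsort(-frac)[: n - counts.sum()]:
        counts[i] += 1
    while (deficit := counts < min_group).any():
        i = int(np.argmax(deficit))
        need = min_group - counts[i]
        counts[i] += need
        counts[int(np.argmax(counts))] -= need
    if counts.min() < min_group:
        raise ValueError(f"cannot allocate {min_group} samples per genotype group out of n={n}")
    return counts


def simulate_genotypes(
    n: int,
    maf: float,
    min_group: int = 10,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    mode: Literal["expected", "multinomial"] = "expected",
    max_attempts: int = 1000,
) -> np.ndarray:
    """Genotype vector (minor allele counts 0/1/2) under Hardy-Weinberg proportions.

    Every genotype class contains at least ``min_group`` samples.  The default
    'expected' mode fixes the class sizes at their (rounded) HWE expectations,
    floored at ``min_group`` — sample size and allele frequency determine the
    group sizes, and the constraint always holds.  Mode 'multinomial' draws
    class sizes multinomially and rejection-resamples whole vectors until the
    constraint holds; when the expected minor-homozygote count is far below
    ``min_group`` (e.g. n=1000, maf=0.05: expectation 2.5) rejection cannot
    realistically succeed and the attempt cap raises instead.
    """
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    if n < 3 * min_group:
        raise ValueError(f"n={n} cannot host three genotype groups of >= {min_group}")
    if rng is None:
        rng = np.random.default_rng(seed)
    if mode == "expected":
        counts = _expected_counts(n, maf, min_group)
    elif mode == "multinomial":
        props = _hwe_proportions(maf)
        for _ in range(max_attempts):
            counts = rng.multinomial(n, props)
            if counts.min() >= min_group:
                break
        else:
            raise RuntimeError(
                f"rejection sampling failed after {max_attempts} attempts: expected "
                f"minor-homozygote count maf^2*n = {maf**2 * n:.2f} is incompatible "
                f"with min_group={min_group}"
            )
    else:
        raise ValueError(f"unknown genotype sampling mode {mode!r}")
    g = np.repeat(np.arange(3), counts)
    rng.shuffle(g)
    return g


def simulate_exposure(
    spec: ExposureSpec,
    n: int,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    g: np.ndarray | None = None,
    a_mean: float = 0.0,
    genetic_exposure: bool = False,
) -> np.ndarray:
    """Exposure vector on its native (raw) scale.

    Binary exposures assign exactly ``round(f_exposed * n)`` samples to the
    exposed code in randomized order, so the stated category proportions hold
    exactly; continuous exposures are i.i.d. draws and proportions are not
    controlled.  With ``genetic_exposure`` the returned vector is
    E1 = E + a_mean * G on raw scales.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if spec.kind == "binary":
        n_exposed = int(round(spec.f_exposed * n))
        if not 0 < n_exposed < n:
            raise ValueError(f"f_exposed={spec.f_exposed} leaves an empty exposure category at n={n}")
        if spec.encode_variance_only:
            code_exposed, code_unexposed = binary_exposure_encoding(spec.f_exposed)
        else:
            code_exposed, code_unexposed = 1.0, 0.0
        e = np.full(n, code_unexposed)
        e[:n_exposed] = code_exposed
        rng.shuffle(e)
    elif spec.kind == "uniform":
        e = rng.uniform(spec.low, spec.high, n)
    else:
        e = rng.normal(spec.mu, spec.sd, n)
    if genetic_exposure:
        if g is None:
            raise ValueError("genetic_exposure requires the genotype vector")
        e = e + a_mean * np.asarray(g, dtype=float)
    return e


def _draw_error(spec: ErrorSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.kind == "normal":
        return rng.standard_normal(n)
    if spec.kind == "chisq":
        return rng.chisquare(spec.df, n)
    return rng.gamma(spec.shape, 1.0 / spec.rate, n)


def simulate_trait(scenario: SimulationScenario, seed: int | None = None) -> SimulatedCohort:
    """Realize one cohort: genotypes, exposure, interaction, error, and trait.

    Each of the four component terms is min-max normalized independently and
    the trait is their weighted sum with weights
    (a_mean, a_env, a_var, a_error).  Fully reproducible from the seed
    (``seed`` overrides ``scenario.seed``).
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    g = simulate_genotypes(scenario.n, scenario.maf, scenario.min_group, rng=rng)
    g_int = (2 - g) if scenario.interact_flipped else g
    e_raw = simulate_exposure(
        scenario.exposure,
        scenario.n,
        rng=rng,
        g=g_int,
        a_mean=scenario.a_mean,
        genetic_exposure=scenario.genetic_exposure,
    )
    err = _draw_error(scenario.error, scenario.n, rng)
    terms = {
        "genotype": minmax(g_int.astype(float)),
        "exposure": minmax(e_raw),
        "interaction": minmax(g_int * e_raw),
        "error": minmax(err),
    }
    y = (
        scenario.a_mean * terms["genotype"]
        + scenario.a_env * terms["exposure"]
        + scenario.a_var * terms["interaction"]
        + scenario.a_error * terms["error"]
    )
    return SimulatedCohort(y=y, g=g, e_raw=e_raw, terms=terms, scenario=scenario)


def export_cohort(cohort: SimulatedCohort, path: str) -> None:
    """Write a cohort as plain TSV with columns sample_id, y, g, e_raw."""
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i:06d}" for i in range(len(cohort.y))],
            "y": cohort.y,
            "g": cohort.g,
            "e_raw": cohort.e_raw,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def null_scenario(**overrides) -> SimulationScenario:
    """Convenience constructor for the fully null binary-exposure setting."""
    defaults = dict(
        n=1000,
        maf=0.05,
        a_mean=0.0,
        a_var=0.0,
        a_error=0.2,
        exposure=ExposureSpec(kind="binary", f_exposed=0.1, encode_variance_only=True),
        error=ErrorSpec(kind="normal"),
    )
    defaults.update(overrides)
    return SimulationScenario(**defaults)


# The study's default parameter grids.
GRID_N = (500, 1_000, 5_000, 10_000, 20_000, 50_000, 100_000, 200_000)
GRID_MAF = (0.05, 0.1, 0.2, 0.3)
GRID_F_EXPOSED = (0.1, 0.3, 0.5)
GRID_EFFECT = (0.0, 0.005, 0.01, 0.03, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4)
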