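"""Canonical study settings for the headline benchmark experiments.

Thin constructors for the scenarios the benchmark revolves around: the
fully null discrete-exposure setting, variance-only designs for the power
analysis (binary, uniform and normal exposures), and mean-only settings
for the inflation experiments.  Defaults are the study conditions
(a_error = 0.2, MAF 0.05, 10%/90% exposure split).
"""

from __future__ import annotations

from .simulate import ErrorSpec, ExposureSpec, SimulationScenario

__all__ = [
    "null_discrete",
    "variance_only_binary",
    "variance_only_uniform",
    "variance_only_normal",
    "mean_only_binary",
]


def _binary(f_exposed: float) -> ExposureSpec:
    return ExposureSpec(kind="binary", f_exposed=f_exposed, encode_variance_only=True)


def null_discrete(
    n: int = 1000,
    maf: float = 0.05,
    f_exposed: float = 0.1,
    error: ErrorSpec | None = None,
) -> SimulationScenario:
    """No genetic effect on mean or variance; binary exposure."""
    return SimulationScenario(
        n=n, maf=maf, a_mean=0.0, a_var=0.0, a_error=0.2,
        exposure=_binary(f_exposed), error=error or ErrorSpec(kind="normal"),
    )


def variance_only_binary(
    a_var: float,
    n: int,
    maf: float = 0.05,
    f_exposed: float = 0.1,
    error: ErrorSpec | None = None,
) -> SimulationScenario:
    """Variance-only vQTL: zero-mean binary encoding, a_mean = 0."""
    return SimulationScenario(
        n=n, maf=maf, a_mean=0.0, a_var=a_var, a_error=0.2,
        exposure=_binary(f_exposed), error=error or ErrorSpec(kind="normal"),
    )


def variance_only_uniform(a_var: float, n: int, maf: float = 0.05) -> SimulationScenario:
    """Variance-affecting vQTL with a uniform(20, 70) continuous exposure."""
    return SimulationScenario(
        n=n, maf=maf, a_mean=0.0, a_var=a_var, a_error=0.2,
        exposure=ExposureSpec(kind="uniform"),
    )


def variance_only_normal(a_var: float, n: int, maf: float = 0.05) -> SimulationScenario:
    """Variance-affecting vQTL with a normal(25, 3) continuous exposure."""
    return SimulationScenario(
        n=n, maf=maf, a_mean=0.0, a_var=a_var, a_error=0.2,
        exposure=ExposureSpec(kind="normal"),
    )


def mean_only_binary(
    a_mean: float,
    n: int = 1000,
    maf: float = 0.05,
    f_exposed: float = 0.1,
    error: ErrorSpec | None = None,
) -> SimulationScenario:
    """Mean-acting variant only (a_var = 0); used for the inflation experiments."""
    return SimulationScenario(
        n=n, maf=maf, a_mean=a_mean, a_var=0.0, a_error=0.2,
        exposure=_binary(f_exposed), error=error or ErrorSpec(kind="normal"),
    )
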