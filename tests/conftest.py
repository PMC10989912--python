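import numpy as np
import pytest

from vqtlbench.simulate import ErrorSpec, ExposureSpec, SimulationScenario


def mc_tol(rate: float, n_reps: int) -> float:
    """Monte-Carlo acceptance band half-width for a rate estimated over n_reps."""
    return max(0.03, 3.0 * np.sqrt(rate * (1.0 - rate) / n_reps))


@pytest.fixture
def binary10():
    return ExposureSpec(kind="binary", f_exposed=0.1, encode_variance_only=True)


@pytest.fixture
def null_binary(binary10):
    """Fully null setting: no genetic effect on mean or variance, normal errors."""
    return SimulationScenario(
        n=1000, maf=0.05, a_mean=0.0, a_var=0.0, a_error=0.2,
        exposure=binary10, error=ErrorSpec(kind="normal"),
    )
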