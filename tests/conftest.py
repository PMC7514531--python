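import numpy as np
import pytest

from etfe.glr_spc import ThresholdTable, calibrate_thresholds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_table() -> ThresholdTable:
    """A quickly calibrated table (ARL 100, H 60) for alarm-path tests."""
    return calibrate_thresholds(arl=100, H=60, reps=1000, seed=7, startup=10,
                                tail_horizon=150)


@pytest.fixture(scope="session")
def inf_table() -> ThresholdTable:
    """Thresholds at +inf: the chart can never alarm."""
    return ThresholdTable(arl=1e9, H=60, q0=11, deltas=np.full(50, np.inf),
                          delta_tail=float("inf"), reps=0, seed=0)
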