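import numpy as np
import pytest

from singlechan.gating import (
    GatingModel,
    hs_like_model,
    hyperexponential_model,
    ls_like_model,
)


@pytest.fixture(scope="session")
def two_state_model() -> GatingModel:
    """C <-> O with opening 100 /s and closing 500 /s.

    Closed dwell tau = 10 ms, open dwell tau = 2 ms.
    """
    Q = np.array([[-100.0, 100.0], [500.0, -500.0]])
    return GatingModel(
        state_names=["C", "O"],
        conductance_class=["closed", "open_small"],
        class_amplitude={"closed": 0.0, "open_small": 1.35},
        Q=Q,
    )


@pytest.fixture(scope="session")
def chain_model() -> GatingModel:
    """C1 <-> C2 <-> O chain with rates (10, 20, 500, 250) /s.

    C1 -> C2 at 10, C2 -> C1 at 20, C2 -> O at 500, O -> C2 at 250.
    """
    Q = np.array(
        [
            [-10.0, 10.0, 0.0],
            [20.0, -520.0, 500.0],
            [0.0, 250.0, -250.0],
        ]
    )
    return GatingModel(
        state_names=["C1", "C2", "O"],
        conductance_class=["closed", "closed", "open_small"],
        class_amplitude={"closed": 0.0, "open_small": 1.0},
        Q=Q,
    )


@pytest.fixture(scope="session")
def hs_model() -> GatingModel:
    return hs_like_model()


@pytest.fixture(scope="session")
def ls_model() -> GatingModel:
    return ls_like_model()


@pytest.fixture(scope="session")
def fast_burst_model() -> GatingModel:
    """Small scheme with brisk bursting for quick burst-analysis tests."""
    return hyperexponential_model(
        closed_components=[(0.8, 0.5), (80.0, 0.5)],
        open_components=[(2.0, 1.0)],
        amplitude_pA=1.35,
    )
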