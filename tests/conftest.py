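import numpy as np
import pytest

from motorexplore import (
    MODEL_SPECS,
    REFERENCE_PARAMS,
    ModelParams,
    TargetGeometry,
    simulate_session,
)


@pytest.fixture(scope="session")
def reference_geometry() -> TargetGeometry:
    """Target whose minor width follows the baseline-scaling rule at the
    reference motor-noise SD."""
    return TargetGeometry(minor_width=0.65 * REFERENCE_PARAMS.sigma_M_x)


@pytest.fixture(scope="session")
def reinforcement_session(reference_geometry):
    """One 200-trial reinforcement-condition session at the reference parameters."""
    return simulate_session(
        REFERENCE_PARAMS,
        MODEL_SPECS[1],
        "reinforcement",
        reference_geometry,
        n_trials=200,
        seed=1234,
    )


@pytest.fixture(scope="session")
def uniform_gain_params() -> ModelParams:
    """All four noise SDs at 0.5 cm and every gain at 0.5."""
    return ModelParams(*([0.5] * 10))
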