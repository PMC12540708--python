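import numpy as np
import pytest

from jnkdyn import (
    ExpressionProfile,
    ModelParameters,
    make_stimulus,
    minmax_scale,
    sample_target,
    simulate,
)

RNA_TIMES = [0.0, 2.0, 4.0, 6.0, 8.0]


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def alpha_grid() -> np.ndarray:
    return np.linspace(0.02, 1.4, 200)


@pytest.fixture(scope="session")
def make_profile(params):
    """Factory: scaled 5-point expression profile generated from the model."""

    def _make(condition, alpha_m, variant="mass_action", K=None, n_target=1.8, tau=0.0):
        overrides = {"alpha_m": alpha_m}
        if K is not None:
            overrides.update(K=K, n_target=n_target)
        if tau:
            overrides["tau"] = tau
        traj = simulate(params.with_(**overrides), make_stimulus(condition),
                        variant=variant)
        values = minmax_scale(sample_target(traj, RNA_TIMES))
        return ExpressionProfile(condition, tuple(values))

    return _make
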