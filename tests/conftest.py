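import numpy as np
import pytest

import dropphage as dp


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260)


@pytest.fixture(scope="session")
def two_mode_emulsion():
    """Mid-occupancy single-alpha emulsion with well-separated green modes."""
    spec = dp.EmulsionSpec(
        n_droplets=50_000, alpha_mode="fixed", alpha_values=0.5,
        volume_modes=((50.0, 1.0),), c_p=2e7, c_b_nominal=1.6e9, seed=7,
    )
    events, truth = dp.simulate_emulsion(spec)
    return spec, events, truth


@pytest.fixture(scope="session")
def saturated_lambda_b_spec():
    """alpha = 0.5, V = 50 pL, lambda_b ~ 40, lambda_p = 0.5."""
    return dp.EmulsionSpec(
        n_droplets=200_000, alpha_mode="fixed", alpha_values=0.5,
        volume_modes=((50.0, 1.0),), c_p=2e7, c_b_nominal=1.6e9, seed=11,
    )
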