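import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from oligokin import mds, synthetic

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

SEED = 12345


@pytest.fixture(scope="session")
def cal3():
    """Default range-3 channel calibration (3 nm anchor at 0.42)."""
    return mds.default_calibration(3)


@pytest.fixture(scope="session")
def fig4d_points():
    return synthetic.generate_titrations(
        synthetic.ScenarioConfig("fig4d", seed=SEED)
    )


@pytest.fixture(scope="session")
def fig3a_traces():
    return synthetic.generate_kinetics(
        synthetic.ScenarioConfig("fig3a", seed=SEED)
    )


@pytest.fixture(scope="session")
def noiseless(request):
    """Factory for noiseless scenario configs."""
    def make(scenario_id, **overrides):
        return synthetic.ScenarioConfig(
            scenario_id, seed=SEED,
            noise={"tht": 0.0, "fraction": 0.0, "r_h": 0.0, "saxs_frac": 0.0},
            overrides=overrides,
        )
    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
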