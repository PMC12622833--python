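import numpy as np
import pytest

from gaitbench import MuscleParams, SynthConfig, gen_gait_trial


@pytest.fixture(scope="session")
def generic_muscle() -> MuscleParams:
    """A generic lower-limb-scale test muscle."""
    return MuscleParams(name="generic", f_iso_max=3000.0, l_opt=0.10,
                        l_tendon_slack=0.20, alpha_opt=0.10, frac_slow=0.5)


@pytest.fixture(scope="session")
def unpennated_muscle() -> MuscleParams:
    return MuscleParams(name="flat", f_iso_max=1000.0, l_opt=0.08,
                        l_tendon_slack=0.16, alpha_opt=0.0, frac_slow=0.3)


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """Down-scaled generator config for fast tests (structure unchanged)."""
    return SynthConfig(seed=42, n_muscles=6, n_timesteps=81)


@pytest.fixture(scope="session")
def small_trial(small_cfg):
    return gen_gait_trial(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
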