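import numpy as np
import pytest

from dimerdyn import mc_sim

# Paper-derived study conditions used across the suite
K_ON = 0.081  # um^2/s
K_OFF = 0.58  # 1/s
D_MON = 1.63
D_DIM = 1.27
COLLISION_DIAMETER = 0.005  # um

# coarsest elementary step preserving encounter resolution (rms step =
# half the collision diameter); used for production-scale runs
DT_COARSE = mc_sim.max_allowed_timestep(D_MON, COLLISION_DIAMETER)


def make_config(**kw):
    kw.setdefault("D_mon", D_MON)
    kw.setdefault("D_dim", D_DIM)
    kw.setdefault("k_off", K_OFF)
    kw.setdefault("dT", DT_COARSE)
    return mc_sim.SimulationConfig(**kw)


@pytest.fixture(scope="session")
def calibration():
    """Collision probability calibrated once per session to k_on = 0.081."""
    base = make_config(n_particles=300, density=5.0, p_collision=0.0,
                      k_off=0.0, duration=1.0, seed=0)
    return mc_sim.calibrate_collision_probability(K_ON, base, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
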