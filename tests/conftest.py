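import numpy as np
import pytest

import polwater as pw


@pytest.fixture(scope="session")
def ff():
    return pw.ForceField("polarizable")


@pytest.fixture(scope="session")
def small_water(ff):
    """Equilibrated-ish 27-bead box in a roomy cell (decohered satellites)."""
    system = pw.build_water_box(27, 120.0, seed=7)
    protocol = pw.Protocol(ensemble="NVT", n_steps=200, T_target=300, seed=7)
    final, _, _ = pw.run_md(system, ff, protocol)
    return final


@pytest.fixture(scope="session")
def short_nvt(ff):
    """216-bead NVT run shared by engine/observable contract tests."""
    system = pw.build_water_box(216, 1043.0, seed=5)
    protocol = pw.Protocol(ensemble="NVT", n_steps=3000, T_target=300,
                           seed=5, traj_stride=50, log_stride=10)
    return pw.run_md(system, ff, protocol)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
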