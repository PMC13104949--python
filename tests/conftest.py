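import numpy as np
import pytest

from bindkin.synthetic import (LangevinMetadSpec, ToySystemSpec,
                               gen_toy_complex_trajectory, run_langevin_metad)


@pytest.fixture(scope="session")
def metad_run():
    """One well-tempered toy run on the default 6 kcal/mol double well,
    shared across reweighting tests (the acceptance test runs its own)."""
    return run_langevin_metad(LangevinMetadSpec(n_steps=400_000, seed=11))


@pytest.fixture(scope="session")
def bound_complex():
    topo, traj = gen_toy_complex_trajectory(ToySystemSpec(seed=0))
    return topo, traj


@pytest.fixture(scope="session")
def escaping_complex():
    topo, traj = gen_toy_complex_trajectory(
        ToySystemSpec(ligand_motion_model="escaping", seed=1))
    return topo, traj


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
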