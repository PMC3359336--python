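import numpy as np
import pytest

from pocketlig import synthetic as syn


@pytest.fixture(scope="session")
def binding_site():
    """Synthetic tripartite binding-site model + planted ground truth."""
    return syn.make_binding_site_model(seed=0)


@pytest.fixture(scope="session")
def cage():
    return syn.make_cage(inner_radius=8.0, atom_radius=1.5, n_shell_atoms=1600,
                         seed=0, probe_radius=1.4)


@pytest.fixture(scope="session")
def lbp_model():
    return syn.make_lbp_model(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
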