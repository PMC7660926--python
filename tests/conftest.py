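import pytest

from stabscan.energy import ScorerSpec
from stabscan.ddg import ProtocolConfig
from stabscan.synthetic import (SyntheticStructureSpec, make_ideal_helix,
                                make_two_helix_bundle)


@pytest.fixture(scope="session")
def helix20():
    return make_ideal_helix(20)


@pytest.fixture(scope="session")
def helix21():
    return make_ideal_helix(21)


@pytest.fixture(scope="session")
def bundle():
    """(structure, ground-truth classes) for the packed two-helix bundle."""
    return make_two_helix_bundle(SyntheticStructureSpec())


@pytest.fixture()
def fast_spec():
    """Builtin scorer with few descent steps: protocol tests, not physics."""
    return ScorerSpec(params={"max_steps": 6})


@pytest.fixture()
def fast_cfg():
    """Small ensembles for protocol-shape tests (counts asserted elsewhere)."""
    return ProtocolConfig(n_models=3, n_traj=2, n_iter_missense=2, master_seed=11)
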