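import numpy as np
import pytest

import avmnet as av


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def atlas20():
    return av.make_synthetic_atlas(20)


@pytest.fixture(scope="session")
def atlas90():
    return av.make_synthetic_atlas(90)


@pytest.fixture(scope="session")
def template_sc40():
    """Connected 40-node synthetic structural connectome (fixed seed)."""
    cfg = av.SynthConfig(n_nodes=40, rng_seed=11)
    return av.gen_structural_connectome(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny full cohort shared across tests (8 patients + 10 controls)."""
    cfg = av.SynthConfig(n_nodes=40, n_patients=8, n_controls=10, rng_seed=3)
    return av.gen_cohort(cfg)


def make_matrix(weights, modality="SC", **kw):
    return av.ConnectivityMatrix(weights=np.asarray(weights, dtype=float),
                                 modality=modality, **kw)


@pytest.fixture
def matrix_factory():
    return make_matrix
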