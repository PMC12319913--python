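import numpy as np
import pytest

from phvaspec import acetone_like_spec, make_cluster, with_coupling


@pytest.fixture(scope="session")
def acetone_spec():
    """Coupled acetone-like cluster spec (20 environment atoms)."""
    return acetone_like_spec(n_env=20, k_c=0.01)


@pytest.fixture(scope="session")
def decoupled_spec(acetone_spec):
    return with_coupling(acetone_spec, 0.0)


@pytest.fixture(scope="session")
def decoupled_snapshot(decoupled_spec):
    """Unperturbed zero-coupling snapshot + full-system Hessian."""
    return make_cluster(decoupled_spec, seed=None)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_rotation(rng):
    """Haar-ish random proper rotation matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
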