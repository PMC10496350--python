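import numpy as np
import pytest

from fcg import keys
from fcg.backend import backend_from_bundle
from fcg.collab import SharedSpace, make_site_contexts
from fcg.params import emulated_params, toy_params

TOY_N = 256
N_SITES = 3


@pytest.fixture(scope="session")
def toy_bundle():
    """Small real-RLWE key bundle shared by the whole session."""
    params = toy_params(n_sites=N_SITES, poly_degree=TOY_N, depth=6)
    return keys.make_key_bundle(params, seed=2024, keep_master=True)


@pytest.fixture(scope="session")
def emu_bundle():
    params = emulated_params(n_sites=N_SITES, poly_degree=1024, depth=6)
    return keys.make_key_bundle(
        params, seed=2024, keep_master=True, with_eval_keys=False
    )


@pytest.fixture(params=["emulated", "toy_ckks"])
def backend_kind(request):
    return request.param


@pytest.fixture
def bundle(backend_kind, toy_bundle, emu_bundle):
    return toy_bundle if backend_kind == "toy_ckks" else emu_bundle


@pytest.fixture
def backend(backend_kind, bundle):
    return backend_from_bundle(
        bundle, backend_kind, rng=np.random.default_rng(7)
    )


@pytest.fixture
def shares(bundle):
    return [
        keys.open_site_share(bundle, s, keys.default_passphrases(N_SITES)[s - 1])[0]
        for s in range(1, N_SITES + 1)
    ]


@pytest.fixture
def sites(backend_kind, bundle):
    return make_site_contexts(bundle, backend_kind, seed=99)


@pytest.fixture
def space(tmp_path):
    return SharedSpace(tmp_path / "shared", poll_interval=0.01, timeout=5.0)


def decrypt_oracle(em, backend, bundle):
    """Master-key decryption helper used across matrix tests."""
    from fcg.matrix import decrypt_matrix_with_master

    return decrypt_matrix_with_master(em, backend, bundle.master_key).values
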