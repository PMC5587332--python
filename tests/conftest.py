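import numpy as np
import pytest
from hypothesis import settings

import flexibal as fb

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def toy_spec_1d():
    # small, fast system reused across sampler/model tests
    return fb.ToyEnsembleSpec(n_structures=10, n_residues=12,
                              generative_dims=1, noise_sigma=0.02, rng_seed=2)


@pytest.fixture(scope="session")
def toy_ensemble_1d(toy_spec_1d):
    return fb.generate_toy_ensemble(toy_spec_1d)


@pytest.fixture(scope="session")
def fitted_1d(toy_ensemble_1d):
    ensemble, params = toy_ensemble_1d
    data = fb.build_data_matrix(ensemble)
    results = fb.GPLVM(data, n_latent=1).fit(seed=0)
    return results, params


@pytest.fixture(scope="session")
def rotamers():
    return fb.generate_toy_rotamer_set(2)


@pytest.fixture
def rigid_pair():
    """A structure and a rigidly rotated + translated copy."""
    s = fb.toy.hinged_helix(10, bend_deg=15.0)
    rng = np.random.default_rng(5)
    A = rng.standard_normal((3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = np.array([4.0, -2.5, 7.0])
    moved = s.coords.reshape(-1, 3) @ Q.T + t
    return s, s.with_coords(moved.reshape(-1, 4, 3))


def make_sampler_config(**kwargs):
    defaults = dict(n_chains=2, n_iterations=100, save_stride=10, burn_in=0,
                    rng_seed=0, design_positions=(0, 1, 2))
    defaults.update(kwargs)
    return fb.SamplerConfig(**defaults)
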