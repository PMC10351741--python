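import numpy as np
import pytest

from dockens.synthgen import (
    PlantParams,
    StackParams,
    build_ideal_stack,
    make_cleavage_ensemble,
    model_protease_specs,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    from scipy.spatial.transform import Rotation

    return Rotation.from_quat(q).as_matrix()


@pytest.fixture
def stack_factory():
    """Seeded in-register stack builder: (sequence, n_chains, sigma, seed)."""

    def make(sequence="SNFLNCYVSGFHPSDIEVDLLK", n_chains=5, sigma=0.0, seed=0):
        return build_ideal_stack(StackParams(
            sequence=sequence, n_chains=n_chains, noise_sigma=sigma, seed=seed))

    return make


@pytest.fixture
def planted_pose_factory():
    """Seeded planted cleavage ensemble builder with its specs and truth."""

    def make(substrate="KPAEFIRL", bond=5, n_models=200, bound_fraction=0.3,
             sigma=1.0, seed=0, **kwargs):
        params = PlantParams(
            substrate_sequence=substrate, planted_bond=bond, n_models=n_models,
            bound_fraction=bound_fraction, bound_noise_sigma=sigma, seed=seed,
            **kwargs)
        ensemble, truth = make_cleavage_ensemble(params)
        site, flap = model_protease_specs(bond)
        return ensemble, truth, site, flap

    return make
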