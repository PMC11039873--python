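import numpy as np
import pytest

from canalssm import CanalParams, PopulationSpec, STRAIGHT, generate_canal


@pytest.fixture(scope="session")
def cylinder_params():
    """Degenerate tube: straight circular cylinder, L=150 mm, d=12 mm."""
    return CanalParams(length_mm=150.0, curvature_radius_mm=STRAIGHT,
                       diameter_distal_mm=12.0, diameter_min_mm=12.0,
                       ellipticity_mm=0.0, z_min_frac=0.5, proximal_flare_mm=0.0)


@pytest.fixture(scope="session")
def cylinder_mesh(cylinder_params):
    return generate_canal(cylinder_params, 64, 75)


@pytest.fixture(scope="session")
def curved_params():
    """Bowed canal with Rc = 700 mm and the default profile."""
    return CanalParams(length_mm=150.0, curvature_radius_mm=700.0)


@pytest.fixture(scope="session")
def curved_mesh(curved_params):
    return generate_canal(curved_params, 64, 75)


@pytest.fixture(scope="session")
def default_mesh():
    return generate_canal(CanalParams(), 32, 61)


@pytest.fixture(scope="session")
def small_cohort_spec():
    """Coarse-resolution cohort used by several cross-module tests."""
    return PopulationSpec(n_subjects=10, seed=7,
                          n_circumferential=24, n_longitudinal=41)


def rng_for(test_seed: int) -> np.random.Generator:
    return np.random.default_rng(test_seed)
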