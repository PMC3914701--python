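"""Shared fixtures: all test data is generated, nothing is read from disk."""

from __future__ import annotations

import numpy as np
import pytest

from cardiatlas.core import Atlas, LandmarkSet, VolumeImage
from cardiatlas.phantom import PhantomSpec, generate_atlas_pool, generate_phantom


@pytest.fixture(scope="session")
def sphere_phantom():
    """Concentric-sphere shell r_endo=20, r_epi=30 mm at 1 mm isotropic."""
    spec = PhantomSpec(
        endo_semiaxes=(20.0, 20.0, 20.0),
        wall_thickness=10.0,
        base_fraction=2.0,  # untruncated closed shell
        noise_sd=0.0,
        rng_seed=7,
    )
    return generate_phantom(spec, (1.0, 1.0, 1.0)) + (spec,)


@pytest.fixture(scope="session")
def lv_phantom():
    """Truncated-ellipsoid LV-like phantom at coarse spacing (fast)."""
    spec = PhantomSpec(noise_sd=0.0, rng_seed=3)
    return generate_phantom(spec, (2.0, 2.0, 2.0)) + (spec,)


@pytest.fixture(scope="session")
def atlas_pool_small():
    """Five noisy phantom atlases at 2.5 mm spacing."""
    return generate_atlas_pool(
        PhantomSpec(noise_sd=20.0), n_atlases=5, rng_seed=11, spacing=(2.5, 2.5, 2.5)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
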