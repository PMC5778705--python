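"""Shared fixtures: phantoms at unit-test scale and at study scale.

The study-scale atlas (0.1 mm, 128^3) matches the generator defaults and
is built once per session; unit tests use a smaller, faster spiral.
"""

import numpy as np
import pytest

from cochmetric.imaging import FiducialSet
from cochmetric.phantom import (
    DeformationSpec,
    PhantomSpec,
    generate_phantom,
    make_target,
    phantom_atlas_bundle,
    sample_deformation,
)
from cochmetric.registration import RegistrationConfig

#: small spiral for fast unit tests (not the study conditions)
SMALL_SPEC = PhantomSpec(
    basal_radius=2.2,
    turns=2.0,
    tube_radius=0.35,
    height_pitch=1.0,
    radius_decay=0.5,
    grid_shape=(48, 48, 48),
    spacing=(0.15, 0.15, 0.15),
    noise_sd=1.0,
    blur_fwhm=0.3,
    seed=7,
)

#: reduced-effort registration settings for unit-scale problems; the affine
#: fraction is raised so the ~10x smaller unit phantom still yields the same
#: ~1000-point sparse sample as the study-scale grids
FAST_CONFIG = RegistrationConfig(
    affine_sample_fraction=0.01,
    max_samples_bspline=4000,
    max_iterations_affine=100,
    max_iterations_bspline=50,
)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_bundle():
    bundle, true_a = phantom_atlas_bundle(SMALL_SPEC)
    return bundle, true_a


@pytest.fixture(scope="session")
def study_bundle():
    """Atlas-scale phantom at the generator defaults (0.1 mm, 128^3)."""
    bundle, true_a = phantom_atlas_bundle(PhantomSpec(seed=1))
    return bundle, true_a


def all_fiducials(bundle) -> FiducialSet:
    return FiducialSet(
        {**bundle.aval_fiducials.points, **bundle.init_landmarks.points},
        bundle.laterality,
    )


def deformed_target(bundle, seed, target_spacing=(0.6, 0.6, 0.6),
                    target_shape=(64, 64, 64), **deform_kwargs):
    """Clinical-like target: random affine + smooth FFD applied to the
    phantom, rendered on a coarse grid.  Returns (target, mapped fiducials,
    true A-value)."""
    chain = sample_deformation(
        DeformationSpec(domain=bundle.volume.extent_roi(), seed=seed,
                        **deform_kwargs)
    )
    return make_target(
        bundle.volume,
        all_fiducials(bundle),
        chain,
        target_spacing=target_spacing,
        target_shape=target_shape,
        seed=seed + 10_000,
    ) + (chain,)
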