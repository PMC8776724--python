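import numpy as np
import pytest

from couinaud import (
    PhantomSpec,
    assign_segments,
    build_planes,
    make_phantom_mask,
    place_landmarks,
    segment_volumes,
)


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_mask(default_spec):
    return make_phantom_mask(default_spec)


@pytest.fixture(scope="session")
def canonical_landmarks(default_spec):
    """The worked landmark set: IVC along z through the origin, MHV
    (0,10,90), GB (0,50,10), RHV (40,10,80), UF (-25,55,15), RPV
    (30,20,45), LPV (-20,15,50)."""
    return place_landmarks(default_spec)


@pytest.fixture(scope="session")
def canonical_planes(canonical_landmarks):
    return build_planes(canonical_landmarks)


@pytest.fixture(scope="session")
def default_labels(default_mask, canonical_planes):
    return assign_segments(default_mask, canonical_planes)


@pytest.fixture(scope="session")
def default_report(default_labels):
    return segment_volumes(default_labels)


def small_phantom(seed: int):
    """A randomized ~20^3 phantom with valid scaled-down landmarks.

    Returns (spec, mask, landmarks, planes) with a caudate radius scaled
    to the phantom size so all nine segments can appear.
    """
    rng = np.random.default_rng(seed)
    semi = rng.uniform(8.0, 12.0, size=3)
    center = rng.uniform(-5.0, 5.0, size=3)
    spec = PhantomSpec(
        semi_axes_mm=tuple(semi),
        center_mm=tuple(center),
        voxel_size_mm=(1.2, 1.2, 1.2),
        margin_mm=2.0,
        seed=seed,
        perturb_amplitude=float(rng.uniform(0.0, 0.15)),
    )
    mask = make_phantom_mask(spec)
    landmarks = place_landmarks(spec)
    planes = build_planes(landmarks, caudate_radius_mm=3.0)
    return spec, mask, landmarks, planes
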