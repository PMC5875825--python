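"""Shared fixtures: compact phantoms reused across the suite.

Session scope amortizes phantom construction; tests must not mutate the
returned volumes (copy first when needed).
"""

from __future__ import annotations

import numpy as np
import pytest

import srsrescan as sr


@pytest.fixture(scope="session")
def example_ct_and_masks():
    """The standard two-target asymmetric head phantom (2 mm grid)."""
    spec = sr.example_spec(seed=1)
    ct, masks = sr.make_head_phantom(spec)
    return spec, ct, masks


@pytest.fixture(scope="session")
def example_ct(example_ct_and_masks):
    return example_ct_and_masks[1]


@pytest.fixture(scope="session")
def sphere_shell_ct():
    """Noise-free spherical shell, inner radius 70 mm, 1 mm grid."""
    spec = sr.PhantomSpec(
        skull_outer_radii=(76.0, 76.0, 76.0),
        skull_thickness=6.0,
        spacing=(1.0, 1.0, 1.0),
        noise_sigma=0.0,
    )
    ct, masks = sr.make_head_phantom(spec)
    return spec, ct, masks


@pytest.fixture(scope="session")
def small_dose():
    """Analytic SRS dose for a 6 mm GTV on the default 1 mm grid."""
    target = sr.Target((0.0, 0.0, 0.0), 6.0, target_id="d0")
    return target, sr.make_srs_dose(target, sr.DoseSpec())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
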