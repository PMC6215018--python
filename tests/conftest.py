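"""Shared synthetic fixtures.

All fixtures are generated at test time with fixed seeds; the expensive
mesoscope-scale tilted-layer pair is session-scoped and shared by the
sectioning tests.
"""

import numpy as np
import pytest

from hilo.simulate import (
    NoiseModel,
    SpeckleParams,
    TiltGeometry,
    bilayer_phantom,
    mesoscope_model,
    render_pair,
    tilted_layer_phantom,
)

#: Default camera/noise conditions for rendered fixtures: ~2000 expected
#: counts per unit emission, 3-count read noise, small constant pedestal.
STANDARD_NOISE = NoiseModel(photon_scale=2000.0, read_sd=3.0, offset=0.05)

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def standard_model():
    return mesoscope_model(noise=STANDARD_NOISE)


@pytest.fixture(scope="session")
def tilted_fixture_large(standard_model):
    """2048x512 tilted-layer pair spanning +/-30 um axially across columns."""
    ny, nx = 512, 2048
    geometry = TiltGeometry(
        height_difference_um=60.0,
        base_length_um=nx * standard_model.pixel_size_um,
        focus_column=nx // 2,
    )
    specimen = tilted_layer_phantom(geometry, 0.8, (ny, nx), standard_model)
    pair = render_pair(
        specimen,
        standard_model,
        0.0,
        SpeckleParams(grain_px=3.0, seed=FIXTURE_SEED),
        seed=FIXTURE_SEED,
    )
    return pair, geometry


@pytest.fixture(scope="session")
def tilted_fixture_small(standard_model):
    """512x512 tilted-layer pair (gentler tilt so the strip fits the frame)."""
    ny, nx = 512, 512
    geometry = TiltGeometry(
        height_difference_um=15.0,
        base_length_um=nx * standard_model.pixel_size_um,
        focus_column=nx // 2,
    )
    specimen = tilted_layer_phantom(geometry, 0.8, (ny, nx), standard_model)
    pair = render_pair(
        specimen,
        standard_model,
        0.0,
        SpeckleParams(grain_px=3.0, seed=FIXTURE_SEED),
        seed=FIXTURE_SEED,
    )
    return pair, geometry


@pytest.fixture(scope="session")
def bilayer_fixture(standard_model):
    """Banded in-focus plane plus a uniform plane defocused by 3x axial FWHM."""
    specimen = bilayer_phantom(21.0, (512, 512), standard_model)
    pair = render_pair(
        specimen,
        standard_model,
        0.0,
        SpeckleParams(grain_px=3.0, seed=2),
        seed=2,
    )
    return pair


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
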