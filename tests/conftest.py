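"""Shared fixtures: analytic phantom contours and rendered test scenes.

Everything is generated programmatically from fixed seeds; no image files
are stored in the repository.
"""

from __future__ import annotations

import numpy as np
import pytest

from rodmorph import phantoms, simulator, validation
from rodmorph.core import Image
from rodmorph.simulator import CellGeometry, NoiseModel, OpticsParams


@pytest.fixture(scope="session")
def optics() -> OpticsParams:
    return OpticsParams()


@pytest.fixture(scope="session")
def diffraction_psf(optics):
    return validation.validation_psf(optics, 0.75)


def render_cell(width_um: float, length_um: float, seed: int,
                optics: OpticsParams, psf=None,
                density: float = 2000.0) -> tuple[Image, CellGeometry]:
    """One noisy PF image of a centered surface-labeled spherocylinder."""
    g0 = CellGeometry(width_um, length_um)
    if psf is None:
        psf = validation.validation_psf(optics, g0.radius_um + 0.2)
    shape = validation._fov_shape(g0, optics.pixel_size_um)
    g = CellGeometry(width_um, length_um,
                     center=(shape[1] * optics.pixel_size_um / 2,
                             shape[0] * optics.pixel_size_um / 2, 0.0))
    field = simulator.sample_surface(g, density, seed=seed)
    img = simulator.render_frame(field, psf, 0.0, shape,
                                 optics.pixel_size_um)
    img = simulator.apply_noise(img, NoiseModel(seed=seed + 1))
    return img, g


@pytest.fixture(scope="session")
def single_cell_image(optics, diffraction_psf):
    """Noisy PF image of a 1 x 4 um cell (the workhorse test subject)."""
    return render_cell(1.0, 4.0, seed=101, optics=optics,
                      psf=diffraction_psf)


@pytest.fixture(scope="session")
def ten_cell_scene(optics, diffraction_psf):
    """Field of 10 non-overlapping cells with ground-truth geometry."""
    px = optics.pixel_size_um
    shape = (512, 512)
    cells = phantoms.place_cells(10, 25.6, seed=1)
    rng = np.random.default_rng(2)
    pixels = np.zeros(shape)
    for g in cells:
        f = simulator.sample_surface(g, 2000.0, seed=rng)
        pixels += simulator.render_frame(f, diffraction_psf, 0.0, shape,
                                         px).pixels
    img = simulator.apply_noise(Image(pixels, px), NoiseModel(seed=3))
    truth = phantoms.footprint_mask(cells, shape, px)
    return img, cells, truth
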