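"""Fluorophore sampling, PSF models, rendering, and noise."""

import numpy as np
import pytest
from scipy.stats import chisquare, kstest

from rodmorph import simulator as sim
from rodmorph.core import Image
from rodmorph.simulator import (CellGeometry, FluorophoreField, NoiseModel,
                                OpticsParams, load_psf, synthesize_psf)


@pytest.fixture(scope="module")
def psf():
    return synthesize_psf(OpticsParams())


def test_surface_area_and_volume_closed_forms():
    g = CellGeometry(1.0, 4.0)
    assert g.surface_area_um2 == pytest.approx(4 * np.pi, rel=1e-12)
    assert g.volume_um3 == pytest.approx(3 * np.pi / 4 + np.pi / 6,
                                         rel=1e-12)


def test_sample_surface_count_follows_poisson():
    g = CellGeometry(1.0, 4.0)
    n = len(sim.sample_surface(g, 1000.0, seed=0).positions)
    lam = 1000.0 * g.surface_area_um2
    assert abs(n - lam) < 3 * np.sqrt(lam)


def test_sample_surface_points_lie_on_surface():
    g = CellGeometry(1.0, 4.0)
    f = sim.sample_surface(g, 500.0, seed=1)
    ax = np.clip(f.positions[:, 0], -1.5, 1.5)
    d = np.sqrt((f.positions[:, 0] - ax) ** 2 + f.positions[:, 1] ** 2
                + f.positions[:, 2] ** 2)
    assert np.abs(d - 0.5).max() < 1e-9


def test_sample_surface_axial_uniformity():
    g = CellGeometry(1.0, 10.0)
    f = sim.sample_surface(g, 3000.0, seed=2)
    x = f.positions[:, 0]
    cyl = np.abs(x) < 4.5
    hist, _ = np.histogram(x[cyl], bins=20, range=(-4.5, 4.5))
    assert chisquare(hist).pvalue > 0.01


def test_sample_volume_count_and_radial_cdf():
    g = CellGeometry(1.0, 4.0)
    f = sim.sample_volume(g, 2000.0, seed=3)
    lam = 2000.0 * g.volume_um3
    assert abs(len(f.positions) - lam) < 3 * np.sqrt(lam)
    sel = np.abs(f.positions[:, 0]) < 1.4
    r = np.sqrt(f.positions[sel, 1] ** 2 + f.positions[sel, 2] ** 2) / 0.5
    assert kstest(r, lambda q: q ** 2).pvalue > 0.01


def test_parametric_psf_formulas(psf):
    o = OpticsParams()
    assert psf.sigma0_um == pytest.approx(0.21 * o.wavelength_um / o.na)
    assert psf.sigma_um(psf.z_r_um) == pytest.approx(np.sqrt(2)
                                                     * psf.sigma0_um)
    peaks = [psf.plane(z, 0.05).max() for z in (0.0, 0.2, 0.4, 0.8)]
    assert np.all(np.diff(peaks) < 0)


def test_psf_requires_na_below_index():
    with pytest.raises(ValueError):
        OpticsParams(na=1.6, refractive_index=1.515)


def test_load_psf_roundtrip_and_blend(psf):
    planes = [psf.plane(z, 0.05) for z in (-0.2, 0.0, 0.2)]
    size = max(p.shape[0] for p in planes)
    padded = []
    for p in planes:
        d = size - p.shape[0]
        padded.append(np.pad(p, ((d // 2, d - d // 2), (d // 2, d - d // 2))))
    model = load_psf(np.stack(padded), 0.2, 0.05)
    assert model.focus_index == 1
    assert np.allclose(model.plane(0.0, 0.05),
                       padded[1] / padded[1].sum())
    blend = model.plane(0.1, 0.05)
    expected = 0.5 * (model.stack[1] + model.stack[2])
    assert np.allclose(blend, expected)
    with pytest.raises(ValueError):
        load_psf(np.ones((3, 4)), 0.1, 0.05)


def test_render_conserves_photons_single_molecule(psf):
    f = FluorophoreField(np.array([[3.2, 2.7, 0.0]]), np.array([5.0]))
    img = sim.render_frame(f, psf, 0.0, (128, 128), 0.05)
    assert img.pixels.sum() == pytest.approx(5.0, rel=1e-3)


def test_render_is_linear_superposition(psf):
    p1 = np.array([[2.0, 2.0, 0.0]])
    p2 = np.array([[4.0, 3.0, 0.1]])
    both = FluorophoreField(np.vstack([p1, p2]), np.array([1.0, 2.0]))
    i_both = sim.render_frame(both, psf, 0.0, (128, 128), 0.05)
    i1 = sim.render_frame(FluorophoreField(p1, np.array([1.0])), psf, 0.0,
                          (128, 128), 0.05)
    i2 = sim.render_frame(FluorophoreField(p2, np.array([2.0])), psf, 0.0,
                          (128, 128), 0.05)
    assert np.allclose(i_both.pixels, i1.pixels + i2.pixels, atol=1e-12)


def test_render_equivariant_under_whole_pixel_shift(psf):
    f = FluorophoreField(np.array([[2.0, 2.0, 0.0]]), np.array([1.0]))
    g = FluorophoreField(np.array([[2.5, 2.0, 0.0]]), np.array([1.0]))
    a = sim.render_frame(f, psf, 0.0, (128, 128), 0.05).pixels
    b = sim.render_frame(g, psf, 0.0, (128, 128), 0.05).pixels
    assert np.allclose(np.roll(a, 10, axis=1), b, atol=1e-9)


def test_surface_render_has_bright_boundary(optics, diffraction_psf):
    g = CellGeometry(1.0, 4.0, center=(3.2, 2.0, 0.0))
    f = sim.sample_surface(g, 2000.0, seed=4)
    img = sim.render_frame(f, diffraction_psf, 0.0, (80, 128), 0.05).pixels
    mid_col = img[:, 64]
    rim = mid_col[int(1.5 / 0.05):int(1.62 / 0.05)].max()
    center = mid_col[int(1.95 / 0.05):int(2.05 / 0.05)].mean()
    assert rim > 1.5 * center


def test_zstack_offsets_and_mirror_symmetry(psf):
    f = FluorophoreField(np.array([[1.0, 1.0, 0.2], [1.0, 1.0, -0.2]]),
                        np.ones(2))
    stack = sim.render_zstack(f, psf, [-0.3, 0.0, 0.3], (40, 40), 0.05)
    assert [im.z_offset for im in stack] == [-0.3, 0.0, 0.3]
    assert np.allclose(stack[0].pixels, stack[2].pixels)
    single = sim.render_frame(f, psf, 0.0, (40, 40), 0.05)
    assert np.allclose(stack[1].pixels, single.pixels)


def test_poisson_noise_moments():
    img = Image(np.full((100, 100), 100.0), 0.05)
    noisy = sim.apply_noise(img, NoiseModel(camera_offset=0, read_sigma=0,
                                            photons_per_intensity=1.0,
                                            shot=True, seed=5))
    assert noisy.pixels.mean() == pytest.approx(100.0, rel=0.05)
    assert noisy.pixels.var() == pytest.approx(100.0, rel=0.05)


def test_noise_shot_off_gives_offset_shift():
    img = Image(np.full((50, 50), 10.0), 0.05)
    out = sim.apply_noise(img, NoiseModel(camera_offset=100.0, read_sigma=2.0,
                                          photons_per_intensity=1.0,
                                          shot=False, seed=6))
    assert out.pixels.mean() == pytest.approx(110.0, abs=0.5)


def test_noise_seeded_reproducibility():
    img = Image(np.full((50, 50), 10.0), 0.05)
    n = NoiseModel(seed=7)
    a = sim.apply_noise(img, n).pixels
    b = sim.apply_noise(img, n).pixels
    assert np.array_equal(a, b)


def test_tirf_weighting():
    pos = np.array([[0, 0, 0.0], [0, 0, 0.1], [0, 0, 0.3], [0, 0, -0.1]])
    f = FluorophoreField(pos, np.ones(4))
    out = sim.tirf_weight(f, penetration_depth_um=0.1, interface_z_um=0.0)
    assert out.intensities[0] == pytest.approx(1.0)
    assert out.intensities[1] == pytest.approx(np.exp(-1))
    assert out.intensities[2] < out.intensities[1]
    assert out.intensities[3] == 0.0


def test_photobleach_mean_field_and_stochastic():
    g = CellGeometry(1.0, 4.0)
    f = sim.sample_surface(g, 200.0, seed=8)
    assert np.array_equal(
        sim.photobleach(f, 0.0, 1.0, "mean_field").intensities,
        f.intensities)
    halved = sim.photobleach(f, np.log(2), 1.0, "mean_field")
    assert halved.intensities.sum() == pytest.approx(
        0.5 * f.intensities.sum())
    # ensemble of stochastic runs approaches the mean-field fraction
    n_mol = len(f.positions)
    reps = 200
    surv = [sim.photobleach(f, np.log(2), 1.0, "stochastic",
                            seed=s).intensities.sum() / n_mol
            for s in range(reps)]
    se = np.sqrt(0.5 * 0.5 / (n_mol * reps))
    assert abs(np.mean(surv) - 0.5) < 3 * se


def test_photobleach_region_restricts_bleaching():
    pos = np.array([[-1.0, 0, 0], [1.0, 0, 0]])
    f = FluorophoreField(pos, np.ones(2))
    out = sim.photobleach(f, np.log(2), 1.0, "mean_field",
                          region=lambda p: p[:, 0] > 0)
    assert out.intensities[0] == 1.0
    assert out.intensities[1] == pytest.approx(0.5)


def test_boxcar_static_equals_single_frame(psf):
    frames = [np.array([[1.0, 1.0, 0.0]])] * 4
    f = FluorophoreField(frames[0], np.ones(1), frames=frames)
    box = sim.boxcar_render(f, psf, 0.0, (40, 40), 0.05, exposure_window=4)
    single = sim.render_frame(f, psf, 0.0, (40, 40), 0.05)
    assert np.allclose(box.pixels, single.pixels)


def test_boxcar_moving_molecule_streaks_and_conserves(psf):
    frames = [np.array([[0.8 + 0.15 * t, 1.0, 0.0]]) for t in range(5)]
    f = FluorophoreField(frames[0], np.ones(1), frames=frames)
    box = sim.boxcar_render(f, psf, 0.0, (40, 40), 0.05, exposure_window=5)
    single = sim.render_frame(f, psf, 0.0, (40, 40), 0.05)
    assert box.pixels.sum() == pytest.approx(single.pixels.sum(), rel=1e-6)
    # the streak spreads along x: larger x-variance of the image
    xs = np.arange(40)

    def xvar(img):
        w = img.sum(axis=0)
        mu = (xs * w).sum() / w.sum()
        return ((xs - mu) ** 2 * w).sum() / w.sum()

    assert xvar(box.pixels) > xvar(single.pixels) + 1.0
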