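"""Object detection: preprocessing, boundary maps, watershed splitting,
false-positive filtering, and frame linking."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from rodmorph import segmentation as seg
from rodmorph import simulator, validation
from rodmorph.core import Image
from rodmorph.segmentation import SegParams
from rodmorph.simulator import CellGeometry, NoiseModel

from conftest import render_cell


def test_preprocess_identity_settings_stretch_only():
    rng = np.random.default_rng(0)
    img = Image(rng.uniform(10, 200, (64, 64)), 0.05)
    out = seg.preprocess(img, SegParams(rescale_factor=1.0,
                                        background_radius_px=0))
    assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0
    # monotone transform: ordering of pixels preserved
    flat_in = img.pixels.ravel()
    flat_out = out.pixels.ravel()
    order = np.argsort(flat_in)
    assert np.all(np.diff(flat_out[order]) >= -1e-12)


def test_preprocess_constant_image_raises():
    with pytest.raises(ValueError, match="no contrast"):
        seg.preprocess(Image(np.full((32, 32), 7.0), 0.05))


def test_preprocess_rescale_updates_pixel_size():
    img = Image(np.random.default_rng(1).uniform(0, 1, (64, 64)), 0.05)
    out = seg.preprocess(img, SegParams(rescale_factor=2.0))
    assert out.pixel_size == pytest.approx(0.025)
    assert out.pixels.shape == (128, 128)


def test_background_removal_suppresses_illumination_ramp(optics,
                                                         diffraction_psf):
    img, g = render_cell(1.0, 4.0, seed=11, optics=optics,
                         psf=diffraction_psf)
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    ramped = Image(img.pixels + 0.5 * img.pixels.max() * xx / img.shape[1],
                   img.pixel_size)
    pre = seg.preprocess(ramped, SegParams(background_radius_px=25))

    free = np.hypot((xx - img.shape[1] / 2) * 0.05,
                    (yy - img.shape[0] / 2) * 0.05) > 1.6

    def ramp_slope(arr):
        a = np.column_stack([xx[free], yy[free], np.ones(free.sum())])
        coef, *_ = np.linalg.lstsq(a, arr[free], rcond=None)
        return abs(coef[0]) * img.shape[1]

    norm = (ramped.pixels - ramped.pixels.min()) / np.ptp(ramped.pixels)
    assert ramp_slope(norm) / ramp_slope(pre.pixels) >= 10.0


def test_boundary_map_pf_identity(single_cell_image):
    img, _ = single_cell_image
    pre = seg.preprocess(img)
    assert seg.boundary_intensity_map(pre) is pre


def test_boundary_map_if_disk_rim():
    yy, xx = np.mgrid[0:64, 0:64]
    disk = (np.hypot(xx - 32, yy - 32) < 15).astype(float)
    disk = gaussian_filter(disk, 2)
    img = Image(disk, 0.05, modality="IF")
    bmap = seg.boundary_intensity_map(img)
    r = np.hypot(xx - 32, yy - 32)
    assert bmap.pixels[r < 8].max() < 0.05
    rim = bmap.pixels[(r > 13) & (r < 17)]
    assert rim.max() == pytest.approx(1.0)


def test_boundary_map_offset_invariance_after_normalization():
    rng = np.random.default_rng(2)
    base = gaussian_filter(rng.uniform(0, 1, (64, 64)), 2)
    b1 = seg.boundary_intensity_map(Image(base, 0.05, modality="IF"))
    b2 = seg.boundary_intensity_map(Image(base + 5.0, 0.05, modality="IF"))
    assert np.allclose(b1.pixels, b2.pixels, atol=1e-12)


def test_two_separated_cells_give_two_objects(optics, diffraction_psf):
    px = optics.pixel_size_um
    shape = (200, 200)
    pixels = np.zeros(shape)
    for cx, cy, ang in ((3.0, 3.0, 0.3), (7.0, 7.0, 1.8)):
        g = CellGeometry(1.0, 3.5, center=(cx, cy, 0.0), axis_angle=ang)
        f = simulator.sample_surface(g, 2000.0, seed=int(cx * 10))
        pixels += simulator.render_frame(f, diffraction_psf, 0.0, shape,
                                         px).pixels
    img = simulator.apply_noise(Image(pixels, px), NoiseModel(seed=5))
    pre = seg.preprocess(img)
    bmap = seg.boundary_intensity_map(pre)
    labels = seg.segment_objects(bmap, intensity_img=pre)
    assert labels.max() == 2


def test_touching_cells_split_by_watershed(optics, diffraction_psf):
    # two cells end to end with a small gap producing an intensity neck
    px = optics.pixel_size_um
    shape = (160, 320)
    pixels = np.zeros(shape)
    for cx in (3.9, 7.7):
        g = CellGeometry(1.0, 3.6, center=(cx, 4.0, 0.0))
        f = simulator.sample_surface(g, 2000.0, seed=int(cx * 10))
        pixels += simulator.render_frame(f, diffraction_psf, 0.0, shape,
                                         px).pixels
    img = simulator.apply_noise(Image(pixels, px), NoiseModel(seed=9))
    pre = seg.preprocess(img)
    bmap = seg.boundary_intensity_map(pre)
    labels = seg.segment_objects(bmap, intensity_img=pre)
    assert labels.max() == 2


def test_small_objects_excluded(single_cell_image):
    img, _ = single_cell_image
    pre = seg.preprocess(img)
    bmap = seg.boundary_intensity_map(pre)
    huge_min = SegParams(min_area_px=10 ** 6, max_area_px=10 ** 7)
    assert seg.segment_objects(bmap, huge_min, intensity_img=pre).max() == 0


def test_empty_foreground_yields_empty_mask():
    rng = np.random.default_rng(3)
    noise = Image(np.abs(rng.normal(0.5, 0.001, (64, 64))), 0.05)
    labels = seg.segment_objects(noise, SegParams(min_area_px=4000))
    assert labels.max() == 0


def test_fp_filter_retains_cell_at_default_threshold(optics,
                                                     diffraction_psf):
    # a micron-wide cell has a bright rim: its boundary/interior ratio
    # clearly exceeds both the default threshold and the ~1.0 of debris
    img, _ = render_cell(1.0, 4.0, seed=21, optics=optics,
                         psf=diffraction_psf)
    pre = seg.preprocess(img)
    bmap = seg.boundary_intensity_map(pre)
    labels = seg.segment_objects(bmap, intensity_img=pre)
    ratio = seg.boundary_interior_ratio(labels == 1, bmap.pixels)
    assert ratio > 1.3
    kept = seg.false_positive_filter(labels, bmap, SegParams())
    assert kept.max() == 1


def test_fp_filter_drops_uniform_blob():
    rng = np.random.default_rng(4)
    pixels = np.zeros((80, 80)) + 0.01
    pixels[20:60, 20:60] = 1.0
    pixels += np.abs(rng.normal(0, 0.01, (80, 80)))
    bmap = Image(pixels, 0.05)
    mask = (pixels > 0.5).astype(np.int32)
    kept = seg.false_positive_filter(mask, bmap,
                                     SegParams(fp_ratio_threshold=1.2))
    assert kept.max() == 0


def test_fp_filter_threshold_zero_is_noop(single_cell_image):
    img, _ = single_cell_image
    pre = seg.preprocess(img)
    bmap = seg.boundary_intensity_map(pre)
    labels = seg.segment_objects(bmap, intensity_img=pre)
    out = seg.false_positive_filter(labels, bmap,
                                    SegParams(fp_ratio_threshold=0.0))
    assert np.array_equal(out, labels)


def test_fp_filter_labels_stay_contiguous(ten_cell_scene):
    img, cells, truth = ten_cell_scene
    pre = seg.preprocess(img)
    bmap = seg.boundary_intensity_map(pre)
    labels = seg.segment_objects(bmap, intensity_img=pre)
    kept = seg.false_positive_filter(labels, bmap)
    assert kept.max() <= labels.max()
    present = np.unique(kept[kept > 0])
    assert list(present) == list(range(1, kept.max() + 1))


def test_link_frames_static_objects_keep_tracks():
    m = np.zeros((40, 40), int)
    m[5:10, 5:10] = 1
    m[25:30, 25:30] = 2
    rows = seg.link_frames([m, m, m], max_disp_px=5)
    tracks = {}
    for frame, label, track in rows:
        tracks.setdefault((label), set()).add(track)
    assert all(len(t) == 1 for t in tracks.values())
    assert len(rows) == 6


def test_link_frames_large_jump_starts_new_track():
    m1 = np.zeros((40, 40), int)
    m1[5:10, 5:10] = 1
    m2 = np.zeros((40, 40), int)
    m2[5:10, 25:30] = 1
    rows = seg.link_frames([m1, m2], max_disp_px=5)
    assert rows[0][2] != rows[1][2]


def test_link_frames_swap_follows_proximity_not_identity():
    # two objects exchanging positions are tracked by nearest centroid:
    # a documented limitation of greedy linking
    m1 = np.zeros((40, 60), int)
    m1[10:14, 5:9] = 1
    m1[10:14, 15:19] = 2
    m2 = np.zeros((40, 60), int)
    m2[10:14, 13:17] = 1   # object 1 moved near object 2's old spot
    m2[10:14, 7:11] = 2    # object 2 moved near object 1's old spot
    rows = seg.link_frames([m1, m2], max_disp_px=6)
    t = {(f, lab): tr for f, lab, tr in rows}
    assert t[(1, 1)] == t[(0, 2)]
    assert t[(1, 2)] == t[(0, 1)]
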