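"""Curvature, pole detection, meshes, and scalar measurements against
analytic spherocylinder geometry."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from rodmorph import meshing, phantoms
from rodmorph.core import (Contour, arc_length, resample_open, rotate_points,
                           turning_angle_sum)
from rodmorph.meshing import (MeshError, WindowTooSmall,
                              build_branching_mesh, build_centerline_mesh,
                              classify_meshlines, curvature_profile,
                              find_poles, measure_cell, profile_fluorescence)


@pytest.fixture(scope="module")
def sphero():
    c = phantoms.spherocylinder_contour(1.0, 4.0)
    prof = curvature_profile(c, 0.25)
    poles = find_poles(prof, c)
    mesh = build_centerline_mesh(c, poles.indices)
    return c, prof, poles, mesh


def test_circle_curvature_is_inverse_radius():
    c = phantoms.circle_contour(1.0)
    prof = curvature_profile(c, 0.25)
    assert prof.kappa == pytest.approx(np.full_like(prof.kappa, 1.0),
                                       rel=0.01)


def test_spherocylinder_curvature_caps_and_flanks(sphero):
    c, prof, _, _ = sphero
    v = c.vertices_um()
    caps = np.abs(v[:, 0]) > 1.85
    flanks = np.abs(v[:, 0]) < 1.2
    assert prof.kappa[caps].mean() == pytest.approx(2.0, rel=0.02)
    assert np.abs(prof.kappa[flanks]).max() < 0.05


def test_concave_regions_have_negative_curvature():
    c = phantoms.indented_rod_contour(1.0, 5.0, depth_frac=0.35)
    prof = curvature_profile(c, 0.25)
    assert prof.kappa.min() < -0.1


def test_curvature_window_too_small_raises():
    c = phantoms.spherocylinder_contour(1.0, 4.0, spacing_um=0.2)
    with pytest.raises(WindowTooSmall):
        curvature_profile(c, 0.05)


@pytest.mark.parametrize("name,contour,accept", [
    ("rod", phantoms.spherocylinder_contour(1.0, 4.0), True),
    ("thin_rod", phantoms.spherocylinder_contour(0.4, 3.4), True),
    ("long_rod", phantoms.spherocylinder_contour(0.8, 8.0), True),
    ("bent_rod", phantoms.bent_rod_contour(1.0, 4.0, 3.0), True),
    ("indented_rod", phantoms.indented_rod_contour(1.0, 5.0), True),
    ("circle", phantoms.circle_contour(1.0), False),
    ("y_shape", phantoms.y_contour(), False),
])
def test_pole_filter_accepts_exactly_the_rods(name, contour, accept):
    result = find_poles(curvature_profile(contour, 0.25), contour)
    assert result.accepted == accept
    if name == "y_shape":
        assert result.n_found == 3
    if name == "circle":
        assert result.n_found == 0


def test_pole_locations_are_cap_apices(sphero):
    c, _, poles, _ = sphero
    v = c.vertices_um()
    xs = np.sort(np.abs(v[list(poles.indices), 0]))
    assert xs[0] == pytest.approx(2.0, abs=0.05)
    assert xs[1] == pytest.approx(2.0, abs=0.05)


def test_centerline_mesh_width_profile(sphero):
    _, _, _, mesh = sphero
    assert mesh.widths[0] == 0.0 and mesh.widths[-1] == 0.0
    flank = np.abs(mesh.midline[:, 0]) < 1.2
    assert mesh.widths[flank] == pytest.approx(
        np.full(flank.sum(), 1.0), abs=0.02)


def test_straight_rod_midline_is_straight(sphero):
    _, _, _, mesh = sphero
    assert np.sqrt(np.mean(mesh.midline[:, 1] ** 2)) < 0.02


def test_measure_cell_closed_forms(sphero):
    c, _, _, mesh = sphero
    m = measure_cell(c, mesh)
    assert m.length_um == pytest.approx(4.0, abs=0.02)
    assert m.mean_width_um == pytest.approx(1.0, abs=0.02)
    assert m.max_width_um >= m.mean_width_um
    assert m.area_um2 == pytest.approx(3.785, rel=0.01)
    assert m.width_cv < 0.01


def test_measure_cell_scales_linearly():
    c = phantoms.spherocylinder_contour(2.0, 8.0)
    poles = find_poles(curvature_profile(c, 0.25), c)
    m = measure_cell(c, build_centerline_mesh(c, poles.indices))
    assert m.length_um == pytest.approx(8.0, abs=0.04)
    assert m.mean_width_um == pytest.approx(2.0, abs=0.04)
    assert m.area_um2 == pytest.approx(4 * 3.785, rel=0.01)


def test_width_cv_of_sinusoidal_modulation():
    # SD of a sinusoid is amplitude / sqrt(2): 10% modulation -> cv 0.0707
    c = phantoms.modulated_rod_contour(1.0, 6.0, 0.10, n_periods=3)
    v = c.vertices_um()
    poles = (int(np.argmin(v[:, 0])), int(np.argmax(v[:, 0])))
    m = measure_cell(c, build_centerline_mesh(c, tuple(sorted(poles))))
    assert m.width_cv == pytest.approx(0.0707, rel=0.10)


def test_bent_cell_midline_longer_than_chord():
    c = phantoms.bent_rod_contour(1.0, 4.0, 3.0)
    poles = find_poles(curvature_profile(c, 0.25), c)
    mesh = build_centerline_mesh(c, poles.indices)
    chord = np.linalg.norm(mesh.midline[-1] - mesh.midline[0])
    assert arc_length(mesh.midline, closed=False) > chord + 0.05


def test_rigid_motion_leaves_measurements_unchanged():
    c = phantoms.spherocylinder_contour(1.0, 4.0)
    poles = find_poles(curvature_profile(c, 0.25), c)
    m0 = measure_cell(c, build_centerline_mesh(c, poles.indices))
    moved = Contour(rotate_points(c.vertices, 1.1) + [7.0, -3.0], 1.0)
    prof = curvature_profile(moved, 0.25)
    poles2 = find_poles(prof, moved)
    m1 = measure_cell(moved, build_centerline_mesh(moved, poles2.indices))
    for attr in ("length_um", "mean_width_um", "area_um2"):
        assert getattr(m1, attr) == pytest.approx(getattr(m0, attr),
                                                  rel=0.005)
    assert prof.kappa.max() == pytest.approx(
        curvature_profile(c, 0.25).kappa.max(), rel=0.005)


def test_turning_number_of_accepted_contours(sphero):
    c, _, _, _ = sphero
    assert turning_angle_sum(c.vertices) == pytest.approx(2 * np.pi,
                                                          abs=1e-6)


def test_classify_meshlines_by_endpoint_curvature():
    c = phantoms.spherocylinder_contour(1.0, 4.0)
    prof = curvature_profile(c, 0.25)
    mesh = build_centerline_mesh(c, find_poles(prof, c).indices)
    assert set(classify_meshlines(mesh, prof, c)) == {"both_positive"}

    bent = phantoms.bent_rod_contour(1.0, 4.0, 2.0)
    prof_b = curvature_profile(bent, 0.25)
    mesh_b = build_centerline_mesh(bent, find_poles(prof_b, bent).indices)
    assert "mixed" in classify_meshlines(mesh_b, prof_b, bent)

    dent = phantoms.indented_rod_contour(1.0, 5.0, depth_frac=0.35)
    prof_d = curvature_profile(dent, 0.25)
    mesh_d = build_centerline_mesh(dent, find_poles(prof_d, dent).indices)
    assert "both_negative" in classify_meshlines(mesh_d, prof_d, dent)


def test_branching_mesh_matches_centerline_on_rod(sphero):
    c, _, _, mesh = sphero
    bmesh = build_branching_mesh(c)
    a = resample_open(bmesh.midline, 400)
    b = resample_open(mesh.midline, 400)
    d = cdist(a, b)
    hausdorff = max(d.min(axis=1).max(), d.min(axis=0).max())
    assert hausdorff < 0.05
    # width agreement on the cylindrical flank
    flank = np.abs(a[:, 0]) < 1.2
    widths_a = bmesh.widths[np.abs(bmesh.midline[:, 0]) < 1.2]
    assert np.abs(widths_a - 1.0).max() < 0.05


def test_branching_mesh_resolves_y_shape():
    y = phantoms.y_contour()
    mesh = build_branching_mesh(y)
    assert mesh.kind == "branching"
    assert len(mesh.arms) == 3
    assert mesh.branch_points is not None and len(mesh.branch_points) == 1


def test_branching_mesh_circle_degenerates_gracefully():
    mesh = build_branching_mesh(phantoms.circle_contour(1.0))
    assert mesh.kind == "branching"  # collapses toward the center; no crash


def test_profile_fluorescence_constant_image():
    from rodmorph.core import Image

    c = phantoms.spherocylinder_contour(1.0, 3.0, center=(3.2, 2.4))
    cpx = Contour(c.vertices_um() / 0.05, 0.05)
    s, prof = profile_fluorescence(cpx, Image(np.full((96, 128), 7.0), 0.05))
    assert np.allclose(prof, 7.0)
    assert s[0] == 0.0 and np.all(np.diff(s) > 0)


def test_profile_fluorescence_flags_outside_vertices():
    from rodmorph.core import Image

    c = phantoms.spherocylinder_contour(1.0, 3.0, center=(0.2, 1.0))
    cpx = Contour(c.vertices_um() / 0.05, 0.05)  # pokes past x = 0
    _, prof = profile_fluorescence(cpx, Image(np.full((48, 64), 1.0), 0.05))
    assert np.isnan(prof).any() and np.isfinite(prof).any()


def test_polar_labeling_peaks_at_poles(optics, diffraction_psf):
    # fluorophores only on the caps: the boundary profile peaks there
    from rodmorph import simulator
    from rodmorph.core import Image
    from rodmorph.simulator import CellGeometry, NoiseModel

    g = CellGeometry(1.0, 4.0, center=(3.2, 2.0, 0.0))
    field = simulator.sample_surface(g, 4000.0, seed=5)
    on_cap = np.abs(field.positions[:, 0] - 3.2) > 1.5
    field.intensities[~on_cap] = 0.0
    img = simulator.render_frame(field, diffraction_psf, 0.0, (80, 128),
                                 optics.pixel_size_um)
    c = phantoms.spherocylinder_contour(1.0, 4.0, center=(3.2, 2.0))
    cpx = Contour(c.vertices_um() / optics.pixel_size_um,
                  optics.pixel_size_um)
    _, prof = profile_fluorescence(cpx, img, half_width_px=2.0)
    v = c.vertices_um()
    at_poles = np.abs(v[:, 0] - 3.2) > 1.8
    assert np.nanmean(prof[at_poles]) > 3 * np.nanmean(prof[~at_poles])


def test_mesh_rejects_bad_pole_indices(sphero):
    c, _, _, _ = sphero
    with pytest.raises(MeshError):
        build_centerline_mesh(c, (5, 5))
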