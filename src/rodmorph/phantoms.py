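"""Analytic cell shapes and synthetic scenes used as ground truth.

Every generator returns closed counterclockwise contours in micrometers
(``pixel_size=1``) so that closed-form geometry — perimeter, area, curvature
— is known exactly. These phantoms drive both the test oracles and the
``fixtures`` CLI subcommand.

A spherocylinder (stadium in 2D cross-section) of width ``w = 2r`` and
pole-to-pole length ``L`` has:

* midplane perimeter ``2(L - w) + pi*w``
* midplane area ``w*(L - w) + pi*(w/2)**2``
* surface area ``pi*w*(L - w) + pi*w**2``
* volume ``pi*(w/2)**2*(L - w) + (pi/6)*w**3``
"""

from __future__ import annotations

import numpy as np

from .core import Contour, ensure_ccw, resample_closed


def stadium_outline(width_um: float, length_um: float,
                    spacing_um: float = 0.02) -> np.ndarray:
    """Midplane outline of a spherocylinder: two flat flanks joined by
    semicircular caps. Centered on the origin, axis along x, CCW."""
    if not (length_um >= width_um > 0):
        raise ValueError("need length >= width > 0")
    r = width_um / 2.0
    flank = length_um - width_um  # straight section length
    half = flank / 2.0

    n_flank = max(2, int(round(flank / spacing_um)))
    n_cap = max(8, int(round(np.pi * r / spacing_um)))

    # bottom flank left->right, right cap, top flank right->left, left cap
    xs_b = np.linspace(-half, half, n_flank, endpoint=False)
    bottom = np.column_stack([xs_b, np.full(n_flank, -r)])
    th_r = np.linspace(-np.pi / 2, np.pi / 2, n_cap, endpoint=False)
    cap_r = np.column_stack([half + r * np.cos(th_r), r * np.sin(th_r)])
    xs_t = np.linspace(half, -half, n_flank, endpoint=False)
    top = np.column_stack([xs_t, np.full(n_flank, r)])
    th_l = np.linspace(np.pi / 2, 3 * np.pi / 2, n_cap, endpoint=False)
    cap_l = np.column_stack([-half + r * np.cos(th_l), r * np.sin(th_l)])
    return np.vstack([bottom, cap_r, top, cap_l])


def spherocylinder_contour(width_um: float, length_um: float,
                           spacing_um: float = 0.02,
                           center: tuple[float, float] = (0.0, 0.0),
                           angle: float = 0.0) -> Contour:
    v = stadium_outline(width_um, length_um, spacing_um)
    if angle != 0.0:
        from .core import rotate_points

        v = rotate_points(v, angle)
    v = v + np.asarray(center)
    return Contour(ensure_ccw(v), pixel_size=1.0)


def circle_contour(radius_um: float, spacing_um: float = 0.02,
                   center: tuple[float, float] = (0.0, 0.0)) -> Contour:
    n = max(16, int(round(2 * np.pi * radius_um / spacing_um)))
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    v = np.column_stack([radius_um * np.cos(th), radius_um * np.sin(th)])
    return Contour(v + np.asarray(center), pixel_size=1.0)


def ellipse_contour(a_um: float, b_um: float, n: int = 400) -> Contour:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    v = np.column_stack([a_um * np.cos(th), b_um * np.sin(th)])
    # equal-arclength vertices keep downstream moments unbiased
    v = resample_closed(v, n=n)
    return Contour(v, pixel_size=1.0)


def bent_rod_contour(width_um: float, length_um: float,
                     bend_radius_um: float,
                     spacing_um: float = 0.02) -> Contour:
    """Banana: a stadium bent along a circular arc of the given radius
    (measured at the midline). Widths along meshlines are preserved."""
    if bend_radius_um <= length_um / np.pi:
        raise ValueError("bend radius too small for this length")
    v = stadium_outline(width_um, length_um, spacing_um)
    phi = v[:, 0] / bend_radius_um
    rad = bend_radius_um + v[:, 1]
    bent = np.column_stack([rad * np.sin(phi), bend_radius_um - rad * np.cos(phi)])
    return Contour(ensure_ccw(bent), pixel_size=1.0)


def modulated_rod_contour(width_um: float, length_um: float,
                          amp_frac: float, n_periods: int = 4,
                          spacing_um: float = 0.02) -> Contour:
    """Rod whose flank half-width is modulated sinusoidally by
    ``amp_frac`` over an integer number of periods (caps unmodulated)."""
    v = stadium_outline(width_um, length_um, spacing_um)
    r = width_um / 2.0
    half = (length_um - width_um) / 2.0
    on_flank = (np.abs(v[:, 0]) <= half) & (np.abs(np.abs(v[:, 1]) - r) < 1e-9)
    phase = 2 * np.pi * n_periods * (v[:, 0] + half) / (2 * half)
    scale = 1.0 + amp_frac * np.sin(phase)
    out = v.copy()
    out[on_flank, 1] *= scale[on_flank]
    return Contour(ensure_ccw(out), pixel_size=1.0)


def tapered_rod_contour(width_um: float, length_um: float,
                        taper_frac: float = 0.3,
                        spacing_um: float = 0.02) -> Contour:
    """Asymmetric rod: flank half-width shrinks linearly toward +x by
    ``taper_frac``; used to exercise chirality/reflection handling."""
    v = stadium_outline(width_um, length_um, spacing_um)
    half = (length_um - width_um) / 2.0
    t = np.clip((v[:, 0] + half) / (2 * half), 0.0, 1.0)
    scale = 1.0 - taper_frac * t
    out = v.copy()
    out[:, 1] *= scale
    out[:, 0] *= 1.0  # length unchanged
    return Contour(ensure_ccw(out), pixel_size=1.0)


def indented_rod_contour(width_um: float, length_um: float,
                         depth_frac: float = 0.25,
                         extent_frac: float = 0.25,
                         spacing_um: float = 0.02) -> Contour:
    """Rod with a smooth symmetric waist (inward indentation) at midcell."""
    v = stadium_outline(width_um, length_um, spacing_um)
    half = (length_um - width_um) / 2.0
    sigma = extent_frac * (length_um - width_um) / 2.0
    dent = depth_frac * np.exp(-0.5 * (v[:, 0] / sigma) ** 2)
    on_flank = np.abs(v[:, 0]) <= half
    out = v.copy()
    out[on_flank, 1] *= (1.0 - dent[on_flank])
    return Contour(ensure_ccw(out), pixel_size=1.0)


def y_contour(arm_length_um: float = 2.0, width_um: float = 0.8,
              spacing_um: float = 0.02) -> Contour:
    """Y-shaped (branched) outline: union of three rounded arms at 120
    degrees, as seen in branching bacteria."""
    from shapely.geometry import LineString
    from shapely.ops import unary_union

    arms = []
    for k in range(3):
        ang = np.pi / 2 + 2 * np.pi * k / 3
        tip = (arm_length_um * np.cos(ang), arm_length_um * np.sin(ang))
        arms.append(LineString([(0, 0), tip]).buffer(width_um / 2.0,
                                                     quad_segs=64))
    shape = unary_union(arms)
    xy = np.asarray(shape.exterior.coords)[:-1]
    v = resample_closed(xy, spacing=spacing_um)
    return Contour(ensure_ccw(v), pixel_size=1.0)


# ---------------------------------------------------------------------------
# Synthetic scenes and populations


def place_cells(n_cells: int, fov_um: float, width_range=(0.9, 1.1),
                length_range=(2.5, 4.0), margin_um: float = 1.5,
                min_gap_um: float = 0.8, seed: int = 0, max_tries: int = 5000):
    """Place ``n_cells`` non-overlapping spherocylinders in a square field
    of view, by rejection on bounding circles. Returns CellGeometry list."""
    from .simulator import CellGeometry

    rng = np.random.default_rng(seed)
    cells: list[CellGeometry] = []
    radii: list[float] = []
    for _ in range(max_tries):
        if len(cells) == n_cells:
            break
        w = rng.uniform(*width_range)
        length = rng.uniform(*length_range)
        ang = rng.uniform(0, np.pi)
        r_bound = length / 2.0
        cx = rng.uniform(margin_um + r_bound, fov_um - margin_um - r_bound)
        cy = rng.uniform(margin_um + r_bound, fov_um - margin_um - r_bound)
        ok = True
        for c, rb in zip(cells, radii):
            d = np.hypot(cx - c.center[0], cy - c.center[1])
            if d < r_bound + rb + min_gap_um:
                ok = False
                break
        if ok:
            cells.append(CellGeometry(width_um=w, length_um=length,
                                      center=(cx, cy, 0.0), axis_angle=ang))
            radii.append(r_bound)
    if len(cells) < n_cells:
        raise RuntimeError("could not place all cells; enlarge the field")
    return cells


def footprint_mask(cells, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    """Ground-truth label mask: pixel centers within the midplane footprint
    (capsule of half-width w/2 around the axis segment) of each cell."""
    h, w_px = shape
    yy, xx = np.mgrid[0:h, 0:w_px]
    xs = xx * pixel_size
    ys = yy * pixel_size
    labels = np.zeros(shape, dtype=np.int32)
    for k, g in enumerate(cells, start=1):
        half = (g.length_um - g.width_um) / 2.0
        dx = np.cos(g.axis_angle) * half
        dy = np.sin(g.axis_angle) * half
        ax, ay = g.center[0] - dx, g.center[1] - dy
        bx, by = g.center[0] + dx, g.center[1] + dy
        px = xs - ax
        py = ys - ay
        ux, uy = bx - ax, by - ay
        denom = ux * ux + uy * uy
        t = np.clip((px * ux + py * uy) / denom, 0.0, 1.0) if denom > 0 else 0.0
        d2 = (px - t * ux) ** 2 + (py - t * uy) ** 2
        labels[d2 <= (g.width_um / 2.0) ** 2] = k
    return labels


def length_varying_population(n_cells: int, width_um: float = 1.0,
                              length_range=(2.0, 5.0), seed: int = 0,
                              spacing_um: float = 0.05) -> list[Contour]:
    """Population whose only shape variation is elongation."""
    rng = np.random.default_rng(seed)
    lengths = rng.uniform(*length_range, size=n_cells)
    return [spherocylinder_contour(width_um, float(L), spacing_um)
            for L in lengths]
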