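"""Sub-pixel closed-contour refinement by contour-energy minimization.

The boundary-intensity map (bright along the cell outline for every
modality) is treated as an interpolated energy landscape: a closed polyline
initialized at the segmented object boundary descends

    E = sum_i [ -I(v_i) + alpha |v_{i+1} - v_i|^2
                        + beta  |v_{i+1} - 2 v_i + v_{i-1}|^2 ]

by explicit gradient descent with backtracking (a step that raises E or
self-intersects is reverted and the step size halved), with periodic
arclength reparameterization. I is a bicubic interpolation of the map
scaled to [0, 1], so the image term dominates the weak smoothness terms and
the result tracks the intensity ridge to sub-pixel accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .core import Contour, Image, ensure_ccw, is_simple, resample_closed


class ContourCollapse(RuntimeError):
    """Persistent self-intersection / failure to descend; drop the object."""


@dataclass
class SnakeParams:
    """Numerical controls for the contour descent (not shape priors).

    alpha : tension weight on first differences (px^-2 units).
    beta : stiffness weight on second differences.
    step : initial gradient-descent step (px per unit force).
    tol : convergence threshold on max vertex displacement (px).
    max_iter : iteration cap.
    spacing_px : target vertex spacing for (re)parameterization.
    """

    alpha: float = 0.05
    beta: float = 0.5
    step: float = 0.2
    tol: float = 1e-3
    max_iter: int = 500
    spacing_px: float = 1.0
    ridge_snap: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "step", "tol", "spacing_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tol >= 0.1:
            raise ValueError("tol must be below 0.1 px")


def seed_boundary(mask: np.ndarray) -> np.ndarray:
    """Closed (x, y) pixel-coordinate boundary of a binary object mask."""
    from skimage import measure

    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("empty seed mask")
    rc = max(contours, key=len)          # (row, col)
    xy = rc[:, ::-1]
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    return xy


def _energy(v: np.ndarray, interp, alpha: float, beta: float) -> float:
    image_term = -np.sum(interp.ev(v[:, 1], v[:, 0]))
    d1 = np.roll(v, -1, axis=0) - v
    d2 = np.roll(v, -1, axis=0) - 2 * v + np.roll(v, 1, axis=0)
    return float(image_term + alpha * np.sum(d1 * d1) + beta * np.sum(d2 * d2))


def _gradient(v: np.ndarray, interp, alpha: float, beta: float) -> np.ndarray:
    gx = interp.ev(v[:, 1], v[:, 0], dy=1)   # d/dx (x is the 2nd spline axis)
    gy = interp.ev(v[:, 1], v[:, 0], dx=1)
    g_img = -np.column_stack([gx, gy])
    g_t = 2 * alpha * (2 * v - np.roll(v, -1, axis=0) - np.roll(v, 1, axis=0))
    g_s = 2 * beta * (np.roll(v, -2, axis=0) - 4 * np.roll(v, -1, axis=0)
                      + 6 * v - 4 * np.roll(v, 1, axis=0)
                      + np.roll(v, 2, axis=0))
    return g_img + g_t + g_s


def _snap_to_ridge(v: np.ndarray, img: np.ndarray,
                   seed_mask: np.ndarray) -> np.ndarray:
    """Move each seed-boundary vertex to the boundary-map maximum along its
    inward normal.

    The descent itself has only short-range attraction (the image force
    vanishes on the flat halo of defocused light outside a cell), so the
    initialization must land within ~1 px of the intensity ridge. The
    search extent is bounded by the object's half-thickness so a vertex
    cannot jump across a thin cell to the opposite rim.
    """
    from scipy import ndimage as ndi
    from scipy.ndimage import map_coordinates

    smooth = ndi.gaussian_filter(img, 1.0, mode="nearest")
    dist = ndi.distance_transform_edt(seed_mask).astype(float)
    reach = float(np.clip(dist.max(), 2.0, 15.0))

    vv = ensure_ccw(v)
    tang = np.roll(vv, -1, axis=0) - np.roll(vv, 1, axis=0)
    tn = np.linalg.norm(tang, axis=1, keepdims=True)
    tn[tn == 0] = 1.0
    # CCW: interior on the left of travel -> inward normal is the left normal
    inward = np.column_stack([-tang[:, 1], tang[:, 0]]) / tn
    offsets = np.linspace(0.0, reach, max(8, int(2 * reach) + 1))
    n = len(vv)
    h, w = img.shape
    vals = np.empty((n, len(offsets)))
    dvals = np.empty((n, len(offsets)))
    for j, off in enumerate(offsets):
        pts = vv + off * inward
        pts[:, 0] = np.clip(pts[:, 0], 0, w - 1)
        pts[:, 1] = np.clip(pts[:, 1], 0, h - 1)
        vals[:, j] = map_coordinates(smooth, [pts[:, 1], pts[:, 0]], order=1)
        dvals[:, j] = map_coordinates(dist, [pts[:, 1], pts[:, 0]], order=1)
    # each ray stops at the object's medial axis (where the distance
    # transform peaks): a vertex must not jump across a thin cell
    limit = np.argmax(dvals, axis=1)
    masked = np.where(np.arange(len(offsets))[None, :] <= limit[:, None],
                      vals, -np.inf)
    best = offsets[np.argmax(masked, axis=1)]
    # smooth the offsets along the contour so converging normals at the
    # poles cannot cross and create self-intersections
    kernel = np.ones(5) / 5.0
    pad = 2
    best = np.convolve(np.concatenate([best[-pad:], best, best[:pad]]),
                       kernel, mode="valid")
    return vv + best[:, None] * inward


def _make_simple(v: np.ndarray) -> np.ndarray:
    """Repair a self-intersecting closed polyline by taking the exterior
    of its zero-buffer polygon (largest piece)."""
    from shapely.geometry import MultiPolygon, Polygon

    poly = Polygon(v).buffer(0)
    if isinstance(poly, MultiPolygon):
        poly = max(poly.geoms, key=lambda g: g.area)
    if poly.is_empty:
        raise ContourCollapse("contour collapse: degenerate seed")
    return np.asarray(poly.exterior.coords)[:-1]


def fit_contour(bmap: Image, seed_mask: np.ndarray,
                p: SnakeParams | None = None) -> Contour:
    """Fit a closed sub-pixel contour to the intensity ridge of the
    boundary map, seeded at the given object's pixel boundary.

    Raises ContourCollapse if the descent cannot keep the contour simple.
    """
    p = p or SnakeParams()
    img = np.asarray(bmap.pixels, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi > lo:
        img = (img - lo) / (hi - lo)
    h, w = img.shape
    interp = RectBivariateSpline(np.arange(h), np.arange(w), img, kx=3, ky=3)

    try:
        v = resample_closed(seed_boundary(seed_mask), spacing=p.spacing_px)
    except ValueError as err:
        raise ContourCollapse(f"contour collapse: {err}") from err
    v[:, 0] = np.clip(v[:, 0], 0, w - 1)
    v[:, 1] = np.clip(v[:, 1], 0, h - 1)
    if p.ridge_snap:
        try:
            v = _snap_to_ridge(v, img, seed_mask)
            if not is_simple(v):
                v = _make_simple(v)
            v = resample_closed(v, spacing=p.spacing_px)
        except ValueError as err:
            raise ContourCollapse(f"contour collapse: {err}") from err
        v[:, 0] = np.clip(v[:, 0], 0, w - 1)
        v[:, 1] = np.clip(v[:, 1], 0, h - 1)

    step = p.step
    energy = _energy(v, interp, p.alpha, p.beta)
    trace = [(0, energy, False)]
    accepted = 0
    it = 0
    while it < p.max_iter:
        it += 1
        grad = _gradient(v, interp, p.alpha, p.beta)
        v_new = v - step * grad
        v_new[:, 0] = np.clip(v_new[:, 0], 0, w - 1)
        v_new[:, 1] = np.clip(v_new[:, 1], 0, h - 1)
        e_new = _energy(v_new, interp, p.alpha, p.beta)
        if e_new > energy + 1e-12:
            step *= 0.5
            if step < p.step / 1024.0:
                break  # stalled at a minimum of the discretized landscape
            continue
        disp = float(np.max(np.linalg.norm(v_new - v, axis=1)))
        v, energy = v_new, e_new
        accepted += 1
        trace.append((it, energy, False))
        if accepted % 10 == 0:
            if not is_simple(v):
                # revert is impossible post-assignment; shrink the step and
                # reparameterize, which repairs near-degenerate geometry
                step *= 0.5
                if step < p.step / 1024.0:
                    raise ContourCollapse("contour collapse: persistent "
                                          "self-intersection")
            try:
                v = resample_closed(v, spacing=p.spacing_px)
            except ValueError as err:
                raise ContourCollapse(f"contour collapse: {err}") from err
            energy = _energy(v, interp, p.alpha, p.beta)
            trace.append((it, energy, True))
        if disp < p.tol:
            break

    try:
        v = resample_closed(v, spacing=p.spacing_px)
    except ValueError as err:
        raise ContourCollapse(f"contour collapse: {err}") from err
    if not is_simple(v):
        raise ContourCollapse("contour collapse: result self-intersects")
    if len(v) < 20:
        raise ContourCollapse("contour collapse: too few vertices")
    v = ensure_ccw(v)
    return Contour(v, pixel_size=bmap.pixel_size,
                   diagnostics={"energy_trace": trace, "iterations": it,
                                "final_step": step})


def translate_contour(c: Contour, dx: float, dy: float) -> Contour:
    """Rigid translation in pixels, e.g. to correct inter-channel optical
    shifts; every derived measurement is invariant."""
    return Contour(c.vertices + np.array([dx, dy]), pixel_size=c.pixel_size,
                   diagnostics=dict(c.diagnostics))
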