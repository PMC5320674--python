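"""Cellular coordinate system: curvature profiles, pole detection,
midline meshes, and scalar shape measurements.

The mesh turns a closed contour into a midline with perpendicular
meshlines connecting opposite sides of the cell; meshline lengths are the
local cell widths and the midline arc length is the cell length. Pole
detection doubles as the segmentation-error filter: only contours with
exactly two well-separated high-curvature maxima are accepted.

Sign convention (counterclockwise contours): curvature is positive where
the outline is locally convex (bulging outward, e.g. the poles) and
negative where it is concave (indentations, the inside of a bend).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (Contour, arc_length, cumulative_arclength, resample_open,
                   segment_lengths, signed_area)


class MeshError(ValueError):
    """Raised when a contour cannot be meshed (mesh failure)."""


class WindowTooSmall(ValueError):
    """Curvature window covers fewer than 5 vertices."""


@dataclass
class CurvatureProfile:
    """Signed curvature (1/um) at each contour vertex."""

    kappa: np.ndarray
    window_arc_um: float


@dataclass
class PoleResult:
    """Outcome of the two-pole filter; ``accepted`` iff exactly two
    high-curvature maxima were found."""

    accepted: bool
    indices: tuple[int, int] | None
    n_found: int


@dataclass
class Mesh:
    midline: np.ndarray          # (M, 2) um
    left: np.ndarray             # (M, 2) um, one side of the contour
    right: np.ndarray            # (M, 2) um, opposite side
    widths: np.ndarray           # (M,) um
    pole_indices: tuple[int, int] | None
    kind: str                    # "centerline" or "branching"
    arms: list | None = None     # branching only: list of (K,2) polylines
    branch_points: np.ndarray | None = None


@dataclass
class CellMeasurement:
    length_um: float
    mean_width_um: float
    max_width_um: float
    area_um2: float
    width_cv: float
    n_poles: int = 2


def _fit_circle(points: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Algebraic (Kasa) least-squares circle fit on centered coordinates.

    Returns None for (near-)collinear windows — the rank-deficient system
    would otherwise produce an arbitrary min-norm center — so callers treat
    them as locally flat (kappa = 0).
    """
    mean = points.mean(axis=0)
    q = points - mean
    cov = q.T @ q / len(q)
    evals = np.linalg.eigvalsh(cov)
    if evals[-1] <= 0 or evals[0] / evals[-1] < 1e-8:
        return None
    a_mat = np.column_stack([q, np.ones(len(q))])
    b = np.sum(q * q, axis=1)
    try:
        sol, *_ = np.linalg.lstsq(a_mat, b, rcond=None)
    except np.linalg.LinAlgError:
        return None
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx * cx + cy * cy
    if not np.isfinite(r2) or r2 <= 0:
        return None
    return np.array([cx, cy]) + mean, float(np.sqrt(r2))


def curvature_profile(c: Contour, window_arc_um: float = 0.25) -> CurvatureProfile:
    """Least-squares circle fit within ±window_arc_um of arclength around
    each vertex; kappa = ±1/R with the sign set by which side of the
    contour the fitted center lies on."""
    v = c.vertices_um()
    n = len(v)
    s = cumulative_arclength(v, closed=True)
    per = arc_length(v, closed=True)
    mean_spacing = per / n
    halfwin = max(1, int(round(window_arc_um / mean_spacing)))
    if 2 * halfwin + 1 < 5:
        raise WindowTooSmall(
            f"window of ±{window_arc_um} um covers only "
            f"{2 * halfwin + 1} vertices")

    ccw = signed_area(v) > 0
    kappa = np.zeros(n)
    idx = np.arange(-halfwin, halfwin + 1)
    # tangent by central differences (periodic)
    tang = np.roll(v, -1, axis=0) - np.roll(v, 1, axis=0)
    for i in range(n):
        win = v[(i + idx) % n]
        fit = _fit_circle(win)
        if fit is None:
            continue
        center, radius = fit
        # guard: collinear windows blow the radius up; treat as flat
        if radius > 100.0 * per:
            continue
        # guard: at inflections the algebraic fit can return a spuriously
        # tiny radius; the chord/sagitta of the window bounds the credible
        # curvature, so reject fits far beyond it (window is locally flat)
        chord_vec = win[-1] - win[0]
        chord = np.linalg.norm(chord_vec)
        if chord > 0:
            t_hat = chord_vec / chord
            dev = np.abs((win - win[0]) @ np.array([-t_hat[1], t_hat[0]]))
            kappa_sag = 8.0 * dev.max() / chord ** 2
            if 1.0 / radius > 4.0 * kappa_sag + 1e-9:
                continue
        t = tang[i]
        tn = np.linalg.norm(t)
        if tn == 0:
            continue
        # inward normal: left of travel for CCW, right for CW
        n_in = np.array([-t[1], t[0]]) / tn
        if not ccw:
            n_in = -n_in
        sign = 1.0 if np.dot(center - v[i], n_in) > 0 else -1.0
        kappa[i] = sign / radius
    return CurvatureProfile(kappa=kappa, window_arc_um=window_arc_um)


def find_poles(prof: CurvatureProfile, c: Contour,
               n_mads: float = 2.0,
               min_separation_frac: float = 0.25) -> PoleResult:
    """Locate the cell poles as curvature maxima above median + n_mads*MAD,
    mutually separated by at least ``min_separation_frac`` of the
    perimeter. Accept iff exactly two exist (the rod-shape filter)."""
    n = len(prof.kappa)
    v = c.vertices_um()
    s = cumulative_arclength(v, closed=True)
    per = arc_length(v, closed=True)

    # detection uses a coarser, denoised profile: wide cells pair low cap
    # curvature (2/w) with unchanged contour noise, and circle-fit noise
    # falls quadratically with window size. The window is capped at
    # 0.5 um so it stays inside typical cylindrical flanks, and the
    # vertices are pre-smoothed along arclength (detection only; the
    # reported profile is untouched)
    det_window = max(prof.window_arc_um, min(per / 30.0, 0.5))
    if det_window > 1.5 * prof.window_arc_um or n >= 100:
        from scipy.ndimage import gaussian_filter1d

        sigma_v = (0.67 * det_window) / (per / n)
        if sigma_v > 0.5:
            v_s = gaussian_filter1d(c.vertices, sigma=sigma_v, axis=0,
                                    mode="wrap")
            c_s = Contour(v_s, pixel_size=c.pixel_size)
        else:
            c_s = c
        prof = curvature_profile(c_s, det_window)

    # light smoothing on top, so single-vertex spikes cannot be runs
    win = max(3, int(round(det_window / (per / n))) | 1)
    kernel = np.ones(win) / win
    pad = win // 2
    wrapped = np.concatenate([prof.kappa[-pad:], prof.kappa,
                              prof.kappa[:pad]])
    kappa = np.convolve(wrapped, kernel, mode="valid")

    from scipy.signal import find_peaks

    kmin = float(kappa.min())
    kmax = float(kappa.max())
    # numerical-noise floor: a uniform profile (circle) must yield no maxima
    if kmax - kmin < 1e-6 * max(abs(kmax), abs(kmin), 1e-12):
        return PoleResult(False, None, 0)

    # background level = 10th percentile: the flat flanks always hold at
    # least a modest share of the vertices, while any median-like statistic
    # is dragged to cap level for short fat rods whose caps dominate the
    # perimeter; poles must rise at least halfway from background to the
    # profile maximum, and clear the background by n_mads MADs
    low = kappa[kappa <= np.percentile(kappa, 20)]
    med_low = float(np.median(low))
    mad = float(np.median(np.abs(low - med_low)))
    bg = float(np.percentile(kappa, 10))
    scale = kmax - bg
    height = max(bg + 0.5 * scale, med_low + n_mads * mad)

    # circular peak finding: wrap, detect, keep peaks in the central copy
    ext = np.concatenate([kappa[-n // 2:], kappa, kappa[:n // 2]])
    locs, _ = find_peaks(ext, height=height, prominence=0.25 * scale)
    peaks = sorted({int((i - n // 2) % n) for i in locs
                    if n // 2 <= i < n // 2 + n})
    if not peaks:
        return PoleResult(False, None, 0)

    # valley merge: two maxima belong to the same pole region when the
    # profile between them never falls back toward background (e.g. noise
    # peaks on one broad cap); only a genuine low-curvature valley (a
    # flank) separates distinct poles
    valley = bg + 0.25 * scale

    def merged_with_valley(ps):
        if len(ps) < 2:
            return ps
        ps = sorted(ps)
        out = []

        def same_region(lo_peak, hi_peak, seg_k):
            # the dividing valley must fall at least halfway back toward
            # background relative to the smaller of the two peaks — a
            # merely-convex stretch (e.g. the outer flank of a bent cell)
            # does not merge two genuine poles
            lim = max(valley,
                      bg + 0.5 * (min(kappa[lo_peak], kappa[hi_peak]) - bg))
            return seg_k.min() > lim

        groups = [[ps[0]]]
        for i in ps[1:]:
            prev = groups[-1][-1]
            if same_region(prev, i, kappa[prev:i + 1]):
                groups[-1].append(i)
            else:
                groups.append([i])
        # wrap-around: first and last group may be one region
        if len(groups) > 1:
            seg_k = np.concatenate([kappa[groups[-1][-1]:],
                                    kappa[:groups[0][0] + 1]])
            if same_region(groups[-1][-1], groups[0][0], seg_k):
                groups[0] = groups.pop() + groups[0]
        for grp in groups:
            out.append(max(grp, key=lambda i: kappa[i]))
        return out

    peaks = merged_with_valley(peaks)

    # greedy clustering: keep the strongest peak, absorb any peak closer
    # than the separation threshold along the contour
    order = sorted(peaks, key=lambda i: -kappa[i])
    kept: list[int] = []
    min_sep = min_separation_frac * per
    for i in order:
        close = False
        for j in kept:
            d = abs(s[i] - s[j])
            d = min(d, per - d)
            if d < min_sep:
                close = True
                break
        if not close:
            kept.append(i)
    # a genuine pole turns the contour substantially; integrate the
    # detected curvature over each cluster's high region and discard
    # clusters turning less than pi/4 (tall-but-narrow noise bumps)
    ds = per / n
    thr_r = bg + 0.25 * scale

    def turning_of(peak: int) -> float:
        total = kappa[peak] * ds
        i = peak
        while kappa[(i - 1) % n] >= thr_r and (peak - i) % n < n - 1:
            i = (i - 1) % n
            total += kappa[i] * ds
        i = peak
        while kappa[(i + 1) % n] >= thr_r and (i - peak) % n < n - 1:
            i = (i + 1) % n
            total += kappa[i] * ds
        return total

    kept = [i for i in kept if turning_of(i) >= np.pi / 4]
    if len(kept) != 2:
        return PoleResult(False, None, len(kept))

    # refine pole locations: curvature peaks localize poorly on flat or
    # noisy cap plateaus, so once the two-pole topology is established,
    # place the poles at the mutually farthest vertex pair (iterated to a
    # fixed point from the detected peaks) — for capped rods, the apices
    a, b = kept
    for _ in range(3):
        a_new = int(np.argmax(np.linalg.norm(v - v[b], axis=1)))
        b_new = int(np.argmax(np.linalg.norm(v - v[a_new], axis=1)))
        if (a_new, b_new) == (a, b):
            break
        a, b = a_new, b_new
    i1, i2 = sorted((a, b))
    return PoleResult(True, (i1, i2), 2)


def _segments_cross(p1, p2, q1, q2) -> bool:
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1 = orient(q1, q2, p1)
    d2 = orient(q1, q2, p2)
    d3 = orient(p1, p2, q1)
    d4 = orient(p1, p2, q2)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def build_centerline_mesh(c: Contour, poles: tuple[int, int],
                          n_stations: int | None = None) -> Mesh:
    """Split the contour at the two poles, resample both arcs to M equally
    spaced points, pair opposite points into meshlines, and refine the
    pairing once so meshlines are perpendicular to the local midline."""
    v = c.vertices_um()
    n = len(v)
    i1, i2 = poles
    if not (0 <= i1 < n and 0 <= i2 < n and i1 != i2):
        raise MeshError("invalid pole indices")

    arc_a = v[i1:i2 + 1]
    arc_b = np.vstack([v[i2:], v[:i1 + 1]])[::-1]  # pole1 -> pole2 too

    per_px = arc_length(v, closed=True) / c.pixel_size
    m = n_stations or max(50, int(round(per_px / 2)))
    a = resample_open(arc_a, m)
    b = resample_open(arc_b, m)

    def midline_of(a_pts, b_pts):
        return 0.5 * (a_pts + b_pts)

    mid = midline_of(a, b)

    # one refinement pass: re-pair each a-point with the b-point whose
    # connecting segment is most nearly perpendicular to the local
    # (smoothed) midline; monotone pairing prevents crossings. The refined
    # pairing is kept only if it actually improves perpendicularity — for
    # straight rods the symmetric equal-arclength pairing is already
    # optimal and re-pairing against a noisy tangent field would only
    # inject station jitter, while for bent cells the refinement wins.
    from scipy.ndimage import gaussian_filter1d as _g1d

    def perp_error(bb):
        d = bb - a
        dn = np.linalg.norm(d, axis=1)
        dn[dn == 0] = 1.0
        mid_s = _g1d(0.5 * (a + bb), sigma=max(1.0, m / 100), axis=0,
                     mode="nearest")
        t = np.gradient(mid_s, axis=0)
        tn = np.linalg.norm(t, axis=1, keepdims=True)
        tn[tn == 0] = 1.0
        dots = ((d / dn[:, None]) * (t / tn)).sum(axis=1)
        return float(np.mean(np.abs(dots[1:-1])))

    mid_s = _g1d(mid, sigma=max(1.0, m / 100), axis=0, mode="nearest")
    tan = np.gradient(mid_s, axis=0)
    norm = np.linalg.norm(tan, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    tan = tan / norm
    win = max(3, m // 8)
    pair = np.arange(m)
    for i in range(1, m - 1):
        lo = max(1, i - win)
        hi = min(m - 1, i + win + 1)
        cand = np.arange(lo, hi)
        d = b[cand] - a[i]
        dn = np.linalg.norm(d, axis=1)
        dn[dn == 0] = 1.0
        score = np.abs((d / dn[:, None] * tan[i]).sum(axis=1))
        pair[i] = cand[np.argmin(score)]
    pair = np.maximum.accumulate(pair)
    pair = np.clip(pair, 0, m - 1)
    pair[0], pair[-1] = 0, m - 1
    if perp_error(b[pair]) < perp_error(b):
        b_ref = b[pair]
    else:
        b_ref = b.copy()
    mid = midline_of(a, b_ref)
    widths = np.linalg.norm(a - b_ref, axis=1)

    def crossing_of(bb):
        # crossings among the vanishing meshlines at the poles are benign
        # (they never enter any measurement); only substantive ones count
        wmax = float(np.linalg.norm(a - bb, axis=1).max())
        floor = 0.2 * wmax
        return [i for i in range(1, m - 2)
                if np.linalg.norm(a[i] - bb[i]) >= floor
                and np.linalg.norm(a[i + 1] - bb[i + 1]) >= floor
                and _segments_cross(a[i], bb[i], a[i + 1], bb[i + 1])]

    crossing = crossing_of(b_ref)
    if crossing:
        for i in crossing:  # local reorder
            b_ref[[i, i + 1]] = b_ref[[i + 1, i]]
        if crossing_of(b_ref):
            # fall back to the plain equal-arclength pairing
            b_ref = b.copy()
            if crossing_of(b_ref):
                raise MeshError("mesh failure: crossing meshlines persist")
        mid = midline_of(a, b_ref)
        widths = np.linalg.norm(a - b_ref, axis=1)

    widths[0] = 0.0
    widths[-1] = 0.0

    # light smoothing of the midline (~0.1 um): station-level jitter from
    # image noise otherwise accumulates into a systematic overestimate of
    # the arc length, while genuine cell bending (radii >> 0.1 um) is
    # preserved; the pole endpoints stay pinned
    from scipy.ndimage import gaussian_filter1d

    station = arc_length(mid, closed=False) / max(m - 1, 1)
    sigma = 0.1 / max(station, 1e-9)
    if sigma > 0.5:
        ends = mid[[0, -1]].copy()
        mid = gaussian_filter1d(mid, sigma=sigma, axis=0, mode="nearest")
        mid[[0, -1]] = ends

    return Mesh(midline=mid, left=a, right=b_ref, widths=widths,
                pole_indices=(i1, i2), kind="centerline")


def measure_cell(c: Contour, m: Mesh) -> CellMeasurement:
    """Scalar geometry of one cell from its centerline mesh.

    The mean width and its intracellular variability are computed over the
    central region only — stations at least max_width/2 of midline
    arclength away from each pole — so the tapering caps do not bias them.
    """
    if m.kind != "centerline":
        raise MeshError("measurements require a centerline mesh")
    seg = segment_lengths(m.midline, closed=False)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    length = float(s[-1])
    max_w = float(np.max(m.widths))
    central = (s >= max_w / 2.0) & (s <= length - max_w / 2.0)
    if not np.any(central):
        central = np.ones_like(s, dtype=bool)
    wc = m.widths[central]
    mean_w = float(np.mean(wc))
    cv = float(np.std(wc) / mean_w) if mean_w > 0 else 0.0
    area = abs(signed_area(c.vertices_um()))
    return CellMeasurement(length_um=length, mean_width_um=mean_w,
                           max_width_um=max_w, area_um2=float(area),
                           width_cv=cv, n_poles=2)


def classify_meshlines(m: Mesh, prof: CurvatureProfile, c: Contour) -> list[str]:
    """Label each meshline by the curvature signs at its two endpoints:
    ``both_positive`` (cyan in the classic rendering), ``both_negative``
    (indented on both sides), or ``mixed`` (the cell body curves there).
    Exact zero counts as positive."""
    v = c.vertices_um()

    def sign_at(point):
        i = int(np.argmin(np.sum((v - point) ** 2, axis=1)))
        return 1.0 if prof.kappa[i] >= 0 else -1.0

    labels = []
    for left, right in zip(m.left, m.right):
        sl, sr = sign_at(left), sign_at(right)
        if sl > 0 and sr > 0:
            labels.append("both_positive")
        elif sl < 0 and sr < 0:
            labels.append("both_negative")
        else:
            labels.append("mixed")
    return labels


def profile_fluorescence(c: Contour, fluor_img, half_width_px: float = 1.0,
                         n_samples: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Boundary fluorescence profile: bilinear intensity at each vertex,
    averaged over ±half_width_px along the local normal. Returns
    (arclength_um, profile); entries are NaN where sampling left the image.
    """
    from scipy.ndimage import map_coordinates

    v = c.vertices  # pixel coords
    img = np.asarray(fluor_img.pixels if hasattr(fluor_img, "pixels")
                     else fluor_img, dtype=float)
    tang = np.roll(v, -1, axis=0) - np.roll(v, 1, axis=0)
    tn = np.linalg.norm(tang, axis=1, keepdims=True)
    tn[tn == 0] = 1.0
    normal = np.column_stack([-tang[:, 1], tang[:, 0]]) / tn
    offsets = np.linspace(-half_width_px, half_width_px, max(1, n_samples))
    samples = np.empty((len(v), len(offsets)))
    h, w = img.shape
    for j, off in enumerate(offsets):
        pts = v + off * normal
        inside = ((pts[:, 0] >= 0) & (pts[:, 0] <= w - 1)
                  & (pts[:, 1] >= 0) & (pts[:, 1] <= h - 1))
        vals = map_coordinates(img, [pts[:, 1], pts[:, 0]], order=1,
                               mode="nearest")
        vals[~inside] = np.nan
        samples[:, j] = vals
    bad = np.any(np.isnan(samples), axis=1)
    profile = np.full(len(v), np.nan)
    if np.any(~bad):
        profile[~bad] = samples[~bad].mean(axis=1)
    s_um = cumulative_arclength(v, closed=True) * c.pixel_size
    return s_um, profile


# ---------------------------------------------------------------------------
# Branching (medial-axis) mesh


def build_branching_mesh(c: Contour, resample_um: float = 0.03) -> Mesh:
    """Medial-axis mesh via the Voronoi diagram of the densely resampled
    contour, pruned of spurs shorter than one local width, with the
    surviving leaf ends extended to the contour. Supports non-rod shapes
    (a Y-shaped cell yields a three-armed midline with one branch point).
    """
    import networkx as nx
    from scipy.spatial import Voronoi, cKDTree
    from shapely.geometry import Point, Polygon

    from .core import resample_closed

    v = resample_closed(c.vertices_um(), spacing=resample_um)
    poly = Polygon(v)
    vor = Voronoi(v)
    verts = vor.vertices
    inside = np.array([poly.contains(Point(p)) for p in verts])
    tree = cKDTree(v)
    radius, _ = tree.query(verts)

    g = nx.Graph()
    for (p, q) in vor.ridge_vertices:
        if p < 0 or q < 0 or not (inside[p] and inside[q]):
            continue
        w = float(np.linalg.norm(verts[p] - verts[q]))
        g.add_edge(p, q, weight=w)
    if g.number_of_nodes() == 0:
        raise MeshError("empty medial axis")
    # largest connected component
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp).copy()

    # iteratively prune leaf branches shorter than the local width (2*radius)
    changed = True
    while changed and g.number_of_nodes() > 2:
        changed = False
        leaves = [n for n in g.nodes if g.degree(n) == 1]
        for leaf in leaves:
            path = [leaf]
            length = 0.0
            node = leaf
            while g.degree(node) <= 2:
                nbrs = [x for x in g.neighbors(node) if x not in path]
                if not nbrs:
                    break
                nxt = nbrs[0]
                length += g[node][nxt]["weight"]
                path.append(nxt)
                node = nxt
                if g.degree(node) >= 3:
                    break
            attach = path[-1]
            local_width = 2.0 * radius[attach]
            if g.degree(attach) >= 3 and length < local_width:
                g.remove_nodes_from(path[:-1])
                changed = True

    # decompose into arms (paths between endpoints/junctions)
    junctions = [n for n in g.nodes if g.degree(n) >= 3]
    leaves = [n for n in g.nodes if g.degree(n) == 1]
    endpoints = set(junctions) | set(leaves)
    arms = []
    visited_edges = set()
    for start in endpoints:
        for nbr in g.neighbors(start):
            edge = frozenset((start, nbr))
            if edge in visited_edges:
                continue
            path = [start, nbr]
            visited_edges.add(edge)
            while path[-1] not in endpoints:
                nxts = [x for x in g.neighbors(path[-1]) if x != path[-2]]
                if not nxts:
                    break
                visited_edges.add(frozenset((path[-1], nxts[0])))
                path.append(nxts[0])
            arm = verts[path]
            # free (leaf) arm ends wander inside the caps, where the
            # Voronoi skeleton of a sampled boundary grows spurs that can
            # merge into the trunk: trim one local radius off the end,
            # then extend straight to the contour along a tangent
            # estimated over a radius-long window
            for end in (0, -1):
                if g.degree(path[end]) != 1:
                    continue
                r_end = float(radius[path[end]])
                a_ = arm if end == 0 else arm[::-1]
                seg = np.linalg.norm(np.diff(a_, axis=0), axis=1)
                s_ = np.concatenate([[0.0], np.cumsum(seg)])
                cut = int(np.searchsorted(s_, r_end))
                cut = min(cut, max(len(a_) - 2, 0))
                a_ = a_[cut:]
                if len(a_) >= 2:
                    ref = int(np.searchsorted(
                        np.concatenate([[0.0], np.cumsum(
                            np.linalg.norm(np.diff(a_, axis=0), axis=1))]),
                        r_end))
                    ref = min(max(ref, 1), len(a_) - 1)
                    d = a_[0] - a_[ref]
                    nd = np.linalg.norm(d)
                    if nd > 0:
                        from shapely.geometry import LineString

                        ray = LineString([a_[0], a_[0] + d / nd * 4 * r_end])
                        hit = ray.intersection(poly.exterior)
                        if not hit.is_empty:
                            if hasattr(hit, "geoms"):
                                hit = min(
                                    hit.geoms,
                                    key=lambda gg: np.linalg.norm(
                                        np.asarray(gg.coords)[0] - a_[0]))
                            pt = np.asarray(hit.coords)[0]
                            a_ = np.vstack([pt, a_])
                arm = a_ if end == 0 else a_[::-1]
            arms.append(arm)

    # main midline: longest arm chain (for rods: the single arm)
    def arm_len(a):
        return arc_length(a, closed=False)

    arms.sort(key=arm_len, reverse=True)
    midline = arms[0]

    # meshlines: inscribed-circle diameters perpendicular to the axis
    tan = np.gradient(midline, axis=0)
    tn = np.linalg.norm(tan, axis=1, keepdims=True)
    tn[tn == 0] = 1.0
    tan = tan / tn
    nrm = np.column_stack([-tan[:, 1], tan[:, 0]])
    rad_mid, _ = tree.query(midline)
    left = midline + nrm * rad_mid[:, None]
    right = midline - nrm * rad_mid[:, None]
    widths = 2.0 * rad_mid
    bp = verts[junctions] if junctions else None
    return Mesh(midline=midline, left=left, right=right, widths=widths,
                pole_indices=None, kind="branching", arms=arms,
                branch_points=bp)
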