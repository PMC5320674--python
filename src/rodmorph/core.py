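"""Shared primitives: the image container and closed-polyline geometry.

All geometry in this package lives in one of two coordinate systems:

* pixel coordinates — 0-based, row-major arrays; ``x`` is the column index,
  ``y`` the row index; pixel centers sit at integer coordinates.
* physical coordinates — micrometers, obtained by multiplying pixel
  coordinates by ``pixel_size``.

Closed contours are stored as ``(N, 2)`` arrays of ``(x, y)`` vertices with
no repeated endpoint, oriented counterclockwise (interior on the left of the
direction of travel), so the outward normal and the curvature sign convention
are fixed package-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODALITIES = ("PC", "IF", "PF")


@dataclass
class Image:
    """A single grayscale micrograph with physical calibration.

    Parameters
    ----------
    pixels : 2D float array of non-negative intensities.
    pixel_size : micrometers per pixel (> 0).
    modality : "PC" (phase contrast), "IF" (interior fluorescence) or
        "PF" (peripheral / surface fluorescence).
    z_offset : focal-plane offset in micrometers (0 for experimental data).
    """

    pixels: np.ndarray
    pixel_size: float
    modality: str = "PF"
    z_offset: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class Contour:
    """Closed sub-pixel cell outline.

    ``vertices`` are ``(x, y)`` in pixel units; multiply by ``pixel_size``
    for micrometers. Orientation is counterclockwise.
    """

    vertices: np.ndarray
    pixel_size: float
    diagnostics: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be (N, 2)")
        if len(self.vertices) < 3:
            raise ValueError("a closed contour needs at least 3 vertices")

    def vertices_um(self) -> np.ndarray:
        return self.vertices * self.pixel_size

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


def segment_lengths(vertices: np.ndarray, closed: bool = True) -> np.ndarray:
    """Edge lengths; for a closed polyline the last edge wraps around."""
    v = np.asarray(vertices, dtype=float)
    nxt = np.roll(v, -1, axis=0) if closed else v[1:]
    cur = v if closed else v[:-1]
    return np.linalg.norm(nxt - cur, axis=1)


def arc_length(vertices: np.ndarray, closed: bool = True) -> float:
    return float(segment_lengths(vertices, closed).sum())


def cumulative_arclength(vertices: np.ndarray, closed: bool = True) -> np.ndarray:
    """Arclength station of each vertex, starting at 0 for vertex 0."""
    seg = segment_lengths(vertices, closed)
    s = np.concatenate([[0.0], np.cumsum(seg[:-1] if closed else seg)])
    return s


def signed_area(vertices: np.ndarray) -> float:
    """Shoelace area; positive for counterclockwise orientation."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def ensure_ccw(vertices: np.ndarray) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    if signed_area(v) < 0:
        v = v[::-1].copy()
    return v


def resample_closed(vertices: np.ndarray, n: int | None = None,
                    spacing: float | None = None) -> np.ndarray:
    """Resample a closed polyline at equal arclength.

    Exactly one of ``n`` (vertex count) or ``spacing`` (target edge length)
    must be given. Vertex 0 of the result coincides with vertex 0 of the
    input.
    """
    v = np.asarray(vertices, dtype=float)
    per = arc_length(v, closed=True)
    if per <= 0:
        raise ValueError("degenerate contour with zero perimeter")
    if (n is None) == (spacing is None):
        raise ValueError("give exactly one of n or spacing")
    if n is None:
        n = max(4, int(round(per / spacing)))
    s = cumulative_arclength(v, closed=True)
    # append the wrap-around point so interpolation covers the full loop
    s_ext = np.concatenate([s, [per]])
    v_ext = np.vstack([v, v[:1]])
    targets = np.linspace(0.0, per, n, endpoint=False)
    x = np.interp(targets, s_ext, v_ext[:, 0])
    y = np.interp(targets, s_ext, v_ext[:, 1])
    return np.column_stack([x, y])


def resample_open(vertices: np.ndarray, n: int) -> np.ndarray:
    """Resample an open polyline to ``n`` points at equal arclength,
    keeping both endpoints."""
    v = np.asarray(vertices, dtype=float)
    seg = segment_lengths(v, closed=False)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        return np.repeat(v[:1], n, axis=0)
    targets = np.linspace(0.0, s[-1], n)
    x = np.interp(targets, s, v[:, 0])
    y = np.interp(targets, s, v[:, 1])
    return np.column_stack([x, y])


def turning_angle_sum(vertices: np.ndarray) -> float:
    """Sum of discrete exterior turning angles; +2*pi for a simple CCW loop."""
    v = np.asarray(vertices, dtype=float)
    e = np.roll(v, -1, axis=0) - v
    ang = np.arctan2(e[:, 1], e[:, 0])
    d = np.diff(np.concatenate([ang, ang[:1]]))
    d = (d + np.pi) % (2 * np.pi) - np.pi
    return float(d.sum())


def is_simple(vertices: np.ndarray) -> bool:
    """True iff the closed polyline does not self-intersect."""
    from shapely.geometry import LinearRing

    try:
        return LinearRing(vertices).is_valid
    except Exception:
        return False


def rotate_points(points: np.ndarray, angle: float,
                  center: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    p = np.asarray(points, dtype=float) - center
    return p @ rot.T + center
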