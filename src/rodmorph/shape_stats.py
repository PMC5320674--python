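"""Population-level morphology: contour alignment, PCA shape modes, and
per-strain summary statistics.

Each accepted contour is centered on its vertex centroid, rotated so the
major principal axis lies along x, disambiguated (180-degree and mirror
ambiguities resolved by the signs of the third moments of x and y), and
resampled to 300 equal-arclength points starting from the point of maximal
x — giving every cell the same 600-coordinate representation
(x1..x300, y1..y300). PCA of the covariance (or correlation) matrix of
these coordinates then yields population shape modes: for rod-shaped
bacteria the dominant mode is elongation, followed by bending, widening,
and tapering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (Contour, arc_length, cumulative_arclength, ensure_ccw,
                   resample_closed)

N_POINTS = 300


@dataclass
class AlignedContourSet:
    """n_cells x 600 matrix of aligned contour coordinates in um."""

    matrix: np.ndarray
    n_points: int = N_POINTS

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != 2 * self.n_points:
            raise ValueError("matrix must have 2*n_points columns")


@dataclass
class ShapeModes:
    mean_contour: np.ndarray             # (600,)
    eigenvectors: np.ndarray             # (n_modes, 600)
    eigenvalues: np.ndarray              # (n_modes,), non-increasing
    variance_fraction: np.ndarray
    projections: np.ndarray              # (n_cells, n_modes)
    basis: str                           # "covariance" or "correlation"
    kept_columns: np.ndarray | None = None


def align_contour(c: Contour, n_points: int = N_POINTS) -> np.ndarray:
    """Map one contour to the common 2*n_points coordinate frame."""
    v = c.vertices_um()
    v = v - v.mean(axis=0)
    extent = np.ptp(v, axis=0)
    if np.all(extent < 1e-12):
        raise ValueError("degenerate (zero-extent) contour")

    # principal axes of the vertex second-moment tensor
    cov = v.T @ v / len(v)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    theta = np.arctan2(major[1], major[0])
    rot = np.array([[np.cos(-theta), -np.sin(-theta)],
                    [np.sin(-theta), np.cos(-theta)]])
    v = v @ rot.T

    # 180-degree and reflection ambiguities: third moments must be >= 0
    if np.sum(v[:, 0] ** 3) < 0:
        v[:, 0] = -v[:, 0]
    if np.sum(v[:, 1] ** 3) < 0:
        v[:, 1] = -v[:, 1]
    v = ensure_ccw(v)

    # resample at equal arclength starting exactly at the max-x point
    # (dense first pass so the start phase is resolved well below the
    # final point spacing)
    fine = resample_closed(v, n=max(8000, 8 * len(v)))
    start = int(np.argmax(fine[:, 0]))
    fine = np.roll(fine, -start, axis=0)
    pts = resample_closed(fine, n=n_points)
    return np.concatenate([pts[:, 0], pts[:, 1]])


def align_contours(contours: list[Contour],
                   n_points: int = N_POINTS) -> AlignedContourSet:
    mat = np.vstack([align_contour(c, n_points) for c in contours])
    return AlignedContourSet(mat, n_points)


def subsample_per_strain(contours_by_strain: dict, n: int = 150,
                         seed: int = 0) -> dict:
    """Seeded random subsample of exactly ``n`` contours per strain,
    keeping only strains with at least ``n`` available — the selection
    used before aligning strains for population PCA, so no strain is
    over-represented."""
    rng = np.random.default_rng(seed)
    out = {}
    for strain in sorted(contours_by_strain):
        items = contours_by_strain[strain]
        if len(items) < n:
            continue
        idx = rng.choice(len(items), size=n, replace=False)
        out[strain] = [items[i] for i in sorted(idx)]
    return out


def pca_shape_modes(s: AlignedContourSet,
                    basis: str = "covariance") -> ShapeModes:
    """Eigendecomposition of the covariance (or correlation) matrix of the
    aligned coordinates, via SVD of the centered data matrix."""
    if basis not in ("covariance", "correlation"):
        raise ValueError("basis must be 'covariance' or 'correlation'")
    x = s.matrix
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells for PCA")
    mean = x.mean(axis=0)
    xc = x - mean
    kept = None
    if basis == "correlation":
        sd = xc.std(axis=0, ddof=1)
        kept = np.where(sd > 0)[0]
        xc = xc[:, kept] / sd[kept]
    u, sing, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic eigenvector orientation: point "outward" along the
    # mean shape (positive amplitude of an elongation-like mode then grows
    # the contour); fall back to largest-entry-positive when orthogonal
    ref = mean[kept] if kept is not None else mean
    for k in range(vt.shape[0]):
        d = float(vt[k] @ ref)
        if abs(d) < 1e-9 * (np.linalg.norm(ref) + 1e-300):
            d = vt[k][np.argmax(np.abs(vt[k]))]
        if d < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    evals = sing ** 2 / (n - 1)
    total = evals.sum()
    frac = evals / total if total > 0 else np.zeros_like(evals)
    projections = u * sing
    return ShapeModes(mean_contour=mean, eigenvectors=vt,
                      eigenvalues=evals, variance_fraction=frac,
                      projections=projections, basis=basis,
                      kept_columns=kept)


def mode_render(modes: ShapeModes, k: int, amplitude: float | None = None,
                n_sigma: float = 0.0) -> np.ndarray:
    """Contour polyline for mean + amplitude * mode k (amplitude defaults
    to n_sigma standard deviations of that mode's projection)."""
    if amplitude is None:
        amplitude = n_sigma * float(np.sqrt(modes.eigenvalues[k]))
    vec = modes.eigenvectors[k]
    coords = modes.mean_contour.copy()
    if modes.kept_columns is not None:
        full = np.zeros_like(coords)
        full[modes.kept_columns] = vec
        vec = full
    coords = coords + amplitude * vec
    half = len(coords) // 2
    return np.column_stack([coords[:half], coords[half:]])


def population_stats(measurements, inclusion_n: int = 150):
    """Per-strain morphology summary from a per-cell measurement table.

    ``measurements`` is a DataFrame with columns (strain, length_um,
    mean_width_um, width_cv). A strain is flagged ``included`` only when at
    least ``inclusion_n`` cells passed the upstream filters.
    """
    import pandas as pd

    df = pd.DataFrame(measurements)
    required = {"strain", "length_um", "mean_width_um", "width_cv"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns {sorted(missing)}")
    grp = df.groupby("strain")
    out = pd.DataFrame({
        "n_cells": grp.size(),
        "width_mean_um": grp["mean_width_um"].mean(),
        "width_sd_um": grp["mean_width_um"].std(ddof=0),
        "length_mean_um": grp["length_um"].mean(),
        "length_sd_um": grp["length_um"].std(ddof=0),
        "width_cv_mean": grp["width_cv"].mean(),
    })
    out["included"] = out["n_cells"] >= inclusion_n
    return out.reset_index()


def binned_trend(x, y, n_bins: int = 10):
    """Equal-count binning plus a least-squares line through bin means.

    Returns (bin_centers, bin_means, bin_ses, (slope, intercept)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_bins < 2:
        raise ValueError("need at least 2 bins to fit a trend")
    order = np.argsort(x)
    idx_bins = np.array_split(order, n_bins)
    centers = np.array([x[b].mean() for b in idx_bins])
    means = np.array([y[b].mean() for b in idx_bins])
    ses = np.array([y[b].std(ddof=1) / np.sqrt(len(b)) if len(b) > 1 else 0.0
                    for b in idx_bins])
    slope, intercept = np.polyfit(centers, means, 1)
    return centers, means, ses, (float(slope), float(intercept))
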