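"""Object detection: preprocessing, boundary-intensity maps, watershed
segmentation, false-positive filtering, and frame linking.

Segmentation operates on a *boundary-intensity map* that is bright along
the cell outline regardless of modality: peripheral-fluorescence (PF)
images are used as-is, while phase-contrast (PC) and interior-fluorescence
(IF) images are converted via the magnitude of the image gradient — the
common basis for contour fitting downstream. Detected objects are filtered
on size, interior intensity, and the ratio of boundary to interior
brightness (real cells have bright rims on the boundary map; uniform debris
does not).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening
from skimage.segmentation import watershed
from skimage.transform import rescale as sk_rescale

from .core import Image

logger = logging.getLogger(__name__)


@dataclass
class SegParams:
    min_area_px: int = 100
    max_area_px: int = 500_000
    intensity_floor: float = 0.0          # fraction of image dynamic range
    intensity_ceiling: float = 1.0
    fp_ratio_threshold: float = 1.2
    background_radius_px: int = 0         # 0 disables background removal
    rescale_factor: float = 1.0
    threshold_method: str = "otsu"        # or "fixed:<value in [0,1]>"
    seed_merge_px: int = 3

    def __post_init__(self) -> None:
        if self.min_area_px >= self.max_area_px:
            raise ValueError("need min_area_px < max_area_px")
        if self.fp_ratio_threshold < 0:
            raise ValueError("fp_ratio_threshold must be non-negative")


def preprocess(img: Image, p: SegParams | None = None) -> Image:
    """Optional rescale, percentile contrast stretch to [0, 1], and
    morphological-opening background removal.

    The stretch uses the 0.1th/99.9th percentiles so isolated hot pixels do
    not compress the dynamic range. Raises on constant images.
    """
    p = p or SegParams()
    pixels = np.asarray(img.pixels, dtype=float)
    pixel_size = img.pixel_size
    if p.rescale_factor != 1.0:
        pixels = sk_rescale(pixels, p.rescale_factor, order=1,
                            anti_aliasing=p.rescale_factor < 1.0)
        pixel_size = pixel_size / p.rescale_factor
    lo, hi = np.percentile(pixels, [0.1, 99.9])
    if hi <= lo:
        raise ValueError("no contrast")
    pixels = np.clip((pixels - lo) / (hi - lo), 0.0, 1.0)
    if p.background_radius_px > 0:
        background = opening(pixels, disk(p.background_radius_px))
        pixels = np.clip(pixels - background, 0.0, None)
    return Image(pixels, pixel_size, modality=img.modality,
                 z_offset=img.z_offset)


def boundary_intensity_map(img: Image) -> Image:
    """Common basis for contour fitting: |grad I| (central differences),
    normalized to max 1, for PC and IF; the image itself for PF."""
    if img.modality == "PF":
        return img
    gy, gx = np.gradient(img.pixels)
    mag = np.hypot(gx, gy)
    peak = mag.max()
    if peak > 0:
        mag = mag / peak
    return Image(mag, img.pixel_size, modality=img.modality,
                 z_offset=img.z_offset)


def _threshold(bmap: np.ndarray, method: str) -> float:
    if method == "otsu":
        return float(threshold_otsu(bmap))
    if method.startswith("fixed:"):
        return float(method.split(":", 1)[1])
    raise ValueError(f"unknown threshold method {method!r}")


def segment_objects(bmap: Image, p: SegParams | None = None,
                    intensity_img: Image | None = None) -> np.ndarray:
    """Watershed/distance-transform segmentation of the boundary map.

    Thresholds the map, fills enclosed regions, seeds a watershed from the
    regional maxima of the distance transform (merged within
    ``seed_merge_px``) to split touching cells, then filters objects on
    area and mean interior intensity. Returns an int label mask (0 =
    background); an empty foreground yields an all-zero mask.
    """
    from skimage.feature import peak_local_max

    p = p or SegParams()
    data = np.asarray(bmap.pixels, dtype=float)
    if data.max() <= data.min():
        return np.zeros(data.shape, dtype=np.int32)
    thr = _threshold(data, p.threshold_method)
    fg = ndi.binary_fill_holes(data > thr)
    if not np.any(fg):
        return np.zeros(data.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(fg)
    # seeds: the high-distance core of each blob (the ridge of a rod stays
    # one connected seed; a neck between touching cells falls below the
    # relative threshold and splits them), merged within seed_merge_px
    comp, ncomp = ndi.label(fg)
    seed_mask = np.zeros(data.shape, dtype=bool)
    for k in range(1, ncomp + 1):
        inside = comp == k
        dmax = dist[inside].max()
        seed_mask |= inside & (dist > 0.6 * dmax)
    if p.seed_merge_px > 0:
        merged = ndi.binary_dilation(seed_mask,
                                     iterations=p.seed_merge_px)
    else:
        merged = seed_mask
    merged_labels, nseed = ndi.label(merged)
    markers = np.where(seed_mask, merged_labels, 0).astype(np.int32)
    if nseed == 0:
        labels, _ = ndi.label(fg)
    else:
        labels = watershed(-dist, markers, mask=fg)

    ref = intensity_img.pixels if intensity_img is not None else data
    lo = ref.min()
    span = ref.max() - lo
    keep = []
    for lbl in range(1, labels.max() + 1):
        obj = labels == lbl
        area = int(obj.sum())
        if not (p.min_area_px <= area <= p.max_area_px):
            logger.debug("object %d dropped: area %d outside bounds",
                         lbl, area)
            continue
        mean_frac = (ref[obj].mean() - lo) / span if span > 0 else 0.0
        if not (p.intensity_floor <= mean_frac <= p.intensity_ceiling):
            logger.debug("object %d dropped: intensity fraction %.3f",
                         lbl, mean_frac)
            continue
        keep.append(lbl)
    out = np.zeros(data.shape, dtype=np.int32)
    for new, lbl in enumerate(keep, start=1):
        out[labels == lbl] = new
    return out


def boundary_interior_ratio(obj: np.ndarray, bmap_pixels: np.ndarray,
                            inset_px: int = 1, guard_px: int = 1,
                            max_band_px: int = 4) -> float:
    """Mean boundary-band intensity over mean interior intensity on the
    boundary map.

    The band is an annulus inset one pixel from the thresholded object
    edge (the intensity ridge of a real cell rim sits a few pixels inside
    the cut), at most ``max_band_px`` wide and shrunk adaptively for small
    objects; a one-pixel guard separates it from the interior. Returns NaN
    when the object is too small to partition.
    """
    dist = ndi.distance_transform_edt(obj)
    dmax = dist.max()
    band_w = max(1, min(max_band_px, int((dmax - inset_px - guard_px) // 2)))
    band = (dist > inset_px) & (dist <= inset_px + band_w)
    interior = dist > inset_px + band_w + guard_px
    if not band.any() or not interior.any():
        # fall back to the smallest possible partition
        interior = ndi.binary_erosion(obj, iterations=1)
        band = obj & ~interior
        if not band.any() or not interior.any():
            return float("nan")
    mean_int = float(bmap_pixels[interior].mean())
    mean_bnd = float(bmap_pixels[band].mean())
    if mean_int <= 0:
        return float("inf")
    return mean_bnd / mean_int


def false_positive_filter(mask: np.ndarray, bmap: Image,
                          p: SegParams | None = None) -> np.ndarray:
    """Drop objects whose boundary/interior intensity ratio on the
    boundary map falls below ``fp_ratio_threshold``: real cells have
    bright rims there while uniform debris scores ~1. A threshold of 0
    disables the filter. Labels are re-packed to 1..K."""
    p = p or SegParams()
    if p.fp_ratio_threshold == 0:
        return mask
    data = np.asarray(bmap.pixels, dtype=float)
    out = np.zeros_like(mask)
    new = 0
    for lbl in range(1, mask.max() + 1):
        obj = mask == lbl
        if not np.any(obj):
            continue
        ratio = boundary_interior_ratio(obj, data)
        if np.isnan(ratio):
            logger.info("object %d dropped: too small to partition", lbl)
            continue
        if ratio >= p.fp_ratio_threshold:
            new += 1
            out[obj] = new
        else:
            logger.info("object %d dropped: boundary/interior ratio %.2f "
                        "< %.2f", lbl, ratio, p.fp_ratio_threshold)
    return out


def half_max_core(obj: np.ndarray, bmap_pixels: np.ndarray) -> np.ndarray:
    """Half-max support of one object's boundary-map intensity.

    The thresholded foreground includes the diffuse halo of defocused
    light around a cell; the half-max core tracks the rim ridge and is the
    pixel set reported for the object (and the seed for contour fitting).
    Falls back to the input mask for degenerate cases."""
    vals = bmap_pixels[obj]
    if vals.size == 0:
        return obj
    core = obj & (bmap_pixels > 0.5 * vals.max())
    core = ndi.binary_fill_holes(core)
    lab, n = ndi.label(core)
    if n == 0:
        return obj
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
    core = lab == (1 + int(np.argmax(sizes)))
    if core.sum() < max(9, 0.05 * obj.sum()):
        return obj
    return core


def refine_objects(mask: np.ndarray, bmap: Image) -> np.ndarray:
    """Apply half_max_core to every labeled object."""
    data = np.asarray(bmap.pixels, dtype=float)
    out = np.zeros_like(mask)
    for lbl in range(1, mask.max() + 1):
        obj = mask == lbl
        if np.any(obj):
            out[half_max_core(obj, data)] = lbl
    return out


def link_frames(masks: list[np.ndarray], max_disp_px: float):
    """Greedy nearest-centroid tracking across a time-lapse.

    Returns a list of (frame, label, track_id) rows. Matches closer than
    ``max_disp_px`` continue a track; everything else starts a new one.
    Known limitation: objects that swap positions are followed by
    proximity, not identity.
    """
    rows = []
    next_track = 0
    prev: dict[int, tuple[np.ndarray, int]] = {}
    for t, mask in enumerate(masks):
        cents = {}
        for lbl in range(1, mask.max() + 1):
            ys, xs = np.nonzero(mask == lbl)
            if len(xs):
                cents[lbl] = np.array([xs.mean(), ys.mean()])
        assigned: dict[int, int] = {}
        used_prev = set()
        # greedy: closest pairs first
        pairs = sorted(
            ((np.linalg.norm(c - pc), lbl, plbl)
             for lbl, c in cents.items()
             for plbl, (pc, _) in prev.items()),
            key=lambda x: x[0])
        for d, lbl, plbl in pairs:
            if d > max_disp_px or lbl in assigned or plbl in used_prev:
                continue
            assigned[lbl] = prev[plbl][1]
            used_prev.add(plbl)
        cur: dict[int, tuple[np.ndarray, int]] = {}
        for lbl, c in cents.items():
            if lbl not in assigned:
                assigned[lbl] = next_track
                next_track += 1
            rows.append((t, lbl, assigned[lbl]))
            cur[lbl] = (c, assigned[lbl])
        prev = cur
    return rows
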