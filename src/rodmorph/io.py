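"""TIFF and table I/O."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import Image

FLOAT_FORMAT = "%.6g"


def read_image(path, pixel_size_um: float | None = None,
               modality: str = "PF") -> Image | list[Image]:
    """Read a single- or multi-page grayscale TIFF.

    Pixel size comes from the TIFF resolution tags when present, but an
    explicit ``pixel_size_um`` always wins. Multi-page files return a list
    of Images. RGB data is rejected.
    """
    with tifffile.TiffFile(str(path)) as tif:
        pages = [p.asarray() for p in tif.pages]
        tag_px = _pixel_size_from_tags(tif.pages[0])
    px = pixel_size_um if pixel_size_um is not None else tag_px
    if px is None:
        raise ValueError("pixel size not in TIFF tags; pass pixel_size_um")
    imgs = []
    for arr in pages:
        if arr.ndim == 3:
            raise ValueError("grayscale required")
        imgs.append(Image(arr.astype(float), px, modality=modality))
    return imgs[0] if len(imgs) == 1 else imgs


def _pixel_size_from_tags(page) -> float | None:
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags.get("ResolutionUnit")
        num, den = xres
        if num == 0:
            return None
        per_unit = num / den
        # unit 3 = cm -> um; anything else is treated as already-um metadata
        scale = 1e4 if (unit is not None and unit.value == 3) else 1.0
        return scale / per_unit
    except (KeyError, TypeError, ZeroDivisionError):
        return None


def write_image(path, data, dtype=np.uint16) -> None:
    """Write an Image, array, or list thereof (multi-page) as grayscale
    TIFF. Integer input is written bit-exactly; float input is scaled to
    the full 16-bit range."""
    items = data if isinstance(data, list) else [data]
    arrays = []
    for item in items:
        arr = item.pixels if isinstance(item, Image) else np.asarray(item)
        if np.issubdtype(arr.dtype, np.integer):
            arrays.append(arr.astype(dtype))
        else:
            peak = arr.max()
            scale = (65535.0 / peak) if peak > 0 else 1.0
            arrays.append(np.clip(arr * scale, 0, 65535).astype(dtype))
    tifffile.imwrite(str(path), np.stack(arrays) if len(arrays) > 1
                     else arrays[0], photometric="minisblack")


def write_table(path, df: pd.DataFrame) -> None:
    """CSV with a mandatory header, UTF-8, floats at 6 significant digits,
    locale-independent decimal points."""
    df.to_csv(str(path), index=False, float_format=FLOAT_FORMAT,
              encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(str(path))


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True),
                          encoding="utf-8")


def contours_frame(results) -> pd.DataFrame:
    rows = []
    for res in results:
        for i, (x, y) in enumerate(res.contour.vertices):
            rows.append({"cell_id": res.cell_id, "vertex_idx": i,
                         "x_px": x, "y_px": y})
    return pd.DataFrame(rows, columns=["cell_id", "vertex_idx",
                                       "x_px", "y_px"])


def mesh_frame(results) -> pd.DataFrame:
    rows = []
    for res in results:
        m = res.mesh
        for i in range(len(m.midline)):
            rows.append({"cell_id": res.cell_id, "station_idx": i,
                         "mid_x_um": m.midline[i, 0],
                         "mid_y_um": m.midline[i, 1],
                         "width_um": m.widths[i],
                         "left_x": m.left[i, 0], "left_y": m.left[i, 1],
                         "right_x": m.right[i, 0],
                         "right_y": m.right[i, 1]})
    return pd.DataFrame(rows, columns=["cell_id", "station_idx", "mid_x_um",
                                       "mid_y_um", "width_um", "left_x",
                                       "left_y", "right_x", "right_y"])


def objects_frame(mask: np.ndarray, frame: int = 0) -> pd.DataFrame:
    rows = []
    for lbl in range(1, int(mask.max()) + 1):
        ys, xs = np.nonzero(mask == lbl)
        if len(xs) == 0:
            continue
        rows.append({"frame": frame, "label": lbl,
                     "centroid_x_px": xs.mean(), "centroid_y_px": ys.mean(),
                     "area_px": len(xs)})
    return pd.DataFrame(rows, columns=["frame", "label", "centroid_x_px",
                                       "centroid_y_px", "area_px"])
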