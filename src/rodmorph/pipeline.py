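"""End-to-end measurement: image -> objects -> contours -> meshes ->
per-cell geometry, with an audit log of every object's disposition."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import contour as contour_mod
from . import meshing, segmentation
from .core import Contour, Image
from .meshing import CellMeasurement, CurvatureProfile, Mesh
from .segmentation import SegParams


@dataclass
class RunLog:
    """Per-object dispositions; accepted + rejected = detected."""

    records: list = field(default_factory=list)

    def note(self, obj_id: int, disposition: str, reason: str = "") -> None:
        self.records.append({"object": int(obj_id),
                             "disposition": disposition, "reason": reason})

    @property
    def n_detected(self) -> int:
        return len(self.records)

    @property
    def n_accepted(self) -> int:
        return sum(1 for r in self.records if r["disposition"] == "accepted")

    @property
    def n_rejected(self) -> int:
        return sum(1 for r in self.records if r["disposition"] == "rejected")

    def to_dict(self) -> dict:
        return {"records": self.records,
                "counts": {"detected": self.n_detected,
                           "accepted": self.n_accepted,
                           "rejected": self.n_rejected}}


@dataclass
class CellResult:
    cell_id: int
    contour: Contour
    curvature: CurvatureProfile
    mesh: Mesh
    measurement: CellMeasurement


def measure_image(img: Image, seg: SegParams | None = None,
                  snake: contour_mod.SnakeParams | None = None,
                  window_arc_um: float = 0.25,
                  log: RunLog | None = None) -> tuple[list[CellResult], RunLog]:
    """Run the full measurement chain on one micrograph.

    Objects failing the false-positive filter, the two-pole filter, contour
    fitting, or meshing are rejected with a reason in the RunLog rather
    than silently dropped.
    """
    seg = seg or SegParams()
    snake = snake or contour_mod.SnakeParams()
    log = log if log is not None else RunLog()

    pre = segmentation.preprocess(img, seg)
    bmap = segmentation.boundary_intensity_map(pre)
    labels = segmentation.segment_objects(bmap, seg, intensity_img=pre)
    labels = segmentation.false_positive_filter(labels, bmap, seg)
    labels = segmentation.refine_objects(labels, bmap)

    results: list[CellResult] = []
    for lbl in range(1, labels.max() + 1):
        obj_mask = labels == lbl
        try:
            c = contour_mod.fit_contour(bmap, obj_mask, snake)
        except contour_mod.ContourCollapse as err:
            log.note(lbl, "rejected", f"contour collapse: {err}")
            continue
        try:
            prof = meshing.curvature_profile(c, window_arc_um)
        except meshing.WindowTooSmall as err:
            log.note(lbl, "rejected", str(err))
            continue
        poles = meshing.find_poles(prof, c)
        if not poles.accepted:
            log.note(lbl, "rejected",
                     f"pole count {poles.n_found} != 2")
            continue
        try:
            mesh = meshing.build_centerline_mesh(c, poles.indices)
        except meshing.MeshError as err:
            log.note(lbl, "rejected", f"mesh failure: {err}")
            continue
        meas = meshing.measure_cell(c, mesh)
        log.note(lbl, "accepted")
        results.append(CellResult(cell_id=lbl, contour=c, curvature=prof,
                                  mesh=mesh, measurement=meas))
    return results, log


def measurements_frame(results: list[CellResult]):
    """Per-cell measurement table (one row per accepted cell)."""
    import pandas as pd

    rows = [{"cell_id": r.cell_id,
             "length_um": r.measurement.length_um,
             "mean_width_um": r.measurement.mean_width_um,
             "max_width_um": r.measurement.max_width_um,
             "area_um2": r.measurement.area_um2,
             "width_cv": r.measurement.width_cv}
            for r in results]
    return pd.DataFrame(rows, columns=["cell_id", "length_um",
                                       "mean_width_um", "max_width_um",
                                       "area_um2", "width_cv"])
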