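"""Colocalization and region-restricted counting.

Answers the uptake questions of a phagocytosis experiment: how much cargo
(protocells, bacteria) sits inside versus outside the detected cells, what
fraction of cells are positive for a reporter within a region around the
wound or fracture, and how a per-cell signal evolves over a time-lapse.

A cargo voxel is "inside" iff it coincides with a nonzero cell label;
volumes are attributed to the coinciding cell. Cells are assigned to a
region of interest by their centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import DetectionParams, detect_objects
from .roi import RegionOfInterest
from .stack import LabeledObjects, voxel_volume_um3


@dataclass
class UptakeResult:
    """Per-cell and aggregate cargo-uptake volumes (µm³)."""

    per_cell: pd.DataFrame  # cell_id, cargo_volume_inside_um3, contains_cargo
    n_cells: int
    n_cells_with_cargo: int
    percent_cells_with_cargo: float
    total_cargo_volume_inside_um3: float
    total_cargo_volume_outside_um3: float


@dataclass
class IntensityTimecourse:
    """Per-cell mean-intensity curves and the population-mean AUC."""

    times_min: np.ndarray
    per_cell: pd.DataFrame  # rows: frames, columns: cell ids, NaN = absent
    population_mean: np.ndarray  # NaN where no surviving cells
    auc: float  # trapezoidal, intensity · minutes


def measure_inside_outside(
    cargo: LabeledObjects,
    cells: LabeledObjects,
    min_overlap_um3: float = 0.0,
) -> UptakeResult:
    """Split cargo volume into inside- and outside-cell fractions.

    A cell "contains cargo" when the cargo volume coinciding with its
    label exceeds ``min_overlap_um3`` (default: any overlap, i.e. one
    voxel suffices). Inside + outside volumes sum exactly to the total
    cargo volume (voxel-count partition).
    """
    if cargo.labels.shape != cells.labels.shape:
        raise ValueError("cargo and cells must share spatial shape")
    vox = voxel_volume_um3(cargo.voxel_size)
    cargo_fg = cargo.labels > 0
    coincident = cells.labels[cargo_fg]
    n_cells = cells.n_objects
    overlap_vox = np.bincount(coincident, minlength=n_cells + 1)
    inside_vox = int(overlap_vox[1:].sum())
    total_vox = int(cargo_fg.sum())
    per_cell = pd.DataFrame(
        {
            "cell_id": np.arange(1, n_cells + 1, dtype=int),
            "cargo_volume_inside_um3": overlap_vox[1:] * vox,
        }
    )
    if min_overlap_um3 > 0:
        per_cell["contains_cargo"] = per_cell["cargo_volume_inside_um3"] >= min_overlap_um3
    else:
        per_cell["contains_cargo"] = per_cell["cargo_volume_inside_um3"] > 0
    n_with = int(per_cell["contains_cargo"].sum())
    return UptakeResult(
        per_cell=per_cell,
        n_cells=n_cells,
        n_cells_with_cargo=n_with,
        percent_cells_with_cargo=100.0 * n_with / n_cells if n_cells else float("nan"),
        total_cargo_volume_inside_um3=inside_vox * vox,
        total_cargo_volume_outside_um3=(total_vox - inside_vox) * vox,
    )


def _cells_in_roi(cells: LabeledObjects, roi: RegionOfInterest) -> np.ndarray:
    """Ids of cells whose (y, x) centroid lies in the roi."""
    if cells.n_objects == 0:
        return np.array([], dtype=int)
    cent = cells.centroids_um()[:, 1:]  # (y, x)
    inroi = roi.contains_points(cent)
    return cells.table.loc[inroi, "object_id"].to_numpy(dtype=int)


def percent_cells_positive(
    cells: LabeledObjects,
    marker_channel: np.ndarray,
    marker_params: DetectionParams,
    roi: RegionOfInterest | None = None,
    min_marker_volume_um3: float = 0.0,
    exclude_ids=(),
) -> float:
    """Percentage of roi cells positive for a reporter marker.

    Marker objects are detected from the marker channel with the standard
    detection chain; a cell is positive iff the marker volume inside it
    exceeds ``min_marker_volume_um3``. Returns NaN (flagged undefined,
    not 0) when the roi contains no cells. ``exclude_ids`` drops
    accidentally detected non-target objects, the batch analogue of
    manual curation.
    """
    if roi is None:
        roi = RegionOfInterest(kind="whole")
    if exclude_ids:
        cells = cells.drop_ids(exclude_ids)
    marker = detect_objects(marker_channel, cells.voxel_size, marker_params)
    uptake = measure_inside_outside(marker, cells, min_overlap_um3=min_marker_volume_um3)
    roi_ids = _cells_in_roi(cells, roi)
    if len(roi_ids) == 0:
        return float("nan")
    pos = uptake.per_cell.set_index("cell_id").loc[roi_ids, "contains_cargo"]
    return 100.0 * float(pos.sum()) / len(roi_ids)


def count_objects(
    objects: LabeledObjects, roi: RegionOfInterest | None = None
) -> tuple[int, float]:
    """Count of roi objects and their summed volume (burden proxy)."""
    if roi is None:
        roi = RegionOfInterest(kind="whole")
    ids = _cells_in_roi(objects, roi)
    if len(ids) == 0:
        return 0, 0.0
    sub = objects.table.set_index("object_id").loc[ids]
    return len(ids), float(sub["volume_um3"].sum())


def per_cell_timecourse(
    cell_masks_per_frame: list[LabeledObjects],
    signal_channel: np.ndarray,
    min_cell_area_um2: float = 0.0,
    time_interval_min: float = 1.0,
) -> IntensityTimecourse:
    """Mean reporter intensity per cell over a time-lapse, with AUC.

    ``signal_channel`` is a ``(t, y, x)`` (or ``(t, z, y, x)``) array
    aligned frame-for-frame with the cell masks. Cells smaller than
    ``min_cell_area_um2`` are discarded per frame. The population mean is
    the unweighted mean over surviving cells; frames with no cells are
    NaN. The AUC integrates the population curve trapezoidally over its
    defined frames (intensity · minutes).
    """
    signal = np.asarray(signal_channel, dtype=float)
    n_frames = len(cell_masks_per_frame)
    if signal.shape[0] != n_frames:
        raise ValueError("one cell mask per signal frame required")
    times = np.arange(n_frames, dtype=float) * time_interval_min
    records: dict[int, dict] = {}
    pop = np.full(n_frames, np.nan)
    for f, cells in enumerate(cell_masks_per_frame):
        vs = cells.voxel_size
        pix_area = vs[-1] * vs[-2]
        frame_sig = signal[f]
        means = []
        for _, row in cells.table.iterrows():
            area = row["voxel_count"] * pix_area
            if area < min_cell_area_um2:
                continue
            m = float(frame_sig[cells.labels == row["object_id"]].mean())
            records.setdefault(int(row["object_id"]), {})[f] = m
            means.append(m)
        if means:
            pop[f] = float(np.mean(means))
    per_cell = pd.DataFrame(records, index=pd.RangeIndex(n_frames, name="frame"))
    valid = ~np.isnan(pop)
    auc = float(np.trapezoid(pop[valid], times[valid])) if valid.sum() >= 2 else 0.0
    return IntensityTimecourse(
        times_min=times, per_cell=per_cell, population_mean=pop, auc=auc
    )
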