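"""Calibrated image containers.

Two containers are shared by every analysis stage:

``ImageStack``
    A multichannel intensity array in canonical ``(channel, t, z, y, x)``
    order with a physical voxel size in micrometres. Singleton axes are
    allowed, so a plain 2D image is a ``(1, 1, 1, y, x)`` stack.

``LabeledObjects``
    A segmentation result: an integer label image (0 = background, labels
    contiguous from 1) together with a per-object table of voxel counts,
    physical volumes and centroids in micrometre coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage


def _as_voxel_size(voxel_size) -> tuple[float, ...]:
    vs = tuple(float(v) for v in voxel_size)
    if any(v <= 0 or not np.isfinite(v) for v in vs):
        raise ValueError(f"voxel_size components must be positive, got {vs}")
    return vs


@dataclass
class ImageStack:
    """Calibrated multichannel intensity data.

    Parameters
    ----------
    data : ndarray
        Intensities in ``(channel, t, z, y, x)`` order; singleton axes
        allowed. All values must be finite and non-negative.
    voxel_size : (dz, dy, dx)
        Physical voxel pitch in µm, strictly positive.
    channel_names : list of str
        One name per channel.
    time_interval : float or None
        Minutes per frame; ``None`` for single-time-point data.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channel_names: list[str] = field(default_factory=list)
    time_interval: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim > 5:
            raise ValueError("at most 5 axes (c, t, z, y, x) are supported")
        # left-pad singleton axes up to the canonical 5
        while self.data.ndim < 5:
            self.data = self.data[np.newaxis]
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        self.voxel_size = _as_voxel_size(self.voxel_size)
        if len(self.voxel_size) != 3:
            raise ValueError("voxel_size must be (dz, dy, dx)")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        if self.time_interval is not None and self.time_interval <= 0:
            raise ValueError("time_interval must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def channel_index(self, key: int | str) -> int:
        if isinstance(key, str):
            try:
                return self.channel_names.index(key)
            except ValueError:
                raise KeyError(
                    f"unknown channel {key!r}; have {self.channel_names}"
                ) from None
        return int(key)

    def channel(self, key: int | str, t: int = 0) -> np.ndarray:
        """One channel at one time point as a ``(z, y, x)`` array."""
        return self.data[self.channel_index(key), t]

    def channel_movie(self, key: int | str) -> np.ndarray:
        """One channel across time as a ``(t, z, y, x)`` array."""
        return self.data[self.channel_index(key)]


def _spatial_voxel_size(ndim: int, voxel_size) -> tuple[float, ...]:
    """Per-axis spacing matching an image's spatial dimensionality.

    2D images use (dy, dx); 3D use (dz, dy, dx). The voxel *volume* always
    includes dz so that single-slice areas extrude to volumes consistently.
    """
    vs = _as_voxel_size(voxel_size)
    if len(vs) < ndim:
        raise ValueError(f"voxel_size {vs} too short for {ndim}D image")
    return vs[-ndim:]


def voxel_volume_um3(voxel_size) -> float:
    vs = _as_voxel_size(voxel_size)
    return float(np.prod(vs))


@dataclass
class LabeledObjects:
    """Segmented objects over a spatial grid.

    ``labels`` has the source's spatial shape (2D or 3D), with 0 as
    background and object ids contiguous from 1. ``table`` carries one row
    per object: ``object_id``, ``voxel_count``, ``volume_um3``, centroid
    coordinates in µm and the pixel bounding box.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    table: pd.DataFrame = None

    CENTROID_COLS_3D = ["centroid_z_um", "centroid_y_um", "centroid_x_um"]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim not in (2, 3):
            raise ValueError("labels must be a 2D or 3D spatial array")
        self.voxel_size = _as_voxel_size(self.voxel_size)
        if self.table is None:
            self.labels, self.table = self._build_table(self.labels, self.voxel_size)

    @staticmethod
    def _build_table(labels, voxel_size):
        labels = np.asarray(labels)
        ids = np.unique(labels)
        ids = ids[ids > 0]
        # relabel contiguously from 1
        if len(ids) and (ids[0] != 1 or ids[-1] != len(ids)):
            remap = np.zeros(int(ids[-1]) + 1, dtype=labels.dtype)
            remap[ids] = np.arange(1, len(ids) + 1)
            labels = remap[labels]
            ids = np.arange(1, len(ids) + 1)
        vs = _spatial_voxel_size(labels.ndim, voxel_size)
        vol = voxel_volume_um3(voxel_size)
        rows = []
        if len(ids):
            counts = np.bincount(labels.ravel(), minlength=len(ids) + 1)[1:]
            centroids = ndimage.center_of_mass(
                np.ones_like(labels, dtype=np.uint8), labels, ids
            )
            slices = ndimage.find_objects(labels)
            for i, lab in enumerate(ids):
                c_um = tuple(c * s for c, s in zip(centroids[i], vs))
                if labels.ndim == 2:
                    c_um = (0.0,) + c_um
                sl = slices[lab - 1]
                rows.append(
                    {
                        "object_id": int(lab),
                        "voxel_count": int(counts[i]),
                        "volume_um3": float(counts[i] * vol),
                        "centroid_z_um": c_um[0],
                        "centroid_y_um": c_um[1],
                        "centroid_x_um": c_um[2],
                        "bbox": tuple((s.start, s.stop) for s in sl),
                    }
                )
        table = pd.DataFrame(
            rows,
            columns=[
                "object_id",
                "voxel_count",
                "volume_um3",
                "centroid_z_um",
                "centroid_y_um",
                "centroid_x_um",
                "bbox",
            ],
        )
        return labels, table

    @classmethod
    def from_labels(cls, labels, voxel_size) -> "LabeledObjects":
        return cls(labels=labels, voxel_size=voxel_size)

    @property
    def n_objects(self) -> int:
        return len(self.table)

    @property
    def total_volume_um3(self) -> float:
        return float(self.table["volume_um3"].sum())

    def centroids_um(self) -> np.ndarray:
        """Object centroids as an ``(n, 3)`` array of (z, y, x) µm coords."""
        return self.table[self.CENTROID_COLS_3D].to_numpy(dtype=float)

    def filter_volume(self, min_volume_um3: float) -> "LabeledObjects":
        """Remove objects with physical volume below ``min_volume_um3``."""
        if min_volume_um3 < 0:
            raise ValueError("min_volume_um3 must be >= 0")
        keep = self.table.loc[
            self.table["volume_um3"] >= min_volume_um3, "object_id"
        ].to_numpy()
        mask = np.isin(self.labels, keep)
        return LabeledObjects.from_labels(
            np.where(mask, self.labels, 0), self.voxel_size
        )

    def drop_ids(self, ids) -> "LabeledObjects":
        """Batch analogue of manual curation: exclude the listed object ids."""
        ids = np.asarray(list(ids), dtype=int)
        mask = np.isin(self.labels, ids)
        return LabeledObjects.from_labels(
            np.where(mask, 0, self.labels), self.voxel_size
        )
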