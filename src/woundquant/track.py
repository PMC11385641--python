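"""Nucleus tracking and motility statistics.

Nuclei are detected per frame (Gaussian filter → rolling-ball background
subtraction → moments auto-threshold → watershed split), linked between
frames by deterministic greedy nearest-pair assignment, and summarized per
track by two behavioural features:

* velocity — mean speed, path length over duration (µm/min);
* directionality ratio — net displacement over path length, in [0, 1]:
  1 for perfectly directed motion, near 0 for wandering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import DetectionParams, detect_objects, subtract_background
from .stack import LabeledObjects


@dataclass
class Track:
    """Time-ordered positions of one tracked nucleus.

    Positions are (y, x) in µm; frames strictly increase. Derived motility
    metrics are exposed as properties and are NaN (flagged undefined) for
    single-sample or zero-length tracks.
    """

    track_id: int
    frames: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    times_min: np.ndarray = field(default_factory=lambda: np.empty(0))
    positions_um: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.positions_um = np.atleast_2d(np.asarray(self.positions_um, dtype=float))
        if self.positions_um.size == 0:
            self.positions_um = self.positions_um.reshape(0, 2)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.frames)

    @property
    def path_length_um(self) -> float:
        if self.n_samples < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.positions_um, axis=0), axis=1).sum())

    @property
    def net_displacement_um(self) -> float:
        if self.n_samples < 2:
            return 0.0
        return float(np.linalg.norm(self.positions_um[-1] - self.positions_um[0]))

    @property
    def duration_min(self) -> float:
        if self.n_samples < 2:
            return 0.0
        return float(self.times_min[-1] - self.times_min[0])

    @property
    def velocity_um_per_min(self) -> float:
        if self.n_samples < 2 or self.duration_min <= 0:
            return float("nan")
        return self.path_length_um / self.duration_min

    @property
    def net_velocity_um_per_min(self) -> float:
        if self.n_samples < 2 or self.duration_min <= 0:
            return float("nan")
        return self.net_displacement_um / self.duration_min

    @property
    def directionality_ratio(self) -> float:
        if self.n_samples < 2 or self.path_length_um == 0:
            return float("nan")
        return self.net_displacement_um / self.path_length_um


DEFAULT_NUCLEUS_PARAMS = DetectionParams(
    prefilter="gaussian",
    prefilter_sigma=1.0,
    threshold_method="moments",
    split_touching=True,
)


def detect_nuclei(
    frame: np.ndarray,
    voxel_size,
    params: DetectionParams | None = None,
    background_radius: float = 50.0,
) -> LabeledObjects:
    """Detect nuclei in one frame with the behavioural-assay chain."""
    if params is None:
        params = DEFAULT_NUCLEUS_PARAMS
    cleaned = subtract_background(np.asarray(frame, dtype=float), background_radius)
    return detect_objects(cleaned, voxel_size, params)


def link_tracks(
    detections_per_frame: list[np.ndarray],
    max_link_distance_um: float,
    max_gap_frames: int = 0,
    time_interval_min: float = 1.0,
) -> list[Track]:
    """Link per-frame (y, x) µm centroids into tracks.

    Deterministic greedy globally-nearest-pair assignment per frame
    transition: candidate (track, detection) pairs within
    ``max_link_distance_um`` are taken in order of increasing distance,
    ties broken by earlier detection index then earlier track id. Gaps of
    up to ``max_gap_frames`` missed frames are bridged; unmatched
    detections start new tracks.
    """
    if max_link_distance_um <= 0:
        raise ValueError("max_link_distance_um must be > 0")
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be >= 0")
    tracks: list[dict] = []  # {'id', 'frames', 'pos', 'last_frame'}
    next_id = 0
    for f, dets in enumerate(detections_per_frame):
        dets = np.atleast_2d(np.asarray(dets, dtype=float))
        if dets.size == 0:
            dets = dets.reshape(0, 2)
        active = [
            t for t in tracks if f - t["last_frame"] <= max_gap_frames + 1
        ]
        pairs = []
        for ti, t in enumerate(active):
            last = t["pos"][-1]
            for di in range(len(dets)):
                d = float(np.hypot(*(dets[di] - last)))
                if d <= max_link_distance_um:
                    pairs.append((d, di, t["id"], ti))
        pairs.sort()
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for d, di, tid, ti in pairs:
            if di in used_dets or ti in used_tracks:
                continue
            t = active[ti]
            t["frames"].append(f)
            t["pos"].append(dets[di])
            t["last_frame"] = f
            used_tracks.add(ti)
            used_dets.add(di)
        for di in range(len(dets)):
            if di not in used_dets:
                tracks.append(
                    {
                        "id": next_id,
                        "frames": [f],
                        "pos": [dets[di]],
                        "last_frame": f,
                    }
                )
                next_id += 1
    return [
        Track(
            track_id=t["id"],
            frames=np.array(t["frames"]),
            times_min=np.array(t["frames"], dtype=float) * time_interval_min,
            positions_um=np.array(t["pos"]),
        )
        for t in tracks
    ]


def track_metrics(track: Track) -> tuple[float, float]:
    """(velocity µm/min, directionality ratio); NaN-flagged if undefined."""
    return track.velocity_um_per_min, track.directionality_ratio


def summarize_tracks(tracks: list[Track], min_samples: int = 3) -> pd.DataFrame:
    """Per-track metric table, excluding tracks shorter than min_samples."""
    rows = [
        {
            "track_id": t.track_id,
            "n_samples": t.n_samples,
            "path_length_um": t.path_length_um,
            "net_displacement_um": t.net_displacement_um,
            "duration_min": t.duration_min,
            "velocity_um_per_min": t.velocity_um_per_min,
            "net_velocity_um_per_min": t.net_velocity_um_per_min,
            "directionality_ratio": t.directionality_ratio,
        }
        for t in tracks
        if t.n_samples >= min_samples
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "track_id",
            "n_samples",
            "path_length_um",
            "net_displacement_um",
            "duration_min",
            "velocity_um_per_min",
            "net_velocity_um_per_min",
            "directionality_ratio",
        ],
    )
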