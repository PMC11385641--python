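"""User-defined regions of interest in physical (µm) coordinates.

ROIs are 2D shapes in the (y, x) plane — a circle, a polygon, or the whole
image — applied either to a 2D image/projection or extruded through z as a
cylinder for 3D stacks. Object membership is decided by the object's
centroid, so a region counts whole cells rather than partial overlaps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as _MplPath


def _segments_intersect(p1, p2, p3, p4) -> bool:
    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    d1 = cross(p3, p4, p1)
    d2 = cross(p3, p4, p2)
    d3 = cross(p1, p2, p3)
    d4 = cross(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


@dataclass
class RegionOfInterest:
    """Circle / polygon / whole-image region in µm coordinates.

    For ``kind='circle'`` supply ``center_um=(y, x)`` and ``radius_um``;
    for ``kind='polygon'`` a non-self-intersecting ``vertices_um`` list of
    (y, x) pairs. 3D stacks are handled as a cylinder through z.
    """

    kind: str = "whole"
    center_um: tuple[float, float] | None = None
    radius_um: float | None = None
    vertices_um: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in ("circle", "polygon", "whole"):
            raise ValueError(f"unknown roi kind {self.kind!r}")
        if self.kind == "circle":
            if self.center_um is None or self.radius_um is None:
                raise ValueError("circle roi needs center_um and radius_um")
            if self.radius_um <= 0:
                raise ValueError("radius_um must be > 0")
            self.center_um = (float(self.center_um[0]), float(self.center_um[1]))
        if self.kind == "polygon":
            if len(self.vertices_um) < 3:
                raise ValueError("polygon roi needs >= 3 vertices")
            v = [tuple(map(float, p)) for p in self.vertices_um]
            n = len(v)
            for i in range(n):
                a1, a2 = v[i], v[(i + 1) % n]
                for j in range(i + 1, n):
                    if abs(i - j) in (1, n - 1) or (i == 0 and j == n - 1):
                        continue
                    if _segments_intersect(a1, a2, v[j], v[(j + 1) % n]):
                        raise ValueError("polygon is self-intersecting")
            self.vertices_um = v

    # -- membership -------------------------------------------------------

    def contains_points(self, points_yx_um: np.ndarray) -> np.ndarray:
        """Boolean membership for an ``(n, 2)`` array of (y, x) µm points."""
        pts = np.atleast_2d(np.asarray(points_yx_um, dtype=float))
        if self.kind == "whole":
            return np.ones(len(pts), dtype=bool)
        if self.kind == "circle":
            d = np.hypot(pts[:, 0] - self.center_um[0], pts[:, 1] - self.center_um[1])
            return d <= self.radius_um
        path = _MplPath(np.asarray(self.vertices_um)[:, ::-1])  # (x, y) order
        return path.contains_points(pts[:, ::-1])

    def mask(self, shape_yx: tuple[int, int], pixel_size_yx) -> np.ndarray:
        """Rasterize onto a pixel grid with the given (dy, dx) µm spacing."""
        ny, nx = shape_yx
        dy, dx = pixel_size_yx
        yy, xx = np.meshgrid(
            np.arange(ny) * dy, np.arange(nx) * dx, indexing="ij"
        )
        pts = np.column_stack([yy.ravel(), xx.ravel()])
        return self.contains_points(pts).reshape(ny, nx)

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.kind == "circle":
            d["center_um"] = list(self.center_um)
            d["radius_um"] = self.radius_um
        elif self.kind == "polygon":
            d["vertices_um"] = [list(v) for v in self.vertices_um]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RegionOfInterest":
        return cls(
            kind=d["kind"],
            center_um=tuple(d["center_um"]) if "center_um" in d else None,
            radius_um=d.get("radius_um"),
            vertices_um=[tuple(v) for v in d.get("vertices_um", [])],
        )

    @classmethod
    def from_json(cls, path) -> "RegionOfInterest":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
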