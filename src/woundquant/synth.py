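"""Ground-truth synthetic microscopy scenes.

Every input class the pipeline consumes can be generated here with known
ground truth, so each stage is verifiable by parameter recovery without
any microscopy data: bright blob-like cells with sub-cellular cargo
particles over an autofluorescent background, moving nuclei with tunable
speed and persistence, tubular branching networks, oriented fibril fields
with controlled angular dispersion, pigment patches in brightfield, and
fracture/control intensity pairs.

Rendering is deterministic given the seed. Noise, when requested, is
Poisson (shot) with a gain followed by additive Gaussian read noise,
applied last and clamped at zero. The defaults keep scenes small (≤ 256³
voxels, ≤ 60 frames) so full parameter-recovery suites run at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from scipy import ndimage

from .stack import LabeledObjects


# --------------------------------------------------------------------------
# noise and primitives


def apply_noise(
    image: np.ndarray,
    rng: np.random.Generator,
    poisson_gain: float = 1.0,
    gaussian_sigma: float = 2.0,
) -> np.ndarray:
    """Poisson–Gaussian camera noise: shot noise at the given gain, then
    additive Gaussian read noise, clamped at zero."""
    img = np.asarray(image, dtype=float)
    if poisson_gain > 0:
        img = rng.poisson(np.clip(img, 0, None) * poisson_gain) / poisson_gain
    if gaussian_sigma > 0:
        img = img + rng.normal(0.0, gaussian_sigma, size=img.shape)
    return np.clip(img, 0.0, None)


def _physical_grid(shape, voxel_size):
    vs = np.asarray(voxel_size, dtype=float)[-len(shape):]
    axes = [np.arange(n) * s for n, s in zip(shape, vs)]
    return np.meshgrid(*axes, indexing="ij"), vs


def render_spheres(
    shape,
    voxel_size,
    centers_um: np.ndarray,
    radii_um: np.ndarray,
    smooth_sigma_px: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize spheres; returns (float mask in [0,1], label image).

    Later spheres overwrite earlier ones where they overlap. Labels are
    the rendered ground-truth masks (before smoothing).
    """
    labels = np.zeros(shape, dtype=np.int32)
    grids, _ = _physical_grid(shape, voxel_size)
    for i, (c, r) in enumerate(zip(np.atleast_2d(centers_um), np.atleast_1d(radii_um))):
        d2 = sum((g - cc) ** 2 for g, cc in zip(grids, c))
        labels[d2 <= r * r] = i + 1
    mask = (labels > 0).astype(float)
    if smooth_sigma_px > 0:
        mask = ndimage.gaussian_filter(mask, smooth_sigma_px)
    return mask, labels


def render_tubes(
    shape,
    voxel_size,
    segments: list[tuple[tuple, tuple]],
    radius_um: float,
) -> np.ndarray:
    """Rasterize capsule tubes (segments with a circular cross-section).

    ``segments`` is a list of (start, end) points in µm (same
    dimensionality as ``shape``). Returns a boolean mask.
    """
    grids, _ = _physical_grid(shape, voxel_size)
    pts = np.stack([g.ravel() for g in grids], axis=1)
    mask = np.zeros(pts.shape[0], dtype=bool)
    for a, b in segments:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip((pts - a) @ ab / denom, 0.0, 1.0) if denom > 0 else 0.0
        closest = a + np.outer(t, ab) if denom > 0 else np.broadcast_to(a, pts.shape)
        d2 = np.sum((pts - closest) ** 2, axis=1)
        mask |= d2 <= radius_um**2
    return mask.reshape(shape)


def tube_probability_map(
    shape, voxel_size, segments, radius_um: float, softness_um: float = 1.0
) -> np.ndarray:
    """Soft vessel-probability map: 1 on the axis, 0.5 at the tube wall,
    decaying outward over ``softness_um`` (logistic in wall distance)."""
    grids, _ = _physical_grid(shape, voxel_size)
    pts = np.stack([g.ravel() for g in grids], axis=1)
    dmin = np.full(pts.shape[0], np.inf)
    for a, b in segments:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip((pts - a) @ ab / denom, 0.0, 1.0) if denom > 0 else 0.0
        closest = a + np.outer(t, ab) if denom > 0 else np.broadcast_to(a, pts.shape)
        dmin = np.minimum(dmin, np.sqrt(np.sum((pts - closest) ** 2, axis=1)))
    prob = 1.0 / (1.0 + np.exp((dmin - radius_um) / softness_um))
    return prob.reshape(shape)


# --------------------------------------------------------------------------
# scene: cells with cargo (uptake / colocalization)


def cells_cargo_scene(
    shape=(24, 96, 96),
    voxel_size=(1.0, 1.0, 1.0),
    n_cells: int = 5,
    cell_radius_um: float = 8.0,
    n_cargo: int = 20,
    cargo_radius_um: float = 1.5,
    fraction_inside: float = 0.7,
    cell_intensity: float = 200.0,
    cargo_intensity: float = 200.0,
    background: float = 10.0,
    gaussian_sigma: float = 0.0,
    poisson_gain: float = 0.0,
    seed: int = 0,
) -> dict[str, Any]:
    """Cells plus cargo particles with an exact inside/outside assignment.

    ``round(fraction_inside * n_cargo)`` particles are *placed* strictly
    inside cells (assigned, not sampled, so the count is exact by
    construction); the rest are placed clear of every cell. Returns the
    two intensity channels, ground-truth label images and a truth table.
    """
    rng = np.random.default_rng(seed)
    extent = np.array(shape, dtype=float) * np.asarray(voxel_size)[-len(shape):]
    margin = cell_radius_um + 2.0

    cell_centers = []
    for _ in range(20000):
        if len(cell_centers) == n_cells:
            break
        c = rng.uniform(margin, extent - margin)
        if all(np.linalg.norm(c - o) > 2 * cell_radius_um + 2 for o in cell_centers):
            cell_centers.append(c)
    if len(cell_centers) < n_cells:
        raise ValueError("could not place non-overlapping cells; reduce n_cells")
    cell_centers = np.array(cell_centers)

    n_inside = int(round(fraction_inside * n_cargo))
    cargo_centers = []
    inside_flags = []
    for i in range(n_cargo):
        want_inside = i < n_inside
        for _ in range(20000):
            if want_inside:
                host = cell_centers[rng.integers(n_cells)]
                u = rng.normal(size=len(shape))
                u /= np.linalg.norm(u)
                r = rng.uniform(0, cell_radius_um - cargo_radius_um - 1.0)
                c = host + u * r
            else:
                c = rng.uniform(cargo_radius_um + 1, extent - cargo_radius_um - 1)
                if np.min(np.linalg.norm(cell_centers - c, axis=1)) <= (
                    cell_radius_um + cargo_radius_um + 1.0
                ):
                    continue
            if all(
                np.linalg.norm(c - o) > 2 * cargo_radius_um + 1 for o in cargo_centers
            ):
                cargo_centers.append(c)
                inside_flags.append(want_inside)
                break
        else:
            raise ValueError("could not place cargo particle")
    cargo_centers = np.array(cargo_centers)

    cell_mask, cell_labels = render_spheres(
        shape, voxel_size, cell_centers, np.full(n_cells, cell_radius_um)
    )
    cargo_mask, cargo_labels = render_spheres(
        shape, voxel_size, cargo_centers, np.full(n_cargo, cargo_radius_um)
    )
    cell_img = background + cell_intensity * cell_mask
    cargo_img = background + cargo_intensity * cargo_mask
    if gaussian_sigma > 0 or poisson_gain > 0:
        cell_img = apply_noise(cell_img, rng, poisson_gain, gaussian_sigma)
        cargo_img = apply_noise(cargo_img, rng, poisson_gain, gaussian_sigma)
    return {
        "cell_image": cell_img,
        "cargo_image": cargo_img,
        "cell_labels": cell_labels,
        "cargo_labels": cargo_labels,
        "cell_centers_um": cell_centers,
        "cargo_centers_um": cargo_centers,
        "cargo_inside": np.array(inside_flags, dtype=bool),
        "voxel_size": tuple(voxel_size),
    }


def spheres_scene(
    radii_um=(4.0, 6.0, 8.0),
    shape=(32, 72, 72),
    voxel_size=(1.0, 1.0, 1.0),
    foreground: float = 200.0,
    background: float = 10.0,
    seed: int = 0,
) -> dict[str, Any]:
    """Well-separated bright spheres on a dim background (detection
    fixture). Truth volumes are brute-force voxel counts of the rendered
    masks times the voxel volume."""
    rng = np.random.default_rng(seed)
    extent = np.array(shape, dtype=float) * np.asarray(voxel_size)[-len(shape):]
    centers = []
    for r in radii_um:
        for _ in range(20000):
            c = rng.uniform(r + 2, extent - r - 2)
            if all(
                np.linalg.norm(c - o) > r + ro + 4
                for o, ro in zip(centers, radii_um)
            ):
                centers.append(c)
                break
        else:
            raise ValueError("could not place spheres")
    centers = np.array(centers)
    mask, labels = render_spheres(shape, voxel_size, centers, np.asarray(radii_um))
    image = background + (foreground - background) * mask
    vox = float(np.prod(voxel_size))
    true_volumes = np.array(
        [np.count_nonzero(labels == i + 1) * vox for i in range(len(radii_um))]
    )
    return {
        "image": image,
        "labels": labels,
        "centers_um": centers,
        "true_volumes_um3": true_volumes,
        "voxel_size": tuple(voxel_size),
    }


# --------------------------------------------------------------------------
# scene: moving nuclei (tracking)


def random_walk_positions(
    n_steps: int,
    step_um: float,
    turning_kappa: float,
    rng: np.random.Generator,
    start=(0.0, 0.0),
    initial_heading: float | None = None,
) -> np.ndarray:
    """2D persistent random walk: fixed step length, wrapped-normal-like
    turning angles drawn from a von Mises with concentration
    ``turning_kappa`` (0 = unbiased random walk, large = nearly straight).
    Returns ``(n_steps + 1, 2)`` positions in (y, x) µm."""
    heading = rng.uniform(-np.pi, np.pi) if initial_heading is None else initial_heading
    pos = [np.asarray(start, dtype=float)]
    for _ in range(n_steps):
        if turning_kappa > 0:
            heading += rng.vonmises(0.0, turning_kappa)
        else:
            heading = rng.uniform(-np.pi, np.pi)
        pos.append(pos[-1] + step_um * np.array([np.sin(heading), np.cos(heading)]))
    return np.array(pos)


def straight_track_positions(
    n_steps: int, step_um: float, heading: float = 0.3, start=(0.0, 0.0)
) -> np.ndarray:
    """Perfectly directed track: collinear unit steps."""
    d = step_um * np.array([np.sin(heading), np.cos(heading)])
    return np.asarray(start, dtype=float) + np.outer(np.arange(n_steps + 1), d)


def nuclei_movie(
    n_walkers: int = 5,
    n_frames: int = 30,
    shape_yx=(128, 128),
    pixel_size_um: float = 1.0,
    speed_um_per_min: float = 2.0,
    time_interval_min: float = 1.0,
    turning_kappa: float = 1.0,
    nucleus_sigma_px: float = 2.0,
    amplitude: float = 200.0,
    background: float = 5.0,
    min_separation_um: float = 12.0,
    gaussian_sigma: float = 0.0,
    poisson_gain: float = 0.0,
    seed: int = 0,
) -> dict[str, Any]:
    """Time-lapse of drifting nuclei rendered as Gaussian blobs.

    Walker trajectories are scripted first (and returned as ground
    truth); sets whose walkers ever come closer than
    ``min_separation_um`` are re-drawn so tracks are non-crossing by
    construction.
    """
    rng = np.random.default_rng(seed)
    extent = np.array(shape_yx, dtype=float) * pixel_size_um
    step = speed_um_per_min * time_interval_min
    margin = step * n_frames / 3 + 5

    for _attempt in range(200):
        starts = rng.uniform(margin, extent - margin, size=(n_walkers, 2))
        trajs = np.stack(
            [
                random_walk_positions(n_frames - 1, step, turning_kappa, rng, start=s)
                for s in starts
            ]
        )
        if np.any(trajs < 2) or np.any(trajs > extent - 2):
            continue
        ok = True
        for f in range(n_frames):
            p = trajs[:, f]
            d = np.linalg.norm(p[:, None] - p[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < min_separation_um:
                ok = False
                break
        if ok:
            break
    else:
        raise ValueError("could not script non-crossing walkers; loosen parameters")

    yy, xx = np.meshgrid(
        np.arange(shape_yx[0]) * pixel_size_um,
        np.arange(shape_yx[1]) * pixel_size_um,
        indexing="ij",
    )
    movie = np.empty((n_frames,) + tuple(shape_yx))
    for f in range(n_frames):
        frame = np.full(shape_yx, background, dtype=float)
        for w in range(n_walkers):
            cy, cx = trajs[w, f]
            frame += amplitude * np.exp(
                -((yy - cy) ** 2 + (xx - cx) ** 2)
                / (2 * (nucleus_sigma_px * pixel_size_um) ** 2)
            )
        if gaussian_sigma > 0 or poisson_gain > 0:
            frame = apply_noise(frame, rng, poisson_gain, gaussian_sigma)
        movie[f] = frame
    return {
        "movie": movie,
        "trajectories_um": trajs,  # (walker, frame, yx)
        "time_interval_min": time_interval_min,
        "pixel_size_um": pixel_size_um,
    }


# --------------------------------------------------------------------------
# scene: vessel networks


def straight_tube_scene(
    length_um: float = 100.0,
    radius_um: float = 3.0,
    shape=(16, 32, 128),
    voxel_size=(1.0, 1.0, 1.0),
) -> dict[str, Any]:
    zc, yc = shape[0] // 2, shape[1] // 2
    x0 = (shape[2] - length_um / voxel_size[2]) / 2
    a = (zc * voxel_size[0], yc * voxel_size[1], x0 * voxel_size[2])
    b = (zc * voxel_size[0], yc * voxel_size[1], x0 * voxel_size[2] + length_um)
    binary = render_tubes(shape, voxel_size, [(a, b)], radius_um)
    return {
        "binary": binary,
        "prob_map": tube_probability_map(shape, voxel_size, [(a, b)], radius_um),
        "segments": [(a, b)],
        "true_length_um": length_um,
        "voxel_size": tuple(voxel_size),
    }


def ytube_scene(
    trunk_length_um: float = 50.0,
    branch_lengths_um=(35.0, 35.0),
    branch_angle_deg: float = 35.0,
    radius_um: float = 2.0,
    shape=(10, 72, 128),
    voxel_size=(1.0, 1.0, 1.0),
    clip_first_branch: bool = False,
) -> dict[str, Any]:
    """Y-shaped tube: a trunk splitting into two symmetric branches with
    individually set lengths.

    Ground truth: 1 junction, 3 end points, 3 edges. With
    ``clip_first_branch`` the first branch is run past the image border
    so its free end results from clipping.
    """
    zc = shape[0] // 2 * voxel_size[0]
    yc = shape[1] // 2 * voxel_size[1]
    x0 = 8.0 * voxel_size[2]
    fork = (zc, yc, x0 + trunk_length_um)
    ang = np.radians(branch_angle_deg)
    segs = [((zc, yc, x0), fork)]
    lengths = [trunk_length_um]
    for sgn, L, clip in (
        (1, branch_lengths_um[0], clip_first_branch),
        (-1, branch_lengths_um[1], False),
    ):
        if clip:
            # overshoot the y border so the free end is an image-edge cut
            L = (shape[1] * voxel_size[1] - yc) / np.sin(ang) + 6.0
        end = (
            zc,
            yc + sgn * L * np.sin(ang),
            fork[2] + L * np.cos(ang),
        )
        segs.append((fork, end))
        lengths.append(L)
    binary = render_tubes(shape, voxel_size, segs, radius_um)
    return {
        "binary": binary,
        "segments": segs,
        "branch_lengths_um": lengths,
        "n_junctions": 1,
        "n_end_points": 3,
        "n_edges": 3,
        "voxel_size": tuple(voxel_size),
    }


# --------------------------------------------------------------------------
# scene: fibril fields


def stripe_field(
    angle_deg: float,
    shape=(128, 128),
    period_px: float = 8.0,
    amplitude: float = 80.0,
    offset: float = 100.0,
) -> np.ndarray:
    """Parallel stripes whose fibril axis lies at ``angle_deg`` (CCW from
    the x-axis). Intensity is constant along the stripes and sinusoidal
    across them."""
    rows, cols = np.indices(shape)
    x = cols.astype(float)
    y_c = -rows.astype(float)  # Cartesian y up
    th = np.radians(angle_deg)
    phase = -x * np.sin(th) + y_c * np.cos(th)  # coordinate along the normal
    return offset + amplitude * np.cos(2 * np.pi * phase / period_px)


def sample_axial_vonmises(
    theta0_deg: float, kappa: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Axial von Mises orientation sample in degrees within (−90, 90].

    Sampled on the doubled angle (2θ), so κ = 0 gives uniformly random
    orientations and large κ concentrates at θ₀.
    """
    if kappa > 0:
        phi = rng.vonmises(np.radians(2 * theta0_deg), kappa, size=n)
    else:
        phi = rng.uniform(-np.pi, np.pi, size=n)
    theta = np.degrees(phi) / 2.0
    theta = np.mod(theta + 90.0, 180.0) - 90.0
    theta[theta == -90.0] = 90.0
    return theta


def fibril_field(
    theta0_deg: float = 30.0,
    kappa: float = 4.0,
    n_fibrils: int = 500,
    fibril_length_px: float = 15.0,
    shape=(192, 192),
    amplitude: float = 150.0,
    background: float = 10.0,
    line_sigma_px: float = 0.8,
    gaussian_sigma: float = 0.0,
    seed: int = 0,
) -> dict[str, Any]:
    """Field of straight fibril segments with von Mises orientations.

    Each fibril is a line segment of fixed length drawn at a random
    position with orientation sampled from the axial von Mises
    (θ₀, κ); segments are rendered as thin Gaussian-profile lines.
    """
    rng = np.random.default_rng(seed)
    angles = sample_axial_vonmises(theta0_deg, kappa, n_fibrils, rng)
    img = np.zeros(shape, dtype=float)
    half = fibril_length_px / 2.0
    for th in angles:
        cy = rng.uniform(half, shape[0] - half)
        cx = rng.uniform(half, shape[1] - half)
        t = np.radians(th)
        # CCW-positive axis in image coords: row decreases with +angle
        dy, dx = -np.sin(t), np.cos(t)
        s = np.linspace(-half, half, int(2 * fibril_length_px))
        ys = np.clip(np.round(cy + s * dy).astype(int), 0, shape[0] - 1)
        xs = np.clip(np.round(cx + s * dx).astype(int), 0, shape[1] - 1)
        img[ys, xs] = 1.0
    img = ndimage.gaussian_filter(img, line_sigma_px)
    img = background + amplitude * img / max(img.max(), 1e-12)
    if gaussian_sigma > 0:
        img = apply_noise(img, rng, poisson_gain=0.0, gaussian_sigma=gaussian_sigma)
    return {
        "image": img,
        "angles_deg": angles,
        "theta0_deg": theta0_deg,
        "kappa": kappa,
    }


# --------------------------------------------------------------------------
# scene: pigment, fractures, epithelial sheets


def pigment_scene(
    shape=(5, 128, 128),
    roi_center_px=(64, 64),
    roi_radius_px: float = 40.0,
    covered_fraction: float = 0.5,
    focus_slice: int = 2,
    bright: float = 200.0,
    dark: float = 20.0,
    seed: int = 0,
) -> dict[str, Any]:
    """Brightfield z-stack with a dark pigment patch covering a set
    fraction of a circular roi, sharp only in one focal slice.

    The patch is the half-plane cut of the roi circle whose area fraction
    matches ``covered_fraction``; the true fraction is recomputed from
    the rasterized masks.
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.indices(shape[1:])
    cy, cx = roi_center_px
    roi_mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= roi_radius_px**2
    # half-plane cut at the x position giving the requested area fraction
    xs = np.sort(xx[roi_mask])
    cut = xs[min(int(covered_fraction * len(xs)), len(xs) - 1)]
    patch = roi_mask & (xx <= cut)
    stack = np.full(shape, bright, dtype=float)
    stack += rng.normal(0, 1.0, size=shape)
    # pigment is textured (speckled melanin), so the in-focus slice wins
    # the local-contrast comparison everywhere inside the patch
    texture = dark * np.abs(1.0 + 0.4 * rng.normal(size=patch.sum()))
    stack[focus_slice][patch] = texture
    true_fraction = float(patch.sum()) / float(roi_mask.sum())
    return {
        "stack": np.clip(stack, 0, None),
        "roi_mask": roi_mask,
        "patch_mask": patch,
        "true_percent": 100.0 * true_fraction,
        "roi_center_px": roi_center_px,
        "roi_radius_px": roi_radius_px,
    }


def fracture_pair_scene(
    shape=(128, 128),
    target_center_px=(32, 32),
    control_center_px=(96, 96),
    roi_radius_px: float = 16.0,
    control_intensity: float = 100.0,
    ratio: float = 2.0,
    background: float = 30.0,
) -> dict[str, Any]:
    """Single-slice image whose fracture region is ``ratio`` × as bright
    as the uninjured control region."""
    yy, xx = np.indices(shape)
    img = np.full(shape, background, dtype=float)
    t_mask = (yy - target_center_px[0]) ** 2 + (xx - target_center_px[1]) ** 2 <= roi_radius_px**2
    c_mask = (yy - control_center_px[0]) ** 2 + (xx - control_center_px[1]) ** 2 <= roi_radius_px**2
    img[c_mask] = control_intensity
    img[t_mask] = control_intensity * ratio
    return {
        "image": img,
        "true_ratio": ratio,
        "target_center_px": target_center_px,
        "control_center_px": control_center_px,
        "roi_radius_px": roi_radius_px,
    }


def shape_gallery() -> dict[str, np.ndarray]:
    """Label masks of reference shapes for morphometry checks."""
    out = {}
    disk = np.zeros((80, 80), dtype=np.int32)
    yy, xx = np.indices(disk.shape)
    disk[(yy - 40) ** 2 + (xx - 40) ** 2 <= 30**2] = 1
    out["disk_r30"] = disk
    sq = np.zeros((60, 60), dtype=np.int32)
    sq[10:50, 10:50] = 1
    out["square_40"] = sq
    for k in (5, 10, 20, 40):
        rect = np.zeros((20, k + 10), dtype=np.int32)
        rect[9:12, 5 : 5 + k] = 1  # 3×k bar
        out[f"bar_3x{k}"] = rect
    return out


# --------------------------------------------------------------------------
# spec-driven dispatch and the canonical fixture suite


@dataclass
class SceneSpec:
    """Declarative scene request: a kind plus its generator parameters."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    KINDS = (
        "cells_cargo",
        "spheres",
        "nuclei_movie",
        "straight_tube",
        "ytube",
        "stripe_field",
        "fibril_field",
        "pigment",
        "fracture_pair",
    )

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown scene kind {self.kind!r}")


_SEEDED: dict[str, Callable] = {
    "cells_cargo": cells_cargo_scene,
    "spheres": spheres_scene,
    "nuclei_movie": nuclei_movie,
    "fibril_field": fibril_field,
    "pigment": pigment_scene,
}
_UNSEEDED: dict[str, Callable] = {
    "straight_tube": straight_tube_scene,
    "ytube": ytube_scene,
    "fracture_pair": fracture_pair_scene,
}


def render(spec: SceneSpec) -> dict[str, Any]:
    """Render a scene from its spec; deterministic given the seed."""
    if spec.kind == "stripe_field":
        return {"image": stripe_field(**spec.params)}
    if spec.kind in _SEEDED:
        return _SEEDED[spec.kind](seed=spec.seed, **spec.params)
    return _UNSEEDED[spec.kind](**spec.params)


def make_fixture_suite(seed: int = 0) -> dict[str, dict]:
    """The canonical ground-truth fixtures used across the test suite."""
    return {
        "three_spheres": spheres_scene(seed=seed),
        "cells_cargo": cells_cargo_scene(seed=seed),
        "walkers": nuclei_movie(seed=seed),
        "tube100": straight_tube_scene(),
        "ytube": ytube_scene(),
        "ytube_short_branch": ytube_scene(branch_lengths_um=(8.0, 35.0)),
        "ytube_clipped": ytube_scene(
            branch_lengths_um=(8.0, 35.0), clip_first_branch=True
        ),
        "stripes30": {"image": stripe_field(30.0), "theta0_deg": 30.0},
        "vonmises_k4": fibril_field(kappa=4.0, seed=seed),
        "half_pigment": pigment_scene(seed=seed),
        "ratio2x": fracture_pair_scene(),
        "shapes": shape_gallery(),
    }
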