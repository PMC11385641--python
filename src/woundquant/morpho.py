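"""Morphometry and intensity readouts.

Covers the remaining per-sample measurements of a wound / fracture study:
cell area and circularity in a wound region, reference-relative
high-fluorescence volume, pigment area fraction on an all-in-focus
brightfield projection, fracture-to-control intensity ratios, and
stain-positive area fraction.

Circularity is 4π·A/P² with the perimeter estimated, by default, as the
length of the subpixel 0.5-level contour of the Gaussian-smoothed (σ = 1
px) object mask — a low-bias estimator that reads a rasterized disk as
nearly ideal while keeping a square near the analytic π/4. The Crofton
approximation is available as an alternative. Circularity is clamped to 1
so digitization cannot exceed the ideal disk value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import find_contours, regionprops

from .detect import DetectionParams, adjusted_threshold, _prefilter
from .roi import RegionOfInterest
from .stack import _as_voxel_size


@dataclass
class RatioResult:
    numerator_mean_intensity: float
    denominator_mean_intensity: float
    ratio: float


def _smooth_contour_perimeter(mask: np.ndarray, sigma: float = 1.0) -> float:
    """Length of the subpixel 0.5-contour of the smoothed binary mask."""
    f = ndimage.gaussian_filter(np.pad(mask.astype(float), 3), sigma)
    return float(
        sum(
            np.sqrt((np.diff(c, axis=0) ** 2).sum(axis=1)).sum()
            for c in find_contours(f, 0.5)
        )
    )


def cell_shape_metrics(
    labels: np.ndarray,
    pixel_size_um: float,
    roi: RegionOfInterest | None = None,
    perimeter_method: str = "smooth_contour",
) -> pd.DataFrame:
    """Area, perimeter and circularity per labeled cell inside the roi.

    Works on a 2D label mask (cells segmented on a maximum projection);
    only cells whose centroid falls in the roi are reported. Columns:
    cell_id, area_um2, perimeter_um, circularity.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("label mask must be 2D")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    if perimeter_method not in ("smooth_contour", "crofton"):
        raise ValueError(f"unknown perimeter method {perimeter_method!r}")
    if roi is None:
        roi = RegionOfInterest(kind="whole")
    rows = []
    for rp in regionprops(labels):
        cy, cx = rp.centroid
        if not roi.contains_points([(cy * pixel_size_um, cx * pixel_size_um)])[0]:
            continue
        area = rp.area * pixel_size_um**2
        if perimeter_method == "smooth_contour":
            perim = _smooth_contour_perimeter(rp.image) * pixel_size_um
        else:
            perim = rp.perimeter_crofton * pixel_size_um
        circ = 4.0 * np.pi * area / perim**2 if perim > 0 else float("nan")
        rows.append(
            {
                "cell_id": int(rp.label),
                "area_um2": float(area),
                "perimeter_um": float(perim),
                "circularity": float(min(circ, 1.0)),
            }
        )
    return pd.DataFrame(rows, columns=["cell_id", "area_um2", "perimeter_um", "circularity"])


def _roi_mask_3d(roi: RegionOfInterest, shape, voxel_size) -> np.ndarray:
    """Rasterize a 2D roi as a cylinder through z (or plain 2D mask)."""
    vs = _as_voxel_size(voxel_size)
    if len(shape) == 2:
        return roi.mask(shape, vs[-2:])
    m2d = roi.mask(shape[-2:], vs[-2:])
    return np.broadcast_to(m2d, shape)


def high_fluorescence_volume(
    stack: np.ndarray,
    voxel_size,
    reference_roi: RegionOfInterest,
    wound_roi: RegionOfInterest,
    factor: float = 2.0,
) -> float:
    """Volume (µm³) of bright signal in the wound, thresholded relative
    to a reference region selected away from the wound.

    The global threshold is ``factor ×`` the mean intensity of the
    reference roi; the returned volume counts suprathreshold voxels
    inside the wound roi. Monotone non-increasing in ``factor``.
    """
    stack = np.asarray(stack, dtype=float)
    vs = _as_voxel_size(voxel_size)
    ref_mask = _roi_mask_3d(reference_roi, stack.shape, vs)
    if not ref_mask.any():
        raise ValueError("reference roi is empty")
    thr = factor * float(stack[ref_mask].mean())
    wound_mask = _roi_mask_3d(wound_roi, stack.shape, vs)
    n = int(np.count_nonzero((stack >= thr) & wound_mask))
    return n * float(np.prod(vs))


def focus_stack(zstack: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """All-in-focus 2D image by per-pixel best-focus slice selection.

    Focus is scored per slice as the Gaussian-weighted local variance of
    intensity (window set by ``sigma``, default ≈ 9×9 px support); each
    output pixel takes the z slice maximizing the score.
    """
    z = np.asarray(zstack, dtype=float)
    if z.ndim == 2:
        return z
    if z.ndim != 3:
        raise ValueError("expect a (z, y, x) stack")
    scores = np.empty_like(z)
    for k in range(z.shape[0]):
        mu = ndimage.gaussian_filter(z[k], sigma)
        scores[k] = ndimage.gaussian_filter((z[k] - mu) ** 2, sigma)
    best = np.argmax(scores, axis=0)
    return np.take_along_axis(z, best[np.newaxis], axis=0)[0]


def pigmentation_percent(
    brightfield: np.ndarray,
    roi: RegionOfInterest,
    pixel_size_yx=(1.0, 1.0),
    focus_sigma: float = 2.0,
    threshold_multiplier: float = 1.0,
    bright_pigment: bool = False,
) -> float:
    """Percentage of the roi area covered by pigment in brightfield.

    The z-stack is reduced to an all-in-focus image with a Gaussian stack
    focuser, binarized with an adjusted Otsu threshold, and the dark
    fraction (pigment absorbs in brightfield; ``bright_pigment`` inverts)
    inside the roi is reported. A uniformly bright field gives 0%.
    """
    focused = focus_stack(brightfield, sigma=focus_sigma)
    mask = roi.mask(focused.shape, pixel_size_yx)
    if not mask.any():
        raise ValueError("roi is empty")
    try:
        thr = adjusted_threshold(focused, "otsu", threshold_multiplier, 0.0)
    except ValueError:
        return 0.0 if not bright_pigment else 100.0  # uniform field: no pattern
    pigment = focused >= thr if bright_pigment else focused < thr
    return 100.0 * float(np.count_nonzero(pigment & mask)) / float(mask.sum())


def intensity_ratio(
    image: np.ndarray,
    target_roi: RegionOfInterest,
    control_roi: RegionOfInterest,
    pixel_size_yx=(1.0, 1.0),
) -> RatioResult:
    """Mean-intensity ratio of a target region to an uninjured control."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expect a single-slice 2D image")
    t_mask = target_roi.mask(img.shape, pixel_size_yx)
    c_mask = control_roi.mask(img.shape, pixel_size_yx)
    if not t_mask.any() or not c_mask.any():
        raise ValueError("roi is empty")
    num = float(img[t_mask].mean())
    den = float(img[c_mask].mean())
    if den <= 0:
        raise ValueError("control mean intensity must be > 0")
    return RatioResult(num, den, num / den)


def stain_positive_percent(
    image: np.ndarray,
    roi: RegionOfInterest,
    params: DetectionParams | None = None,
    pixel_size_yx=(1.0, 1.0),
) -> float:
    """Percentage of the roi area positive for a stain.

    The image is binarized with the standard adjusted-threshold chain and
    the suprathreshold fraction of the roi is returned. A constant image
    yields 0% when a positive threshold floor is set (no stain contrast).
    """
    if params is None:
        params = DetectionParams()
    img = np.asarray(image, dtype=float)
    filtered = _prefilter(img, params)
    mask = roi.mask(img.shape[-2:], pixel_size_yx)
    if not mask.any():
        raise ValueError("roi is empty")
    try:
        thr = adjusted_threshold(
            filtered,
            params.threshold_method,
            params.threshold_multiplier,
            params.threshold_floor,
        )
    except ValueError:
        if params.threshold_floor > 0:
            thr = params.threshold_floor
        else:
            raise
    positive = filtered >= thr
    if positive.ndim == 3:
        positive = positive.max(axis=0)
    return 100.0 * float(np.count_nonzero(positive & mask)) / float(mask.sum())
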