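"""Object detection front end shared by every fluorescence stage.

The chain is the classical one: optional noise prefilter (2D median,
slice-wise, or nD Gaussian), automatic thresholding (Otsu or the
moment-preserving "moments" method) with a user multiplier and a minimum
permitted threshold to keep background out, connected-component labelling
under full connectivity, a physical-volume size filter, and an optional
intensity-based watershed to split objects merged during binarization.

All filters operate in pixel units; every reported volume or length is
converted to µm via the stack's voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.restoration import rolling_ball
from skimage.segmentation import watershed

from .stack import LabeledObjects

#: full connectivity: 8-connected in 2D, 26-connected in 3D
def _full_structure(ndim: int) -> np.ndarray:
    return np.ones((3,) * ndim, dtype=bool)


@dataclass
class DetectionParams:
    """Parameters of the detection chain.

    prefilter : {'none', 'median', 'gaussian'}
        Noise filter applied before thresholding. The median filter runs
        slice-wise in 2D with a ``prefilter_size`` × ``prefilter_size``
        kernel; the Gaussian runs in nD with ``prefilter_sigma`` px.
    threshold_method : {'otsu', 'moments'}
    threshold_multiplier : float > 0
        Multiplies the automatic threshold.
    threshold_floor : float >= 0
        Minimum permitted threshold, guarding against background
        segmentation when the automatic value is too low.
    min_object_volume : float >= 0, µm³
        Objects smaller than this are discarded.
    split_touching : bool
        Apply the watershed split after labelling.
    """

    prefilter: str = "none"
    prefilter_size: int = 3
    prefilter_sigma: float = 1.0
    threshold_method: str = "otsu"
    threshold_multiplier: float = 1.0
    threshold_floor: float = 0.0
    min_object_volume: float = 0.0
    split_touching: bool = False

    def __post_init__(self):
        if self.prefilter not in ("none", "median", "gaussian"):
            raise ValueError(f"unknown prefilter {self.prefilter!r}")
        if self.threshold_method not in ("otsu", "moments"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold_multiplier must be > 0")
        if self.threshold_floor < 0:
            raise ValueError("threshold_floor must be >= 0")
        if self.min_object_volume < 0:
            raise ValueError("min_object_volume must be >= 0")


def _moments_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Moment-preserving (Tsai) threshold on a 256-bin histogram.

    Chooses the gray level whose below/above split preserves the first
    three moments of the image histogram.
    """
    lo, hi = float(image.min()), float(image.max())
    counts, edges = np.histogram(image, bins=n_bins, range=(lo, hi))
    p = counts / counts.sum()
    z = 0.5 * (edges[:-1] + edges[1:])  # bin centers on the intensity scale
    # work on normalized bin indices for conditioning, threshold via fraction
    idx = np.arange(n_bins, dtype=float)
    m1 = float(np.sum(idx * p))
    m2 = float(np.sum(idx**2 * p))
    m3 = float(np.sum(idx**3 * p))
    cd = m2 - m1 * m1
    if cd <= 0:
        raise ValueError("degenerate histogram")
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        disc = 0.0
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        raise ValueError("degenerate histogram")
    p0 = (z1 - m1) / (z1 - z0)  # target fraction of the lower class
    cum = np.cumsum(p)
    t_bin = int(np.searchsorted(cum, p0))
    t_bin = min(max(t_bin, 0), n_bins - 1)
    return float(z[t_bin])


def adjusted_threshold(
    image: np.ndarray,
    method: str = "otsu",
    multiplier: float = 1.0,
    floor: float = 0.0,
) -> float:
    """Automatic threshold adjusted by a multiplier and a minimum floor.

    Returns ``max(multiplier * t_auto, floor)`` where ``t_auto`` maximizes
    between-class variance (``'otsu'``) or preserves the first three image
    moments (``'moments'``, Tsai's method on a 256-bin histogram).

    Raises
    ------
    ValueError
        ``"degenerate histogram"`` for a constant image; a parameter error
        for a non-positive multiplier.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    if floor < 0:
        raise ValueError("floor must be >= 0")
    image = np.asarray(image)
    if image.min() == image.max():
        raise ValueError("degenerate histogram")
    if method == "otsu":
        vals = np.unique(image)
        if len(vals) == 2:
            # exact two-class case: any cut between the two levels is
            # optimal; return the midpoint so >= keeps the bright class
            t_auto = float(vals.sum() / 2.0)
        else:
            t_auto = float(threshold_otsu(image.ravel(), nbins=256))
    elif method == "moments":
        t_auto = _moments_threshold(image)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return float(max(multiplier * t_auto, floor))


def _prefilter(image: np.ndarray, params: DetectionParams) -> np.ndarray:
    if params.prefilter == "median":
        # slice-wise 2D median, matching how z-stacks are denoised in
        # practice (no mixing across focal planes)
        out = np.empty_like(image)
        if image.ndim == 2:
            out = ndimage.median_filter(image, size=params.prefilter_size)
        else:
            for z in range(image.shape[0]):
                out[z] = ndimage.median_filter(image[z], size=params.prefilter_size)
        return out
    if params.prefilter == "gaussian":
        return ndimage.gaussian_filter(
            np.asarray(image, dtype=float), sigma=params.prefilter_sigma
        )
    return image


def detect_objects(
    image: np.ndarray,
    voxel_size,
    params: DetectionParams | None = None,
) -> LabeledObjects:
    """Detect bright objects in a single-channel 2D image or 3D stack.

    Prefilter → adjusted threshold (foreground = intensity >= threshold)
    → connected components (full connectivity) → optional watershed split
    → physical-volume size filter, relabelled contiguously.

    A constant image is an error ("degenerate histogram") unless the
    threshold floor is positive, in which case the floor alone defines
    foreground (an all-zero stack with a positive floor yields 0 objects).
    """
    if params is None:
        params = DetectionParams()
    image = np.asarray(image)
    filtered = _prefilter(image, params)
    try:
        thr = adjusted_threshold(
            filtered,
            method=params.threshold_method,
            multiplier=params.threshold_multiplier,
            floor=params.threshold_floor,
        )
    except ValueError:
        if params.threshold_floor > 0:
            thr = params.threshold_floor
        else:
            raise
    binary = filtered >= thr
    labels, _ = ndimage.label(binary, structure=_full_structure(binary.ndim))
    objects = LabeledObjects.from_labels(labels, voxel_size)
    if params.split_touching and objects.n_objects:
        objects = split_touching(objects, filtered)
    if params.min_object_volume > 0:
        objects = objects.filter_volume(params.min_object_volume)
    return objects


def split_touching(
    objects: LabeledObjects,
    intensity: np.ndarray,
    smooth_sigma: float = 1.0,
) -> LabeledObjects:
    """Separate touching objects along intensity valleys.

    Seeds are the local maxima of the Gaussian-smoothed (``smooth_sigma``
    px) intensity within each object; adjacent maxima forming a plateau
    collapse to one seed. A watershed on the inverted smoothed intensity,
    masked to the original foreground, partitions each object. Objects
    with a single maximum pass through unchanged; the output voxel set
    equals the input voxel set (pure partition).
    """
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape != objects.labels.shape:
        raise ValueError("intensity shape must match label shape")
    fg = objects.labels > 0
    if not fg.any():
        return objects
    smoothed = ndimage.gaussian_filter(intensity, sigma=smooth_sigma)
    struct = _full_structure(intensity.ndim)
    # regional maxima restricted to foreground; plateaus merge to one seed
    dil = ndimage.maximum_filter(smoothed, footprint=struct)
    maxima = fg & (smoothed >= dil)
    markers, n_seeds = ndimage.label(maxima, structure=struct)
    if n_seeds <= objects.n_objects:
        return objects
    new_labels = watershed(-smoothed, markers=markers, mask=fg)
    # safety: any foreground voxel left unassigned keeps its original label
    orphan = fg & (new_labels == 0)
    if orphan.any():
        new_labels = np.where(orphan, markers.max() + objects.labels, new_labels)
    return LabeledObjects.from_labels(new_labels, objects.voxel_size)


def subtract_background(image: np.ndarray, radius: float) -> np.ndarray:
    """Rolling-ball background subtraction, clamped at zero.

    A ball of the given radius (px) is rolled under each 2D slice to
    estimate the slowly varying background, which is subtracted; features
    much narrower than the radius are preserved.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        bg = rolling_ball(image, radius=radius)
    else:
        bg = np.empty_like(image)
        for z in range(image.shape[0]):
            bg[z] = rolling_ball(image[z], radius=radius)
    return np.clip(image - bg, 0.0, None)
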