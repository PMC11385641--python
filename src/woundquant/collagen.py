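"""Collagen fibril orientation and the alignment index.

Local fibril orientation is estimated from image gradients (structure
tensor by default, plain local gradients as an alternative backend) and
accumulated into an energy-weighted angular histogram over (−90°, 90°],
where the angle is that of the fibril axis from the image x-axis,
counterclockwise positive. The histogram is split at 0° into the
(0, 90] and (0, −90] ranges, a background pedestal is subtracted per
range, and each range is summarized by the alignment index

    AI = Σᵢ wᵢ · cos 2(θᵢ − θ_th) / Σᵢ wᵢ ,
    θ_th = ½ · atan2(Σᵢ wᵢ sin 2θᵢ, Σᵢ wᵢ cos 2θᵢ)

— the axial (period-π) analogue of the circular mean resultant length,
with θ_th the mean orientation angle. AI = 1 means no angular dispersion
(full fibril alignment); AI = 0 means randomly aligned fibrils. Angles
are axial quantities, so all trigonometry is on 2θ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class AngularHistogram:
    """Binned fibril orientation weights.

    ``bin_centers`` in degrees within (−90, 90], uniform width;
    ``weights`` non-negative, one per bin. ``range_tag`` records whether
    the histogram covers the full axial range or one half-range.
    """

    bin_centers: np.ndarray
    weights: np.ndarray
    range_tag: str = "full"  # 'full' | 'pos' (0..90] | 'neg' (0..-90]

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.bin_centers.shape != self.weights.shape:
            raise ValueError("bin_centers and weights must have equal length")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if len(self.bin_centers) > 1:
            widths = np.diff(self.bin_centers)
            if not np.allclose(widths, widths[0]):
                raise ValueError("bins must be uniform")

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


@dataclass
class AlignmentResult:
    """Mean orientation and alignment index of one angular range."""

    theta_mean_deg: float
    alignment_index: float
    n_effective: float


def _local_orientations(
    image: np.ndarray, sigma: float, method: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel fibril angle (deg, (−90, 90]) and orientation energy.

    Image rows increase downward, so the Cartesian y-gradient is the
    negated row gradient; the fibril axis is perpendicular to the local
    gradient direction.
    """
    img = np.asarray(image, dtype=float)
    gy = -ndimage.gaussian_filter(img, sigma, order=(1, 0))  # Cartesian y up
    gx = ndimage.gaussian_filter(img, sigma, order=(0, 1))
    if method == "gradient":
        energy = gx**2 + gy**2
        theta_grad = np.arctan2(gy, gx)
        theta = np.degrees(theta_grad) + 90.0
    elif method == "structure_tensor":
        rho = 2.0 * sigma  # tensor integration scale
        jxx = ndimage.gaussian_filter(gx * gx, rho)
        jxy = ndimage.gaussian_filter(gx * gy, rho)
        jyy = ndimage.gaussian_filter(gy * gy, rho)
        # dominant eigenvector = gradient direction; fibril axis is +90°
        theta_grad = 0.5 * np.arctan2(2.0 * jxy, jxx - jyy)
        theta = np.degrees(theta_grad) + 90.0
        energy = np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy**2)  # anisotropic part
    else:
        raise ValueError(f"unknown orientation method {method!r}")
    # wrap axial angles into (−90, 90]
    theta = np.mod(theta + 90.0, 180.0) - 90.0
    theta[theta == -90.0] = 90.0
    return theta, energy


def orientation_histogram(
    image: np.ndarray,
    n_bins: int = 90,
    sigma: float = 2.0,
    method: str = "structure_tensor",
) -> AngularHistogram:
    """Energy-weighted fibril orientation histogram over (−90°, 90°].

    A z-stack is reduced to its maximum-intensity projection first. The
    default 90 bins give 2° resolution. A constant image carries no
    orientation signal and raises a ValueError.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.max(axis=0)
    if img.ndim != 2:
        raise ValueError("expect a 2D image or a z-stack")
    if img.min() == img.max():
        raise ValueError("no orientation signal")
    theta, energy = _local_orientations(img, sigma, method)
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    weights, _ = np.histogram(theta.ravel(), bins=edges, weights=energy.ravel())
    centers = 0.5 * (edges[:-1] + edges[1:])
    return AngularHistogram(bin_centers=centers, weights=weights, range_tag="full")


def histogram_from_angles(
    angles_deg: np.ndarray, n_bins: int = 90, weights=None
) -> AngularHistogram:
    """Histogram raw per-measurement angles (deg) into the axial range."""
    ang = np.mod(np.asarray(angles_deg, dtype=float) + 90.0, 180.0) - 90.0
    ang[ang == -90.0] = 90.0
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    w, _ = np.histogram(ang, bins=edges, weights=weights)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return AngularHistogram(bin_centers=centers, weights=w, range_tag="full")


def subtract_histogram_background(
    hist: AngularHistogram, baseline: str = "min", percentile: float = 10.0
) -> AngularHistogram:
    """Remove the isotropic pedestal from an angular histogram.

    The baseline is the minimum bin weight (default) or a low percentile;
    weights are clamped at zero. A uniform histogram becomes all-zero and
    is flagged as degenerate downstream.
    """
    if baseline == "min":
        base = float(hist.weights.min()) if len(hist.weights) else 0.0
    elif baseline == "percentile":
        base = float(np.percentile(hist.weights, percentile))
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    return AngularHistogram(
        bin_centers=hist.bin_centers,
        weights=np.clip(hist.weights - base, 0.0, None),
        range_tag=hist.range_tag,
    )


def alignment_index(hist: AngularHistogram) -> AlignmentResult:
    """Mean orientation θ_th and alignment index of a histogram.

    AI = Σ w·cos 2(θ − θ_th) / Σ w, clamped to [0, 1]: 1 for a single
    orientation (no angular dispersion), 0 for uniformly random fibrils.
    Raises ValueError("degenerate histogram") when all weights are zero.
    """
    w = hist.weights
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate histogram")
    theta2 = 2.0 * np.radians(hist.bin_centers)
    s = float(np.sum(w * np.sin(theta2)))
    c = float(np.sum(w * np.cos(theta2)))
    theta_th = 0.5 * np.arctan2(s, c)
    ai = float(np.sum(w * np.cos(2.0 * np.radians(hist.bin_centers) - 2.0 * theta_th)) / total)
    ai = min(max(ai, 0.0), 1.0)
    return AlignmentResult(
        theta_mean_deg=float(np.degrees(theta_th)),
        alignment_index=ai,
        n_effective=float(total),
    )


def alignment_from_angles(angles_deg: np.ndarray, weights=None) -> AlignmentResult:
    """AI computed directly on raw angles rather than binned weights."""
    ang2 = 2.0 * np.radians(np.asarray(angles_deg, dtype=float))
    w = np.ones_like(ang2) if weights is None else np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate histogram")
    theta_th = 0.5 * np.arctan2(float(np.sum(w * np.sin(ang2))), float(np.sum(w * np.cos(ang2))))
    ai = float(np.sum(w * np.cos(ang2 - 2.0 * theta_th)) / total)
    return AlignmentResult(
        theta_mean_deg=float(np.degrees(theta_th)),
        alignment_index=min(max(ai, 0.0), 1.0),
        n_effective=float(total),
    )


def split_ranges(hist: AngularHistogram) -> tuple[AngularHistogram, AngularHistogram]:
    """Partition a full-range histogram at 0° into (0, 90] and (0, −90]."""
    pos = hist.bin_centers > 0
    neg = hist.bin_centers < 0
    return (
        AngularHistogram(hist.bin_centers[pos], hist.weights[pos], "pos"),
        AngularHistogram(hist.bin_centers[neg], hist.weights[neg], "neg"),
    )


def alignment_by_range(
    image: np.ndarray,
    n_bins: int = 90,
    sigma: float = 2.0,
    method: str = "structure_tensor",
    background: str = "min",
) -> dict[str, AlignmentResult | None]:
    """Alignment index per half-range of the orientation histogram.

    The full histogram is split at 0°, background-subtracted per range,
    and summarized; a range left with zero weight after subtraction is
    degenerate and reported as ``None``.
    """
    hist = orientation_histogram(image, n_bins=n_bins, sigma=sigma, method=method)
    out: dict[str, AlignmentResult | None] = {}
    for sub in split_ranges(hist):
        sub = subtract_histogram_background(sub, baseline=background)
        try:
            out[sub.range_tag] = alignment_index(sub)
        except ValueError:
            out[sub.range_tag] = None
    return out
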