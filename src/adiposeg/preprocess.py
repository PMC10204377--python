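"""MR bias-field correction and modality-specific fat thresholds.

Fat-only Dixon MR suffers smooth multiplicative signal inhomogeneity
from the B1 radiofrequency field.  Because the fat threshold is defined
as a fraction of the maximum body intensity, the field must be divided
out before thresholding or dim-coil fat drops below the cut.  The
correction here is homomorphic: the field is estimated by heavy low-pass
filtering of the log intensity restricted to a rough body support, then
divided out and the body-mean intensity restored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes, gaussian_filter

from .image import AbdominalImage, Modality

CT_FAT_WINDOW = (-190.0, -45.0)  # HU, inclusive
MR_FRACTION = 0.5
MR_ROBUST_PERCENTILE = 99.5
BIAS_SMOOTHING_MM = 60.0


@dataclass(frozen=True)
class ThresholdSpec:
    """Fat-classification window for one modality.

    CT uses an absolute Hounsfield window (default -190..-45 HU,
    inclusive on both ends).  MR uses a single lower threshold at a
    fraction (default 0.5) of the robust maximum intensity inside the
    body, with no upper bound.
    """

    modality: Modality
    lower: float
    upper: float = np.inf
    basis: str = "absolute_HU"  # or "fraction_of_max"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"lower ({self.lower}) must be < upper ({self.upper})")
        if self.basis not in ("absolute_HU", "fraction_of_max"):
            raise ValueError(f"unknown basis {self.basis!r}")

    @classmethod
    def ct_default(cls) -> "ThresholdSpec":
        return cls(Modality.CT, CT_FAT_WINDOW[0], CT_FAT_WINDOW[1], "absolute_HU")

    @classmethod
    def mr_default(cls, fraction: float = MR_FRACTION) -> "ThresholdSpec":
        return cls(Modality.MR, fraction, np.inf, "fraction_of_max")

    def resolve(self, image: AbdominalImage, body_mask: np.ndarray | None = None) -> tuple[float, float]:
        """Absolute (lower, upper) bounds for this image."""
        if self.basis == "absolute_HU":
            return (self.lower, self.upper)
        if body_mask is None:
            raise ValueError("fraction_of_max threshold needs a body mask")
        thr = mr_fat_threshold(image, body_mask, fraction=self.lower)
        return (thr, self.upper)


def rough_body_support(pixels: np.ndarray, modality: Modality) -> np.ndarray:
    """Coarse foreground support (body outline) for mean-preservation."""
    if modality is Modality.CT:
        mask = pixels > -500.0
    else:
        finite = pixels[np.isfinite(pixels)]
        mask = pixels > 0.1 * np.percentile(finite, 99.5)
    return binary_fill_holes(mask)


FAT_SUPPORT_FRACTION = 0.3


def _fat_support(pixels: np.ndarray) -> np.ndarray:
    """Fat-dominant pixels used to estimate the bias field.

    On fat-only Dixon images the fat signal is an order of magnitude above
    water-dominant tissue, so pixels above ~30% of the robust maximum are
    fat even under strong shading (a 0.3-amplitude field leaves fat above
    0.7x its nominal signal).  Restricting the field estimate to these
    pixels keeps anatomy (bright subcutaneous ring around a dim visceral
    interior) out of the estimated field: over fat, log intensity equals a
    constant plus the log field.
    """
    finite = pixels[np.isfinite(pixels)]
    return pixels > FAT_SUPPORT_FRACTION * np.percentile(finite, MR_ROBUST_PERCENTILE)


def correct_bias_field(
    image: AbdominalImage, smoothing_scale_mm: float = BIAS_SMOOTHING_MM
) -> AbdominalImage:
    """Divide out a smooth multiplicative inhomogeneity field (MR only).

    The field is exp(lowpass(log I)) computed with normalised (mask-
    weighted) Gaussian convolution over the fat-dominant support, where
    the log intensity is the log field plus a constant; normalised
    convolution extrapolates the smooth field into fat-free regions.
    The output is rescaled to preserve the mean intensity over the body,
    making the operation idempotent up to residual low-frequency content.
    """
    if image.modality is not Modality.MR:
        raise ValueError("bias-field correction applies to MR images only")
    if image.bias_corrected:
        raise ValueError("image is already bias-corrected")
    if smoothing_scale_mm <= 0:
        raise ValueError("smoothing_scale_mm must be positive")

    pixels = image.pixels
    support = _fat_support(pixels)
    if not support.any():
        raise ValueError("empty fat support; cannot estimate bias field")

    sigma_px = (
        smoothing_scale_mm / image.pixel_spacing[0],
        smoothing_scale_mm / image.pixel_spacing[1],
    )
    floor = max(1e-6, 1e-6 * float(np.max(pixels)))
    log_img = np.log(np.maximum(pixels, floor))

    w = support.astype(float)
    num = gaussian_filter(log_img * w, sigma_px, mode="nearest")
    den = gaussian_filter(w, sigma_px, mode="nearest")
    smooth_log = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
    # field normalised to unit geometric mean over the support
    field = np.exp(smooth_log - smooth_log[support].mean())
    field = np.clip(field, 0.1, 10.0)

    corrected = pixels / field
    mean_before = pixels[support].mean()
    mean_after = corrected[support].mean()
    if mean_after > 0:
        corrected *= mean_before / mean_after
    corrected = np.clip(corrected, 0.0, None)
    return image.with_pixels(corrected, bias_corrected=True)


def mr_fat_threshold(
    image: AbdominalImage,
    body_mask: np.ndarray,
    fraction: float = MR_FRACTION,
    robust_percentile: float = MR_ROBUST_PERCENTILE,
) -> float:
    """Fat threshold as a fraction of the robust maximum body intensity.

    The robust maximum is a high percentile (default 99.5) of the
    intensities inside the body mask, so isolated hot pixels cannot
    inflate the threshold.
    """
    if image.modality is not Modality.MR:
        raise ValueError("mr_fat_threshold applies to MR images only")
    body_mask = np.asarray(body_mask, dtype=bool)
    if not body_mask.any():
        raise ValueError("empty body mask")
    robust_max = float(np.percentile(image.pixels[body_mask], robust_percentile))
    thr = fraction * robust_max
    if thr <= 0:
        raise ValueError(f"non-positive threshold {thr}; image appears empty")
    return thr
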