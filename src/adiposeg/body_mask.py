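"""External body-mask extraction by thresholding, region growing and cleanup.

The body mask is the filled outline of the patient cross-section: CT
pixels above -190 HU (everything denser than the fat window's lower
bound) or MR pixels above half the robust maximum intensity, grown from
the image-centre seed, hole-filled, and cleared of the scanner table.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .image import AbdominalImage, Modality
from . import preprocess

MIN_FOREGROUND_FRAC = 0.01
DEFAULT_EROSION_MM = 8.0
_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity


class MaskKind(str, Enum):
    OUTER_BODY = "outer_body"
    INNER_SEED = "inner_seed"


@dataclass
class BodyMask:
    mask: np.ndarray
    kind: MaskKind

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.kind = MaskKind(self.kind)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def _remove_table_components(labels: np.ndarray, n: int) -> np.ndarray:
    """Drop components that touch the bottom border and are small.

    The CT couch is the common contaminant: it appears as a thin structure
    along the inferior image border, far smaller than the body.
    """
    if n <= 1:
        return labels
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    largest = sizes.max()
    bottom = np.unique(labels[-1, :])
    keep = np.ones(n + 1, dtype=bool)
    for lab in bottom:
        if lab > 0 and sizes[lab - 1] < 0.2 * largest:
            keep[lab] = False
    out = labels.copy()
    out[~keep[labels]] = 0
    return out


def compute_body_mask(
    image: AbdominalImage,
    min_foreground_frac: float = MIN_FOREGROUND_FRAC,
) -> BodyMask:
    """Extract the single filled body component of an axial slice.

    CT: foreground = pixels > -190 HU.  MR: foreground = pixels above
    50% of the robust maximum (the image must be bias-corrected first,
    otherwise shaded fat falls below the cut).  The component containing
    the image centre is kept (largest component as fallback), holes such
    as bowel gas are filled, and table artefacts are removed.
    """
    pixels = image.pixels
    if image.modality is Modality.CT:
        fg = pixels > preprocess.CT_FAT_WINDOW[0]
    else:
        if not image.bias_corrected:
            raise ValueError("MR image must be bias-corrected before body masking")
        finite = pixels[np.isfinite(pixels)]
        robust_max = np.percentile(finite, preprocess.MR_ROBUST_PERCENTILE)
        fg = pixels > preprocess.MR_FRACTION * robust_max

    if fg.sum() < min_foreground_frac * fg.size:
        raise ValueError(
            f"foreground covers {fg.mean():.2%} of the image "
            f"(< {min_foreground_frac:.0%}); no body in the field of view"
        )

    labels, n = ndimage.label(fg, structure=_STRUCT8)
    labels = _remove_table_components(labels, n)

    # Fill before seeding: on fat-only MR the foreground is just the fat,
    # so the raw component under the centre seed may be a single visceral
    # blob; filling merges the subcutaneous ring with everything inside it.
    filled = ndimage.binary_fill_holes(labels > 0)
    flabels, fn = ndimage.label(filled, structure=_STRUCT8)
    if fn == 0:
        raise ValueError("no foreground component remains after cleanup")
    centre = (fg.shape[0] // 2, fg.shape[1] // 2)
    seed_label = flabels[centre]
    if seed_label == 0:
        sizes = np.bincount(flabels.ravel())
        sizes[0] = 0
        seed_label = int(sizes.argmax())

    body = ndimage.binary_fill_holes(flabels == seed_label)
    return BodyMask(mask=body, kind=MaskKind.OUTER_BODY)


def inner_seed_mask(
    body: BodyMask,
    erosion_mm: float = DEFAULT_EROSION_MM,
    pixel_spacing: tuple[float, float] | None = None,
) -> BodyMask:
    """Erode the body mask by a physical margin to seed the inner stage."""
    if body.kind is not MaskKind.OUTER_BODY:
        raise ValueError("inner_seed_mask expects an outer_body mask")
    if erosion_mm < 0:
        raise ValueError("erosion_mm must be >= 0")
    if erosion_mm == 0:
        return BodyMask(mask=body.mask.copy(), kind=MaskKind.INNER_SEED)
    if pixel_spacing is None:
        raise ValueError("pixel_spacing is required for a physical erosion margin")

    r_px = max(int(round(erosion_mm / pixel_spacing[0])), 1)
    c_px = max(int(round(erosion_mm / pixel_spacing[1])), 1)
    rr, cc = np.mgrid[-r_px : r_px + 1, -c_px : c_px + 1]
    selem = (rr / r_px) ** 2 + (cc / c_px) ** 2 <= 1.0
    eroded = ndimage.binary_erosion(body.mask, structure=selem)
    if not eroded.any():
        raise ValueError(f"erosion by {erosion_mm} mm empties the mask")
    return BodyMask(mask=eroded, kind=MaskKind.INNER_SEED)
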