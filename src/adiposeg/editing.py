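"""Programmatic result correction: false-positive removal and contour edits.

In clinical use the automatic result is reviewed and corrected by a
reader — typically to remove fat inside the spinal canal and neural
foramina, intramuscular fat in the paravertebral muscles, and (CT)
intracolonic contents.  This module expresses those corrections as
data: an exclusion mask clears fat pixels (removal-only — editing can
never add fat), and a replacement contour triggers re-partition of the
classified fat.  `auto_exclude_spine` proposes, but never applies, an
exclusion for the common spine-region false positives.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from . import geometry
from .fat_quant import FatMasks, partition_sat_vat
from .image import AbdominalImage, Modality
from .snake import Contour, WallContours

BONE_HU = 150.0
MAX_ISLET_CM2 = 0.3


def remove_fp_regions(masks: FatMasks, exclusion: np.ndarray) -> FatMasks:
    """Clear SAT/VAT pixels under the exclusion mask; never adds pixels."""
    exclusion = np.asarray(exclusion, dtype=bool)
    if exclusion.shape != masks.sat.shape:
        raise ValueError("exclusion grid does not match the mask grid")
    return FatMasks(sat=masks.sat & ~exclusion, vat=masks.vat & ~exclusion)


def auto_exclude_spine(
    image: AbdominalImage,
    masks: FatMasks,
    max_islet_cm2: float = MAX_ISLET_CM2,
    bone_hu: float = BONE_HU,
) -> np.ndarray:
    """Propose an exclusion mask for spine-region false-positive fat.

    Flags small connected fat components (area below `max_islet_cm2`)
    that are enclosed by bone (CT: dilated border mostly above
    `bone_hu`) or, as the modality-agnostic fallback, lie in the
    posterior midline box where the spinal canal sits.  Large components
    are never flagged, so genuine visceral fat depots survive.  The
    proposal is advisory: callers decide whether to apply it with
    `remove_fp_regions`.
    """
    fat = masks.sat | masks.vat
    px_cm2 = image.pixel_area_cm2
    labels, n = ndimage.label(fat, structure=np.ones((3, 3), dtype=bool))
    proposal = np.zeros_like(fat)
    if n == 0:
        return proposal

    rows, cols = fat.shape
    # posterior midline box: central fifth of columns, posterior 45% of rows
    box = np.zeros_like(fat)
    box[int(0.55 * rows) :, int(0.4 * cols) : int(0.6 * cols)] = True

    objects = ndimage.find_objects(labels)
    for lab, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        comp = labels[slc] == lab
        area_cm2 = comp.sum() * px_cm2
        if area_cm2 > max_islet_cm2:
            continue
        grown = np.zeros_like(fat)
        grown[slc] = comp
        border = ndimage.binary_dilation(grown, iterations=2) & ~grown
        flagged = False
        if image.modality is Modality.CT and border.any():
            flagged = np.mean(image.pixels[border] > bone_hu) >= 0.5
        if not flagged:
            flagged = (grown & box).sum() >= 0.5 * grown.sum()
        if flagged:
            proposal |= grown
    return proposal


def replace_contour(
    contours: WallContours,
    which: str,
    new_points: Contour,
    image: AbdominalImage,
    fat: np.ndarray,
) -> tuple[WallContours, FatMasks]:
    """Swap one wall contour and re-partition the classified fat pixels."""
    if which not in ("outer", "inner"):
        raise ValueError(f"which must be 'outer' or 'inner', got {which!r}")
    if which == "outer":
        edited = WallContours(outer=new_points, inner=contours.inner)
    else:
        edited = WallContours(outer=contours.outer, inner=new_points)
    masks = partition_sat_vat(np.asarray(fat, dtype=bool), edited)
    return edited, masks


def exclusion_from_rle(rle: list[list[int]], shape: tuple[int, int]) -> np.ndarray:
    """Decode an exclusion mask from (row, col_start, col_stop) runs."""
    mask = np.zeros(shape, dtype=bool)
    for row, start, stop in rle:
        mask[row, start:stop] = True
    return mask


def rle_from_exclusion(mask: np.ndarray) -> list[list[int]]:
    """Encode an exclusion mask as (row, col_start, col_stop) runs."""
    mask = np.asarray(mask, dtype=bool)
    runs = []
    for row in range(mask.shape[0]):
        line = mask[row]
        diffs = np.flatnonzero(np.diff(np.concatenate([[0], line.view(np.int8), [0]])))
        for start, stop in zip(diffs[::2], diffs[1::2]):
            runs.append([int(row), int(start), int(stop)])
    return runs
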