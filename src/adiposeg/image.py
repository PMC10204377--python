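"""Core in-memory containers for single axial abdominal slices.

Intensities are kept on the physically meaningful scale for each modality:
Hounsfield units for CT (air near -1000 HU, fat near -100 HU) and arbitrary
units for fat-only Dixon MR (non-negative, fat bright).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np


class Modality(str, Enum):
    CT = "CT"
    MR = "MR"


@dataclass
class AbdominalImage:
    """One axial slice with calibrated intensities and pixel spacing.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols)
        HU for CT; arbitrary non-negative units for fat-only Dixon MR.
    modality : Modality
    pixel_spacing : (row_mm, col_mm)
        Physical size of one pixel; both components strictly positive.
    source_id : str
        Opaque identifier carried through to results.
    bias_corrected : bool
        MR only; True after the B1 inhomogeneity field has been divided out.
    """

    pixels: np.ndarray
    modality: Modality
    pixel_spacing: tuple[float, float]
    source_id: str = ""
    bias_corrected: bool = field(default=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        self.modality = Modality(self.modality)
        rs, cs = self.pixel_spacing
        if not (rs > 0 and cs > 0):
            raise ValueError(f"pixel_spacing must be strictly positive, got {self.pixel_spacing}")
        self.pixel_spacing = (float(rs), float(cs))
        if self.modality is Modality.MR and self.pixels.min() < 0:
            raise ValueError("MR pixels must be non-negative")
        if self.modality is Modality.CT and self.bias_corrected:
            raise ValueError("bias_corrected applies to MR images only")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area_cm2(self) -> float:
        """Area of one pixel in cm^2."""
        return self.pixel_spacing[0] * self.pixel_spacing[1] / 100.0

    def with_pixels(self, pixels: np.ndarray, **changes) -> "AbdominalImage":
        return replace(self, pixels=pixels, **changes)
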