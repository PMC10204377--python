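"""Fat-pixel classification, SAT/VAT partition and area quantification.

SAT is the adipose tissue between the skin (outer contour) and the
inner abdominal wall (inner contour); VAT is the adipose tissue inside
the inner contour.  Classification is a Hounsfield window on CT
(-190..-45 HU, inclusive) and a fraction-of-max threshold on
bias-corrected fat-only Dixon MR.  Pixel membership relative to a
contour uses a pixel-centre point-in-polygon test with on-edge points
counting as inside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry
from .body_mask import BodyMask, compute_body_mask
from .image import AbdominalImage, Modality
from .preprocess import ThresholdSpec, correct_bias_field
from .snake import (
    DEFAULT_INNER_PARAMS,
    DEFAULT_OUTER_PARAMS,
    SnakeParams,
    WallContours,
    detect_inner_contour,
    detect_outer_contour,
)


@dataclass
class FatMasks:
    """Disjoint binary SAT and VAT masks on the image grid."""

    sat: np.ndarray
    vat: np.ndarray

    def __post_init__(self) -> None:
        self.sat = np.asarray(self.sat, dtype=bool)
        self.vat = np.asarray(self.vat, dtype=bool)
        if self.sat.shape != self.vat.shape:
            raise ValueError("sat and vat masks must share a grid")
        if (self.sat & self.vat).any():
            raise ValueError("sat and vat masks overlap")


@dataclass
class QuantResult:
    """Per-slice areas in cm^2."""

    outer_area_cm2: float
    inner_area_cm2: float
    sat_area_cm2: float
    vat_area_cm2: float
    modality: Modality
    source_id: str = ""

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        for name in ("outer_area_cm2", "inner_area_cm2", "sat_area_cm2", "vat_area_cm2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.inner_area_cm2 > self.outer_area_cm2:
            raise ValueError("inner area cannot exceed outer area")
        if self.vat_area_cm2 > self.inner_area_cm2:
            raise ValueError("VAT area cannot exceed the inner region area")

    def to_dict(self) -> dict:
        return {
            "source_id": self.source_id,
            "modality": self.modality.value,
            "outer_cm2": round(self.outer_area_cm2, 2),
            "inner_cm2": round(self.inner_area_cm2, 2),
            "sat_cm2": round(self.sat_area_cm2, 2),
            "vat_cm2": round(self.vat_area_cm2, 2),
        }


class StageError(RuntimeError):
    """Pipeline failure annotated with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.__cause__ = cause


def classify_fat(
    image: AbdominalImage,
    threshold_spec: ThresholdSpec,
    body: BodyMask,
) -> np.ndarray:
    """Binary fat mask inside the body: window (CT) or threshold (MR)."""
    if threshold_spec.modality is not image.modality:
        raise ValueError(
            f"threshold spec is for {threshold_spec.modality.value}, "
            f"image is {image.modality.value}"
        )
    if image.modality is Modality.MR and not image.bias_corrected:
        raise ValueError("MR image must be bias-corrected before fat classification")
    lo, hi = threshold_spec.resolve(image, body.mask)
    fat = (image.pixels >= lo) & (image.pixels <= hi)
    return fat & body.mask


def partition_sat_vat(fat: np.ndarray, contours: WallContours) -> FatMasks:
    """Split fat pixels into SAT (between contours) and VAT (inside inner).

    Fat outside the outer contour (skin-surface partial volume) is
    discarded so SAT never exceeds the annulus between the contours.
    """
    fat = np.asarray(fat, dtype=bool)
    inside_outer = geometry.polygon_mask(contours.outer.points, fat.shape)
    inside_inner = geometry.polygon_mask(contours.inner.points, fat.shape)
    if (inside_inner & ~inside_outer).any():
        raise ValueError("inner region is not contained in the outer region")
    sat = fat & inside_outer & ~inside_inner
    vat = fat & inside_inner
    return FatMasks(sat=sat, vat=vat)


def compute_areas(
    masks: FatMasks,
    contours: WallContours,
    pixel_spacing: tuple[float, float],
    modality: Modality | str = Modality.CT,
    source_id: str = "",
) -> QuantResult:
    """Areas in cm^2: pixel counts for masks, shoelace for contours."""
    px_cm2 = pixel_spacing[0] * pixel_spacing[1] / 100.0
    mm2_per_px2 = pixel_spacing[0] * pixel_spacing[1]
    return QuantResult(
        outer_area_cm2=contours.outer.area_px2() * mm2_per_px2 / 100.0,
        inner_area_cm2=contours.inner.area_px2() * mm2_per_px2 / 100.0,
        sat_area_cm2=float(masks.sat.sum()) * px_cm2,
        vat_area_cm2=float(masks.vat.sum()) * px_cm2,
        modality=modality,
        source_id=source_id,
    )


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end configuration; defaults reproduce the standard pipeline."""

    outer_params: SnakeParams = DEFAULT_OUTER_PARAMS
    inner_params: SnakeParams = DEFAULT_INNER_PARAMS
    mr_fraction: float = 0.5
    bias_smoothing_mm: float = 60.0
    ct_window: tuple[float, float] = (-190.0, -45.0)


def quantify_slice(
    image: AbdominalImage,
    config: PipelineConfig | None = None,
) -> tuple[WallContours, FatMasks, QuantResult]:
    """Full single-slice pipeline, deterministic end to end.

    MR: bias correct -> body mask -> outer snake -> inner snake ->
    classify fat -> partition -> areas.  CT skips the bias step.
    Each stage's failure is re-raised tagged with the stage name.
    """
    cfg = config or PipelineConfig()

    if image.modality is Modality.MR and not image.bias_corrected:
        try:
            image = correct_bias_field(image, cfg.bias_smoothing_mm)
        except Exception as e:  # noqa: BLE001 - stage tagging
            raise StageError("bias_correction", e) from e

    try:
        body = compute_body_mask(image)
    except Exception as e:
        raise StageError("body_mask", e) from e

    if image.modality is Modality.CT:
        spec = ThresholdSpec(Modality.CT, cfg.ct_window[0], cfg.ct_window[1], "absolute_HU")
    else:
        spec = ThresholdSpec.mr_default(cfg.mr_fraction)

    try:
        outer = detect_outer_contour(image, body, cfg.outer_params)
    except Exception as e:
        raise StageError("outer_contour", e) from e

    try:
        inner = detect_inner_contour(
            image, outer, cfg.inner_params, body=body, threshold_spec=spec
        )
        contours = WallContours(outer=outer, inner=inner)
    except Exception as e:
        raise StageError("inner_contour", e) from e

    try:
        fat = classify_fat(image, spec, body)
        masks = partition_sat_vat(fat, contours)
        result = compute_areas(
            masks, contours, image.pixel_spacing, image.modality, image.source_id
        )
    except Exception as e:
        raise StageError("fat_quantification", e) from e

    return contours, masks, result
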