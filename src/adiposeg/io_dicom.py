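"""DICOM ingestion and result export.

Reads single-frame CT or MR slices into calibrated `AbdominalImage`s
(CT rescale slope/intercept applied so air sits near -1000 HU), writes
segmentation overlays as RGB secondary-capture DICOM, and serialises
area results to CSV/JSON.
"""

from __future__ import annotations

import csv
import datetime
import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import (
    ExplicitVRLittleEndian,
    SecondaryCaptureImageStorage,
    CTImageStorage,
    MRImageStorage,
    generate_uid,
)
from skimage.draw import polygon_perimeter

from .fat_quant import FatMasks, QuantResult
from .image import AbdominalImage, Modality
from .snake import WallContours

# Figure-style colour convention for burned-in overlays (RGB)
COLOR_OUTER = (0, 255, 0)  # green
COLOR_INNER = (255, 0, 0)  # red
COLOR_SAT = (255, 0, 255)  # magenta
COLOR_VAT = (0, 255, 255)  # cyan

CT_DISPLAY_WINDOW = (-190.0, 200.0)  # HU, for the grayscale base image only

CSV_COLUMNS = ["source_id", "modality", "outer_cm2", "inner_cm2", "sat_cm2", "vat_cm2"]


def read_slice(path: str | Path) -> AbdominalImage:
    """Read one single-frame CT or MR DICOM slice.

    CT stored values are mapped through RescaleSlope/RescaleIntercept to
    Hounsfield units.  Pixel spacing is mandatory: without it the areas
    downstream would be meaningless.
    """
    ds = pydicom.dcmread(str(path))
    modality_str = getattr(ds, "Modality", None)
    if modality_str not in ("CT", "MR"):
        raise ValueError(f"unsupported modality {modality_str!r}; expected CT or MR")
    modality = Modality(modality_str)

    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None or len(spacing) != 2:
        raise ValueError(f"{path}: PixelSpacing is missing; areas would be meaningless")

    pixels = ds.pixel_array.astype(float)
    if pixels.ndim != 2:
        raise ValueError("only single-frame 2-D slices are supported")
    if modality is Modality.CT:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        pixels = pixels * slope + intercept
    else:
        pixels = np.clip(pixels, 0.0, None)

    return AbdominalImage(
        pixels=pixels,
        modality=modality,
        pixel_spacing=(float(spacing[0]), float(spacing[1])),
        # PatientID pairs the CT and MR acquisitions of one subject/slice;
        # fall back to the unique instance UID when it is absent
        source_id=str(getattr(ds, "PatientID", "") or getattr(ds, "SOPInstanceUID", path)),
    )


def _base_file_meta(sop_class_uid) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class_uid
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _common_tags(ds: Dataset, image: AbdominalImage) -> None:
    now = datetime.datetime.now()
    ds.ContentDate = now.strftime("%Y%m%d")
    ds.ContentTime = now.strftime("%H%M%S")
    ds.PatientName = "PHANTOM"
    ds.PatientID = image.source_id or "UNKNOWN"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.PixelSpacing = [str(image.pixel_spacing[0]), str(image.pixel_spacing[1])]
    ds.Rows, ds.Columns = image.shape


def write_slice(image: AbdominalImage, path: str | Path) -> None:
    """Write an AbdominalImage as a plain single-frame DICOM slice.

    CT is stored as uint16 with slope 1 / intercept -1024 (the standard
    representation); MR as uint16 raw intensities.
    """
    sop_class = CTImageStorage if image.modality is Modality.CT else MRImageStorage
    ds = Dataset()
    ds.file_meta = _base_file_meta(sop_class)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.Modality = image.modality.value
    _common_tags(ds, image)

    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    if image.modality is Modality.CT:
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = "-1024"
        stored = np.clip(np.rint(image.pixels + 1024.0), 0, 65535).astype(np.uint16)
    else:
        stored = np.clip(np.rint(image.pixels), 0, 65535).astype(np.uint16)
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def _windowed_grayscale(image: AbdominalImage) -> np.ndarray:
    """8-bit grayscale base for the overlay; display-only windowing."""
    if image.modality is Modality.CT:
        lo, hi = CT_DISPLAY_WINDOW
    else:
        lo, hi = 0.0, max(float(image.pixels.max()), 1e-9)
    scaled = (np.clip(image.pixels, lo, hi) - lo) / (hi - lo)
    return np.rint(scaled * 255.0).astype(np.uint8)


def _burn_contour(rgb: np.ndarray, points: np.ndarray, color: tuple[int, int, int]) -> None:
    rows = np.clip(np.rint(points[:, 0]).astype(int), 0, rgb.shape[0] - 1)
    cols = np.clip(np.rint(points[:, 1]).astype(int), 0, rgb.shape[1] - 1)
    rr, cc = polygon_perimeter(rows, cols, shape=rgb.shape[:2], clip=True)
    rgb[rr, cc] = color


def render_overlay(
    image: AbdominalImage, contours: WallContours, masks: FatMasks
) -> np.ndarray:
    """RGB overlay: SAT magenta, VAT cyan, outer contour green, inner red.

    Contours are burned last so they win over mask colour at shared pixels.
    """
    if masks.sat.shape != image.shape:
        raise ValueError("mask grid does not match the image grid")
    gray = _windowed_grayscale(image)
    rgb = np.stack([gray] * 3, axis=-1)
    rgb[masks.sat] = COLOR_SAT
    rgb[masks.vat] = COLOR_VAT
    _burn_contour(rgb, contours.outer.points, COLOR_OUTER)
    _burn_contour(rgb, contours.inner.points, COLOR_INNER)
    return rgb


def write_secondary_capture(
    image: AbdominalImage,
    contours: WallContours,
    masks: FatMasks,
    path: str | Path,
) -> None:
    """Write the rendered overlay as an 8-bit RGB secondary-capture DICOM."""
    rgb = render_overlay(image, contours, masks)

    ds = Dataset()
    ds.file_meta = _base_file_meta(SecondaryCaptureImageStorage)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.ConversionType = "WSD"
    _common_tags(ds, image)
    ds.SeriesDescription = f"{image.modality.value} SAT/VAT segmentation overlay"

    ds.SamplesPerPixel = 3
    ds.PhotometricInterpretation = "RGB"
    ds.PlanarConfiguration = 0
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelData = rgb.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def write_results(results: list[QuantResult], path: str | Path) -> None:
    """Write results as CSV, one row per slice, areas at two decimals."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in results:
            d = r.to_dict()
            writer.writerow([d[c] for c in CSV_COLUMNS])


def read_results(path: str | Path) -> list[QuantResult]:
    """Parse a results CSV written by `write_results`."""
    out: list[QuantResult] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                QuantResult(
                    outer_area_cm2=float(row["outer_cm2"]),
                    inner_area_cm2=float(row["inner_cm2"]),
                    sat_area_cm2=float(row["sat_cm2"]),
                    vat_area_cm2=float(row["vat_cm2"]),
                    modality=row["modality"],
                    source_id=row["source_id"],
                )
            )
    return out


def write_result_json(result: QuantResult, path: str | Path, params_digest: str = "") -> None:
    d = result.to_dict()
    d["params_digest"] = params_digest
    Path(path).write_text(json.dumps(d, indent=2) + "\n")
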