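"""Fat classification, SAT/VAT partition and area computation."""

import numpy as np
import pytest

from adiposeg import (
    AbdominalImage,
    Contour,
    Modality,
    ThresholdSpec,
    WallContours,
    classify_fat,
    compute_areas,
    partition_sat_vat,
    quantify_slice,
)
from adiposeg.body_mask import BodyMask, MaskKind
from adiposeg.fat_quant import FatMasks
from adiposeg import geometry


def _square_contour(r0, c0, r1, c1, n=32) -> Contour:
    corners = np.array([[r0, c0], [r0, c1], [r1, c1], [r1, c0]], float)
    return Contour(geometry.resample_closed(corners, n))


def _brute_force_inside(point, polygon) -> bool:
    """Ray-casting oracle, written independently of the geometry module."""
    r, c = point
    crossings = 0
    n = len(polygon)
    for i in range(n):
        r1, c1 = polygon[i]
        r2, c2 = polygon[(i + 1) % n]
        if (r1 > r) != (r2 > r):
            c_at = c1 + (r - r1) * (c2 - c1) / (r2 - r1)
            if c_at > c:
                crossings += 1
    return crossings % 2 == 1


class TestClassifyFat:
    def _ct(self, pixels):
        return AbdominalImage(np.asarray(pixels, float), Modality.CT, (1.0, 1.0))

    @pytest.mark.parametrize(
        "hu,expected",
        [(-190.0, True), (-191.0, False), (-45.0, True), (-44.0, False), (-100.0, True)],
    )
    def test_ct_window_boundaries_inclusive(self, hu, expected):
        pixels = np.full((8, 8), hu)
        body = BodyMask(np.ones((8, 8), bool), MaskKind.OUTER_BODY)
        fat = classify_fat(self._ct(pixels), ThresholdSpec.ct_default(), body)
        assert bool(fat[4, 4]) is expected

    def test_ct_phantom_fat_mask_exact_without_noise(self):
        pixels = np.full((32, 32), 50.0)
        pixels[8:16, 8:24] = -100.0
        body = BodyMask(np.ones((32, 32), bool), MaskKind.OUTER_BODY)
        fat = classify_fat(self._ct(pixels), ThresholdSpec.ct_default(), body)
        assert (fat == (pixels == -100.0)).all()

    def test_mr_threshold_classification(self):
        pixels = np.full((32, 32), 150.0)
        pixels[4:12, 4:12] = 1000.0
        image = AbdominalImage(pixels, Modality.MR, (1.0, 1.0), bias_corrected=True)
        body = BodyMask(np.ones((32, 32), bool), MaskKind.OUTER_BODY)
        fat = classify_fat(image, ThresholdSpec.mr_default(), body)
        assert (fat == (pixels == 1000.0)).all()

    def test_modality_mismatch_rejected(self):
        image = self._ct(np.zeros((8, 8)))
        body = BodyMask(np.ones((8, 8), bool), MaskKind.OUTER_BODY)
        with pytest.raises(ValueError, match="MR"):
            classify_fat(image, ThresholdSpec.mr_default(), body)

    def test_narrowing_window_never_adds_fat(self, ct_phantom):
        image, _ = ct_phantom
        from adiposeg import compute_body_mask

        body = compute_body_mask(image)
        wide = classify_fat(image, ThresholdSpec(Modality.CT, -190, -45), body)
        narrow = classify_fat(image, ThresholdSpec(Modality.CT, -190, -50), body)
        assert not (narrow & ~wide).any()
        assert narrow.sum() <= wide.sum()


class TestPartition:
    def test_empty_fat_gives_empty_masks(self):
        contours = WallContours(
            outer=_square_contour(5, 5, 55, 55), inner=_square_contour(20, 20, 40, 40)
        )
        masks = partition_sat_vat(np.zeros((64, 64), bool), contours)
        assert masks.sat.sum() == 0 and masks.vat.sum() == 0

    def test_ring_between_contours_is_sat_only(self):
        contours = WallContours(
            outer=_square_contour(5, 5, 55, 55), inner=_square_contour(25, 25, 35, 35)
        )
        fat = np.zeros((64, 64), bool)
        fat[10:20, 10:50] = True  # strip inside outer, outside inner
        masks = partition_sat_vat(fat, contours)
        assert masks.sat.sum() == fat.sum()
        assert masks.vat.sum() == 0

    def test_fat_outside_outer_is_discarded(self):
        contours = WallContours(
            outer=_square_contour(20, 20, 44, 44), inner=_square_contour(28, 28, 36, 36)
        )
        fat = np.ones((64, 64), bool)
        masks = partition_sat_vat(fat, contours)
        outside = ~geometry.polygon_mask(contours.outer.points, fat.shape)
        assert not (masks.sat & outside).any() and not (masks.vat & outside).any()

    def test_straddling_blob_split_matches_ray_casting_oracle(self):
        rng = np.random.default_rng(4)
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        inner_poly = np.column_stack(
            [32 + (10 + rng.uniform(-2, 2, 40)) * np.sin(t),
             32 + (12 + rng.uniform(-2, 2, 40)) * np.cos(t)]
        )
        contours = WallContours(
            outer=_square_contour(2, 2, 61, 61), inner=Contour(inner_poly)
        )
        fat = np.zeros((64, 64), bool)
        fat[22:42, 28:48] = True  # blob straddling the inner boundary
        masks = partition_sat_vat(fat, contours)
        for r in range(22, 42):
            for c in range(28, 48):
                inside = _brute_force_inside((r, c), contours.inner.points)
                if masks.vat[r, c]:
                    assert inside or _on_edge((r, c), contours.inner.points)
                else:
                    assert not inside or _on_edge((r, c), contours.inner.points)

    def test_no_double_counting(self, ct_phantom):
        image, _ = ct_phantom
        contours, masks, _ = quantify_slice(image)
        assert not (masks.sat & masks.vat).any()


def _on_edge(point, polygon, tol=1e-9) -> bool:
    """Within tol of a polygon edge (boundary convention differences)."""
    p = np.asarray(point, float)
    n = len(polygon)
    for i in range(n):
        a = polygon[i]
        b = polygon[(i + 1) % n]
        ab = b - a
        denom = ab @ ab
        tproj = 0.0 if denom == 0 else np.clip((p - a) @ ab / denom, 0, 1)
        if np.linalg.norm(a + tproj * ab - p) < tol:
            return True
    return False


class TestComputeAreas:
    def test_unit_spacing_identity(self):
        contours = WallContours(
            outer=_square_contour(0, 0, 60, 60), inner=_square_contour(20, 20, 40, 40)
        )
        sat = np.zeros((64, 64), bool)
        sat[50:52, 0:50] = True  # 100 pixels at 1 x 1 mm
        result = compute_areas(FatMasks(sat=sat, vat=np.zeros_like(sat)), contours, (1.0, 1.0))
        assert result.sat_area_cm2 == pytest.approx(1.0)

    def test_clinical_spacing_arithmetic(self):
        contours = WallContours(
            outer=_square_contour(0, 0, 60, 60), inner=_square_contour(20, 20, 40, 40)
        )
        sat = np.zeros((64, 64), bool)
        sat[45:55, 0:10] = True  # 100 pixels
        result = compute_areas(
            FatMasks(sat=sat, vat=np.zeros_like(sat)), contours, (1.40625, 1.40625)
        )
        assert result.sat_area_cm2 == pytest.approx(1.9775, abs=1e-4)

    def test_square_contour_shoelace(self):
        contours = WallContours(
            outer=_square_contour(0, 0, 100, 100), inner=_square_contour(40, 40, 60, 60)
        )
        empty = FatMasks(sat=np.zeros((128, 128), bool), vat=np.zeros((128, 128), bool))
        result = compute_areas(empty, contours, (1.0, 1.0))
        assert result.outer_area_cm2 == pytest.approx(100.0)


class TestQuantifySlice:
    def test_zero_visceral_fat_gives_zero_vat(self):
        from adiposeg import PhantomSpec, generate_phantom

        spec = PhantomSpec(visceral_blobs=[], spine_confounder=False, seed=8)
        image, truth = generate_phantom(spec, Modality.CT)
        _, _, result = quantify_slice(image)
        assert result.vat_area_cm2 <= 2 * image.pixel_area_cm2

    def test_end_to_end_bit_identical_reruns(self, mr_phantom):
        image, _ = mr_phantom
        _, masks1, r1 = quantify_slice(image)
        _, masks2, r2 = quantify_slice(image)
        np.testing.assert_array_equal(masks1.sat, masks2.sat)
        np.testing.assert_array_equal(masks1.vat, masks2.vat)
        assert r1.sat_area_cm2 == r2.sat_area_cm2

    def test_stage_errors_are_labeled(self):
        from adiposeg.fat_quant import StageError

        image = AbdominalImage(np.full((64, 64), -1000.0), Modality.CT, (1.0, 1.0))
        with pytest.raises(StageError, match=r"\[body_mask\]"):
            quantify_slice(image)
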