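"""Targeting ratios, well aggregation, confocal metrics, thresholds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ldscreen import quantify as q


@pytest.fixture
def square_cell():
    """A 40x40 cell mask with a 6x6 LD block at its centre."""
    cell = np.zeros((50, 50), bool)
    cell[5:45, 5:45] = True
    ld = np.zeros_like(cell)
    ld[22:28, 22:28] = True
    return cell, ld


class TestAutofluorescence:
    def test_constant_image_goes_to_zero(self):
        img = np.full((8, 8), 37.0)
        assert np.all(q.autofluorescence_correct(img, 37.0) == 0)

    def test_zero_control_is_identity(self):
        img = np.arange(16.0).reshape(4, 4)
        np.testing.assert_array_equal(q.autofluorescence_correct(img, 0.0), img)

    def test_mean_shifts_linearly(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(50, 100, (32, 32))
        out = q.autofluorescence_correct(img, 20.0)
        assert out.mean() == pytest.approx(img.mean() - 20.0)

    def test_negative_control_rejected(self):
        with pytest.raises(ValueError):
            q.autofluorescence_correct(np.zeros((2, 2)), -1.0)


class TestCellRatio:
    def test_uniform_image_gives_one(self, square_cell):
        cell, ld = square_cell
        assert q.cell_targeting_ratio(np.full(cell.shape, 9.0), cell, ld) == pytest.approx(1.0)

    def test_simple_means(self, square_cell):
        cell, ld = square_cell
        img = np.where(ld, 10.0, 2.0)
        assert q.cell_targeting_ratio(img, cell, ld) == pytest.approx(5.0)

    def test_no_ld_pixels_undefined(self, square_cell):
        cell, _ = square_cell
        assert np.isnan(q.cell_targeting_ratio(np.ones(cell.shape), cell,
                                               np.zeros_like(cell)))

    def test_empty_cell_mask_rejected(self):
        with pytest.raises(ValueError):
            q.cell_targeting_ratio(np.ones((4, 4)), np.zeros((4, 4), bool),
                                   np.zeros((4, 4), bool))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, k):
        cell = np.zeros((20, 20), bool)
        cell[2:18, 2:18] = True
        ld = np.zeros_like(cell)
        ld[8:12, 8:12] = True
        img = np.where(ld, 30.0, 6.0) + np.arange(400.0).reshape(20, 20) / 100
        base = q.cell_targeting_ratio(img, cell, ld)
        assert q.cell_targeting_ratio(k * img, cell, ld) == pytest.approx(base, rel=1e-9)

    def test_not_offset_invariant(self, square_cell):
        cell, ld = square_cell
        img = np.where(ld, 10.0, 2.0)
        base = q.cell_targeting_ratio(img, cell, ld)
        shifted = q.cell_targeting_ratio(img + 50.0, cell, ld)
        assert shifted != pytest.approx(base, rel=1e-3)
        assert shifted < base  # offsets compress the ratio toward 1

    def test_monotone_in_ld_intensity(self, square_cell):
        cell, ld = square_cell
        img = np.where(ld, 10.0, 2.0)
        base = q.cell_targeting_ratio(img, cell, ld)
        boosted = q.cell_targeting_ratio(img + 5.0 * ld, cell, ld)
        assert boosted > base


class TestAggregateWell:
    def _rec(self, ratio, field=0, label=1):
        return q.CellRecord(plate=1, well="A01", field=field, cell_label=label,
                            targeting_ratio=ratio, cell_area_px=100,
                            ld_area_px=10, ld_count=2)

    def test_odd_median(self):
        wr = q.aggregate_well([self._rec(r) for r in (1.0, 2.0, 3.0)])
        assert wr.x_i == 2.0 and wr.cell_count == 3

    def test_even_median_is_central_mean(self):
        wr = q.aggregate_well([self._rec(r) for r in (1.0, 2.0, 3.0, 4.0)])
        assert wr.x_i == 2.5

    def test_pooling_over_fields_matches_concatenation(self):
        """Brute-force oracle: medians pool across fields, not per field."""
        rng = np.random.default_rng(3)
        records, pooled = [], []
        for f in range(8):
            vals = rng.uniform(1, 4, 5)
            pooled.extend(vals)
            records += [self._rec(v, field=f, label=i) for i, v in enumerate(vals)]
        wr = q.aggregate_well(records)
        assert wr.x_i == pytest.approx(float(np.median(pooled)), abs=1e-12)
        assert wr.cell_count == 40 and wr.n_cells_with_ratio == 40

    def test_undefined_ratios_counted_but_excluded(self):
        wr = q.aggregate_well([self._rec(2.0), self._rec(float("nan"))])
        assert wr.x_i == 2.0 and wr.cell_count == 2 and wr.n_cells_with_ratio == 1

    def test_all_undefined_flagged(self):
        wr = q.aggregate_well([self._rec(float("nan"))])
        assert not wr.x_i_defined

    def test_mixed_wells_rejected(self):
        a = self._rec(1.0)
        b = q.CellRecord(plate=1, well="B02", field=0, cell_label=1,
                         targeting_ratio=1.0, cell_area_px=10, ld_area_px=1, ld_count=1)
        with pytest.raises(ValueError):
            q.aggregate_well([a, b])


class TestConfocalRatio:
    def _scene(self, k=6, protein_in=10.0, protein_out=2.0):
        mask1 = np.zeros((40, 40), bool)
        mask1[2:38, 2:38] = True
        ld_img = np.zeros((40, 40))
        lo = 20 - k // 2
        ld_img[lo:lo + k, lo:lo + k] = 100.0
        shell = np.zeros_like(ld_img, bool)
        shell[lo - 1:lo + k + 1, lo - 1:lo + k + 1] = True
        protein = np.where(shell, protein_in, protein_out)
        return protein, mask1, ld_img, shell, (lo, k)

    def test_bimodal_construction_gives_five(self):
        protein, mask1, ld_img, _, _ = self._scene()
        assert q.confocal_targeting_ratio(protein, mask1, ld_img) == pytest.approx(5.0)

    def test_uniform_protein_gives_one(self):
        _, mask1, ld_img, _, _ = self._scene()
        assert q.confocal_targeting_ratio(np.full((40, 40), 3.3), mask1,
                                          ld_img) == pytest.approx(1.0)

    def test_dilation_adds_exactly_one_pixel_shell(self):
        """Pixel-counting oracle on a square LD: (k+2)^2 vs k^2 pixels."""
        protein, mask1, ld_img, shell, (lo, k) = self._scene()
        with_dil = q.confocal_targeting_ratio(protein, mask1, ld_img, dilate=True)
        without = q.confocal_targeting_ratio(protein, mask1, ld_img, dilate=False)
        n1 = mask1.sum()
        # with dilation, mask2 is the full shell: ratio is exactly 5
        assert with_dil == pytest.approx(5.0)
        # without, the 10-valued shell ring contaminates the outside mean
        ring = (k + 2) ** 2 - k**2
        mean_out = (ring * 10.0 + (n1 - (k + 2) ** 2) * 2.0) / (n1 - k**2)
        assert without == pytest.approx(10.0 / mean_out)

    def test_nuclear_exclusion(self):
        protein, mask1, ld_img, _, _ = self._scene()
        nucleus = np.zeros_like(mask1)
        nucleus[3:10, 3:10] = True
        protein = protein + 50.0 * nucleus  # bright nucleus would bias the outside mean
        excl = q.confocal_targeting_ratio(protein, mask1, ld_img, exclude_nuclear=nucleus)
        assert excl == pytest.approx(5.0)

    def test_constant_ld_channel_rejected(self):
        _, mask1, _, _, _ = self._scene()
        with pytest.raises(ValueError, match="constant"):
            q.confocal_targeting_ratio(np.ones((40, 40)), mask1, np.ones((40, 40)))


class TestAreaNearLd:
    def test_marker_inside_dilated_ld(self):
        roi = np.ones((30, 30), bool)
        ld = np.zeros((30, 30))
        ld[10:20, 10:20] = 100.0
        marker = np.zeros((30, 30))
        marker[12:18, 12:18] = 50.0
        assert q.area_near_ld_fraction(marker, ld, roi) == pytest.approx(1.0)

    def test_distant_marker_gives_zero(self):
        roi = np.ones((30, 30), bool)
        ld = np.zeros((30, 30))
        ld[2:8, 2:8] = 100.0
        marker = np.zeros((30, 30))
        marker[20:26, 20:26] = 50.0
        assert q.area_near_ld_fraction(marker, ld, roi) == 0.0

    def test_constructed_half_overlap(self):
        """Pixel-counting oracle: half the marker within one pixel of LDs."""
        roi = np.ones((40, 40), bool)
        ld = np.zeros((40, 40))
        ld[10:20, 5:14] = 100.0  # dilated mask covers columns 4..14
        marker = np.zeros((40, 40))
        marker[12:18, 9:29] = 50.0  # 20 columns; 9..14 inside dilation = 6
        frac = q.area_near_ld_fraction(marker, ld, roi)
        assert frac == pytest.approx(6 / 20)


class TestHuang:
    def test_separates_bimodal_values(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(20, 2, 4000), rng.normal(120, 5, 1000)])
        t = q.huang_threshold(vals)
        # the foreground mode (20% of values) is isolated by the cutoff
        assert np.mean(vals > t) == pytest.approx(0.2, abs=0.02)

    def test_matches_itk_reference(self):
        """Independent oracle: ITK's Huang filter on 8-bit histograms."""
        sitk = pytest.importorskip("SimpleITK")
        rng = np.random.default_rng(4)
        cases = [
            np.clip(np.concatenate([rng.normal(60, 10, 4000),
                                    rng.normal(180, 15, 1000)]), 0, 255),
            np.clip(np.concatenate([rng.normal(30, 5, 4500),
                                    rng.normal(200, 10, 500)]), 0, 255),
        ]
        for vals in cases:
            u8 = vals.astype(np.uint8)
            binary = sitk.GetArrayFromImage(
                sitk.HuangThreshold(sitk.GetImageFromArray(u8.reshape(50, -1)), 0, 1, 256))
            itk_threshold = u8.reshape(50, -1)[binary == 0].max()
            assert q.huang_threshold(u8.astype(float)) == pytest.approx(
                float(itk_threshold), abs=3.0)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            q.huang_threshold(np.full(100, 5.0))
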