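"""Color deconvolution, watershed segmentation, compartment measurement,
and the evaluation metrics."""

import numpy as np
import pandas as pd
import pytest

from qcscore.imaging import (
    CYTOPLASM,
    DEFAULT_STAIN_BASIS,
    MEMBRANE,
    NUCLEUS,
    CellSegmentation,
    ODMap,
    deconvolve_dab,
    measure_compartment_od,
    segment_cells,
)
from qcscore.metrics import eval_assd, eval_dice, eval_f1_centers, eval_od_correlation
from qcscore.rendering import ImagingParams, render_cells


def _uniform_rgb(absorbance_dab=0.0, absorbance_hem=0.0, shape=(4, 4)):
    a = absorbance_dab * DEFAULT_STAIN_BASIS[1] + absorbance_hem * DEFAULT_STAIN_BASIS[0]
    pixel = np.clip(np.rint(255 * 10.0 ** (-a)), 0, 255).astype(np.uint8)
    return np.broadcast_to(pixel, (*shape, 3)).copy()


class TestDeconvolveDab:
    def test_white_pixel_zero_od(self):
        od = deconvolve_dab(np.full((2, 2, 3), 255, np.uint8))
        assert np.allclose(od.values, 0.0)

    def test_closed_form_beer_lambert(self):
        # pure DAB with absorbance 0.5 -> 50 working OD units at x100 scale
        rgb = _uniform_rgb(absorbance_dab=0.5)
        od = deconvolve_dab(rgb)
        assert od.values.mean() == pytest.approx(50.0, abs=0.5)

    def test_hematoxylin_does_not_leak_into_dab(self):
        rgb = _uniform_rgb(absorbance_hem=0.6)
        od = deconvolve_dab(rgb)
        assert od.values.max() < 1.0

    def test_monotone_in_dab_concentration(self):
        ods = [deconvolve_dab(_uniform_rgb(a, 0.3)).values.mean() for a in (0.05, 0.2, 0.5, 0.9)]
        assert all(a < b for a, b in zip(ods, ods[1:]))

    def test_saturated_black_clipped(self):
        od = deconvolve_dab(np.zeros((2, 2, 3), np.uint8), max_od=300.0)
        assert od.values.max() <= 300.0

    def test_singular_basis_rejected(self):
        basis = np.array([[0.5, 0.5, 0.5], [0.5, 0.5, 0.5], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError):
            deconvolve_dab(np.full((2, 2, 3), 200, np.uint8), stain_basis=basis)


def _ramp_posteriors(shape=(40, 40), ridge_col=20):
    cols = np.arange(shape[1])
    mem = np.tile(1.0 - np.abs(cols - ridge_col) / ridge_col, (shape[0], 1))
    return np.clip(mem, 0, 1), np.zeros(shape)


class TestSegmentCells:
    def test_two_seeds_split_on_posterior_ridge(self):
        mem, nuc = _ramp_posteriors()
        seeds = np.array([[20.0, 5.0], [20.0, 35.0]])
        seg = segment_cells(mem, nuc, seeds, np.ones_like(mem, bool))
        assert len(seg.cell_ids) == 2
        assert np.all(seg.labels[:, :19] == 1)
        assert np.all(seg.labels[:, 22:] == 2)

    def test_no_nuclei_posterior_means_no_nucleus(self):
        mem, nuc = _ramp_posteriors()
        seg = segment_cells(mem, nuc, np.array([[20.0, 5.0]]), np.ones_like(mem, bool))
        inst = seg.labels == 1
        assert not np.any(seg.compartments[inst] == NUCLEUS)
        assert np.array_equal(
            seg.compartments[inst] == CYTOPLASM, ~(seg.compartments[inst] == MEMBRANE)
        )

    def test_zero_seeds_empty_segmentation(self):
        mem, nuc = _ramp_posteriors()
        seg = segment_cells(mem, nuc, np.empty((0, 2)), np.ones_like(mem, bool))
        assert seg.labels.max() == 0
        assert len(seg.cell_ids) == 0

    def test_seed_outside_epithelium_dropped(self):
        mem, nuc = _ramp_posteriors()
        epi = np.zeros_like(mem, bool)
        epi[:, :15] = True
        seeds = np.array([[20.0, 5.0], [20.0, 35.0]])
        seg = segment_cells(mem, nuc, seeds, epi)
        assert seg.n_seeds_dropped == 1
        assert len(seg.cell_ids) == 1
        assert not np.any(seg.labels[~epi])

    def test_posterior_out_of_range_rejected(self):
        mem, nuc = _ramp_posteriors()
        with pytest.raises(ValueError):
            segment_cells(mem * 2.0, nuc, np.array([[20.0, 5.0]]), np.ones_like(mem, bool))

    def test_band_depth_bounds_enforced(self):
        mem, nuc = _ramp_posteriors()
        with pytest.raises(ValueError):
            segment_cells(mem, nuc, np.array([[20.0, 5.0]]), np.ones_like(mem, bool), band_px=5)


def _single_cell_roi(od=8.0, seed=0):
    params = ImagingParams(roi_shape=(48, 48))
    rng = np.random.default_rng(seed)
    return (
        render_cells(np.array([[24.0, 24.0]]), [od], [0.4 * od], [1.0], params, rng),
        params,
    )


class TestRenderingGroundTruth:
    def test_compartment_partition_invariant(self):
        roi, _ = _single_cell_roi()
        inst = roi.instance_labels == 1
        comp = roi.compartment_labels
        assert np.array_equal(comp > 0, inst)
        for code in (MEMBRANE, NUCLEUS, CYTOPLASM):
            assert np.all(inst[comp == code])

    def test_zero_membrane_od_renders_no_dab(self):
        roi, params = _single_cell_roi(od=0.0)
        odmap = deconvolve_dab(roi.rgb)
        band = roi.compartment_labels == MEMBRANE
        assert odmap.values[band].mean() < 0.3

    @pytest.mark.parametrize("od", [5.0, 8.0, 40.0, 110.0])
    def test_round_trip_recovers_true_od_within_2pct(self, od):
        roi, params = _single_cell_roi(od=od)
        odmap = deconvolve_dab(roi.rgb)
        band = roi.compartment_labels == MEMBRANE
        measured = odmap.values[band].mean()
        true = roi.true_ods["od_membrane"].iloc[0]
        assert measured == pytest.approx(true, rel=0.02)
        assert true == pytest.approx(od, rel=0.02)  # dither is mean-preserving

    def test_touching_cells_have_disjoint_instances(self):
        params = ImagingParams(roi_shape=(64, 64), min_center_distance_factor=1.0)
        rng = np.random.default_rng(1)
        r_px = params.cell_radius_um / params.pixel_size_um
        centers = np.array([[32.0, 22.0], [32.0, 22.0 + 2 * r_px]])
        roi = render_cells(centers, [10, 20], [5, 10], [1, 1], params, rng)
        assert set(np.unique(roi.instance_labels)) == {0, 1, 2}
        assert not np.any((roi.instance_labels == 1) & (roi.instance_labels == 2))

    def test_overlapping_cells_raise_or_drop(self):
        params = ImagingParams(roi_shape=(64, 64))
        rng = np.random.default_rng(1)
        centers = np.array([[32.0, 30.0], [32.0, 33.0]])
        with pytest.raises(ValueError, match="packing"):
            render_cells(centers, [10, 20], [5, 10], [1, 1], params, rng)
        params_drop = ImagingParams(roi_shape=(64, 64), on_overlap="drop")
        roi = render_cells(centers, [10, 20], [5, 10], [1, 1], params_drop, rng)
        assert len(roi.true_ods) == 0

    def test_watershed_membrane_band_depth_in_bounds(self):
        from scipy import ndimage

        roi, params = _single_cell_roi()
        seg = segment_cells(
            roi.membrane_posterior, roi.nuclei_posterior, roi.cell_centers_px, roi.epithelium_mask
        )
        inst = seg.labels == 1
        depth = ndimage.distance_transform_edt(np.pad(inst, 1))[1:-1, 1:-1]
        band = seg.compartments == MEMBRANE
        assert depth[band].max() <= 4.0
        shallow = inst & (depth <= 2.0)
        assert np.all(band[shallow])


class TestMeasureCompartmentOd:
    def _tiny_segmentation(self):
        labels = np.zeros((4, 4), np.int32)
        labels[1:3, 1:3] = 1
        comp = np.zeros((4, 4), np.uint8)
        comp[1, 1:3] = MEMBRANE
        comp[2, 1] = NUCLEUS
        comp[2, 2] = CYTOPLASM
        return CellSegmentation(
            labels=labels,
            compartments=comp,
            centroids_px=np.array([[1.5, 1.5]]),
            cell_ids=np.array([1]),
            pixel_size_um=1.0,
        )

    def test_uniform_odmap_every_compartment_mean_v(self):
        seg = self._tiny_segmentation()
        od = ODMap(np.full((4, 4), 7.0), 1.0)
        cells = measure_compartment_od(od, seg)
        assert cells.loc[0, ["od_membrane", "od_nucleus", "od_cytoplasm"]].tolist() == [7.0, 7.0, 7.0]

    def test_two_pixel_membrane_average(self):
        seg = self._tiny_segmentation()
        values = np.zeros((4, 4))
        values[1, 1], values[1, 2] = 6.0, 10.0
        cells = measure_compartment_od(ODMap(values, 1.0), seg)
        assert cells.loc[0, "od_membrane"] == 8.0

    def test_empty_compartment_is_missing(self):
        seg = self._tiny_segmentation()
        seg.compartments[seg.compartments == NUCLEUS] = CYTOPLASM
        cells = measure_compartment_od(ODMap(np.ones((4, 4)), 1.0), seg)
        assert np.isnan(cells.loc[0, "od_nucleus"])

    def test_shape_mismatch_is_error(self):
        seg = self._tiny_segmentation()
        with pytest.raises(ValueError):
            measure_compartment_od(ODMap(np.ones((5, 5)), 1.0), seg)


class TestMetrics:
    def test_identity_cases(self):
        mask = np.zeros((10, 10), bool)
        mask[2:7, 2:7] = True
        assert eval_dice(mask, mask) == 1.0
        centers = np.array([[1.0, 1.0], [5.0, 5.0]])
        assert eval_f1_centers(centers, centers, 1.0).f1 == 1.0
        assert eval_assd(mask, mask) == 0.0

    def test_disjoint_masks_dice_zero(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[:3], b[7:] = True, True
        assert eval_dice(a, b) == 0.0

    def test_empty_mask_conventions(self):
        empty = np.zeros((5, 5), bool)
        full = ~empty
        assert eval_dice(empty, empty) == 1.0
        assert eval_dice(empty, full) == 0.0

    def test_center_matching_brute_force_case(self):
        true = np.array([[0.0, 0.0], [10.0, 0.0], [100.0, 0.0]])
        pred = np.array([[0.5, 0.0], [10.5, 0.0], [50.0, 0.0]])
        res = eval_f1_centers(pred, true, match_radius_um=5.0)
        assert (res.precision, res.recall, res.f1) == (2 / 3, 2 / 3, 2 / 3)

    def test_greedy_matching_is_one_to_one(self):
        true = np.array([[0.0, 0.0]])
        pred = np.array([[0.1, 0.0], [0.2, 0.0]])
        res = eval_f1_centers(pred, true, 5.0)
        assert res.n_matched == 1
        assert res.precision == 0.5

    def test_assd_shifted_square(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[5:15, 5:15] = True
        b[5:15, 7:17] = True  # shifted 2 px right
        assert 0.5 < eval_assd(a, b) < 2.0
        assert eval_assd(a, b, pixel_size_um=0.5) == pytest.approx(0.5 * eval_assd(a, b))

    def test_assd_empty_contour_is_error(self):
        with pytest.raises(ValueError):
            eval_assd(np.zeros((5, 5), bool), np.ones((5, 5), bool))

    def test_od_correlation_perfect_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert eval_od_correlation(2 * x + 1, x) == pytest.approx(1.0)
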