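"""Overlap, boundary-distance and percent-difference metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from stvseg.metrics import (
    ConfusionCounts,
    aggregate_3d,
    confusion,
    derive_metrics,
    evaluate_pair_2d,
    evaluate_pair_3d,
    percent_difference,
    signed_distances_2d,
    signed_surface_distances,
    surface_distances,
)

SPACING = (0.114, 0.114)


def _brute_force_overlap(pred, gt):
    """Pixel-by-pixel oracle, no vectorisation."""
    tp = fp = fn = tn = 0
    for p, g in zip(np.asarray(pred).ravel(), np.asarray(gt).ravel()):
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


class TestConfusion:
    def test_perfect_prediction(self, disc_mask):
        c = confusion(disc_mask, disc_mask)
        k = int(disc_mask.sum())
        assert (c.tp, c.fp, c.fn, c.tn) == (k, 0, 0, disc_mask.size - k)

    def test_crafted_2x2(self):
        gt = np.array([[1, 1], [0, 0]])
        pred = np.array([[0, 1], [0, 1]])
        c = confusion(pred, gt)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_empty_prediction(self, disc_mask):
        c = confusion(np.zeros_like(disc_mask), disc_mask)
        assert (c.tp, c.fp, c.fn) == (0, 0, int(disc_mask.sum()))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            pred = rng.random((16, 16)) > 0.5
            gt = rng.random((16, 16)) > 0.7
            c = confusion(pred, gt)
            assert (c.tp, c.fp, c.fn, c.tn) == _brute_force_overlap(pred, gt)


class TestDeriveMetrics:
    def test_formula_case(self):
        m = derive_metrics(ConfusionCounts(tp=1, fp=1, fn=1, tn=0))
        assert m.precision == pytest.approx(50.0)
        assert m.recall == pytest.approx(50.0)
        assert m.dsc == pytest.approx(50.0)

    def test_perfect_scores(self):
        m = derive_metrics(ConfusionCounts(tp=10, fp=0, fn=0, tn=90))
        assert (m.precision, m.recall, m.accuracy, m.dsc) == (100, 100, 100, 100)
        assert not m.degenerate

    def test_both_empty_convention(self):
        m = derive_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=100))
        assert m.dsc == 100.0
        assert m.degenerate

    def test_empty_pred_convention(self):
        m = derive_metrics(ConfusionCounts(tp=0, fp=0, fn=5, tn=95))
        assert m.precision == 0.0
        assert m.degenerate

    def test_dsc_symmetry_and_duality(self, rng):
        # dsc(a,b) == dsc(b,a); precision(a,b) == recall(b,a)
        for _ in range(10):
            a = rng.random((12, 12)) > 0.5
            b = rng.random((12, 12)) > 0.5
            mab = derive_metrics(confusion(a, b))
            mba = derive_metrics(confusion(b, a))
            assert mab.dsc == pytest.approx(mba.dsc)
            assert mab.precision == pytest.approx(mba.recall)

    def test_dsc_at_least_jaccard(self, rng):
        for _ in range(10):
            a = rng.random((10, 10)) > 0.4
            b = rng.random((10, 10)) > 0.6
            c = confusion(a, b)
            if c.tp + c.fp + c.fn == 0:
                continue
            jaccard = 100.0 * c.tp / (c.tp + c.fp + c.fn)
            assert derive_metrics(c).dsc >= jaccard - 1e-12


class TestAggregate3D:
    def test_identical_slices_equal_single(self):
        c = ConfusionCounts(tp=5, fp=2, fn=1, tn=92)
        single = derive_metrics(c)
        pooled = aggregate_3d([c] * 7)
        assert pooled == single

    def test_average_equals_sum(self, rng):
        # ratios are scale invariant: averaging counts or summing them give
        # identical metrics
        slices = [ConfusionCounts(*rng.integers(0, 50, 4)) for _ in range(9)]
        pooled = aggregate_3d(slices)
        n = len(slices)
        mean_counts = ConfusionCounts(
            tp=sum(c.tp for c in slices),
            fp=sum(c.fp for c in slices),
            fn=sum(c.fn for c in slices),
            tn=sum(c.tn for c in slices))
        averaged = derive_metrics(mean_counts)
        assert pooled.dsc == pytest.approx(averaged.dsc, abs=1e-12)
        assert pooled.precision == pytest.approx(averaged.precision, abs=1e-12)

    def test_pooling_equals_concatenated_grids(self, disc_mask):
        perfect = confusion(disc_mask, disc_mask)
        wrong = confusion(np.zeros_like(disc_mask), disc_mask)
        pooled = aggregate_3d([perfect, wrong])
        concat_pred = np.concatenate([disc_mask, np.zeros_like(disc_mask)])
        concat_gt = np.concatenate([disc_mask, disc_mask])
        direct = derive_metrics(confusion(concat_pred, concat_gt))
        assert pooled == direct

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_3d([])


counts = st.integers(min_value=0, max_value=500)


@given(tp=counts, fp=counts, fn=counts, tn=counts)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_overlap_metric_bounds_and_dsc_jaccard_order(tp, fp, fn, tn):
    if tp + fp + fn + tn == 0:
        return
    m = derive_metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn))
    for v in (m.precision, m.recall, m.accuracy, m.dsc):
        assert 0.0 <= v <= 100.0
    if tp + fp + fn > 0:
        jaccard = 100.0 * tp / (tp + fp + fn)
        assert m.dsc >= jaccard - 1e-12


@given(measured=st.floats(0.0, 1e6), reference=st.floats(1e-6, 1e6))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_percent_difference_sign_magnitude_property(measured, reference):
    absd, signed = percent_difference(measured, reference)
    assert absd == abs(signed)
    assert (signed >= 0) == (measured >= reference)


class TestSurfaceDistances:
    def test_identical_sets_zero(self, rng):
        pts = rng.random((50, 2))
        assert surface_distances(pts, pts) == (0.0, 0.0)

    def test_offset_unit_squares_hd(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        msd, hd = surface_distances(sq, sq + [3.0, 0.0])
        assert hd == pytest.approx(3.0)

    def test_singletons_closed_form(self):
        msd, hd = surface_distances([[0.0, 0.0]], [[3.0, 4.0]])
        assert msd == hd == pytest.approx(5.0)

    def test_matches_all_pairs_oracle(self, rng):
        a = rng.random((150, 3)) * 10
        b = rng.random((180, 3)) * 10
        d = np.linalg.norm(a[:, None] - b[None], axis=-1)
        msd_oracle = 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())
        hd_oracle = max(d.min(axis=1).max(), d.min(axis=0).max())
        msd, hd = surface_distances(a, b)
        assert msd == pytest.approx(msd_oracle, abs=1e-9)
        assert hd == pytest.approx(hd_oracle, abs=1e-9)

    def test_hd_at_least_msd(self, rng):
        for _ in range(10):
            a = rng.random((30, 2))
            b = rng.random((40, 2))
            msd, hd = surface_distances(a, b)
            assert hd >= msd >= 0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            surface_distances(np.empty((0, 2)), [[0.0, 0.0]])


class TestSignedDistances:
    def test_identical_boundaries_zero(self, disc_mask):
        from stvseg.surface import extract_contours

        pts = extract_contours(disc_mask, 0.0, SPACING)[0].points
        smsd, shd = signed_distances_2d(pts, disc_mask, SPACING)
        assert smsd == pytest.approx(0.0, abs=1e-9)

    def test_dilation_positive_one_pixel(self, disc_mask):
        from stvseg.surface import extract_contours

        dil = ndimage.binary_dilation(disc_mask).astype(np.uint8)
        pts = extract_contours(dil, 0.0, SPACING)[0].points
        smsd, shd = signed_distances_2d(pts, disc_mask, SPACING)
        assert smsd > 0
        assert smsd == pytest.approx(0.114, rel=0.30)

    def test_erosion_negative(self, disc_mask):
        from stvseg.surface import extract_contours

        ero = ndimage.binary_erosion(disc_mask).astype(np.uint8)
        pts = extract_contours(ero, 0.0, SPACING)[0].points
        smsd, _ = signed_distances_2d(pts, disc_mask, SPACING)
        assert smsd < 0

    def test_sign_convention_flips(self, disc_mask):
        from stvseg.surface import extract_contours

        dil = ndimage.binary_dilation(disc_mask).astype(np.uint8)
        pts = extract_contours(dil, 0.0, SPACING)[0].points
        pos, _ = signed_distances_2d(pts, disc_mask, SPACING,
                                     outside_positive=True)
        neg, _ = signed_distances_2d(pts, disc_mask, SPACING,
                                     outside_positive=False)
        assert pos == pytest.approx(-neg)

    def test_generic_wrapper_uses_inside_flags(self):
        pred = np.array([[2.0, 0.0], [0.5, 0.0]])
        gt = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        inside = np.array([False, True])
        smsd, shd = signed_surface_distances(pred, gt, inside)
        assert smsd == pytest.approx((1.0 - 0.5) / 2)
        assert shd == pytest.approx(1.0)


class TestPercentDifference:
    def test_equal_is_zero(self):
        assert percent_difference(5.0, 5.0) == (0.0, 0.0)

    def test_clinical_scale_example(self):
        absd, signed = percent_difference(0.30, 0.26)
        assert signed == pytest.approx(15.4, abs=0.05)
        assert absd == pytest.approx(15.4, abs=0.05)

    def test_half_reference(self):
        absd, signed = percent_difference(1.0, 2.0)
        assert (absd, signed) == (50.0, -50.0)

    def test_abs_equals_magnitude_of_signed(self, rng):
        for _ in range(20):
            m, r = rng.random() * 10, rng.random() * 10 + 0.1
            absd, signed = percent_difference(m, r)
            assert absd == abs(signed)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0)


class TestEvaluatePairs:
    def test_identical_masks_perfect_record(self, disc_mask):
        rec = evaluate_pair_2d(disc_mask, disc_mask, SPACING)
        assert rec.dsc == 100.0
        assert rec.msd == pytest.approx(0.0, abs=1e-12)
        assert rec.avpd == pytest.approx(0.0)
        assert not rec.degenerate

    def test_dilated_mask_record_signs(self, disc_mask):
        dil = ndimage.binary_dilation(disc_mask).astype(np.uint8)
        rec = evaluate_pair_2d(dil, disc_mask, SPACING)
        assert rec.signed_msd > 0
        assert rec.signed_avpd > 0
        assert rec.avpd == abs(rec.signed_avpd)

    def test_empty_gt_flagged_degenerate(self, disc_mask):
        rec = evaluate_pair_2d(disc_mask, np.zeros_like(disc_mask), SPACING)
        assert rec.degenerate
        assert math.isnan(rec.avpd)

    def test_3d_record_from_phantom_perturbation(self, crescent_pair):
        from stvseg.phantom import RaterPerturbation, simulate_second_rater
        from stvseg.surface import masks_to_surface
        from stvseg.volume import reslice_label

        _, lab = crescent_pair
        rater2, _ = simulate_second_rater(
            lab, RaterPerturbation(jitter_voxels=1.5, seed=3))
        n = lab.shape[0]
        gs = reslice_label(lab, n)
        ps = reslice_label(rater2, n)
        pred_s, pred_v, _ = masks_to_surface(ps, ps.images)
        gt_s, gt_v, _ = masks_to_surface(gs, gs.images)
        rec = evaluate_pair_3d(ps.images, gs.images, SPACING, pred_s, gt_s,
                               pred_v, gt_v, gt_label=lab)
        assert 50.0 < rec.dsc < 100.0
        assert 0.0 < rec.msd < 1.0  # jitter amplitude is sub-mm
        assert rec.hd >= rec.msd
        assert np.isfinite(rec.signed_msd)

    def test_3d_identity_is_perfect(self, crescent_pair):
        from stvseg.surface import masks_to_surface
        from stvseg.volume import reslice_label

        _, lab = crescent_pair
        gs = reslice_label(lab, lab.shape[0])
        s, v, _ = masks_to_surface(gs, gs.images)
        rec = evaluate_pair_3d(gs.images, gs.images, SPACING, s, s, v, v,
                               gt_label=lab)
        assert rec.dsc == 100.0
        assert rec.msd == 0.0
        assert rec.avpd == 0.0

    def test_disjoint_masks_zero_dsc(self):
        a = np.zeros((12, 12), dtype=np.uint8)
        b = np.zeros((12, 12), dtype=np.uint8)
        a[2:5, 2:5] = 1
        b[8:11, 8:11] = 1
        rec = evaluate_pair_2d(a, b, SPACING)
        assert rec.dsc == 0.0
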