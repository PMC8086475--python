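"""Decision rules: thresholds, the Round-3 override table, coverage, maps."""

import itertools

import numpy as np
import pytest

from fastraman.diagnosis import (
    DecisionConfig,
    apply_round3_logic,
    area_metrics,
    label_adipose,
    label_blood,
    label_contact,
    render_map,
    score_round2,
    select_round3,
)
from fastraman.segmentation import Segment, SegmentationResult

CFG = DecisionConfig()


def _preds(n_bcc, n_total, filler="dermis"):
    return ["bcc"] * n_bcc + [filler] * (n_total - n_bcc)


class TestAdiposeScreen:
    def test_fat_segments_excluded_others_retained(self):
        retained, adipose = label_adipose(
            [1, 2, 3], {1: "fat", 2: "dermis", 3: "bcc"}
        )
        assert adipose == [1]
        assert retained == [2, 3]

    def test_missing_round1_result_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            label_adipose([1, 2], {1: "fat"})


class TestRound2Score:
    @pytest.mark.parametrize(
        "n_bcc,n_total,positive",
        [(9, 20, False), (10, 20, True), (0, 20, False), (20, 20, True)],
    )
    def test_strict_45_percent_boundary(self, n_bcc, n_total, positive):
        frac, pos = score_round2(_preds(n_bcc, n_total), CFG)
        assert frac == pytest.approx(n_bcc / n_total)
        assert pos is positive

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError, match="no classified spectra"):
            score_round2([], CFG)


class TestRound3Selection:
    def test_top_three_by_fraction(self):
        fr = {1: 0.9, 2: 0.5, 3: 0.3, 4: 0.2}
        areas = {i: 100 for i in fr}
        assert select_round3(fr, areas, CFG) == [1, 2, 3]

    def test_zero_fractions_never_selected(self):
        fr = {1: 0.0, 2: 0.0}
        assert select_round3(fr, {1: 10, 2: 10}, CFG) == []

    def test_tie_breaks_by_area_then_id(self):
        fr = {1: 0.5, 2: 0.5, 3: 0.5}
        areas = {1: 40, 2: 80, 3: 40}
        assert select_round3(fr, areas, CFG) == [2, 1, 3]


def _oracle_round3(passes, extra_r2):
    """Independent hand-enumerated truth table for the override rule."""
    seg_ids = [1, 2, 3]
    passed = [s for s, ok in zip(seg_ids, passes) if ok]
    if not passed:
        return set(), "bcc_clear"
    if all(passes):
        return set(passed) | set(extra_r2), "bcc_positive"
    return set(passed), "bcc_positive"


class TestRound3Override:
    @pytest.mark.parametrize("passes", list(itertools.product([True, False], repeat=3)))
    @pytest.mark.parametrize("extra_r2", [[], [7, 9]])
    def test_matches_enumerated_truth_table(self, passes, extra_r2):
        preds = {
            sid: _preds(14 if ok else 12, 16)
            for sid, ok in zip([1, 2, 3], passes)
        }
        r2_positive = [1, 2, 3] + extra_r2
        final, verdict = apply_round3_logic(preds, r2_positive, CFG)
        want_final, want_verdict = _oracle_round3(passes, extra_r2)
        assert verdict == want_verdict
        assert set(final) == want_final

    def test_strict_75_percent_boundary_on_16_spectra(self):
        # 12/16 = 75.0% fails the strict rule, 13/16 passes
        _, verdict12 = apply_round3_logic({1: _preds(12, 16)}, [1], CFG)
        final13, verdict13 = apply_round3_logic({1: _preds(13, 16)}, [1], CFG)
        assert verdict12 == "bcc_clear"
        assert verdict13 == "bcc_positive" and final13 == [1]

    def test_mixed_pass_fail_demotes_unconfirmed_round2_positives(self):
        preds = {1: _preds(16, 16), 2: _preds(16, 16), 3: _preds(12, 16)}
        final, verdict = apply_round3_logic(preds, [1, 2, 3, 8], CFG)
        assert verdict == "bcc_positive"
        assert final == [1, 2]  # 3 failed, 8 demoted

    def test_wrong_raster_size_rejected(self):
        with pytest.raises(ValueError, match="16"):
            apply_round3_logic({1: _preds(10, 15)}, [], CFG)

    def test_no_selected_segments_is_clear(self):
        assert apply_round3_logic({}, [5], CFG) == ([], "bcc_clear")


class TestBloodAndContact:
    @pytest.mark.parametrize(
        "n_blood,n_total,flag", [(7, 10, False), (8, 10, True), (0, 10, False)]
    )
    def test_strict_70_percent_blood_boundary(self, n_blood, n_total, flag):
        preds = ["blood"] * n_blood + ["dermis"] * (n_total - n_blood)
        assert label_blood(preds, CFG) is flag

    @pytest.mark.parametrize(
        "snrs,flag",
        [([3, 5, 6.9], True), ([3, 8], False), ([7.0, 7.0], False)],
    )
    def test_contact_requires_all_snr_strictly_below_seven(self, snrs, flag):
        assert label_contact(snrs, CFG) is flag

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            label_blood([], CFG)
        with pytest.raises(ValueError):
            label_contact([], CFG)


def _seg_result(total_px=1000, blood_px=15, nc_px=12):
    side = int(np.sqrt(total_px))
    assert side * side == total_px or True
    tissue = np.zeros((40, 40), bool)
    tissue.ravel()[:total_px] = True
    rows = np.nonzero(tissue.ravel())[0]

    def mk(seg_id, start, n):
        idx = rows[start : start + n]
        return Segment(
            id=seg_id, rows=idx // 40, cols=idx % 40, mean_af=0.0
        )

    segs = [mk(1, 0, blood_px), mk(2, blood_px, nc_px)]
    return SegmentationResult(
        tissue_mask=tissue, dermis_mask=np.zeros_like(tissue), segments=segs
    )


class TestAreaMetrics:
    def test_no_flags_is_fully_analysed(self):
        res = _seg_result()
        assert area_metrics(res, [], []) == (0.0, 0.0, 100.0)

    def test_pixel_count_arithmetic(self):
        res = _seg_result(1000, 15, 12)
        pct_blood, pct_nc, pct_an = area_metrics(res, [1], [2])
        assert pct_blood == pytest.approx(1.5)
        assert pct_nc == pytest.approx(1.2)
        assert pct_an == pytest.approx(97.3)
        assert pct_blood + pct_nc + pct_an == pytest.approx(100.0, abs=1e-12)

    def test_segment_flagged_both_counts_once_toward_blood(self):
        res = _seg_result(1000, 15, 12)
        pct_blood, pct_nc, _ = area_metrics(res, [1], [1, 2])
        assert pct_blood == pytest.approx(1.5)
        assert pct_nc == pytest.approx(1.2)

    def test_empty_tissue_rejected(self):
        res = _seg_result()
        res.tissue_mask = np.zeros_like(res.tissue_mask)
        with pytest.raises(ValueError, match="empty"):
            area_metrics(res, [], [])


class TestRenderMap:
    def test_clear_layer_has_no_red_pixels(self):
        res = _seg_result()
        af = np.full(res.tissue_mask.shape, 1000.0)
        rgb = render_map(res, af, [], [], [])
        red = (rgb[..., 0] == 255) & (rgb[..., 1] == 0) & (rgb[..., 2] == 0)
        assert not red.any()

    def test_positive_segment_painted_exactly(self):
        res = _seg_result()
        af = np.full(res.tissue_mask.shape, 1000.0)
        rgb = render_map(res, af, [1], [], [])
        red = (rgb[..., 0] == 255) & (rgb[..., 1] == 0) & (rgb[..., 2] == 0)
        seg = res.segment_by_id(1)
        want = np.zeros_like(red)
        want[seg.rows, seg.cols] = True
        assert np.array_equal(red, want)

    def test_blood_and_contact_overlays_are_disjoint(self):
        res = _seg_result()
        af = np.full(res.tissue_mask.shape, 1000.0)
        rgb = render_map(res, af, [], [1], [2])
        yellow = (rgb[..., 0] == 255) & (rgb[..., 1] == 255) & (rgb[..., 2] == 0)
        blue = (rgb[..., 2] == 255) & (rgb[..., 0] == 0)
        assert yellow.any() and blue.any()
        assert not (yellow & blue).any()


def test_decision_config_defaults_and_validation():
    cfg = DecisionConfig()
    assert (
        cfg.round2_bcc_threshold,
        cfg.round3_bcc_threshold,
        cfg.blood_threshold,
        cfg.snr_threshold,
        cfg.round3_segment_count,
        cfg.round2_budget,
    ) == (0.45, 0.75, 0.70, 7.0, 3, 550)
    with pytest.raises(ValueError):
        DecisionConfig(round2_bcc_threshold=1.2)
    with pytest.raises(ValueError):
        DecisionConfig(snr_threshold=0)
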