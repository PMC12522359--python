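"""Tests for overlap metrics and the cohort statistics panel."""

import csv
import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fazseg import (
    cohort_mean_iou,
    cohort_stats,
    confusion_counts,
    evaluate_pair,
    iou,
    miou_two_class,
    quality_gate,
    report,
)
from fazseg.errors import ParameterError, ValidationError

from .oracles import percentile_oracle, random_mask


def block(shape, r0, c0, h, w):
    m = np.zeros(shape, dtype=bool)
    m[r0 : r0 + h, c0 : c0 + w] = True
    return m


class TestConfusionAndIou:
    def test_perfect_prediction(self):
        m = block((10, 10), 2, 2, 5, 5)
        assert confusion_counts(m, m) == (25, 0, 0)
        assert iou(m, m) == 1.0

    def test_all_foreground_prediction(self):
        gt = np.array([[1, 0], [1, 0]])
        pred = np.ones((2, 2), dtype=bool)
        assert confusion_counts(pred, gt) == (2, 2, 0)

    def test_empty_prediction(self):
        gt = block((5, 5), 0, 0, 2, 5)
        pred = np.zeros((5, 5), dtype=bool)
        assert confusion_counts(pred, gt) == (0, 0, 10)
        assert iou(pred, gt) == 0.0

    def test_shifted_blocks_give_4_of_14(self):
        a = block((5, 5), 0, 0, 3, 3)
        b = block((5, 5), 1, 1, 3, 3)
        assert iou(a, b) == pytest.approx(4 / 14)

    def test_disjoint_masks_score_zero(self):
        assert iou(block((6, 6), 0, 0, 2, 2), block((6, 6), 4, 4, 2, 2)) == 0.0

    def test_two_empty_masks_undefined(self):
        z = np.zeros((3, 3), dtype=bool)
        with pytest.raises(ParameterError):
            iou(z, z)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion_counts(np.zeros((2, 2), dtype=bool), np.zeros((3, 3), dtype=bool))

    @given(st.integers(0, 10_000))
    def test_symmetry_and_identity(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_mask(rng, 16), None
        b = rng.random(a.shape) < 0.5
        if not (a.any() or b.any()):
            return
        assert iou(a, b) == iou(b, a)
        if a.any():
            assert iou(a, a) == 1.0

    @given(st.integers(0, 10_000))
    def test_jaccard_distance_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        shape = (8, 8)
        a, b, c = (rng.random(shape) < 0.5 for _ in range(3))
        if not (a.any() and b.any() and c.any()):
            return

        def dist(x, y):
            return 1.0 - iou(x, y) if (x.any() or y.any()) else 0.0

        assert dist(a, c) <= dist(a, b) + dist(b, c) + 1e-12


class TestTwoClassMiou:
    def test_identical_masks(self):
        m = block((10, 10), 1, 1, 3, 3)
        assert miou_two_class(m, m) == 1.0

    def test_empty_prediction_against_ten_of_hundred(self):
        gt = block((10, 10), 0, 0, 2, 5)
        pred = np.zeros((10, 10), dtype=bool)
        assert miou_two_class(pred, gt) == pytest.approx(0.45)

    def test_complement_prediction_scores_zero(self):
        gt = block((10, 10), 2, 2, 4, 4)
        assert miou_two_class(~gt, gt) == 0.0

    @given(st.integers(0, 10_000))
    def test_bounded_by_faz_iou_envelope(self, seed):
        rng = np.random.default_rng(seed)
        gt = random_mask(rng, 12)
        pred = rng.random(gt.shape) < 0.5
        if not gt.any():
            return
        rec = evaluate_pair("s", pred, gt)
        assert rec.iou_faz / 2 - 1e-12 <= rec.miou_two_class <= (rec.iou_faz + 1) / 2 + 1e-12


class TestCohortStats:
    def test_mean_trivials(self):
        recs = [evaluate_pair("a", block((4, 4), 0, 0, 2, 2), block((4, 4), 0, 0, 2, 2))]
        assert cohort_mean_iou(recs) == 1.0

    def test_closed_form_three_value_panel(self):
        s = cohort_stats([0.8, 0.9, 1.0])
        assert s.mean_iou == pytest.approx(0.9)
        assert s.median == pytest.approx(0.9)
        assert s.sd == pytest.approx(0.1)
        assert s.ci95_low == pytest.approx(0.7868, abs=5e-5)
        assert s.ci95_high == pytest.approx(1.0132, abs=5e-5)

    def test_constant_cohort(self):
        s = cohort_stats([0.5] * 7)
        for v in (s.mean_iou, s.median, s.q1, s.q3, s.p10, s.p5, s.p1, s.min, s.max):
            assert v == 0.5
        assert s.sd == 0.0
        assert s.ci95_low == s.ci95_high == 0.5

    def test_single_value_has_no_sd_or_ci(self):
        s = cohort_stats([0.7])
        assert s.sd is None and s.ci95_low is None and s.ci95_high is None

    @given(st.integers(0, 500))
    def test_order_statistics_match_sorting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        xs = rng.uniform(0, 1, size=int(rng.integers(2, 60))).tolist()
        s = cohort_stats(xs)
        for stat, q in [(s.median, 50), (s.q1, 25), (s.q3, 75), (s.p10, 10), (s.p5, 5), (s.p1, 1)]:
            assert stat == pytest.approx(percentile_oracle(xs, q), abs=1e-12)
        s_perm = cohort_stats(list(np.random.default_rng(seed + 1).permutation(xs)))
        assert s_perm.median == s.median and s_perm.q1 == s.q1

    def test_panel_ordering_invariant(self, rng):
        xs = rng.uniform(0, 1, size=50).tolist()
        s = cohort_stats(xs)
        assert s.min <= s.p1 <= s.p5 <= s.p10 <= s.q1 <= s.median <= s.q3 <= s.max
        assert s.min <= s.mean_iou <= s.max
        assert s.ci95_low <= s.mean_iou <= s.ci95_high

    def test_bootstrap_ci_seeded_and_reasonable(self, rng):
        xs = rng.uniform(0.5, 1.0, size=40).tolist()
        a = cohort_stats(xs, bootstrap=True, bootstrap_seed=3)
        b = cohort_stats(xs, bootstrap=True, bootstrap_seed=3)
        assert (a.ci95_low, a.ci95_high) == (b.ci95_low, b.ci95_high)
        assert a.ci95_low <= a.mean_iou <= a.ci95_high


class TestQualityGate:
    def test_all_high_quality_retained(self):
        samples = [{"quality_index": 10} for _ in range(4)]
        assert len(quality_gate(samples)) == 4

    def test_threshold_seven_filters_correctly(self):
        samples = [{"quality_index": q} for q in (6, 7, 8)]
        assert len(quality_gate(samples, min_quality=7)) == 2

    def test_threshold_zero_is_identity(self):
        samples = [{"quality_index": q} for q in (0, 3, 10)]
        assert quality_gate(samples, min_quality=0) == samples

    def test_missing_quality_retained(self):
        samples = [{"quality_index": None}, {"quality_index": 2}]
        assert len(quality_gate(samples, min_quality=7)) == 1


class TestReport:
    def test_report_round_trip_and_self_consistency(self, tmp_path, rng):
        gts = [random_mask(rng, 16, p_fg=0.4) for _ in range(3)]
        gts = [g for g in gts if g.any()] or [np.ones((4, 4), dtype=bool)]
        records = [
            evaluate_pair(f"s{i}", rng.random(g.shape) < 0.4, g) for i, g in enumerate(gts)
        ]
        stats = cohort_stats([r.iou_faz for r in records])
        json_path, csv_path = report(stats, records, tmp_path)

        panel = json.loads(json_path.read_text())
        assert panel["n"] == len(records)
        assert panel["mean_iou"] == pytest.approx(stats.mean_iou, abs=5e-5)

        with csv_path.open() as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == len(records)
        # recomputing the panel from the per-sample CSV reproduces it
        again = cohort_stats([float(r["iou_faz"]) for r in rows])
        assert again.mean_iou == pytest.approx(panel["mean_iou"], abs=5e-4)
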