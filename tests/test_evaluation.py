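"""Dice / mDice segmentation metrics and deviation-score ROC screening."""

import numpy as np
import pandas as pd
import pytest

from caliper3vv.cohort import DEFAULT_STANDARD_RANGE, StandardRange
from caliper3vv.errors import EmptyInput, ShapeMismatch, SingleClass, UndefinedDice
from caliper3vv.evaluation import (
    dice,
    mdice_frame,
    mean_auc,
    rater_evaluation,
    roc_auc,
    screening_score,
)
from caliper3vv.geometry import AO, PA, SVC, LabelMask


def mann_whitney_auc(scores, labels):
    """Independent pair-counting oracle: P(score_CHD > score_normal), ties 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == "CHD"]
    neg = [s for s, l in zip(scores, labels) if l == "normal"]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _mask(arr):
    return LabelMask(np.asarray(arr, dtype=int))


class TestDice:
    def test_identical_masks(self):
        grid = np.zeros((10, 10), dtype=int)
        grid[2:6, 2:6] = PA
        assert dice(_mask(grid), _mask(grid), PA) == 1.0

    def test_disjoint_regions(self):
        gt = np.zeros((10, 10), dtype=int)
        pred = np.zeros((10, 10), dtype=int)
        gt[0:3, 0:3] = PA
        pred[6:9, 6:9] = PA
        assert dice(_mask(gt), _mask(pred), PA) == 0.0

    def test_equation_arithmetic(self):
        # TP=5, FP=5, FN=5 -> 10/20
        gt = np.zeros((4, 10), dtype=int)
        pred = np.zeros((4, 10), dtype=int)
        gt[0, 0:10] = PA          # 10 gt pixels
        pred[0, 5:10] = PA        # 5 overlap
        pred[1, 0:5] = PA         # 5 false positive
        assert dice(_mask(gt), _mask(pred), PA) == 0.5

    def test_shape_mismatch(self):
        with pytest.raises(ShapeMismatch):
            dice(_mask(np.zeros((4, 4), dtype=int)), _mask(np.zeros((5, 5), dtype=int)), PA)

    def test_absent_from_both_undefined(self):
        empty = _mask(np.zeros((4, 4), dtype=int))
        with pytest.raises(UndefinedDice):
            dice(empty, empty, PA)

    def test_symmetry_on_random_pairs(self, rng):
        for _ in range(30):
            gt = _mask(rng.integers(0, 4, size=(12, 12)))
            pred = _mask(rng.integers(0, 4, size=(12, 12)))
            for code in (PA, AO, SVC):
                try:
                    forward = dice(gt, pred, code)
                except UndefinedDice:
                    continue
                assert forward == dice(pred, gt, code)


class TestMDice:
    @staticmethod
    def _frame_pair():
        """Per-class Dice {PA: 0.8, Ao: 0.6, SVC: 0.7} by pixel construction."""
        gt = np.zeros((20, 20), dtype=int)
        pred = np.zeros((20, 20), dtype=int)
        # PA: TP=4, FP=1, FN=1 -> 8/10
        gt[0, 0:5] = PA; pred[0, 1:6] = PA
        # Ao: TP=3, FP=2, FN=2 -> 6/10
        gt[5, 0:5] = AO; pred[5, 2:7] = AO
        # SVC: TP=7, FP=3, FN=3 -> 14/20
        gt[10, 0:10] = SVC; pred[10, 3:13] = SVC
        return _mask(gt), _mask(pred)

    def test_mean_over_classes(self):
        report = mdice_frame(*self._frame_pair())
        assert report.per_class[PA] == pytest.approx(0.8)
        assert report.per_class[AO] == pytest.approx(0.6)
        assert report.per_class[SVC] == pytest.approx(0.7)
        assert report.mdice == pytest.approx(0.7)
        assert report.n_classes_evaluated == 3

    def test_absent_class_excluded(self):
        gt, pred = self._frame_pair()
        gt2 = gt.grid.copy(); pred2 = pred.grid.copy()
        gt2[gt2 == SVC] = 0; pred2[pred2 == SVC] = 0
        report = mdice_frame(_mask(gt2), _mask(pred2))
        assert report.n_classes_evaluated == 2
        assert report.mdice == pytest.approx(0.7)

    def test_absent_as_one_flag(self):
        gt, pred = self._frame_pair()
        gt2 = gt.grid.copy(); pred2 = pred.grid.copy()
        gt2[gt2 == SVC] = 0; pred2[pred2 == SVC] = 0
        report = mdice_frame(_mask(gt2), _mask(pred2), absent_as_one=True)
        assert report.n_classes_evaluated == 3
        assert report.mdice == pytest.approx((0.8 + 0.6 + 1.0) / 3)

    def test_identical_multiclass(self):
        gt, _ = self._frame_pair()
        assert mdice_frame(gt, gt).mdice == 1.0


class TestScreeningScore:
    def test_at_the_mean(self):
        assert screening_score(1.237, DEFAULT_STANDARD_RANGE) == 0.0

    def test_symmetric_deviations(self):
        low = screening_score(0.873, DEFAULT_STANDARD_RANGE)
        high = screening_score(1.601, DEFAULT_STANDARD_RANGE)
        assert low == pytest.approx(0.364)
        assert high == pytest.approx(0.364)

    def test_monotone_in_absolute_deviation(self, rng):
        devs = np.sort(rng.uniform(0, 1.5, size=20))
        scores = [screening_score(1.237 + d, DEFAULT_STANDARD_RANGE) for d in devs]
        assert scores == sorted(scores)


class TestRocAuc:
    def test_perfect_separation(self):
        result = roc_auc([0.9, 0.8, 0.2, 0.1], ["CHD", "CHD", "normal", "normal"])
        assert result.auc == 1.0
        assert result.fpr[0] == 0.0 and result.tpr[0] == 0.0
        assert result.fpr[-1] == 1.0 and result.tpr[-1] == 1.0

    def test_inverted_labels(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], ["normal", "normal", "CHD", "CHD"]).auc == 0.0

    def test_constant_scores_are_chance(self):
        assert roc_auc([0.5] * 6, ["CHD", "normal"] * 3).auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(SingleClass):
            roc_auc([0.1, 0.2], ["CHD", "CHD"])

    def test_matches_mann_whitney_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 60))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = ["CHD" if v else "normal" for v in rng.integers(0, 2, size=n)]
            if len(set(labels)) < 2:
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-9
            )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=30)
        labels = ["CHD" if v else "normal" for v in rng.integers(0, 2, size=30)]
        base = roc_auc(scores, labels).auc
        assert roc_auc(np.exp(scores), labels).auc == pytest.approx(base, abs=1e-12)

    def test_label_flip_complement(self, rng):
        scores = np.round(rng.normal(size=40), 1)
        labels = ["CHD" if v else "normal" for v in rng.integers(0, 2, size=40)]
        flipped = ["normal" if l == "CHD" else "CHD" for l in labels]
        total = roc_auc(scores, labels).auc + roc_auc(scores, flipped).auc
        assert total == pytest.approx(1.0, abs=1e-12)


class TestMeanAuc:
    def test_examples(self):
        assert mean_auc([1.0, 0.5]) == 0.75
        assert mean_auc([0.883]) == 0.883

    def test_permutation_invariant(self, rng):
        vals = list(rng.uniform(0, 1, size=7))
        assert mean_auc(vals) == pytest.approx(mean_auc(vals[::-1]))

    def test_empty_rejected(self):
        with pytest.raises(EmptyInput):
            mean_auc([])


def _rater_frame(rater_id, group, pa_ao_label):
    return pd.DataFrame(
        [
            {"rater_id": rater_id, "skill_group": group, "case_id": f"c{i}",
             "label": lab, "pa_px": pa, "ao_px": ao}
            for i, (pa, ao, lab) in enumerate(pa_ao_label)
        ]
    )


class TestRaterEvaluation:
    def test_perfectly_separating_rater(self):
        rows = [(35, 20, "CHD"), (34, 20, "CHD"), (25, 20, "normal"), (24, 20, "normal")]
        result = rater_evaluation(_rater_frame("r1", "experts", rows))
        assert result["per_rater"]["auc"].iloc[0] == 1.0

    def test_group_mean(self):
        perfect = [(35, 20, "CHD"), (24, 20, "normal"), (36, 20, "CHD"), (25, 20, "normal")]
        chance = [(24, 20, "CHD"), (24, 20, "normal"), (24, 20, "CHD"), (24, 20, "normal")]
        table = pd.concat(
            [_rater_frame("r1", "fellows", perfect), _rater_frame("r2", "fellows", chance)]
        )
        result = rater_evaluation(table)
        assert result["per_group"]["fellows"] == pytest.approx(0.75)

    def test_auc_degrades_with_measurement_noise(self, rng):
        # graded diameter noise should not improve screening (Monte Carlo)
        true_ratios = {"normal": 1.24, "CHD": 1.9}
        mean_aucs = []
        for noise_sd in (0.0, 2.0, 6.0):
            aucs = []
            for _ in range(60):
                rows = []
                for i in range(16):
                    label = "CHD" if i % 2 else "normal"
                    ao = 20.0
                    pa = true_ratios[label] * ao + rng.normal(0, noise_sd)
                    rows.append((max(pa, 1.0), ao, label))
                result = rater_evaluation(_rater_frame("r", "fellows", rows))
                aucs.append(result["overall_mean_auc"])
            mean_aucs.append(np.mean(aucs))
        assert mean_aucs[0] >= mean_aucs[1] >= mean_aucs[2] - 0.02
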