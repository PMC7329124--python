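"""Agreement classes, Cohen's kappa, confusion counts, the six metrics."""

import math
import random
from itertools import product

import numpy as np
import pytest

from tbiextract.evaluate import (
    AnnotationTable,
    ConfusionCounts,
    classification_metrics,
    cohens_kappa,
    compare_cells,
    confusion_counts,
    gold_standard,
    per_target_errors,
)
from tbiextract.labels import AnnotationLabel
from tbiextract.lexicon import CANONICAL_TARGETS

L = AnnotationLabel


def _table(labels, source=""):
    """labels: dict (report, target) -> AnnotationLabel."""
    return AnnotationTable(rows=labels, source=source)


def _uniform(label, reports=("r1",), targets=CANONICAL_TARGETS):
    return {(r, t): label for r in reports for t in targets}


def kappa_oracle(xs, ys):
    """Brute-force p_o / p_e from the label confusion matrix."""
    n = len(xs)
    labels = sorted({*xs, *ys}, key=lambda lab: lab.value)
    p_o = sum(1 for x, y in zip(xs, ys) if x == y) / n
    p_e = sum(
        (xs.count(lab) / n) * (ys.count(lab) / n) for lab in labels
    )
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1 - p_e)


class TestCompareCells:
    def test_identical_tables_all_equivalent(self):
        a = _table(_uniform(L.ABSENT))
        summary = compare_cells(a, a)
        assert summary.n_equivalent == summary.n_total == 27
        assert summary.n_similar == summary.n_divergent == 0

    @pytest.mark.parametrize(
        "x,y,cls",
        [
            (L.PRESENT, L.SUSPECTED, "similar"),
            (L.SUSPECTED, L.PRESENT, "similar"),
            (L.ABSENT, L.PRESENT, "divergent"),
            (L.NORMAL, L.ABNORMAL, "divergent"),
            (L.PRESENT, L.NORMAL, "divergent"),
            (L.SUSPECTED, L.ABSENT, "other"),
            (L.INDETERMINATE, L.PRESENT, "other"),
        ],
    )
    def test_cell_classes(self, x, y, cls):
        a = _table({("r1", "cistern"): x})
        b = _table({("r1", "cistern"): y})
        summary = compare_cells(a, b)
        assert getattr(summary, f"n_{cls}") == 1

    def test_key_mismatch_raises(self):
        a = _table({("r1", "cistern"): L.NORMAL})
        b = _table({("r2", "cistern"): L.NORMAL})
        with pytest.raises(ValueError, match="different cells"):
            compare_cells(a, b)


class TestKappa:
    def test_identical_tables_kappa_one(self):
        rng = random.Random(1)
        rows = {
            ("r%d" % i, t): rng.choice([L.ABSENT, L.PRESENT, L.NORMAL])
            for i in range(5)
            for t in CANONICAL_TARGETS
        }
        a = _table(rows)
        assert cohens_kappa(a, a) == 1.0

    def test_single_label_degenerate_tables(self):
        a = _table(_uniform(L.ABSENT))
        assert cohens_kappa(a, a) == 1.0

    def test_independent_labels_near_zero(self):
        rng = random.Random(2)
        n = 20000
        rows_a = {("r%d" % i, "cistern"): rng.choice([L.ABSENT, L.PRESENT]) for i in range(n)}
        rows_b = {("r%d" % i, "cistern"): rng.choice([L.ABSENT, L.PRESENT]) for i in range(n)}
        kappa = cohens_kappa(_table(rows_a), _table(rows_b))
        assert abs(kappa) < 0.05

    def test_matches_confusion_matrix_oracle_on_toy_table(self):
        xs = [L.ABSENT] * 5 + [L.PRESENT] * 4 + [L.NORMAL] * 3
        ys = [L.ABSENT] * 4 + [L.PRESENT] + [L.PRESENT] * 3 + [L.ABSENT] + [L.NORMAL] * 2 + [L.PRESENT]
        cells = [("r%d" % i, "cistern") for i in range(12)]
        a = _table(dict(zip(cells, xs)))
        b = _table(dict(zip(cells, ys)))
        assert cohens_kappa(a, b) == pytest.approx(kappa_oracle(xs, ys))

    def test_symmetric(self):
        rng = random.Random(3)
        cells = [("r%d" % i, "cistern") for i in range(50)]
        a = _table({c: rng.choice(list(L)) for c in cells})
        b = _table({c: rng.choice(list(L)) for c in cells})
        assert cohens_kappa(a, b) == pytest.approx(cohens_kappa(b, a))

    def test_empty_tables_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa(_table({}), _table({}))


class TestGoldStandard:
    def test_keeps_only_equivalent_cells(self):
        a = _table({("r1", "cistern"): L.NORMAL, ("r1", "atrophy"): L.ABSENT})
        b = _table({("r1", "cistern"): L.NORMAL, ("r1", "atrophy"): L.PRESENT})
        gold = gold_standard(a, b)
        assert set(gold.rows) == {("r1", "cistern")}


class TestConfusionCounts:
    def test_basic_cells(self):
        gold = _table(
            {
                ("r1", "atrophy"): L.PRESENT,
                ("r1", "cistern"): L.ABSENT,
                ("r1", "swelling"): L.PRESENT,
                ("r1", "ischemia"): L.ABSENT,
            }
        )
        pred = _table(
            {
                ("r1", "atrophy"): L.PRESENT,  # TP
                ("r1", "cistern"): L.ABSENT,  # TN
                ("r1", "swelling"): L.ABSENT,  # FN
                ("r1", "ischemia"): L.PRESENT,  # FP
            }
        )
        c = confusion_counts(pred, gold, "case1")
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 1, 1)
        assert c.n_scored == 4

    def test_suspected_positive_only_in_case2(self):
        gold = _table({("r1", "atrophy"): L.SUSPECTED})
        pred = _table({("r1", "atrophy"): L.SUSPECTED})
        c1 = confusion_counts(pred, gold, "case1")
        assert c1.n_scored == 0 and c1.n_excluded == 1
        c2 = confusion_counts(pred, gold, "case2")
        assert c2.tp == 1

    def test_case2_tp_never_below_case1(self):
        rng = random.Random(4)
        pool = [L.PRESENT, L.SUSPECTED, L.ABSENT, L.NORMAL, L.ABNORMAL, L.INDETERMINATE]
        for _ in range(50):
            cells = [("r%d" % i, "atrophy") for i in range(30)]
            gold = _table({c: rng.choice(pool) for c in cells})
            pred = _table({c: rng.choice(pool) for c in cells})
            c1 = confusion_counts(pred, gold, "case1")
            c2 = confusion_counts(pred, gold, "case2")
            assert c2.tp >= c1.tp

    def test_strict_mode_scores_every_cell(self):
        gold = _table({("r1", "atrophy"): L.INDETERMINATE, ("r1", "cistern"): L.ABSENT})
        pred = _table({("r1", "atrophy"): L.ABSENT, ("r1", "cistern"): L.INDETERMINATE})
        c = confusion_counts(pred, gold, "case1", strict=True)
        assert c.n_excluded == 0
        assert c.n_scored == 2

    def test_missing_pred_cells_raise(self):
        gold = _table({("r1", "atrophy"): L.PRESENT})
        with pytest.raises(ValueError, match="missing"):
            confusion_counts(_table({}), gold, "case1")


class TestClassificationMetrics:
    def test_perfect_counts_all_one(self):
        m = classification_metrics(ConfusionCounts(tp=1, tn=1, fp=0, fn=0, case="case1"))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy, m.f1) == (
            1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_hand_computed_example(self):
        m = classification_metrics(ConfusionCounts(tp=75, tn=922, fp=0, fn=3, case="case1"))
        assert m.sensitivity == pytest.approx(75 / 78)
        assert m.specificity == 1.0
        assert m.f1 == pytest.approx(2 * 1.0 * (75 / 78) / (1.0 + 75 / 78))

    def test_zero_denominator_flagged_not_zero(self):
        m = classification_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=5, case="case1"))
        assert m.sensitivity == 0.0
        assert m.ppv is None
        assert m.f1 is None

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(ConfusionCounts(tp=0, tn=0, fp=0, fn=0, case="case1"))

    def test_matches_direct_arithmetic_on_random_counts(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            tp, tn, fp, fn = (int(x) for x in rng.integers(0, 50, size=4))
            if tp + tn + fp + fn == 0:
                continue
            m = classification_metrics(ConfusionCounts(tp, tn, fp, fn, "case1"))
            if tp + fn:
                assert m.sensitivity == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert m.specificity == pytest.approx(tn / (tn + fp))
            if tp + fp:
                assert m.ppv == pytest.approx(tp / (tp + fp))
            if tn + fn:
                assert m.npv == pytest.approx(tn / (tn + fn))
            assert m.accuracy == pytest.approx((tp + tn) / (tp + tn + fp + fn))
            if m.ppv and m.sensitivity:
                assert m.f1 == pytest.approx(
                    2 * m.ppv * m.sensitivity / (m.ppv + m.sensitivity)
                )


class TestPerTargetErrors:
    def _random_tables(self, rng, n_reports=20):
        pool = [L.PRESENT, L.SUSPECTED, L.ABSENT, L.NORMAL, L.ABNORMAL]
        cells = [(f"r{i}", t) for i in range(n_reports) for t in CANONICAL_TARGETS]
        gold = _table({c: rng.choice(pool) for c in cells})
        pred = _table({c: rng.choice(pool) for c in cells})
        return pred, gold

    def test_perfect_prediction(self):
        rng = random.Random(6)
        _, gold = self._random_tables(rng)
        df = per_target_errors(gold, gold, "case1")
        assert (df["fn"] == 0).all() and (df["fp"] == 0).all()
        nonzero = df[df["occurrences"] > 0]
        assert (nonzero["f1"] == 1.0).all()
        assert list(df.index) == list(CANONICAL_TARGETS)

    def test_single_injected_miss_is_local(self):
        gold_rows = {(f"r{i}", t): L.ABSENT for i in range(3) for t in CANONICAL_TARGETS}
        gold_rows[("r0", "contusion")] = L.PRESENT
        pred_rows = dict(gold_rows)
        pred_rows[("r0", "contusion")] = L.ABSENT
        df = per_target_errors(_table(pred_rows), _table(gold_rows), "case1")
        assert df.loc["contusion", "fn"] == 1
        others = df.drop(index="contusion")
        assert (others["fn"] == 0).all() and (others["fp"] == 0).all()

    def test_rows_match_brute_force_recomputation(self):
        rng = random.Random(7)
        pred, gold = self._random_tables(rng)
        df = per_target_errors(pred, gold, "case2")
        positive = {L.PRESENT, L.SUSPECTED, L.ABNORMAL}
        negative = {L.ABSENT, L.NORMAL}
        for t in CANONICAL_TARGETS:
            tp = fp = fn = occ = 0
            for cell, g in gold.rows.items():
                if cell[1] != t:
                    continue
                p = pred.rows[cell]
                if g in positive:
                    occ += 1
                if p in positive and g in positive:
                    tp += 1
                elif p in positive and g in negative:
                    fp += 1
                elif p in negative and g in positive:
                    fn += 1
            assert df.loc[t, "occurrences"] == occ
            assert df.loc[t, "fn"] == fn
            assert df.loc[t, "fp"] == fp
            if tp:
                expected_f1 = 2 * tp / (2 * tp + fp + fn)
                assert df.loc[t, "f1"] == pytest.approx(expected_f1)
            elif fp + fn == 0 and occ == 0:
                assert math.isnan(df.loc[t, "f1"])

    def test_counts_sum_to_global_confusion(self):
        rng = random.Random(8)
        pred, gold = self._random_tables(rng)
        df = per_target_errors(pred, gold, "case1")
        c = confusion_counts(pred, gold, "case1")
        assert df["fn"].sum() == c.fn
        assert df["fp"].sum() == c.fp
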