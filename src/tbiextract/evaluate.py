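"""Evaluation of annotation tables: agreement, kappa, confusion metrics.

An :class:`AnnotationTable` is a (report, target) -> label mapping, either
from a human annotator or from the extractor.  Two annotators are
compared cell-wise (equivalent / similar / divergent) and with Cohen's
kappa over the full multi-label confusion matrix.  The extractor is then
scored against the gold standard — the cells where both annotators agree —
under two positivity cases:

* case 1: positive = {PRESENT, ABNORMAL}
* case 2: positive = {PRESENT, SUSPECTED, ABNORMAL}

with negative = {ABSENT, NORMAL} in both.  Cells whose predicted or gold
label falls outside positive and negative sets (e.g. INDETERMINATE) are
excluded from the counts by default and reported separately; a strict
mode scores every such cell as an error instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .aggregate import ReportSummary
from .labels import AnnotationLabel
from .lexicon import CANONICAL_TARGETS, canonical_target

NEGATIVE_LABELS = frozenset({AnnotationLabel.ABSENT, AnnotationLabel.NORMAL})
POSITIVE_LABELS_CASE1 = frozenset({AnnotationLabel.PRESENT, AnnotationLabel.ABNORMAL})
POSITIVE_LABELS_CASE2 = POSITIVE_LABELS_CASE1 | {AnnotationLabel.SUSPECTED}

Cell = tuple[str, str]


@dataclass(frozen=True)
class AnnotationTable:
    """Labels for every (report, target) cell from one source."""

    rows: Mapping[Cell, AnnotationLabel]
    source: str = ""

    @classmethod
    def from_summaries(
        cls, summaries: Iterable[ReportSummary], source: str = "algorithm"
    ) -> "AnnotationTable":
        rows: dict[Cell, AnnotationLabel] = {}
        for s in summaries:
            for t, lab in s.labels.items():
                rows[(s.report_id, t)] = lab
        return cls(rows=rows, source=source)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, source: str = "") -> "AnnotationTable":
        rows = {
            (str(r.report_id), canonical_target(str(r.target))): AnnotationLabel.parse(
                str(r.annotation)
            )
            for r in df.itertuples()
        }
        return cls(rows=rows, source=source)

    @classmethod
    def from_csv(cls, path: str | Path, source: str = "") -> "AnnotationTable":
        return cls.from_dataframe(pd.read_csv(path), source=source)

    def to_dataframe(self) -> pd.DataFrame:
        recs = [
            {"report_id": rid, "target": t, "annotation": lab.value, "source": self.source}
            for (rid, t), lab in sorted(self.rows.items())
        ]
        return pd.DataFrame.from_records(
            recs, columns=["report_id", "target", "annotation", "source"]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def restrict(self, cells: Iterable[Cell]) -> "AnnotationTable":
        cells = set(cells)
        return AnnotationTable(
            rows={c: lab for c, lab in self.rows.items() if c in cells},
            source=self.source,
        )


@dataclass(frozen=True)
class AgreementSummary:
    n_equivalent: int
    n_similar: int
    n_divergent: int
    n_other: int
    n_total: int
    kappa: float | None = None


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    case: str
    n_excluded: int = 0

    @property
    def n_scored(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """The six classification metrics; None marks a zero-denominator metric."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    f1: float | None


def _check_keys(a: AnnotationTable, b: AnnotationTable) -> None:
    if set(a.rows) != set(b.rows):
        only_a = sorted(set(a.rows) - set(b.rows))[:5]
        only_b = sorted(set(b.rows) - set(a.rows))[:5]
        raise ValueError(
            f"annotation tables cover different cells; e.g. only in first: {only_a}, "
            f"only in second: {only_b}"
        )


def _cell_class(x: AnnotationLabel, y: AnnotationLabel) -> str:
    if x == y:
        return "equivalent"
    if {x, y} == {AnnotationLabel.PRESENT, AnnotationLabel.SUSPECTED}:
        return "similar"
    low = {AnnotationLabel.ABSENT, AnnotationLabel.NORMAL}
    high = {AnnotationLabel.PRESENT, AnnotationLabel.ABNORMAL}
    if (x in low and y in high) or (x in high and y in low):
        return "divergent"
    return "other"


def compare_cells(a: AnnotationTable, b: AnnotationTable) -> AgreementSummary:
    """Classify every shared cell as equivalent, similar, divergent or other."""
    _check_keys(a, b)
    counts = {"equivalent": 0, "similar": 0, "divergent": 0, "other": 0}
    for cell, lab_a in a.rows.items():
        counts[_cell_class(lab_a, b.rows[cell])] += 1
    return AgreementSummary(
        n_equivalent=counts["equivalent"],
        n_similar=counts["similar"],
        n_divergent=counts["divergent"],
        n_other=counts["other"],
        n_total=len(a.rows),
    )


def cohens_kappa(a: AnnotationTable, b: AnnotationTable) -> float:
    """Cohen's kappa over the full multi-label confusion matrix."""
    _check_keys(a, b)
    if not a.rows:
        raise ValueError("cannot compute kappa on empty tables")
    cells = sorted(a.rows)
    xs = [a.rows[c].value for c in cells]
    ys = [b.rows[c].value for c in cells]
    if xs == ys:
        return 1.0  # includes the single-label degenerate case (p_e = 1)
    kappa = cohen_kappa_score(xs, ys)
    return float(kappa)


def gold_standard(a: AnnotationTable, b: AnnotationTable) -> AnnotationTable:
    """Cells where two annotators are equivalent, labelled with their shared label."""
    _check_keys(a, b)
    rows = {c: lab for c, lab in a.rows.items() if b.rows[c] == lab}
    return AnnotationTable(rows=rows, source="gold")


def confusion_counts(
    pred: AnnotationTable,
    gold: AnnotationTable,
    case: str = "case1",
    *,
    strict: bool = False,
) -> ConfusionCounts:
    """TP/TN/FP/FN under the stated positivity case, over gold's cells.

    ``pred`` must cover every gold cell.  With ``strict=True`` cells whose
    predicted or gold label lies outside positive and negative sets are
    scored as errors (FP when the gold label is negative, FN otherwise)
    rather than excluded.
    """
    positive = _positive_set(case)
    missing = sorted(set(gold.rows) - set(pred.rows))[:5]
    if missing:
        raise ValueError(f"prediction table missing gold cells, e.g. {missing}")

    tp = tn = fp = fn = excluded = 0
    for cell, g in gold.rows.items():
        p = pred.rows[cell]
        p_pos = p in positive
        p_neg = p in NEGATIVE_LABELS
        g_pos = g in positive
        g_neg = g in NEGATIVE_LABELS
        if p_pos and g_pos:
            tp += 1
        elif p_neg and g_neg:
            tn += 1
        elif p_pos and g_neg:
            fp += 1
        elif p_neg and g_pos:
            fn += 1
        elif strict:
            # at least one side unclassifiable: an error charged against pred
            if p_pos or (not p_neg and g_neg):
                fp += 1
            else:
                fn += 1
        else:
            excluded += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn, case=case, n_excluded=excluded)


def _positive_set(case: str) -> frozenset[AnnotationLabel]:
    if case == "case1":
        return POSITIVE_LABELS_CASE1
    if case == "case2":
        return POSITIVE_LABELS_CASE2
    raise ValueError(f"case must be 'case1' or 'case2', got {case!r}")


def classification_metrics(c: ConfusionCounts) -> MetricSet:
    """Sensitivity, specificity, PPV, NPV, accuracy and F1 from the counts."""
    if c.n_scored == 0:
        raise ValueError("cannot compute metrics from all-zero confusion counts")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    sens = ratio(c.tp, c.tp + c.fn)
    spec = ratio(c.tn, c.tn + c.fp)
    ppv = ratio(c.tp, c.tp + c.fp)
    npv = ratio(c.tn, c.tn + c.fn)
    acc = (c.tp + c.tn) / c.n_scored
    if ppv is None or sens is None or (ppv + sens) == 0:
        f1 = None
    else:
        f1 = 2 * ppv * sens / (ppv + sens)
    return MetricSet(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv, accuracy=acc, f1=f1
    )


def per_target_errors(
    pred: AnnotationTable,
    gold: AnnotationTable,
    case: str = "case1",
    *,
    strict: bool = False,
) -> pd.DataFrame:
    """Per-target occurrences, FN, FP and F1, in the canonical target order.

    Occurrences count gold-positive cells for the target; F1 is NaN where
    undefined (no gold positives and no false positives).
    """
    positive = _positive_set(case)
    records = []
    for t in CANONICAL_TARGETS:
        cells = [c for c in gold.rows if c[1] == t]
        sub_gold = gold.restrict(cells)
        sub_pred = pred.restrict(set(pred.rows) & set(cells))
        c = confusion_counts(sub_pred, sub_gold, case, strict=strict)
        occurrences = sum(1 for cell in cells if gold.rows[cell] in positive)
        m = classification_metrics(c) if c.n_scored else None
        records.append(
            {
                "target": t,
                "occurrences": occurrences,
                "fn": c.fn,
                "fp": c.fp,
                "f1": (m.f1 if m and m.f1 is not None else math.nan),
            }
        )
    return pd.DataFrame.from_records(records).set_index("target")


def agreement_report(a: AnnotationTable, b: AnnotationTable) -> AgreementSummary:
    """Cell-agreement counts plus Cohen's kappa in one summary."""
    base = compare_cells(a, b)
    return AgreementSummary(
        n_equivalent=base.n_equivalent,
        n_similar=base.n_similar,
        n_divergent=base.n_divergent,
        n_other=base.n_other,
        n_total=base.n_total,
        kappa=cohens_kappa(a, b),
    )
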