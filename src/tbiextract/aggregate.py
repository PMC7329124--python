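"""Report-level aggregation of sentence votes into the 27-row summary.

Three decision-rule stages collapse per-sentence (target, label) votes
into one annotation per common data element:

* *omitted targets* — unmentioned targets receive their default
  annotation: NORMAL for gray-white differentiation and the cisterns,
  ABSENT for the other 25;
* *duplicate targets* — a target mentioned in several sentences takes the
  majority label; when the maximal count ties, the earliest of the tied
  labels in that target's ordered annotation list wins;
* *derived targets* — cross-target inference: a specific extraaxial
  hemorrhage suppresses hemorrhage NOS, asserts an extraaxial fluid
  collection, and any positive trigger finding asserts intracranial
  pathology.

Between the duplicate and derived stages, labels outside a target's
allowed set are replaced with their configured counterpart (e.g. an
ABSENT cistern becomes a NORMAL cistern).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, MutableMapping, Sequence

from .labels import AnnotationLabel
from .lexicon import (
    CANONICAL_TARGETS,
    LexicalEntry,
    TargetCatalog,
    build_catalog,
    canonical_target,
)
from .markup import TargetAssignment, assignments_for_report
from .preprocess import CleanReport

_POSITIVE = (AnnotationLabel.PRESENT, AnnotationLabel.SUSPECTED)

#: Specific extraaxial hemorrhages that drive the derived rules.
HEMORRHAGE_TRIGGERS: tuple[str, ...] = (
    "epidural hemorrhage",
    "subdural hemorrhage",
    "subarachnoid hemorrhage",
)

#: Findings whose positive annotation implies intracranial pathology.
DEFAULT_PATHOLOGY_TRIGGERS: tuple[str, ...] = (
    "gray-white differentiation",
    "cistern",
    "hydrocephalus",
    "pneumocephalus",
    "extraaxial fluid collection",
    "midline shift",
    "mass effect",
    "diffuse axonal injury",
    "anoxic",
    "herniation",
    "aneurysm",
    "contusion",
    "swelling",
    "ischemia",
    "hemorrhage nos",
    "intraventricular hemorrhage",
    "intraparenchymal hemorrhage",
)


@dataclass(frozen=True)
class ReportSummary:
    """The structured summary: all 27 targets, one annotation each."""

    report_id: str
    labels: Mapping[str, AnnotationLabel]
    provenance: Mapping[str, str]

    def __post_init__(self) -> None:
        if set(self.labels) != set(CANONICAL_TARGETS):
            raise ValueError("summary must carry exactly the 27 catalog targets")
        if AnnotationLabel.NOT_SPECIFIED in self.labels.values():
            raise ValueError("NOT_SPECIFIED is never emitted by the extractor")

    def rows(self) -> list[tuple[str, str, str]]:
        """(target, annotation, provenance) rows in canonical order."""
        return [
            (t, self.labels[t].value, self.provenance.get(t, ""))
            for t in CANONICAL_TARGETS
        ]


def fill_omitted(
    assignments: Iterable[TargetAssignment], catalog: TargetCatalog
) -> list[TargetAssignment]:
    """Add a default-label vote for every catalog target with no vote."""
    out = list(assignments)
    seen = {canonical_target(a.target) for a in out}
    for t in catalog.targets:
        if t not in seen:
            out.append(
                TargetAssignment(
                    target=t,
                    label=catalog.default_label(t),
                    sentence_index=-1,
                    source="default",
                )
            )
    return out


def resolve_duplicates(
    assignments: Iterable[TargetAssignment],
    catalog: TargetCatalog,
    *,
    return_provenance: bool = False,
):
    """Majority vote per target; ties fall to the ordered annotation list.

    With ``return_provenance=True`` also returns target -> one of
    ``matched`` / ``default`` / ``tie_break``.
    """
    votes: dict[str, list[TargetAssignment]] = {}
    for a in assignments:
        votes.setdefault(canonical_target(a.target), []).append(a)
    missing = [t for t in catalog.targets if t not in votes]
    if missing:
        raise ValueError(f"no assignment for targets {missing}; run fill_omitted first")

    labels: dict[str, AnnotationLabel] = {}
    provenance: dict[str, str] = {}
    for t, tvotes in votes.items():
        counts = Counter(a.label for a in tvotes)
        top = max(counts.values())
        tied = [lab for lab, c in counts.items() if c == top]
        if len(tied) == 1:
            labels[t] = tied[0]
            provenance[t] = (
                "default" if all(a.source == "default" for a in tvotes) else "matched"
            )
        else:
            order = catalog.ordered_list(t)
            labels[t] = min(tied, key=lambda lab: _order_index(order, lab))
            provenance[t] = "tie_break"
    if return_provenance:
        return labels, provenance
    return labels


def _order_index(order: Sequence[AnnotationLabel], label: AnnotationLabel) -> int:
    try:
        return order.index(label)
    except ValueError:
        return len(order)  # labels outside the ordered list lose all ties


def replace_disallowed(
    labels: Mapping[str, AnnotationLabel], catalog: TargetCatalog
) -> dict[str, AnnotationLabel]:
    """Swap labels outside a target's allowed set for their counterpart."""
    out: dict[str, AnnotationLabel] = {}
    for t, lab in labels.items():
        t = canonical_target(t)
        out[t] = lab if lab in catalog.allowed_labels(t) else catalog.counterpart(t, lab)
    return out


def apply_derived_rules(
    labels: Mapping[str, AnnotationLabel],
    catalog: TargetCatalog | None = None,
    provenance: MutableMapping[str, str] | None = None,
    pathology_triggers: Sequence[str] = DEFAULT_PATHOLOGY_TRIGGERS,
) -> dict[str, AnnotationLabel]:
    """Cross-target derived decision rules, applied in a fixed order.

    (a) any specific extraaxial hemorrhage PRESENT or SUSPECTED
        -> hemorrhage NOS is ABSENT;
    (b) any PRESENT -> extraaxial fluid collection PRESENT; otherwise any
        SUSPECTED while the collection still holds its ABSENT default
        -> SUSPECTED;
    (c) any trigger finding PRESENT, SUSPECTED or ABNORMAL -> intracranial
        pathology PRESENT (rule c sees rule b's update).

    ``provenance``, when supplied, is updated in place: targets rewritten
    here are marked ``derived``, and it informs the "ABSENT by default"
    test in rule (b).  Without provenance, an ABSENT collection is treated
    as default-eligible.
    """
    out = dict(labels)
    hem = [out.get(t) for t in HEMORRHAGE_TRIGGERS]

    def _set(target: str, label: AnnotationLabel) -> None:
        if out.get(target) != label or (provenance or {}).get(target) != "derived":
            out[target] = label
            if provenance is not None:
                provenance[target] = "derived"

    # (a) specific hemorrhage suppresses the unspecified-hemorrhage target
    if any(lab in _POSITIVE for lab in hem):
        _set("hemorrhage nos", AnnotationLabel.ABSENT)

    # (b) specific hemorrhage implies an extraaxial fluid collection
    efc = "extraaxial fluid collection"
    if any(lab is AnnotationLabel.PRESENT for lab in hem):
        _set(efc, AnnotationLabel.PRESENT)
    elif any(lab is AnnotationLabel.SUSPECTED for lab in hem):
        efc_default = (
            provenance.get(efc) in ("default", None) if provenance is not None else True
        )
        if out.get(efc) is AnnotationLabel.ABSENT and efc_default:
            _set(efc, AnnotationLabel.SUSPECTED)

    # (c) any positive trigger finding implies intracranial pathology
    positive = (
        AnnotationLabel.PRESENT,
        AnnotationLabel.SUSPECTED,
        AnnotationLabel.ABNORMAL,
    )
    if any(out.get(canonical_target(t)) in positive for t in pathology_triggers):
        _set("intracranial pathology", AnnotationLabel.PRESENT)

    return out


def summarize_assignments(
    report_id: str,
    assignments: Iterable[TargetAssignment],
    catalog: TargetCatalog,
    pathology_triggers: Sequence[str] = DEFAULT_PATHOLOGY_TRIGGERS,
) -> ReportSummary:
    """Aggregate pooled sentence votes into a ReportSummary."""
    filled = fill_omitted(assignments, catalog)
    labels, provenance = resolve_duplicates(filled, catalog, return_provenance=True)
    labels = replace_disallowed(labels, catalog)
    labels = apply_derived_rules(
        labels, catalog, provenance=provenance, pathology_triggers=pathology_triggers
    )
    return ReportSummary(report_id=report_id, labels=labels, provenance=provenance)


def summarize_report(
    report: CleanReport,
    targets: Sequence[LexicalEntry],
    modifiers: Sequence[LexicalEntry],
    catalog: TargetCatalog | None = None,
    pathology_triggers: Sequence[str] = DEFAULT_PATHOLOGY_TRIGGERS,
) -> ReportSummary:
    """Full extraction pipeline for one cleaned report."""
    if catalog is None:
        catalog = build_catalog(targets)
    assignments = assignments_for_report(report.sentences, targets, modifiers)
    return summarize_assignments(
        report.report_id, assignments, catalog, pathology_triggers
    )
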