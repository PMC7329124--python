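"""Seeded synthetic head-CT reports with known ground-truth summaries.

Each generated report mimics a short institutional radiology narrative:
an exam/history preamble, a FINDINGS section of roughly 9-15 sentences, an
IMPRESSION section, and a signature trailer.  Findings sentences are drawn
from a template bank keyed by (target, label): negation phrasings for
ABSENT, hedges for SUSPECTED, multi-etiology phrasing for INDETERMINATE,
and so on.  Unseeded targets go unmentioned, so they exercise the default
annotations.

Two ground truths accompany every report:

* ``truth`` — what a human reader would conclude, including mentions that
  are deliberately phrased outside the starter lexicon's coverage;
* ``visible_truth`` — the conclusion reachable from lexicon-covered
  mentions only.

On a non-adversarial corpus the two coincide and the extractor should
reproduce them exactly; on an adversarial corpus every extractor/truth
mismatch is attributable to a cell where the two differ, which mirrors the
documented failure modes of lexicon-based extraction (unmatched target
phrasings, findings with no nearby assertion phrase, stale smart-phrase
boilerplate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .aggregate import ReportSummary, summarize_assignments
from .labels import AnnotationLabel
from .lexicon import CANONICAL_TARGETS, NORMAL_DEFAULT_TARGETS, TargetCatalog, build_catalog
from .markup import TargetAssignment
from .preprocess import RawReport

#: The boilerplate blanket-negation sentence and the targets it asserts ABSENT.
SMARTPHRASE = (
    "There is no evidence of intracranial hemorrhage, mass effect, "
    "midline shift or abnormal extraaxial fluid collection."
)
SMARTPHRASE_TARGETS: tuple[str, ...] = (
    "hemorrhage nos",
    "mass effect",
    "midline shift",
    "extraaxial fluid collection",
)

#: Surface phrase and plurality used to render each target in templates.
TARGET_SURFACES: dict[str, tuple[str, bool]] = {
    "intraparenchymal hemorrhage": ("intraparenchymal hemorrhage", False),
    "facial fracture": ("facial fracture", False),
    "extraaxial fluid collection": ("extraaxial fluid collection", False),
    "hypodensities": ("hypodensities", True),
    "skull fracture": ("skull fracture", False),
    "intraventricular hemorrhage": ("intraventricular hemorrhage", False),
    "herniation": ("herniation", False),
    "mass effect": ("mass effect", False),
    "subarachnoid hemorrhage": ("subarachnoid hemorrhage", False),
    "subdural hemorrhage": ("subdural hematoma", False),
    "hyperdensities": ("hyperdensities", True),
    "atrophy": ("atrophy", False),
    "contusion": ("contusion", False),
    "hemorrhage nos": ("intracranial hemorrhage", False),
    "swelling": ("brain swelling", False),
    "pneumocephalus": ("pneumocephalus", False),
    "ischemia": ("ischemia", False),
    "epidural hemorrhage": ("epidural hematoma", False),
    "anoxic": ("anoxic brain injury", False),
    "aneurysm": ("aneurysm", False),
    "hydrocephalus": ("hydrocephalus", False),
    "intracranial pathology": ("intracranial pathology", False),
    "gray-white differentiation": ("gray-white differentiation", False),
    "cistern": ("basal cisterns", True),
    "midline shift": ("midline shift", False),
    "diffuse axonal injury": ("diffuse axonal injury", False),
    "microhemorrhage": ("microhemorrhages", True),
}

# {t}: surface; {T}: capitalized surface; {is}/{was}: number-agreed verb
_TEMPLATES: dict[AnnotationLabel, tuple[str, ...]] = {
    AnnotationLabel.PRESENT: (
        "There is evidence of {t}.",
        "{T} {is} present.",
        "{T} {is} identified.",
        "{T} {is} seen.",
    ),
    AnnotationLabel.ABSENT: (
        "No {t}.",
        "There is no evidence of {t}.",
        "{T} {is} not seen.",
        "No {t} {is} identified.",
    ),
    AnnotationLabel.SUSPECTED: (
        "Possible {t}.",
        "Findings suspicious for {t}.",
        "{T} may be present.",
    ),
    AnnotationLabel.INDETERMINATE: (
        "{T} {was} not excluded.",
        "{T} cannot be excluded.",
    ),
    AnnotationLabel.NORMAL: (
        "The {t} {is} normal.",
        "The {t} {is} within normal limits.",
    ),
    AnnotationLabel.ABNORMAL: (
        "The {t} {is} abnormal.",
        "The {t} {is} effaced.",
    ),
}

_TEMPLATE_OVERRIDES: dict[tuple[str, AnnotationLabel], tuple[str, ...]] = {
    ("gray-white differentiation", AnnotationLabel.NORMAL): (
        "Gray-white differentiation is preserved.",
        "The gray-white differentiation is normal.",
    ),
    ("gray-white differentiation", AnnotationLabel.ABNORMAL): (
        "The gray-white differentiation is effaced.",
    ),
    ("cistern", AnnotationLabel.NORMAL): (
        "The basal cisterns are patent.",
        "The basal cisterns are normal.",
    ),
    ("cistern", AnnotationLabel.ABNORMAL): (
        "Effacement of the basal cisterns.",
    ),
}

#: PRESENT-label phrasings deliberately outside starter-lexicon coverage;
#: a human reads the finding, the lexicon-driven extractor cannot.
OUT_OF_COVERAGE: dict[str, tuple[str, ...]] = {
    "atrophy": ("There is cerebellar volume loss.",),
    "facial fracture": (
        "Fracture through the anterior wall of the maxillary sinus is noted.",
    ),
    "intraparenchymal hemorrhage": (
        "Focal intra-axial blood products in the right temporal lobe.",
    ),
    "subdural hemorrhage": (
        "Thin crescentic extracerebral collection along the left convexity.",
    ),
    "herniation": (
        "Downward displacement of the cerebellar tonsils below the foramen magnum.",
    ),
    "contusion": ("Hemorrhagic foci within the bifrontal parenchyma.",),
}

#: Filler sentences with no lexical-target hits.
FILLERS: tuple[str, ...] = (
    "The visualized paranasal sinuses are clear.",
    "The mastoid air cells are well aerated.",
    "The calvarium is intact.",
    "The sella is unremarkable.",
    "Comparison is made with the prior examination.",
    "The patient is status post recent trauma.",
    "The globes are intact.",
    "The craniocervical junction is maintained.",
    "Mild mucosal thickening of the ethmoid air cells.",
    "The soft tissues of the scalp are unremarkable.",
)

_HISTORIES: tuple[str, ...] = (
    "Fall from standing height.",
    "Motor vehicle collision.",
    "Assault with loss of consciousness.",
    "Found down, trauma evaluation.",
)

#: Default per-target mention probabilities, shaped after the relative
#: frequencies of findings reported for an institutional trauma corpus.
DEFAULT_PREVALENCE: dict[str, float] = {
    "intraparenchymal hemorrhage": 0.12,
    "facial fracture": 0.12,
    "extraaxial fluid collection": 0.10,
    "hypodensities": 0.15,
    "skull fracture": 0.12,
    "intraventricular hemorrhage": 0.08,
    "herniation": 0.06,
    "mass effect": 0.15,
    "subarachnoid hemorrhage": 0.25,
    "subdural hemorrhage": 0.20,
    "hyperdensities": 0.12,
    "atrophy": 0.12,
    "contusion": 0.08,
    "hemorrhage nos": 0.08,
    "swelling": 0.08,
    "pneumocephalus": 0.08,
    "ischemia": 0.05,
    "epidural hemorrhage": 0.05,
    "anoxic": 0.02,
    "aneurysm": 0.03,
    "hydrocephalus": 0.03,
    "intracranial pathology": 0.20,
    "gray-white differentiation": 0.30,
    "cistern": 0.30,
    "midline shift": 0.20,
    "diffuse axonal injury": 0.02,
    "microhemorrhage": 0.02,
}

#: Label mix for seeded mentions of ordinary finding targets.
DEFAULT_LABEL_MIX: dict[AnnotationLabel, float] = {
    AnnotationLabel.PRESENT: 0.45,
    AnnotationLabel.ABSENT: 0.35,
    AnnotationLabel.SUSPECTED: 0.12,
    AnnotationLabel.INDETERMINATE: 0.08,
}

#: Label mix for the two anatomy-state targets (gray-white, cisterns).
DEFAULT_STATE_LABEL_MIX: dict[AnnotationLabel, float] = {
    AnnotationLabel.NORMAL: 0.60,
    AnnotationLabel.ABNORMAL: 0.22,
    AnnotationLabel.SUSPECTED: 0.10,
    AnnotationLabel.INDETERMINATE: 0.08,
}


@dataclass(frozen=True)
class GenerationConfig:
    """Knobs of the synthetic corpus generator."""

    n_reports: int = 100
    seed: int = 0
    sentence_count_range: tuple[int, int] = (9, 15)
    target_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    label_mix: Mapping[AnnotationLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_MIX)
    )
    state_label_mix: Mapping[AnnotationLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_STATE_LABEL_MIX)
    )
    smartphrase_rate: float = 0.30
    conflict_rate: float = 0.0
    adversarial_rate: float = 0.0

    def __post_init__(self) -> None:
        probs = [
            *self.target_prevalence.values(),
            *self.label_mix.values(),
            *self.state_label_mix.values(),
            self.smartphrase_rate,
            self.conflict_rate,
            self.adversarial_rate,
        ]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        unknown = set(self.target_prevalence) - set(CANONICAL_TARGETS)
        if unknown:
            raise ValueError(f"prevalence keyed by unknown targets: {sorted(unknown)}")


@dataclass(frozen=True)
class SyntheticReport:
    """A generated report with its human and lexicon-visible ground truths."""

    report: RawReport
    truth: ReportSummary
    visible_truth: ReportSummary
    adversarial_targets: frozenset[str] = frozenset()

    @property
    def is_adversarial(self) -> bool:
        return bool(self.adversarial_targets)

    def attributable_cells(self) -> frozenset[str]:
        """Targets where an extractor/truth mismatch is expected by design."""
        return frozenset(
            t
            for t in CANONICAL_TARGETS
            if self.truth.labels[t] != self.visible_truth.labels[t]
        )


def _render(target: str, label: AnnotationLabel, rng: np.random.Generator) -> str:
    bank = _TEMPLATE_OVERRIDES.get((target, label)) or _TEMPLATES[label]
    template = bank[int(rng.integers(len(bank)))]
    surface, plural = TARGET_SURFACES[target]
    return template.format(
        t=surface,
        T=surface[0].upper() + surface[1:],
        **{"is": "are" if plural else "is", "was": "were" if plural else "was"},
    )


def _draw_label(
    target: str, config: GenerationConfig, rng: np.random.Generator
) -> AnnotationLabel:
    mix = (
        config.state_label_mix
        if target in NORMAL_DEFAULT_TARGETS
        else config.label_mix
    )
    labels = list(mix.keys())
    weights = np.asarray([mix[lab] for lab in labels], dtype=float)
    weights = weights / weights.sum()
    return labels[int(rng.choice(len(labels), p=weights))]


def generate_report(
    config: GenerationConfig,
    index: int,
    catalog: TargetCatalog | None = None,
) -> SyntheticReport:
    """Generate one synthetic report; deterministic in (seed, index)."""
    if catalog is None:
        catalog = build_catalog()
    rng = np.random.default_rng([config.seed % (2**31), index])
    report_id = f"synth-{config.seed}-{index:05d}"

    # mention plan: (target, label, in_coverage)
    plan: list[tuple[str, AnnotationLabel, bool]] = []
    for t in CANONICAL_TARGETS:
        if rng.random() >= config.target_prevalence.get(t, 0.0):
            continue
        label = _draw_label(t, config, rng)
        in_coverage = True
        if (
            config.adversarial_rate > 0
            and t in OUT_OF_COVERAGE
            and label is AnnotationLabel.PRESENT
            and rng.random() < config.adversarial_rate
        ):
            in_coverage = False
        plan.append((t, label, in_coverage))

    use_smartphrase = rng.random() < config.smartphrase_rate

    sentences: list[str] = []
    human: list[TargetAssignment] = []
    visible: list[TargetAssignment] = []
    adversarial: set[str] = set()

    def _emit(sentence: str, votes: list[tuple[str, AnnotationLabel]], seen: bool) -> None:
        idx = len(sentences)
        sentences.append(sentence)
        for t, lab in votes:
            human.append(TargetAssignment(t, lab, idx))
            if seen:
                visible.append(TargetAssignment(t, lab, idx))

    if use_smartphrase:
        _emit(SMARTPHRASE, [(t, AnnotationLabel.ABSENT) for t in SMARTPHRASE_TARGETS], True)

    body: list[tuple[str, list[tuple[str, AnnotationLabel]], bool]] = []
    for t, label, in_coverage in plan:
        if in_coverage:
            body.append((_render(t, label, rng), [(t, label)], True))
            if config.conflict_rate > 0 and rng.random() < config.conflict_rate:
                # duplicate contradictory mention, outvoted 2:1 by the majority
                allowed = sorted(
                    catalog.allowed_labels(t) - {label}, key=lambda lab: lab.value
                )
                conflict = allowed[int(rng.integers(len(allowed)))]
                body.append((_render(t, label, rng), [(t, label)], True))
                body.append((_render(t, conflict, rng), [(t, conflict)], True))
        else:
            bank = OUT_OF_COVERAGE[t]
            adversarial.add(t)
            body.append((bank[int(rng.integers(len(bank)))], [(t, label)], False))

    lo, hi = config.sentence_count_range
    total = int(rng.integers(lo, hi + 1))
    n_fillers = max(0, total - len(body) - int(use_smartphrase) - 1)
    filler_idx = rng.permutation(len(FILLERS))
    for i in range(n_fillers):
        body.append((FILLERS[filler_idx[i % len(FILLERS)]], [], True))

    order = rng.permutation(len(body))
    for i in order:
        _emit(*body[i])

    # impression: restate one covered positive finding, else a blanket negative
    positives = [
        (t, lab)
        for t, lab, cov in plan
        if cov and lab is AnnotationLabel.PRESENT
    ]
    if positives:
        t, lab = positives[int(rng.integers(len(positives)))]
        impression = _render(t, lab, rng)
        impression_votes = [(t, lab)]
    else:
        impression = "No acute intracranial abnormality."
        impression_votes = [("intracranial pathology", AnnotationLabel.ABSENT)]

    history = _HISTORIES[int(rng.integers(len(_HISTORIES)))]
    findings_text = " ".join(sentences)
    text = (
        "EXAM: CT HEAD WITHOUT CONTRAST\n"
        f"CLINICAL HISTORY: {history}\n\n"
        f"FINDINGS: {findings_text}\n\n"
        f"IMPRESSION: {impression}\n\n"
        "Electronically signed by the attending radiologist."
    )

    idx = len(sentences)
    for t, lab in impression_votes:
        human.append(TargetAssignment(t, lab, idx))
        visible.append(TargetAssignment(t, lab, idx))

    truth = summarize_assignments(report_id, human, catalog)
    visible_truth = summarize_assignments(report_id, visible, catalog)
    return SyntheticReport(
        report=RawReport(report_id=report_id, text=text),
        truth=truth,
        visible_truth=visible_truth,
        adversarial_targets=frozenset(adversarial),
    )


def generate_corpus(
    config: GenerationConfig, catalog: TargetCatalog | None = None
) -> list[SyntheticReport]:
    """Generate ``config.n_reports`` independent reports from the seeded stream."""
    if catalog is None:
        catalog = build_catalog()
    return [generate_report(config, i, catalog) for i in range(config.n_reports)]
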