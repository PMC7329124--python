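"""Lexicons of lexical targets and lexical modifiers, and the target catalog.

The extraction pipeline is parameterized entirely by two tab-separated
lexicon files.  Each row is one *itemData* record::

    literal <TAB> category [<TAB> regex [<TAB> rule]]

A lexical *target* names a clinical finding to index (e.g. ``subdural
hemorrhage``); its category is the finding's name.  A lexical *modifier*
is a contextual phrase (negation, hedge, affirmation); its category is the
annotation label it assigns, and its rule says which direction its scope
extends within a sentence (forward, backward, bidirectional).

The :class:`TargetCatalog` fixes the roster of 27 traumatic-brain-injury
common data elements together with their per-target default labels, the
allowed-label sets, label counterparts for disallowed annotations, and the
ordered lists used to break majority-vote ties.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .labels import AnnotationLabel, DirectionRule


class LexiconError(ValueError):
    """A lexicon file or catalog configuration is malformed."""


#: The 27 common data elements, in the canonical reporting order.
CANONICAL_TARGETS: tuple[str, ...] = (
    "intraparenchymal hemorrhage",
    "facial fracture",
    "extraaxial fluid collection",
    "hypodensities",
    "skull fracture",
    "intraventricular hemorrhage",
    "herniation",
    "mass effect",
    "subarachnoid hemorrhage",
    "subdural hemorrhage",
    "hyperdensities",
    "atrophy",
    "contusion",
    "hemorrhage nos",
    "swelling",
    "pneumocephalus",
    "ischemia",
    "epidural hemorrhage",
    "anoxic",
    "aneurysm",
    "hydrocephalus",
    "intracranial pathology",
    "gray-white differentiation",
    "cistern",
    "midline shift",
    "diffuse axonal injury",
    "microhemorrhage",
)

#: Alternate spellings mapped onto canonical target names.
_TARGET_ALIASES: dict[str, str] = {
    "hemorrhage": "hemorrhage nos",
    "hemorrhage (nos)": "hemorrhage nos",
    "hemorrhage not otherwise specified": "hemorrhage nos",
    "brain swelling": "swelling",
    "gray white differentiation": "gray-white differentiation",
    "gray-white matter differentiation": "gray-white differentiation",
    "gray white matter differentiation": "gray-white differentiation",
    "cisterns": "cistern",
}

#: Targets whose unmentioned state is NORMAL anatomy rather than an absent finding.
NORMAL_DEFAULT_TARGETS: frozenset[str] = frozenset(
    {"gray-white differentiation", "cistern"}
)

#: Targets using the absence-first ordered annotation list for tie-breaking.
ABSENT_FIRST_TARGETS: frozenset[str] = frozenset(
    {"extraaxial fluid collection", "hemorrhage nos", "intracranial pathology"}
)

_ORDER_ABSENT_FIRST: tuple[AnnotationLabel, ...] = (
    AnnotationLabel.ABSENT,
    AnnotationLabel.INDETERMINATE,
    AnnotationLabel.SUSPECTED,
    AnnotationLabel.PRESENT,
    AnnotationLabel.NORMAL,
    AnnotationLabel.ABNORMAL,
)
_ORDER_PRESENT_FIRST: tuple[AnnotationLabel, ...] = (
    AnnotationLabel.PRESENT,
    AnnotationLabel.SUSPECTED,
    AnnotationLabel.INDETERMINATE,
    AnnotationLabel.ABSENT,
    AnnotationLabel.ABNORMAL,
    AnnotationLabel.NORMAL,
)

_ALLOWED_STATE_TARGETS: frozenset[AnnotationLabel] = frozenset(
    {
        AnnotationLabel.NORMAL,
        AnnotationLabel.ABNORMAL,
        AnnotationLabel.SUSPECTED,
        AnnotationLabel.INDETERMINATE,
    }
)
_ALLOWED_FINDING_TARGETS: frozenset[AnnotationLabel] = frozenset(
    {
        AnnotationLabel.PRESENT,
        AnnotationLabel.SUSPECTED,
        AnnotationLabel.INDETERMINATE,
        AnnotationLabel.ABSENT,
    }
)


def canonical_target(token: str) -> str:
    """Normalize a target name/category token to its canonical roster name."""
    norm = re.sub(r"\s+", " ", token.strip().lower().replace("_", " "))
    return _TARGET_ALIASES.get(norm, norm)


def _autogenerate_pattern(literal: str) -> str:
    """Build a regex from a literal: escaped, with flexible whitespace."""
    parts = [re.escape(tok) for tok in literal.split()]
    return r"\s+".join(parts)


def _compile(pattern: str, *, literal: str) -> re.Pattern[str]:
    # word-boundary anchoring + case-insensitivity applied uniformly; a lexicon
    # pattern can still override interior behaviour (lookarounds, alternation)
    wrapped = rf"\b(?:{pattern})\b"
    try:
        return re.compile(wrapped, re.IGNORECASE)
    except re.error as exc:
        raise LexiconError(f"malformed regex for literal {literal!r}: {exc}") from exc


@dataclass(frozen=True)
class LexicalEntry:
    """One lexicon row: literal phrase, category, compiled pattern, rule.

    For targets ``category`` is the canonical target name and ``rule`` is
    ``None``; for modifiers ``category`` is an :class:`AnnotationLabel` and
    ``rule`` a :class:`DirectionRule`.
    """

    literal: str
    category: str | AnnotationLabel
    pattern: str
    rule: DirectionRule | None = None
    compiled: re.Pattern[str] = field(compare=False, hash=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.compiled is None:
            object.__setattr__(self, "compiled", _compile(self.pattern, literal=self.literal))

    @property
    def is_modifier(self) -> bool:
        return isinstance(self.category, AnnotationLabel)


def load_lexicon(
    path: str | Path,
    kind: str,
    *,
    header: bool = False,
) -> list[LexicalEntry]:
    """Load a tab-separated lexicon of the given ``kind`` (target/modifier).

    Columns are literal, category, optional regex, optional rule; empty
    trailing columns are permitted.  Missing regexes are generated from the
    literal (whitespace made flexible, matching case-insensitively).
    """
    if kind not in ("target", "modifier"):
        raise ValueError(f"kind must be 'target' or 'modifier', got {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"lexicon file not found: {path}")

    entries: list[LexicalEntry] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for i, row in enumerate(reader):
            if header and i == 0:
                continue
            if not row or not "".join(row).strip():
                continue
            row = [c.strip() for c in row]
            if len(row) < 2 or not row[0] or not row[1]:
                raise LexiconError(f"{path}:{i + 1}: need at least literal and category")
            literal, cat_token = row[0], row[1]
            pattern = row[2] if len(row) > 2 and row[2] else _autogenerate_pattern(literal)
            rule_token = row[3] if len(row) > 3 and row[3] else ""

            if kind == "modifier":
                try:
                    category: str | AnnotationLabel = AnnotationLabel.parse(cat_token)
                except ValueError:
                    raise LexiconError(
                        f"{path}:{i + 1}: unknown modifier category {cat_token!r}"
                    ) from None
                if not rule_token:
                    raise LexiconError(f"{path}:{i + 1}: modifier row missing direction rule")
                try:
                    rule: DirectionRule | None = DirectionRule.parse(rule_token)
                except ValueError:
                    raise LexiconError(
                        f"{path}:{i + 1}: unknown direction rule {rule_token!r}"
                    ) from None
            else:
                category = canonical_target(cat_token)
                rule = None
                if rule_token:
                    raise LexiconError(f"{path}:{i + 1}: target rows take no direction rule")

            entries.append(LexicalEntry(literal=literal, category=category, pattern=pattern, rule=rule))
    return entries


def write_lexicon(entries: Iterable[LexicalEntry], path: str | Path) -> None:
    """Write entries back to TSV (literal, category, pattern, rule)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        for e in entries:
            cat = e.category.value if isinstance(e.category, AnnotationLabel) else e.category
            writer.writerow([e.literal, cat, e.pattern, e.rule.value if e.rule else ""])


@dataclass(frozen=True)
class TargetCatalog:
    """The fixed roster of 27 targets with their label semantics.

    ``counterpart`` maps a (target, disallowed label) pair to the label the
    extractor substitutes; ``ordered_list`` gives the per-target preference
    order used when a majority vote among duplicate mentions ties.
    """

    targets: tuple[str, ...]
    _defaults: Mapping[str, AnnotationLabel]
    _allowed: Mapping[str, frozenset[AnnotationLabel]]
    _counterpart: Mapping[tuple[str, AnnotationLabel], AnnotationLabel]
    _ordered: Mapping[str, tuple[AnnotationLabel, ...]]

    def default_label(self, target: str) -> AnnotationLabel:
        return self._defaults[canonical_target(target)]

    def allowed_labels(self, target: str) -> frozenset[AnnotationLabel]:
        return self._allowed[canonical_target(target)]

    def ordered_list(self, target: str) -> tuple[AnnotationLabel, ...]:
        return self._ordered[canonical_target(target)]

    def counterpart(self, target: str, label: AnnotationLabel) -> AnnotationLabel:
        key = (canonical_target(target), label)
        if key not in self._counterpart:
            raise LexiconError(
                f"no counterpart configured for disallowed label {label} on target {key[0]!r}"
            )
        return self._counterpart[key]

    def __contains__(self, target: str) -> bool:
        return canonical_target(target) in self._defaults


def build_catalog(
    target_entries: Iterable[LexicalEntry] | None = None,
    config: Mapping[str, object] | None = None,
) -> TargetCatalog:
    """Build the 27-target catalog, optionally validated against a lexicon.

    ``config`` may override ``counterparts`` (list of [target, from, to]),
    ``ordered_lists`` (target -> label sequence), ``allowed_labels``
    (target -> label set) and ``defaults`` (target -> label).  When target
    lexicon entries are supplied their categories must cover exactly the 27
    roster names.
    """
    config = dict(config or {})

    if target_entries is not None:
        seen = {canonical_target(str(e.category)) for e in target_entries}
        missing = sorted(set(CANONICAL_TARGETS) - seen)
        extra = sorted(seen - set(CANONICAL_TARGETS))
        if missing or extra:
            raise LexiconError(
                f"target lexicon must cover exactly the 27 catalog targets; "
                f"missing={missing}, extra={extra}"
            )

    defaults: dict[str, AnnotationLabel] = {}
    allowed: dict[str, frozenset[AnnotationLabel]] = {}
    ordered: dict[str, tuple[AnnotationLabel, ...]] = {}
    counterpart: dict[tuple[str, AnnotationLabel], AnnotationLabel] = {}

    for t in CANONICAL_TARGETS:
        if t in NORMAL_DEFAULT_TARGETS:
            defaults[t] = AnnotationLabel.NORMAL
            allowed[t] = frozenset(_ALLOWED_STATE_TARGETS)
            counterpart[(t, AnnotationLabel.ABSENT)] = AnnotationLabel.NORMAL
            counterpart[(t, AnnotationLabel.PRESENT)] = AnnotationLabel.ABNORMAL
            counterpart[(t, AnnotationLabel.NOT_SPECIFIED)] = AnnotationLabel.NORMAL
        else:
            defaults[t] = AnnotationLabel.ABSENT
            allowed[t] = frozenset(_ALLOWED_FINDING_TARGETS)
            counterpart[(t, AnnotationLabel.NORMAL)] = AnnotationLabel.ABSENT
            counterpart[(t, AnnotationLabel.ABNORMAL)] = AnnotationLabel.PRESENT
            counterpart[(t, AnnotationLabel.NOT_SPECIFIED)] = AnnotationLabel.ABSENT
        ordered[t] = _ORDER_ABSENT_FIRST if t in ABSENT_FIRST_TARGETS else _ORDER_PRESENT_FIRST

    for t, lab in dict(config.get("defaults", {})).items():  # type: ignore[arg-type]
        defaults[canonical_target(t)] = AnnotationLabel.parse(str(lab))
    for t, labs in dict(config.get("allowed_labels", {})).items():  # type: ignore[arg-type]
        allowed[canonical_target(t)] = frozenset(AnnotationLabel.parse(str(x)) for x in labs)
    for t, labs in dict(config.get("ordered_lists", {})).items():  # type: ignore[arg-type]
        ordered[canonical_target(t)] = tuple(AnnotationLabel.parse(str(x)) for x in labs)
    for t, src, dst in list(config.get("counterparts", [])):  # type: ignore[arg-type]
        counterpart[(canonical_target(t), AnnotationLabel.parse(str(src)))] = AnnotationLabel.parse(str(dst))

    return TargetCatalog(
        targets=CANONICAL_TARGETS,
        _defaults=defaults,
        _allowed=allowed,
        _counterpart=counterpart,
        _ordered=ordered,
    )


def default_lexicon_paths() -> tuple[Path, Path]:
    """Paths of the starter target and modifier lexicons shipped as package data."""
    data = Path(__file__).parent / "data"
    return data / "targets.tsv", data / "modifiers.tsv"


def load_default_lexicons() -> tuple[list[LexicalEntry], list[LexicalEntry]]:
    """Load the starter lexicons shipped with the package."""
    tpath, mpath = default_lexicon_paths()
    return load_lexicon(tpath, "target"), load_lexicon(mpath, "modifier")
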