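"""Sentence markup: concept matching, span/modifier/distance pruning.

Each sentence is independently marked with every lexical-target and
lexical-modifier pattern match.  Three pruning stages then reduce the
markup so that each surviving target occurrence carries exactly one
modifier:

1. *span pruning* — a match whose character span is strictly contained in
   another match of the same concept type is removed;
2. *modifier linking/pruning* — each modifier is linked to the targets
   inside its directional scope (forward / backward / bidirectional);
   modifiers linked to no target are dropped;
3. *distance pruning* — when several modifiers link to one target, the
   modifier nearest in characters wins.

Targets left with no modifier yield no assignment; the report-level
default fills them in later.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

from .labels import AnnotationLabel, DirectionRule
from .lexicon import LexicalEntry, canonical_target

ConceptType = Literal["target", "modifier"]


@dataclass(frozen=True)
class ConceptSpan:
    """One lexicon match in a sentence, with 0-based [start, end) offsets."""

    concept_type: ConceptType
    entry: LexicalEntry
    start: int
    end: int
    matched_text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span offsets [{self.start}, {self.end})")

    def gap_to(self, other: "ConceptSpan") -> int:
        """Character gap between the nearest edges of two spans (0 if touching)."""
        if self.end <= other.start:
            return other.start - self.end
        if other.end <= self.start:
            return self.start - other.end
        return 0


@dataclass(frozen=True)
class SentenceMarkup:
    """Markup state of one sentence as it moves through the pruning stages."""

    sentence: str
    sentence_index: int = 0
    targets: tuple[ConceptSpan, ...] = ()
    modifiers: tuple[ConceptSpan, ...] = ()
    #: target span -> modifier spans linked to it (post linking); after
    #: distance pruning each tuple has length exactly one.
    links: dict[ConceptSpan, tuple[ConceptSpan, ...]] = field(default_factory=dict)


@dataclass(frozen=True)
class TargetAssignment:
    """One sentence-level (target, label) vote feeding report aggregation."""

    target: str
    label: AnnotationLabel
    sentence_index: int
    source: Literal["matched", "default", "derived"] = "matched"


def mark_sentence(
    sentence: str,
    targets: Sequence[LexicalEntry],
    modifiers: Sequence[LexicalEntry],
    sentence_index: int = 0,
) -> SentenceMarkup:
    """Record every target and modifier pattern match as a ConceptSpan."""
    tspans = _find_spans(sentence, targets, "target")
    mspans = _find_spans(sentence, modifiers, "modifier")
    return SentenceMarkup(
        sentence=sentence,
        sentence_index=sentence_index,
        targets=tuple(tspans),
        modifiers=tuple(mspans),
    )


def _find_spans(
    sentence: str, entries: Sequence[LexicalEntry], concept_type: ConceptType
) -> list[ConceptSpan]:
    spans: list[ConceptSpan] = []
    for entry in entries:  # lexicon order fixes downstream tie-breaks
        for m in entry.compiled.finditer(sentence):
            if m.start() == m.end():
                continue
            spans.append(
                ConceptSpan(
                    concept_type=concept_type,
                    entry=entry,
                    start=m.start(),
                    end=m.end(),
                    matched_text=m.group(0),
                )
            )
    return spans


def prune_spans(markup: SentenceMarkup) -> SentenceMarkup:
    """Span pruning: drop spans strictly contained in a same-type span.

    Duplicate-extent spans of the same type keep only the first (by start
    offset, then lexicon order, which is the listing order).
    """
    return replace(
        markup,
        targets=tuple(_prune_group(markup.targets)),
        modifiers=tuple(_prune_group(markup.modifiers)),
        links={},
    )


def _prune_group(spans: Sequence[ConceptSpan]) -> list[ConceptSpan]:
    # dedupe identical extents, keeping the earliest-listed span
    by_extent: dict[tuple[int, int], ConceptSpan] = {}
    for s in sorted(spans, key=lambda s: s.start):
        by_extent.setdefault((s.start, s.end), s)
    unique = list(by_extent.values())
    survivors = [
        s
        for s in unique
        if not any(
            o is not s and o.start <= s.start and s.end <= o.end for o in unique
        )
    ]
    survivors.sort(key=lambda s: s.start)
    return survivors


def _in_scope(modifier: ConceptSpan, target: ConceptSpan) -> bool:
    rule = modifier.entry.rule
    if rule is None:
        raise ValueError(f"modifier entry {modifier.entry.literal!r} has no rule")
    forward = target.start >= modifier.end
    backward = target.end <= modifier.start
    if rule is DirectionRule.FORWARD:
        return forward
    if rule is DirectionRule.BACKWARD:
        return backward
    return forward or backward  # bidirectional; overlapping spans never link


def link_modifiers(markup: SentenceMarkup) -> SentenceMarkup:
    """Link each modifier to every target in its directional scope.

    Modifiers linked to no target are dropped (modifier pruning).
    """
    links: dict[ConceptSpan, list[ConceptSpan]] = {t: [] for t in markup.targets}
    surviving: list[ConceptSpan] = []
    for mod in markup.modifiers:
        linked = [t for t in markup.targets if _in_scope(mod, t)]
        if linked:
            surviving.append(mod)
            for t in linked:
                links[t].append(mod)
    return replace(
        markup,
        modifiers=tuple(surviving),
        links={t: tuple(ms) for t, ms in links.items()},
    )


def distance_prune(markup: SentenceMarkup) -> SentenceMarkup:
    """Keep, per target, only the nearest linked modifier in characters.

    Ties prefer the modifier preceding the target; a remaining tie goes to
    the smaller start offset.
    """
    new_links: dict[ConceptSpan, tuple[ConceptSpan, ...]] = {}
    for t, mods in markup.links.items():
        if not mods:
            new_links[t] = ()
            continue
        best = min(
            mods,
            key=lambda m: (t.gap_to(m), 0 if m.start < t.start else 1, m.start),
        )
        new_links[t] = (best,)
    kept_mods = {m for ms in new_links.values() for m in ms}
    return replace(
        markup,
        modifiers=tuple(m for m in markup.modifiers if m in kept_mods),
        links=new_links,
    )


def markup_sentence(
    sentence: str,
    targets: Sequence[LexicalEntry],
    modifiers: Sequence[LexicalEntry],
    sentence_index: int = 0,
) -> SentenceMarkup:
    """Full per-sentence pipeline: mark, span-prune, link, distance-prune."""
    m = mark_sentence(sentence, targets, modifiers, sentence_index)
    return distance_prune(link_modifiers(prune_spans(m)))


def sentence_assignments(markup: SentenceMarkup) -> list[TargetAssignment]:
    """Convert fully pruned markup into (target, label) votes.

    Targets without a surviving modifier produce no vote; the report-level
    default fills them.  Votes are emitted in target start-offset order.
    """
    out: list[TargetAssignment] = []
    for t in sorted(markup.links, key=lambda s: s.start):
        mods = markup.links[t]
        if not mods:
            continue
        label = mods[0].entry.category
        if not isinstance(label, AnnotationLabel):
            raise TypeError("modifier category must be an AnnotationLabel")
        out.append(
            TargetAssignment(
                target=canonical_target(str(t.entry.category)),
                label=label,
                sentence_index=markup.sentence_index,
                source="matched",
            )
        )
    return out


def markup_to_graph(markup: SentenceMarkup):
    """Render markup as a directed concept graph (modifier -> target edges).

    Nodes carry span metadata; useful for debugging through standard graph
    tooling (GraphML, DOT).  Imported lazily so the core pipeline does not
    require networkx at call time.
    """
    import networkx as nx

    g = nx.DiGraph()
    for s in (*markup.targets, *markup.modifiers):
        g.add_node(
            _node_id(s),
            concept_type=s.concept_type,
            category=str(s.entry.category),
            literal=s.entry.literal,
            start=s.start,
            end=s.end,
            matched_text=s.matched_text,
        )
    for t, mods in markup.links.items():
        for m in mods:
            g.add_edge(_node_id(m), _node_id(t))
    return g


def markup_to_rows(markup: SentenceMarkup) -> list[dict[str, object]]:
    """Tabular per-span debug view (serializable to CSV)."""
    rows = []
    for s in (*markup.targets, *markup.modifiers):
        linked = markup.links.get(s, ()) if s.concept_type == "target" else ()
        rows.append(
            {
                "sentence_index": markup.sentence_index,
                "concept_type": s.concept_type,
                "category": str(s.entry.category),
                "start": s.start,
                "end": s.end,
                "matched_text": s.matched_text,
                "linked_modifier": str(linked[0].entry.category) if linked else "",
            }
        )
    return rows


def _node_id(s: ConceptSpan) -> str:
    return f"{s.concept_type}:{s.start}-{s.end}:{s.entry.literal}"


def assignments_for_report(
    sentences: Iterable[str],
    targets: Sequence[LexicalEntry],
    modifiers: Sequence[LexicalEntry],
) -> list[TargetAssignment]:
    """Run the sentence pipeline over a report's sentences and pool the votes."""
    out: list[TargetAssignment] = []
    for i, sent in enumerate(sentences):
        out.extend(sentence_assignments(markup_sentence(sent, targets, modifiers, i)))
    return out
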