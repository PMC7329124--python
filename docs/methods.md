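# Methods

This note documents the model behind `tbiextract`, the choices made where
the design was genuinely open, what the synthetic-data generator does and
does not emulate, and the package's known limits.

## The extraction model

`tbiextract` treats information extraction from head-CT reports as lexical
target–modifier markup, the NegEx/ConText family of contextual-assertion
algorithms. The unit of reasoning is the sentence: clinical assertions
("no", "is present", "cannot be excluded") scope over findings within the
sentence that contains them, and reports are short enough (typically 9–15
sentences) that no discourse model is attempted.

### Lexicons

All domain knowledge lives in two TSV lexicons with columns
`literal / category / regex / rule` (the last two optional). A missing
regex is generated from the literal by escaping it and making interior
whitespace flexible. Every pattern is compiled case-insensitively and
wrapped in word boundaries — clinical text mixes case freely, and
unanchored matching would let `hemorrhage` fire inside `microhemorrhage`.
A lexicon pattern can still control its own interior (alternation,
optional groups, lookarounds).

Modifier categories are the annotation labels; modifier rules are
`forward` (scope to the sentence end), `backward` (from the sentence
start), or `bidirectional`. Target categories are the target names
themselves. The starter lexicons shipped as package data are intentionally
small and are inputs, not constants: any study should expect to grow them
against its own corpus.

### Pruning

After raw pattern matching, three deterministic reductions run in order:

1. **Span pruning** — a span strictly contained in another span of the same
   concept type is removed; duplicate-extent spans keep the earliest-listed
   entry. This makes longer, more specific phrases beat their fragments
   (`do not appear significantly changed` over `not`; `subdural hematoma`
   over the generic `hematoma`).
2. **Modifier linking and pruning** — each modifier links to every target
   in its directional scope; modifiers that link nothing are dropped.
   A modifier may serve several targets in one sentence (blanket negations
   do exactly this); uniqueness is per target, not per modifier.
3. **Distance pruning** — per target, the linked modifier with the smallest
   character gap between nearest span edges survives. Ties prefer the
   modifier *preceding* the target (clinical assertions usually lead their
   findings), then the smaller start offset. Measuring from nearest edges
   rather than span starts is a choice; it makes adjacency (gap 0–1) beat
   any phrase across the clause regardless of the spans' lengths.

A target whose modifiers are all pruned away yields no vote at all — it
falls to the report-level default, which is the desired behaviour for
mentions like "cerebellar volume loss" that carry no assertion phrase.

### Report-level decision rules

Votes pool across sentences and pass through three stages:

* **Omitted targets.** Unmentioned targets default to NORMAL for the two
  anatomy-state elements (gray-white differentiation, cisterns) and ABSENT
  for the other 25 — an unmentioned structure is presumed normal, an
  unmentioned finding presumed absent.
* **Duplicate targets.** Majority vote per target. When the maximal count
  ties, the earliest tied label in the target's ordered annotation list
  wins: `ABSENT, INDETERMINATE, SUSPECTED, PRESENT, NORMAL, ABNORMAL` for
  the three aggregate targets (extraaxial fluid collection, hemorrhage NOS,
  intracranial pathology) and `PRESENT, SUSPECTED, INDETERMINATE, ABSENT,
  ABNORMAL, NORMAL` for the rest. The asymmetry is deliberate: specific
  findings err toward reporting, aggregate/derived ones toward
  conservatism, since the derived rules below can still raise them.
* **Counterpart replacement.** Labels outside a target's allowed set are
  swapped for a configured counterpart (`cistern: ABSENT → NORMAL`,
  `gray-white differentiation: PRESENT → ABNORMAL`, and mirrored pairs for
  finding targets). Only the cistern pair is canonical; the rest of the
  table generalizes it symmetrically and is overridable in the catalog
  config, because a full mapping for every (target, label) pair was an
  open design point.
* **Derived targets**, applied in a fixed order (a → b → c, with c seeing
  b's update so a positive subdural implies intracranial pathology through
  either path):
  (a) any of epidural/subdural/subarachnoid hemorrhage PRESENT or
  SUSPECTED ⇒ hemorrhage NOS = ABSENT;
  (b) any PRESENT ⇒ extraaxial fluid collection = PRESENT, else any
  SUSPECTED while the collection still holds its ABSENT *default* ⇒
  SUSPECTED (a report that explicitly denied a collection is not
  overridden by mere suspicion — this is why provenance is tracked);
  (c) any trigger finding PRESENT/SUSPECTED/ABNORMAL ⇒ intracranial
  pathology = PRESENT. The default trigger set contains 17 findings
  (including intraparenchymal hemorrhage) and is configurable.
  The composite is idempotent; the test suite sweeps all 7⁴ label states
  of the hemorrhage family to confirm it.

The output is always exactly 27 rows, one label each, never
`NOT_SPECIFIED` (that label survives only for reading legacy annotator
tables). Each row carries provenance: `matched`, `default`, `tie_break`,
or `derived`.

## Preprocessing

Headers are recognized case-insensitively as `findings`/`impression(s)` at
line start (colon optional) or anywhere with a colon; the analyzed span
runs from the Findings header through the end of the Impressions section,
stopping early at signature/attestation trailers. The header tokens are
kept inside the cleaned text (a flagless choice — they match no lexicon
entry and are harmless). Cleaning retains letters, digits, whitespace and
`. , ; : ? ! % / ( ) -`; everything else is stripped, newlines become
spaces, whitespace collapses. Sentence splitting is a deterministic rule:
terminal punctuation followed by whitespace, guarded by a small clinical
abbreviation list (`Dr.`, `vs.`, `cm.` …). A rule-based splitter was chosen
over a statistical one for exact reproducibility; its known cost is that a
sentence genuinely ending in a guarded abbreviation does not split.
Corpus filtering excludes reports lacking the header pair
(`missing_sections`) and reports whose text names more than one scan type
(`multiple_scan_types`, from a configurable exam-title pattern list).

## Corpus tools

Similarity is word n-gram TF-IDF (n = 1..10, lowercased, smoothed IDF,
L2-normalized rows — the documented variant is exactly reproducible from
explicit count vectors, and a brute-force oracle in the tests does so) with
cosine = the normalized matrix times its transpose. Near-duplicate removal
draws a random unprocessed report, collects everything at ≥ 0.70 cosine to
it, keeps one random member and removes the rest, recursively; the anchor
is not privileged. A report whose maximum off-diagonal similarity is below
threshold can never be removed.

Partitioning builds a deck of dataset labels sized by the
largest-remainder method (so 311 reports at 10/40/50 give exactly
31/124/156), shuffles it, and deals: a random unassigned report plus up to
its three most similar unassigned neighbours (no similarity floor, ties by
matrix order) take the next labels. All randomness flows from one
caller-supplied seed.

## Evaluation

Cell agreement is classified `equivalent` (same), `similar`
({PRESENT, SUSPECTED}), `divergent` (one of {ABSENT, NORMAL} against one of
{PRESENT, ABNORMAL}); anything else is `other`. Cohen's κ is computed over
the full multi-label confusion matrix (not binarized), with the degenerate
identical-single-label case defined as 1. The gold standard for scoring the
extractor is the cell subset where both annotators agree. Confusion counts
use positive = {PRESENT, ABNORMAL} (case 1) or + SUSPECTED (case 2) and
negative = {ABSENT, NORMAL}; cells whose predicted or gold label falls in
neither set (notably INDETERMINATE, and SUSPECTED under case 1) are
excluded and counted separately by default — scoring them as errors would
silently conflate "undecidable" with "wrong" — with a `strict` flag for
the literal everything-else-is-an-error reading. Zero-denominator metrics
are reported as missing, never as 0. Per-target tables report gold-positive
occurrences, FN, FP and F1 in the canonical 27-target order.

## The synthetic-data generator

The generator emulates short institutional head-CT narratives: an
exam/history preamble (exercising section trimming), a FINDINGS body of
9–15 sentences, an IMPRESSION that restates a positive finding or issues a
blanket negative, and a signature trailer. Seeded targets are rendered
through a template bank keyed by (target, label) — negations for ABSENT,
hedges for SUSPECTED, "not excluded" phrasings for INDETERMINATE —
with per-target surface forms and number agreement; unseeded targets go
unmentioned. Default per-target prevalences are shaped after the relative
finding frequencies of a trauma-center corpus (subarachnoid and subdural
hemorrhage most common, diffuse axonal injury and microhemorrhage rare);
default label mixes lean positive for seeded finding mentions and normal
for the two anatomy-state targets. A configurable fraction of reports
opens with the blanket smart-phrase boilerplate, and a conflict rate
injects contradictory duplicate mentions resolved 2:1 by majority.

Ground truth is defined *post-derivation* — it is computed by running the
same aggregation rules over the seeded votes, because the post-derivation
summary is the only observable the extractor emits. Two truths are kept:
`truth` (a human reading, including out-of-coverage phrasings) and
`visible_truth` (lexicon-covered mentions only). In adversarial mode some
PRESENT mentions render through phrasings deliberately outside the starter
lexicon (unmatched target wordings, or target words with no assertion
phrase, optionally under a stale smart-phrase), so the two truths diverge
exactly at the injected constructs and every extractor error is
attributable by construction.

What passing the recovery test shows, and what it does not: on
non-adversarial corpora the extractor reproduces ground truth cell-for-cell
(case-2 F1 = 1.0), which validates the *pipeline* — matching, pruning,
linking, aggregation, derivation — end to end. It does not validate the
starter lexicon against real institutional prose, whose phrasing diversity,
compound sentences and stale boilerplate are exactly what the adversarial
mode caricatures. Template-generated text is far more regular than real
reports; measured performance on real corpora will be bounded by lexicon
coverage, not by the machinery tested here.

## Numerical and scale choices

Deterministic throughout: fixed tie-breaks at every stage (lexicon order
for equal spans, preceding-modifier for equal distances, ordered lists for
vote ties, matrix order for similarity ties), a single seed per stochastic
routine, and `numpy` Generator streams derived from (seed, report index)
so corpora are reproducible element-wise. The acceptance script runs at
deliberately modest sizes — 200-report recovery corpus, 100-report
adversarial corpus, 10,000 oracle multisets, the full 2,401-state derived
sweep, 10⁵ κ cells, a 311-report partition — chosen so the whole
recomputation finishes in seconds while keeping every binomial check
well-powered.

## Known limitations

* No termination clues ("but", "however") inside a sentence: a modifier's
  scope runs to the sentence boundary unless a longer lexicon phrase
  absorbs the clause.
* No laterality, size, count or severity extraction; no Marshall/Rotterdam
  scoring; no longitudinal comparison across scans.
* One label per target per report; mixed chronic-plus-acute findings
  collapse to the majority/ordered-list resolution.
* The starter lexicons cover the phrasings used by the generator plus the
  documented examples; they are a starting point, not a validated clinical
  lexicon.
* Reports are assumed de-identified; no PHI handling is attempted.
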