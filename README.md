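# tbiextract

Structured traumatic-brain-injury (TBI) findings from free-text head-CT
radiology reports.

Radiology reports are narrative text written for humans, yet they carry the
single most informative early assessment of a TBI patient: the non-contrast
head CT read. `tbiextract` converts such a report into a structured summary
of **27 TBI common data elements** (subdural hemorrhage, midline shift,
cisterns, mass effect, ...), each annotated with exactly one label from

```
PRESENT · SUSPECTED · INDETERMINATE · ABSENT · NORMAL · ABNORMAL
```

so that subjects can be stratified by visible damage, cohorts assembled, and
manual chart review replaced by a deterministic, auditable algorithm. It is
aimed at clinical-NLP researchers and TBI study teams who need consistent
CT-finding variables at corpus scale.

## The algorithm

`tbiextract` is a lexicon-driven contextual-assertion extractor in the
NegEx/ConText family. Two tab-separated lexicons parameterize everything:

* **lexical targets** — the 27 indexed clinical findings, each a
  `(literal, category, regex)` record, e.g. `microhemorrhage(s)?`;
* **lexical modifiers** — assertion phrases mapped to a label and a
  directional scope rule, e.g. `(was|were)\snot\sexcluded → INDETERMINATE,
  backward`.

Each report is trimmed to its *Findings–Impressions* span, cleaned, and split
into sentences. Per sentence:

1. every target and modifier pattern match is recorded as a character span;
2. **span pruning** — a span strictly contained in another span of the same
   concept type is dropped (`not` inside `do not appear significantly
   changed`);
3. **modifier linking** — each modifier is applied to the targets in its
   directional scope (forward / backward / bidirectional); unlinked
   modifiers are dropped;
4. **distance pruning** — when several modifiers compete for one target, the
   nearest in characters wins.

Sentence-level votes are then collapsed per report by three decision-rule
stages: *omitted* targets receive their default (NORMAL for gray-white
differentiation and cisterns, ABSENT for the other 25), *duplicate* targets
resolve by majority vote with a per-target ordered annotation list breaking
ties, and *derived* targets are inferred across findings (a specific
extraaxial hemorrhage suppresses hemorrhage NOS, asserts an extraaxial fluid
collection, and any positive trigger finding asserts intracranial
pathology).

The package also ships the surrounding study machinery: word n-gram (1–10)
TF-IDF cosine similarity with greedy near-duplicate removal at 0.70,
similarity-aware 10/40/50 dataset dealing, annotator-agreement evaluation
(equivalent / similar / divergent, Cohen's κ, two-case confusion metrics,
per-target error tables), and a seeded synthetic-report generator with known
ground truth.

## Worked example

```python
from tbiextract import (
    build_catalog, clean_and_split, load_default_lexicons, summarize_report,
)

targets, modifiers = load_default_lexicons()
catalog = build_catalog(targets)

report = clean_and_split(
    "FINDINGS: There is no evidence of intracranial hemorrhage, mass effect, "
    "midline shift or abnormal extraaxial fluid collection. "
    "Subdural hematoma is identified along the left convexity. "
    "The basal cisterns are patent. "
    "IMPRESSION: Left subdural hematoma.",
    report_id="example-1",
)
summary = summarize_report(report, targets, modifiers, catalog)
for target, annotation, provenance in summary.rows():
    if annotation != "ABSENT" or provenance != "default":
        print(f"{target:30s} {annotation:10s} {provenance}")
```

prints

```
extraaxial fluid collection    PRESENT    derived
mass effect                    ABSENT     matched
subdural hemorrhage            PRESENT    matched
hemorrhage nos                 ABSENT     derived
intracranial pathology         PRESENT    derived
gray-white differentiation     NORMAL     default
cistern                        NORMAL     matched
midline shift                  ABSENT     matched
```

The first sentence is a blanket-negation "smart phrase": it marks mass
effect, midline shift, hemorrhage NOS and the extraaxial fluid collection
ABSENT. The body then asserts a subdural hematoma, and the derived rules
take over: the specific hemorrhage forces *extraaxial fluid collection* to
PRESENT (overriding the stale boilerplate), suppresses the unspecified
*hemorrhage NOS*, and asserts *intracranial pathology*. The remaining 19
targets sit at their ABSENT defaults, and the unmentioned gray-white
differentiation defaults to NORMAL.

The same pipeline is available from a shell:

```bash
tbiextract synth --n 100 --seed 7 --out reports/ --truth truth.csv
tbiextract run --reports reports/ --out summary.csv
tbiextract eval --pred summary.csv --gold truth.csv --case case2
tbiextract corpus split --reports reports/ --seed 7 --out datasets.csv
```

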