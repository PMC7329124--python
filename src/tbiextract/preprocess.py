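"""Report cleaning: section trimming, symbol removal, sentence splitting.

A raw head-CT report typically reads

    EXAM: CT HEAD WITHOUT CONTRAST. HISTORY: ... FINDINGS: ... IMPRESSION: ...

Only the Findings-through-Impressions span is analyzed; text before the
Findings header and after the Impressions section (signatures,
attestations) is discarded.  Reports lacking either header, or containing
more than one scan type, are excluded from the corpus.

Cleaning replaces newlines with spaces, strips characters outside a
retained set (letters, digits, whitespace and basic clinical punctuation)
and collapses runs of whitespace.  Sentence splitting is deterministic and
rule-based: terminal punctuation followed by whitespace, guarded against
common clinical abbreviations and decimal numbers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True)
class RawReport:
    """A report as captured: identifier plus verbatim text."""

    report_id: str
    text: str
    scan_types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("report text must be non-empty")


@dataclass(frozen=True)
class CleanReport:
    """A cleaned report: whitespace-normalized sentences plus joined text."""

    report_id: str
    sentences: tuple[str, ...]
    full_text: str


# headers match at line start (optional colon) or anywhere with a colon
def _header_re(word: str) -> re.Pattern[str]:
    return re.compile(
        rf"(?im)(?:^[ \t]*{word}s?\b[ \t]*:?|\b{word}s?[ \t]*:)"
    )

_FINDINGS_RE = _header_re("finding")
_IMPRESSIONS_RE = _header_re("impression")

#: Section headers that terminate the report body after the impression.
TRAILER_PATTERNS: tuple[str, ...] = (
    r"electronically\s+signed",
    r"dictated\s+by",
    r"attestation",
    r"signed\s+by",
    r"end\s+of\s+(report|impression)",
)

#: Exam-title patterns used to count distinct scan types in a report header.
SCAN_TYPE_PATTERNS: tuple[tuple[str, str], ...] = (
    ("head", r"\bCT\s+(?:OF\s+THE\s+)?(?:HEAD|BRAIN)\b"),
    ("maxillofacial", r"\bCT\s+(?:OF\s+THE\s+)?(?:MAXILLOFACIAL|FACIAL\s+BONES?)\b"),
    ("cervical spine", r"\bCT\s+(?:OF\s+THE\s+)?(?:CERVICAL|C)[\s-]SPINE\b"),
    ("chest", r"\bCT\s+(?:OF\s+THE\s+)?(?:CHEST|THORAX)\b"),
    ("abdomen", r"\bCT\s+(?:OF\s+THE\s+)?(?:ABDOMEN|PELVIS)\b"),
)

#: Characters retained by cleaning, beyond letters, digits and whitespace.
RETAINED_PUNCTUATION = ".,;:?!%/()-"

_STRIP_RE = re.compile(rf"[^A-Za-z0-9\s{re.escape(RETAINED_PUNCTUATION)}]+")

#: Abbreviations whose trailing period does not end a sentence.
ABBREVIATIONS: frozenset[str] = frozenset(
    {"dr", "mr", "mrs", "ms", "vs", "cf", "approx", "cm", "mm", "e.g", "i.e", "no"}
)


def extract_findings_span(
    text: str, trailer_patterns: Sequence[str] = TRAILER_PATTERNS
) -> str | None:
    """Return the Findings-through-Impressions span, or None if absent.

    The span starts at the Findings header and runs through the end of the
    Impressions section (up to a recognized trailer header, else the end
    of the text).  Header matching is case-insensitive.
    """
    f = _FINDINGS_RE.search(text)
    if f is None:
        return None
    imp = _IMPRESSIONS_RE.search(text, f.end())
    if imp is None:
        return None
    end = len(text)
    for pat in trailer_patterns:
        m = re.search(pat, text[imp.end():], flags=re.IGNORECASE)
        if m:
            end = min(end, imp.end() + m.start())
    return text[f.start():end].strip()


def split_sentences(text: str) -> list[str]:
    """Deterministic sentence splitting on terminal punctuation.

    Splits after ``.``, ``?`` or ``!`` followed by whitespace, unless the
    period terminates a known abbreviation or sits inside a decimal number.
    """
    sentences: list[str] = []
    start = 0
    for m in re.finditer(r"[.?!]+(?=\s)", text):
        end = m.end()
        word = text[:m.start()].rsplit(None, 1)[-1].lower() if text[:m.start()].strip() else ""
        word = word.rstrip(".")
        if word in ABBREVIATIONS:
            continue
        # decimal such as "5.3" never splits (no whitespace follows), but a
        # trailing digit before the period is still a sentence end
        chunk = text[start:end].strip()
        if chunk:
            sentences.append(chunk)
        start = end
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def clean_text(text: str) -> str:
    """Replace newlines with spaces, strip symbols, collapse whitespace."""
    flat = text.replace("\r", " ").replace("\n", " ")
    flat = _STRIP_RE.sub("", flat)
    return re.sub(r"\s+", " ", flat).strip()


def clean_and_split(text: str, report_id: str = "") -> CleanReport:
    """Clean trimmed report text and partition it into sentences."""
    if not text or not text.strip():
        raise ValueError("cannot clean empty report text")
    cleaned = clean_text(text)
    if not cleaned:
        raise ValueError("report text is empty after cleaning")
    sentences = tuple(split_sentences(cleaned))
    return CleanReport(
        report_id=report_id, sentences=sentences, full_text=" ".join(sentences)
    )


def detect_scan_types(
    text: str, patterns: Sequence[tuple[str, str]] = SCAN_TYPE_PATTERNS
) -> tuple[str, ...]:
    """Distinct scan types named by exam-title patterns in the report."""
    found = []
    for name, pat in patterns:
        if re.search(pat, text, flags=re.IGNORECASE):
            found.append(name)
    return tuple(found)


def filter_corpus(
    reports: Iterable[RawReport],
    *,
    scan_patterns: Sequence[tuple[str, str]] = SCAN_TYPE_PATTERNS,
) -> tuple[list[CleanReport], list[tuple[str, str]]]:
    """Apply the corpus exclusion rules and clean the surviving reports.

    Exclusion reasons: ``missing_sections`` (no Findings and Impressions
    pair) and ``multiple_scan_types``.  Kept and excluded jointly
    partition the input.
    """
    kept: list[CleanReport] = []
    excluded: list[tuple[str, str]] = []
    for raw in reports:
        span = extract_findings_span(raw.text)
        if span is None:
            excluded.append((raw.report_id, "missing_sections"))
            continue
        scans = raw.scan_types or detect_scan_types(raw.text, scan_patterns)
        if len(set(scans)) > 1:
            excluded.append((raw.report_id, "multiple_scan_types"))
            continue
        kept.append(clean_and_split(span, report_id=raw.report_id))
    return kept, excluded
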