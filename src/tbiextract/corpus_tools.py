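"""Corpus-level tooling: similarity, near-duplicate removal, partitioning.

Radiology reports are heavily templated, so a corpus destined for human
annotation is first thinned of near-duplicates: reports are vectorized
with word n-gram TF-IDF (n = 1..10), pairwise cosine similarity is the
product of the L2-normalized TF-IDF matrix with its transpose, and groups
of reports at >= 0.70 similarity are reduced to a single random
representative.

The surviving corpus is then dealt into initialization / training /
validation datasets (10% / 40% / 50%) by a shuffled deck: repeatedly draw
a random unassigned report plus up to its three most similar unassigned
neighbours and give them the next deck labels, so that highly similar
reports scatter across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer

from .preprocess import CleanReport

DATASET_NAMES: tuple[str, str, str] = ("initialization", "training", "validation")
DEFAULT_PROPORTIONS: tuple[float, float, float] = (0.10, 0.40, 0.50)
DEFAULT_DEDUP_THRESHOLD = 0.70


@dataclass(frozen=True)
class SimilarityMatrix:
    """Pairwise cosine similarities over an ordered report collection."""

    report_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.report_ids)
        v = self.values
        if v.shape != (n, n):
            raise ValueError(f"similarity matrix must be {n}x{n}, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-9):
            raise ValueError("similarity matrix diagonal must be 1")
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("similarities must lie in [0, 1]")

    def value(self, a: str, b: str) -> float:
        i, j = self.report_ids.index(a), self.report_ids.index(b)
        return float(self.values[i, j])


@dataclass(frozen=True)
class DatasetAssignment:
    """Report -> dataset mapping produced by the deck partition."""

    assignment: Mapping[str, str]
    seed: int

    def sizes(self) -> dict[str, int]:
        out = {name: 0 for name in DATASET_NAMES}
        for ds in self.assignment.values():
            out[ds] += 1
        return out


def _texts_and_ids(
    reports: Sequence[CleanReport] | Mapping[str, str] | Sequence[str],
) -> tuple[list[str], list[str]]:
    if isinstance(reports, Mapping):
        ids, texts = list(reports.keys()), list(reports.values())
    else:
        items = list(reports)
        if items and isinstance(items[0], CleanReport):
            ids = [r.report_id for r in items]  # type: ignore[union-attr]
            texts = [r.full_text for r in items]  # type: ignore[union-attr]
        else:
            ids = [str(i) for i in range(len(items))]
            texts = [str(t) for t in items]
    return texts, ids


def tfidf_cosine(
    reports: Sequence[CleanReport] | Mapping[str, str] | Sequence[str],
    ngram_min: int = 1,
    ngram_max: int = 10,
) -> SimilarityMatrix:
    """Word n-gram TF-IDF cosine similarity between every report pair.

    Uses lowercased word n-grams with smoothed IDF and L2 row
    normalization, so the similarity matrix is exactly the normalized
    TF-IDF matrix times its transpose.
    """
    texts, ids = _texts_and_ids(reports)
    if len(texts) < 2:
        raise ValueError("need at least two reports to compute similarities")
    vec = TfidfVectorizer(lowercase=True, ngram_range=(ngram_min, ngram_max))
    x = vec.fit_transform(texts)
    sim = np.asarray((x @ x.T).todense(), dtype=float)
    np.fill_diagonal(sim, 1.0)
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix(report_ids=tuple(ids), values=sim)


def dedup_corpus(
    sim: SimilarityMatrix,
    threshold: float = DEFAULT_DEDUP_THRESHOLD,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Greedy near-duplicate removal at the given cosine threshold.

    Repeatedly draw a random unprocessed report, collect every
    unprocessed report at >= threshold similarity to it (itself included),
    keep one random member of that set and remove the rest, until all
    reports are processed.  The anchor is not privileged: it may itself be
    the one removed.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    rng = np.random.default_rng(seed)
    ids = sim.report_ids
    remaining = list(range(len(ids)))
    kept_idx: set[int] = set()
    removed_idx: set[int] = set()
    while remaining:
        anchor = remaining[int(rng.integers(len(remaining)))]
        group = [j for j in remaining if sim.values[anchor, j] >= threshold]
        keep = group[int(rng.integers(len(group)))]
        kept_idx.add(keep)
        removed_idx.update(j for j in group if j != keep)
        remaining = [j for j in remaining if j not in group]
    kept = [ids[i] for i in sorted(kept_idx)]
    removed = [ids[i] for i in sorted(removed_idx)]
    return kept, removed


def deck_sizes(n: int, proportions: Sequence[float]) -> list[int]:
    """Deck composition by the largest-remainder method (sizes sum to n)."""
    exact = [p * n for p in proportions]
    base = [int(np.floor(e)) for e in exact]
    short = n - sum(base)
    order = sorted(range(len(exact)), key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def partition_corpus(
    kept: Sequence[str],
    sim: SimilarityMatrix,
    proportions: Sequence[float] = DEFAULT_PROPORTIONS,
    seed: int = 0,
) -> DatasetAssignment:
    """Similarity-aware random deal into the three datasets.

    A shuffled deck with the configured composition is consumed by
    repeatedly drawing a random unassigned report plus up to its three
    most similar unassigned reports (ties by matrix order) and dealing
    them the next deck labels.
    """
    if not kept:
        raise ValueError("cannot partition an empty report set")
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {tuple(proportions)}")
    if len(proportions) != len(DATASET_NAMES):
        raise ValueError("expected three dataset proportions")

    rng = np.random.default_rng(seed)
    idx_of = {r: sim.report_ids.index(r) for r in kept}
    sizes = deck_sizes(len(kept), proportions)
    deck = [name for name, k in zip(DATASET_NAMES, sizes) for _ in range(k)]
    rng.shuffle(deck)

    unassigned = list(kept)
    assignment: dict[str, str] = {}
    pos = 0
    while unassigned:
        anchor = unassigned[int(rng.integers(len(unassigned)))]
        others = [r for r in unassigned if r != anchor]
        others.sort(key=lambda r: (-sim.values[idx_of[anchor], idx_of[r]], idx_of[r]))
        group = [anchor] + others[:3]
        for r in group:
            assignment[r] = deck[pos]
            pos += 1
        unassigned = [r for r in unassigned if r not in group]
    return DatasetAssignment(assignment=assignment, seed=seed)
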