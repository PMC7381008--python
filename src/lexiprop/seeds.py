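"""TF-IDF term scoring and seed-set assembly.

Seed words are the small, manually curated set of domain words with known
polarity (depressive -1 / nondepressive +1) that anchor both the
embedding-threshold expansion and the label propagation.  Candidate seeds are
surfaced by TF-IDF ranking over the corpus; the final curated lists are an
input, not a computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from lexiprop.corpus_io import Corpus

__all__ = [
    "TermScoreTable",
    "SeedSet",
    "compute_tfidf",
    "rank_terms",
    "assemble_seed_set",
    "load_seed_file",
    "bundled_seed_set",
]


@dataclass
class TermScoreTable:
    """Corpus-level TF-IDF scores.

    ``scores[w]`` is the mean over all D documents of tf(w, j) * idf(w),
    where tf(w, j) is the relative frequency of w in document j and
    idf(w) = ln(D / DF(w)).  Documents not containing w contribute 0 to the
    mean, so a word occurring in every document scores exactly 0.
    """

    scores: dict[str, float]
    df: dict[str, int]
    D: int
    corpus_id: str = ""

    def __post_init__(self) -> None:
        if self.D < 1:
            raise ValueError("D must be >= 1")


@dataclass
class SeedSet:
    """Disjoint polarity-labeled seed word sets.

    Label convention: depressive words carry -1, nondepressive +1.
    """

    depressive: set[str] = field(default_factory=set)
    nondepressive: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.depressive & self.nondepressive
        if overlap:
            raise ValueError(f"seed word(s) in both polarity lists: {sorted(overlap)}")

    @property
    def labels(self) -> dict[str, int]:
        out = {w: -1 for w in self.depressive}
        out.update({w: +1 for w in self.nondepressive})
        return out

    def __len__(self) -> int:
        return len(self.depressive) + len(self.nondepressive)


def compute_tfidf(corpus: Corpus) -> TermScoreTable:
    """Score each corpus word by mean per-document tf-idf.

    tf(i, j) = n_ij / sum_k n_kj  (relative frequency within document j),
    idf(i) = ln(D / DF(i)) with DF(i) the number of documents containing i,
    score(i) = (sum_j tf(i, j)) * idf(i) / D.
    """
    docs = corpus.documents
    if not docs:
        raise ValueError("empty corpus")
    D = len(docs)
    tf_sum: dict[str, float] = {}
    df: dict[str, int] = {}
    for doc in docs:
        total = len(doc)
        counts: dict[str, int] = {}
        for tok in doc:
            counts[tok] = counts.get(tok, 0) + 1
        for w, n in counts.items():
            tf_sum[w] = tf_sum.get(w, 0.0) + n / total
            df[w] = df.get(w, 0) + 1
    scores = {w: tf_sum[w] * math.log(D / df[w]) / D for w in tf_sum}
    return TermScoreTable(scores=scores, df=df, D=D)


def rank_terms(table: TermScoreTable, k: int) -> list[str]:
    """Top-k words by descending score; ties broken by descending document
    frequency, then lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(table.scores, key=lambda w: (-table.scores[w], -table.df[w], w))
    return ordered[:k]


def assemble_seed_set(depressive: Iterable[str], nondepressive: Iterable[str]) -> SeedSet:
    """Build a validated SeedSet from two curated word lists.

    Duplicates within a list collapse; a word present in both lists is a
    curation error and raises.
    """
    dep = set(depressive)
    non = set(nondepressive)
    if not dep or not non:
        raise ValueError("both polarity lists must be non-empty")
    return SeedSet(depressive=dep, nondepressive=non)


def load_seed_file(path: str | Path) -> SeedSet:
    """Read a seed list: one ``word<TAB>polarity`` per line, polarity in
    {dep, nondep}; ``#`` lines are comments."""
    dep: list[str] = []
    non: list[str] = []
    for ln in Path(path).read_text(encoding="utf-8").splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) != 2 or parts[1] not in {"dep", "nondep"}:
            raise ValueError(f"bad seed line: {ln!r}")
        (dep if parts[1] == "dep" else non).append(parts[0])
    return assemble_seed_set(dep, non)


def bundled_seed_set() -> SeedSet:
    """The 40+40 curated Chinese depression/nondepression seeds shipped with
    the package."""
    ref = resources.files("lexiprop.data") / "seeds_zh.tsv"
    with resources.as_file(ref) as path:
        return load_seed_file(path)
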