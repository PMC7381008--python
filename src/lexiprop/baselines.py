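"""Comparison lexicon builders: nearest-seed inheritance (W2V),
semantic orientation from embeddings (SO-W2V), and SO-PMI.

All three consume the same seed set and, where applicable, the same
expansion threshold as the propagation method, so lexicon comparisons are
like-for-like.  Seeds always enter the output lexicon clamped at -1/+1,
matching the propagation method's treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import log2
from typing import Iterable

import numpy as np

from lexiprop.corpus_io import Corpus
from lexiprop.embeddings import CandidateSet, EmbeddingSpace, extend_candidates
from lexiprop.graph_lpa import Lexicon
from lexiprop.seeds import SeedSet

__all__ = [
    "CooccurrenceTable",
    "w2v_baseline",
    "so_w2v",
    "build_cooccurrence",
    "so_pmi",
]


@dataclass
class CooccurrenceTable:
    """Document-level binary co-occurrence counts.

    ``pair_counts[(a, b)]`` (a < b) is the number of documents containing
    both words; ``word_counts[w]`` the number containing w; ``D`` the total
    document count.
    """

    pair_counts: dict[tuple[str, str], int]
    word_counts: dict[str, int]
    D: int

    def pair(self, a: str, b: str) -> int:
        if a > b:
            a, b = b, a
        return self.pair_counts.get((a, b), 0)


def w2v_baseline(seeds: SeedSet, space: EmbeddingSpace, T_c: float) -> Lexicon:
    """Label inheritance from the most similar extending seed.

    Each word within ``T_c`` of some seed inherits the polarity of its
    highest-similarity seed; an exact similarity tie between opposite
    polarities excludes the word.  The score is the signed winning
    similarity.
    """
    cand = extend_candidates(seeds, space, T_c)
    labels = seeds.labels
    dep: dict[str, float] = {}
    non: dict[str, float] = {}
    best: dict[str, tuple[float, set[int]]] = {}
    for a, b, s in cand.edges:
        for w, other in ((a, b), (b, a)):
            if other in labels and w not in labels:
                cur = best.get(w)
                if cur is None or s > cur[0]:
                    best[w] = (s, {labels[other]})
                elif s == cur[0]:
                    cur[1].add(labels[other])
    for w, (s, labs) in best.items():
        if len(labs) > 1:
            continue  # exact tie across polarities
        lab = next(iter(labs))
        (dep if lab < 0 else non)[w] = lab * s
    for w in cand.words & seeds.depressive:
        dep[w] = -1.0
    for w in cand.words & seeds.nondepressive:
        non[w] = 1.0
    return Lexicon(depressive=dep, nondepressive=non)


def so_w2v(seeds: SeedSet, space: EmbeddingSpace, candidates: CandidateSet | Iterable[str]) -> Lexicon:
    """Semantic orientation from embeddings.

    score(w) = mean_{s in nondep} cos(w, s) - mean_{s in dep} cos(w, s);
    positive scores are nondepressive, negative depressive, exact zero is
    excluded.  Means (not sums) keep unbalanced seed sets from biasing the
    sign.  Seeds are clamped at -1/+1.
    """
    words = candidates.words if isinstance(candidates, CandidateSet) else set(candidates)
    dep_seeds = sorted(seeds.depressive & set(space.vectors))
    non_seeds = sorted(seeds.nondepressive & set(space.vectors))
    if not dep_seeds or not non_seeds:
        raise ValueError("need at least one in-vocabulary seed of each polarity")
    scorable = sorted(w for w in words if w in space and w not in seeds.labels)
    dep: dict[str, float] = {w: -1.0 for w in words & seeds.depressive}
    non: dict[str, float] = {w: 1.0 for w in words & seeds.nondepressive}
    if scorable:
        _, WM = space.matrix(scorable)
        WM = WM / np.linalg.norm(WM, axis=1, keepdims=True)
        _, DM = space.matrix(dep_seeds)
        DM = DM / np.linalg.norm(DM, axis=1, keepdims=True)
        _, NM = space.matrix(non_seeds)
        NM = NM / np.linalg.norm(NM, axis=1, keepdims=True)
        score = (WM @ NM.T).mean(axis=1) - (WM @ DM.T).mean(axis=1)
        for w, s in zip(scorable, score):
            s = float(s)
            if s < 0:
                dep[w] = s
            elif s > 0:
                non[w] = s
    return Lexicon(depressive=dep, nondepressive=non)


def build_cooccurrence(corpus: Corpus, vocabulary: Iterable[str]) -> CooccurrenceTable:
    """Count binary per-document co-occurrence for words in ``vocabulary``.

    A word repeated within one document contributes one to its document
    count; a pair contributes one per document containing both.
    """
    vocab = set(vocabulary)
    pair_counts: dict[tuple[str, str], int] = {}
    word_counts: dict[str, int] = {}
    docs = corpus.documents
    for doc in docs:
        present = sorted(set(doc) & vocab)
        for w in present:
            word_counts[w] = word_counts.get(w, 0) + 1
        for a, b in combinations(present, 2):
            pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
    return CooccurrenceTable(pair_counts=pair_counts, word_counts=word_counts, D=len(docs))


def so_pmi(
    seeds: SeedSet,
    table: CooccurrenceTable,
    candidates: Iterable[str],
    epsilon: float = 0.5,
) -> Lexicon:
    """Semantic orientation by pointwise mutual information.

    PMI(w, s) = log2((count(w, s) + eps) * D / ((count(w) + eps) * (count(s) + eps)))
    with add-half smoothing (eps = 0.5) so zero counts stay defined;
    SO-PMI(w) = sum_{s in nondep} PMI(w, s) - sum_{s in dep} PMI(w, s).
    Positive orientation is nondepressive, negative depressive, zero
    excluded.  Seeds are clamped at -1/+1.
    """
    words = set(candidates)
    dep: dict[str, float] = {w: -1.0 for w in words & seeds.depressive}
    non: dict[str, float] = {w: 1.0 for w in words & seeds.nondepressive}
    dep_seeds = sorted(seeds.depressive)
    non_seeds = sorted(seeds.nondepressive)

    def pmi(w: str, s: str) -> float:
        joint = table.pair(w, s) + epsilon
        return log2(joint * table.D / ((table.word_counts.get(w, 0) + epsilon)
                                       * (table.word_counts.get(s, 0) + epsilon)))

    for w in sorted(words - seeds.depressive - seeds.nondepressive):
        so = sum(pmi(w, s) for s in non_seeds) - sum(pmi(w, s) for s in dep_seeds)
        if so < 0:
            dep[w] = so
        elif so > 0:
            non[w] = so
    return Lexicon(depressive=dep, nondepressive=non)
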