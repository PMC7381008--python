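"""Lexicon scoring against gold labels and parameter-sweep harnesses.

The positive class in all word-level metrics is *depressive*: TP counts
depressive gold words predicted depressive, FP nondepressive gold words
predicted depressive, FN depressive gold words predicted nondepressive.
Words predicted but absent from the gold standard are excluded from the
confusion table and reported separately.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from lexiprop.baselines import build_cooccurrence, so_pmi, so_w2v, w2v_baseline
from lexiprop.corpus_io import Corpus
from lexiprop.embeddings import EmbeddingSpace, extend_candidates
from lexiprop.graph_lpa import Lexicon, build_graph, propagate_to_convergence, threshold_lexicon
from lexiprop.seeds import SeedSet

__all__ = [
    "ConfusionTable",
    "confusion",
    "precision_recall_f1",
    "auc_score",
    "build_lexicon",
    "parameter_sweep",
]


@dataclass
class ConfusionTable:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0
    n_unscored: int = 0  # predicted words absent from gold

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion(predicted: Lexicon, gold: Mapping[str, int]) -> ConfusionTable:
    """Four-way count of predicted vs gold polarity (gold: word -> -1/+1).

    Only predicted words present in gold are scored; the rest are counted in
    ``n_unscored``.  Raises if nothing is scorable.
    """
    t = ConfusionTable()
    for w, pol in predicted.polarity.items():
        if w not in gold:
            t.n_unscored += 1
            continue
        g = gold[w]
        if pol == -1 and g == -1:
            t.TP += 1
        elif pol == -1 and g == +1:
            t.FP += 1
        elif pol == +1 and g == -1:
            t.FN += 1
        else:
            t.TN += 1
    if t.total == 0:
        raise ValueError("no predicted word appears in the gold standard")
    return t


def precision_recall_f1(t: ConfusionTable) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R).

    Degenerate denominators yield NaN with a warning rather than 0.
    """
    if t.TP + t.FP == 0:
        warnings.warn("precision undefined: no word predicted depressive")
        p = math.nan
    else:
        p = t.TP / (t.TP + t.FP)
    if t.TP + t.FN == 0:
        warnings.warn("recall undefined: no depressive word in gold")
        r = math.nan
    else:
        r = t.TP / (t.TP + t.FN)
    if math.isnan(p) or math.isnan(r) or p + r == 0:
        f1 = math.nan
    else:
        f1 = 2 * p * r / (p + r)
    return p, r, f1


def auc_score(scores: Mapping[str, float], gold: Mapping[str, int]) -> float:
    """Rank AUC for separating depressive from nondepressive gold words.

    Scores follow the lexicon convention (negative = depressive), so this is
    the probability that a random depressive word scores *lower* than a
    random nondepressive one, with ties counting one half.  Computed over
    the words present in both mappings.
    """
    common = [w for w in scores if w in gold]
    y = np.array([gold[w] == -1 for w in common])
    if not y.any() or y.all():
        raise ValueError("AUC needs both gold classes among the scored words")
    s = np.array([-scores[w] for w in common])  # higher = more depressive
    ranks = rankdata(s)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# sweeps

def build_lexicon(
    seeds: SeedSet,
    space: EmbeddingSpace,
    method: str = "w2v-lpa",
    T_c: float = 0.5,
    cut: float = 0.5,
    corpus: Corpus | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> Lexicon:
    """Run one lexicon-construction method end to end.

    ``method`` is one of ``w2v-lpa`` (embedding expansion + label
    propagation), ``w2v``, ``so-w2v`` or ``so-pmi`` (requires ``corpus``).
    All methods share the same seed set and expansion threshold.
    """
    if method == "w2v-lpa":
        cand = extend_candidates(seeds, space, T_c)
        graph = build_graph(cand, seeds)
        state = propagate_to_convergence(graph, tol=tol, max_iter=max_iter)
        return threshold_lexicon(state, graph, cut=cut)
    if method == "w2v":
        return w2v_baseline(seeds, space, T_c)
    if method == "so-w2v":
        cand = extend_candidates(seeds, space, T_c)
        return so_w2v(seeds, space, cand)
    if method == "so-pmi":
        if corpus is None:
            raise ValueError("so-pmi needs the corpus for co-occurrence counts")
        cand = extend_candidates(seeds, space, T_c)
        table = build_cooccurrence(corpus, cand.words | seeds.depressive | seeds.nondepressive)
        return so_pmi(seeds, table, cand.words)
    raise ValueError(f"unknown method {method!r}")


def subsample_seeds(seeds_full: SeedSet, size: int, rng_seed: int) -> SeedSet:
    """Deterministic balanced subsample of ``size`` seeds (size/2 per
    polarity).

    Subsamples are nested: the order of each polarity list is shuffled once
    from ``rng_seed``, and a prefix is taken, so a larger ``size`` always
    contains the smaller one.
    """
    if size % 2:
        raise ValueError("seed size must be even (balanced halves)")
    half = size // 2
    rng = np.random.default_rng(rng_seed)
    dep = sorted(seeds_full.depressive)
    non = sorted(seeds_full.nondepressive)
    rng.shuffle(dep)
    rng.shuffle(non)
    return SeedSet(depressive=set(dep[:half]), nondepressive=set(non[:half]))


def parameter_sweep(
    space: EmbeddingSpace,
    seeds_full: SeedSet,
    gold: Mapping[str, int],
    seed_sizes: Sequence[int],
    thresholds: Sequence[float],
    method: str = "w2v-lpa",
    rng_seed: int = 0,
    corpus: Corpus | None = None,
    cut: float = 0.5,
) -> pd.DataFrame:
    """Grid sweep over seed-set size and expansion threshold T_c.

    For each cell a balanced seed subsample is drawn (deterministically from
    ``rng_seed``, nested across sizes), the method runs, and precision /
    recall / F1 against ``gold`` plus lexicon size are recorded.  Infeasible
    cells (e.g. a polarity with no surviving seeds) are skipped with a
    warning.  Returns a tidy DataFrame with columns seed_size, T_c,
    precision, recall, F1, lexicon_size.
    """
    rows = []
    for size in seed_sizes:
        sub = subsample_seeds(seeds_full, size, rng_seed)
        for tc in thresholds:
            if not 0 < tc < 1:
                raise ValueError("thresholds must lie in (0, 1)")
            try:
                lex = build_lexicon(sub, space, method=method, T_c=tc, cut=cut, corpus=corpus)
                p, r, f1 = precision_recall_f1(confusion(lex, gold))
            except ValueError as exc:
                warnings.warn(f"sweep cell (size={size}, T_c={tc}) skipped: {exc}")
                continue
            rows.append({"seed_size": size, "T_c": tc, "precision": p,
                         "recall": r, "F1": f1, "lexicon_size": len(lex)})
    return pd.DataFrame(rows, columns=["seed_size", "T_c", "precision", "recall", "F1", "lexicon_size"])
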