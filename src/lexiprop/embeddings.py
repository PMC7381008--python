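"""Word vectors, cosine geometry, and threshold-based candidate expansion.

Vectors can be loaded from the standard word2vec text format or trained
in-package.  The in-package trainer is count-based: a positive pointwise
mutual information (PPMI) matrix over symmetric context windows, factorized
with truncated SVD — the classical spectral route to skip-gram-like
embeddings, and fully deterministic given a seed.

Candidate expansion implements the seed-neighborhood rule: any vocabulary
word whose cosine similarity to a seed reaches the threshold T_c joins the
candidate set C (together with that seed), and all pairwise similarities
within C that reach T_c become weighted edges of the semantic graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import TruncatedSVD

from lexiprop.corpus_io import Corpus
from lexiprop.seeds import SeedSet

__all__ = [
    "EmbeddingSpace",
    "CandidateSet",
    "train_embeddings",
    "load_embeddings",
    "save_embeddings",
    "cosine_similarity",
    "extend_candidates",
]


@dataclass
class EmbeddingSpace:
    """A word -> d-dimensional real vector mapping with cosine geometry."""

    dim: int
    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.vectors:
            raise ValueError("empty vocabulary")
        for w, v in self.vectors.items():
            if v.shape != (self.dim,):
                raise ValueError(f"vector for {w!r} has shape {v.shape}, expected ({self.dim},)")
            if not np.any(v):
                raise ValueError(f"all-zero vector for {w!r}")

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __getitem__(self, word: str) -> np.ndarray:
        return self.vectors[word]

    @property
    def vocabulary(self) -> list[str]:
        return list(self.vectors)

    def matrix(self, words: list[str] | None = None) -> tuple[list[str], np.ndarray]:
        """Stacked (and row-ordered) vector matrix for ``words`` (default:
        whole vocabulary)."""
        words = list(self.vectors) if words is None else words
        return words, np.vstack([self.vectors[w] for w in words])


@dataclass
class CandidateSet:
    """Expansion output: candidate words C plus the thresholded similarity
    edges among them (undirected, stored once with endpoints in sorted
    order)."""

    words: set[str]
    edges: list[tuple[str, str, float]]
    T_c: float

    def __post_init__(self) -> None:
        if not 0 < self.T_c <= 1:
            raise ValueError("T_c must be in (0, 1]")
        for a, b, s in self.edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if a > b:
                raise ValueError(f"edge ({a!r}, {b!r}) not in canonical order")
            if s < self.T_c - 1e-12:
                raise ValueError(f"edge ({a}, {b}) similarity {s} below T_c={self.T_c}")
            if a not in self.words or b not in self.words:
                raise ValueError(f"edge endpoint not in candidate words: ({a}, {b})")


# ---------------------------------------------------------------------------
# training and I/O

def _cooccurrence_counts(docs: list[list[str]], vocab_index: dict[str, int], window: int) -> sp.csr_matrix:
    rows: list[int] = []
    cols: list[int] = []
    for doc in docs:
        idx = [vocab_index.get(t, -1) for t in doc]
        n = len(idx)
        for i, wi in enumerate(idx):
            if wi < 0:
                continue
            for j in range(i + 1, min(i + 1 + window, n)):
                wj = idx[j]
                if wj < 0:
                    continue
                rows.extend((wi, wj))
                cols.extend((wj, wi))
    data = np.ones(len(rows), dtype=np.float64)
    V = len(vocab_index)
    return sp.csr_matrix((data, (rows, cols)), shape=(V, V))


def train_embeddings(
    corpus: Corpus,
    dim: int = 100,
    window: int = 5,
    min_count: int = 5,
    rng_seed: int = 0,
) -> EmbeddingSpace:
    """Train PPMI-SVD word embeddings on a tokenized corpus.

    Co-occurrence is counted within a symmetric window of ``window`` tokens
    inside each document; the PPMI matrix max(0, log(p(i,j)/(p(i)p(j)))) is
    factorized by truncated SVD and word vectors are U * sqrt(S).

    Deterministic given ``rng_seed``.  Words below ``min_count`` total
    frequency are excluded; an empty surviving vocabulary raises.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    docs = corpus.documents
    freq: dict[str, int] = {}
    for doc in docs:
        for t in doc:
            freq[t] = freq.get(t, 0) + 1
    vocab = sorted(w for w, c in freq.items() if c >= min_count)
    if not vocab:
        raise ValueError("vocabulary empty after min_count filtering")
    index = {w: i for i, w in enumerate(vocab)}
    C = _cooccurrence_counts(docs, index, window)
    total = C.sum()
    if total == 0:
        raise ValueError("no co-occurrence pairs; documents too short for the window")
    row_sums = np.asarray(C.sum(axis=1)).ravel()

    C = C.tocoo()
    with np.errstate(divide="ignore"):
        pmi = np.log(C.data * total / (row_sums[C.row] * row_sums[C.col]))
    keep = pmi > 0
    ppmi = sp.csr_matrix((pmi[keep], (C.row[keep], C.col[keep])), shape=C.shape)

    k = min(dim, len(vocab) - 1)
    svd = TruncatedSVD(n_components=k, random_state=rng_seed, algorithm="randomized", n_iter=7)
    U = svd.fit_transform(ppmi)  # = U * S
    with np.errstate(divide="ignore", invalid="ignore"):
        vecs = U / np.sqrt(svd.singular_values_)[None, :]  # U * sqrt(S)
    vecs = np.nan_to_num(vecs)
    if k < dim:
        vecs = np.pad(vecs, ((0, 0), (0, dim - k)))
    # words with no positive-PMI context would get a zero vector; give them a
    # tiny deterministic direction so cosine stays defined
    rng = np.random.default_rng(rng_seed)
    jitter = rng.normal(scale=1e-8, size=(len(vocab), dim))
    norms = np.linalg.norm(vecs, axis=1)
    vecs[norms == 0] = jitter[norms == 0]
    return EmbeddingSpace(dim=dim, vectors={w: vecs[i].copy() for w, i in index.items()})


def load_embeddings(path: str | Path) -> EmbeddingSpace:
    """Read vectors in word2vec text format: header ``vocab_size dim``, then
    one ``word v1 ... v_dim`` per line."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split()
    if len(header) != 2:
        raise ValueError(f"{path}: bad header {lines[0]!r}")
    n, dim = int(header[0]), int(header[1])
    vectors: dict[str, np.ndarray] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip().split(" ")
        if len(parts) != dim + 1:
            raise ValueError(f"{path}: line {lineno} has {len(parts) - 1} values, expected {dim}")
        vectors[parts[0]] = np.array([float(x) for x in parts[1:]], dtype=np.float64)
    if len(vectors) != n:
        raise ValueError(f"{path}: header promises {n} words, found {len(vectors)}")
    return EmbeddingSpace(dim=dim, vectors=vectors)


def save_embeddings(space: EmbeddingSpace, path: str | Path) -> None:
    """Write vectors in word2vec text format (repr floats: lossless
    round-trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(space.vectors)} {space.dim}\n")
        for w, v in space.vectors.items():
            fh.write(w + " " + " ".join(repr(float(x)) for x in v) + "\n")


# ---------------------------------------------------------------------------
# geometry

def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """cos(a, b) = a.b / (|a| |b|); raises on zero vectors or shape
    mismatch."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero vector")
    return float(np.dot(a, b) / (na * nb))


def extend_candidates(seeds: SeedSet, space: EmbeddingSpace, T_c: float) -> CandidateSet:
    """Expand the seed set through the embedding space.

    Every vocabulary word within cosine ``T_c`` of some in-vocabulary seed
    joins the candidate set C together with that seed; then all pairwise
    similarities within C reaching T_c are recorded as undirected edges.
    Out-of-vocabulary seeds are skipped with a warning; each polarity must
    retain at least one in-vocabulary seed.
    """
    if not 0 < T_c < 1:
        raise ValueError("T_c must be in (0, 1)")
    missing = [s for s in sorted(seeds.depressive | seeds.nondepressive) if s not in space]
    if missing:
        warnings.warn(f"{len(missing)} seed(s) missing from the embedding vocabulary: "
                      f"{missing[:10]}{'...' if len(missing) > 10 else ''}")
    dep = sorted(seeds.depressive & set(space.vectors))
    non = sorted(seeds.nondepressive & set(space.vectors))
    if not dep or not non:
        raise ValueError("need at least one in-vocabulary seed of each polarity")

    words, M = space.matrix()
    M = M / np.linalg.norm(M, axis=1, keepdims=True)
    index = {w: i for i, w in enumerate(words)}
    seed_words = dep + non
    S = M[[index[s] for s in seed_words]]
    sims = S @ M.T  # (n_seeds, vocab)

    cand: set[str] = set()
    for si, s in enumerate(seed_words):
        hits = np.nonzero(sims[si] >= T_c)[0]
        for wi in hits:
            w = words[wi]
            if w == s:
                continue
            cand.add(s)
            cand.add(w)

    cwords = sorted(cand)
    edges: list[tuple[str, str, float]] = []
    if cwords:
        CM = M[[index[w] for w in cwords]]
        csims = CM @ CM.T
        n = len(cwords)
        for i in range(n):
            row = csims[i, i + 1 :]
            for off in np.nonzero(row >= T_c)[0]:
                j = i + 1 + off
                edges.append((cwords[i], cwords[j], float(csims[i, j])))
    return CandidateSet(words=cand, edges=edges, T_c=T_c)
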