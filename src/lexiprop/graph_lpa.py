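"""Semantic graph construction and clamped label propagation.

The semantic graph has one node per candidate word; edge weights are the
cosine similarities that passed the expansion threshold.  Seeds are clamped
at -1 (depressive) / +1 (nondepressive); every other node starts at 0 and is
repeatedly replaced by the similarity-weighted average of its neighbors'
labels until the labels stop moving.  Because each update is a convex
combination of values in [-1, +1], labels stay bounded, and on any component
containing a seed the iteration contracts to a unique fixed point, which
``solve_exact`` computes directly as a linear system.

Nodes whose converged label magnitude exceeds the cut (default 0.5, strict)
enter the output lexicon on the side of their sign; seeds enter at +-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from lexiprop.embeddings import CandidateSet
from lexiprop.seeds import SeedSet

__all__ = [
    "SemanticGraph",
    "LabelState",
    "Lexicon",
    "build_graph",
    "transition_matrix",
    "init_labels",
    "propagate_step",
    "propagate_to_convergence",
    "solve_exact",
    "threshold_lexicon",
]

SEED_DEP = "seed_dep"
SEED_NONDEP = "seed_nondep"
UNKNOWN = "unknown"


@dataclass
class SemanticGraph:
    """Weighted undirected word graph with clamped-seed flags.

    ``nodes`` fixes the matrix indexing: depressive seeds first
    (lexicographic), then nondepressive seeds, then unknowns.
    ``weights`` is the symmetric sparse similarity matrix (zero diagonal).
    """

    nodes: list[str]
    flags: list[str]
    weights: sp.csr_matrix

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix shape does not match node count")
        if len(self.flags) != n:
            raise ValueError("flags length does not match node count")

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def seed_mask(self) -> np.ndarray:
        return np.array([f != UNKNOWN for f in self.flags])

    @property
    def seed_values(self) -> np.ndarray:
        return np.array([-1.0 if f == SEED_DEP else (1.0 if f == SEED_NONDEP else 0.0)
                         for f in self.flags])

    @property
    def isolated(self) -> list[str]:
        deg = np.asarray(self.weights.getnnz(axis=0))
        return [w for w, d in zip(self.nodes, deg) if d == 0]


@dataclass
class LabelState:
    """Current propagated labels over the graph's node order."""

    V: np.ndarray
    iteration: int = 0
    converged: bool = False


@dataclass
class Lexicon:
    """Polarity lexicon: word -> propagated score, split by sign.

    Depressive scores are negative, nondepressive positive; the two maps are
    disjoint.
    """

    depressive: dict[str, float] = field(default_factory=dict)
    nondepressive: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.depressive) & set(self.nondepressive)
        if overlap:
            raise ValueError(f"word(s) on both sides of the lexicon: {sorted(overlap)}")

    def __len__(self) -> int:
        return len(self.depressive) + len(self.nondepressive)

    @property
    def polarity(self) -> dict[str, int]:
        out = {w: -1 for w in self.depressive}
        out.update({w: +1 for w in self.nondepressive})
        return out

    @property
    def scores(self) -> dict[str, float]:
        return {**self.depressive, **self.nondepressive}

    def to_tsv(self, path: str | Path) -> None:
        """word <TAB> dep|nondep <TAB> score, sorted by polarity then
        descending |score| (review-friendly)."""
        rows = [(w, "dep", s) for w, s in self.depressive.items()]
        rows += [(w, "nondep", s) for w, s in self.nondepressive.items()]
        rows.sort(key=lambda r: (r[1], -abs(r[2]), r[0]))
        with open(path, "w", encoding="utf-8") as fh:
            for w, pol, s in rows:
                fh.write(f"{w}\t{pol}\t{s:.6f}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        dep: dict[str, float] = {}
        non: dict[str, float] = {}
        for ln in Path(path).read_text(encoding="utf-8").splitlines():
            if not ln.strip() or ln.startswith("#"):
                continue
            w, pol, s = ln.split("\t")
            (dep if pol == "dep" else non)[w] = float(s)
        return cls(depressive=dep, nondepressive=non)


# ---------------------------------------------------------------------------
# construction

def build_graph(candidates: CandidateSet, seeds: SeedSet) -> SemanticGraph:
    """Assemble the semantic graph from expansion output.

    Node order: depressive seeds, nondepressive seeds, unknowns, each block
    lexicographic.  Raises if either polarity is unrepresented or there are
    no edges at all.
    """
    words = candidates.words
    dep = sorted(words & seeds.depressive)
    non = sorted(words & seeds.nondepressive)
    unk = sorted(words - seeds.depressive - seeds.nondepressive)
    if not dep or not non:
        raise ValueError("graph needs at least one candidate seed of each polarity")
    if not candidates.edges:
        raise ValueError("candidate set has no edges; nothing to propagate over")
    nodes = dep + non + unk
    flags = [SEED_DEP] * len(dep) + [SEED_NONDEP] * len(non) + [UNKNOWN] * len(unk)
    index = {w: i for i, w in enumerate(nodes)}
    rows, cols, data = [], [], []
    for a, b, s in candidates.edges:
        i, j = index[a], index[b]
        rows.extend((i, j))
        cols.extend((j, i))
        data.extend((s, s))
    W = sp.csr_matrix((data, (rows, cols)), shape=(len(nodes), len(nodes)))
    graph = SemanticGraph(nodes=nodes, flags=flags, weights=W)
    iso = graph.isolated
    if iso:
        warnings.warn(f"{len(iso)} isolated node(s) in the semantic graph: "
                      f"{iso[:10]}{'...' if len(iso) > 10 else ''}")
    return graph


def transition_matrix(graph: SemanticGraph, normalization: str = "column") -> sp.csr_matrix:
    """Normalized transition matrix T.

    With the default ``column`` normalization, T[i][j] = w_ij / sum_k w_kj:
    each node j's incoming weights sum to 1, so the update
    Label[j] = sum_i T[i][j] V[i] is a weighted average of j's neighbors.
    ``row`` normalization (T[i][j] = w_ij / sum_k w_ik) is exposed for
    sensitivity checks.  Isolated nodes get an all-zero column/row.
    """
    W = graph.weights.tocsc(copy=True).astype(np.float64)
    if normalization == "column":
        sums = np.asarray(W.sum(axis=0)).ravel()
        scale = np.divide(1.0, sums, out=np.zeros_like(sums), where=sums > 0)
        T = W @ sp.diags(scale)
    elif normalization == "row":
        sums = np.asarray(W.sum(axis=1)).ravel()
        scale = np.divide(1.0, sums, out=np.zeros_like(sums), where=sums > 0)
        T = sp.diags(scale) @ W
    else:
        raise ValueError("normalization must be 'column' or 'row'")
    return T.tocsr()


def init_labels(graph: SemanticGraph) -> LabelState:
    """Initial label vector: -1 for depressive seeds, +1 for nondepressive,
    0 for unknowns."""
    return LabelState(V=graph.seed_values.copy(), iteration=0, converged=False)


def propagate_step(T: sp.csr_matrix, state: LabelState, graph: SemanticGraph) -> LabelState:
    """One propagation round: Label[j] = sum_i T[i][j] V[i] for unknowns;
    seeds are reset to their clamped values."""
    new = np.asarray(T.T @ state.V).ravel()
    # mathematically a convex combination of values in [-1, 1]; clip the
    # float roundoff so the bound holds exactly
    np.clip(new, -1.0, 1.0, out=new)
    mask = graph.seed_mask
    new[mask] = graph.seed_values[mask]
    # isolated unknowns have an all-zero column and stay at 0
    return LabelState(V=new, iteration=state.iteration + 1, converged=state.converged)


def propagate_to_convergence(
    graph: SemanticGraph,
    tol: float = 1e-6,
    max_iter: int = 1000,
    normalization: str = "column",
) -> LabelState:
    """Iterate propagation until the maximum absolute per-node change drops
    below ``tol`` (or ``max_iter`` rounds, with a warning)."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    T = transition_matrix(graph, normalization)
    state = init_labels(graph)
    for _ in range(max_iter):
        nxt = propagate_step(T, state, graph)
        delta = float(np.max(np.abs(nxt.V - state.V)))
        state = nxt
        if delta < tol:
            state.converged = True
            return state
    warnings.warn(f"label propagation did not converge in {max_iter} iterations")
    state.converged = False
    return state


def solve_exact(graph: SemanticGraph, normalization: str = "column") -> LabelState:
    """Closed-form fixed point of the clamped iteration.

    Writing M for the update matrix (M = T' under the default column
    normalization), the unknown block satisfies
    f_U = (I - M_UU)^{-1} M_UL f_L.  Unknown nodes whose connected component
    contains no seed have no unique fixed point; they are assigned 0 and
    reported via a warning.
    """
    M = transition_matrix(graph, normalization).T.tocsr()
    mask = graph.seed_mask
    V = graph.seed_values.copy()
    n_comp, comp = connected_components(graph.weights, directed=False)
    seeded_comps = set(comp[mask])
    solvable = np.array([not m and comp[i] in seeded_comps for i, m in enumerate(mask)])
    orphan = [w for i, w in enumerate(graph.nodes) if not mask[i] and not solvable[i]]
    if orphan:
        warnings.warn(f"{len(orphan)} unknown node(s) in seed-free components kept at 0: "
                      f"{orphan[:10]}{'...' if len(orphan) > 10 else ''}")
    if solvable.any():
        U = np.nonzero(solvable)[0]
        L = np.nonzero(mask)[0]
        A = sp.identity(len(U), format="csc") - M[np.ix_(U, U)]
        b = M[np.ix_(U, L)] @ V[L]
        V[U] = sp.linalg.spsolve(A, b) if len(U) > 1 else np.linalg.solve(A.toarray(), np.atleast_1d(b))
    return LabelState(V=V, iteration=0, converged=True)


def threshold_lexicon(state: LabelState, graph: SemanticGraph, cut: float = 0.5) -> Lexicon:
    """Split converged labels into the lexicon by sign and magnitude.

    Unknown nodes enter only when |label| strictly exceeds ``cut``; seeds
    always enter their own polarity at -1/+1.
    """
    if not 0 < cut < 1:
        raise ValueError("cut must be in (0, 1)")
    dep: dict[str, float] = {}
    non: dict[str, float] = {}
    for w, f, v in zip(graph.nodes, graph.flags, state.V):
        v = float(v)
        if f == SEED_DEP:
            dep[w] = -1.0
        elif f == SEED_NONDEP:
            non[w] = 1.0
        elif v < 0 and abs(v) > cut:
            dep[w] = v
        elif v > 0 and abs(v) > cut:
            non[w] = v
    return Lexicon(depressive=dep, nondepressive=non)
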