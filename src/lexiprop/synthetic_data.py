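"""Synthetic corpora and embedding spaces with planted polarity structure.

The generator emulates the statistical shape of a two-cohort microblog
collection: a *depressed* and a *nondepressed* user group share a large
background vocabulary, while each group over-uses its own planted polarity
vocabulary (depressive words in the depressed group, and vice versa) by a
fixed enrichment factor.  A companion geometric embedding space places the
two planted vocabularies in separable Gaussian clusters on opposite sides
of the origin, with the background vocabulary isotropic around the origin.

Everything is deterministic given ``rng_seed``.  The default parameter sets
(the lexicon-construction benchmark and the harder detection benchmark) are
stored in ``data/benchmarks.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from importlib import resources

import numpy as np
import yaml

from lexiprop.corpus_io import Corpus, Post
from lexiprop.embeddings import EmbeddingSpace

__all__ = [
    "SyntheticSpec",
    "generate_vocabulary",
    "generate_corpus",
    "generate_embeddings",
]


@dataclass
class SyntheticSpec:
    """Parameters of the planted two-group benchmark.

    ``enrichment`` multiplies the sampling weight of a group's own polarity
    words and divides that of the opposite group's words (background weight
    is 1), so the two cohorts differ only in their planted vocabularies.
    ``cluster_separation`` is the Euclidean distance between the two
    polarity cluster centers; ``noise_sd`` the per-coordinate spread around
    a center.  With separation 2*sqrt(2), dimension 50 and noise 0.1 the
    expected within-cluster cosine is about 0.8 and the cross-cluster
    cosine about -0.8.
    """

    n_background: int = 100
    n_dep_words: int = 30
    n_nondep_words: int = 30
    n_users_per_group: int = 50
    posts_per_user: int = 20
    tokens_per_post: int = 15
    enrichment: float = 6.0
    embed_dim: int = 50
    cluster_separation: float = 2.8284271247461903
    noise_sd: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_background", "n_dep_words", "n_nondep_words",
                     "n_users_per_group", "posts_per_user", "tokens_per_post"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.enrichment <= 1:
            raise ValueError("enrichment must be > 1")
        if self.cluster_separation < 0:
            raise ValueError("cluster_separation must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    @classmethod
    def from_benchmark(cls, name: str = "lexicon", rng_seed: int | None = None) -> "SyntheticSpec":
        """Load a named parameter set from the versioned benchmark file
        (``lexicon`` or ``detection``)."""
        ref = resources.files("lexiprop.data") / "benchmarks.yaml"
        cfg = yaml.safe_load(ref.read_text(encoding="utf-8"))
        if name not in cfg:
            raise ValueError(f"unknown benchmark {name!r}; available: {sorted(cfg)}")
        spec = cls(**cfg[name])
        if rng_seed is not None:
            spec.rng_seed = rng_seed
        return spec

    def to_dict(self) -> dict:
        return asdict(self)


def generate_vocabulary(spec: SyntheticSpec) -> tuple[list[str], list[str], list[str], dict[str, int]]:
    """Disjoint background / depressive / nondepressive word lists plus the
    gold polarity map (-1 depressive, +1 nondepressive) over the planted
    words."""
    background = [f"bg{i:04d}" for i in range(spec.n_background)]
    dep = [f"dep{i:04d}" for i in range(spec.n_dep_words)]
    non = [f"non{i:04d}" for i in range(spec.n_nondep_words)]
    gold = {w: -1 for w in dep}
    gold.update({w: +1 for w in non})
    return background, dep, non, gold


def _group_weights(spec: SyntheticSpec, vocab: list[str], group: str) -> np.ndarray:
    w = np.ones(len(vocab))
    for i, word in enumerate(vocab):
        if word.startswith("dep"):
            w[i] = spec.enrichment if group == "depressed" else 1.0 / spec.enrichment
        elif word.startswith("non"):
            w[i] = spec.enrichment if group == "nondepressed" else 1.0 / spec.enrichment
    return w / w.sum()


def generate_corpus(spec: SyntheticSpec) -> Corpus:
    """Sample the two-cohort corpus; posts arrive user by user, already
    tokenized (text is the space-joined token sequence)."""
    background, dep, non, _ = generate_vocabulary(spec)
    vocab = background + dep + non
    rng = np.random.default_rng(spec.rng_seed)
    corpus = Corpus()
    for group, prefix in (("depressed", "dep_u"), ("nondepressed", "non_u")):
        probs = _group_weights(spec, vocab, group)
        for u in range(spec.n_users_per_group):
            uid = f"{prefix}{u:04d}"
            for _ in range(spec.posts_per_user):
                idx = rng.choice(len(vocab), size=spec.tokens_per_post, p=probs)
                tokens = [vocab[i] for i in idx]
                corpus.posts.append(Post(user_id=uid, text=" ".join(tokens),
                                         group=group, tokens=tokens))
    return corpus


def generate_embeddings(
    spec: SyntheticSpec,
    vocabulary: tuple[list[str], list[str], list[str]] | None = None,
) -> EmbeddingSpace:
    """Geometric embedding space with the planted cluster structure.

    Depressive words are Gaussian around +r*e1 and nondepressive around
    -r*e1 with r = cluster_separation / 2 (noise ``noise_sd`` per
    coordinate); background words are isotropic around the origin with unit
    total norm in expectation.
    """
    if vocabulary is None:
        background, dep, non, _ = generate_vocabulary(spec)
    else:
        background, dep, non = vocabulary
    d = spec.embed_dim
    rng = np.random.default_rng(spec.rng_seed + 1)  # decoupled from the corpus stream
    center = np.zeros(d)
    center[0] = spec.cluster_separation / 2.0
    vectors: dict[str, np.ndarray] = {}
    for w in dep:
        vectors[w] = center + rng.normal(scale=spec.noise_sd, size=d)
    for w in non:
        vectors[w] = -center + rng.normal(scale=spec.noise_sd, size=d)
    for w in background:
        vectors[w] = rng.normal(scale=1.0 / np.sqrt(d), size=d)
    return EmbeddingSpace(dim=d, vectors=vectors)
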