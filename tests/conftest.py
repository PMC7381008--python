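import warnings

import pytest

from lexiprop import (
    SeedSet,
    SyntheticSpec,
    generate_corpus,
    generate_embeddings,
    generate_vocabulary,
)
from lexiprop.embeddings import CandidateSet
from lexiprop.graph_lpa import build_graph


@pytest.fixture(scope="session")
def bench_spec():
    return SyntheticSpec.from_benchmark("lexicon")


@pytest.fixture(scope="session")
def bench_vocab(bench_spec):
    return generate_vocabulary(bench_spec)


@pytest.fixture(scope="session")
def bench_gold(bench_vocab):
    return bench_vocab[3]


@pytest.fixture(scope="session")
def bench_space(bench_spec, bench_vocab):
    bg, dep, non, _ = bench_vocab
    return generate_embeddings(bench_spec, (bg, dep, non))


@pytest.fixture(scope="session")
def bench_corpus(bench_spec):
    return generate_corpus(bench_spec)


@pytest.fixture(scope="session")
def bench_seeds(bench_vocab):
    _, dep, non, _ = bench_vocab
    return SeedSet(depressive=set(dep[:10]), nondepressive=set(non[:10]))


def random_graph(rng, n_max=50, edge_p=0.15, n_dep=None, n_non=None):
    """A random seeded semantic graph for propagation tests."""
    n = int(rng.integers(5, n_max + 1))
    words = [f"w{i:03d}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_p:
                edges.append((words[i], words[j], float(rng.uniform(0.5, 1.0))))
    if not edges:
        edges = [(words[0], words[1], 0.7)]
    n_dep = n_dep or int(rng.integers(1, 4))
    n_non = n_non or int(rng.integers(1, 4))
    perm = rng.permutation(n)
    seeds = SeedSet(
        depressive={words[i] for i in perm[:n_dep]},
        nondepressive={words[i] for i in perm[n_dep : n_dep + n_non]},
    )
    cand = CandidateSet(words=set(words), edges=edges, T_c=0.5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_graph(cand, seeds), seeds
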