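"""Shared fixtures: small random embedding tables and a compact benchmark."""

from itertools import product

import numpy as np
import pytest

from i5hmcvec import (
    EmbeddingTable,
    FixtureSpec,
    MultiKEmbeddings,
    make_benchmark_fixture,
)


def random_table(k: int, dim: int, seed: int = 0) -> EmbeddingTable:
    """Full-vocabulary table with i.i.d. Gaussian vectors (no training)."""
    rng = np.random.default_rng(seed)
    vectors = {
        "".join(p): rng.normal(size=dim) for p in product("ACGT", repeat=k)
    }
    return EmbeddingTable(k=k, dim=dim, vectors=vectors)


@pytest.fixture(scope="session")
def multik_small() -> MultiKEmbeddings:
    """k = 3..5 tables, dim 4 — fast encoding checks."""
    return MultiKEmbeddings(
        tables={k: random_table(k, 4, seed=k) for k in (3, 4, 5)}
    )


@pytest.fixture(scope="session")
def multik_full() -> MultiKEmbeddings:
    """The method's layout: k = 3..8, dim 100 (random vectors)."""
    return MultiKEmbeddings(
        tables={k: random_table(k, 100, seed=k) for k in range(3, 9)}
    )


@pytest.fixture(scope="session")
def small_fixture():
    """Compact synthetic study: 12 transcripts, short peaks."""
    spec = FixtureSpec(
        n_chromosomes=2,
        chromosome_length=20_000,
        n_transcripts=12,
        peak_length_range=(100, 600),
        seed=5,
    )
    return make_benchmark_fixture(spec)
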