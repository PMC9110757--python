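"""Sequence encoding: overlapping k-mers -> averaged embeddings -> one vector.

A length-l RNA sequence is read as its l-k+1 overlapping k-mers; each
in-vocabulary k-mer is looked up in the k-table and the vectors are
averaged, which removes the length dependence across the 200-8000 nt
range of region sizes.  The per-k averages are concatenated in ascending
k order, so with k = 3..8 and 100-dimensional tables a sequence becomes a
600-dimensional feature vector regardless of its length.

Out-of-vocabulary k-mers (including any containing N) are skipped and the
divisor reduced to the number of k-mers actually used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import LabeledDataset
from .embeddings import EmbeddingTable, MultiKEmbeddings
from .errors import TooShortError, UnencodableSequenceError

__all__ = [
    "FeatureVector",
    "segment_kmers",
    "embed_sequence_k",
    "encode",
    "encode_dataset",
]


@dataclass
class FeatureVector:
    """Concatenated multi-k encoding with its block layout."""

    values: np.ndarray
    layout: list[tuple[int, int]]  # ordered (k, dim) blocks

    def __post_init__(self) -> None:
        ks = [k for k, _ in self.layout]
        assert ks == sorted(ks), "blocks must be in ascending k order"
        assert self.values.shape == (sum(d for _, d in self.layout),)


def segment_kmers(sequence: str, k: int) -> list[str]:
    """Overlapping k-mers of a sequence: token j covers positions [j, j+k)."""
    if k < 1:
        raise TooShortError(f"k must be >= 1, got {k}")
    if len(sequence) < k:
        raise TooShortError(
            f"sequence of length {len(sequence)} is shorter than k={k}"
        )
    return [sequence[j : j + k] for j in range(len(sequence) - k + 1)]


def embed_sequence_k(sequence: str, table: EmbeddingTable) -> np.ndarray:
    """Mean embedding of a sequence's in-vocabulary k-mers."""
    tokens = segment_kmers(sequence, table.k)
    rows = table.token_indices(tokens)
    if rows.size == 0:
        raise UnencodableSequenceError(
            f"no {table.k}-mer of the sequence is in the vocabulary"
        )
    return table.matrix[rows].mean(axis=0)


def encode(sequence: str, multik: MultiKEmbeddings) -> FeatureVector:
    """Concatenate per-k mean embeddings in ascending k order."""
    if len(sequence) < multik.max_k:
        raise TooShortError(
            f"sequence of length {len(sequence)} is shorter than max k="
            f"{multik.max_k}"
        )
    blocks = [embed_sequence_k(sequence, t) for t in multik.tables.values()]
    return FeatureVector(
        values=np.concatenate(blocks),
        layout=[(k, multik.dim) for k in multik.ks],
    )


def encode_dataset(
    dataset: LabeledDataset, multik: MultiKEmbeddings
) -> tuple[np.ndarray, np.ndarray]:
    """Encode every sequence; row order mirrors dataset order.

    All failures are collected first so the error names every offending
    sequence rather than just the first.
    """
    rows: list[np.ndarray] = []
    failures: list[str] = []
    for i, seq in enumerate(dataset.sequences):
        name = dataset.provenance[i].id or f"record{i}"
        try:
            rows.append(encode(seq, multik).values)
        except (TooShortError, UnencodableSequenceError) as exc:
            failures.append(f"{name}: {exc}")
    if failures:
        raise UnencodableSequenceError(
            "unencodable sequences: " + "; ".join(failures)
        )
    return np.vstack(rows), np.asarray(dataset.labels, dtype=int)
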