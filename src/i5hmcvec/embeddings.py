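"""Genome corpora and per-k k-mer embedding tables.

The feature pipeline starts from distributed k-mer representations learned
on a genome: chromosomes are cut into long fragments (the "sentences"),
each fragment is read as its stream of overlapping k-mers (the "words"),
and a skip-gram model assigns every observed k-mer a dense vector.  One
independent table is trained per word length k; downstream encoding only
ever averages vectors of a single k, so no cross-k geometry is needed.

Tables are stored in the word2vec text format (header ``vocab_size dim``,
then one ``token v1 .. v_dim`` line per k-mer), so they interoperate with
other embedding tooling.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    EmptyVocabularyError,
    FormatError,
    InvalidInputError,
    MissingReferenceError,
)
from .word2vec import train_skipgram

__all__ = [
    "Corpus",
    "EmbeddingTable",
    "MultiKEmbeddings",
    "build_corpus",
    "kmer_vocabulary",
    "train_kmer_embeddings",
    "train_multi_k",
    "write_table",
    "read_table",
    "write_embeddings",
    "read_embeddings",
]

_DNA = set("ACGTN")
# RNA -> DNA canonicalisation used for every vocabulary lookup
_TO_DNA = str.maketrans("acgtunU", "ACGTTNT")


@dataclass
class Corpus:
    """Training text: uppercase DNA fragments cut from selected chromosomes."""

    fragments: list[str]
    source_chromosomes: list[str]

    def __post_init__(self) -> None:
        for frag in self.fragments:
            if not frag:
                raise InvalidInputError("corpus fragments must be non-empty")
            if set(frag) - _DNA:
                bad = sorted(set(frag) - _DNA)
                raise InvalidInputError(
                    f"corpus fragments must be uppercase ACGTN; found {bad}"
                )

    def __len__(self) -> int:
        return len(self.fragments)


def build_corpus(
    genome: Mapping[str, str],
    chromosomes: Sequence[str],
    fragment_length: int = 10_000,
    *,
    max_k: int = 8,
) -> Corpus:
    """Cut selected chromosomes into consecutive non-overlapping fragments.

    Fragment order is deterministic: chromosomes in the order given, then
    position.  A final remainder shorter than ``fragment_length`` is kept
    only if it still holds at least one ``max_k``-mer.
    """
    if not chromosomes:
        raise InvalidInputError("no chromosomes selected for the corpus")
    if fragment_length < max_k:
        raise InvalidInputError(
            f"fragment_length {fragment_length} < max_k {max_k}"
        )
    missing = [c for c in chromosomes if c not in genome]
    if missing:
        raise MissingReferenceError(
            f"chromosomes absent from genome: {missing}"
        )
    fragments: list[str] = []
    for chrom in chromosomes:
        seq = genome[chrom].upper()
        for start in range(0, len(seq), fragment_length):
            frag = seq[start : start + fragment_length]
            if len(frag) >= max_k:
                fragments.append(frag)
    return Corpus(fragments=fragments, source_chromosomes=list(chromosomes))


def _fragment_tokens(fragment: str, k: int) -> list[str]:
    """Overlapping k-mers of a fragment, dropping any containing N."""
    return [
        tok
        for i in range(len(fragment) - k + 1)
        if "N" not in (tok := fragment[i : i + k])
    ]


def kmer_vocabulary(corpus: Corpus, k: int) -> list[str]:
    """Sorted list of distinct valid (ACGT-only) k-mers observed in the corpus."""
    if k < 1:
        raise InvalidInputError(f"k must be >= 1, got {k}")
    vocab: set[str] = set()
    for frag in corpus.fragments:
        vocab.update(_fragment_tokens(frag, k))
    return sorted(vocab)


@dataclass
class EmbeddingTable:
    """Mapping from k-mer token to a fixed-dimension embedding vector.

    Tokens are DNA (ACGT, length exactly ``k``).  ``lookup`` canonicalises
    RNA input (U -> T, uppercase) before consulting the vocabulary, so the
    encoder can work on RNA strings directly.
    """

    k: int
    dim: int
    vectors: dict[str, np.ndarray]
    training_meta: dict = field(default_factory=dict)

    _index: dict[str, int] = field(default=None, repr=False, compare=False)  # type: ignore[assignment]
    _matrix: np.ndarray = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.k < 1 or self.dim < 1:
            raise InvalidInputError("k and dim must be >= 1")
        if len(self.vectors) > 4**self.k:
            raise InvalidInputError("vocabulary exceeds 4^k tokens")
        for tok, vec in self.vectors.items():
            if len(tok) != self.k or set(tok) - set("ACGT"):
                raise InvalidInputError(
                    f"token {tok!r} is not a length-{self.k} ACGT word"
                )
            if np.asarray(vec).shape != (self.dim,):
                raise InvalidInputError(
                    f"vector for {tok!r} does not have dimension {self.dim}"
                )
        tokens = sorted(self.vectors)
        object.__setattr__(self, "_index", {t: i for i, t in enumerate(tokens)})
        matrix = (
            np.stack([np.asarray(self.vectors[t], dtype=float) for t in tokens])
            if tokens
            else np.empty((0, self.dim))
        )
        object.__setattr__(self, "_matrix", matrix)

    @property
    def tokens(self) -> list[str]:
        return sorted(self.vectors)

    def canonicalize(self, token: str) -> str:
        return token.translate(_TO_DNA)

    def lookup(self, token: str) -> np.ndarray | None:
        """Vector for a token, or ``None`` if out of vocabulary.

        The token may be RNA or DNA, any case.  N-containing tokens are
        never in the vocabulary and return ``None``.  A token of the wrong
        length is a caller error and raises.
        """
        if len(token) != self.k:
            raise InvalidInputError(
                f"token {token!r} has length {len(token)}, table expects k={self.k}"
            )
        i = self._index.get(self.canonicalize(token))
        return None if i is None else self._matrix[i]

    def token_indices(self, tokens: Iterable[str]) -> np.ndarray:
        """Row indices into ``matrix`` for in-vocabulary tokens (vectorised lookup)."""
        idx = self._index
        canon = self.canonicalize
        return np.fromiter(
            (j for t in tokens if (j := idx.get(canon(t))) is not None),
            dtype=np.int64,
        )

    @property
    def matrix(self) -> np.ndarray:
        """Vectors stacked in sorted-token order."""
        return self._matrix


def train_kmer_embeddings(
    corpus: Corpus,
    k: int,
    dim: int = 100,
    *,
    window: int = 10,
    epochs: int = 10,
    negative: int = 5,
    seed: int = 0,
    batch_size: int = 8192,
) -> EmbeddingTable:
    """Train one skip-gram embedding table for word length ``k``.

    Each corpus fragment contributes one sentence: its overlapping k-mers
    in order, with N-containing k-mers dropped.  Identical inputs and seed
    reproduce identical vectors.
    """
    if k < 1:
        raise InvalidInputError(f"k must be >= 1, got {k}")
    if not corpus.fragments:
        raise InvalidInputError("corpus is empty")
    sentences = [_fragment_tokens(frag, k) for frag in corpus.fragments]
    if not any(sentences):
        raise EmptyVocabularyError(f"corpus contains no valid {k}-mer")
    vocab, vectors = train_skipgram(
        sentences,
        dim,
        window=window,
        epochs=epochs,
        negative=negative,
        seed=seed,
        batch_size=batch_size,
    )
    return EmbeddingTable(
        k=k,
        dim=dim,
        vectors={tok: vectors[i] for i, tok in enumerate(vocab)},
        training_meta={
            "window": window,
            "epochs": epochs,
            "negative": negative,
            "seed": seed,
        },
    )


@dataclass
class MultiKEmbeddings:
    """Embedding tables for a fixed ascending set of word lengths."""

    tables: dict[int, EmbeddingTable]

    def __post_init__(self) -> None:
        if not self.tables:
            raise InvalidInputError("at least one table required")
        dims = {t.dim for t in self.tables.values()}
        if len(dims) != 1:
            raise InvalidInputError(f"tables disagree on dimension: {dims}")
        for k, table in self.tables.items():
            if table.k != k:
                raise InvalidInputError(
                    f"table registered under k={k} reports k={table.k}"
                )
        self.tables = dict(sorted(self.tables.items()))

    @property
    def ks(self) -> list[int]:
        return list(self.tables)

    @property
    def dim(self) -> int:
        return next(iter(self.tables.values())).dim

    @property
    def feature_dim(self) -> int:
        return self.dim * len(self.tables)

    @property
    def max_k(self) -> int:
        return max(self.tables)


def train_multi_k(
    corpus: Corpus,
    ks: Sequence[int] = (3, 4, 5, 6, 7, 8),
    dim: int = 100,
    *,
    window: int = 10,
    epochs: int = 10,
    negative: int = 5,
    seed: int = 0,
) -> MultiKEmbeddings:
    """Train an independent table per k (seed offset by k for distinct streams)."""
    tables = {
        k: train_kmer_embeddings(
            corpus,
            k,
            dim,
            window=window,
            epochs=epochs,
            negative=negative,
            seed=(seed + k) % 2**31,
        )
        for k in sorted(ks)
    }
    return MultiKEmbeddings(tables=tables)


def write_table(table: EmbeddingTable, sink: str | os.PathLike | IO[str]) -> None:
    """Write a table in word2vec text format."""
    own = isinstance(sink, (str, os.PathLike))
    fh: IO[str] = open(sink, "w") if own else sink  # type: ignore[arg-type]
    try:
        fh.write(f"{len(table.vectors)} {table.dim}\n")
        for tok in table.tokens:
            vals = " ".join(format(x, ".8g") for x in table.vectors[tok])
            fh.write(f"{tok} {vals}\n")
    finally:
        if own:
            fh.close()


def read_table(source: str | os.PathLike | IO[str]) -> EmbeddingTable:
    """Read a word2vec text-format table; token length defines k."""
    own = isinstance(source, (str, os.PathLike))
    fh: IO[str] = open(source) if own else source  # type: ignore[arg-type]
    try:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError("header must be 'vocab_size dim'")
        try:
            n_vocab, dim = int(header[0]), int(header[1])
        except ValueError as exc:
            raise FormatError("non-integer header fields") from exc
        vectors: dict[str, np.ndarray] = {}
        k: int | None = None
        for line_no, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            tok, vals = parts[0], parts[1:]
            if len(vals) != dim:
                raise FormatError(
                    f"line {line_no}: expected {dim} values, got {len(vals)}"
                )
            if k is None:
                k = len(tok)
            elif len(tok) != k:
                raise FormatError(
                    f"line {line_no}: token length {len(tok)} != {k}"
                )
            try:
                vectors[tok] = np.array([float(v) for v in vals])
            except ValueError as exc:
                raise FormatError(f"line {line_no}: non-numeric value") from exc
        if len(vectors) != n_vocab:
            raise FormatError(
                f"header declares {n_vocab} tokens, file holds {len(vectors)}"
            )
        if k is None:
            raise FormatError("table holds no tokens")
        return EmbeddingTable(k=k, dim=dim, vectors=vectors)
    finally:
        if own:
            fh.close()


def write_embeddings(multik: MultiKEmbeddings, directory: str | os.PathLike) -> None:
    """Write one ``k<k>.w2v`` file per table into ``directory``."""
    os.makedirs(directory, exist_ok=True)
    for k, table in multik.tables.items():
        write_table(table, os.path.join(directory, f"k{k}.w2v"))


def read_embeddings(directory: str | os.PathLike) -> MultiKEmbeddings:
    """Read every ``k*.w2v`` file in ``directory`` into a multi-k set."""
    tables: dict[int, EmbeddingTable] = {}
    for name in sorted(os.listdir(directory)):
        if name.startswith("k") and name.endswith(".w2v"):
            table = read_table(os.path.join(directory, name))
            tables[table.k] = table
    if not tables:
        raise FormatError(f"no k*.w2v tables found in {directory}")
    return MultiKEmbeddings(tables=tables)
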