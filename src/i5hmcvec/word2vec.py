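"""Skip-gram word embeddings with negative sampling (SGNS).

A compact, fully deterministic trainer for the word2vec skip-gram
objective, vectorised with numpy.  It is used to learn distributed
representations of k-mer "words" from a genome corpus, in the spirit of
dna2vec: each sentence is the stream of overlapping k-mers of one genomic
fragment, and a k-mer's vector is shaped by the k-mers that flank it.

The trainer optimises the standard SGNS objective

    log sigma(v_c . u_o) + sum_{i=1..neg} E[ log sigma(-v_c . u_n_i) ]

by minibatch SGD with a linearly decaying learning rate.  Because a k-mer
vocabulary is tiny compared to a minibatch, the same row would receive
hundreds of summed per-pair gradients in one update; row updates are
therefore the *mean* of the per-pair gradients touching that row, which
keeps every step bounded by the learning rate regardless of batch
composition.  Negative words are drawn from the unigram distribution
raised to the 3/4 power.  All randomness flows from a single
``numpy.random.Generator``, so a fixed seed reproduces the embedding
matrix bitwise (single-threaded numpy).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

from .errors import EmptyVocabularyError, InvalidInputError

__all__ = ["train_skipgram"]


def _pair_arrays(
    sentences: list[np.ndarray], window: int
) -> tuple[np.ndarray, np.ndarray]:
    """All (center, context) index pairs within ``window`` positions."""
    centers: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    for sent in sentences:
        n = sent.size
        for off in range(1, window + 1):
            if n <= off:
                break
            # both directions: token at i with token at i+off
            centers.append(sent[:-off])
            contexts.append(sent[off:])
            centers.append(sent[off:])
            contexts.append(sent[:-off])
    if not centers:
        # single-token sentences still define a vocabulary but no pairs
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(centers), np.concatenate(contexts)


def _apply_row_mean(
    matrix: np.ndarray, rows: np.ndarray, grads: np.ndarray, lr: float
) -> None:
    """SGD step where each touched row moves by the mean of its gradients."""
    uniq, inv = np.unique(rows, return_inverse=True)
    acc = np.zeros((uniq.size, matrix.shape[1]))
    np.add.at(acc, inv, grads)
    counts = np.bincount(inv, minlength=uniq.size)
    matrix[uniq] -= lr * acc / counts[:, None]


def train_skipgram(
    sentences: Iterable[Sequence[str]],
    dim: int,
    *,
    window: int = 10,
    epochs: int = 10,
    negative: int = 5,
    learning_rate: float = 0.025,
    seed: int = 0,
    batch_size: int = 8192,
) -> tuple[list[str], np.ndarray]:
    """Train SGNS embeddings over token sentences.

    Parameters
    ----------
    sentences
        Iterable of token sequences ("sentences").  Tokens are arbitrary
        strings; the vocabulary is the set of observed tokens.
    dim
        Embedding dimension.
    window
        Maximum distance between center and context token.
    epochs
        Passes over the (center, context) pair list.
    negative
        Negative samples per positive pair.
    learning_rate
        Initial SGD step size; decays linearly to ~0 over training.
    seed
        Seed for initialisation, pair shuffling and negative sampling.
    batch_size
        Pairs per SGD minibatch.

    Returns
    -------
    (vocab, vectors)
        ``vocab`` is the sorted token list; ``vectors[i]`` is the embedding
        of ``vocab[i]`` (the input/"center" matrix, as in word2vec).
    """
    if dim < 1:
        raise InvalidInputError(f"dim must be >= 1, got {dim}")
    if window < 1 or epochs < 0 or negative < 0:
        raise InvalidInputError("window must be >= 1, epochs/negative >= 0")

    materialised = [list(s) for s in sentences]
    vocab = sorted({tok for sent in materialised for tok in sent})
    if not vocab:
        raise EmptyVocabularyError("no tokens observed in the corpus")
    index = {tok: i for i, tok in enumerate(vocab)}
    encoded = [
        np.fromiter((index[t] for t in sent), dtype=np.int64, count=len(sent))
        for sent in materialised
        if sent
    ]

    n_vocab = len(vocab)
    counts = np.zeros(n_vocab, dtype=np.float64)
    for sent in encoded:
        np.add.at(counts, sent, 1.0)

    rng = np.random.default_rng(seed)
    syn0 = (rng.random((n_vocab, dim)) - 0.5) / dim  # center vectors
    syn1 = np.zeros((n_vocab, dim))  # context vectors

    centers, contexts = _pair_arrays(encoded, window)
    n_pairs = centers.size
    if n_pairs == 0 or epochs == 0:
        return vocab, syn0

    # unigram^(3/4) noise distribution, sampled via inverse CDF
    noise = counts**0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    total = epochs * n_pairs
    done = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_size):
            idx = order[start : start + batch_size]
            c = centers[idx]
            o = contexts[idx]
            b = idx.size
            lr = learning_rate * max(1.0 - done / total, 1e-4)
            done += b

            v = syn0[c]  # (b, d)
            u_pos = syn1[o]  # (b, d)
            g_pos = expit(np.einsum("bd,bd->b", v, u_pos)) - 1.0

            if negative:
                neg = np.searchsorted(noise_cdf, rng.random((b, negative)))
                u_neg = syn1[neg]  # (b, neg, d)
                g_neg = expit(np.einsum("bnd,bd->bn", u_neg, v))
                dv = g_pos[:, None] * u_pos + np.einsum(
                    "bn,bnd->bd", g_neg, u_neg
                )
            else:
                dv = g_pos[:, None] * u_pos

            _apply_row_mean(syn0, c, dv, lr)
            if negative:
                du = np.concatenate(
                    [
                        g_pos[:, None] * v,
                        (g_neg[..., None] * v[:, None, :]).reshape(-1, dim),
                    ]
                )
                rows = np.concatenate([o, neg.reshape(-1)])
            else:
                du, rows = g_pos[:, None] * v, o
            _apply_row_mean(syn1, rows, du, lr)

    return vocab, syn0
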