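"""Separability and embedding-space diagnostics.

The J-score is a Fisher-style criterion: the between-class scatter
(squared distance between class mean vectors) divided by the total
within-class scatter (summed squared deviations of samples from their
class mean).  Both scatter matrices are scalarised by the trace, so J is
invariant under translation and orthogonal transformation of the feature
space; a larger J means better-separated classes.

``reduce`` projects features to 2-D/3-D by PCA or t-SNE for visual
inspection, and ``symmetry_report`` quantifies the mirror arrangement of
complementary / reverse-complementary k-mer embeddings in the principal
plane (the "semantic symmetry" of genome word embeddings).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .embeddings import EmbeddingTable
from .errors import DegenerateInputError, InvalidInputError

__all__ = ["JScoreResult", "SymmetryReport", "j_score", "reduce", "symmetry_report"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class JScoreResult:
    j: float
    s_b_trace: float
    s_w_trace: float
    dim: int
    finite: bool = True


def j_score(features: np.ndarray, labels: np.ndarray) -> JScoreResult:
    """Fisher-style class separability of a labeled feature matrix.

    s_b is the outer product of the class-mean difference; s_w sums the
    outer products of sample deviations from their own class mean (no
    division by class size).  J = trace(s_b) / trace(s_w).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and np.asarray(labels).size > 1:
        X = X.T
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.size:
        raise InvalidInputError("features and labels must align")
    pos = X[y == 1]
    neg = X[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise InvalidInputError("both classes must be non-empty")
    mu_pos = pos.mean(axis=0)
    mu_neg = neg.mean(axis=0)
    diff = mu_pos - mu_neg
    s_b = float(diff @ diff)
    s_w = float(((pos - mu_pos) ** 2).sum() + ((neg - mu_neg) ** 2).sum())
    if s_w == 0.0:
        return JScoreResult(
            j=float("inf"), s_b_trace=s_b, s_w_trace=0.0, dim=X.shape[1], finite=False
        )
    return JScoreResult(j=s_b / s_w, s_b_trace=s_b, s_w_trace=s_w, dim=X.shape[1])


def _fix_pca_signs(components: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make the largest-magnitude loading of each component positive."""
    for i, comp in enumerate(components):
        if comp[np.argmax(np.abs(comp))] < 0:
            components[i] = -comp
            scores[:, i] = -scores[:, i]
    return components, scores


def _pca_project(X: np.ndarray, n_components: int) -> np.ndarray:
    """Sign-fixed PCA scores (largest-magnitude loading made positive)."""
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    _fix_pca_signs(pca.components_, scores)
    return scores


def reduce(
    features: np.ndarray,
    target_dim: int = 2,
    method: str = "pca",
    seed: int = 0,
    perplexity: float = 30.0,
) -> np.ndarray:
    """Project features to 2 or 3 dimensions, rows aligned with input.

    PCA output is sign-fixed (largest-magnitude loading positive) so
    repeated runs are identical; t-SNE is seeded and single-threaded.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise InvalidInputError("features must be a 2-D matrix")
    if target_dim not in (2, 3):
        raise InvalidInputError(f"target_dim must be 2 or 3, got {target_dim}")
    if target_dim >= X.shape[1]:
        raise InvalidInputError("target_dim must be below the input dimension")
    if X.shape[0] < target_dim + 1:
        raise InvalidInputError("need at least target_dim + 1 samples")
    degenerate = bool(np.all(X == X[0]))
    if method == "pca":
        if degenerate:
            warnings.warn("all points identical; PCA output has zero variance")
        return _pca_project(X, target_dim)
    if method == "tsne":
        if degenerate:
            raise DegenerateInputError("t-SNE is undefined for identical points")
        perp = min(perplexity, (X.shape[0] - 1) / 3.0)
        tsne = TSNE(
            n_components=target_dim,
            random_state=seed,
            perplexity=max(perp, 1.0),
            init="pca",
            method="exact" if target_dim == 3 else "barnes_hut",
        )
        return tsne.fit_transform(X)
    raise InvalidInputError(f"unknown method {method!r}")


@dataclass
class SymmetryReport:
    """Pairwise mirror statistics of k-mer embeddings in the principal plane."""

    pairs: pd.DataFrame  # token, partner, relation, y_token, y_partner, pair_score
    scores: dict[str, float]  # relation -> correlation of y(token) with -y(partner)


def _pair_score(y1: float, y2: float) -> float:
    """1 for an exact mirror (y2 = -y1), 0 for a parallel pair; in [0, 1]."""
    denom = abs(y1) + abs(y2)
    if denom == 0:
        return 0.0
    return 1.0 - abs(y1 + y2) / denom


def symmetry_report(table: EmbeddingTable, projection_dim: int = 2) -> SymmetryReport:
    """Mirror-symmetry of complement / reverse-complement embedding pairs.

    All k-mer vectors are PCA-projected; for every token the second
    principal coordinate y is compared with that of its complement and of
    its reverse complement.  The summary score per relation is the Pearson
    correlation between y(token) and -y(partner) over non-palindromic
    pairs: 1 means a perfect mirror about the first principal axis, 0 no
    relation.  Palindromic (self-paired) tokens appear in the table with
    their |y| but are excluded from the correlation.
    """
    if not table.vectors:
        raise InvalidInputError("embedding table is empty")
    if not 2 <= projection_dim <= table.dim:
        raise InvalidInputError(
            "projection_dim must be between 2 and the table dimension"
        )
    tokens = table.tokens
    coords = _pca_project(table.matrix, projection_dim)
    y = {tok: float(coords[i, 1]) for i, tok in enumerate(tokens)}

    relations = {
        "complement": lambda t: t.translate(_COMPLEMENT),
        "reverse_complement": lambda t: t.translate(_COMPLEMENT)[::-1],
    }
    rows = []
    for relation, partner_of in relations.items():
        seen: set[frozenset[str]] = set()
        for tok in tokens:
            partner = partner_of(tok)
            if partner not in y:
                continue
            key = frozenset((tok, partner))
            if key in seen:
                continue
            seen.add(key)
            rows.append(
                {
                    "token": tok,
                    "partner": partner,
                    "relation": relation,
                    "y_token": y[tok],
                    "y_partner": y[partner],
                    "pair_score": _pair_score(y[tok], y[partner])
                    if tok != partner
                    else abs(y[tok]),
                    "palindromic": tok == partner,
                }
            )
    pairs = pd.DataFrame(rows)
    scores: dict[str, float] = {}
    for relation in relations:
        sub = pairs[(pairs.relation == relation) & (~pairs.palindromic)]
        if len(sub) >= 2 and sub.y_token.std() > 0 and sub.y_partner.std() > 0:
            scores[relation] = float(
                np.corrcoef(sub.y_token, -sub.y_partner)[0, 1]
            )
        else:
            scores[relation] = float("nan")
    return SymmetryReport(pairs=pairs, scores=scores)
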