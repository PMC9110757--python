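"""End-to-end convenience pipeline over the synthetic fixtures.

Chains fixture generation, embedding training on the fixture genome,
sequence encoding and SVM cross-validation into one call.  The SVM
operating point defaults to (c, gamma) = (2^4, 2^-5), the optimum
reported for the concatenated multi-k embedding; the grid search in
:mod:`i5hmcvec.classify` remains available for re-calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import SVMClassifier
from .embeddings import Corpus, MultiKEmbeddings, build_corpus, train_multi_k
from .encoder import encode_dataset
from .evaluate import MetricsReport, repeated_cv
from .fixtures import (
    FixtureResult,
    FixtureSpec,
    make_benchmark_fixture,
    reduced_embedding_config,
)

__all__ = ["PipelineResult", "run_fixture_pipeline"]


def iv_corpus_subset(corpus: Corpus, n_fragments: int) -> Corpus:
    """First ``n_fragments`` fragments of a corpus (deterministic subsample)."""
    return Corpus(
        fragments=corpus.fragments[:n_fragments],
        source_chromosomes=corpus.source_chromosomes,
    )


@dataclass
class PipelineResult:
    fixture: FixtureResult
    multik: MultiKEmbeddings
    features: np.ndarray
    labels: np.ndarray
    report: MetricsReport

    def fit_final_model(self) -> SVMClassifier:
        """SVM fitted on the full benchmark at the pipeline operating point."""
        return SVMClassifier(
            c=self._c,
            gamma=self._gamma,
            seed=self.fixture.spec.seed,
            standardize=True,
        ).fit(self.features, self.labels)


def run_fixture_pipeline(
    spec: FixtureSpec | None = None,
    *,
    ks: tuple[int, ...] | None = None,
    dim: int | None = None,
    window: int | None = None,
    epochs: int | None = None,
    negative: int | None = None,
    c: float = 2.0**4,
    gamma: float | str = "scale",
    repeats: int = 1,
    folds: int = 5,
    corpus_chromosomes: list[str] | None = None,
    corpus_nt: int | None = 50_000,
    fragment_length: int = 10_000,
) -> PipelineResult:
    """Fixture -> embeddings -> features -> repeated CV, all from one seed.

    Embedding hyperparameters default to :func:`reduced_embedding_config`.
    ``corpus_chromosomes`` restricts embedding training to a genome
    subset (default: the first chromosome) and ``corpus_nt`` caps the
    corpus size, keeping training desk-scale; the learned geometry is
    shared genome-wide because the fixture genome is compositionally
    homogeneous.  The SVM standardizes features per fit and uses the
    scale-adaptive kernel width, so the operating point transfers across
    embedding magnitudes.
    """
    spec = spec or FixtureSpec()
    cfg = reduced_embedding_config()
    ks = ks or cfg["ks"]
    dim = dim or cfg["dim"]
    window = window or cfg["window"]
    epochs = cfg["epochs"] if epochs is None else epochs
    negative = cfg["negative"] if negative is None else negative

    fixture = make_benchmark_fixture(spec)
    chroms = corpus_chromosomes or [next(iter(fixture.genome))]
    corpus = build_corpus(
        fixture.genome, chroms, fragment_length, max_k=max(ks)
    )
    if corpus_nt is not None:
        keep = max(1, corpus_nt // fragment_length)
        corpus = iv_corpus_subset(corpus, keep)
    multik = train_multi_k(
        corpus,
        ks=ks,
        dim=dim,
        window=window,
        epochs=epochs,
        negative=negative,
        seed=spec.seed,
    )
    X, y = encode_dataset(fixture.dataset, multik)
    report = repeated_cv(
        X,
        y,
        model_factory=lambda s: SVMClassifier(
            c=c, gamma=gamma, seed=s, standardize=True
        ),
        repeats=repeats,
        folds=folds,
        seed=spec.seed,
    )
    result = PipelineResult(
        fixture=fixture, multik=multik, features=X, labels=y, report=report
    )
    result._c = c
    result._gamma = gamma
    return result
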