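"""Seeded synthetic data: genome, annotation and labeled benchmarks.

Every other module can be exercised end-to-end without external
downloads: a multi-chromosome random genome is generated at a Drosophila-
like GC content, transcripts are laid out along the chromosomes, each
transcript hosts exactly one "peak" region (the positive class), and a
short motif is written into peaks so positives carry a recoverable
sequence signal.  Peak lengths are drawn log-uniformly across the
200-8000 nt span typical of region-level hMeRIP-seq windows — real peak
length distributions are strongly right-skewed, so most synthetic peaks
are short with a long upper tail.

Each transcript is sized at 2.5x its peak and the peak is placed so that
a contiguous non-peak stretch at least as long as the peak remains, which
guarantees the one-vs-one negative cropping is always feasible.

All generators are bitwise-deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from Bio.Seq import Seq

from .dataset import GenomicInterval, LabeledDataset, build_benchmark
from .errors import InvalidInputError

__all__ = [
    "FixtureSpec",
    "FixtureResult",
    "generate_genome",
    "generate_annotation",
    "plant_signal",
    "make_benchmark_fixture",
    "reduced_embedding_config",
]

_RNA = set("ACGU")

# deliberately GC-balanced 20-mer with no internal repeats
DEFAULT_MOTIF = "UGCAUGGACGUUAACCGGAU"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study."""

    n_chromosomes: int = 4
    chromosome_length: int = 100_000
    gc_fraction: float = 0.42
    n_transcripts: int = 50
    peak_length_range: tuple[int, int] = (200, 8000)
    motif: str = DEFAULT_MOTIF
    motif_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chromosome_length < 1:
            raise InvalidInputError("need at least one non-empty chromosome")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise InvalidInputError("gc_fraction must lie in [0, 1]")
        if not 0.0 <= self.motif_rate <= 1.0:
            raise InvalidInputError("motif_rate must lie in [0, 1]")
        lo, hi = self.peak_length_range
        if not 0 < lo <= hi:
            raise InvalidInputError("peak_length_range must satisfy 0 < lo <= hi")
        if set(self.motif) - _RNA:
            raise InvalidInputError("motif must be an RNA string (ACGU)")
        if len(self.motif) >= lo:
            raise InvalidInputError("motif must be shorter than the minimum peak")


def _stage_seed(seed: int, stage: int) -> int:
    return (seed * 8 + stage) % 2**31


def generate_genome(spec: FixtureSpec) -> dict[str, str]:
    """i.i.d. nucleotides at the requested GC fraction, per chromosome."""
    rng = np.random.default_rng(_stage_seed(spec.seed, 0))
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    genome = {}
    for i in range(spec.n_chromosomes):
        draws = rng.choice(4, size=spec.chromosome_length, p=probs)
        genome[f"chr{i + 1}"] = alphabet[draws].tobytes().decode()
    return genome


def generate_annotation(
    spec: FixtureSpec, genome: Mapping[str, str]
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Transcripts and their peaks: one peak per transcript.

    Transcripts are packed greedily onto chromosomes with a 50 nt gap.
    Peak placement leaves a contiguous non-peak gap of at least the peak
    length on one side, so a same-length negative always fits.
    """
    rng = np.random.default_rng(_stage_seed(spec.seed, 1))
    lo, hi = spec.peak_length_range
    cursors = {chrom: 0 for chrom in genome}
    transcripts: list[GenomicInterval] = []
    peaks: list[GenomicInterval] = []
    for i in range(spec.n_transcripts):
        peak_len = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        peak_len = min(max(peak_len, lo), hi)
        tx_len = int(2.5 * peak_len) + 10
        chrom = next(
            (
                c
                for c in genome
                if cursors[c] + tx_len <= len(genome[c])
            ),
            None,
        )
        if chrom is None:
            raise InvalidInputError(
                f"genome too small to place transcript {i} of {tx_len} nt"
            )
        tx_start = cursors[chrom]
        cursors[chrom] = tx_start + tx_len + 50
        strand = "+" if rng.random() < 0.5 else "-"
        # offset in [0, tx_len - 2*peak_len] leaves a >= peak_len gap after;
        # mirroring moves the gap before the peak
        offset = int(rng.integers(tx_len - 2 * peak_len + 1))
        if rng.random() < 0.5:
            offset = tx_len - peak_len - offset
        transcripts.append(
            GenomicInterval(chrom, tx_start, tx_start + tx_len, strand, id=f"tx{i}")
        )
        peaks.append(
            GenomicInterval(
                chrom,
                tx_start + offset,
                tx_start + offset + peak_len,
                strand,
                id=f"peak{i}",
            )
        )
    return transcripts, peaks


def plant_signal(
    genome: Mapping[str, str],
    peaks: list[GenomicInterval],
    motif: str,
    motif_rate: float,
    seed: int = 0,
) -> tuple[dict[str, str], int]:
    """Write the motif into each peak with probability ``motif_rate``.

    The motif is given as RNA; it is written strand-aware, so the RNA
    extracted from the peak on its annotated strand contains the motif
    verbatim.  Returns the modified genome copy and the planting count.
    """
    if any(len(motif) > p.length for p in peaks):
        raise InvalidInputError("motif longer than the shortest peak")
    if not 0.0 <= motif_rate <= 1.0:
        raise InvalidInputError("motif_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    motif_dna = motif.replace("U", "T")
    mutable = {chrom: bytearray(seq, "ascii") for chrom, seq in genome.items()}
    planted = 0
    for peak in peaks:
        if rng.random() >= motif_rate:
            continue
        insert = (
            motif_dna
            if peak.strand == "+"
            else str(Seq(motif_dna).reverse_complement())
        )
        offset = int(rng.integers(peak.length - len(insert) + 1))
        start = peak.start + offset
        mutable[peak.chrom][start : start + len(insert)] = insert.encode()
        planted += 1
    return {c: b.decode() for c, b in mutable.items()}, planted


@dataclass
class FixtureResult:
    """Everything one synthetic study produced."""

    spec: FixtureSpec
    genome: dict[str, str]
    transcripts: list[GenomicInterval]
    peaks: list[GenomicInterval]
    dataset: LabeledDataset
    n_planted: int


def make_benchmark_fixture(spec: FixtureSpec | None = None) -> FixtureResult:
    """Genome -> annotation -> motif planting -> paired benchmark."""
    spec = spec or FixtureSpec()
    genome = generate_genome(spec)
    transcripts, peaks = generate_annotation(spec, genome)
    genome, n_planted = plant_signal(
        genome, peaks, spec.motif, spec.motif_rate, seed=_stage_seed(spec.seed, 2)
    )
    dataset = build_benchmark(
        genome, peaks, transcripts, seed=_stage_seed(spec.seed, 3)
    )
    return FixtureResult(
        spec=spec,
        genome=genome,
        transcripts=transcripts,
        peaks=peaks,
        dataset=dataset,
        n_planted=n_planted,
    )


def reduced_embedding_config() -> dict:
    """Desk-scale embedding configuration used by the synthetic studies.

    The word lengths and dimension are kept at the method's operating
    point (k = 3..8, dim 100): a planted element of length M shifts the
    mean-pooled feature of a length-L region by a direction whose squared
    discriminability is roughly sum_k dim * (M - k + 1) / (L * tau_k),
    with tau_k = 1 + L / 4^k the token-repetition factor — so the long
    word lengths and the full dimension carry almost all of the signal,
    and dropping them would make the region-level signal statistically
    invisible at multi-kilobase lengths.  Training effort (window, epochs,
    negatives, corpus size) is what gets reduced instead.
    """
    return {
        "ks": (3, 4, 5, 6, 7, 8),
        "dim": 100,
        "window": 2,
        "epochs": 2,
        "negative": 3,
    }
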