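"""Benchmark construction from peak and transcript annotation.

Positives are hMeRIP-seq peak regions (transcript intervals enriched for
the 5hmC signal); negatives are non-peak stretches of the *same*
transcripts, cropped to the exact length of their paired peak so the two
classes share a length distribution ("one-vs-one" cropping).  Coordinates
follow the BED convention: 0-based, half-open, with strand '+'/'-'.

Extraction is strand-aware: minus-strand intervals are reverse
complemented before the DNA -> RNA transliteration, so every returned
sequence reads 5'->3' on its transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import CoordinateError, InvalidInputError, MissingReferenceError

__all__ = [
    "GenomicInterval",
    "LabeledDataset",
    "extract_sequence",
    "filter_chromosomes",
    "sample_negatives",
    "build_benchmark",
    "length_distribution",
]

logger = logging.getLogger(__name__)

POSITIVE = 1
NEGATIVE = 0


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded region on a named chromosome (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InvalidInputError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise InvalidInputError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class LabeledDataset:
    """Paired RNA sequences, binary labels and source intervals."""

    sequences: list[str]
    labels: np.ndarray
    provenance: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.sequences) == len(self.labels) == len(self.provenance)):
            raise InvalidInputError("sequences, labels, provenance must align")
        if self.labels.size and not set(np.unique(self.labels)) <= {0, 1}:
            raise InvalidInputError("labels must be binary (0/1)")
        if any(not s for s in self.sequences):
            raise InvalidInputError("sequences must be non-empty")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_positive(self) -> int:
        return int((self.labels == POSITIVE).sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == NEGATIVE).sum())


def extract_sequence(genome: Mapping[str, str], interval: GenomicInterval) -> str:
    """RNA sequence of an interval, 5'->3' on the annotated strand."""
    if interval.chrom not in genome:
        raise MissingReferenceError(f"chromosome {interval.chrom!r} not in genome")
    chrom_seq = genome[interval.chrom]
    if interval.end > len(chrom_seq):
        raise CoordinateError(
            f"interval [{interval.start}, {interval.end}) exceeds "
            f"{interval.chrom} length {len(chrom_seq)}"
        )
    dna = chrom_seq[interval.start : interval.end].upper()
    if interval.strand == "-":
        dna = str(Seq(dna).reverse_complement())
    return dna.replace("T", "U")


def filter_chromosomes(
    intervals: Sequence[GenomicInterval], allowed: Sequence[str]
) -> list[GenomicInterval]:
    """Order-preserving subset of intervals on allowed chromosomes."""
    allowed_set = set(allowed)
    return [iv for iv in intervals if iv.chrom in allowed_set]


def _host_transcript(
    peak: GenomicInterval, transcripts: Sequence[GenomicInterval]
) -> GenomicInterval | None:
    """Transcript with greatest overlap; ties broken by leftmost start."""
    best: GenomicInterval | None = None
    best_key = (0, 0)
    for tx in transcripts:
        ov = peak.overlap_length(tx)
        if ov > 0:
            key = (ov, -tx.start)
            if key > best_key:
                best, best_key = tx, key
    return best


def _gaps_within(
    region: GenomicInterval, blockers: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """Maximal sub-intervals of ``region`` that intersect no blocker."""
    spans = sorted(
        (max(b.start, region.start), min(b.end, region.end))
        for b in blockers
        if b.overlaps(region)
    )
    gaps: list[tuple[int, int]] = []
    cursor = region.start
    for s, e in spans:
        if s > cursor:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < region.end:
        gaps.append((cursor, region.end))
    return gaps


def sample_negatives(
    transcripts: Sequence[GenomicInterval],
    peaks: Sequence[GenomicInterval],
    seed: int = 0,
) -> list[GenomicInterval | None]:
    """One length-matched negative interval per peak, or None if infeasible.

    Each negative has the length and strand of its peak, lies inside the
    peak's host transcript (greatest overlap, ties to the leftmost start)
    and intersects no peak at all.  The start is drawn seeded-uniformly
    over every feasible position, so a fixed seed reproduces the set.
    Peaks with no feasible placement yield ``None`` and a logged warning.
    """
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)

    negatives: list[GenomicInterval | None] = []
    for peak in peaks:
        host = _host_transcript(peak, transcripts)
        if host is None:
            logger.warning("peak %s overlaps no transcript; pair dropped", peak)
            negatives.append(None)
            continue
        length = peak.length
        gaps = [
            (s, e)
            for s, e in _gaps_within(host, by_chrom.get(peak.chrom, []))
            if e - s >= length
        ]
        total = sum(e - s - length + 1 for s, e in gaps)
        if total == 0:
            logger.warning(
                "no room for a %d nt negative in transcript %s; pair dropped",
                length,
                host.id or host,
            )
            negatives.append(None)
            continue
        draw = int(rng.integers(total))
        for s, e in gaps:
            n_starts = e - s - length + 1
            if draw < n_starts:
                start = s + draw
                break
            draw -= n_starts
        negatives.append(
            GenomicInterval(
                chrom=peak.chrom,
                start=start,
                end=start + length,
                strand=peak.strand,
                id=f"{peak.id}_neg" if peak.id else None,
            )
        )
    return negatives


def build_benchmark(
    genome: Mapping[str, str],
    peaks: Sequence[GenomicInterval],
    transcripts: Sequence[GenomicInterval],
    allowed_chroms: Sequence[str] | None = None,
    seed: int = 0,
) -> LabeledDataset:
    """Full benchmark: peak positives plus length-matched transcript negatives.

    Positives come first (in peak order), then their negatives in the same
    order, so positive ``i`` pairs with negative ``n_positive + i``.
    Duplicate peak intervals are kept (and logged), mirroring the absence
    of any deduplication in the construction.
    """
    if allowed_chroms is not None:
        peaks = filter_chromosomes(peaks, allowed_chroms)
        transcripts = filter_chromosomes(transcripts, allowed_chroms)
    n_unique = len({(p.chrom, p.start, p.end, p.strand) for p in peaks})
    if n_unique < len(peaks):
        logger.info("benchmark keeps %d duplicate peak(s)", len(peaks) - n_unique)

    negatives = sample_negatives(transcripts, peaks, seed=seed)
    kept = [(p, n) for p, n in zip(peaks, negatives) if n is not None]
    sequences: list[str] = []
    labels: list[int] = []
    provenance: list[GenomicInterval] = []
    for peak, _ in kept:
        sequences.append(extract_sequence(genome, peak))
        labels.append(POSITIVE)
        provenance.append(peak)
    for _, neg in kept:
        sequences.append(extract_sequence(genome, neg))
        labels.append(NEGATIVE)
        provenance.append(neg)
    return LabeledDataset(
        sequences=sequences,
        labels=np.asarray(labels, dtype=int),
        provenance=provenance,
    )


def length_distribution(
    dataset: LabeledDataset, bins: int = 20
) -> tuple[pd.DataFrame, dict[str, tuple[int, int]]]:
    """Per-class histogram of sequence lengths plus per-class (min, max).

    Returns a table with columns ``bin_left``, ``bin_right``, ``positive``,
    ``negative`` and a summary mapping class name to its length range.
    """
    if len(dataset) == 0:
        raise InvalidInputError("dataset is empty")
    lengths = np.array([len(s) for s in dataset.sequences])
    pos = lengths[dataset.labels == POSITIVE]
    neg = lengths[dataset.labels == NEGATIVE]
    edges = np.histogram_bin_edges(lengths, bins=bins)
    pos_counts, _ = np.histogram(pos, bins=edges)
    neg_counts, _ = np.histogram(neg, bins=edges)
    table = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "positive": pos_counts,
            "negative": neg_counts,
        }
    )
    summary: dict[str, tuple[int, int]] = {}
    if pos.size:
        summary["positive"] = (int(pos.min()), int(pos.max()))
    if neg.size:
        summary["negative"] = (int(neg.min()), int(neg.max()))
    return table, summary
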