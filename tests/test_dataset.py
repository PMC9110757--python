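"""Benchmark construction: extraction, filtering, negative sampling."""

import numpy as np
import pytest

from i5hmcvec import (
    GenomicInterval,
    build_benchmark,
    extract_sequence,
    filter_chromosomes,
    length_distribution,
    sample_negatives,
)
from i5hmcvec.dataset import NEGATIVE, POSITIVE
from i5hmcvec.errors import (
    CoordinateError,
    InvalidInputError,
    MissingReferenceError,
)

GENOME = {"c1": "AACGT"}


class TestExtractSequence:
    def test_plus_strand_substring_as_rna(self):
        iv = GenomicInterval("c1", 1, 4, "+")
        assert extract_sequence(GENOME, iv) == "ACG"

    def test_minus_strand_reverse_complement(self):
        iv = GenomicInterval("c1", 1, 4, "-")
        assert extract_sequence(GENOME, iv) == "CGU"

    def test_thymine_becomes_uracil(self):
        iv = GenomicInterval("c1", 0, 5, "+")
        assert extract_sequence(GENOME, iv) == "AACGU"

    def test_out_of_bounds_interval(self):
        with pytest.raises(CoordinateError):
            extract_sequence(GENOME, GenomicInterval("c1", 3, 9, "+"))

    def test_unknown_chromosome(self):
        with pytest.raises(MissingReferenceError):
            extract_sequence(GENOME, GenomicInterval("c9", 0, 2, "+"))

    def test_minus_extraction_is_revcomp_of_plus(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 50))
        genome = {"c": seq}
        plus = extract_sequence(genome, GenomicInterval("c", 5, 30, "+"))
        minus = extract_sequence(genome, GenomicInterval("c", 5, 30, "-"))
        comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
        assert minus == "".join(comp[b] for b in reversed(plus))


class TestIntervalValidation:
    def test_inverted_coordinates_rejected(self):
        with pytest.raises(InvalidInputError):
            GenomicInterval("c1", 4, 2, "+")

    def test_bad_strand_rejected(self):
        with pytest.raises(InvalidInputError):
            GenomicInterval("c1", 0, 2, "*")


class TestFilterChromosomes:
    INTERVALS = [
        GenomicInterval("chr2L", 0, 10),
        GenomicInterval("chrU", 0, 10),
        GenomicInterval("chrX", 5, 15),
    ]

    def test_quality_filter_keeps_allowed_only(self):
        kept = filter_chromosomes(self.INTERVALS, ["chr2L", "chrX"])
        assert [iv.chrom for iv in kept] == ["chr2L", "chrX"]

    def test_empty_allow_list(self):
        assert filter_chromosomes(self.INTERVALS, []) == []

    def test_identity_when_all_allowed(self):
        allowed = ["chr2L", "chrU", "chrX"]
        assert filter_chromosomes(self.INTERVALS, allowed) == self.INTERVALS


class TestSampleNegatives:
    def test_negative_is_length_matched_and_disjoint(self):
        tx = [GenomicInterval("c", 0, 1000, "+", id="t0")]
        peak = [GenomicInterval("c", 100, 300, "+", id="p0")]
        (neg,) = sample_negatives(tx, peak, seed=0)
        assert neg.length == 200
        assert neg.start >= 0 and neg.end <= 1000
        assert not neg.overlaps(peak[0])
        assert neg.strand == "+"

    def test_peak_filling_transcript_is_dropped(self, caplog):
        tx = [GenomicInterval("c", 0, 200, "+", id="t0")]
        peak = [GenomicInterval("c", 0, 200, "+", id="p0")]
        with caplog.at_level("WARNING"):
            result = sample_negatives(tx, peak, seed=0)
        assert result == [None]
        assert "pair dropped" in caplog.text

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        tx, peaks = [], []
        for i in range(20):
            start = i * 2000
            tx.append(GenomicInterval("c", start, start + 1500, "+", id=f"t{i}"))
            peaks.append(
                GenomicInterval("c", start + 100, start + 400, "+", id=f"p{i}")
            )
        a = sample_negatives(tx, peaks, seed=7)
        b = sample_negatives(tx, peaks, seed=7)
        assert a == b

    def test_host_is_transcript_with_greatest_overlap(self):
        tx = [
            GenomicInterval("c", 0, 500, "+", id="short"),
            GenomicInterval("c", 400, 2000, "+", id="long"),
        ]
        peak = [GenomicInterval("c", 450, 650, "+", id="p")]
        (neg,) = sample_negatives(tx, peak, seed=0)
        # 50 nt overlap with "short", 200 nt with "long" -> host is "long"
        assert neg.start >= 400 and neg.end <= 2000


class TestBuildBenchmark:
    def test_paired_construction_on_fixture(self, small_fixture):
        ds = small_fixture.dataset
        n = ds.n_positive
        assert n == ds.n_negative == 12
        for i in range(n):
            assert len(ds.sequences[i]) == len(ds.sequences[n + i])

    def test_negatives_overlap_no_peak(self, small_fixture):
        ds = small_fixture.dataset
        negs = [
            iv for iv, lab in zip(ds.provenance, ds.labels) if lab == NEGATIVE
        ]
        for neg in negs:
            assert not any(neg.overlaps(p) for p in small_fixture.peaks)

    def test_empty_peak_set_gives_empty_dataset(self):
        ds = build_benchmark({"c": "ACGT" * 100}, [], [], seed=0)
        assert len(ds) == 0

    def test_duplicate_peaks_kept(self):
        genome = {"c": "ACGTAACCGGTT" * 200}
        tx = [GenomicInterval("c", 0, 2000, "+", id="t")]
        peak = GenomicInterval("c", 100, 200, "+", id="p")
        ds = build_benchmark(genome, [peak, peak], tx, seed=0)
        assert ds.n_positive == 2
        assert ds.sequences[0] == ds.sequences[1]

    def test_chromosome_filter_applied(self):
        genome = {"good": "ACGT" * 500, "bad": "ACGT" * 500}
        tx = [
            GenomicInterval("good", 0, 1000, "+", id="tg"),
            GenomicInterval("bad", 0, 1000, "+", id="tb"),
        ]
        peaks = [
            GenomicInterval("good", 100, 200, "+", id="pg"),
            GenomicInterval("bad", 100, 200, "+", id="pb"),
        ]
        ds = build_benchmark(genome, peaks, tx, allowed_chroms=["good"], seed=0)
        assert ds.n_positive == 1
        assert ds.provenance[0].chrom == "good"


class TestLengthDistribution:
    def test_classes_share_length_multiset(self, small_fixture):
        ds = small_fixture.dataset
        table, summary = length_distribution(ds)
        assert (table["positive"] == table["negative"]).all()
        assert summary["positive"] == summary["negative"]

    def test_single_sequence_occupies_one_bin(self):
        from i5hmcvec import LabeledDataset

        ds = LabeledDataset(
            sequences=["ACGUACGU"],
            labels=[POSITIVE],
            provenance=[GenomicInterval("c", 0, 8, "+")],
        )
        table, summary = length_distribution(ds, bins=5)
        assert table["positive"].sum() == 1
        assert summary["positive"] == (8, 8)

    def test_empty_dataset_rejected(self):
        from i5hmcvec import LabeledDataset

        ds = LabeledDataset(sequences=[], labels=[], provenance=[])
        with pytest.raises(InvalidInputError):
            length_distribution(ds)
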