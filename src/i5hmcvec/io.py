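"""Reading and writing the standard interchange formats.

FASTA handling goes through Biopython; BED6 and the benchmark manifest are
plain tab-separated tables handled with pandas.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dataset import NEGATIVE, POSITIVE, GenomicInterval, LabeledDataset
from .errors import FormatError

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed6",
    "write_bed6",
    "write_dataset",
    "read_dataset",
]

_BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a multi-record FASTA into an id -> uppercase sequence mapping."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, os.fspath(path), "fasta")


def read_bed6(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read intervals from a BED6 file (chrom, start, end, name, score, strand)."""
    try:
        frame = pd.read_csv(
            path, sep="\t", header=None, names=_BED6_COLUMNS, comment="#"
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"malformed BED6 file {path}: {exc}") from exc
    if frame[["chrom", "start", "end", "strand"]].isna().any().any():
        raise FormatError(f"BED6 file {path} needs all six columns")
    return [
        GenomicInterval(
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            strand=str(row.strand),
            id=None if pd.isna(row.name_) else str(row.name_),
        )
        for row in frame.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def write_bed6(intervals: Sequence[GenomicInterval], path: str | os.PathLike) -> None:
    frame = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "name": [iv.id or f"region{i}" for i, iv in enumerate(intervals)],
            "score": [0] * len(intervals),
            "strand": [iv.strand for iv in intervals],
        }
    )
    frame.to_csv(path, sep="\t", header=False, index=False)


def _record_id(interval: GenomicInterval, index: int, label: int) -> str:
    if interval.id:
        return interval.id
    tag = "pos" if label == POSITIVE else "neg"
    return f"{tag}{index}"


def write_dataset(dataset: LabeledDataset, outdir: str | os.PathLike) -> None:
    """Write positives.fa, negatives.fa and a manifest.tsv with provenance."""
    os.makedirs(outdir, exist_ok=True)
    pos: dict[str, str] = {}
    neg: dict[str, str] = {}
    rows = []
    for i, (seq, label, iv) in enumerate(
        zip(dataset.sequences, dataset.labels, dataset.provenance)
    ):
        rid = _record_id(iv, i, int(label))
        (pos if label == POSITIVE else neg)[rid] = seq
        rows.append(
            {
                "id": rid,
                "label": "positive" if label == POSITIVE else "negative",
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "strand": iv.strand,
            }
        )
    write_fasta(pos, os.path.join(outdir, "positives.fa"))
    write_fasta(neg, os.path.join(outdir, "negatives.fa"))
    pd.DataFrame(rows).to_csv(
        os.path.join(outdir, "manifest.tsv"), sep="\t", index=False
    )


def read_dataset(directory: str | os.PathLike) -> LabeledDataset:
    """Read a dataset written by :func:`write_dataset`."""
    manifest = pd.read_csv(os.path.join(directory, "manifest.tsv"), sep="\t")
    pos = read_fasta(os.path.join(directory, "positives.fa"))
    neg = read_fasta(os.path.join(directory, "negatives.fa"))
    sequences, labels, provenance = [], [], []
    for row in manifest.itertuples(index=False):
        label = POSITIVE if row.label == "positive" else NEGATIVE
        source = pos if label == POSITIVE else neg
        if row.id not in source:
            raise FormatError(f"manifest id {row.id!r} missing from FASTA")
        # FASTA sequences read back as DNA-alphabet uppercase; restore RNA
        sequences.append(source[row.id].replace("T", "U"))
        labels.append(label)
        provenance.append(
            GenomicInterval(
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                id=str(row.id),
            )
        )
    return LabeledDataset(sequences=sequences, labels=labels, provenance=provenance)
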