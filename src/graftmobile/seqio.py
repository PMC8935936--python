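"""Readers and writers for the standard formats the pipeline touches.

All coordinates held in memory are 0-based half-open on the forward
strand; the GFF3 boundary layer converts from the format's 1-based
inclusive convention, and BED export is natively 0-based half-open.
FASTA/FASTQ parsing is delegated to Bio.SeqIO with validation layered on
top (uppercasing, duplicate-id and alphabet checks).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

IUPAC_CHARS = frozenset("ACGTUNRYSWKMBDHV")

_REPEAT_TYPES = {"repeat_region", "transposable_element", "transposon", "repeat"}


class FormatError(ValueError):
    """A file violates its format contract."""


@dataclass
class ReadRecord:
    """A small-RNA read: identifier, sequence, optional replicate label."""

    id: str
    sequence: str
    replicate_label: str | None = None

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.sequence)


@dataclass(frozen=True)
class Interval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    feature_id: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise FormatError(
                f"interval start must precede end: {self.chrom}:{self.start}-{self.end}"
            )

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class FeatureAnnotation:
    """Typed interval sets: stranded genes, repeats and (derived) promoters."""

    genes: list[Interval] = field(default_factory=list)
    repeats: list[Interval] = field(default_factory=list)
    promoters: list[Interval] = field(default_factory=list)


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a name -> uppercased sequence map.

    Raises FormatError on duplicate names, empty sequences or characters
    outside the IUPAC nucleotide alphabet.
    """
    seqs: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seqs:
                raise FormatError(f"duplicate FASTA record name: {rec.id}")
            seq = str(rec.seq).upper()
            if not seq:
                raise FormatError(f"empty sequence for FASTA record: {rec.id}")
            bad = set(seq) - IUPAC_CHARS
            if bad:
                raise FormatError(
                    f"non-IUPAC characters {sorted(bad)} in FASTA record {rec.id}"
                )
            seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> list[ReadRecord]:
    """Read a FASTQ file (plain or gzip) into ReadRecords.

    Truncated records or sequence/quality length mismatches raise
    FormatError (via Bio.SeqIO's parser).
    """
    reads: list[ReadRecord] = []
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                reads.append(ReadRecord(id=rec.id, sequence=str(rec.seq).upper()))
        except ValueError as exc:
            raise FormatError(f"malformed FASTQ in {path}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[ReadRecord], path, quality_char: str = "I") -> None:
    """Write reads as Phred+33 FASTQ with a constant quality string."""
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{quality_char * len(r.sequence)}\n")


_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def _gff_attr_id(attributes: str, fallback: str) -> str:
    for part in str(attributes).split(";"):
        if part.startswith("ID="):
            return part[3:]
    return fallback


def read_gff3(path) -> FeatureAnnotation:
    """Read a GFF3 file, converting 1-based inclusive coordinates to the
    internal 0-based half-open convention. Feature types 'gene',
    repeat-like types and 'promoter' are kept; others are ignored."""
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=_GFF_COLS,
            dtype={"start": int, "end": int},
        )
    except ValueError as exc:
        raise FormatError(f"malformed GFF3 in {path}: {exc}") from exc
    ann = FeatureAnnotation()
    for i, row in enumerate(df.itertuples(index=False)):
        if row.start > row.end:
            raise FormatError(
                f"GFF3 start > end at {row.seqid}:{row.start}-{row.end}"
            )
        iv = Interval(
            chrom=str(row.seqid),
            start=int(row.start) - 1,
            end=int(row.end),
            strand=str(row.strand),
            feature_id=_gff_attr_id(row.attributes, f"{row.type}_{i}"),
        )
        ftype = str(row.type).lower()
        if ftype == "gene":
            ann.genes.append(iv)
        elif ftype in _REPEAT_TYPES:
            ann.repeats.append(iv)
        elif ftype == "promoter":
            ann.promoters.append(iv)
    return ann


def write_gff3(ann: FeatureAnnotation, path, source: str = "graftmobile") -> None:
    """Write annotation back out as GFF3 (converting to 1-based inclusive)."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for ftype, ivs in (
            ("gene", ann.genes), ("repeat_region", ann.repeats), ("promoter", ann.promoters)
        ):
            for iv in ivs:
                fh.write(
                    f"{iv.chrom}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{iv.strand}\t.\tID={iv.feature_id}\n"
                )


def write_bed(rows: Iterable[tuple], path) -> None:
    """Write BED6 rows (chrom, start, end, name, score, strand), 0-based
    half-open per the BED standard."""
    with _open_text(path, "wt") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
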