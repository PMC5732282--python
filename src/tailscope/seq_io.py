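"""Sequence and annotation I/O.

Reads and writes the external formats the pipeline touches (FASTA, FASTQ,
the collapsed "FASTA+" dialect, GFF3 / tabular CDS annotation) and provides
genome access helpers, most importantly extraction of the region
immediately 5' of each start codon where Shine-Dalgarno motifs live.

Coordinates are 0-based half-open on the forward strand throughout; GFF3
input (1-based inclusive) is converted at the boundary.
"""

from __future__ import annotations

import re
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Mapping, NamedTuple, Union

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ParseError",
    "CDSRecord",
    "GenomeAnnotation",
    "Read",
    "ReadSet",
    "UpstreamRegion",
    "revcomp",
    "rna_revcomp",
    "transcribe",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "dedupe_reads",
    "read_fasta_plus",
    "write_fasta_plus",
    "read_annotation_gff3",
    "read_annotation_tsv",
    "write_annotation_gff3",
    "extract_upstream",
]

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_RNA_COMP = str.maketrans("ACGUN", "UGCAN")


class ParseError(ValueError):
    """Malformed input file."""


def revcomp(dna: str) -> str:
    """Reverse complement of a DNA string (N allowed)."""
    return dna.upper().translate(_DNA_COMP)[::-1]


def rna_revcomp(rna: str) -> str:
    """Reverse complement of an RNA string (N allowed)."""
    return rna.upper().translate(_RNA_COMP)[::-1]


def transcribe(dna: str) -> str:
    """DNA -> RNA on the same (coding) strand: T becomes U."""
    return dna.upper().replace("T", "U")


class CDSRecord(NamedTuple):
    gene_id: str
    contig: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+' or '-'


@dataclass
class GenomeAnnotation:
    """A genome with its protein-coding gene coordinates.

    ``sequences`` maps contig id to an uppercase DNA string; ``cds_records``
    hold 0-based half-open intervals on the forward strand.
    """

    sequences: Mapping[str, str]
    cds_records: List[CDSRecord]

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.cds_records:
            if rec.gene_id in seen:
                raise ValueError(f"duplicate gene id {rec.gene_id!r}")
            seen.add(rec.gene_id)
            if rec.strand not in ("+", "-"):
                raise ValueError(f"{rec.gene_id}: strand must be '+' or '-'")
            if rec.contig not in self.sequences:
                raise ValueError(f"{rec.gene_id}: unknown contig {rec.contig!r}")
            clen = len(self.sequences[rec.contig])
            if not (0 <= rec.start < rec.end <= clen):
                raise ValueError(
                    f"{rec.gene_id}: interval [{rec.start},{rec.end}) outside "
                    f"contig of length {clen}"
                )
        self._by_id = {rec.gene_id: rec for rec in self.cds_records}

    def cds(self, gene_id: str) -> CDSRecord:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    @property
    def gene_ids(self) -> List[str]:
        return [rec.gene_id for rec in self.cds_records]


class Read(NamedTuple):
    read_id: str
    sequence: str
    count: int


@dataclass
class ReadSet:
    """A collection of reads, possibly collapsed to distinct sequences.

    ``total_reads`` always reflects the sum of the per-record multiplicities,
    so a deduplicated set and its expanded original are interchangeable for
    counting purposes.
    """

    records: List[Read] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.count < 1:
                raise ValueError(f"{rec.read_id}: count must be >= 1")
            if not re.fullmatch(r"[ACGTN]*", rec.sequence):
                raise ValueError(f"{rec.read_id}: non-ACGTN characters in sequence")

    @property
    def total_reads(self) -> int:
        return sum(rec.count for rec in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True)
class UpstreamRegion:
    """The RNA immediately 5' of a start codon on the coding strand."""

    gene_id: str
    rna: str
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.rna)


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path: Union[str, Path]) -> "OrderedDict[str, str]":
    seqs: "OrderedDict[str, str]" = OrderedDict()
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(sequences: Mapping[str, str], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fastq(path: Union[str, Path]) -> ReadSet:
    """Parse a FASTQ file into one record per read (count = 1).

    Raises :class:`ParseError` naming the (0-based) record index on a
    malformed record, including a quality line whose length does not match
    the sequence.
    """
    records: List[Read] = []
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                break
            except ValueError as exc:
                raise ParseError(f"malformed FASTQ record {index}: {exc}") from exc
            if len(qual) != len(seq):
                raise ParseError(
                    f"malformed FASTQ record {index}: quality length "
                    f"{len(qual)} != sequence length {len(seq)}"
                )
            records.append(Read(title.split()[0], seq.upper(), 1))
            index += 1
    return ReadSet(records)


def write_fastq(reads: Iterable[Read], path: Union[str, Path], quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for rec in reads:
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{quality_char * len(rec.sequence)}\n")


# ---------------------------------------------------------------------------
# FASTA+ (collapsed reads; multiplicity encoded in the id suffix)

def dedupe_reads(reads: ReadSet, prefix: str = "R") -> ReadSet:
    """Collapse identical sequences, preserving total multiplicity.

    Ids are rewritten ``<prefix><i>_<count>``; records are ordered by
    descending count then sequence so the output is deterministic.
    """
    counts: dict = {}
    for rec in reads:
        counts[rec.sequence] = counts.get(rec.sequence, 0) + rec.count
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    records = [
        Read(f"{prefix}{i}_{count}", seq, count)
        for i, (seq, count) in enumerate(ordered, start=1)
    ]
    return ReadSet(records)


def write_fasta_plus(reads: ReadSet, path: Union[str, Path]) -> None:
    """Write collapsed reads with the count as the final ``_##`` id suffix."""
    with open(path, "w") as fh:
        for rec in reads:
            rid = rec.read_id
            # ensure the final underscore-delimited field is the count
            tail = rid.rsplit("_", 1)
            if len(tail) != 2 or not tail[1].isdigit() or int(tail[1]) != rec.count:
                rid = f"{rid}_{rec.count}"
            fh.write(f">{rid}\n{rec.sequence}\n")


def read_fasta_plus(path: Union[str, Path]) -> ReadSet:
    """Read a FASTA+ file; the count is parsed from the final ``_##`` suffix."""
    records: List[Read] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.rsplit("_", 1)
        if len(parts) != 2 or not parts[1].isdigit():
            raise ParseError(f"FASTA+ id {rec.id!r} lacks a trailing _<count> suffix")
        records.append(Read(rec.id, str(rec.seq).upper(), int(parts[1])))
    return ReadSet(records)


# ---------------------------------------------------------------------------
# Annotation

def read_annotation_gff3(
    genome_fasta: Union[str, Path], gff3: Union[str, Path]
) -> GenomeAnnotation:
    """Build a :class:`GenomeAnnotation` from a FASTA and GFF3 CDS rows.

    GFF3 1-based inclusive coordinates become 0-based half-open. The gene id
    is the feature's ``ID`` attribute (falling back to gffutils' assigned id).
    """
    import gffutils

    sequences = read_fasta(genome_fasta)
    db = gffutils.create_db(
        str(gff3), dbfn=":memory:", keep_order=True, merge_strategy="error"
    )
    cds_records = [
        CDSRecord(feat.id, feat.seqid, feat.start - 1, feat.end, feat.strand)
        for feat in db.features_of_type("CDS", order_by=("seqid", "start"))
    ]
    return GenomeAnnotation(sequences, cds_records)


def read_annotation_tsv(
    genome_fasta: Union[str, Path], tsv: Union[str, Path]
) -> GenomeAnnotation:
    """5-column TSV alternative: gene_id, contig, start, end, strand (0-based half-open)."""
    import pandas as pd

    sequences = read_fasta(genome_fasta)
    df = pd.read_csv(
        tsv, sep="\t", header=None,
        names=["gene_id", "contig", "start", "end", "strand"],
        comment="#", dtype={"gene_id": str, "contig": str, "strand": str},
    )
    cds_records = [
        CDSRecord(r.gene_id, r.contig, int(r.start), int(r.end), r.strand)
        for r in df.itertuples(index=False)
    ]
    return GenomeAnnotation(sequences, cds_records)


def write_annotation_gff3(annotation: GenomeAnnotation, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in annotation.cds_records:
            fh.write(
                f"{rec.contig}\ttailscope\tCDS\t{rec.start + 1}\t{rec.end}\t.\t"
                f"{rec.strand}\t0\tID={rec.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Upstream extraction

def extract_upstream(
    annotation: GenomeAnnotation, gene_id: str, width: int = 30
) -> UpstreamRegion:
    """Return the ``width`` nt immediately 5' of the start codon, as RNA.

    For '-' strand CDSs the genomic segment 3' of the interval is
    reverse-complemented so the result always reads 5'->3' on the coding
    strand and ends at the base immediately before the start codon. A CDS
    closer than ``width`` to its contig edge yields the shorter available
    segment with ``truncated=True``. Replication-origin wrap-around is not
    supported.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    rec = annotation.cds(gene_id)
    contig = annotation.sequences[rec.contig]
    if rec.strand == "+":
        lo = max(0, rec.start - width)
        segment = contig[lo : rec.start]
        truncated = rec.start - width < 0
    else:
        hi = min(len(contig), rec.end + width)
        segment = revcomp(contig[rec.end : hi])
        truncated = rec.end + width > len(contig)
    return UpstreamRegion(gene_id, transcribe(segment), truncated)
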