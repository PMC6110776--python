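"""Sequence, interval and gene-model containers plus FASTA/FASTQ/GFF3 I/O.

Coordinates are 1-based inclusive throughout, matching GFF3 and the way
genome coordinates are printed in the literature; conversion to Python's
half-open slices happens only at internal array boundaries.

Parsing of the standard formats is delegated to Biopython (FASTA/FASTQ)
and gffutils (GFF3); this module only adds the validation and the
transcript-order conventions the downstream stages rely on.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SequenceRecord",
    "GenomicInterval",
    "GeneModel",
    "FastaFormatError",
    "GffStructureError",
    "parse_fasta",
    "write_fasta",
    "parse_fastq",
    "write_fastq",
    "parse_gff3_gene_models",
    "write_gene_models_gff3",
    "revcomp",
    "write_newick",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


class GffStructureError(ValueError):
    """Raised when a GFF3 file violates gene/mRNA/exon structure rules."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence (nucleotide or amino acid)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if not self.seq:
            raise ValueError(f"SequenceRecord {self.id!r}: sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive interval on a named contig.

    ``length = end - start + 1``; this is the single place interval
    arithmetic is defined.
    """

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, contig: str, pos: int) -> bool:
        return self.contig == contig and self.start <= pos <= self.end

    def extract(self, contig_seq: str) -> str:
        """Sequence of this interval from its contig (strand-aware)."""
        sub = contig_seq[self.start - 1 : self.end]
        return revcomp(sub) if self.strand == "-" else sub


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron structure of one transcript on one contig.

    ``exons`` are stored in transcript (5'->3') order: ascending genomic
    coordinates on '+' genes, descending on '-' genes.  ``cds`` holds the
    coding intervals in the same order; both lists use genomic coordinates.
    """

    gene_id: str
    contig: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        starts = [e.start for e in self.exons]
        expected = sorted(starts, reverse=(self.strand == "-"))
        if starts != expected:
            raise ValueError(f"gene {self.gene_id}: exons not in transcript order")
        by_start = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(by_start, by_start[1:]):
            if a.end >= b.start:
                raise GffStructureError(
                    f"gene {self.gene_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        """Introns in transcript order (between consecutive exons)."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append(GenomicInterval(self.contig, a.end + 1, b.start - 1, "+"))
            else:
                out.append(GenomicInterval(self.contig, b.end + 1, a.start - 1, "-"))
        return tuple(out)

    @property
    def span(self) -> GenomicInterval:
        lo = min(e.start for e in self.exons)
        hi = max(e.end for e in self.exons)
        return GenomicInterval(self.contig, lo, hi, self.strand)

    def mrna(self, contig_seq: str) -> str:
        """Spliced transcript sequence, 5'->3'."""
        return "".join(e.extract(contig_seq) for e in self.exons)

    def genomic_to_mrna(self, pos: int) -> int:
        """Map a genomic position (must be exonic) to a 1-based mRNA position."""
        offset = 0
        for e in self.exons:
            if e.start <= pos <= e.end:
                if self.strand == "+":
                    return offset + (pos - e.start) + 1
                return offset + (e.end - pos) + 1
            offset += e.length
        raise ValueError(f"position {pos} is not exonic in gene {self.gene_id}")

    @property
    def cds_start(self) -> int | None:
        """Genomic coordinate of the first CDS base (transcript order)."""
        if not self.cds:
            return None
        first = self.cds[0]
        return first.start if self.strand == "+" else first.end


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def parse_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased and whitespace-stripped; record order is
    preserved.  Malformed headers or empty sequences raise
    :class:`FastaFormatError` naming the offending line.
    """
    # Pre-scan for structural problems so errors can name a line number;
    # Biopython is deliberately lenient about these.
    header_lines: list[int] = []
    with open(path) as fh:
        saw_header = False
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                saw_header = True
                header_lines.append(lineno)
                if len(stripped) == 1:
                    raise FastaFormatError(f"{path}: empty FASTA header at line {lineno}")
            elif not saw_header:
                raise FastaFormatError(
                    f"{path}: sequence data before any header at line {lineno}"
                )
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaFormatError(
                f"{path}: record {rec.id!r} (line {header_lines[i]}) has an empty sequence"
            )
        records.append(SequenceRecord(rec.id, seq, rec.description))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                header = f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def parse_fastq(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read FASTQ; qualities are ignored by every downstream kernel."""
    out = []
    with open(path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            out.append(SequenceRecord(title.split()[0], seq.upper(), title))
    return out


def write_fastq(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    """Write FASTQ with constant 'I' qualities (Sanger Q40)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{'I' * len(rec.seq)}\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def parse_gff3_gene_models(
    path: str | os.PathLike,
    contigs: Sequence[SequenceRecord] | None = None,
) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features from a GFF3 file.

    One :class:`GeneModel` is returned per mRNA, exons sorted in transcript
    orientation.  When ``contigs`` is supplied, exon coordinates are
    validated against contig lengths.
    """
    contig_len = {c.id: len(c.seq) for c in contigs} if contigs else {}
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        parents = list(db.parents(mrna, featuretype="gene"))
        if not parents:
            raise GffStructureError(f"mRNA {mrna.id} has no gene parent")
        gene = parents[0]
        strand = mrna.strand
        if strand not in ("+", "-"):
            raise GffStructureError(f"mRNA {mrna.id}: missing strand")
        exons, cds = [], []
        for feat in db.children(mrna, featuretype=("exon", "CDS")):
            if feat.seqid in contig_len and feat.end > contig_len[feat.seqid]:
                raise GffStructureError(
                    f"{feat.featuretype} {feat.start}-{feat.end} of mRNA {mrna.id} "
                    f"extends past the end of contig {feat.seqid} "
                    f"({contig_len[feat.seqid]} bp)"
                )
            iv = GenomicInterval(feat.seqid, feat.start, feat.end, strand)
            (exons if feat.featuretype == "exon" else cds).append(iv)
        if not exons:
            raise GffStructureError(f"mRNA {mrna.id} has no exons")
        rev = strand == "-"
        exons.sort(key=lambda e: e.start, reverse=rev)
        cds.sort(key=lambda e: e.start, reverse=rev)
        models.append(
            GeneModel(gene.id, exons[0].contig, strand, tuple(exons), tuple(cds))
        )
    return models


def write_gene_models_gff3(models: Iterable[GeneModel],
                           path: str | os.PathLike) -> None:
    """Write gene models back out as minimal GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            span = gm.span
            fh.write(
                f"{gm.contig}\tpetalsplit\tgene\t{span.start}\t{span.end}\t.\t"
                f"{gm.strand}\t.\tID={gm.gene_id}\n"
            )
            mrna_id = f"{gm.gene_id}.t1"
            fh.write(
                f"{gm.contig}\tpetalsplit\tmRNA\t{span.start}\t{span.end}\t.\t"
                f"{gm.strand}\t.\tID={mrna_id};Parent={gm.gene_id}\n"
            )
            for i, e in enumerate(sorted(gm.exons, key=lambda x: x.start), 1):
                fh.write(
                    f"{gm.contig}\tpetalsplit\texon\t{e.start}\t{e.end}\t.\t"
                    f"{gm.strand}\t.\tID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
            for i, c in enumerate(sorted(gm.cds, key=lambda x: x.start), 1):
                fh.write(
                    f"{gm.contig}\tpetalsplit\tCDS\t{c.start}\t{c.end}\t.\t"
                    f"{gm.strand}\t0\tID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )


def write_newick(tree, path: str | os.PathLike) -> None:
    """Serialize a phylogenetic tree to Newick (see :mod:`petalsplit.phylo`)."""
    from .phylo import write_newick as _write

    _write(tree, path)
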