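"""Reading genomes, gene models and rRNA tails; strand-aware UTR extraction.

Sequences are stored RNA-uppercase internally (DNA in, T -> U on read).
Coordinates are 1-based inclusive at the file boundary (GFF3 convention)
and 0-based half-open internally.  Gene-relative positions use the start
codon's first base as +1; there is no position 0.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FastaError, GeneTableError

RNA_ALPHABET = set("ACGUN")

#: UTR window: gene-relative positions -19..-2 inclusive (18 nt).  The last
#: window base sits two bases upstream of the start codon, so that nine
#: 10-nt sliding windows cover the region scanned for SD motifs.
DEFAULT_UTR_SPAN = (-19, -2)

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U."""
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    id: str
    sequence: str  # RNA-uppercase

    def __post_init__(self):
        if not self.sequence:
            raise FastaError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise FastaError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene; ``start`` is the 1-based coordinate of the
    first base of the start codon on the forward axis (for minus-strand
    genes this is the feature's end coordinate)."""

    gene_id: str
    contig: str
    start: int
    strand: Literal["+", "-"]
    start_codon: str = ""


@dataclass(frozen=True)
class UTRRecord:
    gene_id: str
    sequence: str  # 5'->3' toward the start codon
    offset_of_first_base: int  # gene-relative position of the first base
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> list[GenomeRecord]:
    """Read a (multi-record, possibly wrapped) FASTA file as RNA records."""
    records = []
    seen = set()
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FastaError(f"duplicate record id {rec.id!r} in {path}")
            seen.add(rec.id)
            seq = normalize_rna(str(rec.seq))
            if not seq:
                raise FastaError(f"record {rec.id!r}: header without sequence")
            records.append(GenomeRecord(rec.id, seq))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path, width: int = 70) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def _parse_gff3(fh, contig_lengths) -> list[GeneModel]:
    genes = []
    for lineno, line in enumerate(fh, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GeneTableError(f"GFF3 line {lineno}: expected 9 columns")
        contig, _src, ftype, start, end, _score, strand, _phase, attrs = fields
        if ftype != "CDS":
            continue
        if strand not in ("+", "-"):
            raise GeneTableError(f"GFF3 line {lineno}: missing/invalid strand {strand!r}")
        attr_map = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        gene_id = attr_map.get("gene_id") or attr_map.get("ID")
        if gene_id is None:
            raise GeneTableError(f"GFF3 line {lineno}: no gene_id/ID attribute")
        start_i, end_i = int(start), int(end)
        first = start_i if strand == "+" else end_i
        _check_bounds(gene_id, contig, first, contig_lengths)
        codon = attr_map.get("start_codon", "")
        genes.append(GeneModel(gene_id, contig, first, strand, codon))
    return genes


def _parse_tsv(fh, contig_lengths) -> list[GeneModel]:
    genes = []
    header = None
    for lineno, line in enumerate(fh, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            required = {"gene_id", "contig", "start", "strand"}
            missing = required - set(header)
            if missing:
                raise GeneTableError(f"gene table: missing columns {sorted(missing)}")
            continue
        row = dict(zip(header, fields))
        strand = row["strand"]
        if strand not in ("+", "-"):
            raise GeneTableError(
                f"gene table line {lineno} ({row.get('gene_id')!r}): "
                f"invalid strand {strand!r}"
            )
        gene_id = row["gene_id"]
        start = int(row["start"])
        _check_bounds(gene_id, row["contig"], start, contig_lengths)
        genes.append(
            GeneModel(gene_id, row["contig"], start, strand, row.get("start_codon", ""))
        )
    if header is None:
        raise GeneTableError("gene table: empty file")
    return genes


def _check_bounds(gene_id, contig, start, contig_lengths):
    if contig_lengths is None:
        return
    if contig not in contig_lengths:
        raise GeneTableError(f"gene {gene_id!r}: unknown contig {contig!r}")
    if not (1 <= start <= contig_lengths[contig]):
        raise GeneTableError(
            f"gene {gene_id!r}: start {start} outside contig {contig!r} "
            f"(length {contig_lengths[contig]})"
        )


def read_gene_models(
    path,
    dialect: Literal["gff3", "tsv"] = "tsv",
    genomes: list[GenomeRecord] | None = None,
) -> list[GeneModel]:
    """Read protein-coding gene models from GFF3 (type=CDS) or a TSV table.

    When ``genomes`` is given, coordinates are validated against contig
    bounds.
    """
    contig_lengths = (
        {g.id: len(g) for g in genomes} if genomes is not None else None
    )
    with open(path) as fh:
        if dialect == "gff3":
            return _parse_gff3(fh, contig_lengths)
        if dialect == "tsv":
            return _parse_tsv(fh, contig_lengths)
    raise ValueError(f"unknown dialect {dialect!r}")


def extract_utr(
    gene: GeneModel,
    genome: GenomeRecord,
    span: tuple[int, int] = DEFAULT_UTR_SPAN,
) -> UTRRecord:
    """Extract the upstream window (default positions -19..-2) 5'->3'.

    Minus-strand genes are reverse-complemented so the returned sequence
    always reads toward the start codon.  If fewer upstream bases exist
    the partial sequence is returned with ``truncated`` set.
    """
    if gene.contig != genome.id:
        raise GeneTableError(
            f"gene {gene.gene_id!r}: contig {gene.contig!r} does not match "
            f"genome {genome.id!r}"
        )
    first_rel, last_rel = span
    n = last_rel - first_rel + 1
    start0 = gene.start - 1  # 0-based index of the start codon's first base
    if gene.strand == "+":
        # gene-relative position p (< 0) maps to genome index start0 + p
        lo = start0 + first_rel
        hi = start0 + last_rel + 1
        clipped_lo = max(lo, 0)
        seq = genome.sequence[clipped_lo:hi]
        truncated = clipped_lo > lo
        if truncated:
            first_rel = first_rel + (clipped_lo - lo)
    else:
        # upstream of a minus-strand gene lies at larger genome coordinates
        lo = start0 - last_rel
        hi = start0 - first_rel + 1
        clipped_hi = min(hi, len(genome))
        seq = reverse_complement(genome.sequence[lo:clipped_hi])
        truncated = clipped_hi < hi
        if truncated:
            first_rel = first_rel + (hi - clipped_hi)
    return UTRRecord(gene.gene_id, seq, first_rel, truncated)
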