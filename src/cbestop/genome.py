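"""Genome sequence and CDS annotation model.

Loads multi-contig FASTA genomes and protein-coding annotation (GenBank flat
file or GFF3) into light-weight containers, and provides the strand-, frame-
and coordinate-safe primitives (CDS extraction, codon translation, genomic
position <-> codon address mapping) that the guide designer and the off-target
profiler build on.

Coordinate convention: everything in memory is 0-based, half-open. GFF3,
GenBank and VCF are all 1-based on disk; conversion happens at the I/O
boundary and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gffutils
from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from intervaltree import IntervalTree

logger = logging.getLogger("cbestop")

VALID_BASES = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
#: bacterial start codons accepted during ORF validation (GTG/TTG are common
#: alternative starts in Corynebacterium and other actinobacteria)
START_CODONS = frozenset({"ATG", "GTG", "TTG"})

_STANDARD_TABLE = unambiguous_dna_by_id[1]
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AmbiguousCodonError(ValueError):
    """Raised when a codon contains an ambiguous base (N)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def translate(codon: str) -> str:
    """Translate one codon with the standard genetic code.

    Returns a one-letter amino acid, or ``"*"`` for TAA/TAG/TGA. Codons
    containing N raise :class:`AmbiguousCodonError`.
    """
    if len(codon) != 3:
        raise ValueError(f"codon must be 3 bases, got {codon!r}")
    codon = codon.upper()
    if "N" in codon:
        raise AmbiguousCodonError(f"ambiguous codon {codon!r}")
    if codon in STOP_CODONS:
        return "*"
    return _STANDARD_TABLE.forward_table[codon]


@dataclass
class Genome:
    """Multi-contig nucleotide sequence, uppercase A/C/G/T/N."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"contig {name!r} contains invalid bases: {sorted(bad)}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def slice(self, contig: str, start: int, end: int) -> str:
        return self.contigs[contig][start:end]

    def reverse_complemented(self) -> "Genome":
        """Mirror image of the genome (used by strand-symmetry checks)."""
        return Genome({name: reverse_complement(seq) for name, seq in self.contigs.items()})


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene as a simple (non-compound) genomic interval.

    ``start``/``end`` are 0-based half-open on the plus strand; ``strand`` is
    ``"+"`` or ``"-"``. The coding length ``end - start`` is divisible by 3.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: empty or inverted interval")
        if (self.end - self.start) % 3 != 0:
            raise ValueError(f"gene {self.gene_id}: length not divisible by 3")

    @property
    def n_codons(self) -> int:
        return (self.end - self.start) // 3

    def mirrored(self, contig_length: int) -> "GeneRecord":
        """The same gene on the reverse-complemented contig."""
        return GeneRecord(
            gene_id=self.gene_id,
            contig=self.contig,
            start=contig_length - self.end,
            end=contig_length - self.start,
            strand="-" if self.strand == "+" else "+",
            product=self.product,
        )


@dataclass(frozen=True)
class CodonAddress:
    """Position inside a gene: 1-based codon index from the start codon and
    1-based offset (1..3) within that codon, both in coding orientation."""

    gene_id: str
    codon_index: int
    offset_in_codon: int


def read_fasta(path: str | Path) -> Genome:
    """Load a (multi-)FASTA file into a :class:`Genome`.

    Lowercase input is uppercased; duplicate contig ids and empty files are
    errors.
    """
    path = Path(path)
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise ValueError(f"{path}: duplicate contig id {record.id!r}")
        contigs[record.id] = str(record.seq).upper()
    if not contigs:
        raise ValueError(f"{path}: no records")
    return Genome(contigs)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome.contigs:
            fh.write(f">{name}\n")
            seq = genome.contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _records_from_genbank(path: Path) -> Iterable[tuple[str, int, int, Optional[str], str, bool]]:
    for rec in SeqIO.parse(str(path), "genbank"):
        counter = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            counter += 1
            quals = feat.qualifiers
            gene_id = (
                quals.get("locus_tag", [None])[0]
                or quals.get("gene", [None])[0]
                or quals.get("protein_id", [None])[0]
                or f"{rec.id}_CDS{counter}"
            )
            product = quals.get("product", [""])[0]
            compound = len(feat.location.parts) > 1
            strand = {1: "+", -1: "-"}.get(feat.location.strand)
            yield (
                gene_id,
                int(feat.location.start),
                int(feat.location.end),
                strand,
                product,
                compound,
            ), rec.id


def _records_from_gff3(path: Path) -> Iterable:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    segments: dict[str, list] = {}
    order: list[str] = []
    for i, feat in enumerate(db.features_of_type("CDS", order_by=("seqid", "start"))):
        gene_id = (
            feat.attributes.get("ID", [None])[0]
            or feat.attributes.get("locus_tag", [None])[0]
            or feat.attributes.get("Parent", [None])[0]
            or f"CDS{i + 1}"
        )
        if gene_id not in segments:
            segments[gene_id] = []
            order.append(gene_id)
        segments[gene_id].append(feat)
    for gene_id in order:
        feats = segments[gene_id]
        compound = len(feats) > 1
        feat = feats[0]
        product = feat.attributes.get("product", [""])[0]
        strand = feat.strand if feat.strand in ("+", "-") else None
        # gffutils keeps GFF3's 1-based inclusive coordinates
        yield (gene_id, feat.start - 1, feat.end, strand, product, compound), feat.seqid


def read_annotation(path: str | Path, fmt: str) -> list[GeneRecord]:
    """Read protein-coding CDS features from GenBank or GFF3.

    Records with a compound (joined) location, an unresolvable strand, or a
    length not divisible by 3 are skipped with a logged warning rather than
    silently dropped.
    """
    path = Path(path)
    if fmt == "genbank":
        raw = _records_from_genbank(path)
    elif fmt == "gff3":
        raw = _records_from_gff3(path)
    else:
        raise ValueError(f"unknown annotation format {fmt!r} (expected 'genbank' or 'gff3')")

    genes: list[GeneRecord] = []
    n_skipped = 0
    for (gene_id, start, end, strand, product, compound), contig in raw:
        if compound:
            logger.warning("skipping %s: compound (joined) CDS location", gene_id)
            n_skipped += 1
            continue
        if strand is None:
            logger.warning("skipping %s: unresolvable strand", gene_id)
            n_skipped += 1
            continue
        if (end - start) % 3 != 0:
            logger.warning("skipping %s: CDS length %d not divisible by 3", gene_id, end - start)
            n_skipped += 1
            continue
        genes.append(GeneRecord(gene_id, contig, start, end, strand, product))
    logger.info("read_annotation: %d CDS records kept, %d skipped", len(genes), n_skipped)
    if not genes:
        raise ValueError(f"{path}: no usable CDS records")
    return genes


def cds_sequence(genome: Genome, gene: GeneRecord) -> str:
    """Coding sequence 5'->3' in coding orientation (reverse complemented for
    minus-strand genes)."""
    if gene.contig not in genome.contigs:
        raise ValueError(f"gene {gene.gene_id}: contig {gene.contig!r} not in genome")
    if gene.end > len(genome.contigs[gene.contig]) or gene.start < 0:
        raise ValueError(f"gene {gene.gene_id}: interval out of contig bounds")
    raw = genome.slice(gene.contig, gene.start, gene.end)
    return reverse_complement(raw) if gene.strand == "-" else raw


def codon_address_of(gene: GeneRecord, genomic_pos: int) -> Optional[CodonAddress]:
    """Map a 0-based genomic position into the gene's coding frame, or None
    if the position lies outside the gene."""
    if not gene.start <= genomic_pos < gene.end:
        return None
    if gene.strand == "+":
        offset = genomic_pos - gene.start
    else:
        offset = gene.end - 1 - genomic_pos
    return CodonAddress(gene.gene_id, offset // 3 + 1, offset % 3 + 1)


def genomic_position_of(gene: GeneRecord, address: CodonAddress) -> int:
    """Inverse of :func:`codon_address_of`."""
    offset = (address.codon_index - 1) * 3 + (address.offset_in_codon - 1)
    if not 0 <= offset < gene.end - gene.start:
        raise ValueError(f"address {address} outside gene {gene.gene_id}")
    if gene.strand == "+":
        return gene.start + offset
    return gene.end - 1 - offset


def gene_interval_index(genes: Iterable[GeneRecord]) -> dict[str, IntervalTree]:
    """Per-contig interval tree over gene bodies, for overlap queries."""
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        trees.setdefault(gene.contig, IntervalTree()).addi(gene.start, gene.end, gene)
    return trees


def validate_orf(genome: Genome, gene: GeneRecord) -> None:
    """Assert that a gene is a clean bacterial ORF: accepted start codon,
    terminal stop, and no internal stop codon."""
    cds = cds_sequence(genome, gene)
    if cds[:3] not in START_CODONS:
        raise ValueError(f"{gene.gene_id}: start codon {cds[:3]} not in {sorted(START_CODONS)}")
    if cds[-3:] not in STOP_CODONS:
        raise ValueError(f"{gene.gene_id}: terminal codon {cds[-3:]} is not a stop")
    for i in range(0, len(cds) - 3, 3):
        if cds[i : i + 3] in STOP_CODONS:
            raise ValueError(f"{gene.gene_id}: internal stop at codon {i // 3 + 1}")
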