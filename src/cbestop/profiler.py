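"""sgRNA-independent off-target SNV profiling from whole-genome variant calls.

A cytosine base editor carried on a plasmid deaminates cytosines genome-wide,
independently of its guide. The resulting mutation load is characterised here
exactly as in WGS follow-up studies of edited strains: variants common with a
negative-control (unedited) sample are subtracted, calls are intersected
across sequencing platforms to drop platform-private false positives, the
intended on-target edits are masked out, and the surviving off-target set is
summarised by strand-collapsed substitution spectrum, +/-2 bp sequence
context around the deaminated C (deaminase signature: 5'-TC), genomic region
(coding / promoter / intergenic) and coding effect (nonsense / missense /
silent).

Variant identity is the key (contig, pos, ref, alt); genotypes and quality
fields are ignored. Alignment and variant calling are upstream of this
module, which consumes VCF 4.x.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from intervaltree import IntervalTree
from scipy.stats import binomtest

from .genome import (
    STOP_CODONS,
    GeneRecord,
    Genome,
    cds_sequence,
    codon_address_of,
    complement_base,
    gene_interval_index,
    reverse_complement,
    translate,
)

logger = logging.getLogger("cbestop")

BASES = ("A", "C", "G", "T")
#: strand-collapsed substitution classes (purine-reference changes are
#: complemented onto the pyrimidine reference)
SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
CONTEXT_OFFSETS = (-2, -1, 0, 1, 2)
DEFAULT_PROMOTER_LENGTH = 100


class Variant(NamedTuple):
    """A single-nucleotide variant; ``pos`` is 1-based as in VCF."""

    contig: str
    pos: int
    ref: str
    alt: str


@dataclass
class VariantSet:
    sample_id: str
    platform: str
    variants: set[Variant] = field(default_factory=set)
    #: records dropped at ingest, e.g. {"indel_or_mnv": 3, "duplicate": 1}
    skipped: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.variants)

    def sorted(self) -> list[Variant]:
        return sorted(self.variants)


def collapse(ref: str, alt: str) -> str:
    """Map a substitution onto the six pyrimidine-reference classes."""
    if ref in "AG":
        ref, alt = complement_base(ref), complement_base(alt)
    return f"{ref}>{alt}"


def read_vcf(
    path: str | Path,
    sample_id: str,
    platform: str = "",
    genome: Optional[Genome] = None,
) -> VariantSet:
    """Ingest biallelic SNVs from a VCF 4.x file.

    Multi-allelic records are split per ALT allele; indels and MNVs are
    skipped and tallied; duplicate keys are deduplicated. If a genome is
    supplied, every REF allele is checked against it and mismatches raise.
    """
    vs = VariantSet(sample_id=sample_id, platform=platform)
    skipped = {"indel_or_mnv": 0, "duplicate": 0}
    mismatches: list[Variant] = []
    for rec in VCF(str(path)):
        ref = rec.REF.upper()
        for alt in rec.ALT:
            alt = alt.upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                skipped["indel_or_mnv"] += 1
                continue
            v = Variant(rec.CHROM, rec.POS, ref, alt)
            if genome is not None and genome.contigs[v.contig][v.pos - 1] != ref:
                mismatches.append(v)
                continue
            if v in vs.variants:
                skipped["duplicate"] += 1
            else:
                vs.variants.add(v)
    if mismatches:
        listing = ", ".join(f"{v.contig}:{v.pos} {v.ref}>{v.alt}" for v in mismatches[:20])
        raise ValueError(f"{path}: REF does not match genome for {len(mismatches)} records: {listing}")
    vs.skipped = skipped
    logger.info("read_vcf %s (%s): %d SNVs, skipped %s", sample_id, platform, len(vs), skipped)
    return vs


def subtract_control(sample: VariantSet, control: VariantSet) -> VariantSet:
    """Remove variants also present in the negative-control sample
    (strain-vs-reference background), keyed on (contig, pos, ref, alt)."""
    return VariantSet(
        sample_id=sample.sample_id,
        platform=sample.platform,
        variants=sample.variants - control.variants,
    )


def intersect_platforms(a: VariantSet, b: VariantSet) -> VariantSet:
    """Keep only calls observed on both sequencing platforms."""
    return VariantSet(
        sample_id=a.sample_id,
        platform=f"{a.platform}&{b.platform}" if a.platform and b.platform else a.platform,
        variants=a.variants & b.variants,
    )


def mask_on_target(
    vs: VariantSet,
    sgrna_intervals: Sequence[tuple[str, int, int]],
    flank: int = 0,
) -> tuple[VariantSet, VariantSet]:
    """Remove the intended edits: variants inside any sgRNA protospacer
    interval (0-based half-open), optionally widened by ``flank`` bp.
    Returns (kept, removed)."""
    trees: dict[str, IntervalTree] = {}
    for contig, start, end in sgrna_intervals:
        trees.setdefault(contig, IntervalTree()).addi(start - flank, end + flank)
    kept, removed = set(), set()
    for v in vs.variants:
        tree = trees.get(v.contig)
        if tree is not None and tree.overlaps_point(v.pos - 1):
            removed.add(v)
        else:
            kept.add(v)
    return (
        VariantSet(vs.sample_id, vs.platform, kept),
        VariantSet(vs.sample_id, vs.platform + ":on_target", removed),
    )


@dataclass
class SubstitutionSpectrum:
    counts: dict[str, int]
    n: int

    @property
    def fractions(self) -> dict[str, float]:
        """Per-class fractions; NaN (undefined) when the set is empty."""
        if self.n == 0:
            return {c: math.nan for c in SPECTRUM_CLASSES}
        return {c: self.counts[c] / self.n for c in SPECTRUM_CLASSES}


def substitution_spectrum(vs: VariantSet) -> SubstitutionSpectrum:
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    for v in vs.variants:
        counts[collapse(v.ref, v.alt)] += 1
    return SubstitutionSpectrum(counts=counts, n=len(vs))


@dataclass
class ContextMatrix:
    """Position-frequency matrix of the bases at -2..+2 around mutated
    cytosines, oriented so the centre base is C (G-reference variants are
    reverse-complemented). ``tc_fraction`` is P(base at -1 == T)."""

    matrix: pd.DataFrame  # rows A,C,G,T; columns -2..+2; columns sum to 1
    n_used: int
    n_skipped_edge: int
    tc_fraction: float


def _c_class_context(v: Variant, genome: Genome) -> Optional[str]:
    """5-mer context centred on the mutated base, oriented C-up, or None if
    the variant is not C-class or sits within 2 bp of a contig end."""
    if collapse(v.ref, v.alt)[0] != "C":
        return None
    seq = genome.contigs[v.contig]
    p = v.pos - 1
    if p - 2 < 0 or p + 3 > len(seq):
        return None
    window = seq[p - 2 : p + 3]
    return window if v.ref == "C" else reverse_complement(window)


def build_context_matrix(vs: VariantSet, genome: Genome) -> ContextMatrix:
    counts = np.zeros((4, 5), dtype=float)
    n_used = 0
    n_edge = 0
    n_tc = 0
    base_row = {b: i for i, b in enumerate(BASES)}
    for v in sorted(vs.variants):
        if collapse(v.ref, v.alt)[0] != "C":
            continue
        ctx = _c_class_context(v, genome)
        if ctx is None:
            n_edge += 1
            continue
        if "N" in ctx:
            n_edge += 1
            continue
        for j, b in enumerate(ctx):
            counts[base_row[b], j] += 1
        n_used += 1
        if ctx[1] == "T":
            n_tc += 1
    if n_used > 0:
        matrix = counts / n_used
        tc_fraction = n_tc / n_used
    else:
        matrix = np.full((4, 5), math.nan)
        tc_fraction = math.nan
    df = pd.DataFrame(matrix, index=list(BASES), columns=list(CONTEXT_OFFSETS))
    return ContextMatrix(matrix=df, n_used=n_used, n_skipped_edge=n_edge, tc_fraction=tc_fraction)


def genome_tc_background(genome: Genome) -> float:
    """Genome-wide fraction of cytosines (either strand) preceded by T:
    plus-strand TC dinucleotides plus minus-strand ones (= plus-strand GA),
    over all Cs with a 5' neighbour."""
    tc = 0
    denom = 0
    for seq in genome.contigs.values():
        tc += seq.count("TC") + seq.count("GA")
        denom += seq[1:].count("C") + seq[:-1].count("G")
    if denom == 0:
        raise ValueError("genome contains no usable C/G positions")
    return tc / denom


def tc_enrichment_test(vs: VariantSet, genome: Genome) -> dict:
    """One-sided exact binomial test of 5'-TC preference among C-class
    variants against the genome-wide TC background. (The underlying studies
    draw sequence logos without a formal test; the test is reporting
    plumbing on top of the same counts.)"""
    background = genome_tc_background(genome)
    n = 0
    n_tc = 0
    for v in vs.variants:
        ctx = _c_class_context(v, genome)
        if ctx is None or "N" in ctx:
            continue
        n += 1
        if ctx[1] == "T":
            n_tc += 1
    if n == 0:
        raise ValueError("no usable C-class variants for TC enrichment test")
    result = binomtest(n_tc, n, background, alternative="greater")
    return {
        "n_c_class": n,
        "n_tc": n_tc,
        "tc_fraction": n_tc / n,
        "background_tc_fraction": background,
        "p_value": result.pvalue,
    }


def default_promoters(
    genes: Iterable[GeneRecord],
    genome: Genome,
    length: int = DEFAULT_PROMOTER_LENGTH,
) -> list[tuple[str, int, int]]:
    """Default promoter model: the ``length`` bp immediately upstream of each
    CDS start on the gene's strand, clipped at contig ends. Meant to be
    overridden with a curated promoter catalogue (BED) when one exists."""
    out = []
    for g in genes:
        clen = len(genome.contigs[g.contig])
        if g.strand == "+":
            start, end = max(0, g.start - length), g.start
        else:
            start, end = g.end, min(clen, g.end + length)
        if end > start:
            out.append((g.contig, start, end))
    return out


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read intervals from a BED3+ file (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2])
    return [(str(c), int(s), int(e)) for c, s, e in df.itertuples(index=False)]


def read_sgrna_tsv(path: str | Path) -> list[dict]:
    """Read an sgRNA spec table (contig, start, end, strand, name) with
    0-based half-open protospacer intervals."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"contig", "start", "end", "strand", "name"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sgRNA table missing columns {sorted(missing)}")
    return [
        {"contig": str(r.contig), "start": int(r.start), "end": int(r.end),
         "strand": str(r.strand), "name": str(r.name)}
        for r in df.itertuples(index=False)
    ]


@dataclass
class RegionBreakdown:
    counts: dict[str, int]
    n: int

    @property
    def fractions(self) -> dict[str, float]:
        if self.n == 0:
            return {k: math.nan for k in self.counts}
        return {k: v / self.n for k, v in self.counts.items()}


def classify_regions(
    vs: VariantSet,
    genes: Iterable[GeneRecord],
    promoters: Sequence[tuple[str, int, int]],
) -> RegionBreakdown:
    """Assign each variant to exactly one of coding / promoter / intergenic,
    with precedence coding > promoter > intergenic (a base can lie inside one
    gene and upstream of another)."""
    coding = gene_interval_index(genes)
    prom: dict[str, IntervalTree] = {}
    for contig, start, end in promoters:
        prom.setdefault(contig, IntervalTree()).addi(start, end)
    counts = {"coding": 0, "promoter": 0, "intergenic": 0}
    for v in vs.variants:
        p = v.pos - 1
        if v.contig in coding and coding[v.contig].overlaps_point(p):
            counts["coding"] += 1
        elif v.contig in prom and prom[v.contig].overlaps_point(p):
            counts["promoter"] += 1
        else:
            counts["intergenic"] += 1
    return RegionBreakdown(counts=counts, n=len(vs))


@dataclass
class EffectBreakdown:
    counts: dict[str, int]  # nonsense / missense / silent / stop_loss
    n_cds_hit: int
    rows: pd.DataFrame  # per (variant, gene) effect annotation


def classify_effects(
    vs: VariantSet, genome: Genome, genes: Iterable[GeneRecord]
) -> EffectBreakdown:
    """Recompute codons before/after each coding SNV, strand-aware, and
    classify: silent (same residue), nonsense (stop gained), missense
    (residue change), stop_loss (native stop destroyed). Variants hitting
    overlapping genes are annotated once per gene."""
    trees = gene_interval_index(genes)
    cds_cache: dict[str, str] = {}
    rows = []
    counts = {"nonsense": 0, "missense": 0, "silent": 0, "stop_loss": 0}
    genes_hit = set()
    for v in sorted(vs.variants):
        tree = trees.get(v.contig)
        if tree is None:
            continue
        p = v.pos - 1
        for iv in sorted(tree.overlap(p, p + 1), key=lambda i: i.data.gene_id):
            gene: GeneRecord = iv.data
            if genome.contigs[v.contig][p] != v.ref:
                raise ValueError(f"{v.contig}:{v.pos}: REF {v.ref} does not match genome")
            addr = codon_address_of(gene, p)
            cds = cds_cache.setdefault(gene.gene_id, cds_sequence(genome, gene))
            ci = addr.codon_index
            codon_before = cds[3 * (ci - 1) : 3 * ci]
            coding_alt = v.alt if gene.strand == "+" else complement_base(v.alt)
            k = addr.offset_in_codon - 1
            codon_after = codon_before[:k] + coding_alt + codon_before[k + 1 :]
            before_stop = codon_before in STOP_CODONS
            after_stop = codon_after in STOP_CODONS
            if before_stop and not after_stop:
                effect = "stop_loss"
            elif not before_stop and after_stop:
                effect = "nonsense"
            elif translate(codon_before) == translate(codon_after):
                effect = "silent"
            else:
                effect = "missense"
            counts[effect] += 1
            genes_hit.add(gene.gene_id)
            rows.append(
                {
                    "contig": v.contig, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                    "gene_id": gene.gene_id, "codon_index": ci,
                    "codon_before": codon_before, "codon_after": codon_after,
                    "effect": effect,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["contig", "pos", "ref", "alt", "gene_id", "codon_index",
                 "codon_before", "codon_after", "effect"],
    )
    return EffectBreakdown(counts=counts, n_cds_hit=len(genes_hit), rows=df)


# ---------------------------------------------------------------------------
# pipeline orchestration and reporting
# ---------------------------------------------------------------------------

def _fmt(x: float) -> Optional[float]:
    """6-significant-digit float for deterministic reports; NaN -> None."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    return float(f"{x:.6g}")


@dataclass
class ProfileResult:
    final: VariantSet
    stages: list[dict]
    spectrum: SubstitutionSpectrum
    context: ContextMatrix
    tc_test: dict
    regions: RegionBreakdown
    effects: EffectBreakdown
    report: dict


def run_profile(
    genome: Genome,
    genes: list[GeneRecord],
    samples: Sequence[VariantSet],
    control: VariantSet,
    sgrna_intervals: Sequence[tuple[str, int, int]] = (),
    promoters: Optional[Sequence[tuple[str, int, int]]] = None,
    metadata: Optional[dict] = None,
) -> ProfileResult:
    """Full off-target profile: subtract control from every platform,
    intersect platforms, mask on-target edits, then characterise the final
    set. Every filter stage records n_in = n_out + n_removed."""
    if not samples:
        raise ValueError("at least one sample VariantSet required")
    if promoters is None:
        promoters = default_promoters(genes, genome)
    stages: list[dict] = []
    filtered = []
    for s in samples:
        out = subtract_control(s, control)
        stages.append(
            {"stage": f"subtract_control[{s.platform or s.sample_id}]",
             "n_in": len(s), "n_out": len(out), "n_removed": len(s) - len(out)}
        )
        filtered.append(out)
    current = filtered[0]
    for other in filtered[1:]:
        merged = intersect_platforms(current, other)
        stages.append(
            {"stage": f"intersect[{current.platform}|{other.platform}]",
             "n_in": len(current), "n_out": len(merged),
             "n_removed": len(current) - len(merged)}
        )
        current = merged
    kept, removed = mask_on_target(current, sgrna_intervals)
    stages.append(
        {"stage": "mask_on_target", "n_in": len(current),
         "n_out": len(kept), "n_removed": len(removed)}
    )
    for st in stages:
        logger.info("%s: %d -> %d (removed %d)", st["stage"], st["n_in"], st["n_out"], st["n_removed"])
        assert st["n_in"] == st["n_out"] + st["n_removed"]

    spectrum = substitution_spectrum(kept)
    context = build_context_matrix(kept, genome)
    try:
        tc_test = tc_enrichment_test(kept, genome)
    except ValueError:
        tc_test = {"n_c_class": 0, "n_tc": 0, "tc_fraction": None,
                   "background_tc_fraction": _fmt(genome_tc_background(genome)),
                   "p_value": None}
    regions = classify_regions(kept, genes, promoters)
    effects = classify_effects(kept, genome, genes)

    report = {
        "metadata": metadata or {},
        "samples": [
            {"sample_id": s.sample_id, "platform": s.platform,
             "n_variants": len(s), "skipped_at_ingest": s.skipped}
            for s in samples
        ],
        "control": {"sample_id": control.sample_id, "n_variants": len(control)},
        "stages": stages,
        "final": {
            "n": len(kept),
            "spectrum_counts": spectrum.counts,
            "spectrum_fractions": {k: _fmt(v) for k, v in spectrum.fractions.items()},
            "context": {
                "n_used": context.n_used,
                "n_skipped_edge": context.n_skipped_edge,
                "tc_fraction": _fmt(context.tc_fraction),
            },
            "tc_test": {k: (_fmt(v) if isinstance(v, float) else v) for k, v in tc_test.items()},
            "regions": {
                "counts": regions.counts,
                "fractions": {k: _fmt(v) for k, v in regions.fractions.items()},
            },
            "effects": {"counts": effects.counts, "n_cds_hit": effects.n_cds_hit},
        },
    }
    return ProfileResult(
        final=kept, stages=stages, spectrum=spectrum, context=context,
        tc_test=tc_test, regions=regions, effects=effects, report=report,
    )


def write_profile(result: ProfileResult, out_dir: str | Path) -> None:
    """Write summary.json, the per-variant effect table and the logo-ready
    context PFM; output is byte-identical across reruns on equal inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "summary.json", "w") as fh:
        json.dump(result.report, fh, indent=2, allow_nan=False)
        fh.write("\n")
    rows = pd.DataFrame(
        [{"contig": v.contig, "pos": v.pos, "ref": v.ref, "alt": v.alt,
          "class": collapse(v.ref, v.alt)} for v in result.final.sorted()],
        columns=["contig", "pos", "ref", "alt", "class"],
    )
    rows.to_csv(out / "variants.tsv", sep="\t", index=False)
    result.effects.rows.to_csv(out / "effects.tsv", sep="\t", index=False)
    ctx = result.context.matrix.round(6)
    ctx.index.name = "base"
    ctx.to_csv(out / "context_matrix.tsv", sep="\t")
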