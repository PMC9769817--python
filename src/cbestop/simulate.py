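"""Synthetic genomes, annotations, sgRNA specs and paired variant-call files.

The generator emulates the data the designer and profiler were built for: a
GC-rich bacterial chromosome (default 54% GC, the Corynebacterium range)
tiled with non-overlapping ORFs, and off-target SNV call sets with the
statistical structure of plasmid-borne cytosine-deaminase activity —
C•G->T•A dominance, 5'-TC context enrichment, promoter-region bias — mixed
with shared strain-background variants (present in the negative control),
platform-private false positives, and the intended on-target edits. Every
simulated record carries a truth-ledger category, so the profiler's filter
chain can be audited for zero leakage and its estimates checked against the
generating parameters.

All randomness flows from a single seed; outputs are byte-identical across
reruns with equal parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import designer
from .genome import GeneRecord, Genome, complement_base, reverse_complement, write_fasta
from .profiler import Variant, VariantSet, default_promoters

logger = logging.getLogger("cbestop")

_STOPS = ("TAA", "TAG", "TGA")
_NONCT_CLASSES = ("C>A", "C>G", "T>A", "T>C", "T>G")


@dataclass
class GenomeSimParams:
    """Parameters of the synthetic chromosome.

    ``gene_length_range`` is in codons including start and stop; defaults
    give a 100 kb contig at 54% GC carrying 60 ORFs of 100-400 codons."""

    n_contigs: int = 1
    contig_length: int = 100_000
    gc_fraction: float = 0.54
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (100, 400)
    min_intergenic: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if self.gene_length_range[0] < 3:
            raise ValueError("genes need at least 3 codons (start, one sense, stop)")


@dataclass
class OfftargetSimParams:
    """Parameters of the off-target variant simulation.

    ``p_ct`` sets the strand-collapsed C>T fraction of the off-target
    spectrum; ``tc_prob`` the probability that a C-class site has T at -1 on
    the deaminated strand; ``promoter_bias`` multiplies the sampling weight
    of promoter positions (promoter = 100 bp upstream of a CDS, minus any
    coding overlap). Background variants are written to both sample and
    control; false positives are private to one platform."""

    n_snvs: int = 1000
    p_ct: float = 0.9
    tc_prob: float = 0.7
    promoter_bias: float = 3.0
    n_background: int = 40
    fp_per_platform: int = 15
    on_target_edits: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_ct", "tc_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_snvs < 0:
            raise ValueError("n_snvs must be >= 0")


def _random_codons(rng: np.random.Generator, n: int, base_p: np.ndarray) -> list[str]:
    """n random sense (non-stop) codons with the given base composition."""
    bases = np.array(list("ACGT"))
    out: list[str] = []
    while len(out) < n:
        draw = rng.choice(bases, size=(n - len(out), 3), p=base_p)
        for row in draw:
            codon = "".join(row)
            if codon not in _STOPS:
                out.append(codon)
    return out


def generate_genome(params: GenomeSimParams) -> tuple[Genome, list[GeneRecord], dict]:
    """Build a genome of non-overlapping clean ORFs (ATG start, single
    terminal stop, no internal stop) over a background whose base
    composition matches ``gc_fraction``; returns (genome, genes, ledger)."""
    rng = np.random.default_rng(params.seed)
    gc = params.gc_fraction
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))

    per_contig = [params.n_genes // params.n_contigs] * params.n_contigs
    for i in range(params.n_genes % params.n_contigs):
        per_contig[i] += 1

    contigs: dict[str, str] = {}
    genes: list[GeneRecord] = []
    gene_no = 0
    for ci in range(params.n_contigs):
        name = f"chr{ci + 1}"
        k = per_contig[ci]
        lens = rng.integers(params.gene_length_range[0], params.gene_length_range[1] + 1, size=k)
        gene_bp = 3 * lens
        needed = int(gene_bp.sum()) + (k + 1) * params.min_intergenic
        if needed > params.contig_length:
            raise ValueError(
                f"contig {name}: {k} genes need {needed} bp but contig_length is "
                f"{params.contig_length}"
            )
        slack = params.contig_length - needed
        extra = rng.multinomial(slack, [1.0 / (k + 1)] * (k + 1)) if k >= 0 else []
        seq = rng.choice(bases, size=params.contig_length, p=base_p)
        cursor = 0
        for gi in range(k):
            cursor += params.min_intergenic + int(extra[gi])
            n_codons = int(lens[gi])
            orf = "ATG" + "".join(_random_codons(rng, n_codons - 2, base_p)) + \
                str(rng.choice(_STOPS))
            strand = str(rng.choice(["+", "-"]))
            placed = reverse_complement(orf) if strand == "-" else orf
            start, end = cursor, cursor + 3 * n_codons
            seq[start:end] = list(placed)
            gene_no += 1
            genes.append(GeneRecord(f"g{gene_no:04d}", name, start, end, strand))
            cursor = end
        contigs[name] = "".join(seq)

    genome = Genome(contigs)
    total = sum(genome.lengths.values())
    realized_gc = sum(s.count("G") + s.count("C") for s in contigs.values()) / total
    ledger = {
        "params": asdict(params),
        "seed": params.seed,
        "realized_gc": realized_gc,
        "genes": [asdict(g) for g in genes],
    }
    return genome, genes, ledger


# ---------------------------------------------------------------------------
# off-target variant simulation
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    samples: dict[str, VariantSet]  # platform -> sample calls
    control: VariantSet
    sgrnas: list[dict]
    truth: dict  # per-variant categories + expected parameter values

    @property
    def truth_offtargets(self) -> set[Variant]:
        return {
            Variant(r["contig"], r["pos"], r["ref"], r["alt"])
            for r in self.truth["variants"]
            if r["category"] == "offtarget"
        }


class _Pool:
    """Pre-shuffled position pool supporting draw-without-replacement."""

    def __init__(self, rng: np.random.Generator, positions: list[tuple[str, int]]):
        self.items = [positions[i] for i in rng.permutation(len(positions))]

    def __len__(self) -> int:
        return len(self.items)

    def pop(self, used: set) -> tuple[str, int]:
        while self.items:
            item = self.items.pop()
            if item not in used:
                used.add(item)
                return item
        raise ValueError("not enough eligible positions in simulation pool")


def _weighted_promoter_prob(bias: float, n_prom: int, n_other: int) -> float:
    if n_prom + n_other == 0:
        return 0.0
    return bias * n_prom / (bias * n_prom + n_other)


def simulate_offtargets(
    genome: Genome,
    genes: list[GeneRecord],
    params: OfftargetSimParams,
    platforms: Sequence[str] = ("illumina", "pacbio"),
) -> SimResult:
    """Simulate paired per-platform sample calls plus a negative control.

    Off-target sites: with probability ``p_ct`` a C•G->T•A substitution,
    otherwise one of the five other classes (uniform). Any C-class site is
    drawn with T at -1 with probability ``tc_prob``; every site is drawn
    from promoter positions with weight ``promoter_bias``. The truth ledger
    records per-variant categories and the exact expected values of the
    recoverable quantities implied by the realized position pools."""
    rng = np.random.default_rng(params.seed)

    prom_iv = default_promoters(genes, genome)
    prom_mask: dict[str, np.ndarray] = {
        c: np.zeros(n, dtype=bool) for c, n in genome.lengths.items()
    }
    for contig, start, end in prom_iv:
        prom_mask[contig][start:end] = True
    for g in genes:  # precedence: coding beats promoter
        prom_mask[g.contig][g.start:g.end] = False

    # position pools, partitioned so every position lies in exactly one pool;
    # 2 bp at contig ends excluded so all sites carry a full +/-2 context
    ct_positions: dict[tuple[bool, bool], list[tuple[str, int]]] = {
        (tc, pr): [] for tc in (True, False) for pr in (True, False)
    }
    at_positions: dict[bool, list[tuple[str, int]]] = {True: [], False: []}
    for contig, seq in genome.contigs.items():
        pm = prom_mask[contig]
        for p in range(2, len(seq) - 2):
            b = seq[p]
            if b == "C":
                ct_positions[(seq[p - 1] == "T", bool(pm[p]))].append((contig, p))
            elif b == "G":
                ct_positions[(seq[p + 1] == "A", bool(pm[p]))].append((contig, p))
            else:
                at_positions[bool(pm[p])].append((contig, p))

    pp_tc = _weighted_promoter_prob(
        params.promoter_bias, len(ct_positions[(True, True)]), len(ct_positions[(True, False)])
    )
    pp_ntc = _weighted_promoter_prob(
        params.promoter_bias, len(ct_positions[(False, True)]), len(ct_positions[(False, False)])
    )
    pp_at = _weighted_promoter_prob(
        params.promoter_bias, len(at_positions[True]), len(at_positions[False])
    )
    p_c_class = params.p_ct + (1 - params.p_ct) * 2 / len(_NONCT_CLASSES)
    expected_promoter = (
        p_c_class * (params.tc_prob * pp_tc + (1 - params.tc_prob) * pp_ntc)
        + (1 - p_c_class) * pp_at
    )

    ct_pools = {key: _Pool(rng, lst) for key, lst in ct_positions.items()}
    at_pools = {key: _Pool(rng, lst) for key, lst in at_positions.items()}
    all_pool = _Pool(
        rng,
        [pos for lst in ct_positions.values() for pos in lst]
        + [pos for lst in at_positions.values() for pos in lst],
    )

    used: set[tuple[str, int]] = set()
    truth_rows: list[dict] = []

    def record(contig: str, p: int, ref: str, alt: str, category: str, **extra) -> Variant:
        v = Variant(contig, p + 1, ref, alt)
        truth_rows.append({"contig": contig, "pos": p + 1, "ref": ref, "alt": alt,
                           "category": category, **extra})
        return v

    # intended on-target edits (C->T on the protospacer strand)
    on_target: list[Variant] = []
    sgrnas: list[dict] = []
    for entry in params.on_target_edits:
        sg = entry["sgrna"]
        sgrnas.append(dict(sg))
        # no simulated variant may fall inside a protospacer: it would be
        # removed by on-target masking and be indistinguishable from an edit
        for p in range(sg["start"], sg["end"]):
            used.add((sg["contig"], p))
        for p in entry["positions"]:
            ref = genome.contigs[sg["contig"]][p]
            if ref not in "CG":
                raise ValueError(f"on-target position {sg['contig']}:{p} is {ref}, not C/G")
            alt = "T" if ref == "C" else "A"
            used.add((sg["contig"], p))
            on_target.append(record(sg["contig"], p, ref, alt, "on_target", sgrna=sg["name"]))

    # genuine sgRNA-independent off-targets (shared across platforms)
    offtargets: list[Variant] = []
    for _ in range(params.n_snvs):
        if rng.random() < params.p_ct:
            cls = "C>T"
        else:
            cls = str(rng.choice(_NONCT_CLASSES))
        if cls[0] == "C":
            tc = bool(rng.random() < params.tc_prob)
            pp = pp_tc if tc else pp_ntc
            prom = bool(rng.random() < pp)
            contig, p = ct_pools[(tc, prom)].pop(used)
        else:
            prom = bool(rng.random() < pp_at)
            contig, p = at_pools[prom].pop(used)
        ref = genome.contigs[contig][p]
        alt = cls[2] if ref == cls[0] else complement_base(cls[2])
        offtargets.append(record(contig, p, ref, alt, "offtarget",
                                 cls=cls, promoter=prom))

    def random_snv(category: str) -> Variant:
        contig, p = all_pool.pop(used)
        ref = genome.contigs[contig][p]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return record(contig, p, ref, alt, category)

    background = [random_snv("background") for _ in range(params.n_background)]
    platform_fps = {
        pl: [random_snv(f"fp_{pl}") for _ in range(params.fp_per_platform)]
        for pl in platforms
    }

    shared = set(offtargets) | set(background) | set(on_target)
    samples = {
        pl: VariantSet(sample_id=f"edited_{pl}", platform=pl,
                       variants=shared | set(platform_fps[pl]))
        for pl in platforms
    }
    control = VariantSet(sample_id="control", platform="", variants=set(background))

    truth = {
        "seed": params.seed,
        "params": {k: v for k, v in asdict(params).items() if k != "on_target_edits"},
        "n_by_category": {
            "offtarget": len(offtargets),
            "background": len(background),
            "on_target": len(on_target),
            **{f"fp_{pl}": len(platform_fps[pl]) for pl in platforms},
        },
        "expected": {
            "p_ct": params.p_ct,
            "tc_fraction": params.tc_prob,
            "promoter_fraction": expected_promoter,
        },
        "variants": truth_rows,
    }
    logger.info(
        "simulated %d off-targets, %d background, %d on-target, %s FPs",
        len(offtargets), len(background), len(on_target),
        {pl: len(v) for pl, v in platform_fps.items()},
    )
    return SimResult(samples=samples, control=control, sgrnas=sgrnas, truth=truth)


# ---------------------------------------------------------------------------
# file writers and named scenarios
# ---------------------------------------------------------------------------

def write_vcf(vs: VariantSet, genome: Genome, path: str | Path, seed: Optional[int] = None) -> None:
    """Write a sites-only VCF 4.2 file, sorted by (contig, pos, alt)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cbestop-simulate\n")
        if seed is not None:
            fh.write(f"##cbestop_seed={seed}\n")
        for contig, length in genome.lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in vs.sorted():
            fh.write(f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\n")


def write_gff3(genes: Sequence[GeneRecord], genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, length in genome.lengths.items():
            fh.write(f"##sequence-region {contig} 1 {length}\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{g.contig}\tcbestop\tCDS\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
            )


def write_sgrna_tsv(sgrnas: Sequence[dict], path: str | Path) -> None:
    """sgRNA spec table: 0-based half-open protospacer intervals."""
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tstrand\tname\n")
        for sg in sgrnas:
            fh.write(f"{sg['contig']}\t{sg['start']}\t{sg['end']}\t{sg['strand']}\t{sg['name']}\n")


def _pick_on_target_edits(
    genome: Genome, genes: list[GeneRecord], n_guides: int
) -> list[dict]:
    """Choose sgRNAs from the designer's own output: the first stop site of
    each of the first ``n_guides`` targetable genes, editing the target C
    plus any immediately adjacent C on the protospacer strand (CC->TT)."""
    sites = designer.find_stop_sites(genome, genes)
    chosen: list[dict] = []
    seen_genes: set[str] = set()
    for site in sites:
        if site.gene_id in seen_genes:
            continue
        seen_genes.add(site.gene_id)
        seq = genome.contigs[site.contig]
        positions = [site.edited_c_pos]
        if site.protospacer_strand == "+":
            nxt = site.edited_c_pos + 1
            if nxt < len(seq) and seq[nxt] == "C":
                positions.append(nxt)
        else:
            nxt = site.edited_c_pos - 1
            if nxt >= 0 and seq[nxt] == "G":
                positions.append(nxt)
        if site.protospacer_strand == "+":
            start = site.edited_c_pos - (site.c_position - 1)
            end = start + 20
        else:
            end = site.edited_c_pos + site.c_position
            start = end - 20
        chosen.append(
            {
                "sgrna": {"contig": site.contig, "start": start, "end": end,
                          "strand": site.protospacer_strand,
                          "name": f"{site.gene_id}-sg{site.c_position}"},
                "positions": positions,
            }
        )
        if len(chosen) == n_guides:
            break
    if len(chosen) < n_guides:
        raise ValueError(f"only {len(chosen)} targetable genes for {n_guides} guides")
    return chosen


#: named scenarios: (guides, rounds, per-round SNV count, spectrum C>T
#: fraction). Scales mirror an observed single-edit strain (~48 off-target
#: SNVs, 98% C>T) and a five-round serially edited strain (~184 SNVs, 82%).
SCENARIOS = {
    "single-edit": {"n_guides": 1, "rounds": 1, "snvs_per_round": 48, "p_ct": 0.98},
    "serial-mge": {"n_guides": 5, "rounds": 5, "snvs_per_round": 37, "p_ct": 0.82},
}


def fixture_bundle(
    out_dir: str | Path,
    scenario: str = "single-edit",
    seed: int = 0,
    genome_params: Optional[GenomeSimParams] = None,
    offtarget_params: Optional[OfftargetSimParams] = None,
) -> dict:
    """Write a complete, deterministic test bundle for a named scenario:
    FASTA + GFF3 + per-platform sample VCFs + control VCF + sgRNA TSV +
    truth JSON. Returns the truth ledger (with per-round labels for the
    serial scenario)."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
    spec = SCENARIOS[scenario]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    gp = genome_params or GenomeSimParams(seed=seed)
    genome, genes, genome_ledger = generate_genome(gp)

    n_total = spec["rounds"] * spec["snvs_per_round"]
    if offtarget_params is None:
        offtarget_params = OfftargetSimParams(n_snvs=n_total, p_ct=spec["p_ct"], seed=seed + 1)
    offtarget_params.on_target_edits = _pick_on_target_edits(genome, genes, spec["n_guides"])
    result = simulate_offtargets(genome, genes, offtarget_params)

    # label off-targets with the editing round that produced them
    per_round = offtarget_params.n_snvs // spec["rounds"]
    idx = 0
    for row in result.truth["variants"]:
        if row["category"] == "offtarget":
            row["round"] = min(idx // max(per_round, 1) + 1, spec["rounds"])
            idx += 1

    write_fasta(genome, out / "genome.fasta")
    write_gff3(genes, genome, out / "genes.gff3")
    write_sgrna_tsv(result.sgrnas, out / "sgrnas.tsv")
    for platform, vs in result.samples.items():
        write_vcf(vs, genome, out / f"sample_{platform}.vcf", seed=offtarget_params.seed)
    write_vcf(result.control, genome, out / "control.vcf", seed=offtarget_params.seed)

    truth = {
        "scenario": scenario,
        "seed": seed,
        "genome": {k: genome_ledger[k] for k in ("params", "realized_gc")},
        **result.truth,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=False)
        fh.write("\n")
    return truth
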