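"""CBE-STOP guide design: genome-wide enumeration of C->T edits that create
premature termination codons.

A cytosine base editor (CBE) converts C•G to T•A inside a window of the
20-nt protospacer, counted 1..20 from the PAM-distal 5' end with the PAM at
positions 21-23. A single C->T edit creates an in-frame stop codon only when
the pre-edit codon is CAA (Gln) -> TAA, CAG (Gln) -> TAG, or CGA (Arg) -> TGA
on the coding strand, or when the protospacer sits on the template strand of
a TGG (Trp) codon, whose template-strand CCA offers two editable Cs
(TGG -> TAG or TGG -> TGA). The designer does not assume this codon table:
it applies the edit in silico and retranslates, so the {CAA, CAG, CGA, TGG}
pre-edit set is an emergent property, checked by tests against brute-force
enumeration.

The deaminase prefers a 5'-T neighbour (motif classes TC > CC > AC > GC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

from .genome import (
    STOP_CODONS,
    CodonAddress,
    GeneRecord,
    Genome,
    codon_address_of,
    complement_base,
    gene_interval_index,
    reverse_complement,
)

logger = logging.getLogger("cbestop")

MOTIF_RANK: tuple[str, ...] = ("TC", "CC", "AC", "GC")

#: window used for genome-wide targetability summaries (protospacer C4-C8)
TARGETABILITY_WINDOW: tuple[int, int] = (4, 8)


@dataclass(frozen=True)
class EditorProfile:
    """A cytosine base editor: its efficient editing window on the
    protospacer (inclusive, positions 1..20 from the PAM-distal end) and its
    sequence-context preference."""

    name: str
    window: tuple[int, int]
    motif_rank: tuple[str, ...] = MOTIF_RANK

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not 1 <= lo <= hi <= 20:
            raise ValueError(f"editor {self.name}: window {self.window} outside 1..20")

    def compatible(self, c_position: int) -> bool:
        return self.window[0] <= c_position <= self.window[1]


#: Built-in editors. BE3 is scored on its high-activity window (C4-C7);
#: "BE3-observed" is the full window where any editing was seen (C3-C12).
#: YE1-BE3 and BE3-R132E are high-fidelity variants with reduced
#: sgRNA-independent deamination; R132E keeps a wider window (C3-C8) than
#: YE1 (C4-C7).
BUILTIN_EDITORS: dict[str, EditorProfile] = {
    "BE3": EditorProfile("BE3", (4, 7)),
    "BE3-observed": EditorProfile("BE3-observed", (3, 12)),
    "YE1-BE3": EditorProfile("YE1-BE3", (4, 7)),
    "BE3-R132E": EditorProfile("BE3-R132E", (3, 8)),
}


@dataclass(frozen=True)
class Protospacer:
    """A 20-nt protospacer with its PAM. ``start``/``end`` are the 0-based
    half-open genomic interval of the protospacer (PAM excluded); on the
    minus strand the PAM lies genomically 5' of the interval."""

    contig: str
    strand: str
    start: int
    end: int
    sequence: str
    pam: str

    def genomic_position(self, c_position: int) -> int:
        """Genomic (plus-strand) coordinate of protospacer position 1..20."""
        if self.strand == "+":
            return self.start + c_position - 1
        return self.end - c_position


@dataclass(frozen=True)
class StopSite:
    """One editable C whose C->T conversion turns a sense codon into a
    premature stop."""

    gene_id: str
    contig: str
    edited_c_pos: int
    protospacer: str
    pam: str
    protospacer_strand: str
    c_position: int
    motif: str
    codon_before: str
    codon_after: str
    codon_address: CodonAddress
    stop_created: str
    bystander_cs: int

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.gene_id, self.edited_c_pos, self.protospacer_strand)


def _pam_matches(pam3: str, mode: str) -> bool:
    if mode == "NGG":
        return pam3[1] == "G" and pam3[2] == "G"
    if mode == "NG":
        return pam3[1] == "G"
    raise ValueError(f"unknown PAM token {mode!r} (expected 'NGG' or 'NG')")


def enumerate_protospacers(genome: Genome, pam: str = "NGG") -> Iterator[Protospacer]:
    """Scan both strands for 20-nt protospacers followed by a PAM.

    Sites whose protospacer + 3-nt PAM context would run past a contig end
    are omitted; protospacers containing N are skipped. Every NGG site is by
    construction also reported in NG mode.
    """
    if pam not in ("NGG", "NG"):
        raise ValueError(f"unknown PAM token {pam!r} (expected 'NGG' or 'NG')")
    for contig, seq in genome.contigs.items():
        n = len(seq)
        # plus strand: protospacer [i, i+20), PAM [i+20, i+23)
        for i in range(0, n - 22):
            pam3 = seq[i + 20 : i + 23]
            if _pam_matches(pam3, pam):
                spacer = seq[i : i + 20]
                if "N" in spacer:
                    continue
                yield Protospacer(contig, "+", i, i + 20, spacer, pam3)
        # minus strand: PAM occupies [j, j+3) on the plus strand,
        # protospacer [j+3, j+23); read 5'->3' on minus they are revcomps
        for j in range(0, n - 22):
            pam3 = reverse_complement(seq[j : j + 3])
            if _pam_matches(pam3, pam):
                spacer = reverse_complement(seq[j + 3 : j + 23])
                if "N" in spacer:
                    continue
                yield Protospacer(contig, "-", j + 3, j + 23, spacer, pam3)


def _site_from_candidate(
    genome: Genome,
    gene: GeneRecord,
    proto: Protospacer,
    c_position: int,
    window: tuple[int, int],
    cds_cache: dict[str, str],
) -> Optional[StopSite]:
    """Apply the C->T edit at one protospacer position and retranslate the
    overlapped codon; emit a StopSite iff a sense codon becomes a stop."""
    pos = proto.genomic_position(c_position)
    seq = genome.contigs[proto.contig]
    plus_base = seq[pos]
    required = "C" if proto.strand == "+" else "G"
    if plus_base != required:
        return None
    address = codon_address_of(gene, pos)
    if address is None or address.codon_index >= gene.n_codons:
        return None  # outside gene, or the native stop codon
    cds = cds_cache.get(gene.gene_id)
    if cds is None:
        raw = genome.slice(gene.contig, gene.start, gene.end)
        cds = reverse_complement(raw) if gene.strand == "-" else raw
        cds_cache[gene.gene_id] = cds
    ci = address.codon_index
    codon_before = cds[3 * (ci - 1) : 3 * ci]
    if "N" in codon_before or codon_before in STOP_CODONS:
        return None
    edited_plus = "T" if proto.strand == "+" else "A"
    coding_base = edited_plus if gene.strand == "+" else complement_base(edited_plus)
    k = address.offset_in_codon - 1
    codon_after = codon_before[:k] + coding_base + codon_before[k + 1 :]
    if codon_after not in STOP_CODONS:
        return None
    if c_position > 1:
        prev = proto.sequence[c_position - 2]
    else:
        flank_pos = proto.start - 1 if proto.strand == "+" else proto.end
        prev = seq[flank_pos] if 0 <= flank_pos < len(seq) else "N"
        if proto.strand == "-":
            prev = complement_base(prev)
    lo, hi = window
    in_window = proto.sequence[lo - 1 : hi]
    bystanders = in_window.count("C") - 1
    return StopSite(
        gene_id=gene.gene_id,
        contig=proto.contig,
        edited_c_pos=pos,
        protospacer=proto.sequence,
        pam=proto.pam,
        protospacer_strand=proto.strand,
        c_position=c_position,
        motif=prev + "C",
        codon_before=codon_before,
        codon_after=codon_after,
        codon_address=address,
        stop_created=codon_after,
        bystander_cs=bystanders,
    )


def find_stop_sites(
    genome: Genome,
    genes: Iterable[GeneRecord],
    window: tuple[int, int] = TARGETABILITY_WINDOW,
    pam: str = "NGG",
) -> list[StopSite]:
    """Enumerate every single-C->T edit that converts a sense codon of any
    gene into a premature stop, restricted to protospacer positions inside
    ``window`` (inclusive).

    One StopSite per editable C per gene; when several protospacers expose
    the same C for the same gene, the site with the smallest
    (c_position, protospacer start) is kept so reports are unique on
    (gene_id, edited_c_pos, strand). A TGG codon can yield two distinct
    sites via its template-strand CCA. Overlapping genes each get their own
    site for a shared edit.
    """
    lo, hi = window
    if not 1 <= lo <= hi <= 20:
        raise ValueError(f"window {window} outside 1..20")
    trees = gene_interval_index(genes)
    cds_cache: dict[str, str] = {}
    best: dict[tuple[str, int, str], tuple[tuple[int, int], StopSite]] = {}
    for proto in enumerate_protospacers(genome, pam):
        tree = trees.get(proto.contig)
        if tree is None:
            continue
        for c_position in range(lo, hi + 1):
            pos = proto.genomic_position(c_position)
            for iv in tree.overlap(pos, pos + 1):
                site = _site_from_candidate(genome, iv.data, proto, c_position, window, cds_cache)
                if site is None:
                    continue
                rank = (site.c_position, proto.start)
                prior = best.get(site.key)
                if prior is None or rank < prior[0]:
                    best[site.key] = (rank, site)
    sites = [site for _, site in best.values()]
    sites.sort(key=lambda s: (s.contig, s.edited_c_pos, s.protospacer_strand, s.gene_id))
    return sites


def annotate_editor_compatibility(
    site: StopSite, profiles: Iterable[EditorProfile]
) -> dict[str, bool]:
    """Which editors can reach this site, i.e. whose window contains the
    site's protospacer C position."""
    return {p.name: p.compatible(site.c_position) for p in profiles}


def summarize_targetability(
    genome: Genome,
    genes: list[GeneRecord],
    pam: str = "NGG",
    window: tuple[int, int] = TARGETABILITY_WINDOW,
) -> dict:
    """Genome-wide targetability: a gene is targetable iff it has at least
    one StopSite with an editable C inside ``window``."""
    if not genes:
        raise ValueError("empty annotation")
    sites = find_stop_sites(genome, genes, window=window, pam=pam)
    per_gene: dict[str, int] = {g.gene_id: 0 for g in genes}
    for site in sites:
        per_gene[site.gene_id] += 1
    n_targetable = sum(1 for v in per_gene.values() if v > 0)
    summary = {
        "pam": pam,
        "window": list(window),
        "n_genes": len(genes),
        "n_targetable": n_targetable,
        "fraction_targetable": n_targetable / len(genes),
        "n_sites": len(sites),
        "per_gene_site_counts": per_gene,
    }
    logger.info(
        "targetability (%s, C%d-C%d): %d/%d genes (%.2f%%), %d sites",
        pam, window[0], window[1], n_targetable, len(genes),
        100.0 * summary["fraction_targetable"], len(sites),
    )
    return summary


REPORT_COLUMNS = [
    "gene_id", "contig", "edited_c_pos", "protospacer_strand", "protospacer",
    "pam", "c_position", "motif", "codon_index", "offset_in_codon",
    "codon_before", "codon_after", "stop_created", "bystander_cs",
]


def design_report(
    sites: Iterable[StopSite],
    editors: Iterable[EditorProfile] = (),
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Tabulate StopSites, one row per site, deterministically sorted by
    (contig, edited_c_pos, strand); optionally written as TSV."""
    editors = list(editors)
    rows = []
    for s in sites:
        row = {
            "gene_id": s.gene_id,
            "contig": s.contig,
            "edited_c_pos": s.edited_c_pos,
            "protospacer_strand": s.protospacer_strand,
            "protospacer": s.protospacer,
            "pam": s.pam,
            "c_position": s.c_position,
            "motif": s.motif,
            "codon_index": s.codon_address.codon_index,
            "offset_in_codon": s.codon_address.offset_in_codon,
            "codon_before": s.codon_before,
            "codon_after": s.codon_after,
            "stop_created": s.stop_created,
            "bystander_cs": s.bystander_cs,
        }
        for name, ok in annotate_editor_compatibility(s, editors).items():
            row[f"editor_{name}"] = ok
        rows.append(row)
    columns = REPORT_COLUMNS + [f"editor_{e.name}" for e in editors]
    df = pd.DataFrame(rows, columns=columns)
    df = df.sort_values(
        ["contig", "edited_c_pos", "protospacer_strand"], kind="mergesort"
    ).reset_index(drop=True)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
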