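"""Off-target profiler: VCF ingest, filter chain, spectrum/context/region/
effect analytics, and report determinism."""

import json
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from cbestop import (
    GeneRecord,
    Genome,
    Variant,
    VariantSet,
    build_context_matrix,
    classify_effects,
    classify_regions,
    default_promoters,
    intersect_platforms,
    mask_on_target,
    read_vcf,
    run_profile,
    substitution_spectrum,
    subtract_control,
    tc_enrichment_test,
    write_profile,
)
from cbestop.genome import reverse_complement
from cbestop.profiler import genome_tc_background
from cbestop.simulate import write_vcf

VCF_HEADER = "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


def vs(*variants, sample="s", platform="p"):
    return VariantSet(sample, platform, set(variants))


def random_variants(rng, n, contig="c1", span=10_000):
    out = set()
    while len(out) < n:
        pos = int(rng.integers(1, span))
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        out.add(Variant(contig, pos, str(ref), str(alt)))
    return out


class TestReadVcf:
    def test_simple_snv(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(VCF_HEADER + "c1\t100\t.\tC\tT\t.\tPASS\t.\n")
        assert read_vcf(p, "s").variants == {Variant("c1", 100, "C", "T")}

    def test_multiallelic_split(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(VCF_HEADER + "c1\t100\t.\tC\tT,G\t.\tPASS\t.\n")
        assert read_vcf(p, "s").variants == {
            Variant("c1", 100, "C", "T"),
            Variant("c1", 100, "C", "G"),
        }

    def test_indels_skipped_and_tallied(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(
            VCF_HEADER
            + "c1\t100\t.\tC\tT\t.\tPASS\t.\n"
            + "c1\t200\t.\tCA\tC\t.\tPASS\t.\n"
            + "c1\t300\t.\tAT\tGC\t.\tPASS\t.\n"
        )
        result = read_vcf(p, "s")
        assert len(result) == 1
        assert result.skipped["indel_or_mnv"] == 2

    def test_ref_mismatch_errors(self, tmp_path):
        genome = Genome({"c1": "AAAA"})
        p = tmp_path / "a.vcf"
        p.write_text(VCF_HEADER + "c1\t2\t.\tC\tT\t.\tPASS\t.\n")
        with pytest.raises(ValueError, match="c1:2"):
            read_vcf(p, "s", genome=genome)

    def test_simulator_round_trip(self, tmp_path):
        genome = Genome({"c1": "ACGT" * 100})
        rng = np.random.default_rng(5)
        variants = {
            Variant("c1", int(pos), genome.contigs["c1"][int(pos) - 1], "T")
            for pos in rng.choice(np.arange(1, 400), size=30, replace=False)
            if genome.contigs["c1"][int(pos) - 1] != "T"
        }
        p = tmp_path / "sim.vcf"
        write_vcf(VariantSet("sim", "x", variants), genome, p)
        assert read_vcf(p, "sim", genome=genome).variants == variants


class TestSetAlgebra:
    def test_subtract_identity_and_annihilation(self):
        a = vs(Variant("c1", 1, "C", "T"), Variant("c1", 2, "G", "A"))
        empty = vs()
        assert subtract_control(a, empty).variants == a.variants
        assert subtract_control(a, a).variants == set()

    def test_random_sets_match_python_set_oracle(self):
        rng = np.random.default_rng(13)
        a = random_variants(rng, 200)
        b = random_variants(rng, 200)
        va, vb = vs(*a), vs(*b)
        assert subtract_control(va, vb).variants == a - b
        assert intersect_platforms(va, vb).variants == a & b
        assert intersect_platforms(vb, va).variants == a & b  # commutative
        assert subtract_control(va, vb).variants & b == set()

    def test_mask_on_target(self):
        inside = Variant("c1", 101, "C", "T")
        adjacent = Variant("c1", 121, "C", "T")
        other = Variant("c2", 101, "C", "T")
        kept, removed = mask_on_target(vs(inside, adjacent, other), [("c1", 100, 120)])
        assert removed.variants == {inside}
        assert kept.variants == {adjacent, other}
        kept2, removed2 = mask_on_target(vs(inside, adjacent, other), [])
        assert kept2.variants == {inside, adjacent, other} and not removed2.variants

    def test_mask_matches_interval_oracle(self):
        rng = np.random.default_rng(17)
        variants = random_variants(rng, 300, span=2000)
        intervals = [("c1", int(s), int(s) + 20) for s in rng.integers(0, 1980, size=10)]
        kept, removed = mask_on_target(vs(*variants), intervals)
        oracle_removed = {
            v for v in variants
            if any(s <= v.pos - 1 < e for _, s, e in intervals)
        }
        assert removed.variants == oracle_removed
        assert kept.variants == variants - oracle_removed

    def test_subtract_mask_order_invariance(self):
        rng = np.random.default_rng(19)
        sample = vs(*random_variants(rng, 150, span=3000))
        control = vs(*random_variants(rng, 80, span=3000))
        intervals = [("c1", 500, 520), ("c1", 1500, 1520)]
        a = mask_on_target(subtract_control(sample, control), intervals)[0]
        b = subtract_control(mask_on_target(sample, intervals)[0], control)
        assert a.variants == b.variants


class TestSpectrum:
    def test_strand_collapse_single_g_to_a(self):
        spec = substitution_spectrum(vs(Variant("c1", 5, "G", "A")))
        assert spec.fractions["C>T"] == 1.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(23)
        spec = substitution_spectrum(vs(*random_variants(rng, 500)))
        assert math.isclose(sum(spec.fractions.values()), 1.0, abs_tol=1e-9)
        assert sum(spec.counts.values()) == spec.n == 500

    def test_empty_set_fractions_undefined(self):
        spec = substitution_spectrum(vs())
        assert all(math.isnan(f) for f in spec.fractions.values())

    def test_complement_invariance(self):
        rng = np.random.default_rng(29)
        variants = random_variants(rng, 300)
        comp = {
            Variant(v.contig, v.pos, str(Seq(v.ref).complement()), str(Seq(v.alt).complement()))
            for v in variants
        }
        assert (
            substitution_spectrum(vs(*variants)).counts
            == substitution_spectrum(vs(*comp)).counts
        )

    def test_binomial_recovery(self):
        rng = np.random.default_rng(31)
        n, p_ct = 500, 0.8
        variants = set()
        pos = 1
        for _ in range(n):
            pos += 1
            if rng.random() < p_ct:
                variants.add(Variant("c1", pos, "C", "T"))
            else:
                variants.add(Variant("c1", pos, "T", "G"))
        frac = substitution_spectrum(vs(*variants)).fractions["C>T"]
        assert abs(frac - p_ct) <= 3 * math.sqrt(p_ct * (1 - p_ct) / n)


class TestContextMatrix:
    def test_one_hot_plus_strand(self):
        genome = Genome({"c1": "ATCGA"})
        cm = build_context_matrix(vs(Variant("c1", 3, "C", "T")), genome)
        for offset, base in zip((-2, -1, 0, 1, 2), "ATCGA"):
            assert cm.matrix.loc[base, offset] == 1.0
        assert cm.tc_fraction == 1.0
        assert cm.matrix.loc["C", 0] == 1.0

    def test_minus_strand_orientation_normalized(self):
        # the same biology with the deaminated C on the minus strand: the
        # plus-strand genome and variant are reverse complements
        genome = Genome({"c1": "TCGAT"})
        cm = build_context_matrix(vs(Variant("c1", 3, "G", "A")), genome)
        for offset, base in zip((-2, -1, 0, 1, 2), "ATCGA"):
            assert cm.matrix.loc[base, offset] == 1.0

    def test_columns_sum_to_one_center_is_c(self, single_edit_bundle):
        out, truth = single_edit_bundle
        from cbestop import read_fasta

        genome = read_fasta(out / "genome.fasta")
        variants = {
            Variant(r["contig"], r["pos"], r["ref"], r["alt"])
            for r in truth["variants"]
            if r["category"] == "offtarget"
        }
        cm = build_context_matrix(vs(*variants), genome)
        assert np.allclose(cm.matrix.sum(axis=0), 1.0, atol=1e-9)
        assert cm.matrix.loc["C", 0] == 1.0

    def test_mirror_invariance(self, single_edit_bundle):
        out, truth = single_edit_bundle
        from cbestop import read_fasta

        genome = read_fasta(out / "genome.fasta")
        variants = {
            Variant(r["contig"], r["pos"], r["ref"], r["alt"])
            for r in truth["variants"]
            if r["category"] == "offtarget"
        }
        L = genome.lengths["chr1"]
        mirrored_vs = {
            Variant(v.contig, L - v.pos + 1,
                    str(Seq(v.ref).complement()), str(Seq(v.alt).complement()))
            for v in variants
        }
        cm = build_context_matrix(vs(*variants), genome)
        cm2 = build_context_matrix(vs(*mirrored_vs), genome.reverse_complemented())
        assert np.allclose(cm.matrix.values, cm2.matrix.values)
        assert cm.tc_fraction == cm2.tc_fraction

    def test_edge_variants_skipped_and_tallied(self):
        genome = Genome({"c1": "CCAACC"})
        cm = build_context_matrix(
            vs(Variant("c1", 1, "C", "T"), Variant("c1", 6, "C", "T")), genome
        )
        assert cm.n_used == 0 and cm.n_skipped_edge == 2


class TestTcEnrichment:
    # Repeating unit TCCACAGCAA: four Cs (contexts TC, CC, AC, GC) plus one
    # G not followed by A, so the genome-wide TC background is exactly
    # 1 / 5 = 0.2 per unit.
    UNIT = "TCCACAGCAA"

    def test_closed_form_all_tc(self):
        genome = Genome({"c1": self.UNIT * 51})
        bg = genome_tc_background(genome)
        assert math.isclose(bg, 0.2, abs_tol=1e-9)
        # the TC-context C sits at 0-based offset 1 of each unit; skip the
        # first unit so every variant has a full +/-2 context
        variants = {Variant("c1", 10 * k + 2, "C", "T") for k in range(1, 51)}
        res = tc_enrichment_test(vs(*variants), genome)
        assert res["tc_fraction"] == 1.0
        assert math.isclose(res["p_value"], bg**50, rel_tol=1e-9)

    def test_background_rate_not_enriched(self):
        genome = Genome({"c1": self.UNIT * 51})
        # all five eligible sites of five units (four Cs plus the
        # minus-strand C recorded as G): observed TC fraction 5/25 == background
        variants = {
            Variant("c1", 10 * k + off, "C", "T")
            for k in range(1, 6)
            for off in (2, 3, 5, 8)
        } | {Variant("c1", 10 * k + 7, "G", "A") for k in range(1, 6)}
        res = tc_enrichment_test(vs(*variants), genome)
        assert res["tc_fraction"] == res["background_tc_fraction"] == 0.2
        assert res["p_value"] >= 0.5

    def test_no_usable_variants_errors(self):
        genome = Genome({"c1": "ATCA" * 10})
        with pytest.raises(ValueError, match="no usable"):
            tc_enrichment_test(vs(Variant("c1", 5, "T", "G")), genome)


class TestRegions:
    def _setup(self):
        genome = Genome({"c1": "A" * 1000})
        genes = [GeneRecord("g1", "c1", 300, 600, "+")]
        promoters = default_promoters(genes, genome)
        return genome, genes, promoters

    def test_default_promoter_is_100bp_upstream(self):
        genome, genes, promoters = self._setup()
        assert promoters == [("c1", 200, 300)]
        minus = [GeneRecord("g2", "c1", 300, 600, "-")]
        assert default_promoters(minus, genome) == [("c1", 600, 700)]

    def test_assignment_and_precedence(self):
        genome, genes, promoters = self._setup()
        breakdown = classify_regions(
            vs(
                Variant("c1", 400, "A", "G"),  # coding
                Variant("c1", 251, "A", "G"),  # 50 bp upstream -> promoter
                Variant("c1", 900, "A", "G"),  # intergenic
            ),
            genes,
            promoters,
        )
        assert breakdown.counts == {"coding": 1, "promoter": 1, "intergenic": 1}

    def test_coding_beats_promoter(self):
        genome = Genome({"c1": "A" * 1000})
        genes = [
            GeneRecord("g1", "c1", 300, 600, "+"),
            GeneRecord("g2", "c1", 600, 900, "+"),  # its promoter overlaps g1
        ]
        promoters = default_promoters(genes, genome)
        breakdown = classify_regions(vs(Variant("c1", 550, "A", "G")), genes, promoters)
        assert breakdown.counts["coding"] == 1

    def test_random_positions_match_interval_oracle(self):
        genome, genes, promoters = self._setup()
        rng = np.random.default_rng(37)
        variants = random_variants(rng, 400, span=999)
        breakdown = classify_regions(vs(*variants), genes, promoters)
        oracle = {"coding": 0, "promoter": 0, "intergenic": 0}
        for v in variants:
            p = v.pos - 1
            if 300 <= p < 600:
                oracle["coding"] += 1
            elif 200 <= p < 300:
                oracle["promoter"] += 1
            else:
                oracle["intergenic"] += 1
        assert breakdown.counts == oracle
        assert math.isclose(sum(breakdown.fractions.values()), 1.0, abs_tol=1e-9)


class TestEffects:
    def test_nonsense_silent_missense_examples(self):
        #         promoter   M  Q->*  A(GCC)  stop
        seq = "T" * 30 + "ATG" + "CAA" + "GCC" + "TAA" + "T" * 30
        genome = Genome({"c1": seq})
        genes = [GeneRecord("g1", "c1", 30, 42, "+")]
        res = classify_effects(
            vs(
                Variant("c1", 34, "C", "T"),  # CAA -> TAA nonsense
                Variant("c1", 39, "C", "T"),  # GCC -> GCT silent (Ala)
            ),
            genome,
            genes,
        )
        assert res.counts == {"nonsense": 1, "missense": 0, "silent": 1, "stop_loss": 0}
        assert res.n_cds_hit == 1
        effects = dict(zip(res.rows.pos, res.rows.effect))
        assert effects == {34: "nonsense", 39: "silent"}

    def test_ref_mismatch_errors(self):
        genome = Genome({"c1": "T" * 30 + "ATGCAAGCCTAA" + "T" * 30})
        genes = [GeneRecord("g1", "c1", 30, 42, "+")]
        with pytest.raises(ValueError, match="REF"):
            classify_effects(vs(Variant("c1", 34, "G", "T")), genome, genes)

    def test_thousand_coding_snvs_match_translate_oracle(self, small_genome):
        genome, genes, _ = small_genome
        rng = np.random.default_rng(41)
        seq = genome.contigs["chr1"]
        coding = [(g, p) for g in genes for p in range(g.start, g.end)]
        picks = rng.choice(len(coding), size=1000, replace=False)
        variants = set()
        for i in picks:
            g, p = coding[int(i)]
            ref = seq[p]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            variants.add(Variant("chr1", p + 1, ref, alt))
        res = classify_effects(vs(*variants), genome, genes)
        oracle = {"nonsense": 0, "missense": 0, "silent": 0, "stop_loss": 0}
        for v in sorted(variants):
            p = v.pos - 1
            for g in genes:
                if not (g.contig == v.contig and g.start <= p < g.end):
                    continue
                mutated = seq[:p] + v.alt + seq[p + 1 :]
                before, after = seq[g.start : g.end], mutated[g.start : g.end]
                if g.strand == "-":
                    before, after = reverse_complement(before), reverse_complement(after)
                prot_b = str(Seq(before).translate())
                prot_a = str(Seq(after).translate())
                diff = [i for i in range(len(prot_b)) if prot_b[i] != prot_a[i]]
                if not diff:
                    oracle["silent"] += 1
                elif prot_b[diff[0]] == "*":
                    oracle["stop_loss"] += 1
                elif prot_a[diff[0]] == "*":
                    oracle["nonsense"] += 1
                else:
                    oracle["missense"] += 1
        assert res.counts == oracle


class TestPipelineReport:
    def test_filter_conservation_and_truth_partition(self, single_edit_bundle):
        out, truth = single_edit_bundle
        from cbestop import read_annotation, read_fasta, read_sgrna_tsv

        genome = read_fasta(out / "genome.fasta")
        genes = read_annotation(out / "genes.gff3", "gff3")
        samples = [
            read_vcf(out / f"sample_{pl}.vcf", pl, pl, genome=genome)
            for pl in ("illumina", "pacbio")
        ]
        control = read_vcf(out / "control.vcf", "control", genome=genome)
        intervals = [
            (sg["contig"], sg["start"], sg["end"])
            for sg in read_sgrna_tsv(out / "sgrnas.tsv")
        ]
        result = run_profile(genome, genes, samples, control, sgrna_intervals=intervals)
        for stage in result.stages:
            assert stage["n_in"] == stage["n_out"] + stage["n_removed"]
        truth_off = {
            Variant(r["contig"], r["pos"], r["ref"], r["alt"])
            for r in truth["variants"]
            if r["category"] == "offtarget"
        }
        assert result.final.variants == truth_off

    def test_report_rerun_byte_identical(self, single_edit_bundle, tmp_path):
        out, _ = single_edit_bundle
        from cbestop import read_annotation, read_fasta

        genome = read_fasta(out / "genome.fasta")
        genes = read_annotation(out / "genes.gff3", "gff3")
        samples = [read_vcf(out / "sample_illumina.vcf", "s", "illumina", genome=genome)]
        control = read_vcf(out / "control.vcf", "control", genome=genome)
        blobs = []
        for run in ("r1", "r2"):
            result = run_profile(genome, genes, samples, control)
            write_profile(result, tmp_path / run)
            blobs.append(
                {
                    f.name: (tmp_path / run / f.name).read_bytes()
                    for f in (tmp_path / run).iterdir()
                }
            )
        assert blobs[0] == blobs[1]

    def test_empty_final_set_flagged(self, small_genome):
        genome, genes, _ = small_genome
        same = vs(Variant("chr1", 50, genome.contigs["chr1"][49], "T")
                  if genome.contigs["chr1"][49] != "T"
                  else Variant("chr1", 50, "T", "G"))
        result = run_profile(genome, genes, [same], same)
        report = result.report["final"]
        assert report["n"] == 0
        assert all(v is None for v in report["spectrum_fractions"].values())
        assert report["tc_test"]["p_value"] is None
        assert json.dumps(result.report)  # serializable with undefined values
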