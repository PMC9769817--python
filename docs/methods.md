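# Methods

## Coordinates, strands, frames

All in-memory coordinates are 0-based half-open on the plus strand; GFF3,
GenBank and VCF coordinates (1-based) are converted exactly once, at the I/O
boundary. Genes are simple (non-compound) CDS intervals with a strand;
compound/joined locations, strandless records and CDSs whose length is not a
multiple of 3 are skipped with a logged warning rather than silently
dropped (joined CDSs are rare in bacteria and outside this package's scope).
Translation uses the standard genetic code; GTG/TTG, the common
actinobacterial alternative starts, are accepted as ORF starts during
validation but still translated by the standard table, since only stop-codon
identity matters for premature-termination design. Codons or protospacers
containing N are excluded and tallied.

## Stop-site enumeration (designer)

Protospacer scanning is a direct sweep of both strands: a site is the 20 nt
immediately 5′ of a PAM, with the PAM occupying protospacer positions 21–23.
`NGG` requires G at 21+1 and 21+2; `NG` only at 21+1, so every NGG site is
also an NG site by construction (PAM monotonicity is asserted in tests).
Sites whose 23-nt footprint would cross a contig end are omitted.

For each protospacer position inside the editing window that carries a C on
the protospacer strand, the designer applies the C→T edit in silico
(plus-strand C→T, or G→A when the protospacer lies on the minus strand),
locates the overlapped codon of every overlapping gene strand-aware, and
emits a stop site iff the codon changes from sense to TAA/TAG/TGA. The
native (terminal) stop codon is excluded, so every reported site truncates
the protein strictly early. No codon table of "editable codons" is assumed;
that the pre-edit codons are exactly {CAA, CAG, CGA, TGG} is a consequence,
checked in the tests by exhaustive enumeration over all sense codons and by
a brute-force genome scan that compares full translations via Biopython.

Conventions that were genuinely open and the choices made:

- **Window numbering.** Protospacer positions 1..20 from the PAM-distal 5′
  end, PAM at 21–23. Genome-wide targetability uses window C4–C8; editor
  activity windows are BE3 C4–C7 (its observed full window C3–C12 is also
  built in), YE1-BE3 C4–C7, BE3-R132E C3–C8.
- **Motif.** The single base 5′ of the edited C *on the protospacer strand*
  (classes TC/CC/AC/GC); at protospacer position 1 the flanking genomic base
  is used (N if the flank is off-contig).
- **Duplicates.** When several protospacers expose the same C for the same
  gene, one row is kept — the candidate with the smallest
  (window position, protospacer start) — so reports are unique on
  (gene, position, strand). Multi-C edits (CC→TT) are represented as one row
  per C plus a bystander count over the window.
- **Overlapping genes** each receive their own site for a shared edit.
- A gene is *targetable* iff it has ≥1 stop site; the summary reports the
  fraction over all CDS features in the annotation (no pseudogene
  filtering — the annotation defines the gene universe).

## Off-target profiling

Variant identity is the key (contig, pos, ref, alt); genotype and quality
fields are ignored. Only biallelic SNVs are ingested (multi-allelic records
are split; indels/MNVs tallied and dropped), and REF alleles are checked
against the genome when it is supplied. The filter chain is

1. subtract the negative-control call set from each platform (removes
   strain-vs-reference background),
2. intersect platforms (removes platform-private false positives; keyed on
   position *and* allele, the stricter choice),
3. mask the intended edits: variants inside any 20-nt sgRNA protospacer
   interval (no PAM, no flank by default; a flank is configurable).

Each stage records n_in = n_out + n_removed, asserted at run time, and the
masked/removed sets are reported separately. Subtraction and masking are
both key-based removals, hence commute (tested).

Analytics on the final set:

- **Spectrum.** Six strand-collapsed classes (purine-reference changes
  complemented onto C/T). Fractions are reported as undefined (null), not
  0, when the set is empty.
- **Context.** C-class variants (collapsed ref C) contribute a ±2 bp window
  oriented so the centre is the deaminated C (G-reference variants are
  reverse-complemented); variants within 2 bp of a contig end are skipped
  and tallied. Columns of the 4×5 position-frequency matrix sum to 1; the
  TC fraction is P(base at −1 = T).
- **TC enrichment.** One-sided exact binomial test of the observed TC count
  against the genome-wide background: the fraction of cytosines on either
  strand preceded by T (plus-strand TC plus GA dinucleotides over all Cs
  with a 5′ neighbour and Gs with a 3′ neighbour). The underlying WGS
  studies drew sequence logos without a formal test; the test is reporting
  plumbing over the same counts, and is labelled as such.
- **Regions.** Mutually exclusive coding > promoter > intergenic (a base
  can sit inside one gene and upstream of another). The default promoter
  model is the 100 bp immediately upstream of each CDS start on the gene's
  strand, clipped at contig ends — a deliberate simplification of curated
  promoter catalogues, overridable with a BED file.
- **Effects.** Codons are recomputed before/after each coding SNV,
  strand-aware: silent (same residue), nonsense (stop gained), missense,
  and stop-loss as its own tally; `n_cds_hit` counts distinct genes. The
  per-(variant, gene) table is written alongside the summary.

## Synthetic data generator

The generator emulates the data this pipeline was designed for, not
sequencing physics (no reads, no error model, no editing-efficiency model).

**Genome.** One or more contigs (default one 100 kb contig at GC 0.54, the
*Corynebacterium* range) carrying non-overlapping ORFs (default 60 genes of
100–400 codons, ≥50 bp intergenic spacing): ATG start, random sense codons
with the target base composition, a single terminal stop, never an internal
stop. Gene placement distributes the slack uniformly, strands are random,
and unsatisfiable parameter combinations fail before anything is written.
Realized GC lands within ±2 pp of the target at 100 kb (tested).

**Variant sets.** Each simulated off-target draws its class first: C→T with
probability `p_ct` (default 0.9), otherwise one of the five other classes
uniformly. Positions come from disjoint pools partitioned by (plus-strand
base, TC context, promoter status): every C-class site has a T at −1 with
probability `tc_prob` (default 0.7) — applied to *all* C-class classes so
the profiler's TC fraction is an unbiased estimate of `tc_prob` — and every
site is drawn from promoter positions (promoter minus any coding overlap,
matching the profiler's precedence) with sampling weight `promoter_bias`
(default 3). The truth ledger records, besides every variant's category,
the *exact* expected promoter fraction implied by the realized pools, which
is what parameter-recovery tests compare against. Background variants
(default 40) are written identically to sample and control; false positives
(default 15) are private per platform; on-target edits are C→T on the
protospacer strand at designer-chosen sites, and no other simulated variant
may fall inside a protospacer interval (it would be removed by masking and
be indistinguishable from an edit). All positions are distinct; positions
within 2 bp of contig ends are excluded so every site carries a full
context. A single seed drives everything; equal parameters give
byte-identical output files.

**Scenarios.** `single-edit` (1 guide, 48 off-target SNVs, 98% C→T) and
`serial-mge` (5 guides over 5 rounds, 37 SNVs/round = 185 total, 82% C→T)
mirror the scale of a single-edit strain and of a strain built by serial
multiplexed editing, where the off-target load accumulates roughly linearly
with plasmid residence time. The remaining defaults (`tc_prob` 0.7 — strong
TC preference over the ≈0.23 genomic background; `promoter_bias` 3; 40
background variants; 15 platform-private FPs, the order of the observed
platform discrepancies) are fixed realistic choices, not fitted values.

## Verification strategy and problem sizes

- Designer: exact set equality against an independent brute-force oracle
  (mutate the genome string, retranslate every gene with Biopython) on 50
  seeded 3 kb genomes, plus soundness (every site truncates early when
  applied) and strand-symmetry on a 20 kb genome.
- Profiler: set operations against Python set/interval oracles; effects
  against a 1,000-SNV translate-and-compare oracle; the TC test against its
  closed form on engineered sequences.
- End-to-end: 100 seeds of simulate → VCF files → profile at n = 1,000
  off-targets on 100 kb genomes; the final set must equal the truth
  off-target set on every seed, and the estimated C→T fraction, TC fraction
  and promoter fraction must fall inside the 99% binomial CI of their
  generating values on ≥95% of seeds.
- Determinism: byte-identical bundles, reports and design tables on rerun;
  floats are written at 6 significant digits, percentages at 2 decimals.

These sizes keep the whole suite under half a minute on one CPU while
giving the statistical checks hundreds of degrees of freedom.

## Known limitations

- Passing tests show the *logic* is right under the generator's idealized
  conditions — independent SNVs, exact truth bookkeeping, no alignment or
  calling artefacts, uniform background composition. Real WGS call sets
  carry caller-specific biases, clustered errors and coverage gaps that the
  generator deliberately does not model; upstream alignment/variant calling
  is out of scope and the profiler trusts its input VCFs.
- Platform intersection cannot distinguish a true variant missed by one
  platform from a false positive; like the studies it mirrors, the profiler
  reports the pre-confirmation intersection (no amplicon re-sequencing
  step).
- The default promoter rule (100 bp upstream) is a proxy; region fractions
  shift with a curated promoter BED.
- No quantitative editing-efficiency prediction and no guide mismatch
  (sgRNA-dependent off-target) search — the designer ranks nothing beyond
  window membership and motif class.
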