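# Methods

This note documents the models and procedures `graftmobile`
implements, the parameters that matter, what the synthetic data
generator does and does not emulate, and the numerical and design
choices made where the problem was genuinely open.

## The detection model

Two graft partners (a scion genotype and a rootstock genotype) have
genomes that are locally identical except at single-nucleotide
polymorphisms (SNPs). A small RNA read sequenced from compartment R is
classified by two successive exact alignments:

1. map to R's own genome with zero mismatches — any hit (either
   strand, anywhere) makes the read **native**, and step-1 precedence
   is strict;
2. map the step-1 failures to the partner genome, again with zero
   mismatches — any hit makes the read **mobile**; the rest are
   unassigned (sequencing errors, unassembled regions, residual
   contaminants).

Consequences of this design, which the package preserves deliberately:

- **Perfect precision under error-free data.** A native read always
  passes step 1, so it can never be called mobile (provided no native
  locus is absent from the native assembly — the generator guarantees
  this by construction, since its genomes are positionally aligned).
- **Sensitivity = SNP-spanning fraction.** A mobile read that spans no
  SNP matches both genomes and is counted native. Detection is
  restricted to reads overlapping ≥ 1 divergent site; with
  per-position divergence *p* and read length *L*, the detectable
  fraction is ≈ 1 − (1 − p)^L (≈ 10% at p = 0.005, L = 21), so real
  exchange is systematically underestimated. When ground truth is
  available the package reports this as
  `snp_spanning_detectable_fraction`.
- **Errors create false positives in principle.** An errored native
  read can fail step 1 and coincidentally match the partner genome.
  No heuristic correction is applied; the generator quantifies the
  rate empirically (it is negligible at small-RNA lengths because a
  coincidental exact 20–24-mer match is ~4^−20).

Mapping is exact-match for *all* genome mapping, not only the mobility
steps: the classification logic is only self-consistent if "maps"
means the same thing in both steps. Mapped-fraction statistics from
aligners with laxer defaults are therefore not comparable and are not
treated as targets.

## Cluster calling

Clusters follow the island/pad description of ShortStack-style
callers:

- an **island** is a maximal run of positions with raw read depth
  ≥ `mincov` (default 5 reads — low enough for sensitivity, high
  enough to suppress background);
- islands separated by ≤ `pad` nucleotides (default 100; boundary
  inclusive — a gap of exactly 100 merges) merge transitively;
- every read overlapping a merged interval is assigned to exactly one
  cluster (first overlapping interval in coordinate order) and the
  cluster interval is extended to the full extent of its reads. The
  read-extent extension is the package's choice: island coordinates
  alone understate cluster length, and reported mean cluster lengths
  (~190–210 bp) are consistent with read-extent inclusion.
- a cluster is **dicer-derived** when ≥ 80% (boundary inclusive) of
  its reads are 20–24 nt; its **size class** is the modal read length
  within 20–24 nt, ties resolved toward the larger length (24-nt
  dominance is the norm in plant siRNA populations; the tie-break is
  otherwise arbitrary and is documented rather than hidden).
- **rpm** normalizes by total mapped reads in the same sample. The
  published per-cluster rpm row could not be reconciled with its
  printed totals under any denominator we tried, so rpm is reported
  but never asserted against published values.

Island-count monotonicity in `mincov` does **not** hold in general (a
depth profile 9, 8, 9 has one island at mincov 8 and two at 9); the
property that does hold, and is tested, is that the island-covered
position set shrinks as mincov rises, each stricter island nested in a
laxer one. Cluster-count monotonicity in `pad` holds and is tested as
stated.

Known-miRNA identification is deliberately simplified: the cluster's
most abundant read sequence is matched as an ungapped substring
(either orientation, ≤ 2 mismatches, fewest-mismatch hit, database
order breaking ties) against a provided hairpin FASTA. Structural
hairpin validation (duplex/star-strand criteria, secondary-structure
folding) is out of scope, so fraction-of-known-miRNA statistics from
structural annotators are not comparison targets.

## Multimapping

Default policy is `random_one`: one occurrence drawn uniformly with a
generator seeded per read id (reproducible and order-independent),
with the genome-wide occurrence count retained on the placement.
Guided multimapper placement (coverage-weighted assignment) is not
re-implemented; cluster definitions here depend only on coverage, and
seeded random placement keeps runs bit-reproducible. `unique_only`
and `all` are available for sensitivity analyses.

## Preprocessing

Fixed stage order: adapter trim → length filter → complexity filter →
decontamination; read counts are non-increasing across stages.

- **Adapter trimming** removes from the earliest position where either
  the full adapter occurs or a 3′-anchored read suffix of ≥
  `min_overlap` (default 3, a common trimmer default) bases equals an
  adapter prefix.
- **Length filter** keeps reads ≥ 17 nt. Published descriptions of
  this step disagree between "longer than 17" and "minimal read size
  of 17"; the ≥ 17 reading is adopted and the boundary is pinned by a
  test.
- **Low-complexity filter** uses mononucleotide Shannon entropy with a
  0.5-bit threshold (boundary kept). The tool named for this step in
  the emulated workflow does not document its method or threshold;
  entropy is the simplest defensible choice and the threshold only
  needs to remove near-homopolymers.
- **Decontamination** removes reads occurring exactly (either strand)
  in any contaminant reference, mirroring 0-mismatch filtering against
  rRNA/tRNA and chloroplast databases.

## Annotation, comparison, enrichment

Overlap semantics are ≥ 1 bp everywhere (bedtools-intersect default).
Promoters are the 2 kb immediately upstream of the annotated 5′ gene
end, strand-aware, clipped at chromosome bounds, omitted when empty.
Co-localization marks a cluster "common" if it overlaps ≥ 1 cluster of
the other set; each side's common count may differ. The coefficient of
variation of per-replicate counts uses the sample (n − 1) standard
deviation — the population/sample choice is not specified in the
emulated workflow and is fixed here by test. Depth categories default
to boundaries (5, 10, 50, 100, 500, 1000), i.e. seven bins with "≤ 5"
first; the exact published boundaries live in supplementary material,
so they are configurable. Term enrichment is a one-sided Fisher exact
test per term at α = 0.05 with **no** multiple-testing correction,
matching the stated procedure; the p-value is cross-checked in tests
against the closed-form hypergeometric tail.

## Target scanning

Candidate targets of mobile clusters on the receptor genome are found
by ungapped seed-and-extend local alignment: exact 12-mer seeds, then
the maximum-scoring segment on the seed diagonal under match +1 /
mismatch −2 (Kadane, first-maximum tie-break). There are no gaps:
reported mismatch counts in the emulated analysis (0–8, no gap
mention) make ungapped alignment faithful, and it keeps mismatch
counts exactly interpretable as SNP counts in simulations. The
E-value of a full BLAST implementation is replaced by a raw score
threshold (default 14 ≈ a 14-nt perfect seed); Karlin–Altschul
calibration is deliberately not re-derived. Hits overlapping repeat
annotation are excluded. Scoring:

    pident       = (aligned_length − mismatches) / aligned_length × 100
    pident_final = pident × aligned_length / cluster_length

`pident_final` down-weights partial coverage of the query cluster and
reproduces the documented extreme of 97.37% for a perfect 37-nt
alignment of a 38-nt cluster. The exact published algebra lives in
supplementary material; this reconstruction is validated against the
printed range endpoints only.

## The synthetic data generator

`simdata` emulates the study conditions end to end:

- **Genomes**: i.i.d. uniform-base chromosomes; SNPs placed i.i.d. per
  position (no clustering — the simplest model that exposes the
  SNP-spanning detection limit) at a default rate of 0.005; the
  alternate allele is uniform over the three non-reference bases.
- **Annotations**: non-overlapping stranded genes (300–1,500 bp),
  repeats (150–800 bp, may overlap genes), promoters derived.
- **Loci**: 21-nt siRNA loci inside gene bodies, 24-nt siRNA loci
  inside promoters/repeats (the RdDM association), miRNA hairpin loci
  anywhere; 60–160 bp long, ≥ 300 bp apart so each locus is
  recoverable as exactly one cluster (separation must exceed
  pad + max read length = 125 nt); expression weights uniform in
  [0.5, 2].
- **Reads**: class length ± 1 nt jitter with probability 0.1 (to
  exercise dicer-call mixtures), strand-faithful genome substrings,
  i.i.d. substitution errors only (an indel in an exact-match world is
  indistinguishable from an unmappable read), 3′-extended with the
  full adapter and A-fill to the 50-nt machine read length, constant
  quality, replicate labels round-robin over 3 replicates, mobile
  reads drawn from the partner genome at the configured fraction
  (default 0.05), contaminant reads drawn as exact substrings of the
  contaminant references at a default 40% admixture. Output is
  bit-identical for a fixed seed.

What it does **not** emulate — hence what passing tests do not show
about real data: realistic base-quality profiles, PCR duplication,
ligation bias, isomiR biogenesis, genome misassembly or presence/
absence variation between genotypes (the two genomes are positionally
aligned, so the zero-false-positive guarantee is a property of the
simulation, not of real assemblies), transcription-level locus
structure, and degradation products. The generator's purpose is to
make every pipeline contract testable against known provenance, not
to be a read-level error model.

## Problem sizes and determinism

The bundled scenarios are `small` (two 2 × 20-kb genomes, 3 × 1,200
reads per compartment; end-to-end in seconds, ≤ 2 MB on disk) and
`medium` (two 2 × 100-kb genomes, 3 × 50,000 reads per compartment) —
the medium scale is what the truth-recovery tests and the acceptance
script use, chosen so that every planted locus exceeds the coverage
floor by a wide margin while a full run stays under a minute. All
randomness flows from explicit integer seeds (genome, annotation,
locus, per-compartment read seeds are derived by fixed offsets from
one scenario seed); reruns are byte-identical, including FASTQ output
and report files.

## Known limitations

- Exact-match mapping makes the pipeline blind to reads from regions
  absent or mis-assembled in either genome; with real assemblies the
  zero-false-positive property degrades accordingly.
- The mobility statistic conditions on SNP-spanning reads; comparing
  absolute mobile fractions between graft systems with different
  divergence is invalid without normalizing by the detectable
  fraction.
- Cluster boundaries (read-extent extension) and the size-class
  tie-break are reconstructions of under-specified behaviour; both are
  pinned by tests so downstream numbers are stable, but other callers
  may differ at the margins.
- The enrichment test deliberately omits multiple-testing correction
  and graph-aware decorrelation; its output is a faithful
  re-implementation of the stated procedure, not a recommendation.
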