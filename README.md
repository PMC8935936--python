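# graftmobile

Detection of graft-mobile small RNAs from small-RNA sequencing data.

When two plant genotypes are joined by grafting (a scion shoot on a
rootstock root), small RNAs — mostly short interfering RNAs (siRNAs) —
can cross the graft junction through the vasculature. `graftmobile`
implements the sequence-based strategy for detecting such exchanges in
a heterograft whose partner genomes differ at single-nucleotide
polymorphisms (SNPs): a small RNA read sequenced from one compartment
that matches *only* the genome of the other genotype must have been
transported across the junction.

The package provides, as composable library modules with a thin
`graftmobile` command-line interface on top:

- **`simdata`** — a synthetic heterograft generator: two SNP-diverged
  genomes with a truth table of divergent sites, planted gene/repeat
  annotations, small-RNA loci of defined size classes (21-nt gene-body
  siRNA loci, 24-nt promoter/repeat siRNA loci, miRNA hairpins), and
  per-compartment machine reads with replicate structure, adapter,
  configurable mobile fraction, error rate and rRNA/tRNA-like
  contaminant admixture — every read carrying full provenance.
- **`preprocess`** — 3′ adapter trimming, ≥17-nt length filter,
  Shannon-entropy low-complexity filter, and exact-match (0-mismatch)
  decontamination against contaminant references.
- **`exactmap`** — exact-occurrence read placement on both strands via
  a seed-hash index with full verification, with `all` /
  `unique_only` / seeded-`random_one` multimapper policies.
- **`clustering`** — ShortStack-style cluster calling: coverage
  islands at per-base depth ≥ mincov (default 5 raw reads), merged
  when ≤ pad (default 100 nt) apart; dicer-call scoring (a cluster is
  dicer-derived when ≥ 80% of its reads are 20–24 nt) and size-class
  assignment by predominant read length; known-miRNA matching against
  a hairpin database.
- **`mobility`** — the two-step classification itself: a read is
  *native* if it occurs exactly in its own compartment's genome,
  otherwise *mobile* if it occurs exactly in the partner genome,
  otherwise unassigned; mobile reads are then clustered on the donor
  genome.
- **`annotate_compare`** — gene-body / 2-kb-promoter / repeat
  annotation of clusters (≥ 1 bp overlap), common/specific
  co-localization of cluster sets, replicate presence and coefficient
  of variation, read-depth categories, and one-sided Fisher-exact term
  enrichment.
- **`targetscan`** — ungapped seed-and-extend local alignment
  (match +1 / mismatch −2) of mobile-cluster sequences on the receptor
  genome, excluding repeat hits, scored by
  `pident_final = pident × aligned_length / cluster_length`.
- **`pipeline`** — a single-config orchestration of all stages with
  deterministic, seed-stamped report tables.

## The core statistic

For a compartment with `N` cleaned reads, step 1 maps each read to the
compartment's own genome with zero mismatches: `N_native` reads match
and are discarded from the mobility search. Step 2 maps the
`N − N_native` remaining reads to the partner genome, again with zero
mismatches: the `N_mobile` exact matches are called mobile. Only reads
spanning at least one SNP between the genomes can fail step 1 yet pass
step 2, so the procedure has (in error-free data) perfect precision
and a sensitivity equal to the SNP-spanning fraction of truly mobile
reads — exchanges are systematically underestimated, which the package
surfaces as a `snp_spanning_detectable_fraction` diagnostic whenever
ground truth is available.

## Worked example

```sh
graftmobile simulate --outdir demo --scale small --seed 2
graftmobile run-all --config demo/config.toml
```

or equivalently in Python:

```python
from graftmobile.pipeline import make_fixture, RunConfig, run_pipeline

paths = make_fixture("demo", scale="small", seed=2)
report = run_pipeline(RunConfig.from_toml(paths["config"]))
print(report["mobility"]["scion_to_rootstock"])
```

which prints (small scale: two 2 × 20-kb genomes, 0.5% SNP rate,
3 replicates × 1,200 reads per compartment, 5% mobile reads, 40%
contaminant admixture):

```
{'counts': {'n_total': 2131, 'n_native': 2120, 'n_unmapped_step1': 11,
            'n_mobile': 11, 'n_unassigned': 0},
 'pct': {'native': 99.5, 'unmapped': 0.5, 'mobile_of_unmapped': 100.0},
 'n_mobile_clusters': 0, ...}
```

Reading: of 2,131 cleaned rootstock-side reads, 2,120 (99.5%) match
the rootstock genome exactly and are native; all 11 step-1 failures
match the scion genome exactly and are called mobile (these are the
SNP-spanning mobile reads — at this scale the remaining ~90% of mobile
reads span no SNP, map to both genomes and are conservatively counted
native). Eleven reads scattered over many loci stay below the 5-read
coverage floor, so no mobile *cluster* is called at small scale; the
medium scale (3 × 50k reads per compartment) yields ~20 mobile
clusters with 21-nt and 24-nt size classes.

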