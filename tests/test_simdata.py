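import pytest
from scipy.stats import binom

import graftmobile as gm
from graftmobile import simdata
from graftmobile.sequtils import revcomp


class TestGenomePair:
    def test_zero_rate_identical_genomes(self):
        pair = gm.simulate_genome_pair(2, 500, 0.0, seed=1)
        assert pair.snp_table == []
        assert pair.donor_genome == pair.receptor_genome

    def test_rate_one_saturates(self):
        pair = gm.simulate_genome_pair(1, 50, 1.0, seed=1)
        assert len(pair.snp_table) == 50
        d, r = pair.donor_genome["chr1"], pair.receptor_genome["chr1"]
        assert sum(a != b for a, b in zip(d, r)) == 50

    def test_seeded_rerun_identical_and_rate_within_binomial_bounds(self):
        pair = gm.simulate_genome_pair(1, 10_000, 0.005, seed=7)
        again = gm.simulate_genome_pair(1, 10_000, 0.005, seed=7)
        assert pair.snp_table == again.snp_table
        assert pair.donor_genome == again.donor_genome
        lo, hi = binom.ppf([0.005, 0.995], 10_000, 0.005)
        assert lo <= len(pair.snp_table) <= hi

    def test_sequences_differ_exactly_at_snp_positions(self):
        pair = gm.simulate_genome_pair(1, 2_000, 0.01, seed=3)
        d, r = pair.donor_genome["chr1"], pair.receptor_genome["chr1"]
        diff = {i for i, (a, b) in enumerate(zip(d, r)) if a != b}
        table = {p for _, p, _, _ in pair.snp_table}
        assert diff == table
        for chrom, p, da, ra in pair.snp_table:
            assert d[p] == da and r[p] == ra and da != ra

    @pytest.mark.parametrize(
        "kwargs", [dict(length=0), dict(snp_rate=-0.1), dict(snp_rate=1.5)]
    )
    def test_argument_errors(self, kwargs):
        args = dict(n_chromosomes=1, length=100, snp_rate=0.1, seed=0)
        args.update(kwargs)
        with pytest.raises(ValueError):
            gm.simulate_genome_pair(**args)


class TestAnnotations:
    def test_empty_annotation(self, small_scenario):
        ann = simdata.plant_annotations(small_scenario["pair"], 0, 0, seed=1)
        assert not ann.genes and not ann.repeats and not ann.promoters

    def test_seeded_determinism(self, small_scenario):
        a = simdata.plant_annotations(small_scenario["pair"], 8, 5, seed=4)
        b = simdata.plant_annotations(small_scenario["pair"], 8, 5, seed=4)
        assert a.genes == b.genes and a.repeats == b.repeats

    def test_promoters_abut_gene_5prime_end(self):
        """Strand-aware arithmetic oracle: + promoters end at gene start,
        - promoters begin at gene end."""
        pair = gm.simulate_genome_pair(1, 10_000, 0.0, seed=2)
        ann = simdata.plant_annotations(pair, 5, 0, seed=2)
        assert len(ann.promoters) >= 1
        by_id = {p.feature_id: p for p in ann.promoters}
        for g in ann.genes:
            p = by_id.get(f"{g.feature_id}_promoter")
            if p is None:  # gene at chromosome edge: promoter omitted
                assert (g.strand == "+" and g.start == 0) or \
                       (g.strand == "-" and g.end == 10_000)
                continue
            if g.strand == "+":
                assert p.end == g.start and p.start == max(0, g.start - 2000)
            else:
                assert p.start == g.end and p.end == min(10_000, g.end + 2000)

    def test_infeasible_packing_rejected(self):
        pair = gm.simulate_genome_pair(1, 1000, 0.0, seed=1)
        with pytest.raises(ValueError):
            simdata.plant_annotations(pair, n_genes=50, n_repeats=0, seed=1)

    def test_genes_do_not_overlap(self, small_scenario):
        genes = sorted(small_scenario["annotation"].genes, key=lambda g: (g.chrom, g.start))
        for a, b in zip(genes, genes[1:]):
            assert a.chrom != b.chrom or a.end <= b.start


class TestSimulateReads:
    def test_no_mobile_no_error_reads_are_native_substrings(self, small_scenario):
        pair = small_scenario["pair"]
        reads, truth = simdata.simulate_reads(
            pair, small_scenario["loci"], "donor", 300,
            mobile_fraction=0.0, error_rate=0.0, adapter="", seed=5,
        )
        assert not truth.mobile_ids()
        for r in reads:
            insert = r.sequence.rstrip("A")
            t = truth[r.id]
            chrom_seq = pair.donor_genome[t.source_locus.chrom]
            assert insert in chrom_seq or revcomp(insert) in chrom_seq

    def test_mobile_fraction_within_binomial_bounds(self, small_scenario):
        n = 4000
        reads, truth = simdata.simulate_reads(
            small_scenario["pair"], small_scenario["loci"], "receptor", n,
            mobile_fraction=0.1, error_rate=0.0, seed=6,
        )
        k = len(truth.mobile_ids())
        lo, hi = binom.ppf([0.005, 0.995], n, 0.1)
        assert lo <= k <= hi

    def test_mobile_reads_source_other_compartment(self, small_scenario):
        reads, truth = simdata.simulate_reads(
            small_scenario["pair"], small_scenario["loci"], "receptor", 500,
            mobile_fraction=0.5, error_rate=0.0, seed=8,
        )
        for rid in truth.mobile_ids():
            assert truth[rid].source_genome == "donor"

    def test_spans_snp_flag_matches_snp_table(self, small_scenario):
        pair = small_scenario["pair"]
        snp_pos = pair.snp_positions()
        reads, truth = simdata.simulate_reads(
            pair, small_scenario["loci"], "receptor", 500,
            mobile_fraction=0.2, error_rate=0.0, adapter="", seed=9,
        )
        for r in reads:
            t = truth[r.id]
            L = len(r.sequence.rstrip("A"))
            chrom_seq = pair.genome(t.source_genome)[t.source_locus.chrom]
            insert = r.sequence.rstrip("A")
            fwd = chrom_seq.find(insert)
            s = fwd if fwd != -1 else chrom_seq.find(revcomp(insert))
            assert s != -1
            overlap = any(s <= p < s + L for p in snp_pos[t.source_locus.chrom])
            # position may be ambiguous for multi-occurrence inserts; only
            # assert when the located occurrence is unique
            if chrom_seq.count(insert) + chrom_seq.count(revcomp(insert)) == 1:
                assert overlap == t.spans_snp

    def test_machine_reads_fixed_length_with_adapter(self, small_scenario):
        reads, _ = simdata.simulate_reads(
            small_scenario["pair"], small_scenario["loci"], "donor", 50,
            mobile_fraction=0.0, error_rate=0.0, seed=10,
        )
        for r in reads:
            assert len(r.sequence) == 50
            assert simdata.DEFAULT_ADAPTER[:10] in r.sequence

    def test_fixed_seed_bit_identical(self, small_scenario):
        args = (small_scenario["pair"], small_scenario["loci"], "donor", 200)
        kw = dict(mobile_fraction=0.1, error_rate=0.01, seed=11)
        a, _ = simdata.simulate_reads(*args, **kw)
        b, _ = simdata.simulate_reads(*args, **kw)
        assert [(r.id, r.sequence, r.replicate_label) for r in a] == \
               [(r.id, r.sequence, r.replicate_label) for r in b]

    def test_replicates_round_robin(self, small_scenario):
        reads, _ = simdata.simulate_reads(
            small_scenario["pair"], small_scenario["loci"], "donor", 9,
            mobile_fraction=0.0, error_rate=0.0, n_replicates=3, seed=12,
        )
        assert [r.replicate_label for r in reads[:6]] == \
               ["rep1", "rep2", "rep3", "rep1", "rep2", "rep3"]

    def test_error_rate_records_n_errors(self, small_scenario):
        reads, truth = simdata.simulate_reads(
            small_scenario["pair"], small_scenario["loci"], "donor", 500,
            mobile_fraction=0.0, error_rate=0.05, adapter="", seed=13,
        )
        errored = [t for t in truth.records.values() if t.n_errors > 0]
        assert errored  # 0.05/base over ~21 nt: virtually certain in 500 reads
        # reads with errors at recorded counts differ from the genome
        pair = small_scenario["pair"]
        for r in reads:
            t = truth[r.id]
            if t.n_errors == 0:
                continue
            insert = r.sequence.rstrip("A")
            chrom_seq = pair.donor_genome[t.source_locus.chrom]
            assert insert not in chrom_seq or t.n_errors == 0

    def test_empty_loci_rejected(self, small_scenario):
        with pytest.raises(ValueError):
            simdata.simulate_reads(
                small_scenario["pair"], [], "donor", 10,
                mobile_fraction=0.0, error_rate=0.0, seed=1,
            )

    def test_contaminants_require_refs(self, small_scenario):
        with pytest.raises(ValueError):
            simdata.simulate_reads(
                small_scenario["pair"], small_scenario["loci"], "donor", 10,
                mobile_fraction=0.0, error_rate=0.0,
                contaminant_fraction=0.3, seed=1,
            )


def test_planted_locus_classes_respect_feature_association(small_scenario):
    """21-nt loci sit in gene bodies; 24-nt loci in promoters or repeats."""
    ann = small_scenario["annotation"]
    for locus in small_scenario["loci"]:
        if locus.locus_class == "siRNA21":
            hosts = ann.genes
        elif locus.locus_class == "siRNA24":
            hosts = ann.promoters + ann.repeats
        else:
            continue
        assert any(
            h.chrom == locus.chrom and h.start <= locus.start and locus.end <= h.end
            for h in hosts
        )


def test_hairpin_database_contains_mature_sequences(small_scenario):
    pair = small_scenario["pair"]
    hairpins = small_scenario["hairpins"]
    mir_loci = [l for l in small_scenario["loci"] if l.locus_class == "miRNA_hairpin"]
    assert len(hairpins) == len(mir_loci)
    for locus in mir_loci:
        mature = pair.donor_genome[locus.chrom][locus.start : locus.end]
        if locus.strand == "-":
            mature = revcomp(mature)
        assert any(mature in hp for hp in hairpins.values())
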