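import pytest

import graftmobile as gm
from graftmobile import simdata


@pytest.fixture(scope="session")
def small_scenario():
    """A small synthetic heterograft: two 2x20-kb genomes at 0.5% SNP
    divergence, annotations, planted loci of all three classes and
    contaminant references."""
    pair = gm.simulate_genome_pair(2, 20_000, 0.005, seed=7)
    annotation = simdata.plant_annotations(pair, n_genes=12, n_repeats=10, seed=8)
    loci = simdata.plant_loci(pair, annotation, 6, 6, 3, seed=9)
    contaminants = simdata.simulate_contaminant_refs(seed=3)
    return {
        "pair": pair,
        "annotation": annotation,
        "loci": loci,
        "contaminants": contaminants,
        "hairpins": simdata.hairpin_database(pair, loci),
    }


def make_read(rid, seq, rep=None):
    return gm.ReadRecord(id=rid, sequence=seq, replicate_label=rep)


def make_placement(rid, chrom, start, length, strand="+", n_occ=1):
    return gm.Placement(
        read_id=rid, chrom=chrom, start=start, end=start + length,
        strand=strand, n_occurrences=n_occ,
    )


@pytest.fixture
def placement_factory():
    return make_placement


@pytest.fixture
def read_factory():
    return make_read
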