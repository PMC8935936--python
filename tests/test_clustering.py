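import random
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from graftmobile.clustering import (
    Cluster, ClusterParams, build_clusters, call_dicer, find_islands,
    match_known_mirna, merge_islands,
)
from tests.conftest import make_placement


def oracle_islands(spans, mincov):
    """Per-base counting oracle."""
    if not spans:
        return []
    depth = Counter()
    for s, e in spans:
        for x in range(s, e):
            depth[x] += 1
    positions = sorted(x for x, d in depth.items() if d >= mincov)
    islands = []
    for x in positions:
        if islands and x == islands[-1][1]:
            islands[-1][1] = x + 1
        else:
            islands.append([x, x + 1])
    return [tuple(i) for i in islands]


class TestIslands:
    def test_five_identical_reads_form_island(self):
        ps = [make_placement(f"r{i}", "c", 100, 24) for i in range(5)]
        assert find_islands(ps, "c", 5) == [(100, 124)]

    def test_four_reads_no_island(self):
        ps = [make_placement(f"r{i}", "c", 100, 24) for i in range(4)]
        assert find_islands(ps, "c", 5) == []

    def test_staggered_depth_profile(self):
        # depth profile rises 1..5 then falls; island spans only >=5 positions
        spans = [(10 + i, 10 + i + 5) for i in range(5)]
        ps = [make_placement(f"r{i}", "c", s, e - s) for i, (s, e) in enumerate(spans)]
        assert find_islands(ps, "c", 5) == oracle_islands(spans, 5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_base_oracle(self, seed):
        rng = random.Random(seed)
        spans = [
            (s, s + rng.randrange(17, 26))
            for s in (rng.randrange(0, 250) for _ in range(40))
        ]
        ps = [make_placement(f"r{i}", "c", s, e - s) for i, (s, e) in enumerate(spans)]
        mincov = rng.randrange(1, 7)
        assert find_islands(ps, "c", mincov) == oracle_islands(spans, mincov)


class TestMergeIslands:
    def test_gap_100_merges(self):
        assert merge_islands([(0, 50), (150, 200)], pad=100) == [(0, 200)]

    def test_gap_101_does_not_merge(self):
        assert merge_islands([(0, 50), (151, 200)], pad=100) == [(0, 50), (151, 200)]

    def test_transitive_chain(self):
        islands = [(0, 10), (60, 80), (180, 200)]
        assert merge_islands(islands, pad=100) == [(0, 200)]


class TestBuildClusters:
    def test_single_island_cluster(self):
        ps = [make_placement(f"r{i}", "c", 100, 24) for i in range(10)]
        clusters = build_clusters(ps, ClusterParams())
        assert len(clusters) == 1
        c = clusters[0]
        assert (c.start, c.end, c.reads_total) == (100, 124, 10)
        assert c.reads_by_length == {24: 10}
        call_dicer(c, ClusterParams())
        assert c.size_class == 24

    def test_zero_placements(self):
        assert build_clusters([], ClusterParams()) == []

    def test_interval_extended_to_read_extent(self):
        # 5 stacked reads + one read hanging off the island edge
        ps = [make_placement(f"r{i}", "c", 100, 24) for i in range(5)]
        ps.append(make_placement("edge", "c", 90, 24))
        c = build_clusters(ps, ClusterParams())[0]
        assert c.start == 90 and c.end == 124 and c.reads_total == 6

    def test_rpm_uses_total_mapped_denominator(self):
        ps = [make_placement(f"r{i}", "c", 0, 20) for i in range(5)]
        c = build_clusters(ps, ClusterParams(), total_mapped=1000)[0]
        assert c.rpm == pytest.approx(5 / 1000 * 1e6)

    def test_ground_truth_recovery(self, small_scenario):
        """Planted well-separated loci with depth >= mincov come back 1:1."""
        import graftmobile as gm
        from graftmobile import simdata

        pair = small_scenario["pair"]
        loci = small_scenario["loci"]
        reads, _ = simdata.simulate_reads(
            pair, loci, "receptor", 5000, mobile_fraction=0.0, error_rate=0.0,
            adapter="", seed=13,
        )
        trimmed = [
            gm.ReadRecord(r.id, r.sequence.rstrip("A")) for r in reads
        ]
        trimmed = [r for r in trimmed if len(r.sequence) >= 17]
        index = gm.build_index(pair.receptor_genome)
        placements, _, _ = gm.map_readset(index, trimmed, gm.MapParams(rng_seed=2))
        clusters = build_clusters(placements, ClusterParams())
        assert len(clusters) == len(loci)
        for c, locus in zip(clusters, sorted(loci, key=lambda l: (l.chrom, l.start))):
            assert c.chrom == locus.chrom
            assert locus.start <= c.start and c.end <= locus.end

    def test_partition_every_read_in_one_cluster(self):
        rng = random.Random(1)
        ps = [
            make_placement(f"r{i}", "c", rng.randrange(0, 500), rng.randrange(20, 25))
            for i in range(200)
        ]
        clusters = build_clusters(ps, ClusterParams(mincov=3, pad=10))
        assigned = [rid for c in clusters for rid in c.read_ids]
        assert len(assigned) == len(set(assigned))  # no double counting


class TestDicerCall:
    def _cluster(self, lengths):
        counts = Counter(lengths)
        return Cluster(
            id="x", chrom="c", start=0, end=100, reads_total=len(lengths),
            reads_by_length=dict(counts),
        )

    def test_exactly_80pct_is_positive(self):
        c = self._cluster([24] * 8 + [19] * 2)
        call_dicer(c, ClusterParams())
        assert c.dicer_call and c.size_class == 24

    def test_below_80pct_negative(self):
        c = self._cluster([24] * 7 + [19] * 3)
        call_dicer(c, ClusterParams())
        assert not c.dicer_call and c.size_class is None

    def test_tie_resolves_to_larger_length(self):
        c = self._cluster([21] * 5 + [24] * 5)
        call_dicer(c, ClusterParams())
        assert c.size_class == 24

    def test_modal_length_restricted_to_dicer_range(self):
        # 19-nt reads are most common overall but outside [20,24]
        c = self._cluster([19] * 2 + [21] * 5 + [24] * 4)
        call_dicer(c, ClusterParams())
        assert c.dicer_call and c.size_class == 21

    def test_empty_cluster_rejected(self):
        c = Cluster(id="x", chrom="c", start=0, end=1, reads_total=0)
        with pytest.raises(ValueError):
            call_dicer(c, ClusterParams())


def oracle_min_hamming(query, subject):
    best = None
    for i in range(len(subject) - len(query) + 1):
        mm = sum(a != b for a, b in zip(query, subject[i : i + len(query)]))
        best = mm if best is None else min(best, mm)
    return best


class TestMirnaMatch:
    HAIRPIN = {"mir1": "GGGACCATTGCAGGACCTGAATTACGATCGATTTACGGATCCAAGGTT"}

    def _cluster_with_reads(self, seq, n=5):
        reads = {f"r{i}": seq for i in range(n)}
        c = Cluster(
            id="x", chrom="c", start=0, end=50, reads_total=n, read_ids=list(reads),
        )
        return c, reads

    def test_exact_substring_matched(self):
        c, reads = self._cluster_with_reads(self.HAIRPIN["mir1"][3:24])
        assert match_known_mirna(c, reads, self.HAIRPIN) == "mir1"

    def test_unrelated_read_unmatched(self):
        c, reads = self._cluster_with_reads("CACACACACACACACACACAC")
        assert match_known_mirna(c, reads, self.HAIRPIN) is None

    @pytest.mark.parametrize("n_mm,expected", [(2, "mir1"), (3, None)])
    def test_mismatch_boundary(self, n_mm, expected):
        seq = list(self.HAIRPIN["mir1"][3:24])
        swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
        for i in range(n_mm):
            seq[3 * i] = swap[seq[3 * i]]
        query = "".join(seq)
        assert oracle_min_hamming(query, self.HAIRPIN["mir1"]) == n_mm
        c, reads = self._cluster_with_reads(query)
        assert match_known_mirna(c, reads, self.HAIRPIN, max_mismatches=2) == expected

    def test_empty_db_rejected(self):
        c, reads = self._cluster_with_reads("ACGT" * 5)
        with pytest.raises(ValueError):
            match_known_mirna(c, reads, {})


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(
        st.tuples(st.integers(0, 300), st.integers(17, 25)), min_size=1, max_size=40
    ),
    st.integers(1, 6),
)
def test_mincov_monotonicity(spans, mincov):
    """Raising mincov only ever shrinks the set of island-covered
    positions (each stricter island nests inside a laxer one)."""
    ps = [make_placement(f"r{i}", "c", s, l) for i, (s, l) in enumerate(spans)]
    low = find_islands(ps, "c", mincov)
    high = find_islands(ps, "c", mincov + 1)
    covered_low = {x for s, e in low for x in range(s, e)}
    covered_high = {x for s, e in high for x in range(s, e)}
    assert covered_high <= covered_low
    assert all(any(ls <= s and e <= le for ls, le in low) for s, e in high)


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(st.tuples(st.integers(0, 500), st.integers(17, 25)), min_size=1, max_size=40),
    st.integers(0, 60),
)
def test_pad_monotonicity(spans, pad):
    """Raising pad never increases the number of clusters."""
    ps = [make_placement(f"r{i}", "c", s, l) for i, (s, l) in enumerate(spans)]
    low = build_clusters(ps, ClusterParams(mincov=2, pad=pad))
    high = build_clusters(ps, ClusterParams(mincov=2, pad=pad + 25))
    assert len(high) <= len(low)


def test_determinism(small_scenario):
    import graftmobile as gm
    from graftmobile import simdata

    pair = small_scenario["pair"]
    reads, _ = simdata.simulate_reads(
        pair, small_scenario["loci"], "receptor", 1000,
        mobile_fraction=0.0, error_rate=0.0, adapter="", seed=17,
    )
    trimmed = [gm.ReadRecord(r.id, r.sequence.rstrip("A")) for r in reads]
    index = gm.build_index(pair.receptor_genome)
    placements, _, _ = gm.map_readset(index, trimmed, gm.MapParams(rng_seed=2))
    a = build_clusters(placements, ClusterParams())
    b = build_clusters(placements, ClusterParams())
    assert [(c.chrom, c.start, c.end, c.reads_total) for c in a] == \
           [(c.chrom, c.start, c.end, c.reads_total) for c in b]
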