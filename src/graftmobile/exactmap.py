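"""Exact-occurrence placement of short reads on a genome, both strands.

Every classification step in the pipeline relies on this mapping
contract: a read "maps" iff its sequence (or reverse complement) occurs
verbatim in the genome — zero mismatches, no indels. The index hashes
fixed-length seeds (default 17 nt, the minimum retained read length) and
verifies candidate hits by full string comparison, which is exact for
reads of at least the seed length.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .seqio import FormatError
from .sequtils import revcomp

VALID_GENOME_CHARS = frozenset("ACGTN")


@dataclass(frozen=True)
class Placement:
    """One exact hit of a read on a genome.

    `n_occurrences` records the genome-wide total number of exact hits of
    the read (both strands), regardless of how many placements were
    retained under the multimapping policy. A '-' strand placement means
    the genome substring equals the reverse complement of the read.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    n_occurrences: int


@dataclass
class MapParams:
    seed_length: int = 17
    multimap_policy: str = "random_one"  # random_one | all | unique_only
    rng_seed: int = 0

    def __post_init__(self):
        if self.multimap_policy not in ("random_one", "all", "unique_only"):
            raise ValueError(f"unknown multimap policy: {self.multimap_policy}")


class ExactIndex:
    """Hash index of fixed-length seeds over a genome, with full-length
    verification of candidate occurrences."""

    def __init__(self, genome: dict[str, str], seed_length: int = 17):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ValueError("cannot index an empty genome")
        if seed_length < 1:
            raise ValueError("seed_length must be positive")
        for name, seq in genome.items():
            bad = set(seq) - VALID_GENOME_CHARS
            if bad:
                raise FormatError(
                    f"chromosome {name} contains non-ACGTN characters: {sorted(bad)}"
                )
        self.genome = genome
        self.seed_length = seed_length
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        k = seed_length
        for name, seq in genome.items():
            seeds = self._seeds
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if kmer in seeds:
                    seeds[kmer].append((name, i))
                else:
                    seeds[kmer] = [(name, i)]

    def occurrences(self, query: str) -> list[tuple[str, int, str]]:
        """All exact occurrences of `query` on both strands, as
        (chromosome, start, strand) sorted deterministically."""
        k = self.seed_length
        if len(query) < k:
            raise ValueError(
                f"query length {len(query)} below seed length {k}"
            )
        hits: list[tuple[str, int, str]] = []
        n = len(query)
        genome = self.genome
        for chrom, pos in self._seeds.get(query[:k], ()):
            if genome[chrom][pos : pos + n] == query:
                hits.append((chrom, pos, "+"))
        rc = revcomp(query)
        for chrom, pos in self._seeds.get(rc[:k], ()):
            if genome[chrom][pos : pos + n] == rc:
                hits.append((chrom, pos, "-"))
        hits.sort()
        return hits

    def contains(self, query: str) -> bool:
        """Whether `query` occurs exactly anywhere in the genome (either
        strand); short-circuits at the first verified hit."""
        k = self.seed_length
        if len(query) < k:
            return False
        n = len(query)
        genome = self.genome
        for chrom, pos in self._seeds.get(query[:k], ()):
            if genome[chrom][pos : pos + n] == query:
                return True
        rc = revcomp(query)
        for chrom, pos in self._seeds.get(rc[:k], ()):
            if genome[chrom][pos : pos + n] == rc:
                return True
        return False


def build_index(genome: dict[str, str], seed_length: int = 17) -> ExactIndex:
    return ExactIndex(genome, seed_length=seed_length)


def place_read(index: ExactIndex, read, params: MapParams) -> list[Placement]:
    """Place one read on the genome under the multimapping policy.

    random_one retains a single occurrence drawn uniformly with a
    per-read deterministic generator (seeded from rng_seed and the read
    id, so results do not depend on call order); unique_only returns
    nothing for multimappers; all returns every occurrence.
    """
    occs = index.occurrences(read.sequence)
    n = len(occs)
    if n == 0:
        return []
    length = len(read.sequence)
    if params.multimap_policy == "unique_only" and n > 1:
        return []
    if params.multimap_policy == "random_one" and n > 1:
        rng = random.Random(f"{params.rng_seed}:{read.id}")
        occs = [occs[rng.randrange(n)]]
    return [
        Placement(
            read_id=read.id, chrom=c, start=p, end=p + length, strand=s, n_occurrences=n
        )
        for c, p, s in occs
    ]


def map_readset(index: ExactIndex, reads, params: MapParams):
    """Map a read set; returns (placements, mapped ids, unmapped ids).

    The mapped/unmapped partition is exact (a read is mapped iff it has
    at least one genome-wide exact occurrence) and deterministic for a
    fixed rng_seed.
    """
    placements: list[Placement] = []
    mapped: list[str] = []
    unmapped: list[str] = []
    for read in reads:
        ps = place_read(index, read, params)
        if ps:
            placements.extend(ps)
            mapped.append(read.id)
        else:
            unmapped.append(read.id)
    return placements, mapped, unmapped
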