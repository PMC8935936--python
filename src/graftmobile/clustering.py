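"""Small-RNA cluster calling from read placements.

Clusters are built the way ShortStack describes them: maximal "islands"
of per-base raw read depth >= mincov are merged when separated by at
most `pad` nucleotides, every read overlapping a merged interval is
assigned to the resulting cluster (extending the interval to the full
extent of its reads), and a cluster is "dicer-derived" when at least
`dicer_call_fraction` of its reads fall in the [dicer_min, dicer_max]
length range, its size class being the predominant read length in that
range (ties resolved toward the larger length).
"""

from __future__ import annotations

from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .sequtils import revcomp


@dataclass
class ClusterParams:
    mincov: int = 5
    pad: int = 100
    dicer_min: int = 20
    dicer_max: int = 24
    dicer_call_fraction: float = 0.8

    def __post_init__(self):
        if self.mincov < 1:
            raise ValueError("mincov must be >= 1")
        if self.pad < 0:
            raise ValueError("pad must be >= 0")
        if self.dicer_min > self.dicer_max:
            raise ValueError("dicer_min must not exceed dicer_max")


@dataclass
class Cluster:
    id: str
    chrom: str
    start: int
    end: int
    reads_total: int
    reads_by_length: dict[int, int] = field(default_factory=dict)
    reads_by_replicate: dict[str, int] = field(default_factory=dict)
    rpm: float = 0.0
    dicer_call: bool = False
    size_class: int | None = None
    mirna_match: str | None = None
    read_ids: list[str] = field(default_factory=list)
    genome: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def find_islands(placements, chromosome: str, mincov: int) -> list[tuple[int, int]]:
    """Maximal intervals on `chromosome` where per-base raw read depth
    is >= mincov, as sorted (start, end) pairs."""
    spans = [(p.start, p.end) for p in placements if p.chrom == chromosome]
    if not spans:
        return []
    max_end = max(e for _, e in spans)
    delta = np.zeros(max_end + 1, dtype=np.int32)
    for s, e in spans:
        delta[s] += 1
        delta[e] -= 1
    depth = np.cumsum(delta)[:-1]
    mask = np.concatenate(([False], depth >= mincov, [False]))
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def merge_islands(islands: list[tuple[int, int]], pad: int) -> list[tuple[int, int]]:
    """Transitively merge sorted non-overlapping islands whose gap
    (next.start - prev.end) is <= pad (inclusive boundary)."""
    if not islands:
        return []
    merged = [islands[0]]
    for s, e in islands[1:]:
        ps, pe = merged[-1]
        if s - pe <= pad:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def build_clusters(
    placements,
    params: ClusterParams,
    replicate_of: dict[str, str] | None = None,
    total_mapped: int | None = None,
    genome_name: str | None = None,
) -> list[Cluster]:
    """Build clusters from single-location placements.

    Each read whose placement overlaps a merged island interval is
    assigned to exactly one cluster (the first overlapping interval in
    coordinate order); the cluster interval is then extended to the min
    start / max end of its assigned reads. rpm uses `total_mapped`
    (default: the number of placements) as denominator.
    """
    if total_mapped is None:
        total_mapped = len(placements)
    by_chrom: dict[str, list] = {}
    for p in placements:
        by_chrom.setdefault(p.chrom, []).append(p)

    clusters: list[Cluster] = []
    for chrom in sorted(by_chrom):
        chrom_placements = by_chrom[chrom]
        islands = find_islands(chrom_placements, chrom, params.mincov)
        merged = merge_islands(islands, params.pad)
        if not merged:
            continue
        starts = [s for s, _ in merged]
        assigned: list[list] = [[] for _ in merged]
        for p in chrom_placements:
            # candidate merged intervals with start < p.end, scanned
            # backwards to find the first one the read overlaps
            i = bisect_right(starts, p.end - 1) - 1
            while i >= 0 and merged[i][1] > p.start:
                i -= 1
            i += 1
            if i < len(merged) and merged[i][0] < p.end and merged[i][1] > p.start:
                assigned[i].append(p)
        for (s, e), members in zip(merged, assigned):
            if not members:
                continue
            start = min(s, min(m.start for m in members))
            end = max(e, max(m.end for m in members))
            lengths = Counter(m.end - m.start for m in members)
            reps: Counter = Counter()
            for m in members:
                label = replicate_of.get(m.read_id, "all") if replicate_of else "all"
                reps[label] += 1
            total = len(members)
            clusters.append(
                Cluster(
                    id="",
                    chrom=chrom,
                    start=start,
                    end=end,
                    reads_total=total,
                    reads_by_length=dict(sorted(lengths.items())),
                    reads_by_replicate=dict(sorted(reps.items())),
                    rpm=total / total_mapped * 1e6 if total_mapped else 0.0,
                    read_ids=[m.read_id for m in members],
                    genome=genome_name,
                )
            )
    for i, c in enumerate(clusters, start=1):
        c.id = f"cl{i}"
    return clusters


def call_dicer(cluster: Cluster, params: ClusterParams) -> Cluster:
    """Set dicer_call and size_class on a cluster (mutates and returns).

    dicer_call is true iff the fraction of reads with length in
    [dicer_min, dicer_max] is >= dicer_call_fraction (boundary
    inclusive: exactly 80% qualifies); the size class is the modal read
    length within that range, larger length winning ties.
    """
    if cluster.reads_total == 0:
        raise ValueError("cannot dicer-call an empty cluster")
    in_range = {
        length: n
        for length, n in cluster.reads_by_length.items()
        if params.dicer_min <= length <= params.dicer_max
    }
    frac = sum(in_range.values()) / cluster.reads_total
    if frac >= params.dicer_call_fraction:
        cluster.dicer_call = True
        best = max(in_range.values())
        cluster.size_class = max(l for l, n in in_range.items() if n == best)
    else:
        cluster.dicer_call = False
        cluster.size_class = None
    return cluster


def _min_hamming_ungapped(query: str, subject: str) -> int | None:
    """Fewest mismatches of `query` against any same-length window of
    `subject`, or None if subject is shorter than query."""
    n, m = len(query), len(subject)
    if m < n:
        return None
    best = n + 1
    for i in range(m - n + 1):
        window = subject[i : i + n]
        mm = sum(1 for a, b in zip(query, window) if a != b)
        if mm < best:
            best = mm
            if best == 0:
                break
    return best


def match_known_mirna(
    cluster: Cluster,
    read_sequences: dict[str, str],
    hairpin_db: dict[str, str],
    max_mismatches: int = 2,
) -> str | None:
    """Match a cluster against known miRNA hairpins.

    The cluster's most abundant read sequence is searched as an ungapped
    substring (either orientation) of each hairpin; the hairpin with the
    fewest mismatches <= max_mismatches wins, ties broken by database
    order. Sets cluster.mirna_match and returns the hairpin id (or None).
    """
    if not hairpin_db:
        raise ValueError("hairpin database must be non-empty")
    seqs = [read_sequences[rid] for rid in cluster.read_ids if rid in read_sequences]
    if not seqs:
        return None
    query = Counter(seqs).most_common(1)[0][0]
    query_rc = revcomp(query)
    best_id = None
    best_mm = max_mismatches + 1
    for name, hairpin in hairpin_db.items():
        for q in (query, query_rc):
            mm = _min_hamming_ungapped(q, hairpin)
            if mm is not None and mm < best_mm:
                best_mm = mm
                best_id = name
    if best_mm <= max_mismatches:
        cluster.mirna_match = best_id
        return best_id
    return None


def clusters_to_table(clusters: list[Cluster]):
    """Flatten clusters into a ShortStack-results-style DataFrame."""
    import pandas as pd

    rows = []
    for c in clusters:
        rows.append(
            {
                "id": c.id,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "reads_total": c.reads_total,
                "reads_by_length": ";".join(f"{l}:{n}" for l, n in c.reads_by_length.items()),
                "reads_by_replicate": ";".join(
                    f"{r}:{n}" for r, n in c.reads_by_replicate.items()
                ),
                "rpm": c.rpm,
                "dicer_call": c.dicer_call,
                "size_class": c.size_class,
                "mirna_match": c.mirna_match,
            }
        )
    return pd.DataFrame(rows)
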