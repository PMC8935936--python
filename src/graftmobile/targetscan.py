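"""Target scanning: score candidate target regions of mobile clusters
on the receptor genome by ungapped local alignment.

Hits are seeded with exact words and extended along the diagonal to the
maximum-scoring ungapped segment (match +1, mismatch -2, no gaps); hits
under the score threshold or overlapping repeat annotation are
discarded. Each surviving hit carries

    pident       = (aligned_length - mismatches) / aligned_length * 100
    pident_final = pident * aligned_length / cluster_length

i.e. the percent identity down-weighted by the fraction of the query
cluster the alignment actually covers, used to rank candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .sequtils import revcomp

DEFAULT_MIN_SCORE = 14  # a 14-nt perfect match
DEFAULT_WORD_SIZE = 12
MATCH_SCORE = 1
MISMATCH_SCORE = -2


@dataclass(frozen=True)
class TargetHit:
    cluster_id: str
    cluster_length: int
    chrom: str
    start: int
    end: int
    strand: str
    aligned_length: int
    n_mismatches: int
    score: int

    @property
    def pident(self) -> float:
        return (self.aligned_length - self.n_mismatches) / self.aligned_length * 100

    @property
    def pident_final(self) -> float:
        return self.pident * self.aligned_length / self.cluster_length


def cluster_consensus(cluster, genome: dict[str, str]) -> str:
    """The cluster's sequence: the + strand genomic substring of its
    interval on the genome the cluster was called on."""
    if cluster.reads_total < 1:
        raise ValueError("cluster has no reads")
    seq = genome.get(cluster.chrom)
    if seq is None or cluster.start < 0 or cluster.end > len(seq):
        raise RuntimeError(
            f"cluster interval {cluster.chrom}:{cluster.start}-{cluster.end} "
            "out of genome bounds"
        )
    return seq[cluster.start : cluster.end]


class WordIndex:
    """Exact-word index over a genome for alignment seeding."""

    def __init__(self, genome: dict[str, str], word_size: int = DEFAULT_WORD_SIZE):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ValueError("cannot index an empty genome")
        self.genome = genome
        self.word_size = word_size
        self._words: dict[str, list[tuple[str, int]]] = {}
        w = word_size
        for name, seq in genome.items():
            words = self._words
            for i in range(len(seq) - w + 1):
                word = seq[i : i + w]
                if word in words:
                    words[word].append((name, i))
                else:
                    words[word] = [(name, i)]


def _best_segment(match: np.ndarray) -> tuple[int, int, int]:
    """Maximum-scoring contiguous segment of a +1/-2 match profile
    (Kadane), returning (start, end, score); deterministic first-maximum
    tie-break."""
    scores = np.where(match, MATCH_SCORE, MISMATCH_SCORE)
    best = 0
    best_range = (0, 0)
    run = 0
    run_start = 0
    for i, sc in enumerate(scores):
        if run <= 0:
            run = int(sc)
            run_start = i
        else:
            run += int(sc)
        if run > best:
            best = run
            best_range = (run_start, i + 1)
    return best_range[0], best_range[1], best


def scan_targets(
    cluster_id: str,
    consensus: str,
    receptor_genome: dict[str, str],
    repeat_annotation=None,
    min_score: int = DEFAULT_MIN_SCORE,
    keep_top: int = 50,
    word_size: int = DEFAULT_WORD_SIZE,
    word_index: WordIndex | None = None,
) -> list[TargetHit]:
    """Ungapped seed-and-extend scan of a cluster sequence against the
    receptor genome, both strands.

    Repeat-overlapping hits are excluded; survivors are ranked by
    pident_final (descending, deterministic tie-break) and the top
    `keep_top` returned. A prebuilt WordIndex may be passed to amortize
    indexing across clusters.
    """
    if not receptor_genome or all(len(s) == 0 for s in receptor_genome.values()):
        raise ValueError("receptor genome is empty")
    if len(consensus) < 9:
        raise ValueError("cluster consensus shorter than 9 nt")
    if word_index is None:
        word_index = WordIndex(receptor_genome, min(word_size, len(consensus)))
    w = word_index.word_size
    n = len(consensus)

    repeat_trees: dict[str, IntervalTree] = {}
    if repeat_annotation is not None:
        for iv in repeat_annotation.repeats:
            repeat_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    hits: dict[tuple, TargetHit] = {}
    for strand, query in (("+", consensus), ("-", revcomp(consensus))):
        seen_diagonals: set[tuple[str, int]] = set()
        for qpos in range(n - w + 1):
            for chrom, gpos in word_index._words.get(query[qpos : qpos + w], ()):
                diag = gpos - qpos
                if (chrom, diag) in seen_diagonals:
                    continue
                seen_diagonals.add((chrom, diag))
                gseq = word_index.genome[chrom]
                qlo = max(0, -diag)
                qhi = min(n, len(gseq) - diag)
                if qhi - qlo < w:
                    continue
                qseg = query[qlo:qhi]
                gseg = gseq[diag + qlo : diag + qhi]
                match = np.frombuffer(qseg.encode(), dtype="S1") == np.frombuffer(
                    gseg.encode(), dtype="S1"
                )
                s, e, score = _best_segment(match)
                if score < min_score:
                    continue
                gstart = diag + qlo + s
                gend = diag + qlo + e
                key = (chrom, strand, gstart, gend)
                if key in hits:
                    continue
                tree = repeat_trees.get(chrom)
                if tree is not None and tree.overlaps(gstart, gend):
                    continue
                aligned = e - s
                mism = int(aligned - match[s:e].sum())
                # report the hit in query (+ strand) orientation: for a
                # '-' strand hit the genomic coordinates are unchanged
                hits[key] = TargetHit(
                    cluster_id=cluster_id,
                    cluster_length=n,
                    chrom=chrom,
                    start=gstart,
                    end=gend,
                    strand=strand,
                    aligned_length=aligned,
                    n_mismatches=mism,
                    score=score,
                )
    ranked = sorted(
        hits.values(),
        key=lambda h: (-h.pident_final, -h.score, h.chrom, h.start, h.strand),
    )
    return ranked[:keep_top]


def hits_to_table(hits: list[TargetHit]):
    import pandas as pd

    rows = [
        {
            "cluster_id": h.cluster_id,
            "chrom": h.chrom,
            "start": h.start,
            "end": h.end,
            "strand": h.strand,
            "aligned_length": h.aligned_length,
            "n_mismatches": h.n_mismatches,
            "pident": h.pident,
            "pident_final": h.pident_final,
            "score": h.score,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "chrom", "start", "end", "strand", "aligned_length",
            "n_mismatches", "pident", "pident_final", "score",
        ],
    )
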