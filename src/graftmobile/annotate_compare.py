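"""Genomic annotation of clusters, cross-set co-localization, replicate
statistics, read-depth categories and Fisher-exact term enrichment.

Overlap semantics throughout are any-overlap (>= 1 bp), the default of
bedtools intersect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import fisher_exact

from .seqio import Interval

PROMOTER_LENGTH = 2000

DEFAULT_DEPTH_BOUNDARIES = (5, 10, 50, 100, 500, 1000)


@dataclass
class ReplicateStats:
    cluster_id: str
    presence_count: int
    cv: float | None  # sd/mean * 100; None when the mean is 0


@dataclass
class CommonSpecificReport:
    """Common/specific cluster counts between two sets (Venn-style).

    A cluster of A is "common" iff it overlaps at least one cluster of B
    by >= 1 bp, and symmetrically; each side's common count may differ
    (one cluster can co-localize with several). Per side:
    n_common + n_specific = set size.
    """

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    n_common_a: int
    n_common_b: int
    n_specific_a: int
    n_specific_b: int

    @property
    def pct_common_a(self) -> float:
        return self.n_common_a / self.n_a * 100 if self.n_a else 0.0

    @property
    def pct_common_b(self) -> float:
        return self.n_common_b / self.n_b * 100 if self.n_b else 0.0


def derive_promoters(
    genes: list[Interval], chrom_lengths: dict[str, int], length: int = PROMOTER_LENGTH
) -> list[Interval]:
    """2-kb promoter intervals immediately upstream of each gene's 5'
    end, strand-aware and clipped to chromosome bounds; empty promoters
    (gene starting at a chromosome edge) are omitted."""
    promoters: list[Interval] = []
    for g in genes:
        if g.strand == "-":
            s, e = g.end, min(chrom_lengths.get(g.chrom, g.end + length), g.end + length)
        else:
            s, e = max(0, g.start - length), g.start
        if s < e:
            promoters.append(Interval(g.chrom, s, e, g.strand, f"{g.feature_id}_promoter"))
    return promoters


def _build_trees(intervals: list[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def annotate_clusters(clusters, annotation) -> dict[str, set[str]]:
    """Label each cluster with every feature class it overlaps by >= 1 bp
    ({'gene_body', 'promoter_2kb', 'repeat'}); an empty set means
    intergenic."""
    trees = {
        "gene_body": _build_trees(annotation.genes),
        "promoter_2kb": _build_trees(annotation.promoters),
        "repeat": _build_trees(annotation.repeats),
    }
    labels: dict[str, set[str]] = {}
    for c in clusters:
        hit = set()
        for label, by_chrom in trees.items():
            tree = by_chrom.get(c.chrom)
            if tree is not None and tree.overlaps(c.start, c.end):
                hit.add(label)
        labels[c.id] = hit
    return labels


def co_localize(set_a, set_b, label_a: str = "A", label_b: str = "B") -> CommonSpecificReport:
    """Common/specific comparison of two cluster sets on the same genome
    (any-overlap rule). Raises if the sets declare different genomes."""
    genomes = {c.genome for c in set_a if c.genome} | {c.genome for c in set_b if c.genome}
    if len(genomes) > 1:
        raise ValueError(f"cluster sets live on different genomes: {sorted(genomes)}")
    trees_b = {}
    for c in set_b:
        trees_b.setdefault(c.chrom, IntervalTree()).addi(c.start, c.end)
    trees_a = {}
    for c in set_a:
        trees_a.setdefault(c.chrom, IntervalTree()).addi(c.start, c.end)
    common_a = sum(
        1 for c in set_a
        if c.chrom in trees_b and trees_b[c.chrom].overlaps(c.start, c.end)
    )
    common_b = sum(
        1 for c in set_b
        if c.chrom in trees_a and trees_a[c.chrom].overlaps(c.start, c.end)
    )
    return CommonSpecificReport(
        label_a=label_a,
        label_b=label_b,
        n_a=len(set_a),
        n_b=len(set_b),
        n_common_a=common_a,
        n_common_b=common_b,
        n_specific_a=len(set_a) - common_a,
        n_specific_b=len(set_b) - common_b,
    )


def replicate_stats(cluster, replicate_labels: list[str]) -> ReplicateStats:
    """Presence count and coefficient of variation of per-replicate read
    counts. CV uses the sample (n-1) standard deviation and is undefined
    (None) when the mean count is zero."""
    if len(replicate_labels) < 2:
        raise ValueError("replicate statistics need at least 2 replicates")
    counts = np.array(
        [cluster.reads_by_replicate.get(label, 0) for label in replicate_labels],
        dtype=float,
    )
    presence = int((counts > 0).sum())
    mean = counts.mean()
    if mean == 0:
        return ReplicateStats(cluster.id, presence, None)
    cv = float(counts.std(ddof=1) / mean * 100)
    return ReplicateStats(cluster.id, presence, cv)


def depth_categories(
    clusters, boundaries: tuple[int, ...] = DEFAULT_DEPTH_BOUNDARIES
) -> pd.Series:
    """Histogram of clusters by total read count in len(boundaries)+1
    bins; the default boundaries (5, 10, 50, 100, 500, 1000) give seven
    categories, the first being '<=5'."""
    b = list(boundaries)
    if any(x >= y for x, y in zip(b, b[1:])):
        raise ValueError("boundaries must be strictly increasing")
    labels = [f"<={b[0]}"] + [f"{x + 1}-{y}" for x, y in zip(b, b[1:])] + [f">{b[-1]}"]
    counts = np.zeros(len(labels), dtype=int)
    arr = np.array([c.reads_total for c in clusters], dtype=int)
    if len(arr):
        idx = np.searchsorted(b, arr, side="left")
        for i in idx:
            counts[i] += 1
    return pd.Series(counts, index=labels, name="n_clusters")


def enrichment_test(
    foreground: set[str],
    background: set[str],
    term_map: dict[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided (over-representation) Fisher exact test per term.

    For each term the 2x2 table contrasts term membership inside and
    outside the foreground within the background universe. No
    multiple-testing correction is applied; `significant` is p < alpha.
    """
    foreground = set(foreground)
    background = set(background)
    if not foreground:
        raise ValueError("foreground gene set is empty")
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    n_fg = len(foreground)
    n_bg = len(background)
    rows = []
    for term, genes in term_map.items():
        genes = set(genes) & background
        k = len(genes & foreground)
        table = [[k, n_fg - k], [len(genes) - k, n_bg - n_fg - (len(genes) - k)]]
        p = float(fisher_exact(table, alternative="greater")[1])
        rows.append(
            {
                "term": term,
                "count_fg": k,
                "count_bg": len(genes),
                "p_value": p,
                "significant": p < alpha,
            }
        )
    df = pd.DataFrame(rows, columns=["term", "count_fg", "count_bg", "p_value", "significant"])
    return df.sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)
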