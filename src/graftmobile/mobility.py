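"""SNP-discriminative detection of graft-mobile small RNAs.

A read sampled from the receptor compartment is classified by two
successive exact alignments: reads occurring verbatim in the receptor
genome are native; of the remainder, reads occurring verbatim in the
donor genome are mobile (they crossed the graft junction); everything
else is unassigned. Step-1 precedence is strict, so only reads spanning
at least one SNP between the two genomes can ever be called mobile —
the method's documented detection limit, surfaced as the
`snp_spanning_detectable_fraction` diagnostic when ground truth is
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .clustering import ClusterParams, build_clusters, call_dicer
from .exactmap import ExactIndex, MapParams, map_readset
from .sequtils import round_half_up

SCION_TO_ROOTSTOCK = "scion_to_rootstock"
ROOTSTOCK_TO_SCION = "rootstock_to_scion"


@dataclass
class MobilityReport:
    direction: str
    n_total: int = 0
    n_native: int = 0
    n_unmapped_step1: int = 0
    n_mobile: int = 0
    n_unassigned: int = 0
    mobile_clusters: list = field(default_factory=list)
    empty_input: bool = False
    snp_spanning_detectable_fraction: float | None = None

    @property
    def pct_native(self) -> float:
        return self.n_native / self.n_total * 100 if self.n_total else 0.0

    @property
    def pct_unmapped(self) -> float:
        return self.n_unmapped_step1 / self.n_total * 100 if self.n_total else 0.0

    @property
    def pct_mobile_of_unmapped(self) -> float:
        if self.n_unmapped_step1 == 0:
            return 0.0
        return self.n_mobile / self.n_unmapped_step1 * 100

    def validate(self) -> None:
        assert self.n_native + self.n_unmapped_step1 == self.n_total
        assert self.n_mobile + self.n_unassigned == self.n_unmapped_step1


def classify_reads(
    reads,
    receptor_index: ExactIndex,
    donor_index: ExactIndex,
    direction: str = SCION_TO_ROOTSTOCK,
) -> tuple[dict[str, str], MobilityReport]:
    """Two-step classification of preprocessed reads.

    Returns (read_id -> 'native'|'mobile'|'unassigned', MobilityReport).
    A read exactly matching the receptor genome is native regardless of
    whether it also matches the donor genome (step-1 precedence).
    """
    labels: dict[str, str] = {}
    n_native = n_mobile = n_unassigned = 0
    for r in reads:
        if receptor_index.contains(r.sequence):
            labels[r.id] = "native"
            n_native += 1
        elif donor_index.contains(r.sequence):
            labels[r.id] = "mobile"
            n_mobile += 1
        else:
            labels[r.id] = "unassigned"
            n_unassigned += 1
    report = MobilityReport(
        direction=direction,
        n_total=len(labels),
        n_native=n_native,
        n_unmapped_step1=n_mobile + n_unassigned,
        n_mobile=n_mobile,
        n_unassigned=n_unassigned,
        empty_input=not labels,
    )
    report.validate()
    return labels, report


def call_mobile_clusters(
    mobile_reads,
    donor_index: ExactIndex,
    cluster_params: ClusterParams | None = None,
    map_params: MapParams | None = None,
    genome_name: str | None = None,
):
    """Place already-labelled mobile reads on the donor genome and run
    the standard cluster calling (islands, pad merge, dicer call)."""
    cluster_params = cluster_params or ClusterParams()
    map_params = map_params or MapParams()
    if not mobile_reads:
        return []
    replicate_of = {
        r.id: r.replicate_label for r in mobile_reads if r.replicate_label is not None
    }
    placements, _, _ = map_readset(donor_index, mobile_reads, map_params)
    clusters = build_clusters(
        placements,
        cluster_params,
        replicate_of=replicate_of or None,
        genome_name=genome_name,
    )
    for c in clusters:
        call_dicer(c, cluster_params)
    return clusters


def summarize_mobility(report: MobilityReport) -> pd.DataFrame:
    """Fraction table for a mobility report: raw counts plus percentages
    rounded half-up to 1 decimal place. Percentages are 0 (flagged) on
    empty input."""
    rows = [
        ("total_reads", report.n_total, ""),
        ("native_step1", report.n_native, round_half_up(report.pct_native)),
        ("unmapped_step1", report.n_unmapped_step1, round_half_up(report.pct_unmapped)),
        ("mobile", report.n_mobile, round_half_up(report.pct_mobile_of_unmapped)),
        ("unassigned", report.n_unassigned, ""),
    ]
    df = pd.DataFrame(rows, columns=["metric", "count", "pct"])
    df.attrs["direction"] = report.direction
    df.attrs["empty_input"] = report.empty_input
    return df


def mobile_size_class_table(clusters) -> pd.DataFrame:
    """Mobile-cluster counts by size class (20–24 nt), the per-direction
    summary of a mobile-cluster analysis."""
    counts = {k: 0 for k in (20, 21, 22, 23, 24)}
    for c in clusters:
        if c.dicer_call and c.size_class in counts:
            counts[c.size_class] += 1
    rows = [{"size_class": k, "n_clusters": v} for k, v in counts.items()]
    rows.append({"size_class": "total_dicer", "n_clusters": sum(counts.values())})
    rows.append({"size_class": "total", "n_clusters": len(clusters)})
    return pd.DataFrame(rows)


def detectable_fraction(truth, read_ids=None) -> float:
    """Fraction of truth-mobile reads that span a SNP and carry no
    sequencing error — the upper bound on what the two-step procedure
    can detect. Optionally restricted to a set of read ids."""
    mobile = [
        t for rid, t in truth.records.items()
        if t.is_mobile and (read_ids is None or rid in read_ids)
    ]
    if not mobile:
        return 0.0
    detectable = sum(1 for t in mobile if t.spans_snp and t.n_errors == 0)
    return detectable / len(mobile)
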