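"""End-to-end orchestration: preprocess -> map -> cluster -> mobility ->
annotate/compare -> target scan, from a single flat config, with
report tables whose every printed percentage is recomputable from the
printed counts. Fully deterministic per seed.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import annotate_compare, mobility, preprocess, simdata, targetscan
from .clustering import (
    ClusterParams, build_clusters, call_dicer, clusters_to_table, match_known_mirna,
)
from .exactmap import MapParams, build_index, map_readset
from .seqio import (
    read_fasta, read_fastq, read_gff3, write_fasta, write_fastq, write_gff3,
    write_tsv,
)
from .sequtils import round_half_up

log = logging.getLogger("graftmobile")


@dataclass
class RunConfig:
    """Flat run configuration; all paths plus every tunable block."""

    donor_genome: str
    receptor_genome: str
    donor_reads: list[str]
    receptor_reads: list[str]
    annotation: str
    outdir: str
    contaminants: str | None = None
    hairpins: str | None = None
    term_map: str | None = None
    adapter: str = simdata.DEFAULT_ADAPTER
    min_overlap: int = preprocess.DEFAULT_MIN_OVERLAP
    min_len: int = preprocess.DEFAULT_MIN_LEN
    entropy_threshold: float = preprocess.DEFAULT_ENTROPY_THRESHOLD
    seed_length: int = 17
    multimap_policy: str = "random_one"
    mincov: int = 5
    pad: int = 100
    dicer_min: int = 20
    dicer_max: int = 24
    dicer_call_fraction: float = 0.8
    depth_boundaries: list[int] = field(
        default_factory=lambda: list(annotate_compare.DEFAULT_DEPTH_BOUNDARIES)
    )
    alpha: float = 0.05
    target_min_score: int = targetscan.DEFAULT_MIN_SCORE
    target_keep_top: int = 10
    seed: int = 0

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)

    def validate_paths(self) -> None:
        paths = [self.donor_genome, self.receptor_genome, self.annotation]
        paths += list(self.donor_reads) + list(self.receptor_reads)
        paths += [p for p in (self.contaminants, self.hairpins, self.term_map) if p]
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")

    def cluster_params(self) -> ClusterParams:
        return ClusterParams(
            mincov=self.mincov, pad=self.pad, dicer_min=self.dicer_min,
            dicer_max=self.dicer_max, dicer_call_fraction=self.dicer_call_fraction,
        )

    def map_params(self) -> MapParams:
        return MapParams(
            seed_length=self.seed_length, multimap_policy=self.multimap_policy,
            rng_seed=self.seed,
        )


def _load_replicates(paths: list[str]):
    reads = []
    for i, path in enumerate(paths, start=1):
        label = f"rep{i}"
        for r in read_fastq(path):
            r.replicate_label = label
            reads.append(r)
    return reads


def _sample_summary(name, n_raw, n_clean, placements, clusters, dicer_clusters):
    """Per-sample summary with the fields of a cluster-prediction report
    table; percentages recomputable from the counts alongside."""
    n_mapped = len(placements)
    reads_in_clusters = sum(c.reads_total for c in dicer_clusters)
    n_mirna = sum(1 for c in dicer_clusters if c.mirna_match)
    lengths = [c.length for c in dicer_clusters]
    return {
        "sample": name,
        "total_reads_raw": n_raw,
        "total_reads_clean": n_clean,
        "reads_mapped": n_mapped,
        "reads_in_clusters": reads_in_clusters,
        "pct_reads_in_clusters": round_half_up(
            reads_in_clusters / n_mapped * 100 if n_mapped else 0.0
        ),
        "n_clusters": len(dicer_clusters),
        "n_mirna_clusters": n_mirna,
        "n_sirna_clusters": len(dicer_clusters) - n_mirna,
        "mean_reads_per_cluster": round_half_up(
            reads_in_clusters / len(dicer_clusters) if dicer_clusters else 0.0
        ),
        "mean_cluster_length_bp": round_half_up(
            sum(lengths) / len(lengths) if lengths else 0.0
        ),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis for one heterograft scenario.

    Per compartment: clean the reads, map them to the native genome,
    call and annotate clusters; then run the two-step mobility
    classification in both directions, cluster the mobile reads on the
    donor-side genome, co-localize mobile clusters with the donor
    compartment's native clusters, and score candidate target regions
    of mobile clusters on the receptor-side genome. Returns the run
    report (also written to the output directory).
    """
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=[
            logging.FileHandler(outdir / "run.log"),
            logging.StreamHandler(),
        ],
        force=True,
    )
    log.info("run config: %s", json.dumps(asdict(config), default=str, sort_keys=True))

    genomes = {
        "donor": read_fasta(config.donor_genome),
        "receptor": read_fasta(config.receptor_genome),
    }
    annotation = read_gff3(config.annotation)
    contaminants = read_fasta(config.contaminants) if config.contaminants else None
    hairpins = read_fasta(config.hairpins) if config.hairpins else None
    cluster_params = config.cluster_params()
    map_params = config.map_params()
    indexes = {
        name: build_index(g, seed_length=config.seed_length)
        for name, g in genomes.items()
    }

    report: dict = {"seed": config.seed, "samples": {}, "mobility": {}}
    compartments = {}
    for name, paths in (("donor", config.donor_reads), ("receptor", config.receptor_reads)):
        raw = _load_replicates(paths)
        pp = preprocess.preprocess_reads(
            raw,
            adapter=config.adapter,
            min_overlap=config.min_overlap,
            min_len=config.min_len,
            entropy_threshold=config.entropy_threshold,
            contaminant_refs=contaminants,
        )
        log.info("%s: preprocess counts %s", name, pp.stage_counts)
        clean = pp.reads
        replicate_of = {r.id: r.replicate_label for r in clean}
        placements, mapped, unmapped = map_readset(indexes[name], clean, map_params)
        clusters = build_clusters(
            placements, cluster_params, replicate_of=replicate_of,
            genome_name=name,
        )
        read_seqs = {r.id: r.sequence for r in clean}
        for c in clusters:
            call_dicer(c, cluster_params)
            if hairpins and c.dicer_call:
                match_known_mirna(c, read_seqs, hairpins)
        dicer_clusters = [c for c in clusters if c.dicer_call]
        compartments[name] = {
            "reads": clean,
            "clusters": clusters,
            "dicer_clusters": dicer_clusters,
            "stage_counts": pp.stage_counts,
        }
        summary = _sample_summary(
            name, len(raw), len(clean), placements, clusters, dicer_clusters
        )
        report["samples"][name] = {"preprocess": pp.stage_counts, "summary": summary}
        write_tsv(
            pd.DataFrame([pp.stage_counts]), outdir / f"{name}_preprocess_counts.tsv"
        )
        write_tsv(clusters_to_table(clusters), outdir / f"{name}_clusters.tsv")
        labels = annotate_compare.annotate_clusters(dicer_clusters, annotation)
        ann_rows = [
            {"cluster_id": cid, "labels": ",".join(sorted(ls)) or "intergenic"}
            for cid, ls in labels.items()
        ]
        write_tsv(pd.DataFrame(ann_rows), outdir / f"{name}_cluster_annotation.tsv")
        depth = annotate_compare.depth_categories(
            dicer_clusters, tuple(config.depth_boundaries)
        )
        report["samples"][name]["depth_categories"] = depth.to_dict()

    # mobility, both directions; "receptor compartment" reads are
    # classified against their own genome first, then the other
    for direction, receptor_side, donor_side in (
        (mobility.SCION_TO_ROOTSTOCK, "receptor", "donor"),
        (mobility.ROOTSTOCK_TO_SCION, "donor", "receptor"),
    ):
        reads = compartments[receptor_side]["reads"]
        labels, mob_report = mobility.classify_reads(
            reads, indexes[receptor_side], indexes[donor_side], direction=direction
        )
        mobile_reads = [r for r in reads if labels[r.id] == "mobile"]
        mobile_clusters = mobility.call_mobile_clusters(
            mobile_reads, indexes[donor_side], cluster_params, map_params,
            genome_name=donor_side,
        )
        mob_report.mobile_clusters = mobile_clusters
        summary_df = mobility.summarize_mobility(mob_report)
        size_table = mobility.mobile_size_class_table(mobile_clusters)
        write_tsv(summary_df, outdir / f"mobility_{direction}.tsv")
        write_tsv(size_table, outdir / f"mobile_clusters_{direction}_size_classes.tsv")
        write_tsv(
            clusters_to_table(mobile_clusters),
            outdir / f"mobile_clusters_{direction}.tsv",
        )
        venn = annotate_compare.co_localize(
            mobile_clusters,
            [c for c in compartments[donor_side]["dicer_clusters"]],
            label_a=f"mobile_{direction}",
            label_b=f"{donor_side}_native",
        )
        report["mobility"][direction] = {
            "counts": {
                "n_total": mob_report.n_total,
                "n_native": mob_report.n_native,
                "n_unmapped_step1": mob_report.n_unmapped_step1,
                "n_mobile": mob_report.n_mobile,
                "n_unassigned": mob_report.n_unassigned,
            },
            "pct": {
                "native": round_half_up(mob_report.pct_native),
                "unmapped": round_half_up(mob_report.pct_unmapped),
                "mobile_of_unmapped": round_half_up(mob_report.pct_mobile_of_unmapped),
            },
            "n_mobile_clusters": len(mobile_clusters),
            "size_classes": {
                str(r["size_class"]): int(r["n_clusters"])
                for _, r in size_table.iterrows()
            },
            "co_localization_with_donor_native": {
                "n_common": venn.n_common_a,
                "n_specific": venn.n_specific_a,
                "pct_common": round_half_up(venn.pct_common_a),
            },
        }

        # candidate targets of mobile 24-nt clusters on the receptor-side genome
        word_index = None
        target_rows = []
        receptor_gen = genomes[receptor_side]
        for c in mobile_clusters:
            if not c.dicer_call or c.length < 9:
                continue
            consensus = targetscan.cluster_consensus(c, genomes[donor_side])
            if word_index is None:
                word_index = targetscan.WordIndex(receptor_gen)
            hits = targetscan.scan_targets(
                c.id, consensus, receptor_gen, annotation,
                min_score=config.target_min_score,
                keep_top=config.target_keep_top,
                word_index=word_index,
            )
            target_rows.append(targetscan.hits_to_table(hits))
        targets = (
            pd.concat(target_rows, ignore_index=True)
            if target_rows
            else targetscan.hits_to_table([])
        )
        write_tsv(targets, outdir / f"targets_{direction}.tsv")
        report["mobility"][direction]["n_target_hits"] = int(len(targets))

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s", outdir / "report.json")
    return report


FIXTURE_SCALES = {
    # n_chrom, chrom_len, genes, repeats, loci (21/24/mir), reads per replicate
    "small": dict(n_chrom=2, chrom_len=20_000, n_genes=12, n_repeats=10,
                  n_si21=6, n_si24=6, n_mir=3, reads_per_rep=1_200),
    "medium": dict(n_chrom=2, chrom_len=100_000, n_genes=40, n_repeats=30,
                   n_si21=25, n_si24=25, n_mir=6, reads_per_rep=50_000),
}


def make_fixture(
    outdir,
    scale: str = "small",
    seed: int = 0,
    snp_rate: float = 0.005,
    mobile_fraction: float = 0.05,
    error_rate: float = 0.0,
    contaminant_fraction: float = 0.4,
    n_replicates: int = 3,
) -> dict:
    """Write a self-contained synthetic heterograft scenario.

    Defaults mirror the emulated study conditions: 3 replicates per
    compartment, 40% contaminant (rRNA/tRNA-like) admixture, 0.5% SNP
    divergence between the graft partner genomes, 5% mobile reads.
    Returns the path map, including a ready-to-run config.toml.
    """
    if scale not in FIXTURE_SCALES:
        raise ValueError(f"unknown scale: {scale}")
    p = FIXTURE_SCALES[scale]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    pair = simdata.simulate_genome_pair(p["n_chrom"], p["chrom_len"], snp_rate, seed)
    annotation = simdata.plant_annotations(
        pair, p["n_genes"], p["n_repeats"], seed + 1
    )
    loci = simdata.plant_loci(
        pair, annotation, p["n_si21"], p["n_si24"], p["n_mir"], seed + 2
    )
    hairpins = simdata.hairpin_database(pair, loci)
    contaminants = simdata.simulate_contaminant_refs(seed + 3)

    paths = {
        "donor_genome": outdir / "donor.fasta",
        "receptor_genome": outdir / "receptor.fasta",
        "annotation": outdir / "annotation.gff3",
        "hairpins": outdir / "hairpins.fasta",
        "contaminants": outdir / "contaminants.fasta",
        "snp_table": outdir / "snp_table.tsv",
    }
    write_fasta(pair.donor_genome, paths["donor_genome"])
    write_fasta(pair.receptor_genome, paths["receptor_genome"])
    write_gff3(annotation, paths["annotation"])
    write_fasta(hairpins, paths["hairpins"])
    write_fasta(contaminants, paths["contaminants"])
    write_tsv(
        pd.DataFrame(
            pair.snp_table, columns=["chrom", "pos", "donor_allele", "receptor_allele"]
        ),
        paths["snp_table"],
    )

    n_reads = p["reads_per_rep"] * n_replicates
    for comp_i, compartment in enumerate(("donor", "receptor")):
        reads, truth = simdata.simulate_reads(
            pair, loci, compartment, n_reads,
            mobile_fraction=mobile_fraction,
            error_rate=error_rate,
            n_replicates=n_replicates,
            contaminant_fraction=contaminant_fraction,
            contaminant_refs=contaminants,
            seed=seed + 10 + comp_i,
        )
        rep_paths = []
        by_rep: dict[str, list] = {}
        for r in reads:
            by_rep.setdefault(r.replicate_label, []).append(r)
        for label in sorted(by_rep):
            path = outdir / f"{compartment}_{label}.fastq"
            write_fastq(by_rep[label], path)
            rep_paths.append(path)
        paths[f"{compartment}_reads"] = rep_paths
        truth_path = outdir / f"{compartment}_truth.tsv"
        write_tsv(simdata.truth_to_table(truth), truth_path)
        paths[f"{compartment}_truth"] = truth_path

    config_path = outdir / "config.toml"
    def _q(path):
        return f'"{path}"'
    with open(config_path, "w") as fh:
        fh.write(f"donor_genome = {_q(paths['donor_genome'])}\n")
        fh.write(f"receptor_genome = {_q(paths['receptor_genome'])}\n")
        fh.write(
            "donor_reads = [" + ", ".join(_q(p) for p in paths["donor_reads"]) + "]\n"
        )
        fh.write(
            "receptor_reads = ["
            + ", ".join(_q(p) for p in paths["receptor_reads"]) + "]\n"
        )
        fh.write(f"annotation = {_q(paths['annotation'])}\n")
        fh.write(f"contaminants = {_q(paths['contaminants'])}\n")
        fh.write(f"hairpins = {_q(paths['hairpins'])}\n")
        fh.write(f"outdir = {_q(outdir / 'results')}\n")
        fh.write(f"seed = {seed}\n")
    paths["config"] = config_path
    return paths
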