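"""Synthetic heterograft data with known ground truth.

Emulates the inputs of a grafted-plant small-RNA sequencing experiment:
two genomes of the graft partners that differ only at SNP positions,
feature annotations (genes, repeats), small-RNA loci of defined size
classes, and per-compartment read populations carrying a configurable
mobile fraction, replicate structure, sequencing error rate and
contaminant admixture. Every read's provenance (source genome, source
locus, mobility, SNP-spanning status, injected errors) is recorded so
downstream detection can be scored against truth.

Loci come in three classes: 21-nt siRNA loci planted in gene bodies
(post-transcriptional silencing class), 24-nt siRNA loci planted in
2-kb promoters and repeats (the RNA-directed DNA methylation class),
and miRNA hairpin loci whose mature 21-nt reads are substrings of a
hairpin database derived from the genomic context.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from .annotate_compare import derive_promoters
from .seqio import FeatureAnnotation, Interval, ReadRecord
from .sequtils import revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# 3' sequencing adapter (Illumina TruSeq small RNA); chosen aperiodic so
# exact trimming is unambiguous
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

MACHINE_READ_LENGTH = 50

_CLASS_LENGTH = {"siRNA21": 21, "siRNA24": 24, "miRNA_hairpin": 21}


@dataclass
class GenomePair:
    """Two SNP-diverged genomes plus the truth table of divergent sites.

    Sequences have identical lengths per chromosome and differ exactly at
    the snp_table positions (0-based), where donor and receptor alleles
    always differ.
    """

    donor_genome: dict[str, str]
    receptor_genome: dict[str, str]
    snp_table: list[tuple[str, int, str, str]]

    def snp_positions(self) -> dict[str, list[int]]:
        pos: dict[str, list[int]] = {c: [] for c in self.donor_genome}
        for chrom, p, _, _ in self.snp_table:
            pos[chrom].append(p)
        for v in pos.values():
            v.sort()
        return pos

    def genome(self, which: str) -> dict[str, str]:
        if which == "donor":
            return self.donor_genome
        if which == "receptor":
            return self.receptor_genome
        raise ValueError(f"unknown genome: {which}")


@dataclass(frozen=True)
class SimLocus:
    chrom: str
    start: int
    end: int
    strand: str
    locus_class: str  # siRNA21 | siRNA24 | miRNA_hairpin
    expression_weight: float = 1.0

    def __post_init__(self):
        if self.expression_weight <= 0:
            raise ValueError("expression_weight must be positive")
        if self.locus_class not in _CLASS_LENGTH:
            raise ValueError(f"unknown locus class: {self.locus_class}")


@dataclass(frozen=True)
class ReadTruth:
    source_genome: str  # donor | receptor | contaminant
    source_locus: SimLocus | None
    is_mobile: bool
    spans_snp: bool
    n_errors: int


@dataclass
class SimTruth:
    """read_id -> provenance record for every simulated read."""

    records: dict[str, ReadTruth] = field(default_factory=dict)

    def __getitem__(self, read_id: str) -> ReadTruth:
        return self.records[read_id]

    def __len__(self) -> int:
        return len(self.records)

    def mobile_ids(self) -> set[str]:
        return {rid for rid, t in self.records.items() if t.is_mobile}


def simulate_genome_pair(
    n_chromosomes: int, length: int, snp_rate: float, seed: int
) -> GenomePair:
    """Simulate two genomes identical except at i.i.d. per-position SNPs.

    SNPs are placed independently at rate `snp_rate`; at each SNP site
    the receptor allele is drawn uniformly from the 3 non-donor bases.
    Deterministic for a fixed seed.
    """
    if length <= 0:
        raise ValueError("chromosome length must be positive")
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    if not 0.0 <= snp_rate <= 1.0:
        raise ValueError("snp_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    donor: dict[str, str] = {}
    receptor: dict[str, str] = {}
    snp_table: list[tuple[str, int, str, str]] = []
    for ci in range(1, n_chromosomes + 1):
        chrom = f"chr{ci}"
        base_idx = rng.integers(0, 4, size=length)
        donor_seq = _BASES[base_idx].tobytes().decode()
        snp_mask = rng.random(length) < snp_rate
        snp_pos = np.flatnonzero(snp_mask)
        recv_idx = base_idx.copy()
        if len(snp_pos):
            offsets = rng.integers(1, 4, size=len(snp_pos))
            recv_idx[snp_pos] = (recv_idx[snp_pos] + offsets) % 4
        receptor_seq = _BASES[recv_idx].tobytes().decode()
        donor[chrom] = donor_seq
        receptor[chrom] = receptor_seq
        for p in snp_pos:
            p = int(p)
            snp_table.append((chrom, p, donor_seq[p], receptor_seq[p]))
    return GenomePair(donor_genome=donor, receptor_genome=receptor, snp_table=snp_table)


def _place_nonoverlapping(
    rng, chrom_lengths: dict[str, int], n: int, len_lo: int, len_hi: int,
    occupied: dict[str, list[tuple[int, int]]] | None = None,
    max_attempts_per_feature: int = 200,
) -> list[tuple[str, int, int]]:
    """Rejection-sample `n` mutually non-overlapping intervals."""
    taken = {c: list(v) for c, v in (occupied or {}).items()}
    out: list[tuple[str, int, int]] = []
    chroms = sorted(chrom_lengths)
    for _ in range(n):
        placed = False
        for _ in range(max_attempts_per_feature):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            L = int(rng.integers(len_lo, len_hi + 1))
            if chrom_lengths[chrom] <= L:
                continue
            s = int(rng.integers(0, chrom_lengths[chrom] - L))
            e = s + L
            if any(s < te and ts < e for ts, te in taken.get(chrom, ())):
                continue
            taken.setdefault(chrom, []).append((s, e))
            out.append((chrom, s, e))
            placed = True
            break
        if not placed:
            raise ValueError(
                "infeasible packing: cannot place requested features in genome"
            )
    return out


def plant_annotations(
    pair: GenomePair, n_genes: int, n_repeats: int, seed: int,
    gene_length: tuple[int, int] = (300, 1500),
    repeat_length: tuple[int, int] = (150, 800),
) -> FeatureAnnotation:
    """Plant stranded, non-overlapping gene intervals and (possibly
    gene-overlapping) repeat intervals; deterministic per seed. Raises on
    infeasible packing."""
    rng = np.random.default_rng(seed)
    chrom_lengths = {c: len(s) for c, s in pair.donor_genome.items()}
    ann = FeatureAnnotation()
    genes = _place_nonoverlapping(rng, chrom_lengths, n_genes, *gene_length)
    for i, (chrom, s, e) in enumerate(genes, start=1):
        strand = "+" if rng.random() < 0.5 else "-"
        ann.genes.append(Interval(chrom, s, e, strand, f"gene{i:04d}"))
    repeats = _place_nonoverlapping(rng, chrom_lengths, n_repeats, *repeat_length)
    for i, (chrom, s, e) in enumerate(repeats, start=1):
        ann.repeats.append(Interval(chrom, s, e, ".", f"repeat{i:04d}"))
    ann.promoters = derive_promoters(ann.genes, chrom_lengths)
    return ann


def plant_loci(
    pair: GenomePair,
    annotation: FeatureAnnotation,
    n_sirna21: int,
    n_sirna24: int,
    n_mirna: int,
    seed: int,
    min_spacing: int = 300,
    locus_length: tuple[int, int] = (60, 160),
) -> list[SimLocus]:
    """Plant small-RNA loci with the class → feature association of real
    plant genomes: 21-nt siRNA loci inside gene bodies, 24-nt siRNA loci
    inside 2-kb promoters or repeats, miRNA loci anywhere. Loci are kept
    at least `min_spacing` nt apart so each is recoverable as its own
    cluster. Expression weights are drawn uniformly in [0.5, 2]."""
    rng = np.random.default_rng(seed)
    chrom_lengths = {c: len(s) for c, s in pair.donor_genome.items()}
    taken: dict[str, list[tuple[int, int]]] = {}
    loci: list[SimLocus] = []

    def try_plant(chrom: str, lo: int, hi: int, locus_class: str) -> bool:
        L = int(rng.integers(locus_length[0], locus_length[1] + 1))
        if hi - lo <= L:
            return False
        s = int(rng.integers(lo, hi - L))
        e = s + L
        pad_s, pad_e = s - min_spacing, e + min_spacing
        if any(pad_s < te and ts < pad_e for ts, te in taken.get(chrom, ())):
            return False
        taken.setdefault(chrom, []).append((s, e))
        strand = "+" if rng.random() < 0.5 else "-"
        loci.append(
            SimLocus(chrom, s, e, strand, locus_class,
                     expression_weight=float(rng.uniform(0.5, 2.0)))
        )
        return True

    def plant_in(features: list[Interval], n: int, locus_class: str) -> None:
        if n == 0:
            return
        if not features:
            raise ValueError(f"no features available to host {locus_class} loci")
        placed = 0
        attempts = 0
        while placed < n:
            attempts += 1
            if attempts > 500 * n:
                raise ValueError("infeasible packing: cannot place requested loci")
            f = features[int(rng.integers(0, len(features)))]
            if try_plant(f.chrom, f.start, f.end, locus_class):
                placed += 1

    plant_in(annotation.genes, n_sirna21, "siRNA21")
    plant_in(annotation.promoters + annotation.repeats, n_sirna24, "siRNA24")
    # miRNA loci: anywhere on the genome
    placed = 0
    attempts = 0
    chroms = sorted(chrom_lengths)
    while placed < n_mirna:
        attempts += 1
        if attempts > 500 * max(n_mirna, 1):
            raise ValueError("infeasible packing: cannot place requested miRNA loci")
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        if try_plant(chrom, 60, chrom_lengths[chrom] - 60, "miRNA_hairpin"):
            placed += 1
    loci.sort(key=lambda l: (l.chrom, l.start))
    return loci


def hairpin_database(
    pair: GenomePair, loci: list[SimLocus], genome: str = "donor", flank: int = 40
) -> dict[str, str]:
    """Hairpin sequences for the planted miRNA loci: the locus plus
    genomic flanks, mimicking a known-miRNA precursor FASTA."""
    seqs = pair.genome(genome)
    db: dict[str, str] = {}
    i = 0
    for locus in loci:
        if locus.locus_class != "miRNA_hairpin":
            continue
        i += 1
        s = max(0, locus.start - flank)
        e = min(len(seqs[locus.chrom]), locus.end + flank)
        hp = seqs[locus.chrom][s:e]
        db[f"sim-MIR{i:03d}"] = hp if locus.strand == "+" else revcomp(hp)
    return db


def simulate_contaminant_refs(
    seed: int, n_refs: int = 3, length: int = 2000
) -> dict[str, str]:
    """Random reference sequences standing in for rRNA/tRNA and
    chloroplast contaminant databases."""
    rng = np.random.default_rng(seed)
    names = ["rRNA_1", "tRNA_1", "chloroplast"] + [
        f"contam_{i}" for i in range(4, n_refs + 1)
    ]
    return {
        name: _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
        for name in names[:n_refs]
    }


def simulate_reads(
    pair: GenomePair,
    loci: list[SimLocus],
    compartment: str,
    n_reads: int,
    mobile_fraction: float,
    error_rate: float,
    n_replicates: int = 3,
    adapter: str = DEFAULT_ADAPTER,
    contaminant_fraction: float = 0.0,
    contaminant_refs: dict[str, str] | None = None,
    seed: int = 0,
    machine_read_length: int = MACHINE_READ_LENGTH,
    jitter_prob: float = 0.1,
) -> tuple[list[ReadRecord], SimTruth]:
    """Simulate one compartment's machine reads with full provenance.

    Each read is a (possibly error-mutated) substring of its source
    genome at its source locus — the native compartment's genome, or the
    other genome at rate `mobile_fraction` — 3'-extended with the
    adapter (then A-fill) up to the machine read length. Read length is
    the locus class length with ±1 nt jitter at `jitter_prob`.
    Contaminant reads are exact substrings of the contaminant
    references. Replicate labels are assigned round-robin. Deterministic
    per seed (bit-identical output).
    """
    if compartment not in ("donor", "receptor"):
        raise ValueError("compartment must be 'donor' or 'receptor'")
    if not loci:
        raise ValueError("loci must be non-empty")
    for frac, name in (
        (mobile_fraction, "mobile_fraction"),
        (error_rate, "error_rate"),
        (contaminant_fraction, "contaminant_fraction"),
    ):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if contaminant_fraction > 0 and not contaminant_refs:
        raise ValueError("contaminant_fraction > 0 requires contaminant_refs")

    rng = np.random.default_rng(seed)
    native_name = compartment
    other_name = "donor" if compartment == "receptor" else "receptor"
    native = pair.genome(native_name)
    other = pair.genome(other_name)
    snp_pos = pair.snp_positions()

    weights = np.array([l.expression_weight for l in loci], dtype=float)
    weights /= weights.sum()
    locus_idx = rng.choice(len(loci), size=n_reads, p=weights)
    is_contam = rng.random(n_reads) < contaminant_fraction
    is_mobile = (~is_contam) & (rng.random(n_reads) < mobile_fraction)
    jitter_draw = rng.random(n_reads)
    jitter_sign = rng.integers(0, 2, size=n_reads) * 2 - 1
    start_u = rng.random(n_reads)

    contam_names = list(contaminant_refs) if contaminant_refs else []

    reads: list[ReadRecord] = []
    truth = SimTruth()
    bases = "ACGT"
    for i in range(n_reads):
        rid = f"{compartment}_r{i:07d}"
        rep = f"rep{(i % n_replicates) + 1}"
        if is_contam[i]:
            ref = contaminant_refs[contam_names[int(rng.integers(0, len(contam_names)))]]
            L = 21 if jitter_draw[i] < 0.5 else 24
            s = int(start_u[i] * (len(ref) - L))
            insert = ref[s : s + L]
            truth.records[rid] = ReadTruth("contaminant", None, False, False, 0)
        else:
            locus = loci[int(locus_idx[i])]
            L = _CLASS_LENGTH[locus.locus_class]
            if jitter_draw[i] < jitter_prob:
                L += int(jitter_sign[i])
            span = locus.end - locus.start - L + 1
            if span < 1:
                s = locus.start
            else:
                s = locus.start + int(start_u[i] * span)
            genome = other if is_mobile[i] else native
            source = other_name if is_mobile[i] else native_name
            insert = genome[locus.chrom][s : s + L]
            if locus.strand == "-":
                insert = revcomp(insert)
            n_errors = 0
            if error_rate > 0:
                # i.i.d. per-base substitutions (no indels)
                err_mask = rng.random(L) < error_rate
                if err_mask.any():
                    chars = list(insert)
                    for j in np.flatnonzero(err_mask):
                        old = chars[j]
                        chars[j] = bases[(bases.index(old) + int(rng.integers(1, 4))) % 4]
                        n_errors += 1
                    insert = "".join(chars)
            pos = snp_pos.get(locus.chrom, [])
            k = bisect_left(pos, s)
            spans_snp = k < len(pos) and pos[k] < s + L
            truth.records[rid] = ReadTruth(
                source, locus, bool(is_mobile[i]), spans_snp, n_errors
            )
        machine = (insert + adapter).ljust(machine_read_length, "A")[:machine_read_length]
        reads.append(ReadRecord(id=rid, sequence=machine, replicate_label=rep))
    return reads, truth


def annotation_chrom_lengths(pair: GenomePair) -> dict[str, int]:
    return {c: len(s) for c, s in pair.donor_genome.items()}


def truth_to_table(truth: SimTruth):
    """Flatten a SimTruth into a DataFrame for TSV export."""
    import pandas as pd

    rows = []
    for rid, t in truth.records.items():
        rows.append(
            {
                "read_id": rid,
                "source_genome": t.source_genome,
                "source_locus": (
                    f"{t.source_locus.chrom}:{t.source_locus.start}-{t.source_locus.end}"
                    if t.source_locus
                    else ""
                ),
                "locus_class": t.source_locus.locus_class if t.source_locus else "",
                "is_mobile": t.is_mobile,
                "spans_snp": t.spans_snp,
                "n_errors": t.n_errors,
            }
        )
    return pd.DataFrame(rows)
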