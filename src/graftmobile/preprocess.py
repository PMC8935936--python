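"""Read cleaning: adapter trimming, length filter, low-complexity
removal and exact-match decontamination against rRNA/tRNA and
chloroplast references.

The stage order is fixed — trim, length, complexity, contaminants — and
the read count is monotonically non-increasing across stages.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .seqio import ReadRecord
from .sequtils import revcomp, shannon_entropy

DEFAULT_MIN_LEN = 17
DEFAULT_ENTROPY_THRESHOLD = 0.5
DEFAULT_MIN_OVERLAP = 3


def trim_adapter(read: ReadRecord, adapter: str, min_overlap: int = DEFAULT_MIN_OVERLAP) -> ReadRecord:
    """Remove the 3' adapter from a read.

    The earliest position at which either the full adapter occurs, or a
    3'-anchored suffix of the read of length >= min_overlap equals a
    prefix of the adapter, is trimmed together with everything 3' of it.
    Reads with no qualifying match are returned unchanged.
    """
    if not 1 <= min_overlap <= len(adapter):
        raise ValueError("require adapter length >= min_overlap >= 1")
    seq = read.sequence
    n = len(seq)
    for i in range(n - min_overlap + 1):
        suffix = seq[i:]
        if suffix.startswith(adapter) or adapter.startswith(suffix):
            return replace(read, sequence=seq[:i])
    return read


def filter_length(reads, min_len: int = DEFAULT_MIN_LEN):
    """Keep reads of length >= min_len (default 17 nt)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [r for r in reads if len(r.sequence) >= min_len]


def filter_low_complexity(reads, entropy_threshold: float = DEFAULT_ENTROPY_THRESHOLD):
    """Remove reads whose mononucleotide Shannon entropy falls below the
    threshold (in bits on the 0–2 scale); reads at exactly the threshold
    are kept."""
    if not 0.0 <= entropy_threshold <= 2.0:
        raise ValueError("entropy threshold must lie in [0, 2] bits")
    return [r for r in reads if shannon_entropy(r.sequence) >= entropy_threshold]


def filter_contaminants(reads, contaminant_refs: dict[str, str]):
    """Drop reads occurring exactly (either strand) in any contaminant
    reference sequence; returns (kept reads, removed count)."""
    if not contaminant_refs:
        raise ValueError("contaminant references must be non-empty")
    refs = list(contaminant_refs.values())
    kept = []
    removed = 0
    for r in reads:
        seq = r.sequence
        rc = revcomp(seq)
        if any(seq in ref or rc in ref for ref in refs):
            removed += 1
        else:
            kept.append(r)
    return kept, removed


@dataclass
class PreprocessResult:
    reads: list
    stage_counts: dict[str, int]


def preprocess_reads(
    reads,
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_len: int = DEFAULT_MIN_LEN,
    entropy_threshold: float = DEFAULT_ENTROPY_THRESHOLD,
    contaminant_refs: dict[str, str] | None = None,
) -> PreprocessResult:
    """Run the full cleaning pipeline in its fixed order, recording the
    surviving read count after each stage."""
    counts = {"input": len(reads)}
    reads = [trim_adapter(r, adapter, min_overlap) for r in reads]
    counts["trimmed"] = len(reads)
    reads = filter_length(reads, min_len)
    counts["length_filtered"] = len(reads)
    reads = filter_low_complexity(reads, entropy_threshold)
    counts["complexity_filtered"] = len(reads)
    if contaminant_refs:
        reads, removed = filter_contaminants(reads, contaminant_refs)
        counts["decontaminated"] = len(reads)
        counts["contaminants_removed"] = removed
    return PreprocessResult(reads=reads, stage_counts=counts)
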