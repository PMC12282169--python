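"""Read triage: quality/length filtering, downsampling, and k-mer binning.

Raw total-RNA reads from a microbiome sample are overwhelmingly rRNA.
The triage stage (a) drops short/low-quality reads, (b) optionally
downsamples to a fixed budget, and (c) bins the survivors into
``rRNA`` / ``host`` / ``retained`` by canonical k-mer containment against
reference indexes, in priority order. The retained bin is what a
metatranscriptome analysis would actually use; the rRNA bin feeds probe
design.

The classifier is a containment test, not an aligner: a read is assigned
the label of the first index for which the fraction of its (N-free)
k-mers found in the index reaches ``min_hit_fraction``.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .records import ReadRecord, ReferenceSeq, reverse_complement

logger = logging.getLogger(__name__)

CATEGORIES = ("rRNA", "host", "retained")

DEFAULT_K = 21
DEFAULT_MIN_HIT_FRACTION = 0.25


@dataclass
class QCConfig:
    """Read-level quality filter: minimum length and minimum mean Phred."""

    min_length: int = 50
    min_mean_quality: float = 20.0

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.min_mean_quality < 0:
            raise ValueError("min_mean_quality must be >= 0")


@dataclass
class KmerIndex:
    """A set of canonical k-mers from one reference category."""

    k: int
    kmers: Set[str]
    label: str


@dataclass
class PartitionReport:
    """Per-sample read counts and fractions over the triage categories.

    ``fractions`` is ``None`` for an empty sample (rather than NaNs).
    """

    sample_id: str
    counts: Dict[str, int]
    fractions: Optional[Dict[str, float]] = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def rrna_fraction(self) -> float:
        if self.fractions is None:
            raise ValueError(f"sample {self.sample_id!r} is empty; fractions undefined")
        return self.fractions["rRNA"]


def quality_filter(
    reads: Sequence[ReadRecord], cfg: QCConfig
) -> Tuple[List[ReadRecord], int]:
    """Keep reads with length >= min_length and mean Phred >= min_mean_quality.

    Returns ``(kept, removed_count)``; input order is preserved. The filter
    is idempotent.
    """
    kept = [
        r
        for r in reads
        if len(r) >= cfg.min_length and r.mean_quality >= cfg.min_mean_quality
    ]
    return kept, len(reads) - len(kept)


def downsample(reads: Sequence[ReadRecord], n: int, seed: int) -> List[ReadRecord]:
    """Uniform random subset of exactly ``n`` reads, input order preserved.

    Returns all reads when ``n`` is at least the input size. Reproducible for
    a fixed seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= len(reads):
        return list(reads)
    rng = random.Random(seed)
    idx = sorted(rng.sample(range(len(reads)), n))
    return [reads[i] for i in idx]


def _canonical_kmers(seq: str, k: int) -> List[str]:
    """Position-wise canonical k-mers of ``seq``; windows containing a
    non-ACGT character are skipped."""
    rc = reverse_complement(seq)
    n = len(seq)
    out: List[str] = []
    bad = [i for i, c in enumerate(seq) if c not in "ACGT"]
    if bad:
        # running count of bad characters, so each window test is O(1)
        cum = [0] * (n + 1)
        for i in bad:
            cum[i + 1] = 1
        for i in range(n):
            cum[i + 1] += cum[i]
    for i in range(n - k + 1):
        if bad and cum[i + k] - cum[i]:
            continue
        fwd = seq[i : i + k]
        rev = rc[n - k - i : n - i]
        out.append(fwd if fwd <= rev else rev)
    return out


def build_kmer_index(refs: Iterable[ReferenceSeq], k: int, label: str) -> KmerIndex:
    """Index every distinct canonical k-mer occurring in the references."""
    if k < 1:
        raise ValueError("k must be >= 1")
    kmers: Set[str] = set()
    for ref in refs:
        kmers.update(_canonical_kmers(ref.sequence, k))
    return KmerIndex(k=k, kmers=kmers, label=label)


def classify_reads(
    reads: Iterable[ReadRecord],
    indexes: Sequence[KmerIndex],
    min_hit_fraction: float = DEFAULT_MIN_HIT_FRACTION,
) -> Dict[str, str]:
    """Assign each read the label of the first index whose k-mer containment
    fraction reaches ``min_hit_fraction``; otherwise ``"retained"``.

    Containment is counted position-wise over the read's N-free k-mers.
    Reads shorter than k (or all-N) fall through to ``"retained"``.
    """
    if not indexes:
        raise ValueError("at least one KmerIndex is required")
    ks = {idx.k for idx in indexes}
    if len(ks) != 1:
        raise ValueError(f"all indexes must share the same k, got {sorted(ks)}")
    k = ks.pop()
    if not (0 < min_hit_fraction <= 1):
        raise ValueError("min_hit_fraction must be in (0, 1]")

    result: Dict[str, str] = {}
    short = 0
    for read in reads:
        kmers = _canonical_kmers(read.sequence, k) if len(read) >= k else []
        if not kmers:
            if len(read) < k:
                short += 1
            result[read.read_id] = "retained"
            continue
        label = "retained"
        for idx in indexes:
            hits = sum(1 for km in kmers if km in idx.kmers)
            if hits / len(kmers) >= min_hit_fraction:
                label = idx.label
                break
        result[read.read_id] = label
    if short:
        logger.warning("%d reads shorter than k=%d classified as 'retained'", short, k)
    return result


def partition_report(classified: Mapping[str, str], sample_id: str) -> PartitionReport:
    """Tally category counts and fractions for one sample."""
    counts = {cat: 0 for cat in CATEGORIES}
    for read_id, cat in classified.items():
        if cat not in counts:
            raise ValueError(f"read {read_id!r}: unknown category {cat!r}")
        counts[cat] += 1
    total = sum(counts.values())
    if total == 0:
        logger.warning("sample %s: empty classification; fractions undefined", sample_id)
        return PartitionReport(sample_id=sample_id, counts=counts, fractions=None)
    fractions = {cat: counts[cat] / total for cat in CATEGORIES}
    return PartitionReport(sample_id=sample_id, counts=counts, fractions=fractions)


def write_partition_report(report: PartitionReport, path) -> None:
    with open(path, "w") as handle:
        handle.write("sample_id\tcategory\tcount\tfraction\n")
        for cat in CATEGORIES:
            frac = "" if report.fractions is None else f"{report.fractions[cat]:.6f}"
            handle.write(f"{report.sample_id}\t{cat}\t{report.counts[cat]}\t{frac}\n")
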