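"""Synthetic communities, references, reads and alignments with ground truth.

The generator emulates total-RNA sequencing of a mixed microbial community
whose read pool is dominated by rRNA: a small set of abundant rRNA taxa
under a geometric (skewed) abundance distribution, a long tail of rare
rRNA taxa, and optional host and mRNA references making up the rest of
the mass. Read start positions are uniform within the source reference
(no secondary-structure coverage bias), substitution errors are i.i.d.,
and the emitted alignments are the true source intervals — a
perfect-aligner surrogate that decouples the design pipeline from any
third-party aligner.

All randomness flows from one integer seed; per-sample sub-simulations
draw child seeds from the top-level generator, so any sample is
independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .records import AlignmentRecord, ReadRecord, ReferenceSeq

logger = logging.getLogger(__name__)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

# read lengths below the QC minimum / Phred for constructed-to-fail reads
_FAIL_LENGTH = 30
_FAIL_QUALITY = 10


def _encode(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains characters outside ACGT")
    return codes.copy()


def _decode(codes: np.ndarray) -> str:
    return _BASE[codes].tobytes().decode()


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """A uniform random DNA sequence."""
    return _decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def mutate_sequence(seq: str, divergence: float, seed: int) -> str:
    """Substitute each position to a *different* base with probability
    ``divergence``; length preserved, deterministic per seed."""
    if not (0 <= divergence <= 1):
        raise ValueError("divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    codes = _encode(seq)
    mask = rng.random(len(codes)) < divergence
    shifts = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
    codes[mask] = (codes[mask] + shifts) % 4
    return _decode(codes)


@dataclass
class ReadTruth:
    """Ground truth for one simulated read."""

    ref_id: str
    start: int
    end: int
    category: str  # rRNA / host / mRNA
    qc_fail: bool = False


@dataclass
class CommunityTruth:
    """Ground truth for one synthetic sample.

    ``abundances`` are sampling proportions per reference (sum to 1);
    ``categories`` maps ref_id to rRNA/host/mRNA; ``abundant_ref_ids``
    names the deliberately abundant rRNA references; ``read_truth`` is
    filled in by :func:`simulate_reads`.
    """

    references: List[ReferenceSeq]
    abundances: Dict[str, float]
    categories: Dict[str, str]
    abundant_ref_ids: List[str] = field(default_factory=list)
    read_truth: Dict[str, ReadTruth] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, expected 1")
        for ref in self.references:
            if ref.ref_id not in self.abundances:
                raise ValueError(f"reference {ref.ref_id!r} has no abundance")

    @property
    def rrna_fraction(self) -> float:
        return sum(
            a for r, a in self.abundances.items() if self.categories[r] == "rRNA"
        )


def read_categories(truth: CommunityTruth) -> Dict[str, str]:
    """Per-read triage categories (mRNA reads are 'retained')."""
    mapping = {"rRNA": "rRNA", "host": "host", "mRNA": "retained"}
    return {rid: mapping[rt.category] for rid, rt in truth.read_truth.items()}


def _geometric_weights(n: int, skew: float) -> np.ndarray:
    w = np.array([skew ** (n - 1 - i) for i in range(n)], dtype=float)
    return w / w.sum()


def simulate_community(
    n_abundant: int = 3,
    n_rare: int = 40,
    ref_length: int = 1500,
    abundance_skew: float = 1.3,
    divergence_grid: Sequence[float] = (),
    seed: int = 0,
    *,
    rrna_fraction: float = 0.97,
    rare_mass: float = 0.05,
    n_host: int = 0,
    n_mrna: int = 0,
    host_fraction: float = 0.01,
    host_length: int = 2000,
    mrna_length: int = 1000,
    id_prefix: str = "",
) -> CommunityTruth:
    """Generate a community with known abundance and identity structure.

    Abundant rRNA references get geometric weights with consecutive ratio
    ``abundance_skew`` (e.g. skew 2 over five taxa gives 16:8:4:2:1); each
    entry of ``divergence_grid`` appends a mutated copy of an abundant
    reference, planting a pair of known pairwise identity ~ 1 - divergence
    to exercise redundancy filtering. Rare rRNA taxa share ``rare_mass`` of
    the rRNA mass uniformly. When host/mRNA references are requested, rRNA
    takes ``rrna_fraction`` of the total mass; otherwise it takes all of it.
    """
    if n_abundant + n_rare < 1:
        raise ValueError("need at least one reference")
    rng = np.random.default_rng(seed)

    abundant: List[ReferenceSeq] = []
    for i in range(n_abundant):
        abundant.append(
            ReferenceSeq(
                ref_id=f"{id_prefix}rRNA_ab{i + 1:02d}",
                sequence=random_sequence(ref_length, rng),
                taxon=f"{id_prefix}Taxon_{i + 1:02d}",
            )
        )
    for j, div in enumerate(divergence_grid):
        if not abundant:
            raise ValueError("divergence_grid requires at least one abundant reference")
        source = abundant[j % n_abundant]
        child_seed = int(rng.integers(0, 2**31 - 1))
        abundant.append(
            ReferenceSeq(
                ref_id=f"{id_prefix}rRNA_div{j + 1:02d}",
                sequence=mutate_sequence(source.sequence, div, child_seed),
                taxon=f"{id_prefix}Taxon_div{j + 1:02d}",
            )
        )

    rare = [
        ReferenceSeq(
            ref_id=f"{id_prefix}rRNA_rare{i + 1:02d}",
            sequence=random_sequence(ref_length, rng),
            taxon=f"{id_prefix}Taxon_rare{i + 1:02d}",
        )
        for i in range(n_rare)
    ]
    hosts = [
        ReferenceSeq(
            ref_id=f"{id_prefix}host_tx{i + 1:02d}",
            sequence=random_sequence(host_length, rng),
            taxon="Host",
        )
        for i in range(n_host)
    ]
    mrnas = [
        ReferenceSeq(
            ref_id=f"{id_prefix}mRNA{i + 1:02d}",
            sequence=random_sequence(mrna_length, rng),
            taxon=f"{id_prefix}Taxon_m{i + 1:02d}",
        )
        for i in range(n_mrna)
    ]

    abundances: Dict[str, float] = {}
    categories: Dict[str, str] = {}
    rrna_mass = rrna_fraction if (n_host + n_mrna) > 0 else 1.0
    abundant_mass = rrna_mass * (1.0 - rare_mass) if rare else rrna_mass
    if abundant:
        for ref, w in zip(abundant, _geometric_weights(len(abundant), abundance_skew)):
            abundances[ref.ref_id] = abundant_mass * w
            categories[ref.ref_id] = "rRNA"
    for ref in rare:
        abundances[ref.ref_id] = (rrna_mass - (abundant_mass if abundant else 0.0)) / len(rare)
        categories[ref.ref_id] = "rRNA"
    other_mass = 1.0 - rrna_mass
    host_mass = min(host_fraction, other_mass) if hosts else 0.0
    if mrnas:
        mrna_mass = other_mass - host_mass
    else:
        host_mass = other_mass if hosts else 0.0
        mrna_mass = 0.0
    for ref in hosts:
        abundances[ref.ref_id] = host_mass / len(hosts)
        categories[ref.ref_id] = "host"
    for ref in mrnas:
        abundances[ref.ref_id] = mrna_mass / len(mrnas)
        categories[ref.ref_id] = "mRNA"

    references = abundant + rare + hosts + mrnas
    # guard against drift from the min() above
    total = sum(abundances.values())
    abundances = {k: v / total for k, v in abundances.items()}
    return CommunityTruth(
        references=references,
        abundances=abundances,
        categories=categories,
        abundant_ref_ids=[r.ref_id for r in abundant],
    )


def simulate_reads(
    truth: CommunityTruth,
    n_reads: int,
    read_length: int = 150,
    error_rate: float = 0.0,
    quality_model: Tuple[float, float] = (36, 0.0),
    seed: int = 0,
    sample_id: str = "S1",
) -> Tuple[List[ReadRecord], List[AlignmentRecord]]:
    """Draw reads from the community and emit truth-interval alignments.

    Source references are chosen proportionally to abundance, start
    positions uniformly within the reference; substitution errors are
    applied at ``error_rate``. ``quality_model`` is ``(mean_phred,
    fail_fraction)``: that fraction of reads is constructed to fail the
    standard length-50/Q20 filter (alternating between truncation to 30 nt
    and constant Q10 qualities) and flagged ``qc_fail`` in the truth.
    ``truth.read_truth`` is updated in place.
    """
    refs = truth.references
    min_len = min(len(r) for r in refs)
    if read_length > min_len:
        raise ValueError(
            f"read_length {read_length} exceeds shortest reference length {min_len}"
        )
    mean_phred, fail_fraction = quality_model
    if not (0 <= fail_fraction <= 1):
        raise ValueError("fail fraction must be in [0, 1]")
    if n_reads == 0:
        return [], []

    rng = np.random.default_rng(seed)
    probs = np.array([truth.abundances[r.ref_id] for r in refs])
    ref_idx = rng.choice(len(refs), size=n_reads, p=probs)
    lengths = np.array([len(r) for r in refs])
    starts = rng.integers(0, lengths[ref_idx] - read_length + 1)

    codes = np.empty((n_reads, read_length), dtype=np.uint8)
    window = np.arange(read_length)
    encoded = {ri: _encode(refs[ri].sequence) for ri in np.unique(ref_idx)}
    for ri, ref_codes in encoded.items():
        mask = ref_idx == ri
        codes[mask] = ref_codes[starts[mask][:, None] + window]

    if error_rate > 0:
        err = rng.random(codes.shape) < error_rate
        shifts = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        codes[err] = (codes[err] + shifts) % 4

    fail = rng.random(n_reads) < fail_fraction

    payload = _BASE[codes].tobytes()
    qual_good = np.full(read_length, int(mean_phred), dtype=np.int64)
    qual_low = np.full(read_length, _FAIL_QUALITY, dtype=np.int64)
    qual_short = np.full(_FAIL_LENGTH, int(mean_phred), dtype=np.int64)

    reads: List[ReadRecord] = []
    alignments: List[AlignmentRecord] = []
    fail_rank = 0
    for i in range(n_reads):
        read_id = f"{sample_id}_r{i + 1}"
        seq = payload[i * read_length : (i + 1) * read_length].decode()
        start = int(starts[i])
        if fail[i]:
            if fail_rank % 2 == 0:  # too short
                seq = seq[:_FAIL_LENGTH]
                qual = qual_short
            else:  # too low-quality
                qual = qual_low
            fail_rank += 1
        else:
            qual = qual_good
        end = start + len(seq)
        ref = refs[ref_idx[i]]
        reads.append(ReadRecord(read_id=read_id, sequence=seq, qualities=qual))
        alignments.append(
            AlignmentRecord(read_id=read_id, ref_id=ref.ref_id, ref_start=start, ref_end=end)
        )
        truth.read_truth[read_id] = ReadTruth(
            ref_id=ref.ref_id,
            start=start,
            end=end,
            category=truth.categories[ref.ref_id],
            qc_fail=bool(fail[i]),
        )
    return reads, alignments


@dataclass
class SampleData:
    """One synthetic sample: reads, truth-interval alignments, ground truth."""

    sample_id: str
    reads: List[ReadRecord]
    alignments: List[AlignmentRecord]
    truth: CommunityTruth


def make_learning_set(
    n_samples: int = 7,
    shared_taxa_fraction: float = 0.6,
    rrna_frac_range: Tuple[float, float] = (0.32, 0.55),
    seed: int = 0,
    *,
    n_reads: int = 150_000,
    read_length: int = 150,
    n_abundant: int = 3,
    n_rare: int = 40,
    ref_length: int = 1500,
    abundance_skew: float = 1.3,
    rare_mass: float = 0.05,
    host_fraction: float = 0.01,
    n_host: int = 1,
    n_mrna: int = 10,
    host_length: int = 2000,
    mrna_length: int = 1000,
    error_rate: float = 0.0,
    quality_model: Tuple[float, float] = (36, 0.0),
) -> List[SampleData]:
    """Generate a multi-sample learning set with a shared abundant core.

    All samples share the abundant rRNA taxa (so equivalent regions exist
    to combine across samples) plus ``shared_taxa_fraction`` of the rare
    taxa; the remaining rare taxa are sample-private. Each sample's rRNA
    read fraction is drawn uniformly within ``rrna_frac_range``. Fully
    seeded: child seeds for each sample derive from the top-level seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    lo, hi = rrna_frac_range
    if not (0 < lo <= hi < 1):
        raise ValueError("rrna_frac_range must satisfy 0 < low <= high < 1")
    if not (0 <= shared_taxa_fraction <= 1):
        raise ValueError("shared_taxa_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    shared_abundant = [
        ReferenceSeq(
            ref_id=f"rRNA_ab{i + 1:02d}",
            sequence=random_sequence(ref_length, rng),
            taxon=f"Taxon_{i + 1:02d}",
        )
        for i in range(n_abundant)
    ]
    n_shared_rare = int(round(shared_taxa_fraction * n_rare))
    shared_rare = [
        ReferenceSeq(
            ref_id=f"rRNA_rare{i + 1:02d}",
            sequence=random_sequence(ref_length, rng),
            taxon=f"Taxon_rare{i + 1:02d}",
        )
        for i in range(n_shared_rare)
    ]
    hosts = [
        ReferenceSeq(
            ref_id=f"host_tx{i + 1:02d}",
            sequence=random_sequence(host_length, rng),
            taxon="Host",
        )
        for i in range(n_host)
    ]
    mrnas = [
        ReferenceSeq(
            ref_id=f"mRNA{i + 1:02d}",
            sequence=random_sequence(mrna_length, rng),
            taxon=f"Taxon_m{i + 1:02d}",
        )
        for i in range(n_mrna)
    ]

    samples: List[SampleData] = []
    for s in range(n_samples):
        sample_id = f"S{s + 1}"
        n_private = n_rare - n_shared_rare
        private = [
            ReferenceSeq(
                ref_id=f"{sample_id}_rare{i + 1:02d}",
                sequence=random_sequence(ref_length, rng),
                taxon=f"{sample_id}_Taxon_rare{i + 1:02d}",
            )
            for i in range(n_private)
        ]
        rrna_frac = float(rng.uniform(lo, hi))

        abundances: Dict[str, float] = {}
        categories: Dict[str, str] = {}
        weights = _geometric_weights(n_abundant, abundance_skew)
        abundant_mass = rrna_frac * (1.0 - rare_mass)
        for ref, w in zip(shared_abundant, weights):
            abundances[ref.ref_id] = abundant_mass * w
            categories[ref.ref_id] = "rRNA"
        rare_refs = shared_rare + private
        for ref in rare_refs:
            abundances[ref.ref_id] = rrna_frac * rare_mass / len(rare_refs)
            categories[ref.ref_id] = "rRNA"
        for ref in hosts:
            abundances[ref.ref_id] = host_fraction / len(hosts)
            categories[ref.ref_id] = "host"
        mrna_mass = 1.0 - rrna_frac - (host_fraction if hosts else 0.0)
        for ref in mrnas:
            abundances[ref.ref_id] = mrna_mass / len(mrnas)
            categories[ref.ref_id] = "mRNA"

        truth = CommunityTruth(
            references=shared_abundant + rare_refs + hosts + mrnas,
            abundances=abundances,
            categories=categories,
            abundant_ref_ids=[r.ref_id for r in shared_abundant],
        )
        child_seed = int(rng.integers(0, 2**31 - 1))
        reads, alignments = simulate_reads(
            truth,
            n_reads,
            read_length=read_length,
            error_rate=error_rate,
            quality_model=quality_model,
            seed=child_seed,
            sample_id=sample_id,
        )
        samples.append(
            SampleData(sample_id=sample_id, reads=reads, alignments=alignments, truth=truth)
        )
    return samples


def sample_abundant_regions(
    sample: "SampleData",
    min_depth: float = 500.0,
    min_region_length: int = 50,
    merge_gap: int = 0,
):
    """Abundant regions of one synthetic sample, using truth categories.

    Truth read labels stand in for the rRNA binning step: only reads whose
    source reference is rRNA contribute to the pileup.
    """
    from .coverage_regions import compute_coverage, extract_regions

    cats = read_categories(sample.truth)
    rrna_refs = [
        r for r in sample.truth.references if sample.truth.categories[r.ref_id] == "rRNA"
    ]
    rrna_alignments = [a for a in sample.alignments if cats.get(a.read_id) == "rRNA"]
    tracks = compute_coverage(rrna_alignments, rrna_refs)
    regions = []
    for ref in rrna_refs:
        regions.extend(
            extract_regions(
                tracks[ref.ref_id],
                ref,
                min_depth=min_depth,
                min_region_length=min_region_length,
                merge_gap=merge_gap,
                sample_id=sample.sample_id,
            )
        )
    return regions


def expected_abundant_intervals(
    truths: Sequence[CommunityTruth],
    n_reads: int,
    read_length: int,
    min_depth: float,
) -> Dict[str, List[Tuple[int, int]]]:
    """Closed-form ground-truth abundant intervals.

    For each shared abundant reference, the expected per-base depth under
    uniform read starts is ``n_reads * abundance * c(x) / (L - l + 1)``
    where ``c(x)`` counts start positions whose read covers x (the depth
    ramps linearly over the first and last read-length bases). The truth
    interval is where the maximum expected depth across samples exceeds
    ``min_depth``.
    """
    ref_lengths: Dict[str, int] = {}
    max_ab: Dict[str, float] = {}
    for truth in truths:
        for rid in truth.abundant_ref_ids:
            ref = next(r for r in truth.references if r.ref_id == rid)
            ref_lengths[rid] = len(ref)
            max_ab[rid] = max(max_ab.get(rid, 0.0), truth.abundances[rid])

    out: Dict[str, List[Tuple[int, int]]] = {}
    for rid, length in ref_lengths.items():
        n_starts = length - read_length + 1
        x = np.arange(length)
        covering = np.minimum(x, length - read_length) - np.maximum(0, x - read_length + 1) + 1
        expected = n_reads * max_ab[rid] * covering / n_starts
        mask = np.concatenate(([False], expected > min_depth, [False]))
        edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
        out[rid] = list(zip(edges[0::2].tolist(), edges[1::2].tolist()))
    return out
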