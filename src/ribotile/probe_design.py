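"""Abundance-guided, taxonomy-neutral antisense probe design.

The design pipeline turns per-sample abundant rRNA regions into a single
oligo pool:

1. rank each sample's regions by median coverage depth and keep the top N;
2. pool the selections across samples (provenance preserved);
3. collapse redundancy — any two regions with >= 80% global-alignment
   identity are considered equivalent, and exactly one representative per
   connected component of the similarity graph is kept, chosen uniformly
   at random under an explicit seed;
4. tile each retained region with fixed-length antisense probes (50 nt by
   default) spaced a configurable gap apart (25-50 nt).

Probe count trades off against depletion stringency through two knobs:
the number of regions kept per sample (``top_n``) and the inter-probe
spacing (``gap``). ``design_matrix`` sweeps both and reports the probe
count per combination; pools are named ``<top_n><gap>`` (e.g. a "5050"
pool uses the top 50 regions spaced 50 nt apart).

Pairwise identity is scored by global alignment with match +1,
mismatch -1, gap -1 (end gaps penalised), identity = matched columns /
total alignment columns. A cheap edit-distance bound (edlib) screens out
pairs that cannot possibly reach the threshold before the full alignment
is computed; the screen is conservative, so the similarity graph is
identical to the one the full all-pairs computation would build.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import edlib
import pandas as pd
import yaml
from Bio import Align

from .coverage_regions import AbundantRegion
from .read_triage import PartitionReport
from .records import ProbeRecord, default_probe_id, reverse_complement

logger = logging.getLogger(__name__)

TOP_N_GRID = (20, 25, 30, 50)
GAP_GRID = (25, 30, 35, 40, 45, 50)


@dataclass
class DesignConfig:
    """All tunable parameters of the probe design pipeline."""

    coverage_min: float = 500.0
    top_n: int = 20
    gap: int = 25
    probe_length: int = 50
    identity_threshold: float = 0.80
    learning_set_min_rrna_frac: float = 0.30
    max_pool_size: int = 384
    seed: int = 0
    merge_gap: int = 0
    min_region_length: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.identity_threshold <= 1):
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.probe_length < 1:
            raise ValueError("probe_length must be >= 1")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "DesignConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ProbeSet:
    """A designed probe pool with its generating configuration and provenance."""

    probes: List[ProbeRecord]
    config: Optional[DesignConfig] = None
    provenance: Dict[str, Tuple[str, int, int, str]] = field(default_factory=dict)
    report: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.probe_id for p in self.probes]
        if len(ids) != len(set(ids)):
            raise ValueError("probe ids must be unique within a ProbeSet")

    def __len__(self) -> int:
        return len(self.probes)


def select_learning_samples(
    reports: Iterable[PartitionReport], min_rrna_frac: float = 0.30
) -> List[str]:
    """Samples whose rRNA read fraction strictly exceeds the threshold,
    in descending rRNA-fraction order."""
    eligible = [
        (r.fractions["rRNA"], r.sample_id)
        for r in reports
        if r.fractions is not None and r.fractions["rRNA"] > min_rrna_frac
    ]
    eligible.sort(key=lambda t: (-t[0], t[1]))
    if not eligible:
        logger.warning("no samples exceed rRNA fraction %.2f", min_rrna_frac)
    return [sample_id for _, sample_id in eligible]


def rank_and_select(regions: Sequence[AbundantRegion], top_n: int) -> List[AbundantRegion]:
    """Top-N regions by median depth, descending; ties broken by
    (ref_id, start) ascending."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    ranked = sorted(regions, key=lambda r: (-r.median_depth, r.ref_id, r.start))
    return ranked[:top_n]


def pool_samples(per_sample_selections: Iterable[Sequence[AbundantRegion]]) -> List[AbundantRegion]:
    """Concatenate per-sample selections; provenance (sample_id) preserved,
    no merging or dedup at this stage."""
    pooled: List[AbundantRegion] = []
    for selection in per_sample_selections:
        pooled.extend(selection)
    return pooled


_ALIGNER: Optional[Align.PairwiseAligner] = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1
        a.mismatch_score = -1
        a.open_gap_score = -1
        a.extend_gap_score = -1
        _ALIGNER = a
    return _ALIGNER


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical columns in an optimal global alignment.

    Scoring: match +1, mismatch -1, gap -1 (end gaps penalised). The
    denominator counts every alignment column, gaps included. Symmetric.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    aln = _aligner().align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def _identity_upper_bound(a: str, b: str) -> float:
    """An upper bound on the global-alignment identity of (a, b).

    Any alignment's mismatch+gap column count is at least the Levenshtein
    distance, and its column count is at most len(a)+len(b), so
    identity <= 1 - d/(len(a)+len(b)). Used only to skip hopeless pairs.
    """
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / (len(a) + len(b))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def deduplicate_regions(
    regions: Sequence[AbundantRegion],
    identity_threshold: float = 0.80,
    seed: int = 0,
) -> List[AbundantRegion]:
    """Collapse mutually similar regions to one representative each.

    Two regions are linked when their pairwise identity reaches the
    threshold; from every connected component of the resulting graph
    exactly one region is retained, chosen uniformly at random with the
    given seed. Output preserves input order. Deterministic per seed.
    """
    n = len(regions)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if uf.find(i) == uf.find(j):
                continue
            a, b = regions[i].sequence, regions[j].sequence
            if _identity_upper_bound(a, b) < identity_threshold:
                continue
            if pairwise_identity(a, b) >= identity_threshold:
                uf.union(i, j)

    components: Dict[int, List[int]] = {}
    for i in range(n):
        components.setdefault(uf.find(i), []).append(i)

    rng = random.Random(seed)
    chosen: List[int] = []
    # components visited in order of their first member, members in input
    # order, so the random draws are reproducible
    for root in sorted(components):
        chosen.append(rng.choice(components[root]))
    return [regions[i] for i in sorted(chosen)]


def tile_probes(
    region: AbundantRegion, probe_length: int = 50, gap: int = 25
) -> List[ProbeRecord]:
    """Place antisense probes left-to-right from the region's 5' end.

    Stride is ``probe_length + gap``; a trailing stretch shorter than one
    probe is not tiled. Each probe sequence is the reverse complement of its
    sense-strand target window.
    """
    if probe_length < 1:
        raise ValueError("probe_length must be >= 1")
    if gap < 0:
        raise ValueError("gap must be >= 0")
    length = len(region)
    if length < probe_length:
        return []
    stride = probe_length + gap
    count = (length - probe_length) // stride + 1
    probes: List[ProbeRecord] = []
    for i in range(count):
        offset = i * stride
        start = region.start + offset
        end = start + probe_length
        window = region.sequence[offset : offset + probe_length]
        probes.append(
            ProbeRecord(
                probe_id=default_probe_id(region.ref_id, start, end),
                ref_id=region.ref_id,
                target_start=start,
                target_end=end,
                sequence=reverse_complement(window),
            )
        )
    return probes


def design_probe_set(
    per_sample_regions: Sequence[Sequence[AbundantRegion]],
    cfg: DesignConfig,
) -> ProbeSet:
    """Full design pipeline: rank/select per sample, pool, deduplicate, tile.

    A probe count above ``cfg.max_pool_size`` is a warning, not an error
    (the cap reflects synthesis economics, not correctness).
    """
    selected = [rank_and_select(regions, cfg.top_n) for regions in per_sample_regions]
    pooled = pool_samples(selected)
    retained = deduplicate_regions(pooled, cfg.identity_threshold, cfg.seed)

    probes: List[ProbeRecord] = []
    provenance: Dict[str, Tuple[str, int, int, str]] = {}
    seen_ids: Dict[str, int] = {}
    for region in retained:
        for probe in tile_probes(region, cfg.probe_length, cfg.gap):
            if probe.probe_id in seen_ids:
                # two retained regions tiled the same window; disambiguate
                seen_ids[probe.probe_id] += 1
                probe = replace(
                    probe, probe_id=f"{probe.probe_id}_{seen_ids[probe.probe_id]}"
                )
            else:
                seen_ids[probe.probe_id] = 1
            probes.append(probe)
            provenance[probe.probe_id] = (
                region.ref_id,
                region.start,
                region.end,
                region.sample_id,
            )

    report = {
        "n_input_regions": [len(r) for r in per_sample_regions],
        "n_selected": [len(s) for s in selected],
        "n_pooled": len(pooled),
        "n_retained": len(retained),
        "n_probes": len(probes),
    }
    if not pooled:
        logger.warning("design received no regions; emitting an empty probe set")
    if len(probes) > cfg.max_pool_size:
        logger.warning(
            "probe count %d exceeds pool-size target %d", len(probes), cfg.max_pool_size
        )
    return ProbeSet(probes=probes, config=cfg, provenance=provenance, report=report)


def pool_name(top_n: int, gap: int) -> str:
    """Pool naming convention: ``<top_n><gap>`` (e.g. 5050, 2025)."""
    return f"{top_n}{gap}"


def design_matrix(
    per_sample_regions: Sequence[Sequence[AbundantRegion]],
    top_n_options: Sequence[int] = TOP_N_GRID,
    gap_options: Sequence[int] = GAP_GRID,
    cfg: Optional[DesignConfig] = None,
) -> pd.DataFrame:
    """Probe counts over the (top_n, gap) design grid, shared seed.

    Each cell equals an independent ``design_probe_set`` run with that
    (top_n, gap); since deduplication depends only on top_n and the seed,
    it is computed once per row. Rows are top_n, columns are gap.
    """
    if not top_n_options or not gap_options:
        raise ValueError("top_n_options and gap_options must be nonempty")
    cfg = cfg or DesignConfig()
    counts = pd.DataFrame(
        index=pd.Index(list(top_n_options), name="top_n"),
        columns=pd.Index(list(gap_options), name="gap"),
        dtype="int64",
    )
    for top_n in top_n_options:
        selected = [rank_and_select(regions, top_n) for regions in per_sample_regions]
        retained = deduplicate_regions(
            pool_samples(selected), cfg.identity_threshold, cfg.seed
        )
        for gap in gap_options:
            counts.loc[top_n, gap] = sum(
                len(tile_probes(r, cfg.probe_length, gap)) for r in retained
            )
    return counts.astype("int64")
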