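"""In-silico assessment of a probe pool and of sample composition.

Depletion is modelled as pure interval overlap: a read is removed when any
of its alignment intervals overlaps any probe target by at least
``min_overlap`` bases (default 25, half a probe). No hybridisation
thermodynamics or mismatch tolerance is modelled — the surrogate is
deliberately transparent so results can be checked against a brute-force
interval scan.

Also provided: Shannon diversity of a taxon profile (natural log),
total-sum scaling of abundance tables (each sample column normalised to
sum to 1), and rank/linear profile correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .read_triage import CATEGORIES
from .records import AlignmentRecord, ProbeRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 25


@dataclass
class DepletionReport:
    """Before/after category tallies for a simulated depletion."""

    reads_before: Dict[str, int]
    reads_after: Dict[str, int]
    depleted_read_count: int
    rrna_fraction_before: float
    rrna_fraction_after: float
    retained_fraction_after: float


def _probe_intervals(probes) -> Dict[str, np.ndarray]:
    if hasattr(probes, "probes"):
        probes = probes.probes
    by_ref: Dict[str, List[Tuple[int, int]]] = {}
    for p in probes:
        by_ref.setdefault(p.ref_id, []).append((p.target_start, p.target_end))
    return {ref: np.asarray(ivals, dtype=np.int64) for ref, ivals in by_ref.items()}


def insilico_depletion(
    alignments: Iterable[AlignmentRecord],
    categories: Mapping[str, str],
    probes,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> DepletionReport:
    """Tally reads removed by probe/alignment interval overlap.

    ``categories`` maps every read to rRNA/host/retained; reads with no
    alignment are never depleted. Fractions are computed on the pre- and
    post-depletion totals respectively.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    targets = _probe_intervals(probes)

    depleted: set = set()
    for aln in alignments:
        if aln.read_id in depleted:
            continue
        ivals = targets.get(aln.ref_id)
        if ivals is None:
            continue
        overlap = np.minimum(aln.ref_end, ivals[:, 1]) - np.maximum(aln.ref_start, ivals[:, 0])
        if (overlap >= min_overlap).any():
            if aln.read_id not in categories:
                logger.warning("alignment for unknown read %r ignored", aln.read_id)
                continue
            depleted.add(aln.read_id)

    before = {cat: 0 for cat in CATEGORIES}
    after = {cat: 0 for cat in CATEGORIES}
    for read_id, cat in categories.items():
        before[cat] += 1
        if read_id not in depleted:
            after[cat] += 1

    total_before = sum(before.values())
    total_after = sum(after.values())
    return DepletionReport(
        reads_before=before,
        reads_after=after,
        depleted_read_count=len(depleted),
        rrna_fraction_before=before["rRNA"] / total_before if total_before else 0.0,
        rrna_fraction_after=after["rRNA"] / total_after if total_after else 0.0,
        retained_fraction_after=after["retained"] / total_after if total_after else 0.0,
    )


def probe_target_footprint(probes, bridge_gap: int = 0) -> Dict[str, List[Tuple[int, int]]]:
    """Union of probe target intervals per reference, merging gaps up to
    ``bridge_gap`` bases (e.g. the design spacing) into one footprint."""
    merged: Dict[str, List[Tuple[int, int]]] = {}
    for ref, ivals in _probe_intervals(probes).items():
        ivals = ivals[np.lexsort((ivals[:, 1], ivals[:, 0]))]
        out: List[List[int]] = []
        for start, end in ivals.tolist():
            if out and start - out[-1][1] <= bridge_gap:
                out[-1][1] = max(out[-1][1], end)
            else:
                out.append([start, end])
        merged[ref] = [(s, e) for s, e in out]
    return merged


def probe_target_coverage(
    probes,
    truth_intervals: Mapping[str, Sequence[Tuple[int, int]]],
    bridge_gap: int = 0,
) -> float:
    """Fraction of truth-interval bases inside the probe footprint.

    ``truth_intervals`` maps ref_id to disjoint intervals (e.g. the spans a
    generator made genuinely abundant). With ``bridge_gap`` set to the
    design spacing, the inter-probe gaps inside a tiled region count as
    covered.
    """
    footprint = probe_target_footprint(probes, bridge_gap=bridge_gap)
    total = 0
    covered = 0
    for ref, intervals in truth_intervals.items():
        spans = footprint.get(ref, [])
        for t_start, t_end in intervals:
            total += t_end - t_start
            for s, e in spans:
                covered += max(0, min(t_end, e) - max(t_start, s))
    if total == 0:
        raise ValueError("truth intervals are empty")
    return covered / total


def shannon_index(profile: Mapping[str, float]) -> float:
    """Shannon diversity H = -sum p_i ln p_i over taxa with positive counts.

    Natural log. Uniform over K taxa gives ln K; a single taxon gives 0.
    """
    counts = np.asarray([c for c in profile.values()], dtype=float)
    if counts.size == 0 or (counts < 0).any() or counts.sum() <= 0:
        raise ValueError("profile must contain non-negative counts with a positive total")
    return float(stats.entropy(counts))


def tss_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Total-sum scaling: divide each sample column by its own sum.

    Column sums become 1; within-column ratios are preserved; idempotent.
    """
    if (table.to_numpy() < 0).any():
        raise ValueError("abundance table must be non-negative")
    sums = table.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample column(s): {list(zero.index)}")
    return table.div(sums, axis=1)


def compare_profiles(a, b, method: str = "spearman") -> float:
    """Spearman (average ranks for ties) or Pearson correlation of two
    paired abundance vectors over the same feature set."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be 1-D vectors over the same feature set")
    if a.size < 3:
        raise ValueError("need at least 3 features")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant profile")
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    raise ValueError(f"unknown method {method!r}")


def write_depletion_report(report: DepletionReport, path, header: str = "") -> None:
    with open(path, "w") as handle:
        if header:
            handle.write(f"# {header}\n")
        handle.write("category\treads_before\treads_after\n")
        for cat in CATEGORIES:
            handle.write(f"{cat}\t{report.reads_before[cat]}\t{report.reads_after[cat]}\n")
        handle.write(f"# depleted_read_count={report.depleted_read_count}\n")
        handle.write(f"# rrna_fraction_before={report.rrna_fraction_before:.6f}\n")
        handle.write(f"# rrna_fraction_after={report.rrna_fraction_after:.6f}\n")
        handle.write(f"# retained_fraction_after={report.retained_fraction_after:.6f}\n")
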