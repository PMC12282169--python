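"""Per-base coverage pileup and abundant-region extraction.

rRNA reads aligned to a reference set produce a depth track per reference.
Contiguous runs of positions whose depth strictly exceeds a threshold
(>500x by default) are the "abundant regions" that seed probe design; runs
separated by at most ``merge_gap`` positions are bridged, and merged runs
shorter than ``min_region_length`` are discarded. Each surviving region
carries its sense-strand sequence and the median depth over its own
positions — median depth is the ranking statistic used downstream.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .records import AlignmentRecord, FormatError, ReferenceSeq

logger = logging.getLogger(__name__)

DEFAULT_MIN_DEPTH = 500
DEFAULT_MIN_REGION_LENGTH = 50
DEFAULT_MERGE_GAP = 0

REGION_TSV_COLUMNS = ["ref_id", "start", "end", "median_depth", "sample_id", "sequence"]


@dataclass
class CoverageTrack:
    """Per-base alignment depth over one reference."""

    ref_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D array")
        if (self.depth < 0).any():
            raise ValueError("depth must be non-negative")


@dataclass
class AbundantRegion:
    """A contiguous high-depth interval on a reference (sense strand)."""

    ref_id: str
    start: int
    end: int
    sequence: str
    median_depth: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region interval [{self.start}, {self.end})")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"region {self.ref_id}:{self.start}-{self.end}: sequence length "
                f"{len(self.sequence)} != span {self.end - self.start}"
            )

    def __len__(self) -> int:
        return self.end - self.start


def compute_coverage(
    alignments: Iterable[AlignmentRecord], refs: Sequence[ReferenceSeq]
) -> Dict[str, CoverageTrack]:
    """Pileup: ``depth[i]`` = number of alignment intervals containing i.

    Every reference gets a track (possibly all-zero). An alignment to an
    unknown reference, or out of bounds, is an error.
    """
    lengths = {r.ref_id: len(r.sequence) for r in refs}
    diffs = {ref_id: np.zeros(n + 1, dtype=np.int64) for ref_id, n in lengths.items()}
    for aln in alignments:
        if aln.ref_id not in diffs:
            raise KeyError(f"alignment {aln.read_id!r} names unknown reference {aln.ref_id!r}")
        if aln.ref_end > lengths[aln.ref_id]:
            raise FormatError(
                f"alignment {aln.read_id!r} interval [{aln.ref_start}, {aln.ref_end}) "
                f"exceeds reference {aln.ref_id!r} length {lengths[aln.ref_id]}"
            )
        diffs[aln.ref_id][aln.ref_start] += 1
        diffs[aln.ref_id][aln.ref_end] -= 1
    return {
        ref_id: CoverageTrack(ref_id=ref_id, depth=np.cumsum(diff[:-1]))
        for ref_id, diff in diffs.items()
    }


def _runs_above(depth: np.ndarray, min_depth: float) -> List[Tuple[int, int]]:
    """Maximal runs of positions with depth strictly greater than min_depth."""
    mask = np.concatenate(([False], depth > min_depth, [False]))
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    return list(zip(edges[0::2].tolist(), edges[1::2].tolist()))


def _merge_runs(runs: List[Tuple[int, int]], merge_gap: int) -> List[Tuple[int, int]]:
    if not runs:
        return []
    merged = [list(runs[0])]
    for start, end in runs[1:]:
        if start - merged[-1][1] <= merge_gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def extract_regions(
    track: CoverageTrack,
    ref: ReferenceSeq,
    min_depth: float = DEFAULT_MIN_DEPTH,
    min_region_length: int = DEFAULT_MIN_REGION_LENGTH,
    merge_gap: int = DEFAULT_MERGE_GAP,
    sample_id: str = "",
) -> List[AbundantRegion]:
    """Extract abundant regions from one coverage track.

    Positions must satisfy ``depth > min_depth`` (strict, matching the
    ">500x" convention); runs separated by <= merge_gap positions are merged;
    merged runs shorter than min_region_length are discarded. Regions are
    returned disjoint and sorted by start.
    """
    if track.ref_id != ref.ref_id:
        raise ValueError(f"track {track.ref_id!r} does not belong to reference {ref.ref_id!r}")
    if len(track.depth) != len(ref.sequence):
        raise ValueError(
            f"track length {len(track.depth)} != reference length {len(ref.sequence)}"
        )
    if merge_gap < 0 or min_region_length < 1:
        raise ValueError("merge_gap must be >= 0 and min_region_length >= 1")

    regions: List[AbundantRegion] = []
    for start, end in _merge_runs(_runs_above(track.depth, min_depth), merge_gap):
        if end - start < min_region_length:
            continue
        regions.append(
            AbundantRegion(
                ref_id=ref.ref_id,
                start=start,
                end=end,
                sequence=ref.sequence[start:end],
                median_depth=float(np.median(track.depth[start:end])),
                sample_id=sample_id,
            )
        )
    return regions


def region_depth_stats(
    region: AbundantRegion, track: CoverageTrack
) -> Tuple[float, float, float]:
    """(median, mean, max) of depth over the region's interval.

    The median of an even-length window is the mean of the two central values.
    """
    if region.ref_id != track.ref_id:
        raise ValueError("region and track reference ids differ")
    if region.end > len(track.depth):
        raise ValueError("region exceeds track bounds")
    window = track.depth[region.start : region.end]
    if window.size == 0:
        raise ValueError("empty region interval")
    return float(np.median(window)), float(np.mean(window)), float(np.max(window))


def write_regions(regions: Iterable[AbundantRegion], path, format: str = "tsv") -> None:
    """Write regions as a TSV (with sequence and median depth) or BED."""
    path = Path(path)
    with open(path, "w") as handle:
        if format == "tsv":
            handle.write("\t".join(REGION_TSV_COLUMNS) + "\n")
            for r in regions:
                handle.write(
                    f"{r.ref_id}\t{r.start}\t{r.end}\t{r.median_depth}\t"
                    f"{r.sample_id}\t{r.sequence}\n"
                )
        elif format == "bed":
            for r in regions:
                name = f"{r.sample_id or 'region'}:{r.ref_id}:{r.start}-{r.end}"
                handle.write(f"{r.ref_id}\t{r.start}\t{r.end}\t{name}\n")
        else:
            raise ValueError(f"unknown region format {format!r}")


def read_regions(path) -> List[AbundantRegion]:
    """Read back the TSV flavour written by :func:`write_regions`."""
    regions: List[AbundantRegion] = []
    with open(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header != REGION_TSV_COLUMNS:
            raise FormatError(f"{path}: unexpected region table header {header}")
        for row in reader:
            if not row:
                continue
            ref_id, start, end, median_depth, sample_id, seq = row
            regions.append(
                AbundantRegion(
                    ref_id=ref_id,
                    start=int(start),
                    end=int(end),
                    sequence=seq,
                    median_depth=float(median_depth),
                    sample_id=sample_id,
                )
            )
    return regions
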