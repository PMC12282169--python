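"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations, kept separate from the package so the
tests compare two unrelated code paths.
"""

from typing import Dict, List, Sequence, Tuple


def nw_identity(a: str, b: str) -> float:
    """Textbook Needleman-Wunsch (match +1, mismatch -1, gap -1, end gaps
    penalised); returns matched columns / total alignment columns of one
    optimal alignment (diagonal-preferring traceback)."""
    n, m = len(a), len(b)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = -i
    for j in range(1, m + 1):
        score[0][j] = -j
    for i in range(1, n + 1):
        ai = a[i - 1]
        row = score[i]
        prev = score[i - 1]
        for j in range(1, m + 1):
            s = 1 if ai == b[j - 1] else -1
            best = prev[j - 1] + s
            up = prev[j] - 1
            if up > best:
                best = up
            left = row[j - 1] - 1
            if left > best:
                best = left
            row[j] = best
    i, j = n, m
    matches = 0
    cols = 0
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and score[i][j] == score[i - 1][j - 1] + (1 if a[i - 1] == b[j - 1] else -1)
        ):
            matches += a[i - 1] == b[j - 1]
            i -= 1
            j -= 1
        elif i > 0 and score[i][j] == score[i - 1][j] - 1:
            i -= 1
        else:
            j -= 1
        cols += 1
    return matches / cols


def nw_score(a: str, b: str) -> int:
    """Optimal global alignment score under the same scoring."""
    n, m = len(a), len(b)
    prev = list(range(0, -(m + 1), -1))
    for i in range(1, n + 1):
        row = [-i] + [0] * m
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = 1 if ai == b[j - 1] else -1
            row[j] = max(prev[j - 1] + s, prev[j] - 1, row[j - 1] - 1)
        prev = row
    return prev[m]


def brute_pileup(intervals: Sequence[Tuple[int, int]], length: int) -> List[int]:
    """depth[i] = number of intervals containing i, by direct membership."""
    return [sum(1 for s, e in intervals if s <= i < e) for i in range(length)]


def brute_regions(
    depth: Sequence[float], min_depth: float, merge_gap: int, min_region_length: int
) -> List[Tuple[int, int]]:
    """Enumerate maximal above-threshold runs, merge, filter — position by
    position."""
    runs = []
    i = 0
    n = len(depth)
    while i < n:
        if depth[i] > min_depth:
            j = i
            while j < n and depth[j] > min_depth:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    merged: List[List[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e - s >= min_region_length]


def brute_tiling(length: int, probe_length: int, gap: int) -> List[Tuple[int, int]]:
    """Place probes left to right by explicit stepping."""
    out = []
    pos = 0
    while pos + probe_length <= length:
        out.append((pos, pos + probe_length))
        pos += probe_length + gap
    return out


def component_count(n: int, edges: Sequence[Tuple[int, int]]) -> int:
    """Connected components by repeated label propagation."""
    labels = list(range(n))
    changed = True
    while changed:
        changed = False
        for i, j in edges:
            lo = min(labels[i], labels[j])
            if labels[i] != lo or labels[j] != lo:
                labels[i] = labels[j] = lo
                changed = True
    return len(set(labels))


REVCOMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_revcomp(seq: str) -> str:
    return "".join(REVCOMP[c] for c in reversed(seq))
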