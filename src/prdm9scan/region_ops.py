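"""Breakpoint-centered windows and exact interval-overlap machinery.

The overlap statistic used throughout is *count-once*: the number of query
regions with >= 1 bp intersection with any subject region. Under half-open
coordinates, touching intervals never overlap. A brute-force all-pairs oracle
(`count_overlaps_bruteforce`) backs the fast sorted-array implementation in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import GenomeAssembly, Interval, RegionSet


@dataclass
class BreakpointSet:
    """Named breakpoint coordinates (single positions, not paired SV ends)."""

    label: str
    positions: list[tuple[str, int]]
    enriched: list[bool] | None = field(default=None, repr=False)  # synthetic truth labels

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("breakpoint set label must be non-empty")

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def from_regions(cls, regions: RegionSet) -> "BreakpointSet":
        """Breakpoints from BED intervals via the midpoint rule floor((start+end)/2)."""
        return cls(
            label=regions.label,
            positions=[(iv.chrom, iv.midpoint) for iv in regions.intervals],
        )


@dataclass
class WindowSet(RegionSet):
    """Fixed-width windows centered on breakpoints (clipped at chromosome ends).

    Each interval's intended center is its source breakpoint; windows are never
    merged, so every breakpoint contributes exactly one region.
    """

    window_width: int = 0
    source_label: str = ""


def make_windows(breaks: BreakpointSet, width: int, assembly: GenomeAssembly) -> WindowSet:
    """Window [p - width/2, p + width/2) per breakpoint, clipped to the chromosome.

    *width* is the total window span (a "100-nt flanking frame" is +-50 around
    the break). Odd widths are rejected; out-of-bounds breakpoints are a hard
    error rather than being silently dropped.
    """
    if width < 2 or width % 2:
        raise ValueError(f"window width must be an even integer >= 2, got {width}")
    half = width // 2
    intervals = []
    for chrom, pos in breaks.positions:
        length = assembly.length_of(chrom)
        if not (0 <= pos < length):
            raise ValueError(f"breakpoint {chrom}:{pos} out of bounds (length {length})")
        intervals.append(Interval(chrom, max(0, pos - half), min(length, pos + half)))
    ws = WindowSet(
        label=f"{breaks.label}.w{width}",
        intervals=intervals,
        window_width=width,
        source_label=breaks.label,
        assembly=assembly,
    )
    sorted_rs = ws.sort(assembly)
    return WindowSet(
        label=ws.label,
        intervals=sorted_rs.intervals,
        is_sorted=True,
        window_width=width,
        source_label=breaks.label,
        assembly=assembly,
    )


def _check_same_assembly(a: RegionSet, b: RegionSet) -> None:
    if a.assembly is not None and b.assembly is not None and a.assembly is not b.assembly:
        if a.assembly.chroms != b.assembly.chroms:
            raise ValueError("region sets are bound to different assemblies")


def regions_to_arrays(regions: RegionSet) -> dict[str, np.ndarray]:
    """Per-chromosome (n, 2) int arrays of [start, end), sorted by start."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in regions.intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        chrom: np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
        for chrom, pairs in by_chrom.items()
    }


def merge_intervals(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge a start-sorted (n, 2) array into disjoint sorted (starts, ends)."""
    if len(arr) == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    starts, ends = [], []
    cur_s, cur_e = arr[0]
    for s, e in arr[1:]:
        if s < cur_e:  # strict: touching intervals stay separate but merging them
            cur_e = max(cur_e, e)  # is immaterial for overlap queries
        else:
            starts.append(cur_s)
            ends.append(cur_e)
            cur_s, cur_e = s, e
    starts.append(cur_s)
    ends.append(cur_e)
    return np.array(starts, np.int64), np.array(ends, np.int64)


def overlaps_any(starts: np.ndarray, ends: np.ndarray, merged: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Boolean per query [start, end): >=1 bp intersection with the merged set."""
    ms, me = merged
    if len(ms) == 0 or len(starts) == 0:
        return np.zeros(len(starts), dtype=bool)
    idx = np.searchsorted(me, starts, side="right")
    ok = idx < len(ms)
    idx_c = np.minimum(idx, len(ms) - 1)
    return ok & (ms[idx_c] < ends)


def count_overlaps(A: RegionSet, B: RegionSet, count_once: bool = True) -> int:
    """Overlap statistic between two region sets.

    With ``count_once`` (the default), the number of A intervals having >= 1 bp
    overlap with any B interval; without it, the number of overlapping (A, B)
    pairs.
    """
    _check_same_assembly(A, B)
    b_arrays = regions_to_arrays(B)
    total = 0
    a_arrays = regions_to_arrays(A)
    for chrom, a in a_arrays.items():
        b = b_arrays.get(chrom)
        if b is None or len(b) == 0:
            continue
        if count_once:
            flags = overlaps_any(a[:, 0], a[:, 1], merge_intervals(b))
            total += int(flags.sum())
        else:
            # pairs overlapping a = (# b starts < a.end) - (# b ends <= a.start)
            b_starts = np.sort(b[:, 0])
            b_ends = np.sort(b[:, 1])
            n_start_lt = np.searchsorted(b_starts, a[:, 1], side="left")
            n_end_le = np.searchsorted(b_ends, a[:, 0], side="right")
            total += int((n_start_lt - n_end_le).sum())
    return total


def count_overlaps_bruteforce(A: RegionSet, B: RegionSet, count_once: bool = True) -> int:
    """O(|A|*|B|) all-pairs oracle for :func:`count_overlaps`."""
    total = 0
    for a in A.intervals:
        n = sum(
            1
            for b in B.intervals
            if b.chrom == a.chrom and min(a.end, b.end) - max(a.start, b.start) >= 1
        )
        total += (n > 0) if count_once else n
    return int(total)


def list_overlaps(A: RegionSet, B: RegionSet) -> pd.DataFrame:
    """Every overlapping (A, B) pair with its intersection length in bp."""
    _check_same_assembly(A, B)
    rows = []
    b_by_chrom: dict[str, list[Interval]] = {}
    for b in B.intervals:
        b_by_chrom.setdefault(b.chrom, []).append(b)
    for a in A.intervals:
        for b in b_by_chrom.get(a.chrom, ()):
            inter = min(a.end, b.end) - max(a.start, b.start)
            if inter >= 1:
                rows.append((a.chrom, a.start, a.end, b.chrom, b.start, b.end, inter))
    return pd.DataFrame(
        rows,
        columns=[
            "a_chrom", "a_start", "a_end",
            "b_chrom", "b_start", "b_end",
            "intersection_bp",
        ],
    )


def annotate_nearest_feature(windows: RegionSet, features: RegionSet) -> pd.DataFrame:
    """Distance from each window midpoint to the nearest feature start (e.g. TSS).

    Same-chromosome only; ties broken by the smaller feature start. Windows on
    chromosomes without any feature get a null feature and NA distance.
    """
    if len(features) == 0:
        raise ValueError("feature set is empty")
    feat_by_chrom: dict[str, np.ndarray] = {}
    for iv in features.intervals:
        feat_by_chrom.setdefault(iv.chrom, []).append(iv.start)  # type: ignore[arg-type]
    feat_by_chrom = {c: np.array(sorted(v), np.int64) for c, v in feat_by_chrom.items()}
    rows = []
    for iv in windows.intervals:
        mid = iv.midpoint
        starts = feat_by_chrom.get(iv.chrom)
        if starts is None:
            rows.append((iv.chrom, iv.start, iv.end, pd.NA, pd.NA))
            continue
        i = int(np.searchsorted(starts, mid))
        candidates = []
        if i < len(starts):
            candidates.append(int(starts[i]))
        if i > 0:
            candidates.append(int(starts[i - 1]))
        # min distance, ties -> smaller feature start
        best = min(candidates, key=lambda s: (abs(mid - s), s))
        rows.append((iv.chrom, iv.start, iv.end, best, abs(mid - best)))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "nearest_feature_start", "distance_bp"],
    )
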