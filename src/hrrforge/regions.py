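"""Mappable / consensus-mappable / callable region derivation.

Each alignment run contributes a "region file" (BED of intervals with
adequate aligned coverage, produced upstream by a callable-loci tool).  The
sample's *mappable regions* are the union of its region files; ranking the
mappable bases by how many region files cover them and keeping the
top-covered fraction (default 99%, base-weighted) gives the *consensus
mappable regions*; subtracting difficult-region masks (simple repeats,
imperfect homopolymers, segmental duplications) gives the *callable
regions* that downstream reproducible-region carving starts from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .model import ConfigurationError, RegionSet, chrom_sort_key

__all__ = [
    "CoverageStack",
    "union_regions",
    "build_coverage_stack",
    "consensus_threshold",
    "select_consensus",
    "subtract_difficult",
]


@dataclass(frozen=True)
class CoverageStack:
    """Run-length encoded per-base count of covering region files.

    ``segments[chrom]`` is an (n, 3) int64 array of rows (start, end, count)
    with count >= 1; segments are disjoint, sorted, and maximal (adjacent
    segments differ in count).
    """

    segments: dict[str, np.ndarray]

    @property
    def chroms(self) -> list[str]:
        return sorted(self.segments, key=chrom_sort_key)

    def iter_segments(self) -> Iterator[tuple[str, int, int, int]]:
        for chrom in self.chroms:
            for s, e, c in self.segments[chrom]:
                yield chrom, int(s), int(e), int(c)

    def bases_by_count(self) -> dict[int, int]:
        """Histogram: coverage count -> number of bases at exactly that count."""
        hist: dict[int, int] = {}
        for arr in self.segments.values():
            for s, e, c in arr:
                hist[int(c)] = hist.get(int(c), 0) + int(e - s)
        return dict(sorted(hist.items()))

    @property
    def covered_bases(self) -> int:
        return sum(self.bases_by_count().values())

    @property
    def max_count(self) -> int:
        hist = self.bases_by_count()
        return max(hist) if hist else 0


def union_regions(region_files: Sequence[RegionSet]) -> RegionSet:
    """Union of per-run region files — the sample's mappable regions."""
    if not region_files:
        raise ConfigurationError("union_regions needs at least one region file")
    out = region_files[0]
    for rs in region_files[1:]:
        out = out.union(rs)
    return out


def build_coverage_stack(region_files: Sequence[RegionSet]) -> CoverageStack:
    """Exact per-base coverage counts over the input region files (sweep line)."""
    if not region_files:
        raise ConfigurationError("build_coverage_stack needs at least one region file")
    chroms = sorted({c for rs in region_files for c in rs.chroms}, key=chrom_sort_key)
    segments: dict[str, np.ndarray] = {}
    for chrom in chroms:
        arrs = [rs.array(chrom) for rs in region_files if rs.array(chrom).size]
        if not arrs:
            continue
        starts = np.concatenate([a[:, 0] for a in arrs])
        ends = np.concatenate([a[:, 1] for a in arrs])
        points = np.concatenate([starts, ends])
        deltas = np.concatenate(
            [np.ones(starts.size, dtype=np.int64), -np.ones(ends.size, dtype=np.int64)]
        )
        order = np.argsort(points, kind="stable")
        points, deltas = points[order], deltas[order]
        # collapse coincident breakpoints, then running coverage per gap
        uniq, idx = np.unique(points, return_index=True)
        net = np.add.reduceat(deltas, idx)
        cov = np.cumsum(net)[:-1]
        seg = np.column_stack([uniq[:-1], uniq[1:], cov])
        seg = seg[seg[:, 2] >= 1]
        # make maximal: merge adjacent equal-count segments
        if seg.shape[0]:
            rows = [list(seg[0])]
            for s, e, c in seg[1:]:
                if s == rows[-1][1] and c == rows[-1][2]:
                    rows[-1][1] = e
                else:
                    rows.append([s, e, c])
            segments[chrom] = np.array(rows, dtype=np.int64)
    return CoverageStack(segments=segments)


def consensus_threshold(stack: CoverageStack, fraction: float = 0.99) -> int:
    """Smallest coverage-count cutoff keeping >= ``fraction`` of mappable bases.

    Returns k* = max{ k >= 1 : bases(count >= k) >= fraction * bases(count >= 1) },
    i.e. the most stringent integer threshold whose selected consensus still
    holds the required base-weighted share of the mappable regions.
    """
    if not (0 < fraction <= 1):
        raise ConfigurationError(f"fraction must be in (0, 1], got {fraction}")
    hist = stack.bases_by_count()
    if not hist:
        raise ConfigurationError("empty coverage stack")
    total = sum(hist.values())
    need = fraction * total
    kstar = 1
    cum = 0  # bases with count >= k, computed from the top down
    for k in sorted(hist, reverse=True):
        cum += hist[k]
        if cum >= need:
            kstar = k
            break
    return kstar


def select_consensus(stack: CoverageStack, k: int) -> RegionSet:
    """Merged regions covered by at least ``k`` region files."""
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    out: dict[str, np.ndarray] = {}
    for chrom, arr in stack.segments.items():
        sel = arr[arr[:, 2] >= k][:, :2]
        if sel.size:
            out[chrom] = sel
    return RegionSet.from_arrays(out)  # re-merge adjacent segments


def subtract_difficult(consensus: RegionSet, masks: Sequence[RegionSet]) -> RegionSet:
    """Remove difficult-region masks from the consensus — the callable regions."""
    out = consensus
    for mask in masks:
        out = out.subtract(mask)
    return out
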