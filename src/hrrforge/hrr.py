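"""Carving highly reproducible regions (HRRs) out of callable regions.

Every discordant variant marks a locus where pipelines disagreed.  A window
of ``flank`` bases on each side of the discordant position is inspected for
HRVs: a side without any HRV is removed wholly; on a side holding an HRV at
distance d only the half-interval adjacent to the discordant variant
(length ceil(d/2), never reaching the HRV itself) is removed.  What remains
of the callable regions after all discordant windows are processed is the
sample's HRR.  Restricting call sets to the HRR gives the upper bound of
reproducibility; unrestricted call sets give the lower bound.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .model import CallSet, GenomicInterval, RegionSet, chrom_sort_key

__all__ = ["carve_hrr", "filter_to_regions"]


def _removal_intervals(
    disc_pos: np.ndarray, hrv_pos: np.ndarray, flank: int
) -> list[tuple[int, int]]:
    """0-based half-open intervals to excise on one chromosome."""
    hrv_pos = np.sort(hrv_pos)
    out: list[tuple[int, int]] = []
    for p in disc_pos:
        p = int(p)
        lo, hi = p - flank, p + flank  # inclusive window [lo, hi]
        i = int(np.searchsorted(hrv_pos, p))
        left_hrv = int(hrv_pos[i - 1]) if i > 0 and hrv_pos[i - 1] >= lo else None
        j = i
        if j < hrv_pos.size and int(hrv_pos[j]) == p:
            # an HRV sharing the discordant position counts for both sides
            left_hrv = right_hrv = p
        else:
            right_hrv = int(hrv_pos[j]) if j < hrv_pos.size and hrv_pos[j] <= hi else None

        # left side
        if left_hrv is None:
            rem_lo = lo
        else:
            d = p - left_hrv
            rem_lo = p - (d + 1) // 2          # half adjacent to the discordant variant
            rem_lo = max(rem_lo, left_hrv + 1)  # never excise the HRV itself
        # right side
        if right_hrv is None:
            rem_hi = hi
        else:
            d = right_hrv - p
            rem_hi = p + (d + 1) // 2
            rem_hi = min(rem_hi, right_hrv - 1) if right_hrv > p else p
        # the discordant position itself is always excised
        rem_lo, rem_hi = min(rem_lo, p), max(rem_hi, p)
        out.append((max(rem_lo, 0), rem_hi + 1))  # to half-open
    return out


def carve_hrr(
    callable_regions: RegionSet,
    hrvs: CallSet,
    discordant: CallSet,
    flank: int = 50,
) -> RegionSet:
    """Excise discordant neighbourhoods from the callable regions.

    The discordant position itself is always removed, so no discordant
    variant lies inside the resulting HRR; HRV positions are never excised.
    """
    if flank < 1:
        raise ValueError(f"flank must be >= 1, got {flank}")
    disc_by_chrom: dict[str, list[int]] = defaultdict(list)
    for v in discordant.variants.values():
        disc_by_chrom[v.chrom].append(v.start0)
    hrv_by_chrom: dict[str, list[int]] = defaultdict(list)
    for v in hrvs.variants.values():
        hrv_by_chrom[v.chrom].append(v.start0)

    to_remove: list[GenomicInterval] = []
    for chrom in sorted(disc_by_chrom, key=chrom_sort_key):
        disc = np.unique(np.array(disc_by_chrom[chrom], dtype=np.int64))
        hrv = np.unique(np.array(hrv_by_chrom.get(chrom, []), dtype=np.int64))
        for s, e in _removal_intervals(disc, hrv, flank):
            if s < e:
                to_remove.append(GenomicInterval(chrom, s, e))
    return callable_regions.subtract(RegionSet(to_remove))


def filter_to_regions(calls: CallSet, regions: RegionSet) -> CallSet:
    """Retain variants whose full REF footprint lies within one region interval."""
    out = CallSet(labels=calls.labels, sample=calls.sample)
    for key, v in calls.variants.items():
        if regions.contains_span(v.chrom, v.start0, v.end0):
            out.variants[key] = v
    return out
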