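"""Shared fixtures and independent per-base oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from hrrforge.model import CallSet, GenomicInterval, RegionSet, VariantCall
from hrrforge.simulate import FamilySpec, SimulationConfig

GENOME_LEN = 10_000


# ---------------------------------------------------------------- oracles


def region_to_vector(rs: RegionSet, chrom: str, length: int) -> np.ndarray:
    """Per-base boolean coverage of one chromosome."""
    v = np.zeros(length, dtype=bool)
    for s, e in rs.array(chrom):
        v[s:e] = True
    return v


def coverage_vector(files, chrom: str, length: int) -> np.ndarray:
    """Per-base count of covering region files."""
    v = np.zeros(length, dtype=int)
    for rs in files:
        for s, e in rs.array(chrom):
            v[s:e] += 1
    return v


def vector_to_regions(v: np.ndarray, chrom: str) -> RegionSet:
    ivs = []
    in_run = False
    for i, x in enumerate(v):
        if x and not in_run:
            start, in_run = i, True
        elif not x and in_run:
            ivs.append(GenomicInterval(chrom, start, i))
            in_run = False
    if in_run:
        ivs.append(GenomicInterval(chrom, start, len(v)))
    return RegionSet(ivs)


def carve_oracle_vector(
    callable_v: np.ndarray,
    disc_pos: list[int],
    hrv_pos: list[int],
    flank: int,
) -> np.ndarray:
    """Per-base reference simulation of discordant-window excision.

    A callable base x is excised iff some discordant position p has
    |x - p| <= flank and, on x's side of p (the discordant position itself
    is always excised): either that side of the window holds no HRV, or the
    nearest HRV on that side (an HRV at p counts for both sides) lies at
    distance d and |x - p| <= ceil(d/2) with x not that HRV's position.
    """
    hrv = sorted(set(hrv_pos))
    hrv_set = set(hrv)
    n = callable_v.size
    keep = callable_v.copy()
    for p in set(disc_pos):
        if p in hrv_set:
            nearest_left = nearest_right = p
        else:
            lefts = [h for h in hrv if p - flank <= h < p]
            rights = [h for h in hrv if p < h <= p + flank]
            nearest_left = max(lefts) if lefts else None
            nearest_right = min(rights) if rights else None
        for x in range(max(0, p - flank), min(n, p + flank + 1)):
            if x == p:
                keep[x] = False
                continue
            nearest = nearest_left if x < p else nearest_right
            if nearest is None:
                keep[x] = False
            else:
                d = abs(nearest - p)
                if abs(x - p) <= math.ceil(d / 2) and x != nearest:
                    keep[x] = False
    return keep


def random_regionset(rng: np.random.Generator, chrom: str = "chr1",
                     length: int = GENOME_LEN, max_intervals: int = 10) -> RegionSet:
    n = int(rng.integers(1, max_intervals + 1))
    ivs = []
    for _ in range(n):
        s = int(rng.integers(0, length - 1))
        e = int(rng.integers(s + 1, min(length, s + length // 4) + 1))
        ivs.append(GenomicInterval(chrom, s, e))
    return RegionSet(ivs)


def snv(pos: int, chrom: str = "chr1", ref: str = "A", alt: str = "G",
        gt=(0, 1), dp=None) -> VariantCall:
    return VariantCall(chrom, pos, ref, alt, gt, dp)


def callset_at(positions, sample: str = "S", labels=None, **kw) -> CallSet:
    """CallSet of het SNVs at the given 1-based positions."""
    return CallSet([snv(p, **kw) for p in positions], labels=labels, sample=sample)


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale quartet study used where full scale is unnecessary."""
    return SimulationConfig(
        genome=(("chr1", 150_000), ("chr2", 100_000)),
        n_sites=300,
        labs=("lab1", "lab2", "lab3"),
        replicates=("r1", "r2", "r3"),
        aligners=("alnA", "alnB"),
        callers=("c1", "c2", "c3"),
        caller_fn=(0.02, 0.04, 0.06),
        aligner_fn=(0.01, 0.02),
        seed=11,
    )


@pytest.fixture(scope="session")
def zero_error_config() -> SimulationConfig:
    return SimulationConfig(
        genome=(("chr1", 120_000),),
        n_sites=200,
        labs=("lab1", "lab2"),
        replicates=("r1", "r2", "r3"),
        aligners=("alnA", "alnB"),
        callers=("c1", "c2", "c3"),
        caller_fn=(0.0, 0.0, 0.0),
        aligner_fn=(0.0, 0.0),
        replicate_fn=0.0,
        caller_fp_rate=0.0,
        private_fp_rate=0.0,
        genotype_error=0.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def trio_config() -> SimulationConfig:
    return SimulationConfig(
        genome=(("chr1", 100_000),),
        n_sites=150,
        families=(FamilySpec("trio", "trio", ("T_F", "T_M", "T_C")),),
        labs=("lab1",),
        replicates=("r1", "r2", "r3"),
        aligners=("alnA", "alnB"),
        callers=("c1", "c2", "c3"),
        caller_fn=(0.02, 0.03, 0.04),
        aligner_fn=(0.01, 0.02),
        seed=23,
    )
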