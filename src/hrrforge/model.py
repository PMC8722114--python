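"""Core domain types for germline call-set concordance analysis.

The vocabulary here mirrors how replication studies of short-read WGS
variant calling are set up: each *call set* is the output of one pipeline
run — one point in the factor grid sample × lab × platform × library ×
replicate × aligner × caller — and holds normalized biallelic variant
records.  Interval sets (``RegionSet``) are kept in BED conventions
(0-based, half-open); VCF positions are 1-based and converted exactly once,
at position queries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional

import numpy as np

__all__ = [
    "VariantClass",
    "VariantCall",
    "FactorLabels",
    "CallSet",
    "GenomicInterval",
    "RegionSet",
    "Pedigree",
    "ComparisonCounts",
    "normalize_variant",
    "classify_variant",
    "match_callsets",
    "InvalidVariantError",
    "ConfigurationError",
    "FormatError",
]

FACTOR_NAMES = ("sample", "lab", "platform", "library", "replicate", "aligner", "caller")

_CHROM_AUTOSOME_RE = re.compile(r"^(chr)?(\d+)$")


class InvalidVariantError(ValueError):
    """A variant record that cannot be normalized (e.g. ref == alt)."""


class ConfigurationError(ValueError):
    """Inconsistent configuration: unknown factor level, missing sample, etc."""


class FormatError(ValueError):
    """Malformed input file content."""


class VariantClass(str, Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"
    MNV = "MNV"
    COMPLEX = "COMPLEX"


def is_autosome(chrom: str) -> bool:
    return _CHROM_AUTOSOME_RE.match(chrom) is not None


def chrom_sort_key(chrom: str) -> tuple:
    """Natural chromosome ordering: chr1 < chr2 < ... < chr10 < chrX-like names."""
    m = _CHROM_AUTOSOME_RE.match(chrom)
    if m:
        return (0, int(m.group(2)), chrom)
    return (1, 0, chrom)


_ALLELE_RE = re.compile(r"^[ACGT]+$")


def classify_variant(ref: str, alt: str) -> VariantClass:
    """Variant class as a pure function of the (normalized) allele pair."""
    if len(ref) == len(alt):
        return VariantClass.SNV if len(ref) == 1 else VariantClass.MNV
    if len(alt) > len(ref):
        return VariantClass.INS if alt.startswith(ref) else VariantClass.COMPLEX
    return VariantClass.DEL


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference: Optional[Mapping[str, str]] = None,
) -> tuple[int, str, str]:
    """Reduce (pos, ref, alt) to minimal representation.

    Trims the common suffix, then the common prefix, always keeping at least
    one base in each allele; ``pos`` (1-based) moves right by the number of
    prefix bases trimmed.  When ``reference`` supplies the chromosome
    sequence, indels are additionally left-aligned by the standard
    shift-left rule before the final prefix trim.

    Raises
    ------
    InvalidVariantError
        if ref == alt or an allele contains non-ACGT characters.
    """
    if not ref or not alt:
        raise InvalidVariantError(f"empty allele at {chrom}:{pos}")
    if ref == alt:
        raise InvalidVariantError(f"ref == alt ({ref}) at {chrom}:{pos}")
    if not _ALLELE_RE.match(ref) or not _ALLELE_RE.match(alt):
        raise InvalidVariantError(f"non-ACGT allele at {chrom}:{pos}: {ref}>{alt}")

    # suffix trim, keep >= 1 base each
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]

    if reference is not None and len(ref) != len(alt):
        seq = reference.get(chrom)
        if seq is not None:
            # left-align: while alleles end in the same base, shift one left
            while (
                ref[-1] == alt[-1]
                and pos > 1
                and len(seq) >= pos - 1 >= 1
            ):
                prev = seq[pos - 2].upper()
                ref = prev + ref[:-1]
                alt = prev + alt[:-1]
                pos -= 1
            while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
                ref, alt = ref[:-1], alt[:-1]

    # prefix trim, keep >= 1 base each
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1

    if ref == alt:
        raise InvalidVariantError(f"ref == alt after trimming at {chrom}:{pos}")
    return pos, ref, alt


Genotype = tuple[int, int]  # sorted pair over {0 (ref), 1 (alt)}


@dataclass(frozen=True, slots=True)
class VariantCall:
    """One normalized biallelic variant observation.

    ``pos`` is the 1-based position of the first REF base; ``genotype`` is
    the unordered diploid pair of allele indices (0 = REF, 1 = ALT);
    ``depth`` is the read depth at the site (None when the caller did not
    report DP).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: Genotype
    depth: Optional[int] = None
    vclass: VariantClass = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.vclass is None:
            object.__setattr__(self, "vclass", classify_variant(self.ref, self.alt))
        gt = tuple(sorted(self.genotype))
        object.__setattr__(self, "genotype", gt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def start0(self) -> int:
        """0-based start of the REF footprint."""
        return self.pos - 1

    @property
    def end0(self) -> int:
        """0-based exclusive end of the REF footprint."""
        return self.pos - 1 + len(self.ref)


@dataclass(frozen=True, slots=True)
class FactorLabels:
    """Position of one call set in the experimental factor grid."""

    sample: str
    lab: str = "-"
    platform: str = "-"
    library: str = "-"
    replicate: str = "-"
    aligner: str = "-"
    caller: str = "-"

    def astuple(self) -> tuple[str, ...]:
        return tuple(getattr(self, f) for f in FACTOR_NAMES)

    def drop(self, *factors: str) -> tuple[str, ...]:
        """Label tuple with the given factors blanked — the pairing key."""
        return tuple(
            "*" if f in factors else getattr(self, f) for f in FACTOR_NAMES
        )


VariantKey = tuple[str, int, str, str]


class CallSet:
    """A labeled collection of VariantCall from one pipeline run.

    Keyed by variant identity (chrom, pos, ref, alt); iteration yields
    variants in (chromosome natural order, position) order.
    """

    __slots__ = ("variants", "labels", "sample")

    def __init__(
        self,
        variants: Iterable[VariantCall] = (),
        labels: Optional[FactorLabels] = None,
        sample: Optional[str] = None,
    ):
        self.variants: dict[VariantKey, VariantCall] = {}
        for v in variants:
            if v.key in self.variants:
                raise ConfigurationError(f"duplicate variant identity {v.key}")
            self.variants[v.key] = v
        self.labels = labels
        self.sample = sample if sample is not None else (labels.sample if labels else None)

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.variants

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(
            sorted(
                self.variants.values(),
                key=lambda v: (chrom_sort_key(v.chrom), v.pos, v.ref, v.alt),
            )
        )

    def get(self, key: VariantKey) -> Optional[VariantCall]:
        return self.variants.get(key)

    def keys(self) -> set[VariantKey]:
        return set(self.variants)

    def subset(self, keys: Iterable[VariantKey]) -> "CallSet":
        out = CallSet(labels=self.labels, sample=self.sample)
        for k in keys:
            if k in self.variants:
                out.variants[k] = self.variants[k]
        return out

    def with_labels(self, labels: FactorLabels) -> "CallSet":
        out = CallSet(labels=labels, sample=labels.sample)
        out.variants = dict(self.variants)
        return out

    def __repr__(self) -> str:
        return f"CallSet(n={len(self)}, sample={self.sample!r})"


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


class RegionSet:
    """Disjoint, sorted genomic intervals with interval-algebra semantics.

    Internally one (n, 2) int64 array of [start, end) rows per chromosome.
    Adjacent or overlapping input intervals are merged on construction, so
    any two stored intervals on a chromosome are separated by >= 1 base.
    """

    __slots__ = ("_per_chrom",)

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        raw: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            raw.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._per_chrom: dict[str, np.ndarray] = {}
        for chrom, pairs in raw.items():
            self._per_chrom[chrom] = _merge_pairs(np.array(pairs, dtype=np.int64))

    @classmethod
    def from_arrays(cls, per_chrom: Mapping[str, np.ndarray], merged: bool = False) -> "RegionSet":
        rs = cls()
        for chrom, arr in per_chrom.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if arr.size == 0:
                continue
            if np.any(arr[:, 0] >= arr[:, 1]) or np.any(arr[:, 0] < 0):
                raise FormatError(f"invalid interval array on {chrom}")
            rs._per_chrom[chrom] = arr if merged else _merge_pairs(arr)
        return rs

    @property
    def chroms(self) -> list[str]:
        return sorted(self._per_chrom, key=chrom_sort_key)

    def array(self, chrom: str) -> np.ndarray:
        return self._per_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))

    @property
    def total_bases(self) -> int:
        return int(
            sum((arr[:, 1] - arr[:, 0]).sum() for arr in self._per_chrom.values())
        )

    def __len__(self) -> int:
        return sum(arr.shape[0] for arr in self._per_chrom.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms:
            for s, e in self._per_chrom[chrom]:
                yield GenomicInterval(chrom, int(s), int(e))

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        if set(self._per_chrom) != set(k for k, v in other._per_chrom.items() if v.size):
            mine = {k for k, v in self._per_chrom.items() if v.size}
            theirs = {k for k, v in other._per_chrom.items() if v.size}
            if mine != theirs:
                return False
        for chrom, arr in self._per_chrom.items():
            if arr.size and not np.array_equal(arr, other.array(chrom)):
                return False
        return True

    def union(self, other: "RegionSet") -> "RegionSet":
        out: dict[str, np.ndarray] = {}
        for chrom in set(self._per_chrom) | set(other._per_chrom):
            stacked = np.vstack([self.array(chrom), other.array(chrom)])
            out[chrom] = _merge_pairs(stacked)
        return RegionSet.from_arrays(out, merged=True)

    def subtract(self, other: "RegionSet") -> "RegionSet":
        out: dict[str, np.ndarray] = {}
        for chrom, arr in self._per_chrom.items():
            out[chrom] = _subtract_pairs(arr, other.array(chrom))
        return RegionSet.from_arrays(out, merged=True)

    def intersect(self, other: "RegionSet") -> "RegionSet":
        out: dict[str, np.ndarray] = {}
        for chrom, arr in self._per_chrom.items():
            out[chrom] = _intersect_pairs(arr, other.array(chrom))
        return RegionSet.from_arrays(out, merged=True)

    def contains_span(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) lies entirely within a single interval."""
        arr = self.array(chrom)
        if arr.size == 0:
            return False
        i = int(np.searchsorted(arr[:, 0], start, side="right")) - 1
        return i >= 0 and arr[i, 0] <= start and end <= arr[i, 1]

    def contains_position(self, chrom: str, pos0: int) -> bool:
        return self.contains_span(chrom, pos0, pos0 + 1)

    def __repr__(self) -> str:
        return f"RegionSet(intervals={len(self)}, bases={self.total_bases})"


def _merge_pairs(arr: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent [start, end) rows; returns sorted disjoint rows."""
    if arr.shape[0] == 0:
        return arr.reshape(0, 2)
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    arr = arr[order]
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:  # overlap or adjacency
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=np.int64)


def _subtract_pairs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if a.shape[0] == 0 or b.shape[0] == 0:
        return a.copy().reshape(-1, 2)
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < b.shape[0] and b[j, 1] <= cur:
            j += 1
        k = j
        while k < b.shape[0] and b[k, 0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, min(bs, e)))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def _intersect_pairs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if a.shape[0] == 0 or b.shape[0] == 0:
        return np.empty((0, 2), dtype=np.int64)
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < a.shape[0] and j < b.shape[0]:
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((int(s), int(e)))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


@dataclass(frozen=True)
class Pedigree:
    """One nuclear family: parents plus either a child or a monozygotic twin pair.

    A trio has roles {father, mother, child}; a quartet has
    {father, mother, twinA, twinB} with the twins monozygotic.
    """

    family: str
    father: str
    mother: str
    child: Optional[str] = None
    twinA: Optional[str] = None
    twinB: Optional[str] = None

    def __post_init__(self):
        has_child = self.child is not None
        has_twins = self.twinA is not None and self.twinB is not None
        if has_child == has_twins:
            raise ConfigurationError(
                f"family {self.family}: need exactly one of a child or a twin pair"
            )
        ids = self.member_ids
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"family {self.family}: duplicate member ids")

    @property
    def is_quartet(self) -> bool:
        return self.twinA is not None

    @property
    def member_ids(self) -> tuple[str, ...]:
        if self.is_quartet:
            return (self.father, self.mother, self.twinA, self.twinB)
        return (self.father, self.mother, self.child)

    @property
    def offspring_ids(self) -> tuple[str, ...]:
        return (self.twinA, self.twinB) if self.is_quartet else (self.child,)


@dataclass(frozen=True, slots=True)
class ComparisonCounts:
    """Matched/unique counts from comparing call set a (query) against b (baseline).

    ``n_a`` = variants of a found in b, ``n_b`` = variants of b found in a;
    with exact-key matching n_a == n_b.  In the query-vs-truth reading,
    Q_c = n_a (common), Q_u = N_a - n_a (query-only), H_u = N_b - n_b
    (truth-only).
    """

    N_a: int
    N_b: int
    n_a: int
    n_b: int

    def __post_init__(self):
        if not (0 <= self.n_a <= self.N_a and 0 <= self.n_b <= self.N_b):
            raise ValueError("inconsistent comparison counts")

    @property
    def Q_c(self) -> int:
        return self.n_a

    @property
    def Q_u(self) -> int:
        return self.N_a - self.n_a

    @property
    def H_u(self) -> int:
        return self.N_b - self.n_b


@dataclass(frozen=True)
class MatchResult:
    """ComparisonCounts plus the four variant subsets behind them."""

    counts: ComparisonCounts
    a_found: CallSet
    a_unique: CallSet
    b_found: CallSet
    b_unique: CallSet
    genotype_matches: int  # among matched keys, pairs with equal GT


def match_callsets(
    a: CallSet, b: CallSet, genotype_strict: bool = False
) -> MatchResult:
    """Compare two normalized call sets by variant identity key.

    Default matching is allele-level on (chrom, pos, ref, alt).  In
    genotype-strict mode a shared key only counts as found when the two
    genotypes are equal.
    """
    shared = a.keys() & b.keys()
    gt_equal = {k for k in shared if a.variants[k].genotype == b.variants[k].genotype}
    found = gt_equal if genotype_strict else shared
    counts = ComparisonCounts(N_a=len(a), N_b=len(b), n_a=len(found), n_b=len(found))
    return MatchResult(
        counts=counts,
        a_found=a.subset(found),
        a_unique=a.subset(a.keys() - found),
        b_found=b.subset(found),
        b_unique=b.subset(b.keys() - found),
        genotype_matches=len(gt_equal),
    )
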