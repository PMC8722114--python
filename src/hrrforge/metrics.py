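"""Reproducibility metrics: depth filtering, R, Jaccard, precision/recall/F.

Reproducibility between two call sets a and b is

    R = 1/2 * (n_a / N_a + n_b / N_b)

where N_x are the set sizes and n_x the cross-found counts.  Benchmarking a
call set against its sample's HRVs uses precision = Q_c/(Q_c+Q_u),
recall = Q_c/(Q_c+H_u) and their harmonic mean F.  Undefined ratios (0/0)
propagate as missing (NaN), never as zero, so downstream averages run over
defined cells only.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .hrr import filter_to_regions
from .model import (
    CallSet,
    ComparisonCounts,
    ConfigurationError,
    FactorLabels,
    RegionSet,
    VariantClass,
    match_callsets,
)

log = logging.getLogger(__name__)

__all__ = [
    "MetricsRecord",
    "depth_filter",
    "auto_max_depth",
    "reproducibility",
    "jaccard",
    "avg_jaccard",
    "precision_recall_f",
    "stratify",
    "reproducibility_table",
    "PAIRING_FACTOR",
]

NA = float("nan")


def auto_max_depth(calls: CallSet) -> Optional[int]:
    """Outlier depth cutoff: round(mean + 3*sd) over the call set's DP values."""
    dps = np.array(
        [v.depth for v in calls.variants.values() if v.depth is not None], dtype=float
    )
    if dps.size == 0:
        return None
    return int(round(dps.mean() + 3 * dps.std(ddof=0)))


def depth_filter(
    calls: CallSet, min_dp: int = 8, max_dp: int | str | None = "auto"
) -> CallSet:
    """Keep variants with min_dp <= DP <= max_dp (inclusive).

    ``max_dp="auto"`` computes mean + 3 sd of the call set's own depths;
    ``None`` disables the upper cutoff.  Records without a DP value are
    retained — callers differ in depth reporting, and dropping them would
    bias cross-caller comparisons.
    """
    if max_dp == "auto":
        max_dp = auto_max_depth(calls)
    if max_dp is not None and min_dp > max_dp:
        raise ConfigurationError(f"min_dp {min_dp} > max_dp {max_dp}")
    out = CallSet(labels=calls.labels, sample=calls.sample)
    n_nodp = 0
    for key, v in calls.variants.items():
        if v.depth is None:
            n_nodp += 1
            out.variants[key] = v
        elif min_dp <= v.depth and (max_dp is None or v.depth <= max_dp):
            out.variants[key] = v
    if n_nodp:
        log.info("depth_filter: kept %d records lacking DP", n_nodp)
    return out


def reproducibility(c: ComparisonCounts) -> float:
    """R = 1/2 (n_a/N_a + n_b/N_b); NaN when either set is empty."""
    if c.N_a == 0 or c.N_b == 0:
        return NA
    return 0.5 * (c.n_a / c.N_a + c.n_b / c.N_b)


def jaccard(a: CallSet, b: CallSet) -> float:
    """|a ∩ b| / |a ∪ b| on identity keys; NaN for two empty sets."""
    ka, kb = a.keys(), b.keys()
    union = len(ka | kb)
    if union == 0:
        return NA
    return len(ka & kb) / union


def avg_jaccard(a: CallSet, b: CallSet, c: CallSet) -> float:
    """Mean of the three pairwise Jaccard indices of replicate call sets.

    ((A∩B)/(A∪B) + (A∩C)/(A∪C) + (B∩C)/(B∪C)) / 3, with any undefined
    (empty-union) term dropped from the mean.
    """
    terms = [jaccard(a, b), jaccard(a, c), jaccard(b, c)]
    defined = [t for t in terms if not math.isnan(t)]
    if len(defined) < len(terms):
        log.warning("avg_jaccard: %d undefined pairwise term(s) dropped", len(terms) - len(defined))
    if not defined:
        return NA
    return sum(defined) / len(defined)


def precision_recall_f(c: ComparisonCounts) -> tuple[float, float, float]:
    """Precision, recall, F-score of the query (a) against the truth set (b).

    precision = Q_c/(Q_c+Q_u), recall = Q_c/(Q_c+H_u),
    F = 2 P R / (P + R) with F = 0 at P = R = 0; empty denominators yield NaN.
    """
    precision = c.Q_c / (c.Q_c + c.Q_u) if (c.Q_c + c.Q_u) > 0 else NA
    recall = c.Q_c / (c.Q_c + c.H_u) if (c.Q_c + c.H_u) > 0 else NA
    if math.isnan(precision) or math.isnan(recall):
        f = NA
    elif precision + recall == 0:
        f = 0.0
    else:
        f = 2 * precision * recall / (precision + recall)
    return precision, recall, f


HEADLINE_CLASSES = (VariantClass.SNV, VariantClass.INS, VariantClass.DEL)


def stratify(calls: CallSet) -> dict[VariantClass, CallSet]:
    """Partition a call set by variant class.

    MNV and COMPLEX variants land in their own buckets and are excluded
    from the three headline classes (SNV / INS / DEL).
    """
    buckets = {vc: CallSet(labels=calls.labels, sample=calls.sample) for vc in VariantClass}
    for key, v in calls.variants.items():
        buckets[v.vclass].variants[key] = v
    return buckets


@dataclass(frozen=True)
class MetricsRecord:
    """One tidy row of pairwise reproducibility metrics."""

    labels_a: FactorLabels
    labels_b: FactorLabels
    vclass: str
    hrr_filtered: bool
    R: float
    jaccard: float
    precision: float = NA
    recall: float = NA
    f_score: float = NA

    def to_dict(self) -> dict:
        d = {f"{f}_a": getattr(self.labels_a, f) for f in self.labels_a.__dataclass_fields__}
        d.update({f"{f}_b": getattr(self.labels_b, f) for f in self.labels_b.__dataclass_fields__})
        d.update(
            vclass=self.vclass,
            hrr_filtered=self.hrr_filtered,
            R=self.R,
            jaccard=self.jaccard,
            precision=self.precision,
            recall=self.recall,
            f_score=self.f_score,
        )
        return d


PAIRING_FACTOR = {
    "technical": "replicate",
    "lab": "lab",
    "aligner": "aligner",
    "caller": "caller",
}


def reproducibility_table(
    callsets: Sequence[CallSet],
    pairing: str,
    hrr: Optional[RegionSet] = None,
    hrvs: Optional[Mapping[str, CallSet]] = None,
    genotype_strict: bool = False,
    per_class: bool = True,
) -> list[MetricsRecord]:
    """All-pairs reproducibility along one factor, other factors held constant.

    Enumerates every pair of call sets that differ only in the pairing
    factor (replicate for "technical"; lab pairing also ignores the
    platform/library labels tied to a lab) and emits R and pairwise Jaccard
    per variant class, plus precision/recall/F of the first set against the
    sample's HRVs when ``hrvs`` is given.  With ``hrr`` supplied each pair
    is measured twice — unrestricted (lower bound) and restricted to the
    HRR (upper bound).
    """
    if pairing not in PAIRING_FACTOR:
        raise ConfigurationError(f"unknown pairing {pairing!r}")
    factor = PAIRING_FACTOR[pairing]
    drop = ("lab", "platform", "library") if factor == "lab" else (factor,)

    groups: dict[tuple, list[CallSet]] = defaultdict(list)
    for cs in callsets:
        if cs.labels is None:
            raise ConfigurationError("reproducibility_table inputs need FactorLabels")
        groups[cs.labels.drop(*drop)].append(cs)

    records: list[MetricsRecord] = []
    hrr_modes = [False] if hrr is None else [False, True]
    for key, members in sorted(groups.items()):
        if len(members) < 2:
            log.info("pairing %s: group %s has no partner; skipped", pairing, key)
            continue
        members = sorted(members, key=lambda cs: cs.labels.astuple())
        for a, b in itertools.combinations(members, 2):
            for use_hrr in hrr_modes:
                ca, cb = a, b
                truth = hrvs.get(a.sample) if hrvs else None
                if use_hrr:
                    ca, cb = filter_to_regions(a, hrr), filter_to_regions(b, hrr)
                    truth = filter_to_regions(truth, hrr) if truth else None
                classes: list[Optional[VariantClass]] = [None]
                if per_class:
                    classes += list(HEADLINE_CLASSES)
                for vc in classes:
                    sa = ca if vc is None else stratify(ca)[vc]
                    sb = cb if vc is None else stratify(cb)[vc]
                    m = match_callsets(sa, sb, genotype_strict)
                    rec_kwargs = dict(
                        labels_a=a.labels,
                        labels_b=b.labels,
                        vclass="ALL" if vc is None else vc.value,
                        hrr_filtered=use_hrr,
                        R=reproducibility(m.counts),
                        jaccard=jaccard(sa, sb),
                    )
                    if truth is not None:
                        st = truth if vc is None else stratify(truth)[vc]
                        p, r, f = precision_recall_f(
                            match_callsets(sa, st, genotype_strict).counts
                        )
                        rec_kwargs.update(precision=p, recall=r, f_score=f)
                    records.append(MetricsRecord(**rec_kwargs))
    return records


def records_to_dataframe(records: Sequence[MetricsRecord]):
    import pandas as pd

    return pd.DataFrame([r.to_dict() for r in records])
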