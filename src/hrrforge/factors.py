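"""Variance decomposition of concordance over experimental factors.

The response is the per-pipeline average Jaccard concordance Y, one value
per cell of the caller × aligner × platform × sample crossing (platform
stands for the platform/library/lab bundle, which are confounded in the
study design).  All four factors and their six 2-way interactions enter a
crossed random-effects model

    Y = Z gamma + eps,   gamma ~ N(0, G),   eps ~ N(0, sigma^2 I)

whose components are estimated by balanced-design ANOVA method of moments
(Henderson I): expected mean squares are equated to observed mean squares
and the resulting triangular system is solved, negative solutions being
truncated to zero before proportions are formed.  For balanced designs this
estimator coincides in expectation with REML.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import ConfigurationError, FactorLabels

log = logging.getLogger(__name__)

__all__ = [
    "DESIGN_FACTORS",
    "ConcordanceDesign",
    "VarianceDecomposition",
    "build_design",
    "estimate_variance_components",
    "contribution_report",
]

DESIGN_FACTORS = ("caller", "aligner", "platform", "sample")
RESIDUAL = "residual"


@dataclass
class ConcordanceDesign:
    """Validated factor design with one concordance response per cell."""

    data: pd.DataFrame  # columns: DESIGN_FACTORS + ["Y"]
    levels: dict[str, list[str]]

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def is_complete(self) -> bool:
        expected = math.prod(len(v) for v in self.levels.values())
        return self.n_rows == expected


@dataclass
class VarianceDecomposition:
    """Estimated variance components and their proportions of the total."""

    components: dict[str, float]            # term -> truncated estimate (>= 0)
    proportions: dict[str, float]           # components / total (NaN if total 0)
    raw: dict[str, float] = field(default_factory=dict)  # pre-truncation solutions
    missing: dict[str, str] = field(default_factory=dict)  # term -> reason


def build_design(
    records: Sequence[tuple[FactorLabels, float]],
    factors: Sequence[str] = DESIGN_FACTORS,
) -> ConcordanceDesign:
    """Assemble (factor levels, Y) records into a validated design.

    Replicates are expected to be already collapsed into one Y (the average
    Jaccard); duplicate cells are averaged with a warning.
    """
    if not records:
        raise ConfigurationError("empty design")
    rows = []
    for labels, y in records:
        if not (isinstance(y, (int, float)) and not math.isnan(y)):
            raise ConfigurationError(f"non-numeric response for {labels}")
        if not 0 <= y <= 1:
            raise ConfigurationError(f"concordance response {y} outside [0, 1]")
        rows.append({f: getattr(labels, f) for f in factors} | {"Y": float(y)})
    df = pd.DataFrame(rows)
    dup = df.duplicated(subset=list(factors), keep=False)
    if dup.any():
        log.warning("build_design: averaging %d duplicate cell rows", int(dup.sum()))
        df = df.groupby(list(factors), as_index=False, sort=True)["Y"].mean()
    levels = {f: sorted(df[f].unique()) for f in factors}
    design = ConcordanceDesign(data=df.reset_index(drop=True), levels=levels)
    if not design.is_complete:
        log.warning(
            "build_design: %d rows for a %s crossing (incomplete design)",
            design.n_rows,
            "x".join(str(len(v)) for v in levels.values()),
        )
    return design


def _term_name(term: tuple[str, ...]) -> str:
    return ":".join(term)


def _effect_ss(df: pd.DataFrame, term: tuple[str, ...], grand: float) -> tuple[float, int]:
    """Sum of squares and df of a factorial term by inclusion-exclusion of means."""
    n = len(df)
    effect = np.zeros(n)
    for r in range(len(term) + 1):
        for sub in itertools.combinations(term, r):
            sign = (-1) ** (len(term) - len(sub))
            if not sub:
                effect += sign * grand
            else:
                effect += sign * df.groupby(list(sub))["Y"].transform("mean").to_numpy()
    ss = float(np.sum(effect**2))
    dfree = 1
    for f in term:
        dfree *= df[f].nunique() - 1
    return ss, dfree


def estimate_variance_components(
    design: ConcordanceDesign,
    factors: Sequence[str] = DESIGN_FACTORS,
    include_interactions: bool = True,
) -> VarianceDecomposition:
    """Henderson I estimates for the crossed random-effects model.

    Includes all main effects, all 2-way interactions (optional) and the
    residual.  A factor with fewer than 2 levels is inestimable and
    reported as missing.  Requires a complete (balanced) crossing; raises
    otherwise, because expected-mean-square coefficients assume balance.
    """
    df = design.data
    usable = [f for f in factors if df[f].nunique() >= 2]
    dropped = {f: "fewer than 2 levels" for f in factors if f not in usable}
    if len(usable) < 1:
        raise ConfigurationError("no factor has >= 2 levels")
    if not design.is_complete:
        raise ConfigurationError(
            "variance components need a complete balanced crossing; "
            f"got {design.n_rows} rows"
        )

    n = len(df)
    grand = float(df["Y"].mean())
    terms: list[tuple[str, ...]] = [(f,) for f in usable]
    if include_interactions:
        terms += list(itertools.combinations(usable, 2))

    ms: dict[tuple[str, ...], float] = {}
    ss_model = 0.0
    df_model = 0
    for term in terms:
        ss, dfree = _effect_ss(df, term, grand)
        ms[term] = ss / dfree
        ss_model += ss
        df_model += dfree

    ss_total = float(np.sum((df["Y"].to_numpy() - grand) ** 2))
    df_total = n - 1
    df_res = df_total - df_model
    if df_res <= 0:
        raise ConfigurationError(
            "design leaves no residual degrees of freedom for the model terms"
        )
    ms_res = max(ss_total - ss_model, 0.0) / df_res

    # EMS coefficients: E[MS_T] = sigma^2 + sum_{U in model, U ⊇ T} (n / L_U) s2_U
    L = {term: math.prod(df[f].nunique() for f in term) for term in terms}
    k = len(terms)
    A = np.zeros((k + 1, k + 1))
    b = np.zeros(k + 1)
    for i, t in enumerate(terms):
        for j, u in enumerate(terms):
            if set(t) <= set(u):
                A[i, j] = n / L[u]
        A[i, k] = 1.0
        b[i] = ms[t]
    A[k, k] = 1.0
    b[k] = ms_res
    sol = np.linalg.solve(A, b)

    raw = {_term_name(t): float(sol[i]) for i, t in enumerate(terms)}
    raw[RESIDUAL] = float(sol[k])
    components = {name: max(v, 0.0) for name, v in raw.items()}
    total = sum(components.values())
    if total > 0:
        proportions = {name: v / total for name, v in components.items()}
    else:
        proportions = {name: float("nan") for name in components}
        log.warning("constant response: variance proportions undefined")
    return VarianceDecomposition(
        components=components, proportions=proportions, raw=raw, missing=dropped
    )


def contribution_report(decomp: VarianceDecomposition) -> pd.DataFrame:
    """Terms ranked by proportion of total variance (ties broken by name)."""
    rows = [
        {"term": name, "variance": decomp.components[name], "proportion": prop}
        for name, prop in decomp.proportions.items()
    ]
    out = pd.DataFrame(rows).sort_values(
        ["proportion", "term"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    for term, reason in decomp.missing.items():
        out = pd.concat(
            [out, pd.DataFrame([{"term": term, "variance": float("nan"),
                                 "proportion": float("nan"), "note": reason}])],
            ignore_index=True,
        )
    return out
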