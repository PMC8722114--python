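"""The concordance cascade that defines highly reproducible variants (HRVs).

Variants from one sample are filtered through successive agreement stages:
replicate concordance (a variant seen in only one replicate of a pipeline is
discordant), lab concordance, aligner concordance, caller concordance (a
variant must be shared by at least ``min_callers`` callers), monozygotic-twin
concordance where the pedigree declares twins, and finally Mendelian-rule
compliance within the family.  Survivors are the sample's HRVs; the pooled
discordant variants from every stage drive reproducible-region carving.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .model import (
    CallSet,
    ConfigurationError,
    FactorLabels,
    Genotype,
    Pedigree,
    VariantKey,
)

log = logging.getLogger(__name__)

__all__ = [
    "ConcordanceResult",
    "CascadeConfig",
    "CascadeOutcome",
    "replicate_concordance",
    "lab_concordance",
    "aligner_concordance",
    "caller_concordance",
    "twin_concordance",
    "mendelian_consistent",
    "mendelian_filter",
    "run_hrv_cascade",
]

HOM_REF: Genotype = (0, 0)


@dataclass(frozen=True)
class ConcordanceResult:
    """Partition of a stage's input union into concordant and discordant calls."""

    concordant: CallSet
    discordant: CallSet
    stage: str


def _support_partition(
    sets: Sequence[CallSet],
    min_support: int,
    stage: str,
    genotype_strict: bool = False,
) -> ConcordanceResult:
    """Variants present in >= min_support of the input sets are concordant.

    In genotype-strict mode, support counts agreeing (key, genotype) pairs:
    the best-supported genotype of a key must clear the threshold.
    """
    # input order must not matter: iterate sets in label order
    ordered = sorted(
        sets, key=lambda cs: cs.labels.astuple() if cs.labels else ()
    )
    support: Counter = Counter()
    gt_votes: dict[VariantKey, Counter] = defaultdict(Counter)
    for cs in ordered:
        for key, v in cs.variants.items():
            gt_votes[key][v.genotype] += 1
            support[(key, v.genotype) if genotype_strict else key] += 1
    if genotype_strict:
        best: dict[VariantKey, int] = {}
        for (key, _gt), n in support.items():
            best[key] = max(best.get(key, 0), n)
        keep = {k for k, n in best.items() if n >= min_support}
    else:
        keep = {k for k, n in support.items() if n >= min_support}

    # representative genotype: modal across carriers, smallest genotype on ties
    modal = {
        key: min(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        for key, votes in gt_votes.items()
    }
    concordant = CallSet(labels=ordered[0].labels, sample=ordered[0].sample)
    discordant = CallSet(labels=ordered[0].labels, sample=ordered[0].sample)
    for cs in ordered:
        for key, v in cs.variants.items():
            target = concordant if key in keep else discordant
            if key not in target.variants and v.genotype == modal[key]:
                target.variants[key] = v
    return ConcordanceResult(concordant, discordant, stage)


def replicate_concordance(
    replicates: Sequence[CallSet],
    min_support: int = 2,
    genotype_strict: bool = False,
) -> ConcordanceResult:
    """Filter variants seen in fewer than ``min_support`` replicates.

    With the study's triplicates and the default threshold, exactly the
    single-replicate variants are discarded as discordant.
    """
    if len(replicates) < 2:
        raise ConfigurationError("replicate concordance needs >= 2 replicates")
    return _support_partition(replicates, min_support, "replicate", genotype_strict)


def lab_concordance(
    per_lab_sets: Sequence[CallSet],
    min_support: int = 2,
    genotype_strict: bool = False,
) -> ConcordanceResult:
    """Filter variants found in only one lab's replicate-concordant set.

    With a single lab the stage is the identity (everything concordant),
    matching how samples sequenced in one lab skip lab comparison.
    """
    if len(per_lab_sets) == 0:
        raise ConfigurationError("lab concordance needs >= 1 input")
    if len(per_lab_sets) == 1:
        cs = per_lab_sets[0]
        empty = CallSet(labels=cs.labels, sample=cs.sample)
        return ConcordanceResult(cs, empty, "lab")
    return _support_partition(per_lab_sets, min_support, "lab", genotype_strict)


def aligner_concordance(
    per_aligner_sets: Sequence[CallSet],
    min_support: int = 2,
    genotype_strict: bool = False,
) -> ConcordanceResult:
    """Filter variants identified by only one aligner."""
    if len(per_aligner_sets) < 2:
        raise ConfigurationError("aligner concordance needs >= 2 aligners")
    return _support_partition(per_aligner_sets, min_support, "aligner", genotype_strict)


def caller_concordance(
    per_caller_sets: Sequence[CallSet],
    min_callers: int = 7,
    genotype_strict: bool = False,
) -> ConcordanceResult:
    """Keep variants shared by at least ``min_callers`` callers.

    The default of 7 discards variants shared by six or fewer callers.
    """
    if len(per_caller_sets) < min_callers:
        raise ConfigurationError(
            f"caller concordance needs >= min_callers={min_callers} caller sets, "
            f"got {len(per_caller_sets)}"
        )
    return _support_partition(per_caller_sets, min_callers, "caller", genotype_strict)


def twin_concordance(
    twinA: CallSet, twinB: CallSet, genotype_strict: bool = False
) -> ConcordanceResult:
    """Monozygotic twins share a germline: keep the identity-key intersection.

    The symmetric difference (plus genotype-disagreeing shared keys in
    strict mode) is discordant.
    """
    shared = twinA.keys() & twinB.keys()
    if genotype_strict:
        shared = {
            k for k in shared
            if twinA.variants[k].genotype == twinB.variants[k].genotype
        }
    concordant = twinA.subset(shared)
    discordant = CallSet(labels=twinA.labels, sample=twinA.sample)
    for cs in (twinA, twinB):
        for key, v in cs.variants.items():
            if key not in shared:
                discordant.variants.setdefault(key, v)
    return ConcordanceResult(concordant, discordant, "twin")


def mendelian_consistent(gF: Genotype, gM: Genotype, gC: Genotype) -> bool:
    """Can the child's diploid genotype arise from one allele per parent?

    Genotypes are unordered pairs over {0 (ref), 1 (alt)} at one biallelic
    site; 0/0 is the legal implicit genotype of a sample lacking the call.
    """
    gC = tuple(sorted(gC))
    return any(
        tuple(sorted((a, b))) == gC for a in set(gF) for b in set(gM)
    )


def mendelian_filter(
    pedigree: Pedigree,
    per_member_sets: Mapping[str, CallSet],
    allele_presence_only: bool = False,
) -> dict[str, ConcordanceResult]:
    """Site-wise Mendelian-rule compliance across a nuclear family.

    Over the union of the family's variant keys, a member without the key is
    treated as homozygous reference.  Variants whose transmission is
    consistent for every offspring are concordant; violating variants
    (including apparent de novo calls) are discordant for every member
    carrying them.  ``allele_presence_only`` relaxes the check to
    presence/absence: a child's variant only needs some parent to carry it,
    and a variant in both parents is never required in the child.
    """
    for member_id in pedigree.member_ids:
        if member_id not in per_member_sets:
            raise ConfigurationError(f"missing call set for family member {member_id}")

    father = per_member_sets[pedigree.father]
    mother = per_member_sets[pedigree.mother]
    offspring = {off: per_member_sets[off] for off in pedigree.offspring_ids}

    all_keys = father.keys() | mother.keys()
    for cs in offspring.values():
        all_keys |= cs.keys()

    def geno(cs: CallSet, key: VariantKey) -> Genotype:
        v = cs.variants.get(key)
        return v.genotype if v is not None else HOM_REF

    consistent_keys: set[VariantKey] = set()
    for key in all_keys:
        gF, gM = geno(father, key), geno(mother, key)
        if allele_presence_only:
            ok = all(
                (1 not in geno(cs, key)) or (1 in gF or 1 in gM)
                for cs in offspring.values()
            )
        else:
            ok = all(
                mendelian_consistent(gF, gM, geno(cs, key))
                for cs in offspring.values()
            )
        if ok:
            consistent_keys.add(key)

    out: dict[str, ConcordanceResult] = {}
    members = {pedigree.father: father, pedigree.mother: mother, **offspring}
    for member_id, cs in members.items():
        keep = cs.keys() & consistent_keys
        out[member_id] = ConcordanceResult(
            cs.subset(keep), cs.subset(cs.keys() - keep), "mendelian"
        )
    return out


@dataclass
class CascadeConfig:
    """Knobs of the HRV cascade."""

    min_support: int = 2       # replicate / lab / aligner presence threshold
    min_callers: int = 7       # caller-concordance threshold ("six or less" fails)
    genotype_strict: bool = False
    mendelian_allele_presence_only: bool = False


@dataclass
class CascadeOutcome:
    """Per-sample result of the full cascade."""

    hrvs: CallSet
    discordant: CallSet        # pooled across every stage
    stage_table: list[dict] = field(default_factory=list)


def _group(callsets: Sequence[CallSet], *factors: str) -> dict[tuple, list[CallSet]]:
    groups: dict[tuple, list[CallSet]] = defaultdict(list)
    for cs in callsets:
        if cs.labels is None:
            raise ConfigurationError("cascade inputs need FactorLabels")
        groups[cs.labels.drop(*factors)].append(cs)
    return dict(sorted(groups.items()))


def run_hrv_cascade(
    callsets: Sequence[CallSet],
    pedigrees: Sequence[Pedigree] = (),
    config: Optional[CascadeConfig] = None,
) -> dict[str, CascadeOutcome]:
    """Run replicate → lab → aligner → caller → twin → Mendelian filtering.

    ``callsets`` covers the factor grid (one CallSet per manifest row) for
    one or more samples; samples appearing in a pedigree additionally pass
    the family stages, while singleton samples' HRVs are their
    caller-concordant variants.
    """
    cfg = config or CascadeConfig()
    by_sample = _group(callsets, "lab", "platform", "library", "replicate", "aligner", "caller")

    outcomes: dict[str, CascadeOutcome] = {}
    caller_concordant: dict[str, CallSet] = {}
    for key, sample_sets in by_sample.items():
        sample = key[0]
        pooled_disc = CallSet(sample=sample)
        table: list[dict] = []

        def record(stage: str, results: list[ConcordanceResult]):
            n_in = sum(len(r.concordant) + len(r.discordant) for r in results)
            n_con = sum(len(r.concordant) for r in results)
            n_dis = sum(len(r.discordant) for r in results)
            table.append(
                {"stage": stage, "input_count": n_in, "concordant": n_con, "discordant": n_dis}
            )
            for r in results:
                for k, v in r.discordant.variants.items():
                    pooled_disc.variants.setdefault(k, v)

        # replicate stage: one result per (lab, aligner, caller) pipeline
        rep_results = []
        rep_sets: list[CallSet] = []
        for _, reps in _group(sample_sets, "replicate").items():
            res = replicate_concordance(reps, cfg.min_support, cfg.genotype_strict)
            rep_results.append(res)
            rep_sets.append(res.concordant)
        record("replicate", rep_results)

        # lab stage: per (aligner, caller) across labs
        lab_results = []
        lab_sets: list[CallSet] = []
        for _, per_lab in _group(rep_sets, "lab", "platform", "library").items():
            res = lab_concordance(per_lab, cfg.min_support, cfg.genotype_strict)
            lab_results.append(res)
            lab_sets.append(res.concordant)
        record("lab", lab_results)

        # aligner stage: per caller across aligners
        aln_results = []
        aln_sets: list[CallSet] = []
        for _, per_aln in _group(lab_sets, "aligner").items():
            if len(per_aln) == 1:
                aln_results.append(ConcordanceResult(per_aln[0], CallSet(sample=sample), "aligner"))
            else:
                aln_results.append(
                    aligner_concordance(per_aln, cfg.min_support, cfg.genotype_strict)
                )
            aln_sets.append(aln_results[-1].concordant)
        record("aligner", aln_results)

        res = caller_concordance(aln_sets, cfg.min_callers, cfg.genotype_strict)
        record("caller", [res])
        caller_concordant[sample] = res.concordant

        outcomes[sample] = CascadeOutcome(hrvs=res.concordant, discordant=pooled_disc, stage_table=table)

    # family stages
    for ped in pedigrees:
        missing = [m for m in ped.member_ids if m not in caller_concordant]
        if missing:
            raise ConfigurationError(
                f"pedigree {ped.family}: no call sets for members {missing}"
            )
        member_sets = {m: caller_concordant[m] for m in ped.member_ids}
        if ped.is_quartet:
            tw = twin_concordance(
                member_sets[ped.twinA], member_sets[ped.twinB], cfg.genotype_strict
            )
            for twin in (ped.twinA, ped.twinB):
                out = outcomes[twin]
                n_in = len(member_sets[twin])
                out.stage_table.append(
                    {
                        "stage": "twin",
                        "input_count": n_in,
                        "concordant": len(tw.concordant),
                        "discordant": n_in - len(member_sets[twin].subset(tw.concordant.keys())),
                    }
                )
                for k, v in tw.discordant.variants.items():
                    out.discordant.variants.setdefault(k, v)
                member_sets[twin] = member_sets[twin].subset(tw.concordant.keys())

        mend = mendelian_filter(
            ped,
            member_sets,
            allele_presence_only=cfg.mendelian_allele_presence_only,
        )
        for member_id, res in mend.items():
            out = outcomes[member_id]
            out.hrvs = res.concordant
            out.stage_table.append(
                {
                    "stage": "mendelian",
                    "input_count": len(res.concordant) + len(res.discordant),
                    "concordant": len(res.concordant),
                    "discordant": len(res.discordant),
                }
            )
            for k, v in res.discordant.variants.items():
                out.discordant.variants.setdefault(k, v)

    return outcomes
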