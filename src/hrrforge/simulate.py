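"""Synthetic study generator: pedigree genotypes, factor-structured call
sets, per-run region files, and difficult-region masks with known truth.

The generator emulates a replicated WGS study design: families (a
monozygotic-twin quartet and/or a trio), each sample sequenced in several
labs in triplicate, aligned with several aligners and called with several
callers — one call set per cell of the factor grid.  Error processes are
compositional and independent across factor axes: each caller, aligner and
replicate contributes a false-negative rate; false positives are drawn per
caller, partly from a caller-specific shared pool (a systematic caller
artifact recurring across labs/replicates/aligners) and partly privately;
genotype errors flip het/hom-alt.  Region files are the genome minus random
coverage-dropout gaps, independent across runs.

Everything is a pure function of (config, seed): a fixed config reproduces
byte-identical VCF/BED outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    CallSet,
    FactorLabels,
    GenomicInterval,
    Pedigree,
    RegionSet,
    VariantCall,
    VariantClass,
    VariantKey,
)

__all__ = [
    "SimulationConfig",
    "FamilySpec",
    "Truth",
    "SimulatedData",
    "simulate_pedigree",
    "simulate_callsets",
    "simulate_region_files",
    "simulate_study",
    "truth_callset",
    "write_outputs",
]

_BASES = np.array(list("ACGT"))
_GT_BY_CODE = {1: (0, 1), 2: (1, 1)}


@dataclass(frozen=True)
class FamilySpec:
    """A family to simulate: 'quartet' (MZ twins) or 'trio'."""

    family: str
    kind: str  # "quartet" | "trio"
    members: tuple[str, ...]  # father, mother, then offspring

    def pedigree(self) -> Pedigree:
        fa, mo, *off = self.members
        if self.kind == "quartet":
            return Pedigree(self.family, fa, mo, twinA=off[0], twinB=off[1])
        return Pedigree(self.family, fa, mo, child=off[0])


def _default_families() -> tuple[FamilySpec, ...]:
    return (
        FamilySpec("quartet", "quartet", ("Q_F", "Q_M", "Q_T1", "Q_T2")),
    )


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults model a desk-scale version of a replicated WGS design: a
    2 x 1 Mb diploid genome with 5000 true variant sites (80% SNV, 10%
    insertions, 10% deletions, indels <= 10 bp), a monozygotic-twin quartet,
    three labs (platform and library kit tied 1:1 to lab, as in a design
    where each lab runs one platform), triplicate runs, three aligners and
    seven callers; ~30x depth.
    """

    genome: tuple[tuple[str, int], ...] = (("chr1", 1_000_000), ("chr2", 1_000_000))
    n_sites: int = 5000
    class_mix: tuple[float, float, float] = (0.8, 0.1, 0.1)  # SNV, INS, DEL
    indel_max_len: int = 10
    af_beta: tuple[float, float] = (0.8, 0.8)  # U-shaped site-frequency spectrum
    families: tuple[FamilySpec, ...] = field(default_factory=_default_families)
    extra_singletons: tuple[str, ...] = ()  # samples outside any pedigree
    labs: tuple[str, ...] = ("lab1", "lab2", "lab3")
    replicates: tuple[str, ...] = ("r1", "r2", "r3")
    aligners: tuple[str, ...] = ("alnA", "alnB", "alnC")
    callers: tuple[str, ...] = ("c1", "c2", "c3", "c4", "c5", "c6", "c7")
    # error model
    caller_fn: tuple[float, ...] = (0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07)
    aligner_fn: tuple[float, ...] = (0.01, 0.02, 0.03)
    replicate_fn: float = 0.01
    caller_fp_rate: float = 0.02        # FP pool size as fraction of n_sites
    shared_fp_fraction: float = 0.9     # chance a pool FP recurs in a given cell
    private_fp_rate: float = 0.002      # per-cell private FPs, fraction of n_sites
    genotype_error: float = 0.005
    # depth model
    depth_mean: float = 30.0
    depth_sd: float = 8.0
    # region-file dropout and difficult masks
    gaps_per_mb: float = 5.0
    gap_mean_len: float = 500.0
    n_masks: int = 20
    mask_mean_len: float = 2000.0
    seed: int = 0

    @property
    def samples(self) -> tuple[str, ...]:
        out: list[str] = []
        for fam in self.families:
            out.extend(fam.members)
        out.extend(self.extra_singletons)
        return tuple(out)

    def platform_of(self, lab: str) -> str:
        return f"plat_{lab}"

    def library_of(self, lab: str) -> str:
        return f"lib_{lab}"


@dataclass
class Truth:
    """Ground-truth sites and per-member genotype codes (0/1/2 alt copies)."""

    sites: pd.DataFrame  # chrom, pos (1-based), ref, alt, vclass, af
    genotypes: dict[str, np.ndarray]
    pedigrees: tuple[Pedigree, ...]

    @property
    def keys(self) -> list[VariantKey]:
        return list(
            zip(self.sites["chrom"], self.sites["pos"], self.sites["ref"], self.sites["alt"])
        )


def _draw_sites(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Distinct variant sites with non-overlapping REF footprints."""
    chroms = [c for c, _ in config.genome]
    lengths = np.array([l for _, l in config.genome], dtype=float)
    margin = config.indel_max_len + 2
    rows = []
    n_chrom = np.round(lengths / lengths.sum() * config.n_sites).astype(int)
    n_chrom[-1] = config.n_sites - int(n_chrom[:-1].sum())
    for (chrom, length), n in zip(config.genome, n_chrom):
        # oversample, sort, enforce footprint spacing, trim to n
        pos = np.sort(
            rng.choice(np.arange(margin, length - margin), size=min(3 * n, length // margin), replace=False)
        )
        keep = [int(pos[0])] if pos.size else []
        for p in pos[1:]:
            if p - keep[-1] > margin:
                keep.append(int(p))
            if len(keep) == n:
                break
        if len(keep) < n:
            raise ValueError(f"cannot place {n} sites on {chrom} of length {length}")
        classes = rng.choice(3, size=n, p=list(config.class_mix))
        afs = rng.beta(*config.af_beta, size=n)
        for p, cls, af in zip(keep, classes, afs):
            ref = str(rng.choice(_BASES))
            if cls == 0:  # SNV
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            elif cls == 1:  # INS: alt extends ref
                ins_len = int(rng.integers(1, config.indel_max_len + 1))
                alt = ref + "".join(rng.choice(_BASES, size=ins_len))
            else:  # DEL: ref extends alt
                del_len = int(rng.integers(1, config.indel_max_len + 1))
                tail = "".join(rng.choice(_BASES, size=del_len))
                # avoid a trimmable suffix: last ref base must differ from alt base
                if tail[-1] == ref:
                    tail = tail[:-1] + ("A" if ref != "A" else "C")
                ref, alt = ref + tail, ref
            rows.append(
                {"chrom": chrom, "pos": p + 1, "ref": ref, "alt": alt,
                 "vclass": [VariantClass.SNV, VariantClass.INS, VariantClass.DEL][cls].value,
                 "af": float(af)}
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def _transmit(parent_codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per site from a parent's genotype codes (alt-copy counts)."""
    het = parent_codes == 1
    gametes = (parent_codes // 2).astype(np.int8)  # 0 -> 0, 2 -> 1
    gametes[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return gametes


def simulate_pedigree(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Truth:
    """Draw ground-truth genotypes: parents from the allele-frequency model,
    offspring by random gamete transmission, monozygotic twins identical.

    Every site is Mendelian-consistent by construction.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    sites = _draw_sites(config, rng)
    afs = sites["af"].to_numpy()
    genotypes: dict[str, np.ndarray] = {}
    for fam in config.families:
        fa, mo, *offspring = fam.members
        genotypes[fa] = rng.binomial(2, afs).astype(np.int8)
        genotypes[mo] = rng.binomial(2, afs).astype(np.int8)
        child = _transmit(genotypes[fa], rng) + _transmit(genotypes[mo], rng)
        if fam.kind == "quartet":
            genotypes[offspring[0]] = child
            genotypes[offspring[1]] = child.copy()
        else:
            genotypes[offspring[0]] = child
    for sid in config.extra_singletons:
        genotypes[sid] = rng.binomial(2, afs).astype(np.int8)
    peds = tuple(fam.pedigree() for fam in config.families)
    return Truth(sites=sites, genotypes=genotypes, pedigrees=peds)


def truth_callset(truth: Truth, sample: str) -> CallSet:
    """The sample's true variants as a CallSet (no depth)."""
    codes = truth.genotypes[sample]
    out = CallSet(sample=sample)
    s = truth.sites
    for i in np.nonzero(codes > 0)[0]:
        v = VariantCall(
            s.at[i, "chrom"], int(s.at[i, "pos"]), s.at[i, "ref"], s.at[i, "alt"],
            _GT_BY_CODE[int(codes[i])], None, VariantClass(s.at[i, "vclass"]),
        )
        out.variants[v.key] = v
    return out


def _fp_site_pool(
    config: SimulationConfig,
    truth: Truth,
    size: int,
    rng: np.random.Generator,
) -> list[VariantCall]:
    """Candidate false-positive SNVs at positions away from true footprints."""
    taken = {
        (row.chrom, p)
        for row in truth.sites.itertuples()
        for p in range(row.pos - 1, row.pos - 1 + len(row.ref) + 1)
    }
    out: list[VariantCall] = []
    chroms = config.genome
    while len(out) < size:
        ci = int(rng.integers(0, len(chroms)))
        chrom, length = chroms[ci]
        p = int(rng.integers(2, length - 2))
        if (chrom, p) in taken:
            continue
        taken.add((chrom, p))
        ref = str(rng.choice(_BASES))
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        out.append(VariantCall(chrom, p + 1, ref, alt, (0, 1), None, VariantClass.SNV))
    return out


@dataclass
class CellTruth:
    """Per-cell reconciliation counts: |truth| = |true emitted| + |FN|."""

    n_truth: int
    n_true_emitted: int
    n_fn: int
    n_fp: int


@dataclass
class SimulatedData:
    truth: Truth
    callsets: list[CallSet]
    fp_keys: dict[FactorLabels, set[VariantKey]]
    cell_truth: dict[FactorLabels, CellTruth]
    region_files: dict[tuple[str, str, str, str], RegionSet]  # (sample, lab, replicate, aligner)
    masks: list[RegionSet]
    config: SimulationConfig


def simulate_callsets(
    truth: Truth, config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[CallSet], dict[FactorLabels, set[VariantKey]], dict[FactorLabels, CellTruth]]:
    """Emit one CallSet per factor-grid cell, with FP labels and FN counts."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    sites = truth.sites
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    ref_arr = sites["ref"].to_numpy()
    alt_arr = sites["alt"].to_numpy()
    vclass_arr = [VariantClass(v) for v in sites["vclass"]]

    pool_size = int(round(config.caller_fp_rate * config.n_sites))
    caller_pools = {
        caller: _fp_site_pool(config, truth, pool_size, rng)
        for caller in config.callers
    }
    private_candidates = _fp_site_pool(
        config, truth, int(round(10 * config.private_fp_rate * config.n_sites)), rng
    )

    callsets: list[CallSet] = []
    fp_keys: dict[FactorLabels, set[VariantKey]] = {}
    cell_truth: dict[FactorLabels, CellTruth] = {}
    for sample in config.samples:
        codes = truth.genotypes[sample]
        present = np.nonzero(codes > 0)[0]
        n_truth = present.size
        for lab, rep, (ai, aligner), (ci, caller) in itertools.product(
            config.labs,
            config.replicates,
            enumerate(config.aligners),
            enumerate(config.callers),
        ):
            labels = FactorLabels(
                sample=sample,
                lab=lab,
                platform=config.platform_of(lab),
                library=config.library_of(lab),
                replicate=rep,
                aligner=aligner,
                caller=caller,
            )
            fn_rate = 1.0 - (
                (1.0 - config.caller_fn[ci % len(config.caller_fn)])
                * (1.0 - config.aligner_fn[ai % len(config.aligner_fn)])
                * (1.0 - config.replicate_fn)
            )
            keep = present[rng.random(n_truth) >= fn_rate]
            gts = codes[keep].copy()
            flips = rng.random(keep.size) < config.genotype_error
            gts[flips] = 3 - gts[flips]  # het <-> hom-alt
            depths = np.maximum(
                1, np.rint(rng.normal(config.depth_mean, config.depth_sd, size=keep.size))
            ).astype(int)

            cs = CallSet(labels=labels, sample=sample)
            for i, gt_code, dp in zip(keep, gts, depths):
                v = VariantCall(
                    chrom_arr[i], int(pos_arr[i]), ref_arr[i], alt_arr[i],
                    _GT_BY_CODE[int(gt_code)], int(dp), vclass_arr[i],
                )
                cs.variants[v.key] = v

            fps: set[VariantKey] = set()
            pool = caller_pools[caller]
            shared_mask = rng.random(len(pool)) < config.shared_fp_fraction
            if private_candidates:
                p_inc = min(1.0, config.private_fp_rate * config.n_sites / len(private_candidates))
                n_private = rng.binomial(len(private_candidates), p_inc)
            else:
                n_private = 0
            private_idx = rng.choice(len(private_candidates), size=min(n_private, len(private_candidates)), replace=False) if n_private else []
            fp_calls = [v for v, m in zip(pool, shared_mask) if m]
            fp_calls += [private_candidates[j] for j in sorted(private_idx)]
            fp_dp = np.maximum(
                1, np.rint(rng.normal(config.depth_mean, config.depth_sd, size=len(fp_calls)))
            ).astype(int)
            for v, dp in zip(fp_calls, fp_dp):
                if v.key in cs.variants:
                    continue
                vv = VariantCall(v.chrom, v.pos, v.ref, v.alt, v.genotype, int(dp), v.vclass)
                cs.variants[vv.key] = vv
                fps.add(vv.key)

            callsets.append(cs)
            fp_keys[labels] = fps
            cell_truth[labels] = CellTruth(
                n_truth=n_truth,
                n_true_emitted=int(keep.size),
                n_fn=int(n_truth - keep.size),
                n_fp=len(fps),
            )
    return callsets, fp_keys, cell_truth


def simulate_region_files(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[dict[tuple[str, str, str, str], RegionSet], list[RegionSet]]:
    """Per-run region files (genome minus dropout gaps) and difficult masks."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    genome_rs = RegionSet(
        [GenomicInterval(c, 0, l) for c, l in config.genome]
    )
    total_mb = sum(l for _, l in config.genome) / 1e6

    def random_intervals(n: int, mean_len: float) -> RegionSet:
        ivs = []
        for _ in range(n):
            ci = int(rng.integers(0, len(config.genome)))
            chrom, length = config.genome[ci]
            glen = max(10, int(rng.exponential(mean_len)))
            start = int(rng.integers(0, max(1, length - glen)))
            ivs.append(GenomicInterval(chrom, start, min(start + glen, length)))
        return RegionSet(ivs)

    region_files: dict[tuple[str, str, str, str], RegionSet] = {}
    for sample in config.samples:
        for lab, rep, aligner in itertools.product(
            config.labs, config.replicates, config.aligners
        ):
            n_gaps = int(rng.poisson(config.gaps_per_mb * total_mb))
            gaps = random_intervals(n_gaps, config.gap_mean_len) if n_gaps else RegionSet()
            region_files[(sample, lab, rep, aligner)] = genome_rs.subtract(gaps)

    masks = [random_intervals(config.n_masks, config.mask_mean_len)] if config.n_masks else []
    return region_files, masks


def simulate_study(config: Optional[SimulationConfig] = None) -> SimulatedData:
    """Full synthetic study: truth, call sets over the grid, region files, masks."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    truth = simulate_pedigree(config, rng)
    callsets, fp_keys, cell_truth = simulate_callsets(truth, config, rng)
    region_files, masks = simulate_region_files(config, rng)
    return SimulatedData(
        truth=truth,
        callsets=callsets,
        fp_keys=fp_keys,
        cell_truth=cell_truth,
        region_files=region_files,
        masks=masks,
        config=config,
    )


def write_outputs(data: SimulatedData, outdir) -> dict[str, object]:
    """Write VCFs, BEDs, pedigree, manifest and truth tables under ``outdir``.

    Returns the paths written (manifest, pedigree, masks, truth tables).
    File bytes are a pure function of the simulation config.
    """
    from .io import write_bed, write_manifest, write_pedigree, write_vcf

    outdir = Path(outdir)
    (outdir / "vcf").mkdir(parents=True, exist_ok=True)
    (outdir / "regions").mkdir(exist_ok=True)
    (outdir / "masks").mkdir(exist_ok=True)

    manifest_entries = []
    for cs in data.callsets:
        lb = cs.labels
        name = f"{lb.sample}_{lb.lab}_{lb.replicate}_{lb.aligner}_{lb.caller}.vcf"
        write_vcf(cs, outdir / "vcf" / name, contigs=data.config.genome)
        # store paths relative to outdir so outputs are byte-stable
        manifest_entries.append((f"vcf/{name}", lb))
    manifest_path = outdir / "manifest.tsv"
    write_manifest(manifest_entries, manifest_path)

    region_manifest_rows = []
    for (sample, lab, rep, aligner), rs in data.region_files.items():
        name = f"{sample}_{lab}_{rep}_{aligner}.bed"
        write_bed(rs, outdir / "regions" / name)
        region_manifest_rows.append(
            {"path": f"regions/{name}", "sample": sample,
             "lab": lab, "replicate": rep, "aligner": aligner}
        )
    pd.DataFrame(region_manifest_rows).to_csv(
        outdir / "region_manifest.tsv", sep="\t", index=False
    )

    mask_paths = []
    for i, mask in enumerate(data.masks, start=1):
        p = outdir / "masks" / f"difficult_{i}.bed"
        write_bed(mask, p)
        mask_paths.append(p)

    ped_path = outdir / "pedigree.ped"
    write_pedigree(list(data.truth.pedigrees), ped_path)

    sites = data.truth.sites.copy()
    for sample, codes in data.truth.genotypes.items():
        sites[f"gt_{sample}"] = codes
    sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)

    summary_rows = []
    for labels, ct in data.cell_truth.items():
        summary_rows.append(
            {f: getattr(labels, f) for f in
             ("sample", "lab", "platform", "library", "replicate", "aligner", "caller")}
            | {"n_truth": ct.n_truth, "n_true_emitted": ct.n_true_emitted,
               "n_fn": ct.n_fn, "n_fp": ct.n_fp}
        )
    pd.DataFrame(summary_rows).to_csv(outdir / "truth_summary.tsv", sep="\t", index=False)

    return {
        "manifest": manifest_path,
        "region_manifest": outdir / "region_manifest.tsv",
        "pedigree": ped_path,
        "masks": mask_paths,
        "truth_sites": outdir / "truth_sites.tsv",
        "truth_summary": outdir / "truth_summary.tsv",
    }
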