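"""End-to-end orchestration: regions → HRV cascade → HRR → metrics → variance.

``run_pipeline`` drives the file-based workflow from a YAML config;
``run_from_objects`` is the in-memory core the CLI, tests and simulations
share.  Outputs are deterministically sorted so reruns on identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import defaultdict
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .concordance import CascadeConfig, CascadeOutcome, run_hrv_cascade
from .factors import build_design, contribution_report, estimate_variance_components
from .hrr import carve_hrr
from .io import read_bed, read_manifest, read_pedigrees, read_vcf, write_bed, write_vcf
from .metrics import (
    avg_jaccard,
    depth_filter,
    records_to_dataframe,
    reproducibility_table,
)
from .model import CallSet, ConfigurationError, Pedigree, RegionSet
from .regions import (
    build_coverage_stack,
    consensus_threshold,
    select_consensus,
    subtract_difficult,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineParams", "PipelineResult", "run_pipeline", "run_from_objects"]


@dataclass
class PipelineParams:
    consensus_fraction: float = 0.99
    flank: int = 50
    min_support: int = 2
    min_callers: int = 7
    min_dp: int = 8
    max_dp: object = "auto"  # int, "auto", or None
    genotype_strict: bool = False
    pairings: tuple[str, ...] = ("technical", "lab", "aligner", "caller")


@dataclass
class PipelineResult:
    callable_regions: dict[str, RegionSet]
    consensus_k: dict[str, int]
    outcomes: dict[str, CascadeOutcome]
    hrr: dict[str, RegionSet]
    metrics: pd.DataFrame
    variance: Optional[dict]
    outdir: Optional[Path] = None


def run_from_objects(
    callsets: Sequence[CallSet],
    pedigrees: Sequence[Pedigree],
    region_files_by_sample: Mapping[str, Sequence[RegionSet]],
    masks: Sequence[RegionSet],
    params: Optional[PipelineParams] = None,
    outdir: Optional[Path] = None,
) -> PipelineResult:
    params = params or PipelineParams()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    samples = sorted({cs.sample for cs in callsets})

    # 1. region derivation per sample
    callable_regions: dict[str, RegionSet] = {}
    consensus_k: dict[str, int] = {}
    for sample in samples:
        files = list(region_files_by_sample.get(sample, ()))
        if not files:
            raise ConfigurationError(f"no region files for sample {sample}")
        stack = build_coverage_stack(files)
        k = consensus_threshold(stack, params.consensus_fraction)
        consensus = select_consensus(stack, k)
        callable_regions[sample] = subtract_difficult(consensus, list(masks))
        consensus_k[sample] = k
        if outdir is not None:
            write_bed(callable_regions[sample], outdir / f"callable.{sample}.bed")
            hist = stack.bases_by_count()
            pd.DataFrame(
                {"count": list(hist), "bases": list(hist.values())}
            ).to_csv(outdir / f"stack.{sample}.tsv", sep="\t", index=False)

    # 2. HRV cascade
    cascade_cfg = CascadeConfig(
        min_support=params.min_support,
        min_callers=params.min_callers,
        genotype_strict=params.genotype_strict,
    )
    outcomes = run_hrv_cascade(callsets, pedigrees, cascade_cfg)

    # 3. HRR carving
    hrr: dict[str, RegionSet] = {}
    for sample in samples:
        out = outcomes[sample]
        hrr[sample] = carve_hrr(
            callable_regions[sample], out.hrvs, out.discordant, params.flank
        )
        if outdir is not None:
            write_vcf(out.hrvs, outdir / f"hrv.{sample}.vcf")
            write_vcf(out.discordant, outdir / f"discordant.{sample}.vcf")
            write_bed(hrr[sample], outdir / f"hrr.{sample}.bed")
            pd.DataFrame(out.stage_table).to_csv(
                outdir / f"attrition.{sample}.tsv", sep="\t", index=False
            )

    # 4. depth filtering + reproducibility tables
    filtered = [
        depth_filter(cs, params.min_dp, params.max_dp) for cs in callsets
    ]
    hrvs_map = {s: outcomes[s].hrvs for s in samples}
    frames = []
    for sample in samples:
        sample_sets = [cs for cs in filtered if cs.sample == sample]
        for pairing in params.pairings:
            recs = reproducibility_table(
                sample_sets,
                pairing,
                hrr=hrr[sample],
                hrvs=hrvs_map,
                genotype_strict=params.genotype_strict,
            )
            if recs:
                df = records_to_dataframe(recs)
                df.insert(0, "pairing", pairing)
                frames.append(df)
    metrics_df = (
        pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    )
    if outdir is not None and not metrics_df.empty:
        metrics_df.to_csv(outdir / "metrics.tsv", sep="\t", index=False, float_format="%.6g")

    # 5. variance decomposition of per-pipeline average Jaccard
    variance = None
    design_records = _jaccard_design(filtered)
    if design_records:
        try:
            design = build_design([(lb, y) for lb, y in design_records])
            decomp = estimate_variance_components(design)
            variance = {
                "components": decomp.components,
                "proportions": decomp.proportions,
            }
            if outdir is not None:
                (outdir / "variance.json").write_text(
                    json.dumps(variance, indent=2, sort_keys=True) + "\n"
                )
                contribution_report(decomp).to_csv(
                    outdir / "variance.tsv", sep="\t", index=False, float_format="%.6g"
                )
        except ConfigurationError as exc:
            log.warning("variance decomposition skipped: %s", exc)

    return PipelineResult(
        callable_regions=callable_regions,
        consensus_k=consensus_k,
        outcomes=outcomes,
        hrr=hrr,
        metrics=metrics_df,
        variance=variance,
        outdir=outdir,
    )


def _jaccard_design(callsets: Sequence[CallSet]):
    """Average-Jaccard response per (caller, aligner, platform, sample) cell.

    Replicates within a (sample, lab, aligner, caller) pipeline are collapsed
    into one average pairwise Jaccard; labs map onto the platform factor
    (platform, library and lab are confounded by design).
    """
    from .model import FactorLabels

    groups: dict[tuple, list[CallSet]] = defaultdict(list)
    for cs in callsets:
        groups[cs.labels.drop("replicate")].append(cs)
    records = []
    for key, reps in sorted(groups.items()):
        if len(reps) != 3:
            log.info("jaccard design: cell %s has %d replicates; needs 3; skipped", key, len(reps))
            continue
        a, b, c = sorted(reps, key=lambda cs: cs.labels.replicate)
        y = avg_jaccard(a, b, c)
        if pd.isna(y):
            continue
        lb = a.labels
        records.append(
            (
                FactorLabels(
                    sample=lb.sample, lab=lb.lab, platform=lb.platform,
                    library=lb.library, replicate="-", aligner=lb.aligner,
                    caller=lb.caller,
                ),
                y,
            )
        )
    return records


def run_pipeline(config_path) -> PipelineResult:
    """File-based pipeline from a YAML config.

    The config names the VCF manifest, pedigree file, region-file manifest,
    difficult-region masks, output directory and stage parameters; every
    intermediate is written to the output directory together with a run log
    carrying the config hash and package version.
    """
    config_path = Path(config_path)
    raw = config_path.read_text()
    cfg = yaml.safe_load(raw)
    for key in ("manifest", "region_manifest", "outdir"):
        if key not in cfg:
            raise ConfigurationError(f"pipeline config missing {key!r}")

    params = PipelineParams(**cfg.get("params", {}))
    if isinstance(params.pairings, list):
        params.pairings = tuple(params.pairings)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)

    # relative paths in manifests resolve against the manifest's directory
    manifest_base = Path(cfg["manifest"]).resolve().parent

    def resolve(p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else manifest_base / p

    entries = read_manifest(cfg["manifest"])
    callsets = []
    for path, labels in entries:
        path = resolve(path)
        if not path.exists():
            raise ConfigurationError(f"VCF listed in manifest not found: {path}")
        callsets.append(read_vcf(path, sample=labels.sample, labels=labels))

    pedigrees: list[Pedigree] = []
    if cfg.get("pedigree"):
        pedigrees = sorted(read_pedigrees(cfg["pedigree"]).values(), key=lambda p: p.family)

    region_df = pd.read_csv(cfg["region_manifest"], sep="\t")
    if "path" not in region_df.columns or "sample" not in region_df.columns:
        raise ConfigurationError("region manifest needs 'path' and 'sample' columns")
    region_base = Path(cfg["region_manifest"]).resolve().parent
    region_files_by_sample: dict[str, list[RegionSet]] = defaultdict(list)
    for row in region_df.itertuples():
        p = Path(row.path)
        p = p if p.is_absolute() else region_base / p
        if not p.exists():
            raise ConfigurationError(f"region file not found: {p}")
        region_files_by_sample[row.sample].append(read_bed(p))

    masks = []
    for mask_path in cfg.get("masks", []) or []:
        p = resolve(mask_path)
        if not p.exists():
            raise ConfigurationError(f"mask file not found: {p}")
        masks.append(read_bed(p))

    result = run_from_objects(
        callsets,
        pedigrees,
        region_files_by_sample,
        masks,
        params=params,
        outdir=outdir,
    )

    run_log = {
        "tool": "hrrforge",
        "version": __version__,
        "config_sha256": hashlib.sha256(raw.encode()).hexdigest(),
        "params": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(params).items()},
        "samples": sorted(result.outcomes),
        "consensus_k": result.consensus_k,
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True) + "\n")
    return result
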