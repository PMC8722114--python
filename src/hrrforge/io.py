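"""Readers and writers for VCF, BED, pedigree, and factor-manifest files.

VCF parsing goes through pysam; everything is written back as sorted plain
text so that a fixed input produces byte-identical output files.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import pysam

from .model import (
    CallSet,
    ConfigurationError,
    FactorLabels,
    FormatError,
    GenomicInterval,
    InvalidVariantError,
    Pedigree,
    RegionSet,
    VariantCall,
    FACTOR_NAMES,
    chrom_sort_key,
    is_autosome,
    normalize_variant,
)

log = logging.getLogger(__name__)

_PASS_FILTERS = frozenset({"PASS", "."})


def read_vcf(
    path: Union[str, Path],
    sample: Optional[str] = None,
    labels: Optional[FactorLabels] = None,
    reference=None,
) -> CallSet:
    """Read one sample's variant calls from a VCF into a normalized CallSet.

    Multiallelic records are split into per-ALT calls with the genotype
    projected per allele; records that are homozygous reference, have a
    missing genotype, or fail FILTER are excluded, as are records on
    non-autosomes (the inheritance machinery assumes diploidy).
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        if sample is None:
            if len(samples) != 1:
                raise ConfigurationError(
                    f"{path}: sample must be named for a multi-sample VCF"
                )
            sample = samples[0]
        elif sample not in samples:
            raise ConfigurationError(f"sample {sample!r} absent from {path} header")

        calls: list[VariantCall] = []
        warned_nonauto = False
        for rec in vf:
            if rec.filter.keys() and not set(rec.filter.keys()) <= _PASS_FILTERS:
                continue
            if not is_autosome(rec.chrom):
                if not warned_nonauto:
                    log.warning("%s: dropping non-autosomal records (e.g. %s)", path, rec.chrom)
                    warned_nonauto = True
                continue
            fmt = rec.samples[sample]
            gt = fmt.get("GT")
            if gt is None or any(al is None for al in gt) or len(gt) != 2:
                continue
            depth = fmt.get("DP")
            if depth is not None:
                depth = int(depth)
            alts = rec.alts or ()
            for ai, alt in enumerate(alts, start=1):
                if alt is None or alt == "*" or alt.startswith("<") or "[" in alt or "]" in alt:
                    continue  # spanning deletion / symbolic / breakend allele
                proj = tuple(sorted(1 if al == ai else 0 for al in gt))
                if proj == (0, 0):
                    continue
                try:
                    pos, ref_n, alt_n = normalize_variant(
                        rec.chrom, rec.pos, rec.ref, alt, reference=reference
                    )
                except InvalidVariantError:
                    log.warning("%s: skipping unnormalizable record at %s:%s", path, rec.chrom, rec.pos)
                    continue
                calls.append(
                    VariantCall(rec.chrom, pos, ref_n, alt_n, proj, depth)
                )
    # split alleles of one record may normalize to the same key as a
    # neighbouring record; keep the first occurrence
    out = CallSet(labels=labels, sample=sample)
    for v in calls:
        out.variants.setdefault(v.key, v)
    return out


VCF_HEADER_TEMPLATE = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
)


def write_vcf(callset: CallSet, path: Union[str, Path], contigs=None) -> None:
    """Write a CallSet as a sorted single-sample VCF (plain text, deterministic)."""
    sample = callset.sample or "SAMPLE"
    lines = [VCF_HEADER_TEMPLATE]
    if contigs:
        for chrom, length in contigs:
            lines.append(f"##contig=<ID={chrom},length={length}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t%s\n" % sample)
    for v in callset:
        gt = "/".join(str(a) for a in v.genotype)
        if v.depth is None:
            fmt, vals = "GT", gt
        else:
            fmt, vals = "GT:DP", f"{gt}:{v.depth}"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\t{fmt}\t{vals}\n"
        )
    Path(path).write_text("".join(lines))


def read_bed(path: Union[str, Path]) -> RegionSet:
    """Read a BED3+ file into a RegionSet; overlapping intervals are merged."""
    intervals = []
    n_raw = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval {parts[0]}:{start}-{end}"
                )
            intervals.append(GenomicInterval(parts[0], start, end))
            n_raw += 1
    rs = RegionSet(intervals)
    if len(rs) < n_raw:
        log.warning("%s: merged %d overlapping/adjacent intervals", path, n_raw - len(rs))
    return rs


def write_bed(regions: RegionSet, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for iv in regions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_pedigrees(path: Union[str, Path]) -> dict[str, Pedigree]:
    """Read a PED-like TSV (family, id, father, mother, sex, twin_group).

    '0' or '.' mean "unset" for father/mother/twin_group.  Members with both
    parents inside the family are offspring; two offspring sharing a
    twin_group are a monozygotic twin pair.
    """
    rows: dict[str, list[tuple[str, str, str, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 pedigree columns")
            fam, sid, fa, mo = parts[0], parts[1], parts[2], parts[3]
            twin = parts[5] if len(parts) > 5 else "0"
            rows.setdefault(fam, []).append((sid, fa, mo, twin))

    out: dict[str, Pedigree] = {}
    for fam, members in rows.items():
        unset = {"0", ".", ""}
        ids = {sid for sid, *_ in members}
        offspring = [
            (sid, twin) for sid, fa, mo, twin in members
            if fa not in unset and mo not in unset
        ]
        if not offspring:
            continue  # founders-only family: no inheritance structure
        fa = next(f for _, f, m, _ in members if f not in unset)
        mo = next(m for _, f, m, _ in members if m not in unset)
        if fa not in ids or mo not in ids:
            raise ConfigurationError(f"{path}: family {fam} parents not in file")
        twins = [sid for sid, twin in offspring if twin not in unset]
        if len(twins) == 2:
            out[fam] = Pedigree(fam, fa, mo, twinA=twins[0], twinB=twins[1])
        elif len(offspring) == 1 and not twins:
            out[fam] = Pedigree(fam, fa, mo, child=offspring[0][0])
        else:
            raise ConfigurationError(
                f"{path}: family {fam} must be a trio or a monozygotic-twin quartet"
            )
    return out


def read_pedigree(path: Union[str, Path], family: Optional[str] = None) -> Pedigree:
    peds = read_pedigrees(path)
    if family is not None:
        if family not in peds:
            raise ConfigurationError(f"family {family!r} not found in {path}")
        return peds[family]
    if len(peds) != 1:
        raise ConfigurationError(
            f"{path} holds {len(peds)} families; name one explicitly"
        )
    return next(iter(peds.values()))


def write_pedigree(pedigrees: list[Pedigree], path: Union[str, Path]) -> None:
    lines = ["#family\tid\tfather\tmother\tsex\ttwin_group\n"]
    for ped in pedigrees:
        lines.append(f"{ped.family}\t{ped.father}\t0\t0\t1\t0\n")
        lines.append(f"{ped.family}\t{ped.mother}\t0\t0\t2\t0\n")
        for i, off in enumerate(ped.offspring_ids):
            twin = f"{ped.family}_mz" if ped.is_quartet else "0"
            lines.append(f"{ped.family}\t{off}\t{ped.father}\t{ped.mother}\t0\t{twin}\n")
    Path(path).write_text("".join(lines))


MANIFEST_COLUMNS = ("path",) + FACTOR_NAMES


def read_manifest(
    path: Union[str, Path],
    levels: Optional[dict[str, set[str]]] = None,
) -> list[tuple[str, FactorLabels]]:
    """Read a factor manifest TSV: one row per VCF, columns path + factor labels.

    When ``levels`` declares closed level sets, any row using an undeclared
    level raises a ConfigurationError.
    """
    import csv

    out: list[tuple[str, FactorLabels]] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "path" not in reader.fieldnames:
            raise FormatError(f"{path}: manifest needs a header with a 'path' column")
        missing = [c for c in MANIFEST_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: manifest missing columns {missing}")
        for row in reader:
            labels = FactorLabels(**{f: row[f] for f in FACTOR_NAMES})
            if levels:
                for factor, allowed in levels.items():
                    val = getattr(labels, factor)
                    if val not in allowed:
                        raise ConfigurationError(
                            f"{path}: {factor} level {val!r} not in declared set"
                        )
            out.append((row["path"], labels))
    return out


def write_manifest(entries: list[tuple[str, FactorLabels]], path: Union[str, Path]) -> None:
    lines = ["\t".join(MANIFEST_COLUMNS) + "\n"]
    for vcf_path, labels in entries:
        lines.append("\t".join((str(vcf_path),) + labels.astuple()) + "\n")
    Path(path).write_text("".join(lines))
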