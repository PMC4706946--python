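"""Readers and writers for the external formats.

Interchange formats are all plain text: a GenomeStudio-final-report-
style long TSV for intensities (and optionally calls), PED/MAP for
genotypes, minimal VCF 4.2 (GT only) for truth genotypes, BED for
off-target regions, JSON for cluster models ("cluster files") and
summaries, and YAML for rulesets and configuration. The proprietary
binary .egt cluster-file format is intentionally unsupported; the JSON
schema below is the documented equivalent.

Coordinates are 1-based everywhere except BED (0-based half-open), per
the respective conventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import AA, AB, BB, NC, ClusterModel, ClusterParams, GenotypeMatrix, IntensityMatrix, TruthGenotypes
from .rules import Rule, ruleset_from_dicts, ruleset_to_dicts

__all__ = [
    "FinalReportDialect",
    "read_final_report",
    "write_final_report",
    "write_ped_map",
    "read_ped_map",
    "write_vcf",
    "read_vcf",
    "write_cluster_json",
    "read_cluster_json",
    "read_off_target_bed",
    "apply_off_target",
    "write_ruleset_yaml",
    "read_ruleset_yaml",
]

CLUSTER_JSON_FORMAT = "exomeqc-cluster-v1"
_CALL_TO_STR = {AA: "AA", AB: "AB", BB: "BB", NC: "NC"}
_STR_TO_CALL = {v: k for k, v in _CALL_TO_STR.items()}


@dataclass(frozen=True)
class FinalReportDialect:
    """Column mapping of a final-report-style long TSV."""

    variant_col: str = "variant_id"
    sample_col: str = "sample_id"
    theta_col: str = "theta"
    r_col: str = "r"
    call_col: str = "call"  # optional in files
    delimiter: str = "\t"
    comment: str = "#"


DEFAULT_DIALECT = FinalReportDialect()


def read_final_report(
    path: str | Path,
    dialect: FinalReportDialect = DEFAULT_DIALECT,
) -> tuple[IntensityMatrix, GenotypeMatrix | None]:
    """Pivot a long-format report into matrices.

    Variants and samples appear in file order; a duplicated
    (variant, sample) row is an error. Rows with unparseable theta/R
    raise with a count of the offending rows. The genotype block is
    returned only when the call column is present.
    """
    df = pd.read_csv(path, sep=dialect.delimiter, comment=dialect.comment, dtype=str)
    required = [dialect.variant_col, dialect.sample_col, dialect.theta_col, dialect.r_col]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"final report is missing required column {col!r}")
    theta = pd.to_numeric(df[dialect.theta_col], errors="coerce")
    r = pd.to_numeric(df[dialect.r_col], errors="coerce")
    missing_val = df[dialect.theta_col].isna() & df[dialect.r_col].isna()
    bad = (theta.isna() | r.isna()) & ~missing_val
    if bad.any():
        raise ValueError(f"{int(bad.sum())} rows with unparseable theta/R "
                         f"(first at line {int(bad.idxmax()) + 2})")
    key = df[dialect.variant_col] + "\x00" + df[dialect.sample_col]
    if key.duplicated().any():
        first = df.loc[key.duplicated(), [dialect.variant_col, dialect.sample_col]].iloc[0]
        raise ValueError(f"duplicated (variant, sample) row: "
                         f"({first.iloc[0]}, {first.iloc[1]})")
    variants = list(dict.fromkeys(df[dialect.variant_col]))
    samples = list(dict.fromkeys(df[dialect.sample_col]))
    v_pos = {v: i for i, v in enumerate(variants)}
    s_pos = {s: j for j, s in enumerate(samples)}
    shape = (len(variants), len(samples))
    th = np.zeros(shape)
    rr = np.zeros(shape)
    mask = np.ones(shape, dtype=bool)
    vi = df[dialect.variant_col].map(v_pos).to_numpy()
    si = df[dialect.sample_col].map(s_pos).to_numpy()
    ok = ~missing_val.to_numpy()
    th[vi[ok], si[ok]] = theta.to_numpy()[ok]
    rr[vi[ok], si[ok]] = r.to_numpy()[ok]
    mask[vi[ok], si[ok]] = False
    intens = IntensityMatrix(variants, samples, th, rr, mask)
    calls = None
    if dialect.call_col in df.columns:
        cm = np.full(shape, NC, dtype=np.int8)
        codes = df[dialect.call_col].map(_STR_TO_CALL)
        if codes.isna().any():
            bad_val = df.loc[codes.isna(), dialect.call_col].iloc[0]
            raise ValueError(f"unknown genotype label {bad_val!r}")
        cm[vi, si] = codes.to_numpy(dtype=np.int8)
        calls = GenotypeMatrix(variants, samples, cm)
    return intens, calls


def write_final_report(
    path: str | Path,
    intensities: IntensityMatrix,
    calls: GenotypeMatrix | None = None,
    dialect: FinalReportDialect = DEFAULT_DIALECT,
) -> None:
    cols = {
        dialect.variant_col: np.repeat(intensities.variant_ids, intensities.n_samples),
        dialect.sample_col: np.tile(intensities.sample_ids, intensities.n_variants),
        dialect.theta_col: np.where(intensities.missing.ravel(), np.nan,
                                    intensities.theta.ravel()),
        dialect.r_col: np.where(intensities.missing.ravel(), np.nan,
                                intensities.r.ravel()),
    }
    if calls is not None:
        cols[dialect.call_col] = [_CALL_TO_STR[c] for c in calls.calls.ravel()]
    pd.DataFrame(cols).to_csv(path, sep=dialect.delimiter, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# PED/MAP

_SEX_TO_PED = {"male": "1", "female": "2"}
_PED_TO_SEX = {"1": "male", "2": "female"}


def write_ped_map(
    prefix: str | Path,
    genotypes: GenotypeMatrix,
    variant_meta: pd.DataFrame,
    sample_meta: pd.DataFrame | None = None,
) -> None:
    """Write <prefix>.ped / <prefix>.map. Genotypes are written as
    ref/alt allele letters from ``variant_meta``; NC as '0 0'."""
    prefix = Path(prefix)
    meta = variant_meta.set_index("variant_id").loc[genotypes.variant_ids]
    with open(prefix.with_suffix(".map"), "w") as fh:
        for vid, row in meta.iterrows():
            fh.write(f"{row['chrom']}\t{vid}\t0\t{row['pos']}\n")
    sex = {}
    if sample_meta is not None and "declared_sex" in sample_meta.columns:
        sex = dict(zip(sample_meta["sample_id"], sample_meta["declared_sex"]))
    ref = meta["ref"].to_numpy()
    alt = meta["alt"].to_numpy()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for j, sid in enumerate(genotypes.sample_ids):
            fields = [sid, sid, "0", "0", _SEX_TO_PED.get(sex.get(sid, ""), "0"), "-9"]
            col = genotypes.calls[:, j]
            for i in range(genotypes.n_variants):
                g = col[i]
                if g == AA:
                    fields += [ref[i], ref[i]]
                elif g == AB:
                    fields += [ref[i], alt[i]]
                elif g == BB:
                    fields += [alt[i], alt[i]]
                else:
                    fields += ["0", "0"]
            fh.write("\t".join(fields) + "\n")


def read_ped_map(
    prefix: str | Path,
    variant_meta: pd.DataFrame | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Read <prefix>.ped / <prefix>.map.

    With ``variant_meta`` (ref/alt per variant) the allele-letter to
    genotype mapping is exact; otherwise the first allele seen is
    treated as ref. '0 0' is a missing call. Returns (genotypes,
    variant_meta, sample_meta)."""
    prefix = Path(prefix)
    mp = pd.read_csv(prefix.with_suffix(".map"), sep="\t", header=None,
                     names=["chrom", "variant_id", "cm", "pos"], dtype=str)
    variants = list(mp["variant_id"])
    ped_rows = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6 + 2 * len(variants):
                raise ValueError("PED row width does not match MAP variant count")
            ped_rows.append(parts)
    samples = [row[1] for row in ped_rows]
    sexes = [_PED_TO_SEX.get(row[4], "") for row in ped_rows]
    if variant_meta is not None:
        meta = variant_meta.set_index("variant_id")
        ref = {v: str(meta.loc[v, "ref"]) for v in variants}
    else:
        ref = {}
        for i, v in enumerate(variants):
            for row in ped_rows:
                a = row[6 + 2 * i]
                if a != "0":
                    ref[v] = a
                    break
            ref.setdefault(v, "A")
    calls = np.full((len(variants), len(samples)), NC, dtype=np.int8)
    for j, row in enumerate(ped_rows):
        alleles = row[6:]
        for i, v in enumerate(variants):
            a1, a2 = alleles[2 * i], alleles[2 * i + 1]
            if a1 == "0" or a2 == "0":
                continue
            calls[i, j] = (a1 != ref[v]) + (a2 != ref[v])
    out_meta = mp[["variant_id", "chrom", "pos"]].copy()
    out_meta["pos"] = out_meta["pos"].astype(int)
    sample_meta = pd.DataFrame({"sample_id": samples, "declared_sex": sexes})
    return GenotypeMatrix(variants, samples, calls), out_meta, sample_meta


# ---------------------------------------------------------------------------
# VCF (minimal GT-only dialect)

def write_vcf(path: str | Path, truth: TruthGenotypes) -> None:
    """Write a minimal VCF 4.2 with GT only; code 0 maps to 0/0 (ref),
    1 to 0/1, 2 to 1/1 and NC to ./."""
    gt_map = {AA: "0/0", AB: "0/1", BB: "1/1", NC: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(truth.sites["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("##INFO=<ID=OT,Number=0,Type=Flag,Description=\"Off-target site\">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(truth.sample_ids) + "\n")
        for i, row in truth.sites.reset_index(drop=True).iterrows():
            info = "OT" if truth.off_target[i] else "."
            gts = "\t".join(gt_map[c] for c in truth.calls[i])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t"
                     f"{row['ref']}\t{row['alt']}\t.\t.\t{info}\tGT\t{gts}\n")


def _read_vcf_text(path: str | Path) -> TruthGenotypes:
    sites = []
    calls = []
    off = []
    samples: list[str] = []
    code = {"0/0": AA, "0|0": AA, "0/1": AB, "1/0": AB, "0|1": AB, "1|0": AB,
            "1/1": BB, "1|1": BB, "./.": NC, ".|.": NC, ".": NC}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.rstrip("\n").split("\t")[9:]
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, pos, vid, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            info = parts[7]
            fmt = parts[8].split(":")
            gt_idx = fmt.index("GT")
            row = [code.get(p.split(":")[gt_idx], NC) for p in parts[9:]]
            sites.append((vid, chrom, pos, ref, alt))
            off.append("OT" in info.split(";"))
            calls.append(row)
    sites_df = pd.DataFrame(sites, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    return TruthGenotypes(sites_df, samples, np.array(calls, dtype=np.int8),
                          np.array(off, dtype=bool))


def read_vcf(path: str | Path) -> TruthGenotypes:
    """Read GT-only genotypes from a VCF 4.x file.

    Uses cyvcf2 when available, falling back to a minimal text parser
    for the GT-only dialect this package writes. Sites with an OT info
    flag are marked off-target."""
    try:
        from cyvcf2 import VCF
    except ImportError:
        return _read_vcf_text(path)
    sites, calls, off = [], [], []
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    for var in vcf:
        sites.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS,
                      var.REF, var.ALT[0] if var.ALT else "N"))
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = NC
        calls.append(gt)
        off.append(bool(var.INFO.get("OT")))
    sites_df = pd.DataFrame(sites, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    return TruthGenotypes(sites_df, samples, np.array(calls, dtype=np.int8),
                          np.array(off, dtype=bool))


# ---------------------------------------------------------------------------
# cluster model JSON

def write_cluster_json(path: str | Path, model: ClusterModel) -> None:
    payload = {
        "format": CLUSTER_JSON_FORMAT,
        "d_max": model.d_max,
        "p_min": model.p_min,
        "provenance": model.provenance,
        "variants": {
            vid: {
                name: (None if not p.populated[g] else {
                    "theta_mean": float(p.theta_mean[g]),
                    "theta_dev": float(p.theta_dev[g]),
                    "r_mean": float(p.r_mean[g]),
                    "r_dev": float(p.r_dev[g]),
                })
                for g, name in enumerate(("AA", "AB", "BB"))
            }
            for vid, p in model.params.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_cluster_json(path: str | Path) -> ClusterModel:
    path = Path(path)
    if path.suffix.lower() == ".egt":
        raise ValueError(
            "binary .egt cluster files are unsupported; export the cluster "
            f"model as JSON (format {CLUSTER_JSON_FORMAT!r}) instead")
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != CLUSTER_JSON_FORMAT:
        raise ValueError(f"not a {CLUSTER_JSON_FORMAT} cluster file: {path}")
    params: dict[str, ClusterParams] = {}
    for vid, clusters in payload["variants"].items():
        theta_mean = np.array([0.1, 0.5, 0.9])
        theta_dev = np.ones(3)
        r_mean = np.ones(3)
        r_dev = np.full(3, 0.1)
        populated = np.zeros(3, dtype=bool)
        for g, name in enumerate(("AA", "AB", "BB")):
            c = clusters.get(name)
            if c is not None:
                populated[g] = True
                theta_mean[g] = c["theta_mean"]
                theta_dev[g] = c["theta_dev"]
                r_mean[g] = c["r_mean"]
                r_dev[g] = c["r_dev"]
        params[vid] = ClusterParams(theta_mean, theta_dev, r_mean, r_dev, populated)
    return ClusterModel(params, payload["d_max"], payload["p_min"],
                        payload.get("provenance", "supplied-file"))


# ---------------------------------------------------------------------------
# BED / ruleset YAML

def read_off_target_bed(path: str | Path) -> pd.DataFrame:
    """Read (chrom, start, end) regions; BED is 0-based half-open."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2], names=["chrom", "start", "end"],
                      dtype={"chrom": str, "start": int, "end": int})
    return bed


def apply_off_target(truth: TruthGenotypes, bed: pd.DataFrame) -> TruthGenotypes:
    """Flag truth sites falling inside any BED region as off-target
    (1-based site position vs 0-based half-open region)."""
    off = truth.off_target.copy()
    pos0 = truth.sites["pos"].to_numpy() - 1
    chrom = truth.sites["chrom"].astype(str).to_numpy()
    for row in bed.itertuples(index=False):
        off |= (chrom == str(row.chrom)) & (pos0 >= row.start) & (pos0 < row.end)
    return TruthGenotypes(truth.sites.copy(), list(truth.sample_ids),
                          truth.calls.copy(), off)


def write_ruleset_yaml(path: str | Path, ruleset) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"rules": ruleset_to_dicts(ruleset)}, fh, sort_keys=False)


def read_ruleset_yaml(path: str | Path) -> tuple[Rule, ...]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return ruleset_from_dicts(payload["rules"])
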