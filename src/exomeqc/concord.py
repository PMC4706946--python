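"""Concordance between array genotype calls and sequencing truth.

Three metrics, each computed per variant and summarized as mean and SD
across variants within minor-allele-frequency (or minor-allele-count)
strata:

- overall concordance: matching genotype pairs / compared pairs;
- non-reference concordance: restricted to pairs where the truth
  genotype carries at least one non-reference allele;
- heteroallele accuracy: among truth heterozygotes, the fraction the
  array also calls heterozygous.

Pairs where either side is NC/missing are excluded from numerator and
denominator alike and tallied separately. MAF strata are assigned from
the array cohort's MAF (common >= 5%, less common [1%, 5%), rare
< 1%); MAC strata from the truth cohort's MAC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AB, NC, GenotypeMatrix, TruthGenotypes

__all__ = [
    "MAF_CLASSES",
    "ConcordanceReport",
    "intersect_sites",
    "concordance_overall",
    "nonref_concordance",
    "het_accuracy",
    "compare_variant_sets",
]

#: (name, lo, hi) with MAF in [lo, hi); assignment from array MAF.
MAF_CLASSES = (
    ("common", 0.05, 0.51),
    ("less_common", 0.01, 0.05),
    ("rare", 0.0, 0.01),
)

_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


def intersect_sites(array_meta: pd.DataFrame, truth: TruthGenotypes) -> pd.DataFrame:
    """Match array variants to truth sites on chrom:pos and alleles.

    Returns one row per shared, on-target site with columns
    (variant_id, truth_index, flip); ``flip`` marks sites whose ref/alt
    orientation is swapped between the two sources (genotypes must be
    flipped hom-ref <-> hom-alt downstream). Strand-ambiguous A/T and
    C/G sites, where a swap cannot be told from a strand flip, are
    excluded; their count is stored in ``df.attrs['n_ambiguous']``,
    off-target exclusions in ``df.attrs['n_off_target']``.
    """
    t = truth.sites.reset_index().rename(columns={"index": "truth_index"})
    t["off_target"] = truth.off_target
    merged = array_meta.merge(
        t, on=["chrom", "pos"], suffixes=("_array", "_truth"), how="inner")
    same = (merged["ref_array"] == merged["ref_truth"]) & (merged["alt_array"] == merged["alt_truth"])
    swapped = (merged["ref_array"] == merged["alt_truth"]) & (merged["alt_array"] == merged["ref_truth"])
    merged = merged[same | swapped].copy()
    merged["flip"] = swapped[same | swapped]
    ambiguous = merged.apply(
        lambda row: {row["ref_array"], row["alt_array"]} in _AMBIGUOUS, axis=1
    ) if len(merged) else pd.Series(dtype=bool)
    n_ambiguous = int(ambiguous.sum()) if len(merged) else 0
    if len(merged):
        merged = merged[~ambiguous]
    n_off = int(merged["off_target"].sum()) if len(merged) else 0
    if len(merged):
        merged = merged[~merged["off_target"]]
    vid_col = "variant_id_array" if "variant_id_array" in merged.columns else "variant_id"
    out = merged[[vid_col, "truth_index", "flip"]].rename(
        columns={vid_col: "variant_id"}).reset_index(drop=True)
    out.attrs["n_ambiguous"] = n_ambiguous
    out.attrs["n_off_target"] = n_off
    return out


@dataclass
class ConcordanceReport:
    """Per-variant values and per-stratum mean +/- SD for one metric."""

    metric: str
    per_variant: pd.DataFrame  # variant_id, value, n_pairs, stratum
    summary: pd.DataFrame      # stratum, mean, sd, n_variants, n_pairs
    n_skipped: int

    def stratum(self, name: str) -> pd.Series:
        rows = self.summary[self.summary["stratum"] == name]
        if rows.empty:
            raise KeyError(f"no stratum {name!r} in report")
        return rows.iloc[0]


def _aligned(array_calls: GenotypeMatrix, truth: TruthGenotypes,
             shared: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Aligned (array, truth) call matrices over shared sites and the
    sample ids common to both (truth flipped where orientation differs)."""
    samples = [s for s in array_calls.sample_ids if s in set(truth.sample_ids)]
    a_sidx = [array_calls.sample_ids.index(s) for s in samples]
    t_sidx = [truth.sample_ids.index(s) for s in samples]
    a_vidx = [array_calls.variant_ids.index(v) for v in shared["variant_id"]]
    t_vidx = list(shared["truth_index"].astype(int))
    a = array_calls.calls[np.ix_(a_vidx, a_sidx)]
    t = truth.calls[np.ix_(t_vidx, t_sidx)].copy()
    flip = shared["flip"].to_numpy(dtype=bool)
    t[flip] = np.where(t[flip] == NC, NC, 2 - t[flip])
    return a, t, samples


def _array_maf(a: np.ndarray) -> np.ndarray:
    called = a != NC
    n_called = called.sum(axis=1)
    alt = np.where(called, a, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_called > 0, alt / (2 * n_called), np.nan)
    return np.minimum(f, 1 - f)


def _truth_mac(t: np.ndarray) -> np.ndarray:
    called = t != NC
    alt = np.where(called, t, 0).sum(axis=1)
    total = 2 * called.sum(axis=1)
    return np.minimum(alt, total - alt)


def _summarize(metric: str, ids: np.ndarray, values: np.ndarray,
               n_pairs: np.ndarray, strata: np.ndarray,
               stratum_order: list[str], n_skipped: int) -> ConcordanceReport:
    ok = np.isfinite(values)
    per_variant = pd.DataFrame({
        "variant_id": ids[ok], "value": values[ok],
        "n_pairs": n_pairs[ok].astype(int), "stratum": strata[ok],
    })
    rows = []
    for name in stratum_order + ["all"]:
        sub = per_variant if name == "all" else per_variant[per_variant["stratum"] == name]
        if len(sub):
            rows.append((name, float(sub["value"].mean()),
                         float(sub["value"].std(ddof=0)),
                         len(sub), int(sub["n_pairs"].sum())))
        else:
            rows.append((name, np.nan, np.nan, 0, 0))
    summary = pd.DataFrame(rows, columns=["stratum", "mean", "sd", "n_variants", "n_pairs"])
    return ConcordanceReport(metric, per_variant, summary, n_skipped)


def _per_variant_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.maximum(den, 1), np.nan)


def concordance_overall(
    array_calls: GenotypeMatrix,
    truth: TruthGenotypes,
    shared: pd.DataFrame,
    maf_classes=MAF_CLASSES,
) -> ConcordanceReport:
    """Overall per-variant concordance, stratified by array MAF."""
    a, t, _ = _aligned(array_calls, truth, shared)
    valid = (a != NC) & (t != NC)
    match = valid & (a == t)
    values = _per_variant_ratio(match.sum(axis=1), valid.sum(axis=1))
    maf = _array_maf(a)
    strata = np.array(["unassigned"] * len(values), dtype=object)
    for name, lo, hi in maf_classes:
        sel = np.isfinite(maf) & (maf >= lo) & (maf < hi)
        strata[sel & (strata == "unassigned")] = name
    order = [name for name, _, _ in maf_classes]
    ids = shared["variant_id"].to_numpy()
    return _summarize("overall", ids, values, valid.sum(axis=1), strata,
                      order, int(np.sum(~np.isfinite(values))))


def nonref_concordance(
    array_calls: GenotypeMatrix,
    truth: TruthGenotypes,
    shared: pd.DataFrame,
    mac_range: tuple[int, int] = (2, 5),
) -> ConcordanceReport:
    """Concordance restricted to pairs whose truth genotype carries a
    non-reference allele, stratified by truth MAC in ``mac_range``."""
    a, t, _ = _aligned(array_calls, truth, shared)
    valid = (a != NC) & (t != NC) & (t != 0)
    match = valid & (a == t)
    values = _per_variant_ratio(match.sum(axis=1), valid.sum(axis=1))
    mac = _truth_mac(t)
    in_range = (mac >= mac_range[0]) & (mac <= mac_range[1])
    values = np.where(in_range, values, np.nan)
    strata = np.array([f"mac{m}" for m in mac], dtype=object)
    order = [f"mac{m}" for m in range(mac_range[0], mac_range[1] + 1)]
    ids = shared["variant_id"].to_numpy()
    return _summarize("nonref", ids, values, valid.sum(axis=1), strata,
                      order, int(np.sum(~np.isfinite(values))))


def het_accuracy(
    array_calls: GenotypeMatrix,
    truth: TruthGenotypes,
    shared: pd.DataFrame,
    mac_range: tuple[int, int] = (2, 5),
) -> ConcordanceReport:
    """Among truth heterozygotes (array NC excluded), the fraction the
    array calls heterozygous; stratified by truth MAC."""
    a, t, _ = _aligned(array_calls, truth, shared)
    valid = (a != NC) & (t == AB)
    match = valid & (a == AB)
    values = _per_variant_ratio(match.sum(axis=1), valid.sum(axis=1))
    mac = _truth_mac(t)
    in_range = (mac >= mac_range[0]) & (mac <= mac_range[1])
    values = np.where(in_range, values, np.nan)
    strata = np.array([f"mac{m}" for m in mac], dtype=object)
    order = [f"mac{m}" for m in range(mac_range[0], mac_range[1] + 1)]
    ids = shared["variant_id"].to_numpy()
    return _summarize("het_accuracy", ids, values, valid.sum(axis=1), strata,
                      order, int(np.sum(~np.isfinite(values))))


def compare_variant_sets(set_a, set_b) -> tuple[int, int, int]:
    """Exact partition of two variant-id sets: (shared, unique to A,
    unique to B)."""
    a, b = set(set_a), set(set_b)
    if len(a) != len(list(set_a)) or len(b) != len(list(set_b)):
        raise ValueError("ids must be unique within each set")
    return len(a & b), len(a - b), len(b - a)
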