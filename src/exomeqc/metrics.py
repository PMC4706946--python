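"""Per-variant SNP statistics consumed by the flagging criteria.

These are the familiar array-QC statistics: call frequency, cluster
separation, per-genotype frequencies, AB cluster mean intensity,
heterozygote excess, per-cluster theta mean/deviation, and minor allele
frequency/count. The exact cluster-separation and het-excess formulas
used by commercial software are undocumented; the closed forms below
are declared surrogates, calibrated so that the conventional thresholds
(cluster separation 0.4, het excess 0.1 / -0.9) are meaningful on data
with the default simulated geometry.

All genotype frequencies are computed over CALLED samples only (NC
excluded). Equality-against-constant criteria (AB Freq = 0, AA Freq =
1, MAF > 0) are evaluated downstream on the integer counts reported
here, never on floating-point frequencies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import AA, AB, BB, NC, ClusterModel, ClusterParams, GenotypeMatrix, IntensityMatrix

__all__ = [
    "het_excess",
    "cluster_separation",
    "maf_mac",
    "compute_variant_metrics",
    "metrics_table",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = [
    "variant_id", "n_aa", "n_ab", "n_bb", "n_nc", "n_called",
    "call_freq", "freq_aa", "freq_ab", "freq_bb", "maf", "mac",
    "het_excess", "cluster_sep", "ab_r_mean",
    "t_mean_aa", "t_dev_aa", "t_mean_ab", "t_dev_ab", "t_mean_bb", "t_dev_bb",
]


def het_excess(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Signed excess of observed heterozygosity over its Hardy-Weinberg
    expectation, scaled to [-1, 1].

    With p the A-allele frequency from the counts, e = 2p(1-p) and
    o = n_ab / n_called: returns (o-e)/(1-e) when o >= e (excess,
    saturating at +1 when every call is heterozygous) and (o-e)/e when
    o < e (deficit, reaching -1 when no heterozygotes remain). A
    monomorphic variant (e = 0, o = 0) scores 0.
    """
    n_called = n_aa + n_ab + n_bb
    if n_called < 1:
        raise ValueError("het_excess needs at least one called sample")
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("counts must be non-negative")
    p = (2 * n_aa + n_ab) / (2 * n_called)
    e = 2.0 * p * (1.0 - p)
    o = n_ab / n_called
    if e == 0.0:
        return 0.0
    if o >= e:
        return (o - e) / (1.0 - e) if e < 1.0 else 0.0
    return (o - e) / e


def cluster_separation(params: ClusterParams) -> float:
    """Separation score in [0, 1] between adjacent populated clusters.

    For each adjacent populated pair with theta means mu1 < mu2 and devs
    s1, s2: sep = dmu / (dmu + 4 (s1 + s2)); the variant's score is the
    minimum over pairs, and 1.0 when at most one cluster is populated.
    """
    pop = np.flatnonzero(params.populated)
    if pop.size <= 1:
        return 1.0
    seps = []
    for a, b in zip(pop[:-1], pop[1:]):
        dmu = params.theta_mean[b] - params.theta_mean[a]
        seps.append(dmu / (dmu + 4.0 * (params.theta_dev[a] + params.theta_dev[b])))
    return float(min(seps))


def maf_mac(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, int]:
    """Minor allele frequency and count from genotype counts."""
    if n_aa + n_ab + n_bb < 1:
        raise ValueError("maf_mac needs at least one called sample")
    a = 2 * n_aa + n_ab
    b = 2 * n_bb + n_ab
    mac = min(a, b)
    return mac / (a + b), mac


def compute_variant_metrics(
    calls: np.ndarray,
    theta: np.ndarray,
    params: ClusterParams,
    r: np.ndarray | None = None,
) -> dict:
    """All statistics for one variant, from its calls, theta values and
    cluster parameters. Fields undefined for unpopulated/empty classes
    are NaN (absent), not zero."""
    calls = np.asarray(calls)
    theta = np.asarray(theta, dtype=float)
    n_aa = int((calls == AA).sum())
    n_ab = int((calls == AB).sum())
    n_bb = int((calls == BB).sum())
    n_nc = int((calls == NC).sum())
    n_called = n_aa + n_ab + n_bb
    total = n_called + n_nc
    out: dict = {
        "n_aa": n_aa, "n_ab": n_ab, "n_bb": n_bb, "n_nc": n_nc,
        "n_called": n_called,
        "call_freq": n_called / total if total else 0.0,
        "cluster_sep": cluster_separation(params),
    }
    if n_called:
        out["freq_aa"] = n_aa / n_called
        out["freq_ab"] = n_ab / n_called
        out["freq_bb"] = n_bb / n_called
        out["maf"], out["mac"] = maf_mac(n_aa, n_ab, n_bb)
        out["het_excess"] = het_excess(n_aa, n_ab, n_bb)
    else:
        for k in ("freq_aa", "freq_ab", "freq_bb", "maf", "mac", "het_excess"):
            out[k] = np.nan
    for code, name in ((AA, "aa"), (AB, "ab"), (BB, "bb")):
        pts = calls == code
        if pts.any():
            out[f"t_mean_{name}"] = float(theta[pts].mean())
            out[f"t_dev_{name}"] = float(theta[pts].std())
        else:
            out[f"t_mean_{name}"] = np.nan
            out[f"t_dev_{name}"] = np.nan
    ab_pts = calls == AB
    if r is not None and ab_pts.any():
        out["ab_r_mean"] = float(np.asarray(r, dtype=float)[ab_pts].mean())
    else:
        out["ab_r_mean"] = np.nan
    return out


def metrics_table(
    genotypes: GenotypeMatrix,
    intensities: IntensityMatrix,
    model: ClusterModel,
) -> pd.DataFrame:
    """The full per-variant metrics table (one row per variant)."""
    rows = []
    for i, vid in enumerate(genotypes.variant_ids):
        row = compute_variant_metrics(
            genotypes.calls[i], intensities.theta[i], model.params[vid],
            intensities.r[i],
        )
        row["variant_id"] = vid
        rows.append(row)
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)
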