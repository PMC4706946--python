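"""Cluster-model building, genotype calling, and automated reclustering.

The genotype caller is a deterministic stand-in for a proprietary array
clustering stack: per variant it fits a three-component constrained
mixture on the normalized allelic angle theta (components anchored near
configurable prior centers with the AA < AB < BB ordering enforced,
points weighted by their total intensity R), then assigns each sample to
the populated cluster with the highest posterior under a per-cluster
diagonal bivariate normal in (theta, R). A sample is a no-call (NC) when
its best Mahalanobis distance exceeds ``d_max`` or its best posterior
falls below ``p_min``.

``recluster_variant`` is the automated surrogate for manual cluster
repair: it drops low-intensity points, refits with robust outlier
trimming, dissolves implausibly wide components, widens over-tight
boundaries, and re-evaluates the variant against the cluster-error
rules to decide whether it was repaired, left untouched, or zeroed
(excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .containers import AA, AB, BB, NC, ClusterModel, ClusterParams, GenotypeMatrix, IntensityMatrix

__all__ = [
    "CallerConfig",
    "build_cluster_model",
    "build_cluster_models",
    "call_genotypes",
    "recluster_variant",
    "recluster_flagged",
    "shrink_devs",
]


@dataclass(frozen=True)
class CallerConfig:
    """Tunable parameters of the caller and the repair pipeline.

    Anchor windows keep mixture components near their prior centers;
    with the defaults the windows ([0, 0.28], [0.32, 0.68], [0.72, 1])
    are disjoint, which guarantees the AA < AB < BB ordering.
    """

    prior_centers: tuple[float, float, float] = (0.10, 0.50, 0.90)
    prior_devs: tuple[float, float, float] = (0.05, 0.05, 0.05)
    anchor_window: float = 0.18
    min_points: int = 2
    max_iter: int = 200
    tol: float = 1e-10
    min_theta_dev: float = 0.005
    min_r_dev: float = 0.02
    # no-call rule
    d_max: float = 4.0
    p_min: float = 0.7
    # repair pipeline
    r_frac: float = 0.4
    trim_sd: float = 3.0
    boundary_widen: float = 1.5
    nc_widen_threshold: float = 0.05
    dev_implausible: float = 0.07
    # a repaired component whose members' mean theta drifts farther
    # than this from its anchor center is dissolved (a genuine cluster
    # is held near its anchor by allele balance)
    mean_drift_max: float = 0.10
    # model-dev shrink applied to short-boundary variants at build time
    short_boundary_shrink: float = 0.25

    def windows(self) -> list[tuple[float, float]]:
        out = []
        for c in self.prior_centers:
            out.append((max(0.0, c - self.anchor_window),
                        min(1.0, c + self.anchor_window)))
        return out


DEFAULT_CONFIG = CallerConfig()


def _em_fit(theta: np.ndarray, weights: np.ndarray, config: CallerConfig
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic anchored EM on theta; returns (mu, sigma, pi, resp)."""
    mu = np.array(config.prior_centers, dtype=float)
    sigma = np.array(config.prior_devs, dtype=float)
    pi = np.full(3, 1.0 / 3.0)
    w = weights / weights.sum()
    wins = config.windows()
    resp = np.zeros((theta.size, 3))
    for _ in range(config.max_iter):
        logp = (
            -0.5 * ((theta[:, None] - mu[None, :]) / sigma[None, :]) ** 2
            - np.log(sigma[None, :])
            + np.log(np.maximum(pi[None, :], 1e-300))
        )
        logp -= logp.max(axis=1, keepdims=True)
        resp = np.exp(logp)
        resp /= resp.sum(axis=1, keepdims=True)
        wr = resp * w[:, None]
        mass = wr.sum(axis=0)
        new_mu = mu.copy()
        new_sigma = sigma.copy()
        for g in range(3):
            if mass[g] > 1e-12:
                m = float(wr[:, g] @ theta / mass[g])
                m = min(max(m, wins[g][0]), wins[g][1])
                v = float(wr[:, g] @ (theta - m) ** 2 / mass[g])
                new_mu[g] = m
                new_sigma[g] = max(math.sqrt(max(v, 0.0)), config.min_theta_dev)
        new_pi = np.maximum(mass, 1e-12)
        new_pi /= new_pi.sum()
        shift = np.abs(new_mu - mu).max()
        mu, sigma, pi = new_mu, new_sigma, new_pi
        if shift < config.tol:
            break
    return mu, sigma, pi, resp


def build_cluster_model(
    theta: np.ndarray,
    r: np.ndarray,
    missing: np.ndarray | None = None,
    config: CallerConfig = DEFAULT_CONFIG,
) -> ClusterParams:
    """Fit one variant's cluster geometry from its intensities.

    Deterministic: anchored EM initialized at the prior centers, no RNG.
    Components with fewer than ``min_points`` hard-assigned members are
    marked unpopulated. R statistics are computed per assigned
    component. With every sample missing, all clusters are unpopulated.
    """
    theta = np.asarray(theta, dtype=float)
    r = np.asarray(r, dtype=float)
    if missing is None:
        missing = np.zeros(theta.shape, dtype=bool)
    ok = ~np.asarray(missing, dtype=bool)
    t, rr = theta[ok], r[ok]
    centers = np.array(config.prior_centers)
    devs = np.array(config.prior_devs)
    empty = ClusterParams(centers.copy(), devs.copy(), np.ones(3), np.full(3, 0.1),
                          np.zeros(3, dtype=bool))
    if t.size == 0:
        return empty
    weights = np.maximum(rr, 1e-12)
    mu, sigma, _, resp = _em_fit(t, weights, config)
    assign = resp.argmax(axis=1)
    wins = config.windows()
    theta_mean = centers.astype(float).copy()
    theta_dev = devs.astype(float).copy()
    r_mean = np.full(3, float(np.median(rr)))
    r_dev = np.full(3, max(config.min_r_dev, 0.1))
    populated = np.zeros(3, dtype=bool)
    for g in range(3):
        pts = assign == g
        n_g = int(pts.sum())
        if n_g >= config.min_points:
            populated[g] = True
            m = float(t[pts].mean())
            theta_mean[g] = min(max(m, wins[g][0]), wins[g][1])
            theta_dev[g] = max(float(t[pts].std()), config.min_theta_dev)
            r_mean[g] = float(rr[pts].mean())
            r_dev[g] = max(float(rr[pts].std()), config.min_r_dev)
    # Rescue pass: EM anchored at the prior centers can starve a
    # component whose true points lie between anchors (e.g. a smeared
    # pseudo-heterozygote band), leaving them as stray outliers. Points
    # beyond d_max theta-distance from every populated cluster that are
    # numerous enough to form a cluster populate the nearest
    # unpopulated component, so downstream statistics see the cluster
    # instead of a silent hole.
    if populated.any() and not populated.all():
        pop = np.flatnonzero(populated)
        z = np.min(np.abs(t[:, None] - theta_mean[None, pop]) / theta_dev[None, pop],
                   axis=1)
        far = z > config.d_max
        if int(far.sum()) >= config.min_points:
            unpop = np.flatnonzero(~populated)
            nearest = unpop[np.argmin(
                np.abs(t[far][:, None] - centers[None, unpop]), axis=1)]
            far_idx = np.flatnonzero(far)
            for g in unpop:
                pts = far_idx[nearest == g]
                if pts.size >= config.min_points:
                    populated[g] = True
                    m = float(t[pts].mean())
                    theta_mean[g] = min(max(m, wins[g][0]), wins[g][1])
                    theta_dev[g] = max(float(t[pts].std()), config.min_theta_dev)
                    r_mean[g] = float(rr[pts].mean())
                    r_dev[g] = max(float(rr[pts].std()), config.min_r_dev)
    return ClusterParams(theta_mean, theta_dev, r_mean, r_dev, populated)


def shrink_devs(params: ClusterParams, factor: float) -> ClusterParams:
    """Scale all cluster deviations by ``factor`` (boundary tightening
    when < 1, widening when > 1)."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    out = params.copy()
    out.theta_dev = out.theta_dev * factor
    out.r_dev = out.r_dev * factor
    return out


def build_cluster_models(
    intensities: IntensityMatrix,
    config: CallerConfig = DEFAULT_CONFIG,
    shrink_variants: set[str] | frozenset[str] = frozenset(),
) -> ClusterModel:
    """Build a full cluster model from a cohort's intensities.

    ``shrink_variants`` lists variants whose model devs are tightened by
    ``config.short_boundary_shrink`` (the short-boundary pathology is a
    model defect, not a data defect).
    """
    params: dict[str, ClusterParams] = {}
    for i, vid in enumerate(intensities.variant_ids):
        p = build_cluster_model(intensities.theta[i], intensities.r[i],
                                intensities.missing[i], config)
        if vid in shrink_variants:
            p = shrink_devs(p, config.short_boundary_shrink)
        params[vid] = p
    return ClusterModel(params, d_max=config.d_max, p_min=config.p_min,
                        provenance="built-from-data")


def _call_one(theta: np.ndarray, r: np.ndarray, missing: np.ndarray,
              p: ClusterParams, d_max: float, p_min: float
              ) -> tuple[np.ndarray, np.ndarray]:
    n = theta.shape[0]
    calls = np.full(n, NC, dtype=np.int8)
    score = np.full(n, np.nan)
    pop = np.flatnonzero(p.populated)
    if pop.size == 0:
        return calls, score
    zt = (theta[:, None] - p.theta_mean[None, pop]) / p.theta_dev[None, pop]
    zr = (r[:, None] - p.r_mean[None, pop]) / p.r_dev[None, pop]
    d2 = zt ** 2 + zr ** 2
    loglik = -0.5 * d2 - np.log(p.theta_dev[None, pop] * p.r_dev[None, pop])
    loglik -= loglik.max(axis=1, keepdims=True)
    post = np.exp(loglik)
    post /= post.sum(axis=1, keepdims=True)
    best = post.argmax(axis=1)
    rows = np.arange(n)
    best_post = post[rows, best]
    best_d = np.sqrt(d2[rows, best])
    ok = (~missing) & (best_d <= d_max) & (best_post >= p_min)
    calls[ok] = pop[best[ok]]
    score[~missing] = best_post[~missing]
    return calls, score


def call_genotypes(
    intensities: IntensityMatrix,
    model: ClusterModel,
    config: CallerConfig | None = None,
) -> GenotypeMatrix:
    """Call genotypes for every (variant, sample) against a cluster model.

    The no-call thresholds come from the model (a cluster file carries
    its own calling rule); ``config`` may override them. Missing
    intensities are NC with an undefined score. Calling is idempotent:
    the same model and intensities always give the same calls.
    """
    d_max = config.d_max if config is not None else model.d_max
    p_min = config.p_min if config is not None else model.p_min
    absent = [v for v in intensities.variant_ids if v not in model]
    if absent:
        raise KeyError(f"variants absent from cluster model: {absent[:10]}"
                       + ("..." if len(absent) > 10 else ""))
    calls = np.full((intensities.n_variants, intensities.n_samples), NC, dtype=np.int8)
    score = np.full(calls.shape, np.nan)
    for i, vid in enumerate(intensities.variant_ids):
        calls[i], score[i] = _call_one(
            intensities.theta[i], intensities.r[i], intensities.missing[i],
            model.params[vid], d_max, p_min,
        )
    return GenotypeMatrix(list(intensities.variant_ids), list(intensities.sample_ids),
                          calls, score)


@dataclass
class ReclusterResult:
    params: ClusterParams
    status: str  # reclustered | zeroed | unchanged
    calls: np.ndarray
    score: np.ndarray


def _geometry_flags(theta: np.ndarray, r: np.ndarray, missing: np.ndarray,
                    params: ClusterParams, calls: np.ndarray, ruleset) -> list:
    """Evaluate the geometry (cluster-error) rules on one variant."""
    from .metrics import compute_variant_metrics
    from .rules import apply_ruleset

    import pandas as pd
    row = compute_variant_metrics(calls, theta, params, r)
    row["variant_id"] = "_v"
    table = pd.DataFrame([row])
    geometry = [rule for rule in ruleset if rule.kind == "geometry"]
    report = apply_ruleset(table, geometry)
    return list(report.hits["rule_id"].unique())


def recluster_variant(
    theta: np.ndarray,
    r: np.ndarray,
    missing: np.ndarray,
    params: ClusterParams,
    flags,
    config: CallerConfig = DEFAULT_CONFIG,
    ruleset=None,
) -> ReclusterResult:
    """Deterministic repair of one flagged variant.

    Pipeline: (1) drop points with R below ``r_frac`` x the variant's
    median R (degraded-intensity points); (2) refit the mixture with
    MAD-based outlier trimming at ``trim_sd`` and dissolve components
    whose theta spread exceeds ``dev_implausible`` (spurious smeared
    heterozygote clusters); (3) widen cluster devs by
    ``boundary_widen`` if the re-call NC rate exceeds
    ``nc_widen_threshold``; then re-evaluate the cluster-error rules.
    Status is ``unchanged`` when the flags were frequency-only and the
    geometry is already clean, ``zeroed`` when a cluster-error rule
    still fires after repair (the variant is excluded downstream), and
    ``reclustered`` otherwise.
    """
    from .rules import builtin_ruleset

    if ruleset is None:
        ruleset = builtin_ruleset("adjusted")
    theta = np.asarray(theta, dtype=float)
    r = np.asarray(r, dtype=float)
    missing = np.asarray(missing, dtype=bool)
    flags = list(flags)

    calls0, score0 = _call_one(theta, r, missing, params, config.d_max, config.p_min)
    nc_rate0 = float((calls0 == NC)[~missing].mean()) if (~missing).any() else 1.0
    freq_only = len(flags) > 0 and all(getattr(f, "kind", "geometry") == "frequency" for f in flags)
    if freq_only and nc_rate0 <= config.nc_widen_threshold:
        if not _geometry_flags(theta, r, missing, params, calls0, ruleset):
            return ReclusterResult(params.copy(), "unchanged", calls0, score0)

    ok = ~missing
    med_r = float(np.median(r[ok])) if ok.any() else 0.0
    keep = ok & (r >= config.r_frac * med_r)

    fit1 = build_cluster_model(theta[keep], r[keep], None, config)
    # robust trim: drop points far from their assigned component centre
    calls_fit, _ = _call_one(theta[keep], r[keep], np.zeros(keep.sum(), bool),
                             fit1, np.inf, 0.0)
    trim = np.zeros(int(keep.sum()), dtype=bool)
    kt = theta[keep]
    for g in np.flatnonzero(fit1.populated):
        pts = calls_fit == g
        if pts.sum() >= 3:
            med = np.median(kt[pts])
            mad = np.median(np.abs(kt[pts] - med)) * 1.4826
            scale = max(mad, config.min_theta_dev)
            trim[pts] = np.abs(kt[pts] - med) / scale > config.trim_sd
    keep_idx = np.flatnonzero(keep)
    refit_idx = keep_idx[~trim]
    fit2 = build_cluster_model(theta[refit_idx], r[refit_idx], None, config)
    # dissolve implausible components: too wide (smeared spurious
    # clusters) or drifted too far off their anchor center
    refit_assign, _ = _call_one(theta[refit_idx], r[refit_idx],
                                np.zeros(refit_idx.size, bool), fit2, np.inf, 0.0)
    for g in range(3):
        if not fit2.populated[g]:
            continue
        members = refit_assign == g
        drift = (abs(float(theta[refit_idx][members].mean()) - config.prior_centers[g])
                 if members.any() else 0.0)
        if fit2.theta_dev[g] > config.dev_implausible or drift > config.mean_drift_max:
            fit2.populated[g] = False

    def _zeroed() -> ReclusterResult:
        z = fit2.copy()
        z.populated[:] = False
        return ReclusterResult(z, "zeroed", np.full(theta.shape, NC, dtype=np.int8),
                               np.full(theta.shape, np.nan))

    if not fit2.populated.any():
        return _zeroed()

    calls1, score1 = _call_one(theta, r, missing, fit2, config.d_max, config.p_min)
    nc_rate = float((calls1 == NC)[ok].mean()) if ok.any() else 1.0
    if nc_rate > config.nc_widen_threshold:
        widened = shrink_devs(fit2, config.boundary_widen)
        calls_w, score_w = _call_one(theta, r, missing, widened, config.d_max, config.p_min)
        nc_w = float((calls_w == NC)[ok].mean()) if ok.any() else 1.0
        if nc_w < nc_rate:
            fit2, calls1, score1 = widened, calls_w, score_w

    if _geometry_flags(theta, r, missing, fit2, calls1, ruleset):
        return _zeroed()
    return ReclusterResult(fit2, "reclustered", calls1, score1)


def recluster_flagged(
    intensities: IntensityMatrix,
    model: ClusterModel,
    flag_report,
    config: CallerConfig = DEFAULT_CONFIG,
    ruleset=None,
) -> tuple[ClusterModel, dict[str, str]]:
    """Repair every flagged variant; returns the revised model and a
    per-variant status map (unflagged variants keep their parameters)."""
    from .rules import builtin_ruleset

    if ruleset is None:
        ruleset = builtin_ruleset("adjusted")
    by_id = {rule.id: rule for rule in ruleset}
    revised = model.copy()
    revised.provenance = "built-from-data"
    status: dict[str, str] = {}
    hits = flag_report.hits
    for vid, group in hits.groupby("variant_id", sort=False):
        i = intensities.variant_index(str(vid))
        flags = [by_id[rid] for rid in group["rule_id"] if rid in by_id]
        res = recluster_variant(
            intensities.theta[i], intensities.r[i], intensities.missing[i],
            model.params[str(vid)], flags, config, ruleset,
        )
        revised.params[str(vid)] = res.params
        status[str(vid)] = res.status
    return revised, status
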