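"""Synthetic exome-array intensity datasets with planted pathologies.

The generator emulates what an exome genotyping chip produces after
normalization: per-variant three-cluster (AA/AB/BB) structure in polar
(theta, R) intensity space, a minor-allele-frequency spectrum dominated
by monomorphic and rare variants, X-chromosome dosage (males
hemizygous), planted duplicate and parent-offspring sample pairs, and
three cluster-misclassification patterns seen on real chips:

``ab_misassign``
    a handful of homozygote samples smeared in theta toward the AB
    cluster, producing a spurious, overdispersed heterozygote cluster;
``low_r_wide_theta``
    a subset of samples with strongly reduced total intensity R and a
    wide theta scatter (degraded hybridization);
``short_boundary``
    the data are clean but the calling model's cluster boundaries are
    artificially tight, so cluster-edge samples become spurious no-calls.

Everything is reproducible from one integer seed; each operation draws
from a named substream so modules can be tested in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .containers import AA, AB, BB, ClusterModel, ClusterParams, GenotypeMatrix, IntensityMatrix, TruthGenotypes

__all__ = [
    "ClusterGeometry",
    "SimConfig",
    "SimBundle",
    "TABLE_MAF_SPECTRUM",
    "COMMON_MAF_SPECTRUM",
    "sample_maf_spectrum",
    "simulate_dataset",
    "inject_error_mode",
    "simulate_truth_seq",
]

ERROR_MODES = ("ab_misassign", "low_r_wide_theta", "short_boundary")

#: Default MAF spectrum: interval masses observed on a large East-Asian
#: exome-chip cohort (monomorphic variants dominate). Each entry is
#: (lo, hi, proportion); a variant assigned to an interval draws its MAF
#: uniformly within it, and a degenerate interval (lo == hi) yields that
#: exact value.
TABLE_MAF_SPECTRUM: tuple[tuple[float, float, float], ...] = (
    (0.0, 0.0, 0.6670),
    (0.0, 0.001, 0.1466),
    (0.001, 0.005, 0.0321),
    (0.005, 0.01, 0.0150),
    (0.01, 0.05, 0.0298),
    (0.05, 0.5, 0.1095),
)

#: All-common spectrum, useful for relatedness / sex-check simulations
#: where polymorphism is required.
COMMON_MAF_SPECTRUM: tuple[tuple[float, float, float], ...] = ((0.05, 0.5, 1.0),)

# Non strand-ambiguous ref/alt pairs (A/T and C/G sites cannot be
# strand-resolved at intersection time, so the simulator avoids them).
_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]


@dataclass(frozen=True)
class ClusterGeometry:
    """Generating cluster geometry shared by all variants.

    theta is Gaussian per genotype cluster; R is lognormal around
    ``r_mean`` with log-scale sigma ``r_sigma``.
    """

    theta_centers: tuple[float, float, float] = (0.10, 0.50, 0.90)
    # 0.02 keeps clean variants' sampled T Dev safely below the 0.025
    # flagging threshold, so the T Dev rules discriminate planted
    # pathologies from sampling noise
    theta_devs: tuple[float, float, float] = (0.02, 0.02, 0.02)
    r_means: tuple[float, float, float] = (1.0, 1.0, 1.0)
    r_sigmas: tuple[float, float, float] = (0.1, 0.1, 0.1)

    def validate(self) -> None:
        c = self.theta_centers
        if not (c[0] < c[1] < c[2]):
            raise ValueError("theta centers must satisfy AA < AB < BB")
        if any(d <= 0 for d in self.theta_devs + self.r_sigmas):
            raise ValueError("all devs must be > 0")
        if any(m <= 0 for m in self.r_means):
            raise ValueError("r means must be > 0")

    def cluster_params(self) -> ClusterParams:
        """The geometry expressed as calling-model parameters.

        The lognormal R is approximated by its Gaussian moments
        (exact enough at sigma ~ 0.1).
        """
        r_mean = np.array(self.r_means) * np.exp(np.array(self.r_sigmas) ** 2 / 2)
        r_dev = r_mean * np.sqrt(np.expm1(np.array(self.r_sigmas) ** 2))
        return ClusterParams(
            theta_mean=np.array(self.theta_centers),
            theta_dev=np.array(self.theta_devs),
            r_mean=r_mean,
            r_dev=r_dev,
            populated=np.ones(3, dtype=bool),
        )


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of a synthetic cohort."""

    n_samples: int = 500
    n_variants: int = 1000
    maf_spectrum: tuple[tuple[float, float, float], ...] = TABLE_MAF_SPECTRUM
    cluster_geometry: ClusterGeometry = field(default_factory=ClusterGeometry)
    x_chrom_fraction: float = 0.04
    dup_pairs: int = 0
    rel_pairs: int = 0
    error_mode_rates: tuple[tuple[str, float], ...] = ()
    error_maf_max: float = 0.05
    missing_rate: float = 0.0
    seed: int = 0
    #: when set, the variant panel (MAFs, positions, alleles) is drawn
    #: from this seed instead of ``seed``, so independent cohorts can
    #: share one panel (two-stage designs).
    panel_seed: int | None = None

    def validate(self) -> None:
        if self.n_samples < 2 or self.n_variants < 1:
            raise ValueError("need n_samples >= 2 and n_variants >= 1")
        props = [p for _, _, p in self.maf_spectrum]
        if any(p < 0 for p in props):
            raise ValueError("maf_spectrum proportions must be >= 0")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("maf_spectrum proportions must sum to 1")
        for lo, hi, _ in self.maf_spectrum:
            if not (0 <= lo <= hi <= 0.5):
                raise ValueError("maf intervals must lie within [0, 0.5]")
        self.cluster_geometry.validate()
        if not (0 <= self.x_chrom_fraction <= 1):
            raise ValueError("x_chrom_fraction must be in [0, 1]")
        for mode, rate in self.error_mode_rates:
            if mode not in ERROR_MODES:
                raise ValueError(f"unknown error mode {mode!r}; valid: {ERROR_MODES}")
            if not (0 <= rate <= 1):
                raise ValueError("error mode rates must be in [0, 1]")
        if 2 * (self.dup_pairs + self.rel_pairs) > self.n_samples:
            raise ValueError("too many planted pairs for n_samples")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SimBundle:
    """Everything one simulated cohort produces: intensities, error-free
    truth genotypes, sample/variant metadata and the planted-error
    registry (variant_id, mode, comma-joined affected sample ids)."""

    config: SimConfig
    intensities: IntensityMatrix
    truth_genotypes: GenotypeMatrix
    sample_meta: pd.DataFrame
    variant_meta: pd.DataFrame
    error_registry: pd.DataFrame

    def generating_model(self, d_max: float = 4.0, p_min: float = 0.7) -> ClusterModel:
        """The true cluster model the intensities were drawn from."""
        base = self.config.cluster_geometry.cluster_params()
        return ClusterModel(
            {v: base.copy() for v in self.intensities.variant_ids},
            d_max=d_max, p_min=p_min, provenance="supplied-file",
        )

    def error_variants(self, mode: str | None = None) -> list[str]:
        reg = self.error_registry
        if mode is not None:
            reg = reg[reg["mode"] == mode]
        return list(reg["variant_id"])


def sample_maf_spectrum(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw one true MAF per variant from the configured interval masses."""
    config.validate()
    spectrum = config.maf_spectrum
    props = np.array([p for _, _, p in spectrum], dtype=float)
    props = props / props.sum()
    idx = rng.choice(len(spectrum), size=config.n_variants, p=props)
    lo = np.array([s[0] for s in spectrum])[idx]
    hi = np.array([s[1] for s in spectrum])[idx]
    return lo + (hi - lo) * rng.random(config.n_variants)


def _draw_variant_meta(config: SimConfig, mafs: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_variants
    ids = [f"var{i:06d}" for i in range(n)]
    n_x = int(round(config.x_chrom_fraction * n))
    x_idx = rng.choice(n, size=n_x, replace=False) if n_x else np.array([], dtype=int)
    chrom = rng.integers(1, 23, size=n).astype(str)
    chrom[x_idx] = "X"
    pos = np.zeros(n, dtype=int)
    for c in np.unique(chrom):
        m = chrom == c
        pos[m] = np.cumsum(rng.integers(100, 10_000, size=int(m.sum()))) + 1_000_000
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    ref = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    alt = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    return pd.DataFrame({
        "variant_id": ids, "chrom": chrom, "pos": pos,
        "ref": ref, "alt": alt, "true_maf": mafs,
    })


def _draw_truth(config: SimConfig, meta: pd.DataFrame, sexes: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Hardy-Weinberg truth genotypes; X variants hemizygous in males
    (coded as the corresponding homozygote)."""
    n_v, n_s = config.n_variants, config.n_samples
    maf = meta["true_maf"].to_numpy()[:, None]
    calls = rng.binomial(2, np.broadcast_to(maf, (n_v, n_s))).astype(np.int8)
    is_x = (meta["chrom"] == "X").to_numpy()
    male = sexes == "male"
    if is_x.any() and male.any():
        hemi = 2 * rng.binomial(1, np.broadcast_to(maf, (n_v, n_s))).astype(np.int8)
        calls[np.ix_(is_x, male)] = hemi[np.ix_(is_x, male)]
    return calls


def _plant_pairs(config: SimConfig, calls: np.ndarray, meta: pd.DataFrame,
                 sexes: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Overwrite planted duplicate / parent-offspring columns.

    Duplicates copy the source genotypes exactly (all chromosomes;
    declared sex is forced equal). Parent-offspring pairs share one
    transmitted allele per autosomal variant; X genotypes of the child
    are left as drawn (no X transmission model).
    """
    n_s = config.n_samples
    rel = np.array(["none"] * n_s, dtype=object)
    partner = np.array([""] * n_s, dtype=object)
    ids = [f"samp{i:05d}" for i in range(n_s)]
    cursor = n_s - 2 * (config.dup_pairs + config.rel_pairs)
    maf = meta["true_maf"].to_numpy()
    autos = (meta["chrom"] != "X").to_numpy()
    for _ in range(config.dup_pairs):
        a, b = cursor, cursor + 1
        calls[:, b] = calls[:, a]
        sexes[b] = sexes[a]
        rel[a], rel[b] = "duplicate", "duplicate"
        partner[a], partner[b] = ids[b], ids[a]
        cursor += 2
    for _ in range(config.rel_pairs):
        a, b = cursor, cursor + 1  # a parent, b offspring
        transmitted = rng.binomial(1, calls[autos, a] / 2.0)
        other = rng.binomial(1, maf[autos])
        calls[autos, b] = (transmitted + other).astype(np.int8)
        rel[a], rel[b] = "parent", "offspring"
        partner[a], partner[b] = ids[b], ids[a]
        cursor += 2
    return pd.DataFrame({
        "sample_id": ids, "declared_sex": sexes,
        "relationship": rel, "partner_id": partner,
    })


def _draw_intensities(config: SimConfig, calls: np.ndarray,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    geom = config.cluster_geometry
    centers = np.array(geom.theta_centers)
    devs = np.array(geom.theta_devs)
    r_means = np.array(geom.r_means)
    r_sigmas = np.array(geom.r_sigmas)
    g = calls.astype(int)
    theta = rng.normal(centers[g], devs[g])
    theta = np.clip(theta, 0.0, 1.0)
    r = r_means[g] * np.exp(rng.normal(0.0, r_sigmas[g]))
    return theta, r


def inject_error_mode(
    theta: np.ndarray,
    r: np.ndarray,
    truth_column: np.ndarray,
    mode: str,
    params: dict | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Plant one misclassification pattern into one variant's intensities.

    Returns modified copies of (theta, r) and the affected sample
    indices (empty for ``short_boundary``, whose effect is applied at
    model-building time, and for k = 0).

    Default parameters (chosen to mimic the patterns on real chips, at
    the default geometry):

    - ``ab_misassign``: ``fraction`` 0.02 of samples (min 2, or explicit
      ``k``) of the major homozygote class get theta redrawn uniformly
      on [``band_lo``, ``band_hi``] = [0.2, 0.5], a smear toward the AB
      center.
    - ``low_r_wide_theta``: ``fraction`` 0.10 of samples get R scaled by
      ``r_factor`` 0.3 (< 0.4) and theta noise of SD ``theta_sd`` 0.15.
    - ``short_boundary``: points untouched; the registry entry instructs
      the model builder to shrink cluster devs for this variant.
    """
    if mode not in ERROR_MODES:
        raise ValueError(f"unknown error mode {mode!r}")
    params = dict(params or {})
    theta = np.array(theta, dtype=float, copy=True)
    r = np.array(r, dtype=float, copy=True)
    n = theta.shape[0]

    if mode == "short_boundary":
        return theta, r, np.array([], dtype=int)

    if "k" in params:
        k = int(params["k"])
    else:
        frac = float(params.get("fraction", 0.02 if mode == "ab_misassign" else 0.10))
        k = max(2, int(round(frac * n))) if frac > 0 else 0
    if k == 0:
        return theta, r, np.array([], dtype=int)

    if mode == "ab_misassign":
        truth_column = np.asarray(truth_column)
        major = AA if (truth_column == AA).sum() >= (truth_column == BB).sum() else BB
        hom_idx = np.flatnonzero(truth_column == major)
        if k > hom_idx.size:
            raise ValueError(
                f"ab_misassign k={k} exceeds {hom_idx.size} available homozygote samples"
            )
        affected = np.sort(rng.choice(hom_idx, size=k, replace=False))
        lo = float(params.get("band_lo", 0.2))
        hi = float(params.get("band_hi", 0.5))
        theta[affected] = rng.uniform(lo, hi, size=k)
        return theta, r, affected

    # low_r_wide_theta
    if k > n:
        raise ValueError(f"low_r_wide_theta k={k} exceeds {n} samples")
    affected = np.sort(rng.choice(n, size=k, replace=False))
    factor = float(params.get("r_factor", 0.3))
    if not (0 < factor < 0.4):
        raise ValueError("r_factor must be in (0, 0.4)")
    sd = float(params.get("theta_sd", 0.15))
    r[affected] *= factor
    theta[affected] = np.clip(theta[affected] + rng.normal(0.0, sd, size=k), 0.0, 1.0)
    return theta, r, affected


def _plant_errors(config: SimConfig, theta: np.ndarray, r: np.ndarray,
                  calls: np.ndarray, meta: pd.DataFrame,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Assign error modes to disjoint low-frequency variants and inject."""
    records: list[dict] = []
    eligible = np.flatnonzero(
        (meta["true_maf"].to_numpy() < config.error_maf_max)
        & (meta["chrom"].to_numpy() != "X")
    )
    eligible = rng.permutation(eligible)
    taken = 0
    ids = meta["variant_id"].to_numpy()
    for mode, rate in config.error_mode_rates:
        count = int(round(rate * config.n_variants))
        chosen = eligible[taken:taken + count]
        taken += count
        if len(chosen) < count:
            raise ValueError("not enough eligible low-MAF variants for error modes")
        for v in chosen:
            theta[v], r[v], affected = inject_error_mode(
                theta[v], r[v], calls[v], mode, None, rng
            )
            records.append({
                "variant_id": ids[v], "mode": mode,
                "sample_ids": ",".join(f"samp{i:05d}" for i in affected),
            })
    return pd.DataFrame(records, columns=["variant_id", "mode", "sample_ids"])


def simulate_dataset(config: SimConfig) -> SimBundle:
    """Generate a full synthetic cohort under the configured conditions."""
    config.validate()
    panel_seed = config.seed if config.panel_seed is None else config.panel_seed
    mafs = sample_maf_spectrum(config, substream(panel_seed, "maf"))
    meta = _draw_variant_meta(config, mafs, substream(panel_seed, "meta"))
    sex_rng = substream(config.seed, "sex")
    sexes = np.where(sex_rng.random(config.n_samples) < 0.5, "female", "male").astype(object)
    calls = _draw_truth(config, meta, sexes, substream(config.seed, "truth"))
    sample_meta = _plant_pairs(config, calls, meta, sexes, substream(config.seed, "pairs"))
    theta, r = _draw_intensities(config, calls, substream(config.seed, "intensity"))
    registry = _plant_errors(config, theta, r, calls, meta, substream(config.seed, "errors"))
    if config.missing_rate > 0:
        missing = substream(config.seed, "missing").random(theta.shape) < config.missing_rate
    else:
        missing = np.zeros(theta.shape, dtype=bool)
    sample_ids = list(sample_meta["sample_id"])
    variant_ids = list(meta["variant_id"])
    intensities = IntensityMatrix(variant_ids, sample_ids, theta, r, missing)
    truth = GenotypeMatrix(variant_ids, sample_ids, calls,
                           np.ones_like(calls, dtype=float))
    return SimBundle(config, intensities, truth, sample_meta, meta, registry)


def simulate_truth_seq(
    truth: GenotypeMatrix,
    variant_meta: pd.DataFrame,
    error_rate: float = 0.0,
    off_target_fraction: float = 0.0,
    rng: np.random.Generator | None = None,
) -> TruthGenotypes:
    """A sequencing-truth surrogate: independent per-genotype flip errors
    plus a random off-target site subset flagged for exclusion."""
    if not (0 <= error_rate < 1):
        raise ValueError("error_rate must be in [0, 1)")
    if not (0 <= off_target_fraction <= 1):
        raise ValueError("off_target_fraction must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(0)
    calls = truth.calls.copy()
    if error_rate > 0:
        flip = rng.random(calls.shape) < error_rate
        # flip to one of the two other genotype classes, uniformly
        shift = rng.integers(1, 3, size=calls.shape)
        calls[flip] = ((calls[flip] + shift[flip]) % 3).astype(np.int8)
    n_sites = len(variant_meta)
    off = np.zeros(n_sites, dtype=bool)
    n_off = int(round(off_target_fraction * n_sites))
    if n_off:
        off[rng.choice(n_sites, size=n_off, replace=False)] = True
    sites = variant_meta[["variant_id", "chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    return TruthGenotypes(sites, list(truth.sample_ids), calls, off)
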