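"""Sample- and variant-level quality control.

Native implementations of the classic GWAS QC battery: relatedness
screening from method-of-moments identity-by-descent (IBD) estimates,
X-chromosome sex checks via the heterozygosity statistic F, per-sample
and per-variant call-rate filters, the Hardy-Weinberg exact test,
minor-allele-count filters and duplicate-record removal.

The cascade runs sample QC first (relatedness, then sex, then call
rate, each recorded at first failure) and variant QC on the surviving
samples (call rate, HWE on autosomes, MAC, duplicates).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AA, AB, BB, NC, GenotypeMatrix

__all__ = [
    "QCConfig",
    "QCReport",
    "hwe_exact_test",
    "estimate_ibd",
    "check_sex",
    "qc_samples",
    "qc_variants",
    "run_qc",
]


@dataclass(frozen=True)
class QCConfig:
    """Thresholds of the QC cascade (conventional defaults).

    ``pi_hat_max`` 0.1875 is the midpoint between the second- and
    third-degree relative expectations. ``mac_min`` 2 removes both
    monomorphic variants and singletons. ``sex_min_expected_het`` is a
    robustness guard: a sample whose expected X heterozygote count is
    below it cannot be sexed reliably and is reported as unknown.
    """

    sample_call_rate_min: float = 0.99
    variant_call_rate_min: float = 0.95
    hwe_p_min: float = 1e-6
    mac_min: int = 2
    pi_hat_max: float = 0.1875
    sex_f_female_max: float = 0.2
    sex_f_male_min: float = 0.8
    sex_min_expected_het: float = 5.0
    #: relatedness screening is skipped (with a warning) below this
    #: many polymorphic variants: PI_HAT sampling noise (SD ~ 1.25 /
    #: sqrt(n)) must sit well below the pi_hat_max cutoff, or unrelated
    #: pairs get excluded by chance
    ibd_min_variants: int = 1000

    def validate(self) -> None:
        for name in ("sample_call_rate_min", "variant_call_rate_min"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0 < self.hwe_p_min < 1):
            raise ValueError("hwe_p_min must be in (0, 1)")
        if self.mac_min < 0:
            raise ValueError("mac_min must be >= 0")
        if not (0 <= self.pi_hat_max <= 1):
            raise ValueError("pi_hat_max must be in [0, 1]")
        if not (0 <= self.sex_f_female_max < self.sex_f_male_min <= 1):
            raise ValueError("sex F bounds must satisfy 0 <= female_max < male_min <= 1")


@dataclass
class QCReport:
    """Exclusions with reasons, plus the surviving matrix dimensions."""

    excluded_samples: pd.DataFrame
    excluded_variants: pd.DataFrame
    surviving_samples: list[str]
    surviving_variants: list[str]
    n_samples_in: int
    n_variants_in: int
    details: dict = field(default_factory=dict)

    def sample_counts(self) -> dict[str, int]:
        return self.excluded_samples["reason"].value_counts().to_dict()

    def variant_counts(self) -> dict[str, int]:
        return self.excluded_variants["reason"].value_counts().to_dict()


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts: enumerates every
    heterozygote count with the right parity, computes each
    configuration's probability under random mating, and sums the
    probabilities not exceeding the observed configuration's. Returns a
    p-value in (0, 1].
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    minor = min(n_a, n_b)
    if minor == 0:
        return 1.0
    lg = math.lgamma
    const = lg(n + 1) + lg(n_a + 1) + lg(n_b + 1) - lg(2 * n + 1)
    hs = list(range(minor % 2, minor + 1, 2))
    logp = []
    for h in hs:
        a = (n_a - h) // 2
        b = (n_b - h) // 2
        logp.append(const - lg(a + 1) - lg(h + 1) - lg(b + 1) + h * math.log(2.0))
    m = max(logp)
    probs = [math.exp(x - m) for x in logp]
    total = sum(probs)
    p_obs = probs[hs.index(n_ab)]
    cutoff = p_obs * (1.0 + 1e-12)
    p = sum(q for q in probs if q <= cutoff) / total
    return min(p, 1.0)


def _allele_freqs(calls: np.ndarray) -> np.ndarray:
    """A-allele frequency per variant over called entries (NaN where no
    calls)."""
    called = calls != NC
    n_called = called.sum(axis=1)
    dose_a = np.where(called, 2 - calls, 0).sum(axis=1)  # A alleles per variant
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, dose_a / (2 * n_called), np.nan)


def estimate_ibd(
    genotypes: GenotypeMatrix,
    pairs: list[tuple[str, str]] | None = None,
    min_variants: int = 100,
) -> pd.DataFrame:
    """Method-of-moments IBD from identity-by-state counts.

    Uses sample allele frequencies; monomorphic variants carry no IBD
    information and are dropped (an all-monomorphic input is an error).
    Z estimates are clipped to [0, 1] and renormalized;
    PI_HAT = Z2 + Z1 / 2.
    """
    calls = genotypes.calls
    p = _allele_freqs(calls)
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("IBD is undefined on monomorphic-only input")
    if poly.sum() < min_variants:
        warnings.warn(f"only {int(poly.sum())} polymorphic variants; "
                      f"IBD estimates will be noisy", stacklevel=2)
    g = calls[poly].astype(float)
    g[g == NC] = np.nan
    pp = p[poly]
    qq = 1.0 - pp
    # expected IBS-state probabilities per variant, given IBD state
    e0_i0 = 2 * pp**2 * qq**2
    e1_i0 = 4 * pp**3 * qq + 4 * pp * qq**3
    e2_i0 = pp**4 + 4 * pp**2 * qq**2 + qq**4
    e1_i1 = 2 * pp**2 * qq + 2 * pp * qq**2
    e2_i1 = pp**3 + pp**2 * qq + pp * qq**2 + qq**3

    ids = genotypes.sample_ids
    index = {s: i for i, s in enumerate(ids)}
    if pairs is None:
        pairs = [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    rows = []
    for id1, id2 in pairs:
        gi, gj = g[:, index[id1]], g[:, index[id2]]
        valid = ~np.isnan(gi) & ~np.isnan(gj)
        n_used = int(valid.sum())
        if n_used == 0:
            rows.append((id1, id2, np.nan, np.nan, np.nan, np.nan, 0))
            continue
        ibs = 2 - np.abs(gi[valid] - gj[valid])
        n0 = float((ibs == 0).sum())
        n1 = float((ibs == 1).sum())
        n2 = float((ibs == 2).sum())
        E0_0 = float(e0_i0[valid].sum())
        E1_0 = float(e1_i0[valid].sum())
        E2_0 = float(e2_i0[valid].sum())
        E1_1 = float(e1_i1[valid].sum())
        E2_1 = float(e2_i1[valid].sum())
        z0 = n0 / E0_0 if E0_0 > 0 else 0.0
        z1 = (n1 - z0 * E1_0) / E1_1 if E1_1 > 0 else 0.0
        z2 = (n2 - z0 * E2_0 - z1 * E2_1) / n_used
        z = np.clip([z0, z1, z2], 0.0, 1.0)
        z = z / z.sum() if z.sum() > 0 else np.array([1.0, 0.0, 0.0])
        pi_hat = z[2] + z[1] / 2.0
        rows.append((id1, id2, z[0], z[1], z[2], pi_hat, n_used))
    return pd.DataFrame(rows, columns=["id1", "id2", "Z0", "Z1", "Z2", "PI_HAT", "n_variants"])


def check_sex(
    x_genotypes: GenotypeMatrix,
    declared: pd.Series | dict,
    config: QCConfig = QCConfig(),
) -> pd.DataFrame:
    """Per-sample X-heterozygosity sex check.

    F = 1 - O(het)/E(het) over polymorphic X variants: ~1 for males
    (hemizygous, no true X heterozygotes), ~0 for females at
    Hardy-Weinberg equilibrium. Inference needs E(het) >=
    ``sex_min_expected_het``; status is ``fail`` only when an inferred
    sex conflicts with a declared one, and samples without a declared
    sex are skipped with a warning status.
    """
    config.validate()
    declared = dict(declared) if not isinstance(declared, dict) else declared
    calls = x_genotypes.calls
    p = _allele_freqs(calls)
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    rows = []
    for j, sid in enumerate(x_genotypes.sample_ids):
        col = calls[poly, j]
        called = col != NC
        e_het = float((2 * p[poly] * (1 - p[poly]))[called].sum())
        o_het = int((col == AB).sum())
        f = 1.0 - o_het / e_het if e_het > 0 else np.nan
        if e_het < config.sex_min_expected_het or not np.isfinite(f):
            inferred = "unknown"
        elif f < config.sex_f_female_max:
            inferred = "female"
        elif f > config.sex_f_male_min:
            inferred = "male"
        else:
            inferred = "unknown"
        dec = declared.get(sid)
        if dec not in ("male", "female"):
            status = "missing_declared"
        elif inferred != "unknown" and inferred != dec:
            status = "fail"
        else:
            status = "ok"
        rows.append((sid, o_het, e_het, f, inferred, dec, status))
    return pd.DataFrame(rows, columns=["sample_id", "o_het", "e_het", "F",
                                       "inferred", "declared", "status"])


def qc_samples(
    genotypes: GenotypeMatrix,
    x_genotypes: GenotypeMatrix | None,
    declared_sexes: pd.Series | dict,
    config: QCConfig = QCConfig(),
) -> QCReport:
    """Sample-level cascade: relatedness, sex check, call rate.

    Of each pair with PI_HAT above threshold the lower-call-rate member
    is dropped (ties: the later sample). Each sample is excluded at
    most once, with the first failing reason.
    """
    config.validate()
    ids = list(genotypes.sample_ids)
    call_rate = dict(zip(ids, genotypes.call_rate_per_sample()))
    excluded: dict[str, str] = {}
    details: dict = {}

    p = _allele_freqs(genotypes.calls)
    n_poly = int((np.isfinite(p) & (p > 0) & (p < 1)).sum())
    if n_poly >= config.ibd_min_variants:
        ibd = estimate_ibd(genotypes, min_variants=config.ibd_min_variants)
        details["ibd"] = ibd
        hits = ibd[ibd["PI_HAT"] > config.pi_hat_max].sort_values(
            "PI_HAT", ascending=False, kind="stable")
        for row in hits.itertuples():
            if row.id1 in excluded or row.id2 in excluded:
                continue
            drop = row.id2 if call_rate[row.id1] >= call_rate[row.id2] else row.id1
            excluded[drop] = "relatedness"
    else:
        warnings.warn(f"only {n_poly} polymorphic variants "
                      f"(< {config.ibd_min_variants}); relatedness check skipped",
                      stacklevel=2)

    if x_genotypes is not None:
        remaining = [s for s in ids if s not in excluded]
        sex = check_sex(x_genotypes, declared_sexes, config)
        details["sex"] = sex
        failed = set(sex.loc[sex["status"] == "fail", "sample_id"])
        for sid in remaining:
            if sid in failed:
                excluded[sid] = "sex_mismatch"

    for sid in ids:
        if sid not in excluded and call_rate[sid] < config.sample_call_rate_min:
            excluded[sid] = "low_call_rate"

    excluded_df = pd.DataFrame(
        [(s, r) for s, r in excluded.items()], columns=["sample_id", "reason"])
    survivors = [s for s in ids if s not in excluded]
    return QCReport(excluded_df, pd.DataFrame(columns=["variant_id", "reason"]),
                    survivors, list(genotypes.variant_ids),
                    len(ids), genotypes.n_variants, details)


def qc_variants(
    genotypes: GenotypeMatrix,
    variant_meta: pd.DataFrame,
    config: QCConfig = QCConfig(),
) -> QCReport:
    """Variant-level cascade: call rate, HWE (autosomes), MAC, duplicates.

    A variant with zero minor alleles is excluded as ``monomorphic``;
    one with 0 < MAC < ``mac_min`` as ``low_mac``. Of duplicate records
    (same chrom, pos, ref, alt) the higher-call-rate one is kept (ties:
    file order)."""
    config.validate()
    meta = variant_meta.set_index("variant_id")
    calls = genotypes.calls
    ids = list(genotypes.variant_ids)
    call_rate = dict(zip(ids, genotypes.call_rate_per_variant()))
    excluded: dict[str, str] = {}

    hwe_p: dict[str, float] = {}
    for i, vid in enumerate(ids):
        if call_rate[vid] < config.variant_call_rate_min:
            excluded[vid] = "low_call_rate"
            continue
        row = calls[i]
        n_aa = int((row == AA).sum())
        n_ab = int((row == AB).sum())
        n_bb = int((row == BB).sum())
        if n_aa + n_ab + n_bb == 0:
            excluded[vid] = "low_call_rate"
            continue
        chrom = str(meta.loc[vid, "chrom"]) if vid in meta.index else ""
        if chrom not in ("X", "Y", "23", "24"):
            p = hwe_exact_test(n_aa, n_ab, n_bb)
            hwe_p[vid] = p
            if p < config.hwe_p_min:
                excluded[vid] = "hwe"
                continue
        mac = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
        if mac == 0:
            excluded[vid] = "monomorphic"
            continue
        if mac < config.mac_min:
            excluded[vid] = "low_mac"
            continue

    survivors = [v for v in ids if v not in excluded]
    if {"chrom", "pos", "ref", "alt"}.issubset(variant_meta.columns):
        key = meta.loc[survivors, ["chrom", "pos", "ref", "alt"]].astype(str).agg(":".join, axis=1)
        by_key: dict[str, str] = {}
        for vid in survivors:
            k = key[vid]
            if k not in by_key:
                by_key[k] = vid
            else:
                kept = by_key[k]
                if call_rate[vid] > call_rate[kept]:
                    excluded[kept] = "duplicate"
                    by_key[k] = vid
                else:
                    excluded[vid] = "duplicate"
        survivors = [v for v in ids if v not in excluded]

    excluded_df = pd.DataFrame(
        [(v, r) for v, r in excluded.items()], columns=["variant_id", "reason"])
    return QCReport(pd.DataFrame(columns=["sample_id", "reason"]), excluded_df,
                    list(genotypes.sample_ids), survivors,
                    genotypes.n_samples, len(ids), {"hwe_p": hwe_p})


def _subset(genotypes: GenotypeMatrix, variant_ids=None, sample_ids=None) -> GenotypeMatrix:
    v_idx = (np.array([genotypes.variant_ids.index(v) for v in variant_ids], dtype=int)
             if variant_ids is not None else np.arange(genotypes.n_variants))
    s_idx = (np.array([genotypes.sample_ids.index(s) for s in sample_ids], dtype=int)
             if sample_ids is not None else np.arange(genotypes.n_samples))
    return GenotypeMatrix(
        [genotypes.variant_ids[i] for i in v_idx],
        [genotypes.sample_ids[j] for j in s_idx],
        genotypes.calls[np.ix_(v_idx, s_idx)],
        genotypes.score[np.ix_(v_idx, s_idx)],
    )


def run_qc(
    genotypes: GenotypeMatrix,
    variant_meta: pd.DataFrame,
    declared_sexes: pd.Series | dict,
    config: QCConfig = QCConfig(),
) -> QCReport:
    """Full cascade: sample QC (autosomes for IBD, X for sex) first,
    then variant QC on the surviving samples."""
    meta = variant_meta.set_index("variant_id")
    chrom = np.array([str(meta.loc[v, "chrom"]) for v in genotypes.variant_ids])
    is_x = np.isin(chrom, ("X", "23"))
    auto_ids = [v for v, x in zip(genotypes.variant_ids, is_x) if not x]
    x_ids = [v for v, x in zip(genotypes.variant_ids, is_x) if x]
    autosomes = _subset(genotypes, variant_ids=auto_ids)
    x_part = _subset(genotypes, variant_ids=x_ids) if x_ids else None
    s_report = qc_samples(autosomes, x_part, declared_sexes, config)
    surviving = _subset(genotypes, sample_ids=s_report.surviving_samples)
    v_report = qc_variants(surviving, variant_meta, config)
    return QCReport(
        s_report.excluded_samples, v_report.excluded_variants,
        s_report.surviving_samples, v_report.surviving_variants,
        genotypes.n_samples, genotypes.n_variants,
        {**s_report.details, **v_report.details},
    )
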