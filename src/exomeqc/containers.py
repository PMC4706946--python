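"""Core in-memory containers shared by all stages.

Genotype calls are encoded as small integers throughout:
``0 = AA`` (homozygous A allele), ``1 = AB`` (heterozygous),
``2 = BB`` (homozygous B allele), ``-1 = NC`` (no call / missing).
The A allele is the array's reference-strand allele; in the VCF view it
maps to REF and B to ALT unless a flip is recorded at site intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

AA: int = 0
AB: int = 1
BB: int = 2
NC: int = -1

GENOTYPE_LABELS = {AA: "AA", AB: "AB", BB: "BB", NC: "NC"}
CLUSTER_NAMES = ("AA", "AB", "BB")


def _as_ids(ids: Sequence[str]) -> list[str]:
    out = [str(i) for i in ids]
    if len(set(out)) != len(out):
        raise ValueError("identifiers must be unique")
    return out


@dataclass
class IntensityMatrix:
    """Per-variant x per-sample normalized polar intensities.

    theta is the normalized allelic angle in [0, 1]; r the normalized
    total intensity (>= 0). ``missing`` marks entries with no usable
    signal.
    """

    variant_ids: list[str]
    sample_ids: list[str]
    theta: np.ndarray
    r: np.ndarray
    missing: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.variant_ids = _as_ids(self.variant_ids)
        self.sample_ids = _as_ids(self.sample_ids)
        self.theta = np.asarray(self.theta, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        shape = (len(self.variant_ids), len(self.sample_ids))
        if self.theta.shape != shape or self.r.shape != shape:
            raise ValueError(f"theta/r must have shape {shape}")
        if self.missing is None:
            self.missing = np.zeros(shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != shape:
            raise ValueError("missing mask shape mismatch")
        ok = ~self.missing
        if np.any((self.theta[ok] < 0) | (self.theta[ok] > 1)):
            raise ValueError("theta outside [0, 1]")
        if np.any(self.r[ok] < 0):
            raise ValueError("r must be >= 0")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def variant_index(self, variant_id: str) -> int:
        return self.variant_ids.index(variant_id)

    def subset(self, variant_ids=None, sample_ids=None) -> "IntensityMatrix":
        vi = ([self.variant_ids.index(v) for v in variant_ids]
              if variant_ids is not None else range(self.n_variants))
        si = ([self.sample_ids.index(s) for s in sample_ids]
              if sample_ids is not None else range(self.n_samples))
        ix = np.ix_(np.fromiter(vi, dtype=int), np.fromiter(si, dtype=int))
        return IntensityMatrix(
            [self.variant_ids[i] for i in vi], [self.sample_ids[j] for j in si],
            self.theta[ix], self.r[ix], self.missing[ix])


@dataclass
class GenotypeMatrix:
    """Calls in {AA, AB, BB, NC} with a per-call confidence score.

    For NC entries the score is the (failing) best-cluster posterior, or
    NaN where no score was ever computed (e.g. missing intensity).
    """

    variant_ids: list[str]
    sample_ids: list[str]
    calls: np.ndarray
    score: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.variant_ids = _as_ids(self.variant_ids)
        self.sample_ids = _as_ids(self.sample_ids)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        shape = (len(self.variant_ids), len(self.sample_ids))
        if self.calls.shape != shape:
            raise ValueError(f"calls must have shape {shape}")
        if not np.isin(self.calls, [AA, AB, BB, NC]).all():
            raise ValueError("calls must be in {0, 1, 2, -1}")
        if self.score is None:
            self.score = np.full(shape, np.nan)
        self.score = np.asarray(self.score, dtype=float)
        if self.score.shape != shape:
            raise ValueError("score shape mismatch")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def variant_index(self, variant_id: str) -> int:
        return self.variant_ids.index(variant_id)

    def call_rate_per_sample(self) -> np.ndarray:
        return (self.calls != NC).mean(axis=0)

    def call_rate_per_variant(self) -> np.ndarray:
        return (self.calls != NC).mean(axis=1)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.variant_ids), list(self.sample_ids),
            self.calls.copy(), self.score.copy(),
        )

    def subset(self, variant_ids=None, sample_ids=None) -> "GenotypeMatrix":
        vi = ([self.variant_ids.index(v) for v in variant_ids]
              if variant_ids is not None else range(self.n_variants))
        si = ([self.sample_ids.index(s) for s in sample_ids]
              if sample_ids is not None else range(self.n_samples))
        ix = np.ix_(np.fromiter(vi, dtype=int), np.fromiter(si, dtype=int))
        return GenotypeMatrix(
            [self.variant_ids[i] for i in vi], [self.sample_ids[j] for j in si],
            self.calls[ix], self.score[ix])


@dataclass
class ClusterParams:
    """Cluster geometry for one variant: AA/AB/BB positions in (theta, R).

    Arrays are length 3, ordered (AA, AB, BB). Unpopulated clusters keep
    placeholder values and are excluded from calling.
    """

    theta_mean: np.ndarray
    theta_dev: np.ndarray
    r_mean: np.ndarray
    r_dev: np.ndarray
    populated: np.ndarray

    def __post_init__(self) -> None:
        for name in ("theta_mean", "theta_dev", "r_mean", "r_dev"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
            if getattr(self, name).shape != (3,):
                raise ValueError(f"{name} must have shape (3,)")
        self.populated = np.asarray(self.populated, dtype=bool)
        if self.populated.shape != (3,):
            raise ValueError("populated must have shape (3,)")
        pop = np.flatnonzero(self.populated)
        means = self.theta_mean[pop]
        if len(means) > 1 and not np.all(np.diff(means) > 0):
            raise ValueError("populated cluster theta means must increase AA < AB < BB")
        if np.any(self.theta_dev[pop] <= 0) or np.any(self.r_dev[pop] <= 0):
            raise ValueError("populated cluster devs must be > 0")

    def copy(self) -> "ClusterParams":
        return ClusterParams(
            self.theta_mean.copy(), self.theta_dev.copy(),
            self.r_mean.copy(), self.r_dev.copy(), self.populated.copy(),
        )


@dataclass
class ClusterModel:
    """A serializable 'cluster file': per-variant ClusterParams plus the
    no-call rule (max Mahalanobis distance, min posterior) and provenance."""

    params: dict[str, ClusterParams]
    d_max: float = 4.0
    p_min: float = 0.7
    provenance: str = "built-from-data"

    def __post_init__(self) -> None:
        if self.d_max <= 0 or not (0 <= self.p_min <= 1):
            raise ValueError("invalid no-call parameters")
        if self.provenance not in ("built-from-data", "supplied-file"):
            raise ValueError("provenance must be built-from-data or supplied-file")

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.params

    def callable_variants(self) -> list[str]:
        """Variants with at least one populated cluster (zeroed variants
        are carried in the file but cannot be called)."""
        return [v for v, p in self.params.items() if bool(p.populated.any())]

    def copy(self) -> "ClusterModel":
        return ClusterModel(
            {v: p.copy() for v, p in self.params.items()},
            self.d_max, self.p_min, self.provenance,
        )


@dataclass
class TruthGenotypes:
    """Sequencing-derived truth: sites, genotypes, and off-target flags.

    ``sites`` is a DataFrame with columns (variant_id, chrom, pos, ref,
    alt); genotype codes follow the package convention with ref treated
    as the A allele.
    """

    sites: pd.DataFrame
    sample_ids: list[str]
    calls: np.ndarray
    off_target: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        required = {"variant_id", "chrom", "pos", "ref", "alt"}
        if not required.issubset(self.sites.columns):
            raise ValueError(f"sites must have columns {sorted(required)}")
        keys = self.sites[["chrom", "pos", "ref", "alt"]].astype(str).agg(":".join, axis=1)
        if keys.duplicated().any():
            raise ValueError("site keys must be unique")
        bad = ~self.sites["ref"].isin(list("ACGT")) | ~self.sites["alt"].isin(list("ACGT"))
        if bad.any():
            raise ValueError("alleles must be single letters in {A,C,G,T}")
        self.sample_ids = _as_ids(self.sample_ids)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        shape = (len(self.sites), len(self.sample_ids))
        if self.calls.shape != shape:
            raise ValueError(f"calls must have shape {shape}")
        if self.off_target is None:
            self.off_target = np.zeros(len(self.sites), dtype=bool)
        self.off_target = np.asarray(self.off_target, dtype=bool)
        if self.off_target.shape != (len(self.sites),):
            raise ValueError("off_target shape mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.sites)
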