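"""QC cascade: HWE exact test, IBD, sex check, sample/variant filters."""

import math

import numpy as np
import pandas as pd
import pytest

import exomeqc as eq
from exomeqc.containers import AA, AB, BB, NC, GenotypeMatrix
from exomeqc.qc import QCConfig, check_sex, estimate_ibd, hwe_exact_test, qc_samples, qc_variants
from exomeqc.simdata import COMMON_MAF_SPECTRUM


def hwe_oracle(n_aa, n_ab, n_bb):
    """Brute-force enumeration with exact integer arithmetic."""
    n = n_aa + n_ab + n_bb
    n_a, n_b = 2 * n_aa + n_ab, 2 * n_bb + n_ab
    if min(n_a, n_b) == 0:
        return 1.0
    f = math.factorial
    weights = {}
    for h in range(min(n_a, n_b) % 2, min(n_a, n_b) + 1, 2):
        a, b = (n_a - h) // 2, (n_b - h) // 2
        weights[h] = f(n) // (f(a) * f(h) * f(b)) * 2 ** h
    w_obs = weights[n_ab]
    total = sum(weights.values())
    num = sum(w for w in weights.values() if w <= w_obs)
    return num * 10 ** 17 // total / 1e17


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_balanced_case_matches_enumeration(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(hwe_oracle(25, 50, 25),
                                                           abs=1e-12)

    def test_exhaustive_small_totals_match_enumeration(self):
        worst = 0.0
        for n in range(1, 61):
            for n_aa in range(n + 1):
                for n_ab in range(n - n_aa + 1):
                    n_bb = n - n_aa - n_ab
                    p = hwe_exact_test(n_aa, n_ab, n_bb)
                    assert 0.0 < p <= 1.0
                    worst = max(worst, abs(p - hwe_oracle(n_aa, n_ab, n_bb)))
        assert worst < 1e-12

    def test_strong_het_deficit_is_extreme(self):
        assert hwe_exact_test(50, 0, 50) < 1e-25

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestEstimateIbd:
    def test_three_relationship_classes_separate(self, related_bundle):
        sm = related_bundle.sample_meta.set_index("sample_id")
        dup = sm[sm.relationship == "duplicate"].index.tolist()
        parent = sm[sm.relationship == "parent"].index[0]
        child = sm.loc[parent, "partner_id"]
        unrel = sm[sm.relationship == "none"].index[:2].tolist()
        ibd = estimate_ibd(related_bundle.truth_genotypes,
                           pairs=[(dup[0], dup[1]), (parent, child),
                                  (unrel[0], unrel[1])])
        assert ibd.loc[0, "PI_HAT"] >= 0.95
        assert abs(ibd.loc[1, "PI_HAT"] - 0.5) <= 0.05
        assert ibd.loc[1, "Z1"] > max(ibd.loc[1, "Z0"], ibd.loc[1, "Z2"])
        assert ibd.loc[2, "PI_HAT"] <= 0.1

    def test_monomorphic_only_input_is_error(self):
        g = GenotypeMatrix(["v1", "v2"], ["s1", "s2"],
                           np.zeros((2, 2), dtype=np.int8))
        with pytest.raises(ValueError, match="monomorphic"):
            estimate_ibd(g)


@pytest.fixture(scope="module")
def x_bundle():
    return eq.simulate_dataset(eq.SimConfig(
        n_samples=120, n_variants=400, x_chrom_fraction=1.0,
        maf_spectrum=COMMON_MAF_SPECTRUM, seed=19))


class TestCheckSex:
    def test_males_have_f_near_one(self, x_bundle):
        sexes = dict(zip(x_bundle.sample_meta.sample_id,
                         x_bundle.sample_meta.declared_sex))
        out = check_sex(x_bundle.truth_genotypes, sexes).set_index("sample_id")
        males = [s for s, v in sexes.items() if v == "male"]
        females = [s for s, v in sexes.items() if v == "female"]
        assert (out.loc[males, "F"] > 0.99).all()
        assert (out.loc[females, "F"].abs() < 0.5).all()
        assert (out["status"] == "ok").all()

    def test_declared_conflict_fails(self, x_bundle):
        sexes = dict(zip(x_bundle.sample_meta.sample_id,
                         x_bundle.sample_meta.declared_sex))
        male = next(s for s, v in sexes.items() if v == "male")
        sexes[male] = "female"
        out = check_sex(x_bundle.truth_genotypes, sexes).set_index("sample_id")
        assert out.loc[male, "status"] == "fail"

    def test_missing_declared_sex_is_warned_not_failed(self, x_bundle):
        sexes = dict(zip(x_bundle.sample_meta.sample_id,
                         x_bundle.sample_meta.declared_sex))
        some = x_bundle.sample_meta.sample_id.iloc[0]
        del sexes[some]
        out = check_sex(x_bundle.truth_genotypes, sexes).set_index("sample_id")
        assert out.loc[some, "status"] == "missing_declared"


class TestQcSamples:
    def test_duplicate_pair_loses_exactly_one_member(self, related_bundle):
        sexes = dict(zip(related_bundle.sample_meta.sample_id,
                         related_bundle.sample_meta.declared_sex))
        report = qc_samples(related_bundle.truth_genotypes, None, sexes)
        sm = related_bundle.sample_meta.set_index("sample_id")
        dup = set(sm[sm.relationship == "duplicate"].index)
        rel_excluded = set(report.excluded_samples.loc[
            report.excluded_samples.reason == "relatedness", "sample_id"])
        assert len(dup & rel_excluded) == 1

    def test_low_call_rate_sample_excluded(self):
        rng = np.random.default_rng(0)
        calls = rng.choice([AA, AB, BB], size=(400, 10)).astype(np.int8)
        calls[:8, 0] = NC  # 2% missing on the first sample
        g = GenotypeMatrix([f"v{i}" for i in range(400)],
                           [f"s{j}" for j in range(10)], calls)
        report = qc_samples(g, None, {}, QCConfig(ibd_min_variants=10 ** 9))
        assert report.excluded_samples.set_index("sample_id").loc["s0", "reason"] \
            == "low_call_rate"

    def test_all_clean_cohort_has_zero_exclusions(self):
        # enough polymorphic variants that PI_HAT sampling noise stays
        # well below the relatedness cutoff
        bundle = eq.simulate_dataset(eq.SimConfig(
            n_samples=40, n_variants=3000, maf_spectrum=COMMON_MAF_SPECTRUM,
            x_chrom_fraction=0.0, seed=29))
        calls = eq.call_genotypes(bundle.intensities, bundle.generating_model())
        sexes = dict(zip(bundle.sample_meta.sample_id,
                         bundle.sample_meta.declared_sex))
        report = qc_samples(calls, None, sexes)
        assert len(report.excluded_samples) == 0


class TestQcVariants:
    def _matrix(self, columns, n_samples=100):
        ids = list(columns)
        calls = np.stack([columns[v] for v in ids])
        return GenotypeMatrix(ids, [f"s{j}" for j in range(n_samples)], calls)

    def _meta(self, ids, pos=None):
        return pd.DataFrame({
            "variant_id": ids,
            "chrom": ["1"] * len(ids),
            "pos": pos if pos is not None else range(100, 100 + len(ids)),
            "ref": ["A"] * len(ids), "alt": ["C"] * len(ids),
        })

    def test_reasons_assigned_correctly(self):
        n = 100
        hwe_violator = np.array([AA] * 50 + [BB] * 50, dtype=np.int8)
        cols = {
            "all_nc": np.full(n, NC, dtype=np.int8),
            "mono": np.full(n, AA, dtype=np.int8),
            "singleton": np.array([AB] + [AA] * (n - 1), dtype=np.int8),
            "hwe_bad": hwe_violator,
            "good": np.array([AA] * 49 + [AB] * 42 + [BB] * 9, dtype=np.int8),
        }
        g = self._matrix(cols)
        report = qc_variants(g, self._meta(list(cols)))
        excluded = report.excluded_variants.set_index("variant_id")["reason"]
        assert excluded["all_nc"] == "low_call_rate"
        assert excluded["mono"] == "monomorphic"
        assert excluded["singleton"] == "low_mac"
        assert excluded["hwe_bad"] == "hwe"
        assert report.surviving_variants == ["good"]

    def test_duplicate_records_keep_higher_call_rate(self):
        n = 100
        better = np.array([AA] * 50 + [AB] * 50, dtype=np.int8)
        worse = better.copy()
        worse[:4] = NC  # 96% call rate: passes the call-rate filter
        cols = {"keep_me": better, "drop_me": worse}
        g = self._matrix(cols)
        meta = self._meta(["keep_me", "drop_me"], pos=[500, 500])
        report = qc_variants(g, meta)
        excluded = report.excluded_variants.set_index("variant_id")["reason"]
        assert excluded["drop_me"] == "duplicate"
        assert "keep_me" in report.surviving_variants

    def test_x_variants_skip_hwe(self):
        n = 100
        col = np.array([AA] * 50 + [BB] * 50, dtype=np.int8)
        g = self._matrix({"xvar": col})
        meta = self._meta(["xvar"])
        meta["chrom"] = "X"
        report = qc_variants(g, meta)
        assert "xvar" in report.surviving_variants

    def test_tightening_thresholds_is_monotone(self, clean_bundle):
        calls = eq.call_genotypes(clean_bundle.intensities,
                                  clean_bundle.generating_model())
        loose = qc_variants(calls, clean_bundle.variant_meta,
                            QCConfig(mac_min=2))
        tight = qc_variants(calls, clean_bundle.variant_meta,
                            QCConfig(mac_min=5, variant_call_rate_min=0.99))
        assert len(tight.excluded_variants) >= len(loose.excluded_variants)
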