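"""Concordance metrics against sequencing truth; variant-set comparison."""

import numpy as np
import pandas as pd
import pytest

import exomeqc as eq
from exomeqc._rng import substream
from exomeqc.containers import AA, AB, BB, NC, GenotypeMatrix, TruthGenotypes
from exomeqc.concord import (
    compare_variant_sets, concordance_overall, het_accuracy, intersect_sites,
    nonref_concordance,
)
from exomeqc.simdata import simulate_truth_seq


def _sites(n, chrom="1", ref="A", alt="C"):
    return pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(n)],
        "chrom": [chrom] * n, "pos": range(100, 100 + n),
        "ref": [ref] * n, "alt": [alt] * n,
    })


def _pair(array_calls, truth_calls, ref="A", alt="C"):
    """Matched (GenotypeMatrix, TruthGenotypes, shared) from call arrays."""
    array_calls = np.asarray(array_calls, dtype=np.int8)
    truth_calls = np.asarray(truth_calls, dtype=np.int8)
    n_v, n_s = array_calls.shape
    sites = _sites(n_v, ref=ref, alt=alt)
    samples = [f"s{j}" for j in range(n_s)]
    array = GenotypeMatrix(list(sites.variant_id), samples, array_calls)
    truth = TruthGenotypes(sites, samples, truth_calls)
    meta = sites.copy()
    shared = intersect_sites(meta, truth)
    return array, truth, shared


class TestIntersectSites:
    def test_disjoint_lists_share_nothing(self, clean_bundle):
        truth = simulate_truth_seq(clean_bundle.truth_genotypes,
                                   clean_bundle.variant_meta, rng=substream(0, "c"))
        shifted = clean_bundle.variant_meta.copy()
        shifted["pos"] = shifted["pos"] + 10 ** 9
        assert len(intersect_sites(shifted, truth)) == 0

    def test_off_target_fraction_removed(self, clean_bundle):
        truth = simulate_truth_seq(clean_bundle.truth_genotypes,
                                   clean_bundle.variant_meta,
                                   off_target_fraction=0.1,
                                   rng=substream(1, "c"))
        shared = intersect_sites(clean_bundle.variant_meta, truth)
        n = len(clean_bundle.variant_meta)
        assert len(shared) == n - round(0.1 * n)
        assert shared.attrs["n_off_target"] == round(0.1 * n)

    def test_swapped_alleles_set_flip_flag(self):
        sites = _sites(2)
        truth = TruthGenotypes(sites, ["s0"], np.array([[AA], [AA]], dtype=np.int8))
        meta = sites.copy()
        meta.loc[1, ["ref", "alt"]] = ["C", "A"]  # swapped orientation
        shared = intersect_sites(meta, truth)
        assert list(shared["flip"]) == [False, True]

    def test_strand_ambiguous_sites_excluded(self):
        sites = _sites(2, ref="A", alt="T")
        truth = TruthGenotypes(sites, ["s0"], np.array([[AA], [AA]], dtype=np.int8))
        shared = intersect_sites(sites.copy(), truth)
        assert len(shared) == 0
        assert shared.attrs["n_ambiguous"] == 2


class TestConcordanceOverall:
    def test_identity_gives_mean_one_sd_zero(self, clean_bundle):
        truth = simulate_truth_seq(clean_bundle.truth_genotypes,
                                   clean_bundle.variant_meta, rng=substream(2, "c"))
        shared = intersect_sites(clean_bundle.variant_meta, truth)
        report = concordance_overall(clean_bundle.truth_genotypes, truth, shared)
        assert (report.summary["mean"].dropna() == 1.0).all()
        assert (report.summary["sd"].dropna() == 0.0).all()

    def test_two_mismatches_of_ten(self):
        a = np.full((1, 10), AA, dtype=np.int8)
        t = a.copy()
        t[0, :2] = BB
        array, truth, shared = _pair(a, t)
        report = concordance_overall(array, truth, shared)
        assert report.per_variant["value"].iloc[0] == pytest.approx(0.8)

    def test_nc_pairs_excluded_from_both_sides(self):
        a = np.array([[AA, AA, NC, AB]], dtype=np.int8)
        t = np.array([[AA, NC, AA, BB]], dtype=np.int8)
        array, truth, shared = _pair(a, t)
        report = concordance_overall(array, truth, shared)
        # two evaluable pairs, one match
        assert report.per_variant["n_pairs"].iloc[0] == 2
        assert report.per_variant["value"].iloc[0] == pytest.approx(0.5)

    def test_flip_error_rate_recovered(self):
        bundle = eq.simulate_dataset(eq.SimConfig(n_samples=150, n_variants=300,
                                                  seed=37))
        eps = 0.02
        truth = simulate_truth_seq(bundle.truth_genotypes, bundle.variant_meta,
                                   error_rate=eps, rng=substream(3, "c"))
        shared = intersect_sites(bundle.variant_meta, truth)
        report = concordance_overall(bundle.truth_genotypes, truth, shared)
        mean = report.stratum("all")["mean"]
        n_pairs = report.stratum("all")["n_pairs"]
        se = np.sqrt(eps * (1 - eps) / n_pairs)
        assert abs(mean - (1 - eps)) <= 3 * se

    def test_symmetric_in_the_two_call_sets(self):
        rng = np.random.default_rng(4)
        a = rng.choice([AA, AB, BB, NC], size=(30, 40), p=[0.5, 0.2, 0.2, 0.1])
        b = rng.choice([AA, AB, BB, NC], size=(30, 40), p=[0.5, 0.2, 0.2, 0.1])
        array1, truth1, shared1 = _pair(a, b)
        array2, truth2, shared2 = _pair(b, a)
        r1 = concordance_overall(array1, truth1, shared1)
        r2 = concordance_overall(array2, truth2, shared2)
        assert np.allclose(r1.per_variant["value"], r2.per_variant["value"])


class TestNonrefConcordance:
    def test_all_hom_ref_truth_is_empty_with_skips(self):
        a = np.full((5, 10), AA, dtype=np.int8)
        array, truth, shared = _pair(a, a)
        report = nonref_concordance(array, truth, shared)
        assert len(report.per_variant) == 0
        assert report.n_skipped == 5

    def test_two_of_three_example(self):
        t = np.array([[AB, AB, AB, AA, AA]], dtype=np.int8)
        a = np.array([[AB, AB, AA, AA, AA]], dtype=np.int8)
        array, truth, shared = _pair(a, t)
        report = nonref_concordance(array, truth, shared, mac_range=(2, 5))
        assert report.per_variant["value"].iloc[0] == pytest.approx(2 / 3)

    def test_perfect_calls_on_rare_variants_score_one(self):
        rng = np.random.default_rng(5)
        t = np.full((20, 50), AA, dtype=np.int8)
        for i in range(20):
            carriers = rng.choice(50, size=rng.integers(2, 6), replace=False)
            t[i, carriers] = AB
        array, truth, shared = _pair(t, t)
        report = nonref_concordance(array, truth, shared)
        assert (report.per_variant["value"] == 1.0).all()
        assert len(report.per_variant) == 20


class TestHetAccuracy:
    def test_identity_is_one(self):
        t = np.array([[AB, AB, AB, AA]], dtype=np.int8)
        array, truth, shared = _pair(t, t)
        report = het_accuracy(array, truth, shared, mac_range=(2, 5))
        assert report.per_variant["value"].iloc[0] == 1.0

    def test_nc_excluded_from_denominator(self):
        t = np.array([[AB, AB, AB, AB, AA]], dtype=np.int8)
        a = np.array([[AB, AB, AB, NC, AA]], dtype=np.int8)
        array, truth, shared = _pair(a, t)
        report = het_accuracy(array, truth, shared, mac_range=(2, 5))
        assert report.per_variant["value"].iloc[0] == 1.0
        assert report.per_variant["n_pairs"].iloc[0] == 3

    def test_evaluable_pairs_nest_across_metrics(self):
        rng = np.random.default_rng(6)
        a = rng.choice([AA, AB, BB, NC], size=(40, 30), p=[0.4, 0.3, 0.2, 0.1])
        t = rng.choice([AA, AB, BB, NC], size=(40, 30), p=[0.4, 0.3, 0.2, 0.1])
        array, truth, shared = _pair(a, t)
        overall = concordance_overall(array, truth, shared)
        max_mac = 30  # ceiling on the minor allele count at 30 samples
        nonref = nonref_concordance(array, truth, shared, mac_range=(0, max_mac))
        het = het_accuracy(array, truth, shared, mac_range=(0, max_mac))
        po = overall.per_variant.set_index("variant_id")["n_pairs"]
        pn = nonref.per_variant.set_index("variant_id")["n_pairs"]
        ph = het.per_variant.set_index("variant_id")["n_pairs"]
        common_n = pn.index.intersection(po.index)
        assert (pn[common_n] <= po[common_n]).all()
        common_h = ph.index.intersection(pn.index)
        assert (ph[common_h] <= pn[common_h]).all()


class TestCompareVariantSets:
    def test_identical_sets(self):
        assert compare_variant_sets(["a", "b"], ["b", "a"]) == (2, 0, 0)

    def test_disjoint_sets(self):
        assert compare_variant_sets(["a"], ["b", "c"]) == (0, 1, 2)

    def test_matches_brute_force_partition(self):
        rng = np.random.default_rng(7)
        a = [f"v{i}" for i in rng.choice(2000, size=800, replace=False)]
        b = [f"v{i}" for i in rng.choice(2000, size=900, replace=False)]
        shared, ua, ub = compare_variant_sets(a, b)
        brute_shared = sum(1 for x in a if x in set(b))
        assert shared == brute_shared
        assert ua == len(a) - brute_shared
        assert ub == len(b) - brute_shared
        assert len(a) == shared + ua and len(b) == shared + ub

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            compare_variant_sets(["a", "a"], ["b"])
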