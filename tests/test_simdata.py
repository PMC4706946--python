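"""Simulator: MAF spectrum, truth genotypes, planted errors, determinism."""

import io

import numpy as np
import pytest

import exomeqc as eq
from exomeqc._rng import substream
from exomeqc.containers import AA, AB
from exomeqc.io_formats import write_final_report
from exomeqc.simdata import (
    TABLE_MAF_SPECTRUM, inject_error_mode, sample_maf_spectrum, simulate_truth_seq,
)


class TestMafSpectrum:
    def test_degenerate_single_interval_gives_constant(self):
        cfg = eq.SimConfig(n_variants=100, maf_spectrum=((0.0, 0.0, 1.0),))
        mafs = sample_maf_spectrum(cfg, substream(0, "maf"))
        assert np.all(mafs == 0.0)

    def test_interval_containment(self):
        cfg = eq.SimConfig(n_variants=500, maf_spectrum=((0.05, 0.5, 1.0),))
        mafs = sample_maf_spectrum(cfg, substream(1, "maf"))
        assert np.all((mafs > 0.05) & (mafs <= 0.5))

    def test_default_spectrum_monomorphic_mass(self):
        # the dominant interval mass is 66.70%; at 100k draws the
        # observed monomorphic fraction is within binomial error
        cfg = eq.SimConfig(n_variants=100_000)
        mafs = sample_maf_spectrum(cfg, substream(2, "maf"))
        assert abs((mafs == 0).mean() - 0.667) <= 0.01

    @pytest.mark.parametrize("spectrum", [
        ((0.0, 0.0, 0.5),),                      # sums to 0.5
        ((0.0, 0.0, 1.2), (0.0, 0.1, -0.2)),     # negative proportion
    ])
    def test_invalid_spectrum_rejected(self, spectrum):
        with pytest.raises(ValueError):
            eq.SimConfig(maf_spectrum=spectrum).validate()


class TestSimulateDataset:
    def test_monomorphic_config_forces_all_aa(self):
        cfg = eq.SimConfig(n_samples=50, n_variants=30,
                           maf_spectrum=((0.0, 0.0, 1.0),), x_chrom_fraction=0.0,
                           seed=5)
        bundle = eq.simulate_dataset(cfg)
        assert np.all(bundle.truth_genotypes.calls == AA)

    def test_truth_contains_no_missing(self, clean_bundle):
        assert np.all(clean_bundle.truth_genotypes.calls >= 0)

    def test_same_seed_is_byte_identical(self):
        cfg = eq.SimConfig(n_samples=40, n_variants=60, seed=9, dup_pairs=1,
                           error_mode_rates=(("low_r_wide_theta", 0.05),))
        a, b = eq.simulate_dataset(cfg), eq.simulate_dataset(cfg)
        for x, y in ((a.intensities.theta, b.intensities.theta),
                     (a.intensities.r, b.intensities.r),
                     (a.truth_genotypes.calls, b.truth_genotypes.calls)):
            assert np.array_equal(x, y)
        assert a.sample_meta.equals(b.sample_meta)
        assert a.variant_meta.equals(b.variant_meta)
        assert a.error_registry.equals(b.error_registry)
        bufs = []
        for bundle in (a, b):
            buf = io.StringIO()
            write_final_report(buf, bundle.intensities)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_hwe_consistency_of_truth(self):
        # het frequency tracks 2p(1-p) within 3 binomial SE for nearly
        # every variant (the bound itself has a ~0.3% miss rate)
        cfg = eq.SimConfig(n_samples=500, n_variants=300,
                           maf_spectrum=((0.05, 0.5, 1.0),),
                           x_chrom_fraction=0.0, seed=13)
        bundle = eq.simulate_dataset(cfg)
        p = bundle.variant_meta["true_maf"].to_numpy()
        e = 2 * p * (1 - p)
        o = (bundle.truth_genotypes.calls == AB).mean(axis=1)
        se = np.sqrt(e * (1 - e) / cfg.n_samples)
        assert ((np.abs(o - e) <= 3 * se).mean()) >= 0.985

    def test_duplicates_copy_and_relatives_share_an_allele(self, related_bundle):
        sm = related_bundle.sample_meta.set_index("sample_id")
        calls = related_bundle.truth_genotypes.calls
        ids = related_bundle.truth_genotypes.sample_ids
        dup = sm[sm.relationship == "duplicate"].index.tolist()
        assert np.array_equal(calls[:, ids.index(dup[0])], calls[:, ids.index(dup[1])])
        parent = sm[sm.relationship == "parent"].index[0]
        child = sm.loc[parent, "partner_id"]
        gp, gc = calls[:, ids.index(parent)], calls[:, ids.index(child)]
        # parent-offspring pairs never show opposite homozygotes
        assert not np.any((gp == 0) & (gc == 2)) and not np.any((gp == 2) & (gc == 0))

    def test_x_males_are_hemizygous(self):
        cfg = eq.SimConfig(n_samples=100, n_variants=200, x_chrom_fraction=1.0,
                           maf_spectrum=((0.05, 0.5, 1.0),), seed=17)
        bundle = eq.simulate_dataset(cfg)
        male = (bundle.sample_meta["declared_sex"] == "male").to_numpy()
        assert not np.any(bundle.truth_genotypes.calls[:, male] == AB)


class TestErrorInjection:
    def test_registry_lists_every_modified_point(self):
        rates = (("ab_misassign", 0.08), ("low_r_wide_theta", 0.08),
                 ("short_boundary", 0.08))
        cfg = eq.SimConfig(n_samples=150, n_variants=100, seed=23,
                           error_mode_rates=rates)
        dirty = eq.simulate_dataset(cfg)
        clean = eq.simulate_dataset(eq.SimConfig(**{
            **{f: getattr(cfg, f) for f in cfg.__dataclass_fields__},
            "error_mode_rates": ()}))
        diff = ((dirty.intensities.theta != clean.intensities.theta)
                | (dirty.intensities.r != clean.intensities.r))
        registered = np.zeros(diff.shape, dtype=bool)
        vids = dirty.intensities.variant_ids
        sids = dirty.intensities.sample_ids
        for row in dirty.error_registry.itertuples():
            if not row.sample_ids:
                continue
            i = vids.index(row.variant_id)
            for s in row.sample_ids.split(","):
                registered[i, sids.index(s)] = True
        assert not np.any(diff & ~registered), "unregistered modification"
        # every ab/low_r registry point is genuinely modified
        modes = dict(zip(dirty.error_registry.variant_id, dirty.error_registry["mode"]))
        for i, v in enumerate(vids):
            if modes.get(v) in ("ab_misassign", "low_r_wide_theta"):
                assert diff[i].any()

    def test_k_zero_is_noop(self):
        rng = substream(0, "t")
        theta, r = rng.random(20), rng.random(20) + 0.5
        truth = np.zeros(20, dtype=np.int8)
        t2, r2, affected = inject_error_mode(theta, r, truth, "ab_misassign",
                                             {"k": 0}, rng)
        assert affected.size == 0
        assert np.array_equal(t2, theta) and np.array_equal(r2, r)

    def test_short_boundary_leaves_points_untouched(self):
        rng = substream(1, "t")
        theta, r = rng.random(20), rng.random(20) + 0.5
        t2, r2, affected = inject_error_mode(theta, r, np.zeros(20, np.int8),
                                             "short_boundary", None, rng)
        assert affected.size == 0
        assert np.array_equal(t2, theta) and np.array_equal(r2, r)

    def test_low_r_forces_low_intensity(self):
        rng = substream(2, "t")
        theta = np.clip(rng.normal(0.1, 0.02, 200), 0, 1)
        r = np.exp(rng.normal(0, 0.1, 200))
        t2, r2, affected = inject_error_mode(theta, r, np.zeros(200, np.int8),
                                             "low_r_wide_theta",
                                             {"fraction": 0.1, "r_factor": 0.3}, rng)
        unaffected = np.setdiff1d(np.arange(200), affected)
        assert np.all(r2[affected] < 0.4 * r2[unaffected].mean())

    def test_ab_k_exceeding_homozygotes_is_error(self):
        rng = substream(3, "t")
        truth = np.array([0, 0, 1, 1, 2], dtype=np.int8)
        with pytest.raises(ValueError, match="homozygote"):
            inject_error_mode(np.full(5, 0.1), np.ones(5), truth,
                              "ab_misassign", {"k": 3}, rng)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="error mode"):
            inject_error_mode(np.ones(3), np.ones(3), np.zeros(3, np.int8),
                              "bogus", None, substream(0, "t"))


class TestTruthSeq:
    def test_zero_error_zero_offtarget_is_identity(self, clean_bundle):
        truth = simulate_truth_seq(clean_bundle.truth_genotypes,
                                   clean_bundle.variant_meta, 0.0, 0.0,
                                   substream(0, "seq"))
        assert np.array_equal(truth.calls, clean_bundle.truth_genotypes.calls)
        assert not truth.off_target.any()

    def test_flip_count_is_binomial(self):
        cfg = eq.SimConfig(n_samples=100, n_variants=100, seed=31)
        bundle = eq.simulate_dataset(cfg)
        truth = simulate_truth_seq(bundle.truth_genotypes, bundle.variant_meta,
                                   0.01, 0.0, substream(5, "seq"))
        flips = int((truth.calls != bundle.truth_genotypes.calls).sum())
        assert 70 <= flips <= 130  # 100 +/- 3 sd on 10,000 draws

    def test_off_target_exact_count(self, clean_bundle):
        truth = simulate_truth_seq(clean_bundle.truth_genotypes,
                                   clean_bundle.variant_meta, 0.0, 0.2,
                                   substream(6, "seq"))
        assert int(truth.off_target.sum()) == round(0.2 * len(clean_bundle.variant_meta))
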