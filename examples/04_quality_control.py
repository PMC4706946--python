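"""Run the sample and variant QC cascade.

Relatedness (IBD), sex check, call-rate filters, the Hardy-Weinberg
exact test, minor-allele-count and duplicate filters — applied in the
standard order: samples first, then variants on the survivors.
"""

import exomeqc as eq
from exomeqc.simdata import COMMON_MAF_SPECTRUM

bundle = eq.simulate_dataset(eq.SimConfig(
    n_samples=40, n_variants=3000, maf_spectrum=COMMON_MAF_SPECTRUM,
    x_chrom_fraction=0.05, dup_pairs=1, seed=8))
calls = eq.call_genotypes(bundle.intensities, bundle.generating_model())
sexes = dict(zip(bundle.sample_meta.sample_id, bundle.sample_meta.declared_sex))

report = eq.run_qc(calls, bundle.variant_meta, sexes)
print(f"samples: {report.n_samples_in} in, "
      f"{len(report.surviving_samples)} surviving")
print(f"  excluded by reason: {report.sample_counts()} "
      "(one member of the planted duplicate pair is dropped)")
print(f"variants: {report.n_variants_in} in, "
      f"{len(report.surviving_variants)} surviving")
print(f"  excluded by reason: {report.variant_counts()}")

p = eq.hwe_exact_test(25, 50, 25)
print(f"HWE exact test at perfect equilibrium (25/50/25): p = {p}")
p = eq.hwe_exact_test(50, 0, 50)
print(f"HWE exact test with no heterozygotes (50/0/50): p = {p:.2e} "
      "(flagged well below the 1e-6 threshold)")
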