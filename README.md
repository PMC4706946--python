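# exomeqc

Genotype-cluster quality control for exome genotyping arrays.

## The problem

Exome chips genotype hundreds of thousands of mostly rare coding
variants by clustering two-channel intensities, per variant, in
normalized polar coordinates: the allelic angle θ ∈ [0, 1] (0 ≈ pure A
allele, 1 ≈ pure B allele) and the total intensity R. Automated
clustering works well for common variants, whose three genotype clouds
(AA, AB, BB) are all populated, but fails quietly on rare and
monomorphic variants — exactly the variants the chip exists to
capture, and overwhelmingly common when the chip's (largely
European-ancestry) design is applied to other populations, where two
thirds of sites can be monomorphic.

Practical QC therefore screens every variant with a battery of cluster
statistics (call frequency, cluster separation, per-genotype
frequencies, AB cluster mean intensity, heterozygote excess, per-cluster
θ mean/deviation, MAF), flags suspicious variants, repairs what can be
repaired by reclustering, and validates the calls against sequencing.
Two published threshold sets are built in: the CHARGE consortium
criteria, and an "adjusted" variant of them for cohorts dominated by
monomorphic sites, which relaxes exactly four rows (call-frequency
bound 1 → 0.99 in three rules; MAF bound 0 → 0.0002 in the "AB Freq =
0" rule) so that rare variants with a handful of no-calls are not
discarded wholesale.

`exomeqc` implements that entire loop as a tested Python library:

- **simdata** — synthetic intensity cohorts: HWE truth genotypes under a
  configurable MAF spectrum (default: the interval masses of a
  14,647-sample Korean cohort — 66.70% monomorphic, 14.66% in (0, 0.001],
  …), X-dosage for sex checks, planted duplicate/parent–offspring pairs,
  and three planted cluster pathologies (a smeared pseudo-heterozygote
  band; low-R/wide-θ degradation; over-tight cluster boundaries).
- **caller** — a deterministic anchored three-component θ-mixture as the
  clustering stand-in, bivariate (θ, R) posterior calling with a
  no-call rule (Mahalanobis > d_max or posterior < p_min), and a
  deterministic reclustering repair pipeline.
- **metrics** — the per-variant statistic vector the criteria consume.
  Het excess is (o−e)/(1−e) for o ≥ e else (o−e)/e with e = 2p(1−p);
  cluster separation is Δμ/(Δμ + 4(σ₁+σ₂)), minimized over adjacent
  populated cluster pairs. Both are documented surrogates for
  undocumented commercial formulas.
- **rules** — the 17-rule flagging engine as data (YAML-definable),
  with redundancy-counted summaries.
- **qc** — sample QC (method-of-moments IBD with PI_HAT = Z2 + Z1/2,
  X-heterozygosity sex check F = 1 − O(het)/E(het), call rate) and
  variant QC (call rate < 95%, Hardy–Weinberg exact test p < 10⁻⁶,
  MAC < 2, duplicate records).
- **concord** — overall / non-reference / heteroallele concordance
  against sequencing truth, stratified by MAF class or MAC, reported as
  mean ± SD across variants.
- **io_formats / pipeline / cli** — plain-text interchange (final-report
  TSV, PED/MAP, minimal VCF, BED, JSON cluster files replacing binary
  .egt) and the two-stage custom-cluster-file workflow.

## A worked example

```sh
python examples/03_flag_and_recluster.py
```

prints, for a 300 × 150 simulated cohort with 5% of variants per
planted pathology:

```
flags (counted with redundancy): 44 on 21 variants
planted-error variants caught: 21 / 24
recluster statuses: {'reclustered': 16, 'zeroed': 5} (zeroed variants are excluded downstream)
concordance on planted-error variants before repair: 0.9606
concordance on planted-error variants after repair: 0.9967
```

The adjusted criteria flag 21 of the 24 planted-error variants (some
flags are redundant — one variant can trip several rules, and the totals
count that redundancy, as the published tallies do). Automated
reclustering repairs 16 and zeroes 5 (still failing a cluster-error rule
after repair, so excluded), raising truth concordance on the planted
variants from 0.9606 to 0.9967. The other examples cover simulation,
calling, the QC cascade, concordance scoring, and the two-stage
workflow.

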