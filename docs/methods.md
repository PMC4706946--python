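# Methods

## Model and scope

The package operates entirely in normalized polar intensity space:
each (variant, sample) observation is a pair (θ, R) with θ ∈ [0, 1] the
allelic angle and R ≥ 0 the total intensity. Raw two-channel
fluorescence, array normalization, and the proprietary binary .egt
cluster-file format are out of scope; inputs are assumed normalized,
and cluster models are exchanged as documented JSON.

Genotypes are coded AA/AB/BB/NC with the A allele mapped to the VCF REF
allele unless a ref/alt swap is detected at site intersection.

## Synthetic cohorts

The simulator is the package's test bed; it generates what the
downstream stack needs to be exercised, not a full physical model of an
array.

- **MAF spectrum.** Each variant draws a true MAF from configurable
  interval masses; the default masses are those observed on a large
  (14,647-sample) Korean exome-chip cohort: 66.70% exactly 0, 14.66% in
  (0, 0.001], 3.21% in (0.001, 0.005], 1.50% in (0.005, 0.01], 2.98% in
  (0.01, 0.05], 10.95% above 0.05. Within an interval the MAF is
  uniform — only interval masses are published, so the within-interval
  law is the package's own choice.
- **Truth genotypes** are Hardy–Weinberg draws per variant; X variants
  are hemizygous in males (coded as homozygotes, θ drawn from the
  homozygote clouds only). Planted duplicates copy genotypes exactly;
  planted relatives are parent–offspring (one transmitted allele per
  autosomal variant; X left untransmitted for simplicity). The
  relationship structure of real excluded relatives is unknown, so
  parent–offspring was fixed as the canonical first-degree case.
- **Cluster geometry.** θ centers 0.10/0.50/0.90 with Gaussian devs
  0.02, R lognormal with unit median and log-SD 0.1, shared by all
  variants. The devs were chosen so that the T Dev > 0.025 criterion
  discriminates planted pathologies from sampling noise: with a true
  dev at exactly 0.025 roughly half of clean variants would be flagged
  by chance, defeating the criterion's purpose. Real cohorts'
  intensity distributions are not published; this geometry is the
  package's own and is fully configurable.
- **Planted pathologies** (all on variants with true MAF < 0.05, the
  regime where these patterns occur, autosomes only, disjoint):
  - *ab_misassign*: 2% of samples (min 2) from the major homozygote
    cluster get θ redrawn uniformly on [0.2, 0.5] — a smear from the
    homozygote cloud toward the AB center that the caller picks up as
    a spurious, overdispersed heterozygote cluster.
  - *low_r_wide_theta*: 10% of samples get R scaled by 0.3 and θ
    Gaussian noise of SD 0.15 — degraded hybridization.
  - *short_boundary*: the data are untouched; the model builder shrinks
    that variant's cluster devs by 0.25, so the calling boundary is too
    tight and cluster-edge samples become spurious no-calls.
  All parameters were fixed when the modes were designed, as plausible
  renderings of the three published misclassification patterns.
- **Sequencing-truth surrogate**: independent genotype flips at a
  configurable error rate (each flip to one of the two other classes,
  uniformly) plus a uniformly chosen off-target site subset. Real
  sequencing errors are not independent flips; this surrogate exists to
  give concordance metrics a known expectation (1 − ε).
- **Determinism**: one global seed; every operation consumes a named
  CRC-32-derived substream, so bundles are bit-reproducible and modules
  can be tested independently.

What passing tests on these cohorts shows: the statistics, rules,
repair logic and QC arithmetic behave as specified under controlled,
well-separated cluster geometry. What they do not show: performance on
real arrays with batch effects, population structure, plate-level
intensity drift, or cluster shapes unlike the configured geometry —
none of which are simulated.

## Calling

Per variant, a three-component 1-D Gaussian mixture on θ is fitted by
EM with deterministic initialization at configurable anchor centers
(default 0.10/0.50/0.90, prior devs 0.05) and points weighted by R, so
low-intensity points influence the fit less. Component means are
constrained to disjoint anchor windows (center ± 0.18), which enforces
the AA < AB < BB ordering; devs are floored at 0.005. After
convergence, points are hard-assigned by maximum responsibility;
components with fewer than 2 members are unpopulated. A rescue pass
then checks for points lying beyond d_max θ-deviations from every
populated cluster: if at least 2 such points fall nearest an
unpopulated component's center, they populate it. This covers bands
lying between anchors (the smeared pseudo-heterozygote pattern), which
anchored EM otherwise starves — the real systems this stands in for
see such bands as clusters, and the flagging statistics must too.

Calling assigns each sample the populated cluster with the highest
posterior under a diagonal bivariate normal in (θ, R) (equal priors
over populated clusters); it is NC when the best Mahalanobis distance
exceeds d_max = 4.0 or the best posterior is below p_min = 0.7. No
public specification of the commercial no-call rule exists; these
defaults are the package's own and are configurable. The per-call
score is the winning posterior (kept, as the failing value, for NC).

## Reclustering repair

Flagged variants go through a deterministic pipeline standing in for
manual cluster review (no parity with human decisions is claimed):

1. Points with R below 0.4 × the variant's median R are dropped from
   fitting (they re-enter calling, where the refit R statistics push
   them to NC).
2. The mixture is refitted; per component, points with MAD-based
   robust z > 3 are trimmed and the fit repeated. A component whose θ
   dev exceeds 0.07 (the same bound the AB T Dev criterion uses) or
   whose members' mean θ drifts more than 0.10 from its anchor center
   is dissolved: genuine genotype clusters are held near their anchors
   by allele balance, smeared artifact bands are not.
3. If the re-call NC rate exceeds 5%, cluster devs are widened by 1.5
   and the widening kept when it helps.
4. The cluster-error (geometry) rules are re-evaluated on the repaired
   model: any remaining hit, or a model with no populated clusters,
   zeroes the variant (all-NC, excluded downstream); otherwise the
   status is `reclustered`. A variant whose flags were all
   frequency-type, whose NC rate is within bounds and whose geometry
   passes is returned `unchanged`.

The criteria for "restored vs excluded" after manual review were never
published; this status logic is the package's own. One consequence is
documented rather than hidden: a data-level smear cannot honestly be
re-called as its true homozygote — repair converts those calls to NC,
which removes them from concordance comparisons instead of correcting
them.

## Statistics and rules

Frequencies are computed over called samples only. Equality criteria
(AB Freq = 0, AA Freq = 1, MAF > 0) are evaluated on integer counts,
never on floats. Het excess uses e = 2p(1−p), o = n_AB/n_called:
(o−e)/(1−e) if o ≥ e else (o−e)/e, zero for e = 0; it is bounded in
[−1, 1]. Cluster separation is Δμ/(Δμ + 4(σ₁+σ₂)) minimized over
adjacent populated pairs, 1.0 with at most one populated cluster. Both
formulas are surrogates for undocumented commercial definitions,
calibrated so the conventional thresholds (0.4; 0.1/−0.9) separate the
planted pathologies from clean variants at the default geometry.

Interval rules: Call Freq 0.95~0.99 is half-open [0.95, 0.99), so a
variant at exactly 0.99 falls through to the MAF-combined rules; T
Mean intervals are closed. The AB R Mean criterion's threshold was
never published; the default is ab_r_mean < 0.3, configurable. Flag
totals are reported counted with redundancy (the sum of per-rule
counts) alongside the unique-variant count; the built-in reference
counts for the consortium column sum exactly to their published total,
while the adjusted column's published total does not equal the sum of
its published per-rule counts — the package defines the total as the
sum and does not emulate that inconsistency.

## QC cascade

Sample QC runs first (relatedness, sex, call rate, reasons recorded at
first failure), then variant QC on the survivors (call rate < 0.95,
HWE exact p < 10⁻⁶ on autosomes, MAC < 2 split into `monomorphic`
(MAC 0) and `low_mac` (MAC 1), duplicates keeping the higher-call-rate
record). The published description of the variant call-rate option is
internally inconsistent with the tool it names; the prose reading —
exclude variants with call rate below 95% — is implemented. The
"monomorphic with MAF > 0.001%" phrasing in the source material is
garbled; MAC < 2 covers both monomorphic and singleton variants.

IBD is the method-of-moments estimator from IBS counts with sample
allele frequencies; Z estimates are clipped to [0, 1] and
renormalized, PI_HAT = Z2 + Z1/2. No relatedness cutoff was published;
the default PI_HAT > 0.1875 is the midpoint between second- and
third-degree expectations. Moment-based IBD is meaningless on few
variants: below `ibd_min_variants` (default 100) polymorphic variants
the relatedness screen is skipped with a warning, and tests that
exercise relatedness use thousands of variants so that PI_HAT sampling
noise (SD ≈ 0.02 at 5,000 common variants) stays far from the cutoff.

The sex check uses F = 1 − O(het)/E(het) on polymorphic X variants
(female if F < 0.2, male if F > 0.8); a sample whose expected X
heterozygote count is below 5 is reported unknown rather than guessed.

The HWE exact test enumerates all heterozygote counts compatible with
the observed allele counts and parity in log-space (lgamma); it agrees
with exact integer enumeration to < 10⁻¹² over every triple with total
≤ 200 (verified exhaustively in the test suite).

## Concordance

Sites are intersected on chrom:pos with allele matching; swapped
ref/alt orientations are flipped, strand-ambiguous A/T and C/G sites
are excluded and counted, off-target sites removed. Pairs with NC or
missing on either side leave both numerator and denominator. Overall
concordance is stratified by array-cohort MAF (common ≥ 5%, less
common [1%, 5%), rare < 1%); non-reference concordance and
heteroallele accuracy (the fraction of truth heterozygotes called
heterozygous) are stratified by truth-cohort MAC, default 2–5. Which
cohort's frequency defines each stratum was not published; array-MAF /
truth-MAC is the default and both are configurable. Summaries are mean
± SD across variants (not pooled pairs), with SD the population SD.

## Problem sizes

Simulated cohorts in the tests and the acceptance script are a few
hundred samples by a few hundred variants (5,000 variants where IBD
needs them), with planted-error rates of a few percent per mode —
orders of magnitude denser than real pathology rates, so that a small
cohort exercises every code path. One visible consequence: with bad
variants at percent-level density, the 99% per-sample call-rate filter
bites harder than on a real 240k-variant chip, where flagged variants
are a much smaller fraction of each sample's genotypes.

## Known limitations

- The caller and repair pipeline are surrogates; no claim of parity
  with GenomeStudio/GenTrain/GenCall or with human manual review.
- No batch effects, population structure, LD, or plate structure in
  the simulator; IBD and HWE behavior under stratification is untested.
- X-chromosome handling is minimal (hemizygous males, no PAR regions,
  no X transmission for planted relatives; HWE skipped on X).
- PED/MAP carries no allele-orientation metadata; round-trips are
  exact only when variant metadata (ref/alt) is supplied to the
  reader, otherwise the first allele seen is taken as reference.
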