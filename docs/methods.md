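# Methods

`ergogwas` re-implements, at desk scale and on fully synthetic data, a
biobank-style analysis chain for cardiorespiratory fitness (CRF) and
physical activity (PA): phenotype derivation from submaximal cycle-ramp
heart-rate traces, accelerometer QC, covariate residualization, per-variant
association, LD clumping, two-stratum sex-heterogeneity meta-analysis, and
disease frequency by phenotype decile.  This note records the models, the
parameters that matter, and the design choices made where the protocol was
genuinely open.

## CRF phenotypes from the ramp test

Each session has pre-test (~15 s), exercise (6 min) and recovery (1 min)
phases with repeated measurements of heart rate (HR, bpm), workload (W) and
cadence (RPM) indexed by an ordinal "trend" counter.  Only participants in
the minimal, small or medium risk categories who tested on the bicycle are
eligible; minimal/small protocols contain a 2-min constant lead-in followed
by a 4-min linear workload ramp, and the ramp alone is modelled, while the
medium protocol cycles at constant workload and the full exercise phase is
used.  Observations with cadence outside 35–125 RPM (inclusive) are
dropped, and at least 20 must survive.

HR is smoothed with a zero-phase low-pass Butterworth filter before any
fitting.  Defaults: order 4, cutoff 0.1 × Nyquist, forward–backward
application.  The filter is applied after extending the signal by odd
(point-symmetric) reflection, long enough that the slowest filter pole has
decayed below 1e-13 at the window boundary.  Odd reflection is the
reflective padding that continues a linear trend exactly, so a perfectly
linear HR ramp passes through the filter unchanged — the property the
noiseless recovery tests rely on.  Sequences shorter than max(20, 3·order)
are passed through unfiltered and logged.

Two phenotypes are derived from the filtered window:

* **CRF-vo2max** (W/kg): fit workload ~ HR by least squares and evaluate
  at the age-predicted maximum heart rate, HRmax = 208 − 0.7·age; divide
  the extrapolated workload by body weight.  The regression direction is
  workload-on-HR because the target is workload *at* a given heart rate.
  An alternative `endpoints` mode draws the line through the first and
  last filtered points instead; regression is the default because it uses
  the whole window, and both are exposed since either reading of the
  derivation is defensible.  A constant-workload window (medium protocol)
  has no slope to extrapolate: the constant workload itself is emitted
  with a `degenerate_workload` flag rather than excluding the participant.
* **CRF-slope** (bpm per trend unit): the OLS slope of filtered HR on
  trend.  Sessions with a strictly negative slope are excluded from this
  phenotype (flagged, not silently dropped); a zero slope is retained —
  "negative" is read literally, and an exactly constant signal returns a
  slope of exactly 0.

Exclusions partition the input: every session is either emitted or counted
under exactly one reason (`bad_risk`, `bad_method`, `low_cadence_n`,
`degenerate_workload`).

## Physical activity QC

A record is included iff the device reported good wear time and good
calibration, no data-problem indicator is present, and the wear-time
adjusted 7-day mean acceleration is ≤ 100 mg (the exclusion is strictly
"> 100", so 100.0 is retained).  Negative accelerations are malformed and
rejected.  Inclusion is a pure conjunction, hence order-independent.

## Residualization

Association runs on trait residuals.  The GWAS preset regresses on age,
age², sex (sex-combined analyses only), genotyping array, assessment
centre and ten principal components, plus risk category and the number of
trend entries for CRF traits; the decile preset uses age and SES only.
Categorical covariates enter as full drop-first indicator sets; rank is
checked by QR and a rank-deficient design raises an error naming the
collinear columns.  Smoking and drinking are deliberately excluded from
the presets (conditioning on heritable covariates biases genetic effect
estimates) but can be added for sensitivity analyses.

## Association, clumping, heterogeneity

Association is per-variant OLS of the residualized trait on a1-allele
dosage with a t reference on n − 2 df.  The synthetic cohort is unrelated
by construction, so no mixed-model/GRM correction is needed; on such data
the pre-residualized OLS estimate coincides in expectation with a
mixed-model fit.  Monomorphic variants are emitted with missing statistics
and a flag.  Genome-wide significance is the conventional p < 5e-8.

Clumping is greedy and p-value-informed: among significant variants in
ascending p (ties broken by chrom, pos, id), the best unassigned variant
seeds a clump and absorbs unassigned variants within ±500 kb with dosage
r² ≥ 0.2 (both configurable; the window is interpreted as ±500 kb from the
index, the PLINK convention).  No secondary member p-threshold is applied.
Variants absent from the LD reference are listed separately, never clumped.

Sex heterogeneity uses fixed-effect inverse-variance pooling of the male
and female estimates with Cochran's Q (df = 1), I² = 100·max(0, (Q−1)/Q),
and the Higgins–Thompson test-based 95% CI on ln H, H = √(Q/df),
se(ln H) = ln Q / (2(√(2Q) − 1)) for Q > k = 2; bounds are transformed via
I² = 100·(H²−1)/H² and truncated below at 0, and the interval is reported
as absent when Q ≤ 2, where that standard-error formula does not apply.
Follow-up of a sex-specific signal in the opposite sex uses a Bonferroni
threshold 0.05/m for m SNPs tested in the trait family.

## Disease deciles

Participants are ranked on the age/SES-residualized phenotype separately
by sex and split into ten groups whose sizes differ by at most one (ties
broken by participant id, so assignment is order-independent).  For each
of ten disease groups, defined by ICD-10 three-character prefix lists
(ischaemic heart disease I20–I25, stroke I60–I69, dementias F01/F03/G30,
lung cancer C33–C34, COPD J40–J44/J47, lower respiratory infection
J09–J18/J20–J22, colorectal cancer C18–C21, diabetes E10–E14, kidney
disease N00–N19, breast cancer C50; overridable via a mapping file), the
per-decile frequency counts each participant at most once per group, with
undiagnosed participants in the denominator.  Prevalent and incident
disease are not distinguished and ICD-9 records are out of scope.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults define the study
conditions used throughout the tests and the acceptance script.

* **Cohort**: age ~ U(40, 69); sex Bernoulli(0.5); weight normal by sex
  (85/70 kg, sd 14, floor 40); Townsend-like SES ~ N(0, 3); six centres;
  array A with probability 0.9; risk categories 60/25/10/5%
  (minimal/small/medium/high); ten standard-normal PCs.
* **Cardiorespiratory truth**: resting HR ~ N(68, 8) clipped to [45, 95];
  HR response 0.40 bpm/W lognormal with 20% CV.  The analytic truth
  true_vo2max = ((208 − 0.7·age) − hr_rest)/hr_per_watt/weight is finite
  and positive across the support, and is what the derivation must
  recover.
* **Traces**: 4 s sampling (~90 exercise observations; the protocol only
  fixes the ≥20-observation rule, so the rate is a plausible default),
  minimal ramp 40→130 W, small 30→90 W, medium constant 30 W.  HR noise
  is stationary AR(1) (ρ = 0.6, sd 3 bpm) — chosen because the derivation
  assumes a linear HR–workload relation and beat-to-beat noise is serially
  correlated — plus salt-and-pepper spikes (p = 0.01, ±30 bpm) that give
  the Butterworth stage something to remove.  Cadence ~ N(60, 5) with 2%
  out-of-range excursions to exercise the 35–125 filter.
* **Genotypes**: block LD by haplotype copying — within a block all
  variants share a MAF (U(0.05, 0.5)) and each haplotype copies the
  previous variant's allele with probability 0.9, giving adjacent-variant
  allele correlation equal to the copy probability and geometric decay;
  blocks are independent and widely separated (300 kb gaps, 5 kb spacing).
  This produces the index/member structure clumping needs, not realistic
  fine-scale LD from reference panels.
* **Phenotype and outcomes**: quantitative trait = small age/sex/SES
  effects + Σ β_sex·dosage + N(0, 1), with default causal architecture of
  one shared (β = 0.25 SD), one male-only (0.3) and one female-only (0.2)
  variant; PA summaries gamma-distributed around 28 mg with configured QC
  failure rates and 1% > 100 mg outliers; disease indicators
  Bernoulli(logistic(α_g + slope·z)) on the standardized true fitness
  value with slope −0.5 and realistic baselines (e.g. CAD 6%), emitting
  ICD-10-style codes with occasional repeat admissions.

What the generator does *not* emulate — relatedness and population
structure, imputation uncertainty, realistic LD, measurement drift within
a session, informative missingness — bounds what passing tests show: they
demonstrate correctness of the derivations and calibration of the
statistics under the stated model, not robustness to those real-data
features.

## Numerical choices and degenerate inputs

All randomness flows from a single root seed through named per-stage
child streams (`numpy` SeedSequence spawning), so any stage can be
reproduced in isolation and per-participant traces are independent of
cohort ordering.  Tie-breaks are always explicit (p-value ties by
position, phenotype ties by participant id).  Zero-variance cases are
handled as data, not errors: monomorphic variants and zero-variance
correlation columns are reported missing with flags, constant workload
yields the degenerate extrapolation above.  The dosage-based r² uses
complete-case Pearson correlation.  VCF output is a minimal v4.2 file
with a DS FORMAT field (4 significant digits; exact for hard-call
dosages).

## Reference scales

Default problem sizes, used by the test suite and `scripts/acceptance.py`:
2000 participants and 500 variants for the end-to-end run; 500
participants for vo2max recovery; 10,000 independent variants at n = 2000
for type-I calibration; 100 random 50-variant instances for the clumping
oracle; 100 seeds at n = 5000 for decile-gradient recovery.  These sizes
give tight Monte-Carlo error for every calibration check while keeping a
full run to tens of seconds on one CPU.

## Known limitations

Single-variant OLS only (no GRM, no X-chromosome model, no interaction
tests); two-stratum fixed-effect meta-analysis only (no random-effects
pooling, no >2 strata); the ICD-10 prefix map is a documented
approximation of WHO cause-of-death groupings; PA is summary-level only
(no raw accelerometry); the trend index is treated as the recorded
ordinal counter, so CRF-slope is per measurement, not per second.
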