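# Methods

This note documents the models behind `pylorimet`, the choices made where
the design was genuinely open, and what the synthetic-data tests do and do
not demonstrate about real data.

## 1. Data model

Three input files describe a study:

- **plate table** (CSV, long format): `plate, well, sample_id, role,
  metabolite, raw_uM` with roles `sample | blank | QC1 | QC2 | QC3`. Raw
  values are concentrations in µM as exported by the quantification
  software, before any inter-plate normalization.
- **sample sheet** (TSV): `sample_id, pair_id, case, sex, year_of_birth,
  …, parity, gestational_age_wk, age_at_sampling_days`, optionally
  `cesarean`, a diagnosis-code indicator (`p92_5`) with the day it was
  assigned (`p92_5_day`), and SNP dosage columns named by rsid.
- **panel** (TSV): one row per metabolite with its class, parsed
  composition (carbons, double bonds, ether/hydroxyl/dicarboxyl modifier)
  and the QC2 target value `TV_m` (µM).

The bundled default panel matches the 408-metabolite composition of the
broad targeted kit (55 acylcarnitines, 21 amino acids, 21 biogenic
amines, 24 LPC + 172 PC, 31 SM + 9 Cer, 1 summed hexose measure, 14
cholesterol esters, 18 DG + 42 TG). Species names that are not fixed by
the analysis (everything except the seven focal metabolites and the
amino-acid list) are deterministic placeholders on realistic
carbon/double-bond grids, and all target values are **synthetic**
(log-uniform draws within order-of-magnitude-realistic per-class µM
ranges). A real kit export in the same TSV layout can be loaded in place
of the bundled panel.

## 2. QC and normalization

For metabolite *m* on plate *p*:

1. `LOD_{m,p}` = median of the triplicate paper-blank raw values on that
   plate (even counts: midpoint convention). LODs are never pooled across
   plates.
2. **Detection filter**: fraction of raw sample values ≤ LOD (non-strict),
   computed separately in cases and controls against each sample's own
   plate LOD. Keep iff the fraction is ≤ `lod_frac` (default 0.20) in at
   least one group; `lod_both_groups=True` switches to the strict-AND
   reading. Sub-LOD values of kept metabolites are retained as measured —
   no imputation.
3. **Plate correction**: `A_{m,p}` = median of the five QC2 replicates
   strictly above LOD; `C_{m,p} = A_{m,p} / TV_m`. A metabolite with no
   usable QC2 value on any one plate is dropped entirely
   (`dropped_correction`) rather than partially analysed.
4. **Normalization**: `Norm = Raw / C_{m,p}`. Algebraic consequence
   (tested exactly): the per-plate median of above-LOD normalized QC2
   values equals `TV_m`, and rescaling all raw values of one plate by any
   λ > 0 leaves the normalized sample matrix unchanged.
5. **CV filter**: pooled normalized QC2 replicates across all plates
   (5 × 8 = 40 observations at study scale); `CV_m` = sample SD (n−1) /
   mean; drop iff `CV_m` > `cv_max` (default 0.25).

Stage order is fixed (detection → correction → CV) and pinned by a
regression test: a metabolite failing both filters is reported as a
detection failure.

## 3. Matched-pair association

Normalized concentrations are rank-based inverse-normal transformed:
value at (average) rank *r* of *n* maps to `Φ⁻¹((r − ½)/n)`; the Blom
offset `(r − 3/8)/(n + ¼)` is available. With average ranks a constant
vector maps to zeros. In era-stratified scans the transform is recomputed
within stratum by default (configurable), since the two eras have
different sampling-age distributions and hence different marginal scales.

The per-metabolite model is a linear mixed model with fixed effects for
case status, sex (factor), year of birth (factor), parity and gestational
age (weeks; cesarean section optionally as a sensitivity term) and a
random intercept per matched pair. Because every pair contributes exactly
one case and one control, REML is computed exactly by splitting each pair
into its within-pair difference and sum,

    d_i ~ N(D_i β, σ²),    s_i ~ N(S_i β, σ²(1 + 2λ)),   λ = τ²/σ²,

profiling σ² analytically and minimizing the restricted −2 log-likelihood
over `u = log(1+2λ) ∈ [0, 25]` (bounded scalar minimization, normal
equations via Cholesky). This agrees with a generic REML mixed-model fit
(statsmodels `MixedLM`, cross-checked in tests to ~10⁻⁵ relative on the
estimate) at a fraction of the cost, which is what makes the
replicate-level calibration studies below practical. With case status as
the only fixed effect, the estimator reduces *exactly* to the mean
within-pair difference with SE = SD(differences)/√n, for any λ — the
closed-form oracle used in tests.

Design handling: factor levels are dummy-coded; year-of-birth levels with
fewer than two pairs are merged into the nearest year (estimability in
small cohorts); collinear columns are pruned greedily with case status
given priority, and pruned columns are reported. Pairs with any missing
covariate are dropped whole.

**P-values.** The case coefficient is tested against a t reference with
containment degrees of freedom (n_pairs − rank of the within-pair
design; 264 for the full model at 267 pairs). This choice was made after
a null calibration study: with 148 independent null metabolites and
Bonferroni correction at α = 0.05, the plain normal reference produced a
family-wise error rate of ≈ 0.064 (1000 replicates) — visibly inflated at
tail thresholds — while the t reference is correctly calibrated. The
normal reference remains available (`pvalue_method="wald_z"`); at this
sample size the two agree closely for headline-scale effects. Bonferroni
correction always uses the number of metabolites actually tested.

Pairwise Pearson correlations between hit metabolites use
pairwise-complete observations with the exact t-test (n−2 df); cells with
fewer than three complete pairs or zero variance are reported as missing.

## 4. Diagnosis-code and SNP models

The 2×2 co-occurrence of a diagnosis code with case status is tested with
Fisher's exact test; the reported estimate is the conditional maximum
likelihood odds ratio under the noncentral hypergeometric distribution,
and the 95 % CI is the exact central interval obtained by inverting
one-sided conditional tests at 0.025 per side (scipy's implementation;
the two-sided p-value is verified against brute-force enumeration over
all tables with the observed margins in tests). Zero cells flag an
unbounded CI side; zero margins are an error.

The code-timing model restricts to code carriers and regresses the
transformed metabolite on an indicator of the code being assigned on the
day of birth, adjusting for sex, year of birth (continuous), parity,
gestational age and case status by OLS. SNP models regress transformed
levels (or the inverse-normal-transformed PC(38:4)/PC(38:3) ratio,
computed on the normalized concentration scale before transformation so
per-sample dilution cancels) on 0/1/2 effect-allele dosage, adjusting for
case status, sex, year of birth (factor), parity and gestational age,
with optional era stratification and a Bonferroni-corrected sweep over
all metabolites. Year of birth enters the timing model linearly but the
SNP models as a factor — the two analyses are specified that way, and the
package follows each. Constant covariates are dropped silently (the
models degrade gracefully to simple regression); a collinear term of
interest is an error naming the collision.

## 5. Synthetic cohort generator

The generator emulates the study design, not mass-spectrometric physics.
Cohort structure (defaults): 267 matched pairs (sex and day of birth
identical within pair; 87.3 % boys), birth years 1997–2014 with
P(pre-2009) = 98/267 and uniform years within each block — this matches
both the reported year-of-birth moments (mean ≈ 2008, SD ≈ 4.9) and the
stratum sizes. Gestational age ~ N(40, 1.5²) wk, parity 1 + Poisson(0.75),
maternal age ~ N(30, 5²), cesarean rates 21.3 %/16.9 % (cases/controls).
Age at DBS sampling is the era median (6 d pre-2009, 2 d post) plus small
integer jitter.

Concentrations are generated on the log scale (multiplicative noise — the
non-normality that motivates the rank transform):

    log x_im = log TV_m + s_m (δ_m case_i + f·max(age_i − 1, 0)·bottle_i·1[m ∈ A]
               + γ g_i 1[m = precursor]) + a F_i 1[m ∈ A] + ε_im

- `A` is the affected set: PC(38:4), PC(36:4), PC-O(36:4), PC(44:1),
  PC(38:3), histidine, AC(2:0). They share a standard-normal latent
  factor `F_i` with loading a = 0.5, making them positively correlated as
  a block; `ε` has log-SD 0.25, and `s_m` is the total log-SD, so all
  configured effects are in SD units.
- `bottle_i` is a latent bottle-feeding indicator (defaults: 60 % of
  cases, 20 % of controls). The feeding effect is **f = −0.30 SD per day
  of age past a one-day onset**: milk intake (breast or formula) is
  negligible right after birth and ramps up within the first week, so
  feeding-pattern contrasts are nearly invisible at day-2 sampling but
  strong at day-6 sampling. This is what generates the era-stratified
  attenuation pattern: expected stratified effects ≈ −0.49 SD (pre-2009)
  vs −0.15 SD (post-2009). These effect sizes are synthetic — chosen once,
  by design, to reproduce the qualitative pattern at realistic magnitudes;
  they are inputs, not estimates.
- The latent feeding state also drives the P92.5 code: carriage
  probabilities (case/bottle 0.10, case/breast 0.02, control/bottle 0.06,
  control/breast 0.006) give ≈ 6.4 % carriage in cases vs ≈ 1.5 % in
  controls; bottle-fed carriers receive the code on the day of birth with
  probability 0.7 (0.2 otherwise).
- Genetics: rs174547 dosage (HWE, MAF 0.33) adds γ = +0.35 SD per allele
  to the *precursor* PC(38:3) only — so the variant moves PC(38:3) and
  the PC(38:4)/PC(38:3) ratio but neither PC(38:4) nor disease status
  (disease risk is never a function of genotype in the generator). A
  second dosage column (rs12721025, MAF 0.07) has no metabolite effect.
- Measurement layer: per-plate multiplicative factors
  `C_{m,p} = exp(N(0, 0.15²))` applied to every well of the plate;
  technical lognormal noise with CV 5 % on all wells; blanks at 2 % of
  `TV_m`; QC2 at `TV_m`, QC1/QC3 at 0.5/2 × `TV_m` (generated, unused by
  the pipeline). Matched pairs are always placed on the same plate;
  pairs are spread evenly across plates.
- **Designed failures** for funnel tests: `fail_lod` metabolites get
  blanks at 1.5 × `TV_m` (samples sink below LOD), `fail_cv` metabolites
  get 40 % QC2 noise. Ground truth (plate factors, feeding states,
  genotypes, effects, failure reasons, true concentrations) is returned
  and serialized to `truth.json`.

With all effect parameters zero, cases and controls are exchangeable by
construction — the basis of the type-I-error study. All randomness flows
from a single seed through named substreams; outputs are byte-identical
across runs.

## 6. What the simulation studies show (and don't)

Measured by the test suite on this generator:

- injected −0.4 SD case–control effects are recovered with mean estimate
  ≈ −0.39 (rank-INT of a shifted mixture attenuates slightly) and CI
  coverage ≈ 0.957 over 1000 replicates;
- the null family-wise error rate of the Bonferroni scan is at its
  nominal level with the t reference (and inflated ≈ 1.3× with a plain
  normal reference — the reason t is the default);
- the pre-2009 stratum shows larger absolute effects than the post-2009
  stratum for the affected metabolites in ≈ 97 % of replicates.

These results validate the *pipeline* under the generator's assumptions:
lognormal concentrations, exchangeable pairs, exactly balanced matching,
homogeneous technical noise, missingness-free measurements. Real DBS data
violate several of these (hemoglobin interference, punch-position and
storage-time effects, batch drifts within plate, informative missingness,
imperfect matching), so passing tests demonstrate correctness of the
statistics, not robustness to every real-world artifact.

## 7. Numerical choices and degenerate inputs

- Medians use the midpoint convention for even counts throughout.
- "≤ LOD" is non-strict for the detection fraction; "above LOD" is strict
  for QC2 cells entering `A_{m,p}`.
- REML: the variance-ratio search is bounded (`u ∈ [0, 25]`), boundary
  λ = 0 is checked explicitly; the normal equations are solved by
  Cholesky with the profiled σ̂² = RSS/(N − p).
- The inverse-normal transform requires ≥ 2 finite values, propagates
  NaN, and maps constant input to zeros (average-rank convention).
- Fisher CI endpoints at zero cells are 0/∞ and flagged; p-values are
  clamped away from exact 0.
- Tiny strata: empty strata are reported and skipped; year levels with a
  single pair are merged before dummy coding.

## 8. Known limitations

- The bundled panel's species names and target values are placeholders;
  analyses of real kit exports must supply the vendor panel file.
- The LOD rule has two published readings (at-least-one-group vs both
  groups); both are implemented, the more permissive is the default, and
  results can differ for metabolites detected in only one group.
- The exact-CI convention (central interval) matches the standard
  exact-test implementation; other conventions (e.g. minimum-width) give
  slightly different endpoints.
- Power/calibration figures above are properties of the synthetic design
  at its default parameters; they move with effect sizes, noise levels
  and cohort size in the obvious directions.
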