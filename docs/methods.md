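# Methods

## Model and procedure

The package treats an epigenetic clock as a two-stage problem: *selection*
of age-associated CpGs that behave consistently across inbred strains, then
*fitting* of a predictor on the selected sites.

**Age normalization.** Chronological ages (weeks) are min–max scaled to
[0, 1] independently within each (strain, sex) group. This puts strains
with different life expectancies on a common "fraction of observed
lifespan" axis, and makes the selection slope interpretable (see below).
A group needs at least two distinct ages; otherwise the scaling is
undefined and an error is raised. An alternative normalization — dividing
age by the strain's life expectancy (2.42 years for C57BL/6, 1.87 for
DBA/2J) — is available via `normalize_ages(..., method="lifespan")`. The
min–max variant is the default because it uses only the cohort itself and
keeps the slope threshold's reading exact on the sampled span; the
lifespan variant is preferable when cohorts sample very unequal portions
of the lifespan. The two differ by an affine factor per strain, so
candidate *rankings* agree; thresholded candidate *sets* can differ.

**Selection statistic.** For each CpG,
`slope_CpG = Σ(xᵢ−x̄)(yᵢ−ȳ)/Σ(xᵢ−x̄)²` with x the normalized age and y the
beta value — the ordinary least-squares slope of beta on normalized age.
Because both axes live on [0, 1], `|slope| > 0.3` means "more than 30%
absolute methylation change over the observed lifespan". Screening on the
slope rather than on Pearson r deliberately favours large-amplitude
changes, which are more robust to normalization differences and easier to
assay by targeted methods; in practice the selected CpGs also have high
|r| (slope = r·sd(y)/sd(x), and sd(x) is bounded on the unit interval).
The threshold is strict (`>`), applied per strain, and candidates are the
*intersection* of the per-strain selections. Betas are used on their
natural [0, 1] scale; "normalized beta" refers to the upstream array
normalization, which this package does not perform (it consumes processed
exports; IDAT-level preprocessing is out of scope).

**Ensemble clock.** Each candidate CpG gets a univariate OLS model of
normalized age on beta; a sample's prediction is the arithmetic mean of
the available per-CpG estimates, mapped to weeks with the training
(strain, sex) age range. Averaging many weak univariate estimators instead
of fitting one multivariable model is forced by the design: with ~12
training animals and ~100 CpGs a joint fit is under-determined. Regressing
age on beta directly (rather than inverting a beta-on-age calibration
line) is the default; the inverse-calibration variant is available as
`fit_ensemble(..., mode="inverse")`. The mean is taken on the normalized
scale and denormalized once — equivalent to per-CpG denormalization when
all models share a group range, which they do within one training strain.
Predicting a (strain, sex) group absent from training reuses the training
range with a warning; this is the cross-strain transfer setting, and any
real lifespan difference then appears as a scale distortion in the output.

**Multivariate clock.** For targeted pyrosequencing panels, every
combination of k=4 CpGs drawn from 4 distinct PCR amplicons is fit by OLS
of age (weeks) on methylation (%); the combination minimizing training MAD
wins. Restricting to one CpG per amplicon avoids the near-collinearity of
neighbouring CpGs and keeps the assay parsimonius. Ties break by higher
r², then lexicographic CpG labels — an arbitrary but deterministic rule.
The published B6 blood clock
(`167.4533 + 1.2421α + 0.9824β − 1.3110γ − 1.6088δ`; α Aspa pos1 /
cg29748675, β Hsf4 pos3, γ Wnt3a pos2, δ Prima1 pos1 / cg31044702) ships
as a frozen model; its output is not clamped, and inputs outside [0, 100]%
only warn, since pyrosequencing noise can exceed the nominal bounds.

**Metrics.** MAE = *median* absolute error, MAD = *mean* absolute
deviation (both weeks), r² = squared Pearson correlation of predicted vs
chronological age. The median/mean naming is a fixed convention of this
package's reporting; r² is correlation-based and therefore insensitive to
scale/offset, which is why it is reported alongside the absolute-error
metrics rather than instead of them.

**Strain comparison.** The sample correlation matrix is pairwise-complete
Pearson over shared probes and *includes* X/Y probes (strain clustering is
a whole-methylome question; clocks exclude X/Y). Differential methylation
between two strains uses the two-sided Wilcoxon rank-sum test per CpG —
the exact null distribution when both groups have ≤ 12 samples and the
probe has no ties, the normal approximation with continuity and tie
correction otherwise — with Bonferroni correction over the probes actually
tested (a fixed divisor, e.g. a full-array count, can be supplied
instead). X/Y, SNP-overlapping and cross-reactive probes are expected to
be removed before the screen. The sex-effect test applies the same
rank-sum machinery to prediction errors (predicted − chronological age).
The global trend reports, per sample, the fraction of probes with
beta > 0.5 ("methylated calls"; the threshold is a documented default, not
a biological constant) and its Pearson correlation with age.

**Resolution of the exact rank-sum screen.** With n₁ = n₂ = 12 the
smallest achievable two-sided exact p-value is 2/C(24,12) ≈ 7.4·10⁻⁷.
Bonferroni control at α = 0.01 therefore cannot flag *anything* once more
than ~13,500 probes are tested, regardless of effect size. This is a
property of the test, not a bug: genome-scale screens at this design
either need larger groups (e.g. pooling training and validation animals
of one strain) or a less conservative error control. The package applies
the test faithfully and leaves the design choice to the user; the test
suite exercises the screen at family sizes where 12 v 12 has resolution.

**Homology mapping.** Homology windows (~121 nt) between the mouse and
human genomes are *input* data — alignments are assembly- and
version-dependent and belong upstream. Human array CpGs on a chromosome
carrying at least one window are categorized: inside a window (1-based,
inclusive ends) → "homolog", distance 0; otherwise "distance" to the
nearest window center, center = floor((start+end)/2), ties toward the
lower start coordinate. Strand flips affect display orientation only.
Human age association is Pearson r per CpG with the exact t transform
t = r·√((n−2)/(1−r²)), n−2 df, two-sided, Bonferroni over the CpGs
analyzed by default (a fixed 450k-scale divisor can be supplied).
Conserved candidates are homolog-category CpGs significant in human whose
correlation sign agrees with both mouse strains.

## Synthetic cohorts

The generator emulates the statistical structure of a two-strain array
study, not the array chemistry. Defaults (all overridable in
`CohortSpec`): 12 B6 females aged 7–91 weeks plus 6 male and 6 female
DBA/2J aged 6–76 weeks, ages evenly spaced per group; 20,000 probes of
which 100 carry sign-shared aging trends (total beta change 0.5 over the
strain's age span), 50 per strain are strain-private, 25 antagonistic
(opposite signs between strains), 1,000 carry constant between-strain
offsets (|shift| uniform in 0.2–0.5), 200 sit on X/Y, ~1% each are flagged
SNP-overlapping or cross-reactive, and the rest are null. Baselines are
drawn per genomic context (islands low, open sea high; mix
30/25/10/35% island/shore/shelf/open sea), with hypermethylation bias in
islands for B6-private and shared probes and the mirror-image bias for
DBA-private probes. Noise is i.i.d. Gaussian on the beta scale
(sd 0.02) followed by clipping to [0, 1] — only the second-moment
behaviour of the noise matters to the statistics under test, so a
beta-binomial intensity model would add realism the tests cannot see.
Planted means are kept at least max(0.02, 3·noise_sd) away from the beta
bounds so planted effects are not flattened by saturation; clipped values
would otherwise create spurious ties and attenuated slopes.

The linked human cohort defaults to 656 donors aged 19–101 years
(uniform), mirroring a large public blood cohort; a configurable fraction
of the shared mouse aging CpGs receive sign-matched trends (mouse effect ×
0.5 over the human span, noise sd 0.05 — human blood is more
heterogeneous than inbred mouse blood), the rest and all background
probes are null. The homology-table generator emits 121-nt windows
containing each linked human CpG; an `attrition` fraction of windows is
displaced to contain no array CpG, emulating the real-world loss when
most mouse homolog regions lack a probe on the human array.

What passing on synthetic data does **not** show: robustness to batch
effects, cell-composition shifts, probe-type bias, or spatially
correlated noise — none of which are simulated. Recovery rates measured
here are upper bounds for real cohorts.

## Numerical choices and degenerate inputs

- Slope/correlation computations are pairwise-complete; a probe needs ≥ 3
  complete pairs. Zero predictor variance raises; zero beta variance gives
  slope 0 and undefined r (NaN in table form, an error in scalar form).
- Probe QC precedes sample QC (bad probes must not inflate sample
  missingness); detection-p filtering is skipped with a warning when no
  detection p-values are provided, as processed beta exports usually lack
  them. Missing tokens: `NA`, `NaN`, empty (case-insensitive).
- The exhaustive multivariate search skips rank-deficient designs; OLS is
  solved by `numpy.linalg.lstsq`. Search size grows as the product of
  per-amplicon CpG counts over 4-amplicon subsets — exact enumeration is
  intended for targeted panels (tens of CpGs), not arrays.
- `evaluate` raises on constant prediction/truth vectors by default
  (r² undefined); `allow_undefined_r2=True` returns NaN r² with MAE/MAD.
- All coordinates are 1-based inclusive; X/Y detection tolerates
  `chr`-prefixed and lower-case labels.
- Every generator output is a deterministic function of the spec seed;
  matrices serialize at 6 decimals, so disk round-trips can perturb
  borderline test statistics by ~1e-6.

## Known limitations

- The package consumes processed beta matrices; IDAT parsing, background
  correction, dye-bias and probe-type adjustment are upstream concerns.
- Clocks are first-generation (chronological age only) and blood-trained
  use is assumed; applying a blood clock to other tissues will offset.
- Candidate selection is univariate by design; with larger cohorts a
  penalized multivariable selection (e.g. elastic net) would likely
  outperform it, and is deliberately not included here.
- The ensemble clock's cross-strain transfer preserves ranking but can
  carry a systematic offset when antagonistic CpGs enter the candidate
  set (see the worked example in the README).
- Test problem sizes are deliberately desk-scale (thousands of probes,
  tens of samples; the full default cohort is 20,000 probes × 24
  samples), chosen so the whole suite runs in seconds while leaving every
  statistical property measurable.
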