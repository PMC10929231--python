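# Methods

## The analysis model

`resiliome` quantifies the perturbation and resilience of the gut
ecosystem in a longitudinal antibiotic-challenge design: subjects are
sampled on a fixed nominal schedule (defaults: days −15, −7, −1, 1, 2,
3, 4, 7, 10, 15, 30, 90 around a treatment start at day 0), and every
measured variable is traced as a *distance from baseline* over time.

Variables are split by dimensionality:

* **Low-dimensional** variables are one scalar per sample — cell counts,
  enzymatic activities, observed richness of each omic layer, the
  β-lactamasome relative abundance and the functional ratios
  (cholesterol conversion, bile-acid transformation, fungal load).
  All except richness counts are log10-transformed before analysis.
  The change from baseline is the difference on the analysis scale;
  the raw distance is its absolute value.
* **High-dimensional** variables are whole composition profiles
  (bacterial species, phage contigs, fungal OTUs, metabolite features).
  The departure from baseline at a given day is `1 − s²`, where `s` is
  the mid-rank Spearman correlation between the day's profile and the
  baseline profile. Squaring makes the distance direction-agnostic:
  both a perfectly preserved and a perfectly rank-reversed community
  score 0; an uncorrelated community scores 1.

**Baseline** is the day −1 sample, falling back to −7 and then −15 when
missing; a subject-variable with no measured pre-treatment sample is
excluded (logged).

**Normalisation.** Raw distances are divided, per subject and variable,
by the mean of that subject's raw distances at the remaining
pre-treatment days (−7 and −15; the baseline day itself, whose distance
is identically 0, is excluded — including it would halve every divisor).
When neither pre-treatment visit exists, the divisor is the cohort
median of the other subjects' divisors for that variable. A zero divisor
(identical pre-treatment samples) leaves the normalised series missing
rather than infinite; downstream statistics are rank-based and tolerate
missingness pairwise. A normalised distance of 1 therefore means "no
further from baseline than this subject's own pre-treatment noise".

**AUCs.** Trajectories are integrated by the trapezoidal rule on actual
stool-emission times from t = 0 to the actual time T of the last sample
with nominal day ≤ 10 (or 30), anchored at t = 0 with the metric's null
value — 0 for signed changes, 1 for normalised distances — and rescaled
by `window/T`. Under this standardisation a null trajectory scores
exactly 0 (scalars) or the window length 10/30 (structures), which are
the references used in the Wilcoxon tests. Low-dimensional AUCs use the
signed change (so transient rises and falls can cancel); the extremes
below use normalised absolute distances. If the day-10/30 sample is
missing, the window ends at the latest available earlier sample (logged
as a window-end substitution).

**Extremes.** *Maximal perturbation* is the largest normalised distance
at nominal days 1–10; *maximal resilience* is the smallest normalised
distance on days 15, 30 or 90 (smaller = closer return to baseline).

## Statistics

* **Variance components.** Pre-treatment values (days < 0, analysis
  scale) are fitted with the random-intercept model
  `y_ij = μ + b_i + e_ij` by REML. Because the model has a single
  variance ratio, the likelihood is profiled over
  `λ = σ_b²/σ_e²` and optimised one-dimensionally (bounded search on
  log λ, checked against λ = 0 so negative between-subject variance
  truncates at zero exactly). Components are reported as CV =
  100·SD/|mean|; the absolute value keeps CVs positive for variables
  whose log10 mean is negative. On balanced designs the estimates agree
  with the closed-form one-way ANOVA estimator to ≈1e−8, and with an
  independent general mixed-model fit on unbalanced designs.
* **Reference tests.** Two-sided one-sample Wilcoxon signed-rank tests
  compare changes (to 0) and normalised distances/AUCs (to 1, 10, 30) at
  fixed endpoints (days 4, 7, 10, 30, 90) and AUC windows; zero
  differences are dropped before ranking, the exact null distribution is
  used for n ≤ 25 without ties, otherwise the continuity-corrected
  normal approximation. Arm contrasts use the two-sample rank-sum test.
* **Correlograms.** Spearman correlations, tested against 0, over all
  C(17,2) = 136 unordered pairs of the default 17-metric panel
  (perturbation and resilience modes) or the 13 × 17 grid of
  untransformed scalar baselines × outcomes. Missing values are dropped
  pairwise, with the pair count recorded. Exact permutation p-values are
  used for n ≤ 9, the t-approximation otherwise. α = 0.05 two-sided
  throughout; the Benjamini–Hochberg step-up correction is applied once
  per analysis (globally, not per row) as a sensitivity check —
  primary inference stays uncorrected, as appropriate for an
  exploratory screen.

## Derived per-sample metrics

* **MGS abundance**: mean count of a species' marker genes (canonically
  100 markers; smaller sets are allowed and the detection rule applies
  fractionally), zeroed when fewer than 10 % of markers are detected
  (any count > 0 counts as detection), then renormalised to sum to 1.
  Optional gene-length scaling can be applied upstream of the marker
  means.
* **Rarefaction**: multivariate-hypergeometric subsampling without
  replacement to a fixed depth; samples shallower than the depth are
  excluded rather than imputed.
* **Observed richness**: features with strictly positive abundance.
* **β-lactamasome relative abundance**: copies mapping to the five
  Ambler β-lactamase families (A, B1–B2, B3, C, D; configurable) over
  all ARD-annotated copies, agnostic to the copy unit; undefined when a
  sample has no ARD copies.
* **Functional ratios**: cholesterol conversion
  `coprostanol/(coprostanol+cholesterol)`; bile-acid transformation
  `(LCA+DCA)/total`; fungal load `fungal DNA / faecal DNA`, with samples
  at or below the faecal-DNA quantification threshold (default 50)
  excluded.

## The synthetic cohort generator

The generator exists so the full pipeline is testable at desk scale. It
emulates a 22-subject, two-arm (1:1), 12-visit design with uniform
±0.25-day collection-time jitter and independent sample missingness
(default rate 0.05), with at least one pre-treatment sample always
retained per subject so the baseline is defined. Arms carry no effect
difference by default, matching the absence of a detectable difference
between the two cephalosporins.

Scalar variables follow `y = μ + b_i + deflection(t) + e` on the
analysis scale with Normal between/within-subject effects; the default
means and SDs for the 13 panel variables are the pre-treatment
variability scales typical of healthy adults (e.g. total bacterial
counts: mean 11.3 log10 CFU/g, between-SD 0.19, within-SD 0.14).
The treatment effect is a gamma pulse `-A·(t/p)·exp(1-t/p)` peaking at
day p = 4 (the end of the 3-day course) with an additional exponential
recovery of half-life 7 days — the published trajectories constrain the
shape only qualitatively, and this is the simplest smooth curve that is
monotone after the peak. Amplitudes are fixed once per variable to
mirror the qualitative response pattern (strong bacterial/resistome
depletion; β-lactamasome, β-lactamase activity and fungal load
*increase*, i.e. negative amplitude; near-null fungal richness).

Compositions are Dirichlet-multinomial: a per-subject baseline
relative-abundance vector, a fixed "susceptible" feature subset
(default 50 % for bacteria) multiplied by a depletion factor (default
0.01) that relaxes to 1 with a 5-day half-life after day 4, then
multinomial counts at fixed depth. The resistome generator assigns a
bla fraction of genes (default 1823/19061) to the five Ambler families
and enriches their expected copies post-treatment.

What the generator does **not** emulate: inter-variable correlation
(variables are simulated independently unless wired together by the
user), compositional coupling between layers, pharmacokinetics, strain
dynamics, and heavy-tailed count overdispersion beyond the
Dirichlet-multinomial. Passing tests therefore demonstrate that the
*pipeline arithmetic and inference are correct and calibrated under the
assumed noise structure*, not that real cohorts satisfy that structure.

## Numerical choices and known limitations

* Spearman support for structure distances: features nonzero in at
  least one of the two profiles; shared absences are excluded (double
  zeros carry no rank information and would inflate `s`). Ties get
  mid-ranks. Supports of fewer than 3 features, or rank-constant
  profiles, yield missing distances.
* Exact-test thresholds: signed-rank n ≤ 25, Spearman n ≤ 9 (full
  permutation enumeration); above these the standard approximations.
* REML search: bounded Brent on log λ ∈ [−30, 30] with xatol 1e−12,
  compared against the λ = 0 endpoint.
* Type-I calibration: over 500 simulated null cohorts the scalar AUC
  test rejects at ≈5 %; the structure AUC test runs slightly hot (≈6 %)
  because the normaliser is a mean of only two pre-treatment distances,
  so normalised distances are right-skewed ratios and the signed-rank
  symmetry assumption is mildly violated. This is a property of the
  normalisation scheme itself, not of the implementation; it stays
  within the 99 % binomial envelope of the nominal rate.
* Simulation sizes in the test-suite and acceptance studies (cohorts of
  6–22 subjects, 40–200 features, depths 2·10³–10⁵, 200–500 null
  replicates, 200 subjects for recovery studies) were chosen as the
  smallest scales at which the checked properties are stable.
* No smoothing, interpolation or imputation beyond the window-end rule;
  no per-arm stratified correlograms; no mixed models beyond the random
  intercept.
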