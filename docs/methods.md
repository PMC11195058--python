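# Methods

This note documents the models, parameter choices, and numerical
conventions behind `organclock`, and what the synthetic-cohort tests do
and do not establish about real data.

## Organ-enriched panels

A gene g is assigned to organ o when `expr(o, g) ≥ fold · max_{o'≠o}
expr(o', g)` with `fold = 4` by default. The comparison is inclusive
("at least four-fold"), so exactly 4× qualifies. Two edge conventions
are ours: a gene expressed in exactly one organ and zero elsewhere is
enriched there (the ratio is infinite), while an all-zero gene is
unassigned. For at most one organ the rule can hold when fold > 1, so
assignments are unique by construction. Enrichment calls are invariant
to global rescaling of the atlas and monotone in `fold` (raising the
threshold never adds a gene). When several genes map to one assay
protein, the protein joins the organ of the highest-fold gene.
Cell-type labels use the arg-max of per-group expression; exact ties
and all-zero genes are left unassigned with an explicit flag.

Organ panels are pairwise disjoint; assay proteins in no organ panel
form the *organismal* panel and the full assay the *conventional* panel,
so organ + organismal panels exactly partition the conventional one.

## Preprocessing contract

Order is fixed: missingness filter → KNN imputation → z-scaling, and a
run manifest records parameters. The filter removes proteins missing in
strictly more than 10% of samples (computed on the combined baseline
matrix, since one global removal count is the natural bookkeeping).
Imputation uses k = round(√n_train) neighbors (half-rounded away from
zero, so n_train = 21,504 gives k = 147; floor 1), fitted on training
samples only, with nan-aware Euclidean distances over co-observed
proteins and proportional rescaling for missing coordinates — the
standard KNN-imputer semantics. Scaling uses training means and
population SDs everywhere; a zero-variance training protein is an error
naming the protein. Consequences tested: imputation is the identity on
complete data, imputed values stay within each protein's training
range, and test columns are *not* re-standardized to their own moments.

## Aging clocks

Each clock is a LASSO regression of chronological age on its panel.
The penalty path is 100 log-spaced values from the data-derived
λ_max = max|Xᵀ(y − ȳ)|/n down to 10⁻⁴·λ_max. Five shuffled, seeded CV
folds score every λ by out-of-fold R²; "performance" in the back-off
rule is the mean CV R². Among all λ whose mean CV R² reaches
`perf_fraction` (default 0.95) of the best, the *largest* (sparsest) is
chosen — the path is sorted descending so the first qualifying index
wins, and the chosen λ is never below the CV optimum. The final model is
refit on all training samples at that λ. A clock whose best CV R² is ≤ 0
is flagged non-predictive and refuses to emit age gaps rather than
emitting noise.

Age gaps: ŷ is regressed on y by OLS over the training samples; the gap
is the residual, and z-gaps standardize it by the training gap mean and
population SD. Residualizer and scale are fitted on training data only
and frozen, which keeps test-set evaluation honest and makes permutation
analyses interpretable. By the OLS normal equations, training gaps have
mean 0 and are orthogonal to age (both checked to tight tolerance).
Sex is not a clock feature; sex differences are measured downstream on
gaps.

The meta-clock regresses the conventional clock's predicted age on the
organ clocks' predicted ages (LASSO, CV-chosen penalty) and reports
variance explained plus |coefficient|-normalized relative weights.

Distilled clocks target the *parent clock's predicted age* (not
chronological age) from a reduced panel, with the back-off fraction at
0.90, followed by recursive feature elimination with CV to shrink the
support further. A child is retained only when its held-out predictions
correlate with the parent's at r ≥ 0.8; the run record states the rule
in both r and r² readings since the threshold is configurable.

## Ageotypes and bins

Extreme ager: any eligible z-gap with |z| ≥ 1.5 — inclusive, and
configurable; at 1.5 the one-sided tail of a standard normal is ≈ 6.7%.
The conventional clock is excluded from eligibility because its signal
nearly duplicates the organismal clock's. Categories: normal (none),
single-organ, multi-organ (≥ 2, same sign, binned 2–4 / 5–7 / 8+, bins
shared between aged and youthful directions), ambiguous (both signs).
Half-SD bins have edges at ±0.5, ±1.0, ±1.5; interior bins are
left-closed/right-open, outer bins unbounded, eight in total.
Transition statistics report the repeat-risk ratio
P(extreme at v2 | extreme at v1) / P(extreme at v2 | not), same-sign
retention among v1 extremes, and identical-bin retention as a secondary
statistic; degenerate denominators are flagged rather than silently
dropped.

## Association machinery

Cox models use lifelines' partial likelihood with Efron tie handling,
time-on-study from the blood draw as timescale, and age-at-draw and sex
as default covariates. A z-scored exposure yields a per-SD hazard
ratio; categorical exposures are dummy-coded against the normal-ager
reference. Zero events, degenerate time distributions, or separation
come back flagged with no estimate instead of raising. Linear
associations are OLS with the same covariate convention; rank-deficient
designs are rejected naming the most collinear pair. BH correction is
the standard step-up, applied within one analysis family at a time
(e.g., a disease×model grid). Note the step-up map is *not* idempotent
on its own output when partial ties arise from the min-accumulation;
only monotonicity and q ≥ p are guaranteed, and the test suite checks
exactly those.

Gini dispersion of an endpoint's per-organ log HRs uses
G = Σᵢⱼ|xᵢ − xⱼ| / (2n²x̄) after clipping negative log HRs to zero
(protective effects don't signal organ-specificity of risk, and the
statistic is ill-defined for mixed signs); an all-zero vector leaves G
undefined and flagged. The mortality-model comparison fits
Lasso-penalized Cox models per feature set (always with age and sex),
choosing the penalty by 3-fold cross-validated partial log-likelihood
over a small grid, and reports train/test concordance plus the combined
model's coefficients.

## FIBA

For each clock protein with nonzero weight: permute its column across
samples (seeded), recompute predicted ages with the fixed linear clock
(a rank-one update, pred + w·(x_perm − x)), recompute z-gaps with the
frozen residualizer and scale, refit the outcome association, and score
the protein by baseline effect minus mean permuted effect over `n_perm`
draws (default 10; the permuted-effect SD is always reported since the
replicate count is a precision knob, not a model choice). Zero-weight
proteins score exactly 0 without computation. Permutation acts on the
analysis-ready (imputed, scaled) matrix so only the clock's use of the
protein is ablated, not preprocessing. Failed replicate fits are
dropped and counted; a protein whose replicates all fail is flagged.
Permuting every clock protein simultaneously must drive the association
to null — tested within ~2 SE of zero.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with every planted parameter kept in a serialized ground-truth record.

* **Subjects.** Ages uniform over (40, 70) — a maximally spread design
  for clock training; sexes Bernoulli(0.5); 21 collection centers
  assigned uniformly; two follow-up visits with intervals
  N(9.1, 1.8²) and N(3.3, 1.6²) years.
* **Latent gaps.** One factor per organ plus a shared "organismal"
  factor; standard normal marginals, equicorrelated at ρ = 0.21
  (positive-definite iff ρ > −1/(k−1); violations are rejected naming ρ
  and k; a user matrix can replace the equicorrelation). Across visits a
  stationary AR(1) with autocorrelation 0.6 keeps marginals standard
  normal at every visit.
* **Proteome.** Protein j of panel o:
  `m_j + a_j·(age − 55) + b_j·gap_o + s_j·male + ε`,
  ε ~ N(0, 0.5²) NPX; age trends a_j ~ ±U(0.02, 0.08) NPX/yr; sex
  effects s_j ~ N(0, 0.2²). The gap loading is tied to the age trend,
  **b_j = a_j · gap_scale_years** (default 5 y/SD): a biologically older
  organ moves its proteins along their own age trajectory, so the latent
  gap reads as extra years. This coupling is essential — if gap loadings
  had signs independent of the age trends, the age regression would
  simply cancel the shared gap factor (it is orthogonal to age) and no
  clock could recover it; with the coupling, predicted age ≈ age +
  5·gap, which is precisely the mechanism by which real clocks pick up
  biological age. Setting `gap_scale_years = 0` gives the null design in
  which clocks can predict age but no gap signal exists.
* **Events.** `h(t|x) = h₀·exp(Σ_o β_o·gap_o + γ·(age−55) + δ·male)`
  with an exponential baseline and inverse-transform sampling
  (`T = Exp(1)/(h₀·e^lp)`), administratively censored at 17 years.
  Defaults: γ = 0.087/yr (hazard doubling every ~8 years), δ = 0.40;
  mortality log HRs spanning 1.2–1.6 per SD across organs with brain
  pinned at 1.58; a brain-only dementia endpoint at HR 1.81/SD and a
  heart-dominant (1.83) endpoint with mild artery/kidney/lung loading.
  The survival function evaluated at uncensored event times is uniform
  (probability-integral transform, KS-tested).
* **Missingness.** MCAR at rate 0.02 by default — matching the
  assumption under which KNN imputation is unbiased.

Sizes used by the default test suite and the acceptance script: 20,000
subjects for distributional checks; 5,000 for hazard-ratio recovery and
clock train/test parity; 10,000 for linear-effect recovery; 2,500 for
the end-to-end clock pipeline; 400 simulated null pairs for type-I
calibration.

What passing tests show: the estimators recover what the generator
plants, at the planted magnitudes, under the stated noise. What they do
not show: robustness to batch/plate effects, assay limits of detection,
informative missingness, non-proportional hazards, or non-linear
protein-age trajectories — none of which the generator emulates
(deliberately: each would confound attribution of a failure).

## Numerical conventions and degenerate inputs

Seeds fan out from one global seed by fixed per-stage derivation
(SHA-256 of `seed:stage`, reduced below 2³¹), so stages are
independently reproducible and the pipeline manifest can promise
bit-identical reruns. Ties: arg-max ties in cell-type labels →
unassigned; the extreme-ager threshold is inclusive; bin edges are
left-closed. Degenerate inputs fail loudly and specifically: single-organ
atlases, empty or total center splits, zero-variance proteins, all-missing
samples, zero-event endpoints, rank-deficient designs, and non-PD gap
correlations each raise (or flag) with the offending name in the message.

## Known limitations

* The distilled-clock retention threshold conflates two readings
  (r vs r²) found in practice; we implement r ≥ 0.8 and record both.
* Marginal per-SD hazard ratios on estimated z-gaps are inflated
  relative to planted organ-specific effects whenever gaps are
  correlated; recovery tests therefore use the true latent gap as the
  exposure, and analyses of estimated gaps should be read as marginal,
  not causal.
* The penalized-Cox comparison uses a small penalty grid (10⁻³–10⁻¹) —
  adequate for ranking feature sets, not for fine-grained risk
  calibration.
* `run_pipeline` persists every stage artifact with a digest manifest;
  resuming a failed run means re-running from the persisted artifacts
  rather than an automatic checkpoint restart.
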