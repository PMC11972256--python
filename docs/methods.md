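# Methods

This note documents the statistical machinery in `vizlit`: what each stage
assumes, the parameters that matter, the numerical choices made where the
design was open, and what the synthetic-data tests do and do not establish.

## The data and the error matrix

The unit of analysis is an **error matrix** `X` of shape m x n (items x
participants) with `X[i, j] = 1` when participant j answered item i
incorrectly, together with the per-item error means `mu` (row means of
`X`).  The built-in combined bank has m = 66 items: a 13-item
graph-literacy scale (GGR: fill-in and three-option multiple choice, items
organized into read-the-data / read-between / read-beyond levels over bar,
line, pie and icon-array graphs) and a 53-item visualization-literacy test
(VLAT: true-false and multiple choice over twelve graph types and eight
task types).  Together the items span 2 tests, 13 graph types and 11
question types; those three taxonomies drive everything downstream.

Grading rules: fill-in responses are trimmed, lowercased and stripped of
thousands separators; when both response and key parse as numbers they are
compared numerically, otherwise as normalized strings.  One GGR item is
graded against a closed numeric interval ([23, 25]) rather than an exact
key.  **A skipped item is scored as an error.**  The source instruments
define no partial credit and do not state a skip rule, so this is a
package decision, applied uniformly and worth knowing about when comparing
against other scorings.  Participants are excluded (not imputed) unless
they have exactly one response per item and a complete demographics row.

The per-item level/task assignment in the built-in bank is a structural
placeholder: it reproduces every published count (13/53 split, response
format counts, facet cardinalities 2/11/13, the single interval-graded
item) but not the copyrighted item text, answer keys, or the exact
item-by-item level assignment of the original instruments.  Real
administrations should supply their own bank file; the JSON/CSV schema is
documented on `load_item_bank`.

## Descriptives

Convergent validity between the two tests is the correlation between
per-participant GGR and VLAT accuracies.  Pearson is the default and
Spearman is available; since the choice of coefficient is a convention,
the pipeline reports both.  The 95% CI uses the Fisher z-transform
(`tanh(atanh(r) +/- 1.96 / sqrt(n - 3))`); a bootstrap CI over
participants is available through the resampling module for users who
prefer a non-parametric interval.  Group summaries report mean accuracy
and SEM (`sd / sqrt(k)`, sample SD) per sample group and per count of
prior math courses.

## Random-intercept logistic GLMM

Item-level correctness is modeled as

    logit P(y_ij = 1) = x_ij' beta + u_j,   u_j ~ N(0, sigma_u^2),

with fixed effects for item taxonomy and participant covariates and one
random intercept per participant.  Estimation is maximum likelihood (not a
REML analogue), so nested fits are directly comparable by the
likelihood-ratio chi-square; p-values use the chi-square reference with
df = difference in free parameter counts.  No multiple-testing correction
is applied across the predictor suite; consumers see raw p-values.

The marginal likelihood integrates `u_j` out by **adaptive Gauss-Hermite
quadrature**: for each participant the integrand is recentred at its mode
(found by Newton iterations; the objective is concave in u) and rescaled
by the curvature there, then a Hermite rule is applied.  The node count is
configurable (default 10; one node reproduces the Laplace approximation).
On small problems the 10-node value agrees with brute-force fine-grid
integration to well below 1e-4 in the log-likelihood, and accuracy
improves monotonically with node count.

Numerical choices: the optimizer is L-BFGS-B on `(beta, log sigma_u)` with
`log sigma_u` bounded in [-8, 3] (so sigma_u = 0 is approached smoothly),
convergence tolerance 1e-6 on relative log-likelihood change, and a plain
logistic-regression IRLS warm start.  Categorical predictors use treatment
contrasts with the alphabetically first level as reference (LRT results
are invariant to this).  If a fitted fixed effect diverges past 15 in
absolute value, complete separation is assumed: the fit is rerun with a
small ridge penalty (1e-3) on the non-intercept coefficients and a warning
is raised.  A stalled optimizer returns `converged=False` rather than
raising.  Wald standard errors, when requested, come from a
central-difference observed information matrix.

The predictor suite tests each main effect (graph type, question type,
test, math courses, sample group) against the intercept-only baseline, and
each `predictor x sample_group` interaction against the additive model
containing both main effects.  The nesting sequence for interactions is a
package choice; other baselines are possible, and the suite's CSV output
states which comparison produced each row.

## Factor models of the error matrix

All models decompose the row-centered error matrix `X - mu = L F + eps`
with loadings `L` (m x f) and per-participant factor scores `F` (f x n).

**Idealized models** fix `L` as the binary indicator matrix of a taxonomy
(test: f = 2, question type: f = 11, graph type: f = 13 on the combined
bank) and estimate only the scores, per participant, by least squares.
For disjoint indicators this closed form is the participant's mean
centered error within each category.  Idealized-model MSE is computed
in-sample by default — only the latent model, whose loadings are
estimated from data, is cross-validated — but a flag (`cv_idealized`)
cross-validates the idealized models too.

**The latent model** estimates `L` by Gaussian maximum-likelihood factor
analysis of the centered matrix, treating participants as observations
and items as variables.  The EM estimator (via scikit-learn, LAPACK SVD,
constant uniqueness initialization, tolerance 1e-6) is deterministic
given the data.  The log-likelihood and BIC are computed from the model
covariance `L L' + diag(psi)` against the sample covariance, so both are
exactly invariant to orthogonal rotation of the loadings.  The BIC
penalty counts `m f + m - f (f - 1) / 2` free parameters (rotational
indeterminacy removed); the selected factor count is the smallest f
attaining the minimum BIC over the requested range.  Uniquenesses driven
to the boundary (Heywood cases) are floored at 1e-3 with a warning.  No
rotation is applied anywhere on the modeling path — predictions are
rotation-invariant — and a varimax rotation exists only for the
interpretive loading heatmap.

Treating a binary matrix with a Gaussian likelihood is a deliberate
working approximation: the factor decomposition is a linear model of
binary data, and the Gaussian ML fit is the estimator for that linear
form.  Tetrachoric-correlation or item-response-theory alternatives are
out of scope.

**Prediction and MSE.**  A model predicts `mu + L F` (unclipped by
default; a flag clips into [0, 1]).  Each participant's score is the mean
of their squared item-level prediction errors (`mean_per_item`), and the
group-level MSE is the unweighted mean over participants;
`sum_over_items` is provided as an alternative scale because summed and
averaged conventions both appear in the literature and differ by a factor
of m.  Note that on binary outcomes the per-item-mean group MSE is
bounded near 1, so MSE magnitudes quoted elsewhere on other scales should
be compared by ordering, not magnitude.

**Cross-validation.**  Participants are dealt into k = 5 seeded folds
(remainder spread across the first folds).  For each fold, `L` and the
item means come from the training participants only; held-out factor
scores are least-squares estimates against the training `L` (using the
training `mu` — which `mu` to use out-of-fold is a package choice), and
the per-participant MSE is assembled from held-out predictions only.

**A calibration caveat.**  Factor scores are free per-participant
parameters estimated from that participant's own m responses — also for
held-out participants.  Under pure noise with residual variance sigma^2,
the expected per-participant MSE of an f-factor model is therefore
approximately `sigma^2 (m - f) / m`: models with more factors fit noise
mechanically better, in-sample and under this CV scheme alike.  Raw MSEs
of idealized models with different f are consequently *not* equal under
the null; the df-adjusted residual variance `MSE * m / (m - f)` is, and
that is what the null-structure test checks.  Comparisons between models
of similar f (for example graph type's 13 vs question type's 11) are
essentially unaffected; comparisons against the 2-factor test model
carry a mechanical advantage of about (f - 2)/m that should be kept in
mind when interpreting small differences.

## Bootstrap confidence intervals

Group-level statistics (chiefly group MSE) get percentile bootstrap CIs:
resample participants with replacement at full sample size, recompute the
mean per replicate (default 10,000 replicates), and take the 2.5th and
97.5th percentiles using numpy's linear-interpolation convention.  BCa
corrections are not applied.  Coverage of the mean on iid data sits at
~95% in the calibration tests.

## The synthetic cohort generator

The generator emulates the structure the pipeline assumes, with defaults
set to the study-scale conditions the pipeline targets: n = 1,113
participants in a 36/64 representative/university split, a 0-3
math-course covariate whose distribution differs by group, ~5%
incompleteness, around 72-75% overall accuracy, a per-course log-odds
effect of 0.2 on correctness, a between-group log-odds gap of 0.25, an
ability SD of 1.0 on the logit scale, and f_true = 4 latent factors with
sparse loadings of strength 1.5.  Item difficulty intercepts are uniform
on [-2.5, 0.5] (logit of error probability) unless overridden per item.

Per cell, the error probability is `sigmoid(d_i + (L F)_ij -
math_effect * c_j - group_effect * g_j - a_j)` under the default logistic
link; `linear_clipped` instead adds the same terms on the probability
scale and clips into [0, 1], matching the factor model's linear form at
the cost of boundary censoring.  Loadings come from a taxonomy indicator,
a random one-factor-per-item sparse scheme, or a user-supplied matrix.
Errors are converted to concrete wrong answers (opposite truth value, a
different option letter, an offset number) so the scoring path is
exercised end to end; the full generative record (loadings, scores,
effects, cell probabilities, the pre-incompleteness error matrix) is
returned so tests never re-derive ground truth.

What the generator does **not** emulate: item-specific guessing floors
tied to the number of response options, response times, learning or
fatigue across the session, non-independence of errors beyond the latent
factors, and real item content.  Passing recovery tests therefore shows
the estimators are correct under the assumed generative family, not that
real assessment data satisfy those assumptions.

## Problem sizes used in tests

The test suite and acceptance checks run at deliberately modest sizes
chosen to make the relevant asymptotics visible: oracle comparisons on
4-participant GLMM problems and 20-item score problems; type-I-error
calibration over 500 null replicates of 40 participants x 12 items; BIC
factor-count recovery over 50 replicates at n = 1,000, m = 66; effect
recovery at n = 2,000 participants x 15 items; model-comparison
self-consistency over 20 replicates at n = 250; bootstrap coverage over
200 datasets of n = 80.  The acceptance script runs the full pipeline
once at the default n = 1,113 cohort scale.

## Known limitations

* The GLMM supports a single random intercept (participant); random
  slopes and crossed item random effects are out of scope, so item-level
  difficulty variation not captured by the fixed taxonomy inflates the
  taxonomy's apparent effect.
* The Gaussian factor likelihood ignores the binomial mean-variance
  relationship of binary errors; BIC values are comparable across f but
  are not calibrated probabilities.
* Idealized loadings must partition items (one category per item);
  overlapping taxonomies would need the general least-squares path with a
  user-supplied loading matrix.
* Bootstrap CIs treat participants as exchangeable; no stratification by
  sample group.
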