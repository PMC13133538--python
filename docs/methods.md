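# Methods

`hyperdim` implements a complete dimensional analysis of ordinal
questionnaire batteries of the kind used to measure hyperarousal across
mental disorders: latent-correlation estimation, item screening and
de-duplication, exploratory factor analysis, short-form construction,
confirmatory modelling and reliability, severity association profiling with
regularized partial-correlation networks, and factor extension onto items
outside the analyzed battery. This note documents the models, the defaults
and why they are what they are, what the synthetic-data generator does and
does not emulate, and the numerical choices that matter.

## Measurement model

Every analysis assumes the standard ordinal factor model. Item *j* has a
continuous standard-normal latent response
`y_j = lambda_j' f + eps_j`, with factors `f ~ MVN(0, Phi)`,
`Var(y_j) = 1`, and the observed code `x_j = c` whenever
`tau_{j,c-1} < y_j <= tau_{j,c}` for the item's strictly increasing
threshold vector `tau_j`. Correlations between items on the latent scale
are polychoric correlations.

### Polychoric estimation (`hyperdim.polychoric`)

The two-step maximum-likelihood estimator is used: thresholds are fixed at
the inverse normal CDF of each item's cumulative margin proportions, then
each pair's correlation maximizes the bivariate-normal multinomial
log-likelihood of the pair's contingency table with thresholds held fixed.
Decisions worth knowing:

- **Continuity correction.** Every zero cell of a pair's table is replaced
  by 0.1 before both margins and likelihood are computed. Entirely empty
  categories are collapsed instead (the correction addresses sampling
  zeros, not structurally absent response options).
- **Pairwise-complete, local thresholds.** Thresholds are re-estimated per
  pair on the pair's complete rows, so missing data never distort other
  pairs.
- **Optimizer.** Bounded Brent scalar minimization on (-0.999, 0.999),
  `xatol = 1e-6`. The likelihood is smooth and unimodal in practice; the
  bound keeps boundary tables (all mass on the diagonal) finite.
- **Bivariate normal CDF.** A vectorized Genz / Drezner-Wesolowsky
  quadrature (`hyperdim._bvn`), accurate to ~1e-14 against an independent
  Owen's-T construction. scipy's `multivariate_normal.cdf` evaluates points
  in a Python loop and is two orders of magnitude too slow for ~2,000
  pairwise optimizations per battery.
- **PSD smoothing.** Pairwise assembly can produce indefinite matrices;
  negative eigenvalues are clipped to 1e-8, the matrix reconstructed and
  rescaled to unit diagonal, and the event flagged. No entry moves by more
  than the magnitude of the most negative eigenvalue.

### Sampling adequacy

Kaiser-Meyer-Olkin: per-item MSA contrasts squared raw correlations with
squared anti-image (partial) correlations from the inverse matrix; items
with MSA below 0.7 (default) are dropped before factoring.

### Redundancy reduction (`hyperdim.reduction`)

Near-duplicate items inflate multicollinearity and distort factors. The
stepwise procedure walks thresholds 0.90, 0.85, ..., 0.50; at each, while
any surviving pair exceeds the threshold in |r|, the pair with the largest
|r| is resolved by removing the member whose **absolute median correlation
with the other surviving items** is higher (it carries less unique
variance). Medians are recomputed on the surviving set after every removal.
Ordering is deterministic (descending |r|, ties by label) and median ties
fall back to an optional caller-supplied priority rank, then label order,
with the tie flagged in the trace. The stop threshold is a parameter
because where to stop is a judgment about how many items remain workable,
not a statistical rule.

### Exploratory factor analysis (`hyperdim.efa`)

- **Retention.** Parallel analysis compares principal-component eigenvalues
  of the observed correlation matrix with the 95th percentile of
  eigenvalues from 200 simulated standard-normal datasets of the same
  shape; the suggested count is the number of leading observed eigenvalues
  above their simulated quantile with no gaps. The pipeline accepts an
  explicit factor-count override, since content-based judgment routinely
  overrides the suggestion on real batteries.
- **Extraction.** Iterated principal-axis factoring: communalities start at
  squared multiple correlations `1 - 1/diag(R^-1)` and the reduced-matrix
  eigendecomposition is iterated until the largest communality change is
  below 1e-6. Heywood cases are clipped to 1 and reported.
- **Rotation.** Promax with power 4: Kaiser-normalized varimax, then an
  oblique least-squares transform to the `sign * |loading|^4` target,
  scaled so the implied factor correlation matrix has unit diagonal. The
  varimax inner loop is run from the identity plus three deterministic
  random-orthonormal starts and keeps the best explicit criterion value,
  because the SVD pairwise iteration stalls on saddle points of exactly
  symmetric loading patterns (a real failure mode on clean synthetic
  data). Factor signs (largest |loading| positive) and order (descending
  structure sum of squares) are fixed conventions so runs reproduce.
- **Variance accounted.** Two conventions are reported side by side:
  structure-loading sums of squares over the item count, and the
  communality partition `diag(Phi L'L)/p`, which totals the mean
  communality and is the figure most packages print per factor. The output
  records which is which.
- **Scores.** Loading-weighted sum scores (responses times pattern
  loadings over all items). A person missing an item that is salient
  (|loading| >= 0.32) on a factor receives a missing score on that factor;
  missing non-salient items drop out of the sum.

### Short form (`hyperdim.shortform`)

Markers per factor default to (4, 5, 4, 4, 4, 2, 4). Selection takes the
highest-|pattern-loading| items whose largest other-factor |loading| stays
at or below 0.32, relaxing the cap in recorded 0.05 steps only if a factor
cannot fill its count; a manual override list stands in for content
judgment and is recorded. Scoring rescales each marker to 0-4 from its
declared coding bounds and averages within factor; a missing marker blanks
that factor's score for that person (the instrument is too short for
available-item means to preserve meaning).

### Confirmatory models and reliability (`hyperdim.cfa`)

Normal-theory ML on a covariance or correlation matrix:
`F = log|Sigma| + tr(S Sigma^-1) - log|S| - p`, congeneric structure (each
item on exactly one factor), factor variances fixed to 1. The factor level
is either unstructured correlations or a higher-order layer
(`Phi = gamma gamma' + diag(1 - gamma^2)`). Gradients are analytic;
optimization is L-BFGS-B from a deterministic start (loadings 0.7 on each
item's scale, uniquenesses 0.51, correlations 0.3) with seeded jitter
restarts. Fit indices: `chi2 = (n-1) F`; CFI/TLI against the independence
baseline on the correlation scale; `RMSEA = sqrt(max(chi2 - df, 0) /
(df (n-1)))`; SRMR as the RMS residual correlation. Nested models compare
by the likelihood-ratio chi-square. The estimator is deliberately
pluggable on the input side: the product-moment covariance of 0-4 rescaled
items is the default, a polychoric matrix can be passed instead; which
matrix entered is recorded in pipeline output since ordinal-robust
estimators would give different absolute fit values.

Cronbach's alpha is computed exactly from its covariance definition;
omega_total from a one-factor ML fit of the subset; omega_hierarchical
(experimental) from the higher-order model via the Schmid-Leiman
projection.

### Association profiles and networks (`hyperdim.association`, `hyperdim.network`)

Severity regressions are OLS on listwise-complete rows with all continuous
variables standardized on the analysis sample (binary covariates such as
sex stay on their own scale), t-based confidence intervals, no
multiple-testing correction beyond what the network bootstrap provides.
Screener classification thresholds at the published cut-points
(ISI >= 10; depression 13, generalized anxiety 11, social anxiety 12,
panic 9, posttraumatic stress 8 on the RMT20 subscales; ASRS >= 4).

The partial-correlation network runs the graphical lasso (scikit-learn's
coordinate-descent solver) over 100 log-spaced penalties from `lambda_max`
(the largest absolute off-diagonal correlation, the smallest penalty that
empties the graph) down to 1% of it, selecting the penalty by
`EBIC = -2 loglik + E log n + 4 gamma E log p` with `gamma = 0.5`. Edge
weights are `-omega_ij / sqrt(omega_ii omega_jj)`. Edge stability uses a
nonparametric person bootstrap (default 2000 resamples) that refits the
entire procedure — penalty re-selection included — per resample and zeroes
edges whose (2.5%, 97.5%) bootstrap interval covers zero. Solver tolerance
is 1e-3 with 100 iterations: along realistic 14-node paths this differs
from tol 1e-4 / 200 iterations by at most 3e-3 in any precision entry
(measured) while being ~8x faster, which is what makes thousands of
bootstrap refits practical. Note that the un-thresholded EBIC selection
deliberately tolerates a few numerically tiny spurious edges (|w| < 0.01
against ~0.3 for real ones); the bootstrap threshold is the step that
removes them, which is why the two are used together.

### Factor extension (`hyperdim.extension`)

For external items never entered into the factor analysis, the extension
structure is `S_e = R_eo R_oo^-1 (Lambda Phi)` and the extension pattern
`Lambda_e = S_e Phi^-1`, where `R_eo` is the external-by-original
correlation block (polychoric by default). Published descriptions of the
method do not fix a formula, so this variant is pinned by a contract: an
external item identical to an analyzed item must reproduce that item's
pattern row exactly, for any positive-definite `Phi` — a property test
enforces it at k = 2 and 7. Note the extension loading of a genuinely new
item is attenuated by factor determinacy (how well the analyzed items pin
down the factor); with well-determined factors the attenuation is a few
percent, with weak ones it is substantial. Indicator items are selected by
the specificity rule (primary |loading| > 0.45, every cross |loading| <=
0.32); dimensions with at least 3 selected items are "representable".
Indicator scores average the available 0-4-rescaled items (item-wise
exclusion of refusal codes, unlike short-form scoring) — recorded in
output metadata.

## Synthetic cohorts (`hyperdim.simulate`)

The generator draws factors from `MVN(0, Phi_true)`, forms unit-variance
latent item responses, discretizes at fixed thresholds, and adds
linear-in-factor severity outcomes, age/sex covariates and MCAR
missingness. One seed drives everything through per-table spawned
substreams, so identical seeds give identical cohorts.

`preset_study_like()` freezes the emulated study conditions: n = 467;
seven correlated factors (pairwise correlations 0.14-0.57, median 0.40);
27 marker items in the (4, 5, 4, 4, 4, 2, 4) pattern with primary loadings
descending 0.80, 0.76, ... within each factor and zero cross-loadings; six
further moderately loading items per factor (0.50-0.60 primary, 0.15 on a
neighbouring factor) so the battery is 69 items with roughly the analyzed
battery's item density and its ~5% share of dichotomous items; severity
outcomes with effect patterns echoing the reported regression profiles,
noise set for population R^2 = 0.55, and affine calibration to the
published screener means and SDs so cut-point classification is
meaningful; female prevalence 0.776, age ~ N(58.3, 13.8) truncated to
[18, 90]; missingness 6e-4 (the reported technical-missingness order of
magnitude); and 22 external indicator-source items of which 17 (8 anxious,
5 irritable, 4 sleep-related at 0.70 primary) satisfy the selection rule
and 5 (cross-loaded or weak) must be rejected, so exactly three dimensions
are representable. `preset_full_battery()` mirrors the full 221-item
battery's category mix (12 dichotomous, 91 four-level, 118 five-level) for
tests that need it.

What the generator does **not** emulate: non-normal latent distributions,
informative (MAR/MNAR) missingness, item wording effects, acquiescence or
other method variance, test-retest attrition, and real screener total
scores built from their own items (severities are continuous latent
composites calibrated to screener moments, intentionally not clipped to
the theoretical score ranges so that standardized-coefficient coverage is
exact). Passing recovery tests therefore demonstrates correctness of the
estimators under the stated measurement model, not robustness to these
real-data features.

## Problem sizes in the test suite and acceptance script

Tests run at the study's own scale (n = 467 cohorts) except where a check
is about asymptotics (n = 2000-5000 for polychoric bias, chain-network
recovery, tau-equivalence) or margins (n = 1e5 for threshold calibration).
The bootstrap-thresholding recovery test uses 250 resamples per replicate
across 25 replicates with a 20-point penalty path; the acceptance script
runs the pipeline's single network at the full 2000 resamples. These sizes
are the package's chosen defaults for its own verification runs.

## Known limitations

- CFA fit values are normal-theory ML on rescaled ordinal items; robust /
  ordinal-weighted estimators (WLSMV-class) are not implemented, so
  absolute fit indices on coarse items are mildly optimistic.
- No oblimin/geomin/target rotations and no maximum-likelihood EFA.
- No measurement-invariance (multi-group) machinery.
- omega_hierarchical depends on a higher-order model that is only
  identified with >= 4 factors (with 3 it is a constrained
  reparameterization of the free model with equal parameter count).
- The reduction procedure's reading of "median correlation with all other
  items" is "other *surviving* items, recomputed after each removal"; the
  alternative (against all original items, single pass) is a configurable
  future extension but not the default.
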