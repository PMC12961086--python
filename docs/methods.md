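# Methods

This note documents the statistical machinery in `wolfreports`: the
models, the synthetic data they are exercised on, the numerical choices,
and what the tests do and do not establish about real report archives.

## Observed/availability design

Use-availability inference treats the archive of observed reports as a
point pattern over space × season and asks how its intensity varies with
covariates, without requiring absence data. For every observed report we
draw `ratio` availability points uniformly inside the region boundary
(rejection sampling from the bounding box), give each a uniform random
date on the integers 1..365, and copy the observed report's reporter
identity onto its availability partners. Logistic regression of the case
indicator on covariates then estimates the coefficients of the log-linear
intensity: if observed covariates have density ∝ exp(β'z) relative to the
availability measure, the log odds of case = 1 is β'z plus a constant, so
the slopes — not the intercept — are ecologically interpretable.

Availability dates are drawn independently of the paired observed date
(the pairing exists only to carry the reporter identity and to keep folds
leak-free), and availability locations are deliberately *not* constrained
by any wolf-density surface: density effects are part of what the model
estimates. The footprint is z-transformed with the sample standard
deviation, pooled over observed + availability rows jointly — pooling is
the only choice that leaves one scale per model — and the (mean, sd) pair
is stored in the `DesignMatrix` so any new data or prediction grid is
placed on the training scale.

Covariates: harmonic pair (sin θ, cos θ) with θ = 2πJ/365, which makes
the seasonal effect continuous across the 31 December / 1 January
boundary; orthonormal polynomial contrasts of the ordinal recolonization
step (equally spaced scores 1..5 by default — the standard construction;
a `zone_scores` option accepts unequal spacings such as calendar
recolonization years, since with only the ordinal ranks the intended
spacing is genuinely ambiguous); and linear + quadratic standardized
footprint to allow an interior optimum. Before fitting, covariates are
screened for pairwise collinearity (|r| < 0.7) and multicollinearity
(VIF < 3, computed as 1/(1−R²) from regressing each covariate on the
others).

## Fitting and inference

All binomial fits use one penalized-IRLS core: iteratively reweighted
least squares with step-halving, so the (penalized) log-likelihood is
non-decreasing across iterations; convergence at relative objective
change ≤ 1e-8, at most 100 iterations; linear predictors clipped at ±30;
quasi-separation flagged when any coefficient exceeds 15 on standardized
covariates. The unpenalized fit is maximum likelihood; the covariance is
the inverse Fisher information at the optimum.

Grouping structure (reporter identity, province) can be absorbed through
random intercepts: group deviations enter as ridge-penalized dummy
coefficients and each factor's variance is chosen on a coarse log grid by
coordinate descent on a Laplace-type approximation to the marginal
likelihood. Random *slopes* are deliberately out of scope: the inferential
surface here (likelihood-ratio df bookkeeping, parameter recovery,
cross-validation) operates at the fixed-effect level, and df accounting
counts fixed-effect parameters only, so the ladder dfs (8 / 2 / 4 / 2 / 1)
are invariant to the random-effects configuration.

Inference is a planned ladder of likelihood-ratio tests against reduced
refits (global test first, then one test per factor), each χ² = 2Δlogℓ
with df equal to the parameter-count difference. P-values are reported as
computed, with no multiple-testing correction: the ladder is a planned
decomposition guarded by the global test. Overdispersion is monitored by
φ = Σ Pearson residuals² / residual df; φ ≈ 1 indicates an adequately
specified binomial response.

## Ratio sensitivity and cross-validation

The availability ratio trades Monte-Carlo error against computation. For
each candidate ratio the design is rebuilt with fresh seeds and refitted;
the selected ratio is the smallest at which the mean slope vector,
scaled by a pooled per-term magnitude (root-mean-square across ratios,
floored at 1e-3), changes by less than 5% when moving to the next larger
ratio. The default grid (1, 2, 5, 8, 11, 15, 20) brackets the operating
point of 11 used throughout.

Because case/availability data are not presence/absence, predictive
skill is validated with an area-adjusted-frequency k-fold scheme: folds
partition *observed reports* (availability rows travel with their paired
report, which both matches the "one fifth of the data" notion and
guarantees no leakage — an assertion enforces it); the model refitted on
the training folds scores withheld rows; withheld availability scores are
cut into `n_bins = 10` equal-count bins (equal-count avoids empty
denominators; bins collapsed by ties are merged); and Spearman's ρ
between bin rank and adjusted frequency (withheld observed share ÷
availability share) summarizes each fold. Constant scores make ρ
undefined and are reported as a failure, not a number. A conservation
identity — availability-share-weighted adjusted frequencies average
to 1 — is tested.

## Valence model

The negative-valence probability uses a penalized cubic B-spline in
standardized footprint: k = 25 basis functions on quantile-spaced knots,
second-order difference penalty, penalty weight selected on a log-spaced
grid (1e-2..1e4) by AIC with effective df = tr(hat matrix). This is a
standard P-spline stand-in for adaptive-penalty smoothers: the scientific
surface of interest is the shape of the fitted curve (rise, optimum,
plateau), which a single grid-selected penalty recovers, not the exact
coefficient values of any particular smoother implementation. Zone
contrasts enter unpenalized. An optional spatial term — a thin-plate
radial basis r²·log r on k = 40 k-means centers of the report
coordinates, ridge-penalized, with its weight on the same AIC grid —
absorbs residual spatial correlation. No reporter random effects are
fitted: with roughly half of all reports being a reporter's only
contribution, a multilevel structure is not estimable, and estimation is
plain penalized maximum likelihood throughout. Accuracy is the AUC
(Mann–Whitney rank form, ties counted half) over repeated stratified
70/30 splits, each repetition refitting the model — including penalty
selection — on its training part. Basis evaluation outside the training
range is clipped to the boundary knots, so extrapolated curves flatten
rather than explode.

## Synthetic data

The generator emulates the structure of a regional report archive on a
100 × 80 km landscape at 1-km resolution (tests use a 50 × 40 km
variant). The footprint surface is Gaussian-smoothed white noise
(σ = 3 cells) mixed with a radial outward trend and rescaled to [0, 50];
the five recolonization zones are concentric equal-area rings (zone 1
innermost, earliest colonized), so the mix weight (default 0.3) induces a
mild zone–footprint correlation around 0.45, matching the regime in which
the collinearity screen must pass while the two effects remain
separable. Provinces are ten angular sectors. Reports are drawn by
rejection sampling against sup λ of the log-linear intensity
λ(x, J) ∝ exp(β_s sin θ + β_c cos θ + γ_S + β_H H + β_H² H²).

Default truth (the package's standing study conditions): seasonal
amplitude 0.55 peaking at the end of February (about a threefold
trough-to-peak ratio); zone effects (0, 0.74, 1.77, 1.56, 2.33) derived
from relative report densities increasing toward recently recolonized
areas; footprint pair β_H = 0.105, β_H² = −0.0012 per raw index unit,
giving an interior optimum near 44. Reporter multiplicities are truncated
geometric with success parameter 1 − q, q = 1 − √s, so the expected share
of reports from single-report reporters equals the target s = 0.473 — a
one-parameter family pinned to the only published statistic; the true
multiplicity distribution of real archives is unknown. Valence labels:
49.5% neutral at random, the rest negative with probability
expit(g(H) + δ_S) where g is a tabulated rise-then-plateau curve
(−0.8 → +0.8, inflection at H = 20) and δ ranges from +0.4 (oldest zone)
to −0.3 (newest).

What the generator does **not** emulate: settlement and road geometry,
reporting-channel effects, temporal trends across years, observer-density
gradients within zones, spatially clustered reporting (duplicate calls
about one animal), or linguistic structure in messages. Passing tests
therefore demonstrate that the estimators recover the truth of this
generative family at realistic sample sizes — not that any real archive
satisfies the model's assumptions.

## Problem sizes and numerical choices

Simulation-based checks use 2000 observed reports at ratio 11 (24 000
rows) with 50 replicates for Wald-coverage recovery, 200 replicates for
the season-test type-I rate, 50 permutation replicates for the
cross-validation null, and 200 repetitions for the repeated-split AUC
(scaled from the 1000 a full analysis would use; the Monte-Carlo error of
a mean AUC at 200 repetitions is already well below the tolerance of
interest). Ties in zone assignment on ring boundaries resolve to the
lower (earlier) zone; raster lookup is nearest cell center, north-up,
half-open intervals, with points in unlabelled rim cells resolved to the
nearest labelled cell and counted in a logged warning. Dates are integers
1..365; leap days are not generated, and CSV round-trips use a fixed
non-leap year. All randomness flows through explicit integer seeds or
`numpy.random.Generator` instances; identical seeds reproduce results
bit-for-bit.

## Interfaces

The package is organised as model objects in the statsmodels idiom —
`OccurrenceModel(...).fit() → OccurrenceResults`,
`ValenceModel(...).fit() → ValenceResults` — with simulation
(`synthetic`), design construction (`design`) and validation
(`validation`) as functions around them; the library surface plus
`scripts/acceptance.py` is the intended interface, so no console entry
point is installed. Landscape rasters are written as ESRI ASCII grids and
vector layers as GeoJSON (via shapely geometry mapping), keeping every
artifact plain text.

## Known limitations

Random slopes and exact mixed-model likelihoods are out of scope (see
above); the valence smoother approximates, not reproduces, adaptive
splines; availability sampling is uniform over the region rather than
population-weighted; the lexicon classifier is a word/pattern matcher
with no claim to reproduce any human coding protocol beyond its examples;
and the intercept of the occurrence model is design-dependent and should
never be interpreted as an absolute reporting rate.
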