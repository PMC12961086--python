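# wolfreports

Citizen reports of wolf sightings — phone calls, messages and emails to a
regional wildlife office — carry fine-grained information about where and
when wolf–human interactions happen and how worried people are about them.
`wolfreports` is a Python package for analysing such report archives with
an **observed/availability (use-availability) design**: the locations and
dates of actual reports are contrasted with randomly sampled "available"
locations and dates, so that a binomial model estimates the *relative*
occurrence of reports across season, recolonization history and an
urbanization gradient. A companion penalized-spline model describes the
probability that a report expresses **negative valence** (fear, anger,
concern). Because real report coordinates are privacy-sensitive, the
package ships a first-class synthetic-data generator with stored ground
truth, and every statistical claim the package makes is exercised against
that truth.

## The models

**Occurrence.** Each observed report (case = 1) is matched with `ratio`
random availability points (case = 0; uniform locations inside the region,
uniform dates over the year, same reporter identity). The case indicator
is modelled with a logit link as

```
logit P(case) = β₀ + β_s sin θ + β_c cos θ + Σ_d γ_d C_d(S) + β_H H_z + β_H² H_z²
```

where θ = 2πJ/365 encodes the Julian day as a circular covariate, C_d are
orthonormal polynomial contrasts of the ordinal recolonization step S
(1 = earliest-colonized … 5 = most recent), and H_z is the z-transformed
human-footprint index (raw scale 0–50, 1-km raster). In this design the
slope coefficients estimate the log-linear relative-occurrence function;
the intercept only reflects the availability ratio. Inference is a planned
likelihood-ratio ladder: full vs null (df 8), then seasonality (df 2),
recolonization step (df 4), footprint (df 2) and the footprint quadratic
alone (df 1). Predictive ability is assessed with a fivefold
cross-validation for use-availability data: withheld availability scores
are cut into equal-count bins and the **area-adjusted frequency** of each
bin (withheld observed share ÷ availability share) is rank-correlated with
bin order (Spearman ρ). The availability ratio itself is chosen by a
coefficient-stability sensitivity analysis (default grid includes the
operating point of 11).

**Valence.** Among reports with an assigned valence, the probability of a
negative one is modelled as `logit P(neg) = f(H_z) + Σ_d δ_d C_d(S) [+ s(x,y)]`
with f a penalized cubic B-spline (k = 25, second-order difference
penalty, weight chosen by AIC with effective df = trace of the hat
matrix) and an optional low-rank thin-plate spatial smoother (k = 40).
Accuracy is summarized by the AUC over repeated stratified 70/30
train/test splits.

## Worked example

```python
import numpy as np
import wolfreports as wr

land = wr.generate_landscape(wr.LandscapeConfig(seed=7))
truth = wr.default_truth()
reports = wr.simulate_reports(land, truth, 914, seed=1)
reports = wr.assign_reporters(reports, truth.singleton_frac, seed=2)
design = wr.build_design(reports, land, ratio=11, seed=3)

results = wr.OccurrenceModel(design, wr.ModelSpec()).fit()
print(results.summary())
print(wr.lrt_ladder(design).round(3))
cv = wr.boyce_crossvalidate(design, wr.ModelSpec(), seed=4)
print("fold rho:", np.round(cv.fold_rho, 3))
```

prints

```
Occurrence model (binomial logit, observed/availability design)
  n rows: 10968   fixed params: 9   logLik: -2797.570   converged: True
        term       coef        se        z         p    [0.025    0.975]
   intercept    -2.8141    0.0568   -49.56         0   -2.9254   -2.7028
       sin_t     0.4677    0.0523     8.94  3.84e-19    0.3652    0.5702
       cos_t     0.3609    0.0520     6.94  4.02e-12    0.2589    0.4629
       S_lin     1.5620    0.1346    11.60  4.03e-31    1.2981    1.8259
      S_quad    -0.1965    0.1157    -1.70    0.0894   -0.4233    0.0302
       S_cub     0.2387    0.1094     2.18    0.0292    0.0242    0.4531
     S_quart     0.4104    0.0912     4.50   6.8e-06    0.2316    0.5891
         H_z     0.3819    0.0544     7.02  2.15e-12    0.2753    0.4884
        H_z2    -0.0618    0.0301    -2.05    0.0401   -0.1209   -0.0028
           factor     chi2  df  pvalue  converged
0          season  130.464   2   0.000       True
1  recolonization  249.774   4   0.000       True
2       footprint   63.358   2   0.000       True
3    footprint_sq    4.429   1   0.035       True
fold rho: [0.954 0.988 1.    0.976 0.976]
```

914 synthetic reports at ratio 11 give the expected 10 968 design rows.
The harmonic terms recover the late-winter seasonal peak built into the
generator (β̂_sin = 0.468 vs truth 0.468, β̂_cos = 0.361 vs 0.289), the
positive linear zone contrast reflects more reports in recently
recolonized areas, and the positive-then-negative footprint pair encodes
occurrence rising along the urbanization gradient before flattening.
Every likelihood-ratio row is the fixed df of its factor; fold ρ near 1
means withheld observed reports concentrate in the highest predicted
score bins.

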