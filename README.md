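# geotriad

Three-perspective spatiotemporal evaluation of small-area
healthcare-resource panels: where resources are unequal (spatial Gini
decomposition), where inequality is clustering and how those clusters
evolve (emerging hot/cold spot analysis), and what drives the variation
(a Bayesian spatiotemporally varying coefficient model with variance
partitioning). It is aimed at health-geography and small-area
epidemiology analysts working with balanced area × year panels such as
county-level hospital-bed counts.

## The statistics

**Response.** Either a raw resource count y or the health resource
density index (HRDI), the geometric mean of resources per 1000
population and per km²: `HRDI = sqrt((y / (P/1000)) · (y / A))`.

**Spatial Gini decomposition.** For the n areas of one region in one
year, with binary contiguity weights w_ij,

    G = Σ_ij w_ij |y_i − y_j| / (2 n² ȳ)  +  Σ_ij (1 − w_ij) |y_i − y_j| / (2 n² ȳ)

The two terms (neighbor, non-neighbor) sum exactly to the classical
Gini. A non-trivial neighbor share signals spatial autocorrelation in
the inequality. Each region's yearly Gini series is tested for monotone
trend with Mann-Kendall plus a Theil–Sen slope.

**Emerging hot/cold spots.** Per year, the Getis-Ord Gi* statistic with
a self-inclusive contiguity neighborhood J(i):

    z_i = (Σ_{j∈J} y_j − ȳ|J|) / (s · sqrt[(n|J| − |J|²)/(n−1)])

with ȳ, s the global mean and population SD. Each area's z-series is
then classified by a rule ladder (new, consecutive, intensifying,
persistent, diminishing, sporadic, oscillating, historical — hot and
cold variants) combining per-year significance at α with a
Mann-Kendall trend on the z-series.

**STVC model.** For strictly positive response and covariates x_itk,

    log(y_it) = Σ_k (β_k + μ_ik + γ_tk) x_itk + ε_it

where μ·k is an intrinsic CAR (ICAR) spatial field ("space-
coefficients", SD σ_μk), γ·k a second-order random-walk temporal path
("time-coefficients", SD σ_γk), both sum-to-zero, β_k flat-prior global
levels, and ε iid Gaussian noise. Fitting is by blocked Gibbs sampling
with conjugate inverse-gamma variance updates.

**STVPI.** Each factor's percentage of explainable spatiotemporal
variation, on the SD scale, per posterior draw:

    ρ_k = (σ_μk + σ_γk) / (Σ_k (σ_μk + σ_γk) + σ_ε) × 100%

with per-factor space/time splits, group shares, scale shares and a
model/residual split; shares per draw sum to 100 exactly.

Because real county-level hospital-bed panels of this kind are not
openly deposited, the package ships a seedable generator that draws
panels from exactly the generative structure the model assumes
(contiguity lattice, block provinces, ICAR fields, RW2 paths,
log-Gaussian noise) plus a deterministic block fixture for the hotspot
classifier, so every stage is tested against known ground truth.

## Worked example

```python
import geotriad as gt

cfg = gt.SimulationConfig(grid_rows=15, grid_cols=15, n_years=10,
                          n_covariates=3, region_blocks=3,
                          sd_mu=(0.5, 0.5, 0.5), sd_gamma=(0.3, 0.3, 0.3),
                          beta=(1.0, 0.5, -0.5), sd_eps=0.2, seed=2002)
panel, weights, truth = gt.simulate_panel(cfg)

spec = gt.STVCSpec(chains=4, iterations=5000, burn_in=2000, thin=3, seed=2003)
post = gt.fit_stvc(gt.build_stvc(panel, weights, spec))
res = gt.compute_stvpi(post, panel.covariate_group)
print(res.summary.loc[["scale[space]", "scale[time]", "model"]].round(2))
```

prints

```
               mean  lo2.5  hi97.5
scale[space]  57.19  50.63   62.47
scale[time]   35.41  29.52   42.83
model         92.60  91.82   93.49
```

i.e. the fitted partition attributes 57.2% of the SD-scale variation to
the spatial coefficient fields and 35.4% to the temporal paths, against
generative truth of 57.7% and 34.6% (`(Σσ_μ)/(Σ(σ_μ+σ_γ)+σ_ε)` with the
configured SDs), and the model explains 92.6% of the variation overall.
The same fit recovers the true coefficient surfaces with correlations
≥ 0.97 (space) and ≥ 0.999 (time); see `analysis/05_fit_stvc.py`.

The staged analysis lives in `analysis/01_simulate.py` …
`06_variance_partition.py` (each prints what it found and writes tables
under `results/study/`), or run everything through one config with
`gt.run_pipeline(gt.RunConfig(...))`.

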