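# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limits of what the test suite shows.

## Data model

A balanced panel of N areas ("counties") over T years, each area in one
region ("province"), with a resource count (beds), population, land
area and K covariates per cell. The working response is the health
resource density index, `HRDI = sqrt((beds/(P/1000)) · (beds/A))`,
which removes the bias of normalizing by population or area alone; raw
bed counts can be selected instead (`response_kind="beds"`). Population
is carried in persons and divided by 1000 internally. Missing cells are
rejected, not imputed: every statistic downstream assumes a balanced
panel.

Spatial structure is a symmetric binary contiguity graph (GAL files,
or rook/queen lattices from the generator). Covariates are screened by
iterated variance inflation factors: VIF_k = 1/(1−R²_k) from regressing
column k on the others (with intercept), dropping the worst column
while any VIF exceeds the threshold (default 5) and recomputing.
Ties — including the infinite VIFs of an exactly collinear set — drop
the later-listed column, so earlier-listed covariates are preferred.
Screening runs on raw covariate columns by default with an optional
standardization flag; dedicated variable-importance ranking (e.g.
random-forest node purity) is out of scope and the shortlist can simply
be passed in.

## Spatial Gini

The Gini double sum over ordered pairs is split by the binary weights
into neighbor and non-neighbor terms; the diagonal contributes zero, so
the split is exact (identity enforced to 1e−12 in tests). The
decomposition is computed within each region-year using only
within-region adjacency, because the region is the inequality unit of
interest; cross-region borders are ignored. Singleton regions are
skipped with a warning. Regional trend verdicts use Mann-Kendall at
α = 0.05 with a Theil–Sen slope for the sign — a nonparametric choice
suited to short annual series; the same Mann-Kendall machinery drives
the hotspot classifier, keeping the two stages consistent.

The neighbor share (neighbor/total × 100) is reported descriptively,
without a significance test.

## Getis-Ord Gi* and emerging patterns

Gi* uses the self-inclusive binary star neighborhood and the global
mean/SD of the cross-section; with binary weights Σw = Σw² = |J|, the
familiar denominator reduces to `s·sqrt((n|J|−|J|²)/(n−1))`. A constant
field has s = 0 and is assigned z ≡ 0 with a warning. The default cube
scores each year independently (`temporal_window=0`); `temporal_window=1`
adds the same star set in adjacent years and pools mean/SD over all N·T
bins, mirroring space-time-cube tools.

The Mann-Kendall statistic uses the tie-corrected variance and the
±1 continuity correction.

Classification applies, per area, a first-match rule ladder on the
per-year hot/cold indicators (|z| ≥ 1.96 at the default α = 0.05) and
the Mann-Kendall trend of the z-series: new → consecutive →
intensifying → persistent → diminishing → sporadic → oscillating →
historical, first for hot, then mirrored for cold (trend orientation
flipped), else "no pattern". `persistence_frac = 0.9` encodes
"at least 9 of 10 years" generically via a ceiling with a float-fuzz
guard. The 90/99% bins are reported but do not drive the rules. The
ladder resolves overlaps deterministically — e.g. an area hot in all
years with a significant rising trend is intensifying, not consecutive;
an area hot only in the final year is new even if it was cold earlier
(the oscillating rule catches final-hot areas with both earlier hot and
earlier cold history). No multiplicity correction is applied across
areas by default (a Benjamini–Hochberg flag is deliberately absent
rather than silently on; per-year z thresholds are the classifier's
inputs, not simultaneous tests).

Percentages in summaries are rounded half-up to 2 decimals, and the
denominator convention is explicit: category shares are of patterned
areas, the patterned share is of all areas.

## The synthetic generator

`simulate_panel` draws exactly the structure the inference assumes:

* rook/queen lattice of `rows × cols` counties, partitioned into
  `region_blocks²` contiguous square provinces;
* per covariate, an ICAR field μ·k (precision σ_μ⁻²(D−W), sampled on
  the rank-(N−1) sum-to-zero subspace via the Laplacian eigenbasis — no
  jitter, so the generative law is the exact twin of the prior) and an
  RW2 path γ·k (iid N(0, σ_γ²) second differences, centered; the
  linear component survives centering by design);
* covariates iid normal or neighborhood-smoothed, then standardized to
  mean 0, SD 1 so coefficient scales (and hence STVPI shares) are
  comparable across factors;
* `log y = Σ_k (β_k + μ_ik + γ_tk) x_itk + ε`, ε iid N(0, σ_ε²);
* log-normal population (~60k persons) and land area (~1100 km²), with
  the bed count back-solved so the HRDI of the fabricated fields
  reproduces y bit-for-bit.

Study conditions used by the analysis scripts and the recovery checks:
15×15 lattice (225 counties), T = 10 years, K = 3 covariates,
σ_μ = 0.5, σ_γ = 0.3, β = (1.0, 0.5, −0.5), σ_ε = 0.2 — a decade-long
panel whose spatial heterogeneity dominates its temporal heterogeneity,
with a ~92% explainable share.

What the generator does **not** emulate: irregular county geometries
and degree distributions, covariate collinearity structure of real
socioeconomic series, heavy-tailed or zero-inflated resource counts,
and policy-driven structural breaks. Passing recovery tests therefore
demonstrates correctness of the machinery under the model's own
assumptions, not robustness to their violation.

The hot/cold fixture (`hotspot_preset`) injects four 4×4 blocks into a
low-noise 12×12 background. Because Gi* is scale invariant, a lone
growing plateau saturates its own z-score (it inflates the global SD it
is measured against), so the fixture anchors the cross-sectional SD
with a constant-amplitude block: the ramping block then genuinely
intensifies, the anchor block's relative prominence declines
(diminishing), one block spikes only in the final year (new), and one
drops from year 5 onward — 6 of 10 steps, below the 90% persistence
threshold, hence consecutive cold. Only the 2×2 block interiors, whose
star neighborhoods lie fully inside their block, carry designed labels.

## STVC inference

The model contains no global coefficients as written; with both varying
parts centered, the average effect of each covariate would be forced to
zero, so flat-prior β_k are included by default (the standard
varying-coefficient identification) and recorded in the diagnostics.

Blocked Gibbs updates: each μ·k and γ·k is drawn jointly from its
Gaussian full conditional and restricted to the sum-to-zero subspace by
conditioning-by-kriging (x ← x − Q⁻¹1(1ᵀQ⁻¹1)⁻¹1ᵀx), which is the exact
conditional distribution given the constraint; β from its Gaussian
conditional; variances from conjugate inverse-gamma conditionals
(default hyperprior IG(1, 0.01), with shape/rate overridable for
sensitivity runs). The RW2 path is constrained to sum to zero only —
its slope is left free, as the temporal trends belong in the
time-coefficients, not the global level.

The key numerical device: the full conditional precision of μ·k is
always `(D−W)/σ_μ² + diag(c_k)/σ_ε²` with fixed c_ki = Σ_t x²_itk, a
scalar combination of two fixed matrices. A one-off generalized
eigendecomposition of (D−W, diag(c_k)) per covariate turns every sweep
into O(N²) matrix-vector work (likewise (RW2 penalty, diag(Σ_i x²))
for γ·k), so the full 4-chain × 5000-iteration default on the
225-county study panel runs in well under a minute. This requires
c_k > 0 — a covariate identically zero across all years for some area
is rejected at build time.

Chains start overdispersed (coefficients jittered, variances drawn from
exp(U(−2, 1))). Convergence is summarized by split-R̂ and bulk ESS (via
ArviZ) on β and the SD components; any variance R̂ > 1.1 flags the
posterior non-converged (returned flagged, never discarded). Fixed
seeds make retained draws bit-reproducible.

Validation is dual-route: `validation.exact_posterior_mean` assembles
the dense design on orthonormal sum-to-zero bases and solves the
fixed-variance Gaussian posterior directly; the sampler (run with
`fix_variances`) must agree within Monte-Carlo error. Covariate
standardization (default on) is a reparameterization: tests verify that
rescaling a covariate, with prior SDs rescaled inversely, leaves the
exact posterior fit unchanged to 1e−8. Calibration is checked by 95%
credible-interval coverage of the three variance components over 50
simulated replications (7×7 lattice, T = 10, K = 1, short chains —
sized so the whole suite stays fast; coverage is a property of the
sampler, not of the lattice size).

Degenerate inputs: non-positive responses are rejected with advice to
floor or exclude (no silent jitter); disconnected graphs are rejected
(the ICAR prior is undefined across components).

## STVPI

Shares are computed per retained draw and then summarized (posterior
mean, 2.5/97.5% bounds), so the credible intervals inherit the joint
posterior dependence between variance components — plugging posterior
means into the formula would understate uncertainty. All quantities are
on the SD scale. The identities Σ_k ρ_k + residual = 100 and
space + time + residual = 100 hold per draw to 1e−9 by construction.
β contributes to neither numerator nor denominator — the index
partitions heterogeneity, not mean effects — a known limitation when
comparing factors whose effects are strong but spatiotemporally flat.
`rank_determinants` sorts by posterior-mean ρ_k and returns the
shortest prefix reaching the cumulative threshold (default 84%).

## Problem sizes and tolerances

Exact identities are asserted at 1e−12 (Gini), 1e−10 (Gi* oracle),
1e−9 (share sums), 1e−8 (constraints). Monte-Carlo checks use 3–5
standard-error bands. Recovery checks run at the 225-county study size
with 2×2500 (test suite) or 4×5000 (analysis and acceptance script)
Gibbs iterations — the posterior medians they assert are stable from a
few hundred retained draws, and determinism makes every number
reproducible from the recorded seeds.
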