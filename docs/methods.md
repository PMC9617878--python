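# Methods

`mineforest` re-creates, on synthetic landscapes with known ground truth, a
quasi-experimental workflow for estimating the causal effect of new mining
developments on deforestation: a canopy-weighted forest-loss response,
treated/control study design around lease polygons, statistical matching,
and a Bayesian spatiotemporal zero-inflated count model for the average
treatment effect (ATE). This note records the models, the choices made
where the design was genuinely open, and what the validation studies do and
do not demonstrate.

## 1. Synthetic landscapes

The generator (`mineforest.landscape`) produces everything the real study
had to assemble from national data products, at desk scale:

* **Rasters.** Tree cover (percent, year 0) and first-loss-year integer
  grids on a planar lattice. Default cell size is 25 m with ~1 ha
  aggregation blocks (4 × 4 cells) nesting exactly into 1 km² analysis
  pixels. The 25 m / 4-cell choice keeps every aggregation scale an exact
  integer multiple of the finer one; the algorithms are scale-parametric,
  so the tests pin the algebra rather than any particular satellite
  geometry.
* **Clearing process.** A discrete-time first-clearing hazard per fine cell
  and year: logit h = baseline + Σ β_c z_c + field(s) + θ·treated(s, t),
  with standardised covariate grids z_c, a Matérn(ν = 1) Gaussian field
  (circulant-embedding sampler; long-range fields are drawn on a coarse
  grid and bilinearly interpolated), and the ground-truth treatment offset
  θ applied inside active lease + buffer areas. Defaults (baseline logit
  −5, field variance 0.6 at 5 km range) give ~0.7 %/yr clearing for an
  average forested cell — a heavily deforested woodland setting.
* **Excess zeros.** An independent block-level suppression event (default
  probability 0.25 per 1 km² block-year) forces zero clearing in that
  block-year. Injecting zero inflation at the block scale, not per cell,
  makes the aggregated 1 km² response exhibit the structural zeros the
  outcome model targets.
* **Leases and confounding.** Exploration leases are irregular polygons
  placed without overlap; each mine is carved inside an exploration lease
  chosen with probability increasing in road proximity
  (exp(−strength · d_road / 5 km)), so mine placement is confounded with a
  driver of clearing. Small-scale leases are placed freely. Activation
  years leave at least five post-activation years.
* **Covariates.** Tree cover, elevation (smooth field + gentle west–east
  tilt), slope (gradient magnitude), Euclidean distance to a Poisson-line
  road network, and population density (kernels around road-anchored
  towns) live on the fine grid and enter the table as pixel means; burning
  evidence, agro-ecological zone (three classes from a long-range field),
  protected-area flags (rectangles) and region labels (vertical-strip
  "provinces") are generated directly at the pixel scale.

What the generator does **not** emulate: real administrative geography,
seasonal/cloud artefacts of optical time series, regrowth and degradation,
multi-date imagery. Passing tests therefore validate the statistical
machinery under the assumed data-generating structure, not the fidelity of
any satellite product.

## 2. Canopy-weighted loss metric

For each year, fine-cell cover is zeroed from the cell's loss year onward;
covers and loss indicators are averaged to blocks; blocks below 10 % year-0
cover are masked (the working definition of forest); and the pixel response
is

    canopy_loss(t) = Σ_{unmasked blocks} block_area × loss_prop(t) × cover_frac(t−1)

in m², with the unweighted variant (`forest_loss`) setting the cover weight
to 1 — the "forest area lost" number comparable to Global Forest Watch
style reporting. Two conventions were open and are fixed as follows:

* the canopy weight uses the block's cover in the year *before* the loss
  (a cleared block has zero cover in its loss year, so weighting by
  same-year cover would nullify every loss);
* pixel cover statistics (mean and SD of tree cover) are computed over
  unmasked blocks from year-0 cover; masked blocks contribute to nothing.

When some blocks in a pixel are masked the metric is a sum over the
forested part, which is what the brute-force fine-cell oracle computes; a
"weighted mean × pixel area" reading would double-count masked area.

## 3. Study design

Treatment is binary: a pixel is treated if its square intersects the
buffered lease polygon with positive area (robust to boundary contact).
Control candidates are pixels touching the exploration-lease area minus all
mining leases with their buffers and minus small-scale leases with a 5 km
halo; a pixel touching an exclusion zone is dropped even if it also touches
remaining area, keeping treated and control sets disjoint by construction.
An "anywhere" pool variant drops the exploration-lease restriction. Both
masks are thinned by a systematic subsample anchored at the raster origin —
one corner pixel per 4 × 4 tile by default (≥ 4 km spacing, no direct
neighbours), with a one-per-2×2 (25 % retention) variant. The per-mine
frame keeps forested pixels (mean cover ≥ 10 %) in the region holding the
majority of treated pixels (configurable region merges), attaches a binary
pre-treatment-loss flag (any canopy loss in the two years before
activation) and five outcome years (three for late-activating mines;
fewer than three aborts that mine).

## 4. Matching

The propensity score is a logistic regression of treatment on the
confounders, fitted by IRLS (statsmodels GLM). PSM is greedy 1-1 nearest
neighbour without replacement: treated units in descending score order
(ties by pixel id), a caliper of 0.25 SD of the probability-scale score
(linear-predictor scale available as an option), exact agreement on
protected status and agro-ecological zone, unmatched treated units dropped.
The greedy order and caliper scale are not canonical anywhere; both are
pinned for determinism. Common support trims both arms to the overlapping
score range first. CEM coarsens continuous confounders into five
equal-frequency bins (configurable), keeps strata containing both arms and
weights controls by (m_T/m_C)(M_C/M_T) within stratum. The unmatched
sensitivity scheme draws controls uniformly without replacement. Balance is
summarised by standardised mean differences with pooled-SD denominators,
weighted after matching; coded categoricals are compared as numerics. In
the pipeline, discrete confounders with a level present in only one arm
are excluded from the propensity model (they would separate it) but still
act through the exact-matching constraint.

## 5. Outcome model

For pixel i, post-activation year t (1 = activation year):

    y_it ~ ZINB(μ_it, k, π)
    log μ_it = x_i'β + γ_t + δ_t 1[treated_i] + u_t(s_i) + v_i

with covariates x (tree cover, its SD, slope, plus protection when it
varies), year main effects γ (year 1 reference), one treatment contrast
δ_t per year, exchangeable per-year replicates u_t of a zero-mean
Matérn(ν = 1) field sharing range ρ and marginal SD σ (a pooled
single-field variant is available), and iid pixel effects v_i ~ N(0, τ²).
The response is canopy loss rounded to whole m² (carried internally as a
``count`` column; ``x`` and ``y`` always remain coordinates). Zero
inflation is intercept-only. Priors: N(0, 10²) on the intercept and
N(0, 2²) on the remaining fixed effects (weakly informative on the
standardised-covariate / log-contrast scale); penalised-complexity priors
on the field — P(ρ < 50 km) = 0.05 and P(σ > σ₀) = 0.05 with σ₀
auto-scaled to the positive-response log-SD unless supplied — an
exponential PC prior on τ likewise, a lognormal(0, 1.5²) prior on k
truncated to [0.2, 3], and a uniform prior on π on [0.05, 0.6]. The
truncations bound the well-identified mixture parameters to the range
desk-scale count data can support.

**Field representation.** Each u_t is expanded in the leading
Karhunen–Loève eigenvectors of the Matérn correlation over the frame's
pixel sites (default rank 40, capturing > 99 % of field variance at all
plausible ranges), centred over pixels so the field cannot impersonate the
intercept or year effects; the range is snapped to a 10 % multiplicative
grid so spectral bases can be cached. A knot-based low-rank field was tried
first and abandoned: unrepresented short-range variance leaks into the
treatment contrasts and visibly degrades interval calibration.

**Inference.** Nested Laplace approximation rather than MCMC: for each hyperparameter vector
φ = (log k, logit π, log σ, log τ, log ρ) the latent block (β, w, v) is
maximised by Newton iterations (block elimination of the diagonal pixel
block) and integrated out by a Gaussian approximation; φ itself is
optimised by Nelder–Mead against the Laplace marginal, whose accuracy was
verified against importance sampling. A joint mode over latents *and*
variances is degenerate (the density spikes as a variance → 0), which is
why the nesting is required. Posterior draws come from a mixture over a
small axial grid of hyperparameter integration points (the mode plus two
shells of steps along each eigenvector of the marginal's inverse Hessian),
each contributing Gaussian latent draws weighted by its marginal value —
plugging in the single hyperparameter mode was measurably overconfident at
the 80 % level. The Laplace marginal was verified against importance
sampling, and the latent-block Gaussian against a preconditioned MALA
reference, on down-scaled instances. Convergence reporting: optimiser status, gradient norm at
the mode, and Hessian positive-definiteness (the Laplace analogues of
sampler diagnostics).

**Treatment-effect estimands.** Two are reported. The headline
*arm contrast* (the decision-rule quantity): per posterior draw, expected
loss (1 − π)·exp(x'β̂ + γ + δ) averaged over treated rows minus over
control rows, per year and aggregated (mean of yearly contrasts), with
fixed effects only by default — the latent field and pixel effects are
zero-mean, so their expected contribution cancels in the contrast (a
plug-in-latents switch exists). The *effect on the treated* (ATT): per
draw, predicted loss minus predicted counterfactual loss (treatment
contrast removed) for treated rows with latent draws included; because
every realised level factor appears on both sides, this is the functional
whose coverage can be judged against a simulated ground truth — an arm
contrast in m² scales with the realised common field level, which no
latent-free truth value can reproduce.
Intervals are highest-posterior-density: the shortest contiguous window
containing ⌈level·S⌉ sorted draws, ties resolved to the smallest lower
bound. DIC uses the conditional deviance at fixed + latent parameters with
p_D = mean deviance − deviance at the posterior mean, and a collinearity
filter (|r| ≥ 0.7) precedes candidate-set comparison.

## 6. Diagnostics

Posterior-predictive replicates are simulated per (thinned) posterior draw
with latent effects plugged in; discrepancies (zero proportion, maximum,
total) are reported as tail probabilities. Randomised quantile residuals
use the standard simulated construction and are Uniform(0, 1) under a
correct model. Residual spatial structure is screened by an empirical
semivariogram (same-year pairs pooled across years; 10 equal-width bins
from the 4 km post-subsample spacing to half the frame diameter) against
pointwise envelopes from 199 random relabelings of residuals over
locations. The envelope is 99 % pointwise because the screen is read
across ~10 bins simultaneously; a 95 % band would flag at least one bin in
roughly 40 % of correct-model runs.

## 7. Validation studies and their scope

Validation runs on matched-style frames drawn directly from the outcome
model's generative process (300 pixels ≥ 4 km apart, 5 years, treated
pixels clustered around a notional mine, covariates shared across matched
pairs so the null contrast is exactly zero):

* **Null calibration** follows the simulation-based-calibration principle:
  each replicate draws (k, π, σ, τ, ρ) from the model's own hyperpriors
  (fixed scales σ₀ = τ₀ = 1, ρ₀ = 50 km, and the truncated k and π
  supports), then θ = 0 data. Under exact inference the 80 %/95 % arm-
  contrast intervals would exclude zero at exactly their nominal rates, so
  the measured rates isolate approximation error.
* **Effect recovery** doubles the treated expected loss (θ = log 2) under
  the same prior-drawn hyperparameters and checks the sign of the
  aggregated estimate and the 95 % coverage of the ATT against its
  realised-sample truth (expected loss with treatment minus without, for
  treated rows, conditional on the realised latents — exactly zero under
  the null, so the two studies share one truth convention).
* **Diagnostics calibration** evaluates the residual and variogram
  machinery with replicates drawn at the true parameters (a well-specified
  check of the diagnostics themselves, affordable at scale; it does not
  re-test the sampler).

Problem sizes throughout (300-pixel frames, 70 km landscapes with 6 km
buffers standing in for the national 25 km design, 1000–2000 posterior
draws in scripted studies vs. the 4000 default) are the package's chosen
desk scale; every algorithm is size-parametric.

## 8. Known limitations

* Inference is approximate: Gaussian latent posteriors around conditional
  modes and a discrete hyperparameter mixture. The null-calibration study
  is the quantitative bound on what this costs; heavier-tailed functionals
  than the ATE may be served less well.
* The intercept absorbs the realised year-1 field mean (a consequence of
  centring the field basis); covariate and treatment contrasts are
  unaffected, but the intercept itself should not be read as the
  population baseline when field variance is large.
* CEM weights are used for balance reporting and control selection; the
  outcome model treats selected rows unweighted, as in the matched-cohort
  tradition.
* The propensity model drops one-arm-only categorical levels rather than
  fitting penalised logistic regressions; with very small frames this can
  leave few usable confounders.
* The variogram screen is design-based (residual relabeling), not a formal
  spatial-correlation test.
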