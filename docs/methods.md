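# Methods

`mpbspread` models the eastward range expansion of mountain pine beetle
(MPB, *Dendroctonus ponderosae*) from lodgepole pine (*Pinus contorta*)
forest into jack pine (*P. banksiana*) forest across a west–east hybrid
zone. The package implements the full analysis chain — survey preparation,
dispersal-kernel beetle pressure, two zero-inflated negative binomial
(ZINB) infestation models with Bayesian fitting, and a counterfactual
forward spread simulator — together with a synthetic-data generator that
stands in for the confidential aerial/ground survey and forest-inventory
rasters the real analysis relies on.

## Data model

The analysis grid is a 1 km² raster on a local planar coordinate system
(km). Per-pixel inputs:

* **pine volume** V(x) (m³/km²), a proxy for forest structure;
* **pine ancestry** Q(x) ∈ [0, 1], the admixture fraction of lodgepole
  ancestry (0 = pure jack, 1 = pure lodgepole), classified as jack
  (Q < 0.1), hybrid (0.1 ≤ Q < 0.9), lodgepole (Q ≥ 0.9);
* **winter survival** θ_t(x) ∈ [0, 1], exogenous (we treat it as a
  pre-computed input raster, constant across years by default);
* yearly surveys of **sanitized green-attack trees** m_t(x) (infested trees
  destroyed by ground crews in year t) and **red-top trees** r_{t+1}(x)
  (trees killed in year t, visible from the air the following summer).

Total infestations in year t are I_t(x) = m_t(x) + r_{t+1}(x); only the
unsanitized part I*_t(x) = r_{t+1}(x) can seed the next year. The final
survey year has no forward red-top attribution and is dropped from the
response. For model fitting, pixels with volume < 1 m³/km² are excluded
(habitat mask; beetles arriving there die) and responses are thinned to
every third row and column to blunt residual spatial autocorrelation. The
thinning lattice offset is configurable (default 0); estimates should be —
and in our synthetic checks are — insensitive to it. Thinning applies to
response pixels only; all pixels at full resolution contribute as dispersal
sources.

## Dispersal and beetle pressure

Dispersal follows a radially symmetric 2-D Student's-t kernel

D(r) = (ν−1)/(2πνρ²) · (1 + r²/(νρ²))^(−(ν+1)/2),

with ν = 1.45 and ρ = 0.0118 km fixed from prior mark–recapture work; the
mass within radius R is 1 − (1 + R²/(νρ²))^(−(ν−1)/2). Both forms are
verified against adaptive quadrature in the tests. The kernel is fat-tailed
(≈15% of mass beyond 1 km, ≈1.4% beyond 200 km) yet extremely peaked: ρ is
on the order of 10 m, far below the pixel scale.

The pixel-to-pixel transition function D̄(Δ) integrates D over the
destination pixel and averages over a uniform source position, approximated
by midpoint sums on a sub-grid (default 20 divisions per edge → 50-m
sub-cells). Because a 50-m midpoint cannot resolve a 10-m-wide peak, the
sub-cells near the origin are refined: the local midpoint spacing is shrunk
below the kernel's variation scale max(r, ρ), which brings the total
discretized mass within 0.2% of the analytic value (a plain midpoint rule
is off by tens of percent; it remains available via `refine_center=False`
for grid-convergence studies). The transition array is truncated at a
support radius (default 200 pixels) without renormalization — the missing
tail is genuine long-distance loss, and renormalizing would both inflate
local pressure and break the analytic-mass cross-check.

Beetle pressure is the linear convolution

B_t(y) = Σ_x I*_{t−1}(x) · c(x) · θ_t(x) · D̄(y−x),

computed with FFTs and zero padding (emigrants beyond the domain are lost).
c(x) is the effective brood size: c_L = 1 fixed (B is only proportional to
beetle counts; absolute density is unobservable from tree-kill data) and
c_J for the jack group. Because c is piecewise constant on the two groups,
the convolution is run once per source group and c_J enters as a scalar
multiplier afterwards — fitting never re-runs an FFT. θ is applied at the
source pixel.

## Observation models

Counts are ZINB: P(y=0) = (1−π) + π·NB(0|μ,φ), P(y>0) = π·NB(y|μ,φ), with
NB in mean/dispersion form. The same log-pmf kernel serves the likelihood
and the forward simulator (single source of truth for the law).

**Species-attack model** (`SpeciesAttackZINB`): logit π and log μ are
linear in log B with separate coefficients (γ0, γ1, β0, β1) and dispersion
k per group, plus c_J. The group L contains lodgepole and hybrid pixels by
default; grouping hybrids with jack instead is the model-selection
alternative. 11 free parameters.

**Ancestry-volume model** (`AncestryVolumeZINB`): shared coefficients on
standardized predictors B* = std(log B), Q* = std(Q), V = std(log volume),
plus an interaction term; both brood sizes fixed at 1. The interaction is
the product of the standardized Q* and V by default (a raw-product switch
exists). Standardization constants are estimated from the training rows
once, globally across years, and frozen; counterfactual scenarios reuse
them. 11 free parameters.

Rows with zero beetle pressure (possible only when no source lies within
the truncated kernel support) are dropped from the likelihood rather than
patched with an epsilon, keeping log B well defined; the count of dropped
rows is recorded.

## Bayesian fitting

Sampling uses the affine-invariant ensemble sampler (emcee) with a
differential-evolution move mixture, which mixes far better than the
stretch move on the weakly identified jack-group directions. Positive
parameters (k_L, k_J, c_J, k) are sampled on the log scale with the
Jacobian folded into the prior. Priors are weakly informative on the model
scale: Normal(0, 5) intercepts, Normal(0, 2.5) slopes, Half-Normal(5)
dispersions, LogNormal(0, 1) on c_J. Defaults: 32 walkers, 600 warmup +
700 retained sweeps, initialized in a small ball around a derivative-free
posterior-mode search. Walker sub-chains are treated as chains for split-
R̂ and ESS (arviz); ensemble samplers have no divergence diagnostic, so the
mean acceptance fraction is reported instead. Fits are bit-reproducible
for a fixed seed.

Per-parameter information is summarized by the posterior contraction
1 − Var_post/Var_prior on the natural scale. Model variants fitted on
identical rows (e.g. the two hybrid groupings) are ranked by PSIS-LOO
expected log predictive density computed from thinned pointwise
log-likelihood draws; the comparison table reports the elpd difference
with its paired standard error and flags ties instead of breaking them.

## Forward simulation and spread metric

A simulated year applies, in order: the control survival fraction
s_t = 1 − (proportion controlled) to last year's infestations; dispersal to
beetle pressure; the fitted ZINB draw per habitat pixel; the habitat mask;
and a host-depletion cap — cumulative infestations per pixel may not exceed
a ceiling fixed before simulation as the 99th percentile (rank resolved
upward) of cumulative infestations over lodgepole pixels (Q > 0.9) with at
least one infestation. The control parameter is accepted as either a
survival or a controlled fraction under explicit names, removing the sign
ambiguity of "multiplying by the proportion controlled". Ensembles draw one
joint posterior sample per replicate, so ensemble spread reflects parameter
uncertainty plus process noise.

Counterfactual scenarios transform a parameter draw or the predictor
rasters: equalizing jack attack-rate coefficients with lodgepole, scaling
c_J, setting Q ≡ 1, or assigning the mean lodgepole pine volume (computed
over Q > 0.9 habitat pixels inside the spread polygon) to all pine pixels.

Spread is measured by projecting every infested tree inside a consistently
surveyed polygon onto a directed west→east line and taking the
count-weighted 99th-percentile eastward distance (weighted nearest rank; an
unweighted per-location variant is a flag). Years with nothing inside the
polygon are flagged undefined rather than reported as zero.

## Synthetic data generator

The generator emulates the study system with known truth. Q follows a
logistic west→east ramp (width 20 km by default) from 1 to 0 with truncated
Gaussian pixel noise, giving a lodgepole west, a ≈10-km hybrid band and a
jack east; volumes are lognormal with species-dependent parameters (denser
lodgepole forest, median ≈2000 vs ≈700 m³/km²) plus 5% near-bare pixels;
θ is logit-normal (median 0.5). Survey histories are generated forward from
the model itself: seeded infestations in the west, yearly ZINB draws from
the dispersal-derived pressure, and a binomial control split (default 30%
controlled per year) into sanitized and red-top records placed at pixel
centers — sub-pixel jitter is irrelevant after 1-km rasterization.
Re-running survey preparation on generated tables reproduces the exact
generating I_t/I*_t fields (round-trip identity).

The default generating truth (γ0_L=0.8, γ1_L=1.1, β0_L=1.8, β1_L=0.8 for
lodgepole; γ0_J=−3.0, γ1_J=0.6, β0_J=0.3, β1_J=0.5 for jack; k_L=0.8,
k_J=0.6, c_L=c_J=1) was fixed once from a pilot forward run as the smallest
coefficient set giving a persistent, slowly advancing western outbreak with
strongly suppressed jack attack — the regime the analysis is about. What
the generator does **not** emulate: spatially autocorrelated survey error,
detection failures, anisotropic (wind-driven) dispersal, within-pixel
forest structure, or year-to-year winter-survival dynamics. Passing tests
therefore demonstrate internal consistency and estimator correctness under
the model's own assumptions, not robustness to the real data's violations
of them.

## Validation studies and problem sizes

The reference studies (`mpbspread.studies`, reported by
`scripts/acceptance.py`) run at desk scale, chosen so the full suite
completes on one CPU in minutes:

* kernel accuracy: support 200 px, sub-grid 10 (the 1% tolerance needs no
  finer grid); convolution oracle on 10×10; ZINB law on an 18-point
  parameter grid and 10⁵ sampler draws;
* parameter recovery: 10 replicate datasets, 48×48 landscape, 8 survey
  years (~1700 likelihood rows each), one fit per dataset;
* non-identifiability: one 48×48 history with a well-established western
  outbreak (the phenomenon's premise is infestation-rich lodgepole forest
  beside nearly uninfested jack forest);
* counterfactual direction: 96×80 landscape, outbreak initialized in a
  band straddling the hybrid zone's western edge, 18 simulated years, 10
  paired replicates per scenario (common random numbers). The tall domain
  and long horizon give the front many independent chances to establish
  across the jack boundary, which is the stochastic bottleneck of the
  comparison;
* model selection: 8 replicate datasets with the initial outbreak spread
  across the western half so hybrid pixels carry infestations (otherwise
  the grouping choice is untestable), two fits each.

## Numerical choices and edge cases

* Linear predictors are clipped at ±35 and log-scale parameters at ±20
  inside the sampler only, to keep stray walkers finite; the priors keep
  stationary samples far from the clips.
* Survey points on pixel boundaries belong to the half-open cell
  [x, x+1) × [y, y+1); rasterization is permutation-invariant and mass-
  conserving, and out-of-grid points are rejected with a report.
* Quantiles on integer-count data use nearest-rank conventions (weighted
  for the spread metric, upward-resolved for the depletion cap) so every
  value is enumerable by brute force.
* The depletion cap is computed once from observed (or synthetic-truth)
  cumulative infestations and not updated from simulated kills.
* An empty likelihood table yields log-likelihood 0, so a fit against no
  data returns the prior (verified in the tests).

## Known limitations

Beetle pressure is truncated at the kernel support radius; on domains
wider than the support, remote sources contribute nothing. The ensemble
sampler explores the jack-group directions slowly when the data barely
constrain them (R̂ up to ≈1.1–1.2 at default lengths); conclusions about
those parameters rest on the priors, which is the point of the
non-identifiability analysis. LOO uses importance sampling over thinned
draws; with few retained draws its Pareto-k diagnostics can be optimistic,
so comparisons report the paired SE alongside the ranking. The simulator
treats control as spatially uniform binomial thinning and host depletion
as a hard per-pixel ceiling.
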