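# mpbspread

Spatial modelling of mountain pine beetle (MPB, *Dendroctonus ponderosae*)
range expansion from lodgepole pine into jack pine forest.

MPB has crossed the Rocky Mountains and is spreading eastward through the
lodgepole → hybrid → jack pine transition zone. Whether jack pine slows the
beetle — and through which mechanism — matters for forecasting spread into
the boreal forest. This package implements the full analysis chain for that
question as a tested, reproducible pipeline on synthetic landscapes (the
real aerial-survey and forest-inventory data are confidential):

* **Beetle pressure.** Yearly infestations disperse through a fat-tailed
  2-D Student's-t kernel, D(r) ∝ (1 + r²/(νρ²))^(−(ν+1)/2) with ν = 1.45,
  ρ = 0.0118 km, discretized to a 1-km pixel transition function D̄ and
  convolved by FFT:
  B_t(y) = Σ_x I*_{t−1}(x)·c(x)·θ_t(x)·D̄(y−x),
  where I* are unsanitized infestations, c is the per-species effective
  brood size (c_L ≡ 1, c_J free) and θ is winter survival.
* **Infestation models.** Counts are zero-inflated negative binomial.
  The *species-attack* model gives each pine group its own attack-rate
  coefficients: logit π = γ0_g + γ1_g log B, log μ = β0_g + β1_g log B,
  φ = k_g for g ∈ {L, J}. The *ancestry-volume* model replaces groups with
  standardized predictors: logit π = γ0 + γ_B B* + γ_Q Q* + γ_V V + γ_QV Q*V
  (and likewise log μ), B* = std(log B), Q* = std(ancestry), V = std(log
  pine volume).
* **Bayesian fitting** by ensemble MCMC with weakly informative priors,
  convergence diagnostics, posterior contraction (1 − Var_post/Var_prior)
  and PSIS-LOO model comparison (e.g. hybrid pixels grouped with lodgepole
  vs jack).
* **Forward simulation** with provincial control, host-depletion capping
  and counterfactual scenarios (equalized jack attack rates, scaled brood
  size, lodgepole ancestry or volume everywhere), measuring spread as the
  count-weighted 99th-percentile eastward distance along a west→east
  projection line.
* **Synthetic data** with known generating truth for every stage, so
  parameter recovery, non-identifiability and scenario ordering are all
  checkable.

See `docs/methods.md` for the model details and design choices.

## Worked example

Generate a synthetic survey history, fit the species-attack model, and run
a counterfactual ensemble:

```python
import numpy as np
import mpbspread as mp

land   = mp.generate_landscape(48, 48, seed=5)
kernel = mp.discretize_kernel(subpixel_n=5, support_radius=48)
truth  = mp.default_true_params("species")
survey = mp.generate_survey_history(land, truth, n_years=8, seed=11, kernel=kernel)

rasters, _ = mp.rasterize_surveys(survey.points, land)
grids  = mp.derive_infestation_vars(rasters["sanitized"], rasters["red_top"],
                                    shape=land.shape)
mask   = mp.build_analysis_mask(land)          # >=1 m3/km2, 3-km thinning
data   = mp.assemble_model_data(land, grids, kernel, mask)

model  = mp.SpeciesAttackZINB(data)
res    = model.fit(seed=3)
print(res.summary().round(2)[["mean", "sd", "ci5", "ci95", "contraction"]])
```

```
          mean    sd   ci5  ci95  contraction
param
gamma0_L  0.09  0.56 -0.68  1.15         0.99
gamma1_L  1.16  0.25  0.79  1.63         0.99
gamma0_J -0.33  4.90 -8.14  7.95         0.04
gamma1_J  0.99  2.42 -3.33  4.62         0.06
beta0_L   2.12  0.27  1.68  2.56         1.00
beta1_L   0.73  0.12  0.53  0.94         1.00
beta0_J  -0.54  4.80 -8.38  7.58         0.08
beta1_J   0.92  2.38 -3.49  4.40         0.10
k_L       1.16  0.46  0.52  2.01         0.98
k_J       4.15  3.05  0.40  9.80        -0.03
c_J       1.71  2.10  0.21  5.82         0.05
```

The lodgepole-group attack parameters (generating truth γ0_L = 0.8,
γ1_L = 1.1, β0_L = 1.8, β1_L = 0.8, k_L = 0.8) are recovered inside the 90%
credible intervals with contraction ≈ 1, while the jack-group parameters
and the brood multiplier c_J stay close to their priors (contraction ≈ 0):
the west-seeded outbreak barely touches jack pine, so those parameters are
genuinely uninformed — the same identifiability split the real survey data
produce.

Counterfactual spread (96×80 landscape, 18 years, paired replicates):

```python
from mpbspread.studies import counterfactual_direction_study
print(counterfactual_direction_study(seed=1))
```

```
attack_equal_wins_of_10: 10   mean spread 50.5 km vs baseline 43.8 km
brood_x2_wins_of_10:      2   mean spread 43.8 km (within ensemble noise)
q1_wins_of_10:           10   mean spread 59.2 km (ancestry-volume model)
```

Equalizing the jack attack-rate parameters pushes the front farther east in
every paired replicate, doubling the jack brood size alone does nothing,
and pretending lodgepole ancestry everywhere (Q ≡ 1) spreads farthest —
a low effective attack rate in jack pine, not a small brood, is what slows
the invasion in this model.

## Command-line pipeline

```bash
mpb-spread all --config run.yaml --seed 1 --out my_run
```

runs synth → prep → pressure → fit → compare → simulate → spread with
cached, hash-manifested stage outputs; each stage is also available as its
own subcommand. See `mpbspread.pipeline.RunConfig` for the YAML keys.

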