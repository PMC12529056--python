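"""Reference validation studies on synthetic data with known truth.

Each function runs one self-contained study — kernel accuracy, convolution
and ZINB oracles, parameter recovery, brood-size non-identifiability,
counterfactual spread direction, prep/metric oracles, hybrid-grouping model
selection — and returns a flat dict of scalar results. The studies are the
package's evidence that the full pipeline behaves as designed; the test
suite asserts on their outputs and ``scripts/acceptance.py`` reports them.

Study sizes are chosen to run on a single CPU at desk scale: recovery uses
10 replicate datasets on 48 x 48 landscapes over 8 survey years;
counterfactual ensembles use a 96 x 80 landscape over 18 simulated years;
model selection uses 8 replicate datasets. Seeds derive from one study seed.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats

from .dispersal import KernelParams, compute_beetle_pressure, discretize_kernel, kernel_density, kernel_mass_within
from .inference import model_compare
from .landscape import generate_landscape
from .likelihoods import model1_linear_predictors
from .models import AncestryVolumeZINB, SpeciesAttackZINB, assemble_model_data
from .prep import build_analysis_mask, classify_ancestry, derive_infestation_vars, rasterize_surveys
from .simulate import Scenario, compute_depletion_cap, measure_spread, run_ensemble
from .synthetic import TrueParams, default_true_params, generate_survey_history
from .zinb import zinb_logpmf, zinb_mean, zinb_rvs, zinb_var

ATTACK_PARAMS = ("gamma0_L", "gamma1_L", "gamma0_J", "gamma1_J",
                 "beta0_L", "beta1_L", "beta0_J", "beta1_J")
L_ATTACK_PARAMS = ("gamma0_L", "gamma1_L", "beta0_L", "beta1_L")


def _seed(seed: int, tag: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed) % (2**31), tag])


# ---------------------------------------------------------------- kernel


def kernel_accuracy_study(seed: int = 0) -> dict:
    """Discretized transition mass vs the analytic radial CDF.

    Compares the summed transition probabilities within radii of 10, 50 and
    200 km (circular selection on pixel offsets) against
    1 - (1 + R^2/(nu rho^2))^(-(nu-1)/2), and checks the continuous
    normalization integral by adaptive quadrature.
    """
    params = KernelParams()
    norm, _ = integrate.quad(
        lambda r: 2 * np.pi * r * kernel_density(r, params), 0, np.inf, limit=200
    )
    kernel = discretize_kernel(params, subpixel_n=10, support_radius=200)
    R_grid = np.hypot(*np.meshgrid(np.arange(-200, 201), np.arange(-200, 201)))
    out = {"normalization_integral": float(norm)}
    for R in (10, 50, 200):
        discrete = float(kernel.array[R_grid <= R].sum())
        analytic = float(kernel_mass_within(float(R), params))
        out[f"mass_within_{R}km_discrete"] = discrete
        out[f"mass_within_{R}km_analytic"] = analytic
        out[f"mass_within_{R}km_rel_err_pct"] = 100.0 * abs(discrete - analytic) / analytic
    return out


def convolution_oracle_study(seed: int = 0) -> dict:
    """FFT beetle pressure vs brute-force double summation on a 10x10 field."""
    rng = np.random.default_rng(_seed(seed, 2))
    kernel = discretize_kernel(KernelParams(nu=2.0, rho=0.8), subpixel_n=5,
                               support_radius=12)
    n = 10
    src = rng.poisson(3.0, (n, n)).astype(float)
    brood = rng.uniform(0.5, 2.0, (n, n))
    theta = rng.uniform(0.2, 1.0, (n, n))
    fast = compute_beetle_pressure(src, brood, theta, kernel).B
    S = src * brood * theta
    direct = np.zeros((n, n))
    for yi in range(n):
        for yj in range(n):
            direct[yi, yj] = sum(
                S[xi, xj] * kernel.value(yi - xi, yj - xj)
                for xi in range(n) for xj in range(n)
            )
    return {"convolution_max_abs_diff": float(np.max(np.abs(fast - direct)))}


# ------------------------------------------------------------------ ZINB


def zinb_law_study(seed: int = 0, n_draws: int = 100_000) -> dict:
    """Normalization of the pmf, the Poisson limit, and sampler moments."""
    worst = 0.0
    for pi in (0.2, 0.8):
        for mu in (0.5, 5.0, 50.0):
            for phi in (0.3, 2.0, 20.0):
                y_max = int(stats.nbinom.ppf(1 - 1e-12, phi, phi / (mu + phi))) + 10
                total = np.exp(zinb_logpmf(np.arange(y_max + 1), pi, mu, phi)).sum()
                worst = max(worst, abs(total - 1.0))
    mu = 7.3
    y = np.arange(51)
    from .zinb import nb_logpmf

    poisson_dev = float(np.max(np.abs(
        np.exp(nb_logpmf(y, mu, 1e6)) - stats.poisson.pmf(y, mu)
    )))
    rng = np.random.default_rng(_seed(seed, 3))
    pi, mu, phi = 0.6, 4.0, 0.8
    draws = zinb_rvs(np.full(n_draws, pi), np.full(n_draws, mu),
                     np.full(n_draws, phi), rng)
    mean_err_se = abs(draws.mean() - zinb_mean(pi, mu)) / np.sqrt(
        zinb_var(pi, mu, phi) / n_draws
    )
    return {
        "pmf_normalization_max_abs_err": float(worst),
        "nb_poisson_limit_max_abs_dev": poisson_dev,
        "sampler_mean_abs_z": float(mean_err_se),
        "sampler_mean": float(draws.mean()),
        "sampler_expected_mean": float(zinb_mean(pi, mu)),
    }


# ------------------------------------------------------- fitting studies


def _make_dataset(land_seed, hist_seed, kernel, n=48, n_years=8,
                  true_params=None, grouping="lodgepole", init_spec=None):
    from .synthetic import InitSpec

    tp = true_params or default_true_params("species")
    land = generate_landscape(n, n, seed=land_seed)
    surv = generate_survey_history(land, tp, n_years=n_years, seed=hist_seed,
                                   kernel=kernel,
                                   init_spec=init_spec or InitSpec())
    rasters, _ = rasterize_surveys(surv.points, land)
    grids = derive_infestation_vars(rasters["sanitized"], rasters["red_top"],
                                    shape=land.shape)
    mask = build_analysis_mask(land, hybrid_grouping=grouping)
    data = assemble_model_data(land, grids, kernel, mask)
    return land, grids, data


def parameter_recovery_study(seed: int = 0, n_reps: int = 10) -> dict:
    """Credible-interval coverage of the generating attack-rate parameters.

    ``n_reps`` independent landscape/history replicates are each fitted;
    coverage counts (parameter, replicate) pairs whose 90% CI contains the
    truth, over the 8 attack-rate parameters. Posterior contraction is
    tracked for the well-informed lodgepole-group parameters.
    """
    tp = default_true_params("species")
    true = tp.params
    kernel = discretize_kernel(subpixel_n=5, support_radius=48)
    base = int(_seed(seed, 4).generate_state(1)[0] % 10_000)
    covered = 0
    contr = {n: [] for n in L_ATTACK_PARAMS}
    ranks = []
    for rep in range(n_reps):
        _, _, data = _make_dataset(base + rep, base + 5000 + rep, kernel)
        res = SpeciesAttackZINB(data).fit(seed=base + 7000 + rep)
        c = res.contraction()
        for name in ATTACK_PARAMS:
            lo, hi = res.credible_interval(name, 0.9)
            covered += int(lo <= getattr(true, name) <= hi)
        for name in L_ATTACK_PARAMS:
            contr[name].append(c[name])
        d = res.draws()["gamma1_L"].to_numpy()
        ranks.append(float((d < true.gamma1_L).mean()))
    out = {
        "coverage_pct_90ci_attack_params": 100.0 * covered / (n_reps * len(ATTACK_PARAMS)),
        "n_replicates": n_reps,
        "rank_stat_spread": float(np.ptp(ranks)),
    }
    for name in L_ATTACK_PARAMS:
        out[f"contraction_median_{name}"] = float(np.median(contr[name]))
    return out


def nonidentifiability_study(seed: int = 0) -> dict:
    """Brood-size non-identifiability on a lodgepole-dominated history.

    With the outbreak confined to lodgepole/hybrid forest, the jack brood
    multiplier c_J is barely informed: its posterior sd should stay a large
    fraction of the prior sd while the L-group attack parameters contract
    strongly. The initial condition seeds a well-established western
    outbreak (the phenomenon's premise is an infestation-rich lodgepole
    forest next to a nearly uninfested jack forest).
    """
    from .synthetic import InitSpec

    kernel = discretize_kernel(subpixel_n=5, support_radius=48)
    base = int(_seed(seed, 5).generate_state(1)[0] % 10_000)
    _, _, data = _make_dataset(
        base + 11, base + 12, kernel,
        init_spec=InitSpec(n_pixels=50, count_low=5, count_high=25),
    )
    model = SpeciesAttackZINB(data)
    res = model.fit(seed=base + 13)
    prior_sd = np.sqrt(model.priors["c_J"].natural_var)
    post_sd = res.posterior_sd()["c_J"]
    c = res.contraction()
    return {
        "cJ_posterior_sd": float(post_sd),
        "cJ_prior_sd": float(prior_sd),
        "cJ_sd_ratio": float(post_sd / prior_sd),
        "median_contraction_L_attack": float(np.median([c[n] for n in L_ATTACK_PARAMS])),
        "min_contraction_L_attack": float(min(c[n] for n in L_ATTACK_PARAMS)),
        "n_rows_infested": int((data.df["I"] > 0).sum()),
        "cJ_ci90_low": res.credible_interval("c_J", 0.9)[0],
        "cJ_ci90_high": res.credible_interval("c_J", 0.9)[1],
    }


# ------------------------------------------------- counterfactual spread


def _counterfactual_setup(seed: int, n_rows=96, n_cols=80):
    land = generate_landscape(n_rows, n_cols, seed=int(_seed(seed, 6).generate_state(1)[0] % 10_000))
    kernel = discretize_kernel(subpixel_n=5, support_radius=n_cols)
    rng = np.random.default_rng(_seed(seed, 7))
    habitat = land.volume >= 1.0
    # outbreak initialized in a band straddling the western edge of the
    # hybrid zone, so the front meets jack pine within a few years
    init = np.zeros(land.shape, dtype=np.int64)
    band = np.zeros(land.shape, bool)
    band[:, int(0.375 * n_cols):int(0.525 * n_cols)] = True
    cand = np.argwhere(habitat & band)
    k = min(2 * n_rows, len(cand))
    sel = cand[rng.choice(len(cand), k, replace=False)]
    init[sel[:, 0], sel[:, 1]] = rng.integers(5, 26, k)
    return land, kernel, init


def counterfactual_direction_study(seed: int = 0, n_sims: int = 10,
                                   n_years: int = 18) -> dict:
    """Counterfactual scenario ordering on a jack-blocked landscape.

    Paired ensembles (common random numbers across scenarios) from the
    generating truth: equalizing jack attack-rate parameters with lodgepole
    should push the front farther east than baseline in nearly all
    replicates, doubling the jack brood size alone should not, and under
    the ancestry-volume model pretending lodgepole everywhere (Q == 1)
    should spread farther.
    """
    land, kernel, init = _counterfactual_setup(seed)
    cap = 500.0
    tp1 = default_true_params("species")
    ens_seed = int(_seed(seed, 8).generate_state(1)[0] % 10_000)

    def finals(params, scen):
        series, _ = run_ensemble(init, land, params, scen, n_years=n_years,
                                 n_sims=n_sims, seed=ens_seed, kernel=kernel,
                                 depletion_cap=cap)
        return np.array([s.final_distance() for s in series])

    base = finals(tp1.params, Scenario(name="baseline", survival_series=(0.7,)))
    eq = finals(tp1.params, Scenario(
        name="attack_equal", attack_param_override="jack_equals_lodgepole",
        survival_series=(0.7,)))
    br2 = finals(tp1.params, Scenario(name="brood_x2", brood_scale=2.0,
                                      survival_series=(0.7,)))
    tp2 = default_true_params("covariate")
    base2 = finals(tp2.params, Scenario(name="baseline", survival_series=(0.7,)))
    q1 = finals(tp2.params, Scenario(name="lodgepole_everywhere", q_override=1.0,
                                     survival_series=(0.7,)))
    return {
        "attack_equal_wins_of_10": int((eq > base).sum()),
        "brood_x2_wins_of_10": int((br2 > base).sum()),
        "q1_wins_of_10": int((q1 > base2).sum()),
        "mean_spread_km_baseline": float(np.nanmean(base)),
        "mean_spread_km_attack_equal": float(np.nanmean(eq)),
        "mean_spread_km_brood_x2": float(np.nanmean(br2)),
        "mean_spread_km_baseline_m2": float(np.nanmean(base2)),
        "mean_spread_km_q1": float(np.nanmean(q1)),
        "n_sims": n_sims,
    }


# ------------------------------------------------------- exact oracles


def metric_and_prep_oracles(seed: int = 0) -> dict:
    """Hand-enumerable checks of the spread metric and data preparation."""
    from shapely.geometry import LineString, box

    from .landscape import LandscapeGrid

    n = 25
    land = LandscapeGrid(
        volume=np.full((n, n), 100.0), Q=np.ones((n, n)),
        theta=np.full((n, n), 0.5),
        spread_polygon=box(0, 0, n, n).buffer(-0.01),
        projection_line=LineString([(0.5, n / 2), (n - 0.5, n / 2)]),
    )
    raster = np.zeros((n, n), dtype=int)
    raster[12, 0], raster[12, 10], raster[12, 20] = 1, 1, 98
    spread99 = measure_spread(raster, land, percentile=99.0)

    m = {2006: np.array([[3]])}
    r = {2007: np.array([[5]])}
    grids = derive_infestation_vars(m, r)

    land_small = generate_landscape(9, 9, seed=1)
    mask = build_analysis_mask(land_small, thin_factor=3)
    species, gL, _ = classify_ancestry(np.array([0.05, 0.1, 0.5, 0.9, 0.95]))

    cap = compute_depletion_cap(np.arange(1, 101).reshape(10, 10), np.ones((10, 10)))
    return {
        "spread_p99_weighted_km": float(spread99),  # oracle: 20.0
        "accounting_total_infested": int(grids.I[2006][0, 0]),          # oracle: 8
        "accounting_unsanitized": int(grids.I_star[2006][0, 0]),  # oracle: 5
        "thin_kept_9x9_factor3": int(mask.thin_keep.sum()),  # oracle: 9
        "volume_mask_excludes_below_1": int(
            (~build_analysis_mask(land_small, volume_threshold=1.0).volume_ok
             & (land_small.volume < 1.0)).sum()
            == (land_small.volume < 1.0).sum()
        ),
        "q_classes_jack_hyb_hyb_lodge_lodge": int(
            list(species) == [0, 1, 1, 2, 2] and bool(gL[2]) and not bool(gL[0])
        ),
        "depletion_cap_1_to_100": float(cap),  # oracle: 100
    }


# ----------------------------------------------------- model selection


def model_selection_study(seed: int = 0, n_datasets: int = 8) -> dict:
    """Hybrid-grouping selection: data generated with hybrids behaving as
    lodgepole should favor the hybrid->lodgepole grouping under LOO."""
    kernel = discretize_kernel(subpixel_n=5, support_radius=48)
    base = int(_seed(seed, 9).generate_state(1)[0] % 10_000)
    tp = default_true_params("species")
    from .synthetic import InitSpec

    wins = 0
    diffs = []
    for rep in range(n_datasets):
        land = generate_landscape(48, 48, seed=base + rep)
        # outbreak seeded across the west AND the full hybrid band, so hybrid
        # pixels carry infestations and the grouping choice has signal
        surv = generate_survey_history(
            land, tp, n_years=8, seed=base + 3000 + rep, kernel=kernel,
            init_spec=InitSpec(n_pixels=100, count_low=3, count_high=20,
                               west_fraction=0.7),
        )
        rasters, _ = rasterize_surveys(surv.points, land)
        grids = derive_infestation_vars(rasters["sanitized"], rasters["red_top"],
                                        shape=land.shape)
        results = {}
        for grouping in ("lodgepole", "jack"):
            mask = build_analysis_mask(land, hybrid_grouping=grouping)
            data = assemble_model_data(land, grids, kernel, mask)
            results[grouping] = SpeciesAttackZINB(data).fit(
                seed=base + 6000 + rep, n_warmup=500, n_samples=500)
        table = model_compare(results)
        diff = table.loc["lodgepole", "elpd"] - table.loc["jack", "elpd"]
        wins += int(diff > 0)
        diffs.append(float(diff))
    return {
        "hybrid_to_lodgepole_wins": wins,
        "n_datasets": n_datasets,
        "hybrid_to_lodgepole_win_pct": 100.0 * wins / n_datasets,
        "mean_elpd_advantage": float(np.mean(diffs)),
    }
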