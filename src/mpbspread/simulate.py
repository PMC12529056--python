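"""Forward spread simulation with control, depletion and counterfactuals.

Starting from an initial infestation raster, each simulated year: (1) last
year's infestations are thinned by the control survival fraction
(1 - proportion controlled), (2) surviving brood disperses through the
kernel to give beetle pressure, (3) the fitted ZINB model turns pressure
into stochastic new infestation counts, (4) non-habitat pixels are zeroed,
and (5) cumulative infestations per pixel are capped by a host-depletion
ceiling fixed in advance from observed cumulative infestations (the 99th
percentile over lodgepole pixels, Q > 0.9, with at least one infestation).

Counterfactual :class:`Scenario` transforms probe mechanisms: equalizing
jack attack-rate parameters with lodgepole, scaling the jack brood
multiplier, pretending lodgepole ancestry (Q == 1) everywhere, or assigning
the mean lodgepole pine volume to all pine pixels.

Spread is measured by projecting every infested tree inside the
consistently surveyed polygon onto a directed west-to-east line and taking
the count-weighted 99th-percentile eastward distance (weighted nearest
rank).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dispersal import TransitionKernel, compute_beetle_pressure
from .landscape import LandscapeGrid
from .likelihoods import Model1Params, Model2Params, model1_linear_predictors, model2_linear_predictors
from .prep import VOLUME_THRESHOLD, classify_ancestry
from .zinb import zinb_rvs

__all__ = [
    "Scenario",
    "SimulationState",
    "SpreadSeries",
    "compute_depletion_cap",
    "step_simulation",
    "run_ensemble",
    "measure_spread",
]


@dataclass(frozen=True)
class Scenario:
    """Counterfactual transform of parameters / predictor rasters.

    ``attack_param_override`` currently supports "jack_equals_lodgepole"
    (copy all four L attack-rate coefficients onto the J slots) or a dict
    of explicit parameter replacements. Control is specified as either
    ``survival_series`` (fraction NOT controlled, used directly in the
    pressure sum) or ``controlled_series`` (its complement) — exactly one.
    """

    name: str = "baseline"
    attack_param_override: str | dict | None = None
    brood_scale: float | None = None
    q_override: float | None = None
    volume_override: str | float | None = None
    survival_series: tuple[float, ...] | None = None
    controlled_series: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.brood_scale is not None and self.brood_scale <= 0:
            raise ValueError("brood_scale must be > 0")
        if self.q_override is not None and not 0 <= self.q_override <= 1:
            raise ValueError("q_override must lie in [0, 1]")
        if self.survival_series is not None and self.controlled_series is not None:
            raise ValueError("give survival_series or controlled_series, not both")
        for series in (self.survival_series, self.controlled_series):
            if series is not None and any(not 0 <= s <= 1 for s in series):
                raise ValueError("control fractions must lie in [0, 1]")

    def survival_for(self, year_index: int) -> float:
        if self.survival_series is not None:
            s = self.survival_series
            return s[min(year_index, len(s) - 1)]
        if self.controlled_series is not None:
            s = self.controlled_series
            return 1.0 - s[min(year_index, len(s) - 1)]
        return 1.0

    def transform_params(self, params):
        """Apply attack-rate and brood overrides to a parameter draw."""
        if isinstance(params, Model1Params):
            if self.attack_param_override == "jack_equals_lodgepole":
                params = replace(
                    params,
                    gamma0_J=params.gamma0_L, gamma1_J=params.gamma1_L,
                    beta0_J=params.beta0_L, beta1_J=params.beta1_L,
                    k_J=params.k_L,
                )
            elif isinstance(self.attack_param_override, dict):
                params = replace(params, **self.attack_param_override)
            elif self.attack_param_override is not None:
                raise ValueError(f"unknown attack_param_override {self.attack_param_override!r}")
            if self.brood_scale is not None:
                params = replace(params, c_J=params.c_J * self.brood_scale)
        else:
            if self.attack_param_override is not None or self.brood_scale is not None:
                raise ValueError(
                    "attack/brood overrides apply only to the species-attack model"
                )
        return params

    def effective_rasters(self, landscape: LandscapeGrid,
                          volume_threshold: float = VOLUME_THRESHOLD):
        """(Q, volume) rasters used for predictor construction."""
        Q = landscape.Q
        V = landscape.volume
        if self.q_override is not None:
            Q = np.full_like(Q, float(self.q_override))
        if self.volume_override is not None:
            if self.volume_override == "lodgepole_mean":
                mean_vol = _lodgepole_mean_volume(landscape, volume_threshold)
            else:
                mean_vol = float(self.volume_override)
            V = np.where(landscape.volume >= volume_threshold, mean_vol, landscape.volume)
        return Q, V


def _lodgepole_mean_volume(landscape: LandscapeGrid, volume_threshold: float) -> float:
    """Mean pine volume of lodgepole forest (Q > 0.9, volume above threshold)
    within the spread-measurement polygon."""
    sel = (landscape.Q > 0.9) & (landscape.volume >= volume_threshold)
    if landscape.spread_polygon is not None:
        sel &= _polygon_mask(landscape)
    if not sel.any():
        raise ValueError("no lodgepole pixels to average volume over")
    return float(landscape.volume[sel].mean())


def _polygon_mask(landscape: LandscapeGrid) -> np.ndarray:
    from shapely import contains_xy

    X, Y = landscape.pixel_centers()
    return contains_xy(landscape.spread_polygon, X.ravel(), Y.ravel()).reshape(landscape.shape)


@dataclass
class SimulationState:
    """One replicate's evolving state."""

    year_index: int
    I: np.ndarray
    cumulative: np.ndarray
    depletion_cap: float
    rng: np.random.Generator
    truncated_trees: int = 0


@dataclass
class SpreadSeries:
    """Yearly spread distances (km along the projection line) and counts.

    Years with no infested trees inside the polygon carry NaN distance and
    are flagged in ``defined``.
    """

    years: np.ndarray
    distance_km: np.ndarray
    n_infested: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.distance_km)

    def final_distance(self) -> float:
        ok = self.defined
        return float(self.distance_km[ok][-1]) if ok.any() else float("nan")


def compute_depletion_cap(cumulative_infestations: np.ndarray, Q: np.ndarray,
                          percentile: float = 99.0) -> float:
    """Host-depletion ceiling: nearest-rank percentile of cumulative
    infestations over lodgepole pixels (Q > 0.9) with >= 1 infestation."""
    cum = np.asarray(cumulative_infestations)
    qualifying = cum[(np.asarray(Q) > 0.9) & (cum >= 1)].ravel()
    if len(qualifying) == 0:
        raise ValueError("no lodgepole pixel with at least one infestation")
    # rank resolved upward: smallest observed value with at least the target
    # fraction of qualifying pixels at or below it
    return float(np.percentile(qualifying, percentile, method="higher"))


def _predictors_for(params, B, active, landscape, Q_eff, V_eff):
    if isinstance(params, Model1Params):
        _, group_L, _ = classify_ancestry(landscape.Q)
        return model1_linear_predictors(B[active], group_L[active], params)
    return model2_linear_predictors(B[active], Q_eff[active], V_eff[active], params)


def step_simulation(
    state: SimulationState,
    landscape: LandscapeGrid,
    params,
    scenario: Scenario,
    kernel: TransitionKernel,
    volume_threshold: float = VOLUME_THRESHOLD,
) -> SimulationState:
    """Advance one year: control, dispersal, ZINB draw, mask, depletion cap."""
    habitat = landscape.volume >= volume_threshold
    params = scenario.transform_params(params)
    if isinstance(params, Model1Params):
        _, group_L, _ = classify_ancestry(landscape.Q)
        brood = np.where(group_L, params.c_L, params.c_J)
    else:
        brood = np.ones(landscape.shape)
    survival = scenario.survival_for(state.year_index)
    B = compute_beetle_pressure(
        state.I, brood, landscape.theta, kernel, mask=habitat,
        survival_fraction=survival,
    ).B
    I_next = np.zeros(landscape.shape, dtype=np.int64)
    active = habitat & (B > 0)
    if active.any():
        Q_eff, V_eff = scenario.effective_rasters(landscape, volume_threshold)
        pi, mu, phi = _predictors_for(params, B, active, landscape, Q_eff, V_eff)
        I_next[active] = zinb_rvs(pi, mu, phi, state.rng)
    # host depletion: cumulative infestations cannot exceed the cap
    headroom = np.maximum(np.floor(state.depletion_cap) - state.cumulative, 0)
    capped = np.minimum(I_next, headroom.astype(np.int64))
    truncated = int((I_next - capped).sum())
    cumulative = state.cumulative + capped
    return SimulationState(
        year_index=state.year_index + 1, I=capped, cumulative=cumulative,
        depletion_cap=state.depletion_cap, rng=state.rng,
        truncated_trees=state.truncated_trees + truncated,
    )


def measure_spread(
    infestation_raster: np.ndarray,
    landscape: LandscapeGrid,
    percentile: float = 99.0,
    weighted: bool = True,
    spread_polygon=None,
    projection_line=None,
) -> float:
    """Count-weighted nearest-rank percentile of eastward projected distance.

    Every infested tree inside the polygon contributes its pixel center's
    scalar projection onto the directed line; ``weighted=False`` uses
    infested pixels instead of trees. Returns NaN when nothing lies inside
    the polygon (flagged, not zero).
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    polygon = spread_polygon if spread_polygon is not None else landscape.spread_polygon
    line = projection_line if projection_line is not None else landscape.projection_line
    if polygon is None or line is None:
        raise ValueError("spread polygon and projection line are required")
    raster = np.asarray(infestation_raster)
    rows, cols = np.nonzero(raster > 0)
    if len(rows) == 0:
        return float("nan")
    x0, y0 = landscape.origin
    h = landscape.pixel_size
    xs = x0 + (cols + 0.5) * h
    ys = y0 + (rows + 0.5) * h
    from shapely import contains_xy

    inside = contains_xy(polygon, xs, ys)
    if not inside.any():
        return float("nan")
    (lx0, ly0), (lx1, ly1) = line.coords[0], line.coords[-1]
    ux, uy = lx1 - lx0, ly1 - ly0
    norm = float(np.hypot(ux, uy))
    ux, uy = ux / norm, uy / norm
    dist = (xs[inside] - lx0) * ux + (ys[inside] - ly0) * uy
    weights = raster[rows, cols][inside].astype(float) if weighted else np.ones(inside.sum())
    order = np.argsort(dist)
    dist, weights = dist[order], weights[order]
    cumw = np.cumsum(weights)
    target = np.ceil(percentile / 100.0 * cumw[-1])
    return float(dist[np.searchsorted(cumw, target)])


def run_ensemble(
    initial_I: np.ndarray,
    landscape: LandscapeGrid,
    draws,
    scenario: Scenario,
    n_years: int,
    n_sims: int,
    seed: int,
    kernel: TransitionKernel,
    depletion_cap: float | None = None,
    percentile: float = 99.0,
    volume_threshold: float = VOLUME_THRESHOLD,
    first_year: int = 0,
) -> tuple[list[SpreadSeries], pd.DataFrame]:
    """Run ``n_sims`` replicates, each with one joint posterior draw.

    ``draws`` may be a fitted results object (``sample_params``), a list of
    parameter objects, or a single parameter object (point mass).
    ``depletion_cap`` defaults to the cap computed from the initial raster.
    Returns the per-replicate spread series and a tidy table
    (replicate, year, distance_km, n_infested).
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    initial_I = np.asarray(initial_I, dtype=np.int64)
    if initial_I.shape != landscape.shape:
        raise ValueError("initial raster shape mismatch")
    if depletion_cap is None:
        depletion_cap = compute_depletion_cap(initial_I, landscape.Q)

    child_seeds = np.random.SeedSequence([int(seed), 0x5E5]).spawn(n_sims)
    series_list: list[SpreadSeries] = []
    records = []
    for rep, ss in enumerate(child_seeds):
        rng = np.random.default_rng(ss)
        if hasattr(draws, "sample_params"):
            params = draws.sample_params(rng)
        elif isinstance(draws, (list, tuple)):
            params = draws[rng.integers(len(draws))]
        else:
            params = draws
        state = SimulationState(
            year_index=0, I=initial_I.copy(),
            cumulative=initial_I.astype(float), depletion_cap=depletion_cap,
            rng=rng,
        )
        years, dists, counts = [], [], []
        for _ in range(n_years):
            state = step_simulation(state, landscape, params, scenario, kernel,
                                    volume_threshold)
            years.append(first_year + state.year_index)
            dists.append(measure_spread(state.I, landscape, percentile))
            counts.append(int(state.I.sum()))
        s = SpreadSeries(np.array(years), np.array(dists, dtype=float),
                         np.array(counts))
        series_list.append(s)
        for yr, d, c in zip(years, dists, counts):
            records.append({"replicate": rep, "year": yr, "distance_km": d,
                            "n_infested": c, "scenario": scenario.name})
    return series_list, pd.DataFrame(records)
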