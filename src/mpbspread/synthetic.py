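"""Forward generation of synthetic survey histories with known truth.

The real infestation surveys are confidential, so every downstream stage is
exercised on histories generated from the analysis's own observation model:
yearly beetle pressure from last year's unsanitized infestations (dispersal
convolution), ZINB draws of new infested-tree counts, and a binomial
control split into sanitized green-attack trees m_t and red-top trees
r_{t+1}. Pushing a generated history through survey preparation returns the
exact I_t / I*_t fields used during generation (round-trip identity), and
the generating parameters are retained as ground truth for parameter
recovery and calibration checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dispersal import TransitionKernel, compute_beetle_pressure
from .landscape import LandscapeGrid
from .likelihoods import Model1Params, Model2Params, model1_linear_predictors, model2_linear_predictors
from .prep import VOLUME_THRESHOLD, classify_ancestry
from .zinb import zinb_rvs

__all__ = ["TrueParams", "InitSpec", "SyntheticSurvey", "generate_survey_history",
           "default_true_params", "seed_initial_infestations"]


@dataclass(frozen=True)
class TrueParams:
    """Generating truth: one parameter set plus the yearly control series."""

    params: Model1Params | Model2Params
    control_series: tuple[float, ...] = ()

    def __post_init__(self):
        if any(not 0.0 <= c <= 1.0 for c in self.control_series):
            raise ValueError("control fractions must lie in [0, 1]")

    @property
    def model_kind(self) -> str:
        return "species" if isinstance(self.params, Model1Params) else "covariate"

    def control_for(self, year_index: int) -> float:
        if not self.control_series:
            return 0.0
        return self.control_series[min(year_index, len(self.control_series) - 1)]


@dataclass(frozen=True)
class InitSpec:
    """Initial-condition specification: where and how hard the outbreak starts.

    Seeds ``n_pixels`` habitat pixels chosen uniformly within the western
    ``west_fraction`` of columns, with counts uniform on
    [count_low, count_high].
    """

    n_pixels: int = 25
    count_low: int = 2
    count_high: int = 20
    west_fraction: float = 0.25

    def __post_init__(self):
        if self.n_pixels < 1 or self.count_low < 1 or self.count_high < self.count_low:
            raise ValueError("invalid init_spec")
        if not 0 < self.west_fraction <= 1:
            raise ValueError("west_fraction must lie in (0, 1]")


@dataclass
class SyntheticSurvey:
    """Per-year survey point table plus the generating truth."""

    points: pd.DataFrame  # columns: year, x, y, count, kind
    seed: int
    first_year: int
    n_years: int
    truth: dict = field(default_factory=dict)  # per-year I, m, r, B rasters

    def to_csv(self, path) -> None:
        self.points.to_csv(path, index=False)


def default_true_params(kind: str = "species") -> TrueParams:
    """Reference generating truth used across tests and examples.

    The species-attack set gives a persistent, slowly advancing outbreak on
    the default synthetic landscape: moderate lodgepole attack rates,
    strongly suppressed jack-pine attack rates (the phenomenon under study),
    equal brood sizes, and 30% yearly control.
    """
    if kind == "species":
        params = Model1Params(
            gamma0_L=0.8, gamma1_L=1.1, gamma0_J=-3.0, gamma1_J=0.6,
            beta0_L=1.8, beta1_L=0.8, beta0_J=0.3, beta1_J=0.5,
            k_L=0.8, k_J=0.6, c_J=1.0,
        )
    elif kind == "covariate":
        from .likelihoods import Standardization

        params = Model2Params(
            gamma0=-0.8, gammaB=1.4, gammaQ=1.2, gammaV=0.5, gammaQV=0.2,
            beta0=1.0, betaB=0.9, betaQ=0.6, betaV=0.3, betaQV=0.1,
            k=0.8,
            standardization=Standardization(
                mean_logB=0.0, sd_logB=1.5, mean_Q=0.5, sd_Q=0.4,
                mean_logV=7.0, sd_logV=0.9,
            ),
        )
    else:
        raise ValueError("kind must be 'species' or 'covariate'")
    return TrueParams(params=params, control_series=(0.3,) * 12)


def seed_initial_infestations(
    landscape: LandscapeGrid,
    init_spec: InitSpec,
    rng: np.random.Generator,
    habitat: np.ndarray,
) -> np.ndarray:
    """Draw the initial infestation raster in the western init region."""
    west_cols = max(1, int(np.ceil(landscape.n_cols * init_spec.west_fraction)))
    cand = np.flatnonzero(habitat[:, :west_cols].ravel())
    if len(cand) == 0:
        raise ValueError("no habitat pixels in the init region")
    chosen = rng.choice(cand, size=min(init_spec.n_pixels, len(cand)), replace=False)
    I0 = np.zeros(landscape.shape, dtype=np.int64)
    flat = I0[:, :west_cols].ravel()
    flat[chosen] = rng.integers(init_spec.count_low, init_spec.count_high + 1,
                                size=len(chosen))
    I0[:, :west_cols] = flat.reshape(-1, west_cols)
    return I0


def _pixel_center_table(landscape: LandscapeGrid, raster: np.ndarray, year: int, kind: str):
    rows, cols = np.nonzero(raster)
    if len(rows) == 0:
        return None
    x0, y0 = landscape.origin
    h = landscape.pixel_size
    return pd.DataFrame({
        "year": year,
        "x": x0 + (cols + 0.5) * h,
        "y": y0 + (rows + 0.5) * h,
        "count": raster[rows, cols],
        "kind": kind,
    })


def generate_survey_history(
    landscape: LandscapeGrid,
    true_params: TrueParams,
    n_years: int,
    init_spec: InitSpec = InitSpec(),
    seed: int = 0,
    kernel: TransitionKernel | None = None,
    first_year: int = 2006,
    volume_threshold: float = VOLUME_THRESHOLD,
) -> SyntheticSurvey:
    """Simulate ``n_years`` of infestation surveys from known parameters.

    Year 0 infestations come from ``init_spec``; each later year draws ZINB
    counts from the beetle pressure generated by the previous year's
    *unsanitized* infestations. Every year's counts are split binomially
    with that year's control fraction into sanitized trees (surveyed in
    year t) and red-tops (surveyed in year t+1). Pixels below the volume
    threshold are never infested. Deterministic for a fixed seed.
    """
    if n_years < 2:
        raise ValueError("n_years must be >= 2")
    if kernel is None:
        from .dispersal import discretize_kernel

        kernel = discretize_kernel(support_radius=max(landscape.shape))
    params = true_params.params
    kind = true_params.model_kind
    habitat = landscape.volume >= volume_threshold
    if kind == "species":
        _, group_L, _ = classify_ancestry(landscape.Q)
        brood = np.where(group_L, params.c_L, params.c_J)
    else:
        brood = np.ones(landscape.shape)

    ss = np.random.SeedSequence([int(seed), 0xB33]).spawn(3)
    rng_init, rng_draw, rng_ctrl = (np.random.default_rng(s) for s in ss)

    I0 = seed_initial_infestations(landscape, init_spec, rng_init, habitat)

    truth = {"I": {}, "m": {}, "r": {}, "B": {}}
    I_prev_unsan = None
    tables = []
    for j in range(n_years):
        year = first_year + j
        if j == 0:
            I_t = I0
            truth["B"][year] = np.zeros(landscape.shape)
        else:
            bp = compute_beetle_pressure(
                I_prev_unsan, brood, landscape.theta, kernel, mask=habitat
            )
            B = bp.B
            truth["B"][year] = B
            I_t = np.zeros(landscape.shape, dtype=np.int64)
            active = habitat & (B > 0)
            if active.any():
                Bv = B[active]
                if kind == "species":
                    _, gL, _ = classify_ancestry(landscape.Q)
                    pi, mu, phi = model1_linear_predictors(Bv, gL[active], params)
                else:
                    pi, mu, phi = model2_linear_predictors(
                        Bv, landscape.Q[active], landscape.volume[active], params
                    )
                I_t[active] = zinb_rvs(pi, mu, phi, rng_draw)
        ctrl = true_params.control_for(j)
        m_t = rng_ctrl.binomial(I_t, ctrl)
        r_next = I_t - m_t
        truth["I"][year] = I_t
        truth["m"][year] = m_t
        truth["r"][year + 1] = r_next
        for raster, yr, knd in ((m_t, year, "sanitized"), (r_next, year + 1, "red_top")):
            tab = _pixel_center_table(landscape, raster, yr, knd)
            if tab is not None:
                tables.append(tab)
        I_prev_unsan = r_next  # unsanitized infestations seed next year's pressure

    points = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=["year", "x", "y", "count", "kind"])
    )
    return SyntheticSurvey(
        points=points, seed=int(seed), first_year=first_year, n_years=n_years,
        truth=truth,
    )
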