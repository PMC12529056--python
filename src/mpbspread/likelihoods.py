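"""ZINB observation models linking beetle pressure to infestation counts.

Two regression structures share the zero-inflated negative binomial law:

* **Species-attack model** (Model #1) — separate attack-rate parameters for
  the lodgepole group L and the jack group J:

      logit pi = gamma0_g + gamma1_g * log B,   g in {L, J}
      log  mu  = beta0_g  + beta1_g  * log B
      phi      = k_g

  plus effective brood sizes c_L (fixed at 1) and c_J scaling the J-group
  contribution to beetle pressure B = B_L + c_J * B_J.

* **Ancestry-volume model** (Model #2) — shared coefficients on standardized
  predictors B* = std(log B), Q* = std(Q), V = std(log volume) and the
  interaction Q*V:

      logit pi = gamma0 + gammaB B* + gammaQ Q* + gammaV V + gammaQV Q*V
      log  mu  = beta0  + betaB  B* + betaQ  Q* + betaV  V + betaQV  Q*V

  with both brood sizes fixed at 1. Standardization constants are fitted on
  the training rows and frozen, so counterfactual scenarios (e.g. Q == 1
  everywhere) reuse the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .zinb import zinb_logpmf

__all__ = [
    "Model1Params",
    "Model2Params",
    "Standardization",
    "PredictorSet",
    "ModelData",
    "model1_linear_predictors",
    "model2_linear_predictors",
    "total_loglik",
]


@dataclass(frozen=True)
class Model1Params:
    """Species-specific attack-rate and brood-size parameters."""

    gamma0_L: float
    gamma1_L: float
    gamma0_J: float
    gamma1_J: float
    beta0_L: float
    beta1_L: float
    beta0_J: float
    beta1_J: float
    k_L: float
    k_J: float
    c_J: float = 1.0
    c_L: float = 1.0

    def __post_init__(self):
        if self.k_L <= 0 or self.k_J <= 0:
            raise ValueError("NB dispersions k_L, k_J must be > 0")
        if self.c_J <= 0 or self.c_L <= 0:
            raise ValueError("brood multipliers must be > 0")

    ATTACK_NAMES = ("gamma0_L", "gamma1_L", "gamma0_J", "gamma1_J",
                    "beta0_L", "beta1_L", "beta0_J", "beta1_J")
    FREE_NAMES = ATTACK_NAMES + ("k_L", "k_J", "c_J")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.FREE_NAMES + ("c_L",)}


@dataclass(frozen=True)
class Standardization:
    """Frozen training-set means/sds for log B, Q and log volume."""

    mean_logB: float
    sd_logB: float
    mean_Q: float
    sd_Q: float
    mean_logV: float
    sd_logV: float

    def __post_init__(self):
        for name in ("sd_logB", "sd_Q", "sd_logV"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_training(cls, logB, Q, logV) -> "Standardization":
        return cls(
            float(np.mean(logB)), float(np.std(logB)),
            float(np.mean(Q)), float(np.std(Q)),
            float(np.mean(logV)), float(np.std(logV)),
        )

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("mean_logB", "sd_logB", "mean_Q", "sd_Q", "mean_logV", "sd_logV")}


@dataclass(frozen=True)
class Model2Params:
    """Standardized-predictor coefficients with a single NB dispersion."""

    gamma0: float
    gammaB: float
    gammaQ: float
    gammaV: float
    gammaQV: float
    beta0: float
    betaB: float
    betaQ: float
    betaV: float
    betaQV: float
    k: float
    standardization: Standardization | None = None
    qv_raw_product: bool = False  # interaction on raw Q*V instead of Q*·V*

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("NB dispersion k must be > 0")

    FREE_NAMES = ("gamma0", "gammaB", "gammaQ", "gammaV", "gammaQV",
                  "beta0", "betaB", "betaQ", "betaV", "betaQV", "k")

    def with_standardization(self, std: Standardization) -> "Model2Params":
        return replace(self, standardization=std)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.FREE_NAMES}
        if self.standardization is not None:
            d["standardization"] = self.standardization.to_dict()
        return d


@dataclass
class PredictorSet:
    """Standardized predictors entering the ancestry-volume model."""

    B_star: np.ndarray
    Q_star: np.ndarray
    V: np.ndarray
    QV: np.ndarray

    @classmethod
    def build(cls, B, Q, volume, std: Standardization, qv_raw_product: bool = False):
        B = np.asarray(B, dtype=float)
        volume = np.asarray(volume, dtype=float)
        if np.any(B <= 0):
            raise ValueError("B must be > 0 for log transformation")
        if np.any(volume <= 0):
            raise ValueError("volume must be > 0 in included pixels")
        B_star = (np.log(B) - std.mean_logB) / std.sd_logB
        Q_star = (np.asarray(Q, dtype=float) - std.mean_Q) / std.sd_Q
        V = (np.log(volume) - std.mean_logV) / std.sd_logV
        QV = np.asarray(Q, dtype=float) * volume if qv_raw_product else Q_star * V
        return cls(B_star=B_star, Q_star=Q_star, V=V, QV=QV)


@dataclass
class ModelData:
    """Likelihood rows assembled from prep + dispersal outputs.

    One row per (masked pixel, year) with the response count I and the two
    beetle-pressure components: B_L from lodgepole-group sources and B_J
    from jack-group sources, so B = B_L + c_J * B_J is recomputable for any
    c_J without re-running the convolution.
    """

    df: pd.DataFrame
    dropped_zero_pressure: int = 0
    meta: dict = field(default_factory=dict)

    REQUIRED = ("year", "row", "col", "I", "B_L", "B_J", "is_L", "Q", "volume")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.df.columns)
        if missing:
            raise ValueError(f"ModelData missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.df)

    def pressure(self, c_J: float = 1.0) -> np.ndarray:
        return self.df["B_L"].to_numpy() + c_J * self.df["B_J"].to_numpy()


def model1_linear_predictors(B, group_is_L, params: Model1Params):
    """Per-row (pi, mu, phi) under the species-attack model.

    ``B`` is total beetle pressure (already including the c_J scaling);
    group L rows use the L coefficient set, J rows the J set.
    """
    B = np.asarray(B, dtype=float)
    if np.any(B <= 0):
        raise ValueError("B must be > 0 in likelihood rows (zero-pressure rows are dropped upstream)")
    group_is_L = np.asarray(group_is_L, dtype=bool)
    logB = np.log(B)
    g0 = np.where(group_is_L, params.gamma0_L, params.gamma0_J)
    g1 = np.where(group_is_L, params.gamma1_L, params.gamma1_J)
    b0 = np.where(group_is_L, params.beta0_L, params.beta0_J)
    b1 = np.where(group_is_L, params.beta1_L, params.beta1_J)
    phi = np.where(group_is_L, params.k_L, params.k_J)
    from scipy.special import expit

    pi = expit(g0 + g1 * logB)
    mu = np.exp(b0 + b1 * logB)
    return pi, mu, phi


def model2_linear_predictors(B, Q, volume, params: Model2Params):
    """Per-row (pi, mu, phi) under the ancestry-volume model."""
    if params.standardization is None:
        raise ValueError("Model2Params.standardization must be set (fit on training data)")
    p = PredictorSet.build(B, Q, volume, params.standardization, params.qv_raw_product)
    from scipy.special import expit

    eta_pi = (params.gamma0 + params.gammaB * p.B_star + params.gammaQ * p.Q_star
              + params.gammaV * p.V + params.gammaQV * p.QV)
    eta_mu = (params.beta0 + params.betaB * p.B_star + params.betaQ * p.Q_star
              + params.betaV * p.V + params.betaQV * p.QV)
    pi = expit(eta_pi)
    mu = np.exp(eta_mu)
    phi = np.full_like(mu, params.k)
    return pi, mu, phi


def total_loglik(data: ModelData, params, model_kind: str):
    """Total and pointwise log-likelihood over the assembled rows.

    ``model_kind`` is "species" (Model #1) or "covariate" (Model #2).
    Invariant to row ordering; an empty table gives 0.
    """
    df = data.df
    if len(df) == 0:
        return 0.0, np.zeros(0)
    y = df["I"].to_numpy()
    if model_kind == "species":
        B = data.pressure(params.c_J)
        pi, mu, phi = model1_linear_predictors(B, df["is_L"].to_numpy(), params)
    elif model_kind == "covariate":
        B = data.pressure(1.0)
        pi, mu, phi = model2_linear_predictors(
            B, df["Q"].to_numpy(), df["volume"].to_numpy(), params
        )
    else:
        raise ValueError("model_kind must be 'species' or 'covariate'")
    if np.any(~np.isfinite(B)):
        raise ValueError("non-finite beetle pressure in likelihood rows")
    pointwise = zinb_logpmf(y, pi, mu, phi)
    return float(pointwise.sum()), pointwise
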