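"""Model classes for the ZINB spatial infestation models.

Usage follows the fit-and-results pattern of statistical modelling
packages: build a model from assembled data, call :meth:`fit`, and work
with the returned results object.

    >>> data = assemble_model_data(landscape, grids, kernel, mask)
    >>> model = SpeciesAttackZINB(data)
    >>> res = model.fit(seed=1)
    >>> res.summary()

:class:`SpeciesAttackZINB` is the species-specific attack-rate model
(separate logistic/NB coefficients for the lodgepole group L and the jack
group J, plus the jack brood multiplier c_J); :class:`AncestryVolumeZINB`
is the standardized-predictor model (shared coefficients on B*, Q*, V and
the Q*V interaction, both brood sizes fixed at 1). Fitting uses an
affine-invariant ensemble sampler initialized at a posterior-mode estimate;
the results object carries posterior draws, convergence diagnostics,
posterior contraction and PSIS-LOO support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .dispersal import TransitionKernel, compute_beetle_pressure
from .inference import FitDiagnostics, PriorSpec, default_priors, posterior_contraction
from .landscape import LandscapeGrid
from .likelihoods import (
    Model1Params,
    Model2Params,
    ModelData,
    Standardization,
    total_loglik,
)
from .prep import AnalysisMask, InfestationGrids
from .zinb import zinb_logpmf_core

__all__ = [
    "assemble_model_data",
    "ZINBSpreadModel",
    "SpeciesAttackZINB",
    "AncestryVolumeZINB",
    "ZINBSpreadResults",
]

_ETA_CLIP = 35.0
_LOG_CLIP = 20.0


def assemble_model_data(
    landscape: LandscapeGrid,
    grids: InfestationGrids,
    kernel: TransitionKernel,
    mask: AnalysisMask,
) -> ModelData:
    """Build likelihood rows from prepared grids and the dispersal kernel.

    For each analysis year t (needs I_t and the previous year's I*), beetle
    pressure is convolved once per source group — B_L from lodgepole-group
    sources and B_J from jack-group sources, both at unit brood — so any
    c_J rescaling is a cheap linear combination afterwards. Response rows
    are the habitat pixels on the thinned lattice; rows whose total
    pressure is zero (no sources within kernel support) are dropped and
    counted.
    """
    years = [t for t in grids.years if (t - 1) in grids.I_star]
    if not years:
        raise ValueError("no year has both a response I_t and a previous-year I*")
    keep = mask.response_keep
    rows_idx, cols_idx = np.nonzero(keep)
    frames = []
    brood1 = np.ones(landscape.shape)
    for t in years:
        src = grids.I_star[t - 1]
        B_L = compute_beetle_pressure(
            src, brood1, landscape.theta, kernel, mask=mask.group_L
        ).B
        B_J = compute_beetle_pressure(
            src, brood1, landscape.theta, kernel, mask=mask.group_J
        ).B
        frames.append(pd.DataFrame({
            "year": t,
            "row": rows_idx,
            "col": cols_idx,
            "I": grids.I[t][keep],
            "B_L": B_L[keep],
            "B_J": B_J[keep],
            "is_L": mask.group_L[keep],
            "Q": landscape.Q[keep],
            "volume": landscape.volume[keep],
        }))
    df = pd.concat(frames, ignore_index=True)
    total = df["B_L"] + df["B_J"]
    dropped = int((total <= 0).sum())
    df = df.loc[total > 0].reset_index(drop=True)
    return ModelData(df=df, dropped_zero_pressure=dropped,
                     meta={"years": years})


class ZINBSpreadModel:
    """Shared fitting machinery; use the concrete subclasses."""

    model_kind: str  # "species" | "covariate"

    def __init__(self, data: ModelData, priors: PriorSpec | None = None):
        self.data = data
        self.priors = priors if priors is not None else default_priors(self.model_kind)
        self._y = data.df["I"].to_numpy(dtype=float)
        self._prepare()

    # subclasses implement _prepare() and _loglik_matrix(X) -> (W,) sums
    def _prepare(self):  # pragma: no cover - abstract
        raise NotImplementedError

    def _pointwise_matrix(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _loglik_matrix(self, X: np.ndarray) -> np.ndarray:
        return self._pointwise_matrix(X).sum(axis=1)

    def logpost_matrix(self, X: np.ndarray) -> np.ndarray:
        """Unnormalized log posterior for a (walkers, n_params) matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lp = self.priors.logpdf_x(X)
        ok = np.isfinite(lp) & np.isfinite(X).all(axis=1)
        out = np.full(X.shape[0], -np.inf)
        if ok.any():
            out[ok] = lp[ok] + self._loglik_matrix(X[ok])
        return out

    def params_from_x(self, x: np.ndarray):
        """Natural-scale parameter object from one sampling-space vector."""
        nat = self.priors.to_natural(np.asarray(x, dtype=float))
        return self._params_from_natural(dict(zip(self.priors.names, nat)))

    def loglik(self, params) -> float:
        """Reference (non-vectorized) total log likelihood for one draw."""
        return total_loglik(self.data, params, self.model_kind)[0]

    def _map_start(self) -> np.ndarray:
        x0 = np.zeros(len(self.priors.names))

        def neg(x):
            v = self.logpost_matrix(x[None, :])[0]
            return -v if np.isfinite(v) else 1e12

        res = optimize.minimize(neg, x0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-4, "fatol": 1e-4})
        res2 = optimize.minimize(neg, res.x, method="Powell",
                                 options={"maxiter": 2000})
        return res2.x if res2.fun <= res.fun else res.x

    def fit(
        self,
        seed: int = 0,
        n_walkers: int = 32,
        n_warmup: int = 600,
        n_samples: int = 700,
        progress: bool = False,
        start: np.ndarray | None = None,
    ) -> "ZINBSpreadResults":
        """Sample the posterior; deterministic for a fixed seed.

        Uses a differential-evolution move mixture, which mixes much better
        than the default stretch move on this posterior's weakly identified
        directions (the jack-group parameters).
        """
        import emcee

        ndim = len(self.priors.names)
        if n_walkers < 2 * ndim:
            raise ValueError("n_walkers must be at least 2 x n_params")
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF17]))
        x_map = self._map_start() if start is None else np.asarray(start, dtype=float)
        p0 = x_map[None, :] + 0.05 * rng.standard_normal((n_walkers, ndim))
        lp0 = self.logpost_matrix(p0)
        for i in np.flatnonzero(~np.isfinite(lp0)):
            for _ in range(100):
                cand = x_map + 0.01 * rng.standard_normal(ndim)
                if np.isfinite(self.logpost_matrix(cand[None, :])[0]):
                    p0[i] = cand
                    break

        sampler = emcee.EnsembleSampler(
            n_walkers, ndim, self.logpost_matrix, vectorize=True,
            moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
        )
        state = emcee.State(
            p0, random_state=np.random.RandomState(int(seed) % (2**31)).get_state()
        )
        sampler.run_mcmc(state, n_warmup + n_samples, progress=progress,
                         skip_initial_state_check=True)
        chain_x = sampler.get_chain(discard=n_warmup)  # (draws, walkers, ndim)
        accept = float(np.mean(sampler.acceptance_fraction))
        return ZINBSpreadResults(
            model=self, chain_x=np.swapaxes(chain_x, 0, 1),  # (walkers, draws, ndim)
            acceptance_fraction=accept, seed=int(seed),
            n_warmup=n_warmup, n_samples=n_samples,
        )


class SpeciesAttackZINB(ZINBSpreadModel):
    """Model #1: species-specific attack rates with the jack brood multiplier."""

    model_kind = "species"

    def _prepare(self):
        df = self.data.df
        self._is_L = df["is_L"].to_numpy(dtype=bool)
        self._B_L = df["B_L"].to_numpy(dtype=float)
        self._B_J = df["B_J"].to_numpy(dtype=float)

    def _pointwise_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        is_L = self._is_L[None, :]
        cJ = np.exp(np.clip(X[:, 10], -_LOG_CLIP, _LOG_CLIP))[:, None]
        B = self._B_L[None, :] + cJ * self._B_J[None, :]
        logB = np.log(B)
        g0 = np.where(is_L, X[:, 0, None], X[:, 2, None])
        g1 = np.where(is_L, X[:, 1, None], X[:, 3, None])
        b0 = np.where(is_L, X[:, 4, None], X[:, 6, None])
        b1 = np.where(is_L, X[:, 5, None], X[:, 7, None])
        kL = np.exp(np.clip(X[:, 8], -_LOG_CLIP, _LOG_CLIP))[:, None]
        kJ = np.exp(np.clip(X[:, 9], -_LOG_CLIP, _LOG_CLIP))[:, None]
        pi = expit(np.clip(g0 + g1 * logB, -_ETA_CLIP, _ETA_CLIP))
        mu = np.exp(np.clip(b0 + b1 * logB, -_ETA_CLIP, _ETA_CLIP))
        phi = np.where(is_L, kL, kJ)
        return zinb_logpmf_core(self._y[None, :], pi, mu, phi)

    def _params_from_natural(self, d: dict) -> Model1Params:
        return Model1Params(
            gamma0_L=d["gamma0_L"], gamma1_L=d["gamma1_L"],
            gamma0_J=d["gamma0_J"], gamma1_J=d["gamma1_J"],
            beta0_L=d["beta0_L"], beta1_L=d["beta1_L"],
            beta0_J=d["beta0_J"], beta1_J=d["beta1_J"],
            k_L=d["k_L"], k_J=d["k_J"], c_J=d["c_J"],
        )


class AncestryVolumeZINB(ZINBSpreadModel):
    """Model #2: standardized beetle-pressure / ancestry / volume predictors."""

    model_kind = "covariate"

    def __init__(self, data: ModelData, priors: PriorSpec | None = None,
                 standardization: Standardization | None = None,
                 qv_raw_product: bool = False):
        self._given_std = standardization
        self.qv_raw_product = qv_raw_product
        super().__init__(data, priors)

    def _prepare(self):
        df = self.data.df
        B = df["B_L"].to_numpy() + df["B_J"].to_numpy()
        logB = np.log(B)
        Q = df["Q"].to_numpy(dtype=float)
        logV = np.log(df["volume"].to_numpy(dtype=float))
        std = self._given_std or Standardization.from_training(logB, Q, logV)
        self.standardization = std
        B_star = (logB - std.mean_logB) / std.sd_logB
        Q_star = (Q - std.mean_Q) / std.sd_Q
        V = (logV - std.mean_logV) / std.sd_logV
        QV = Q * df["volume"].to_numpy() if self.qv_raw_product else Q_star * V
        self._design = np.column_stack([np.ones_like(B_star), B_star, Q_star, V, QV])

    def _pointwise_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        eta_pi = np.clip(X[:, :5] @ self._design.T, -_ETA_CLIP, _ETA_CLIP)
        eta_mu = np.clip(X[:, 5:10] @ self._design.T, -_ETA_CLIP, _ETA_CLIP)
        k = np.exp(np.clip(X[:, 10], -_LOG_CLIP, _LOG_CLIP))[:, None]
        pi = expit(eta_pi)
        mu = np.exp(eta_mu)
        phi = np.broadcast_to(k, mu.shape)
        return zinb_logpmf_core(self._y[None, :], pi, mu, phi)

    def _params_from_natural(self, d: dict) -> Model2Params:
        return Model2Params(
            gamma0=d["gamma0"], gammaB=d["gammaB"], gammaQ=d["gammaQ"],
            gammaV=d["gammaV"], gammaQV=d["gammaQV"],
            beta0=d["beta0"], betaB=d["betaB"], betaQ=d["betaQ"],
            betaV=d["betaV"], betaQV=d["betaQV"], k=d["k"],
            standardization=self.standardization,
            qv_raw_product=self.qv_raw_product,
        )


@dataclass
class ZINBSpreadResults:
    """Posterior draws plus diagnostics for one fitted ZINB spread model.

    ``chain_x`` is (walkers, draws, n_params) in sampling space; natural-
    scale draws (k, c_J exponentiated) are exposed through :meth:`draws`.
    """

    model: ZINBSpreadModel
    chain_x: np.ndarray
    acceptance_fraction: float
    seed: int
    n_warmup: int
    n_samples: int
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.model.priors.names

    def draws(self) -> pd.DataFrame:
        """All posterior draws on the natural scale, one row per draw."""
        if "draws" not in self._cache:
            flat = self.chain_x.reshape(-1, self.chain_x.shape[-1])
            nat = self.model.priors.to_natural(flat)
            self._cache["draws"] = pd.DataFrame(nat, columns=self.param_names)
        return self._cache["draws"]

    def posterior_mean(self) -> dict[str, float]:
        return self.draws().mean().to_dict()

    def posterior_sd(self) -> dict[str, float]:
        return self.draws().std(ddof=1).to_dict()

    def credible_interval(self, name: str, prob: float = 0.9) -> tuple[float, float]:
        a = (1.0 - prob) / 2.0
        q = self.draws()[name].quantile([a, 1.0 - a])
        return float(q.iloc[0]), float(q.iloc[1])

    def params_at(self, index: int):
        flat = self.chain_x.reshape(-1, self.chain_x.shape[-1])
        return self.model.params_from_x(flat[index % len(flat)])

    def sample_params(self, rng: np.random.Generator):
        """One joint posterior draw as a natural-scale parameter object."""
        flat = self.chain_x.reshape(-1, self.chain_x.shape[-1])
        return self.model.params_from_x(flat[rng.integers(len(flat))])

    def mean_params(self):
        means = self.posterior_mean()
        return self.model._params_from_natural(means)

    def contraction(self) -> dict[str, float]:
        """Posterior contraction per parameter on the natural scale."""
        out = {}
        sds = self.draws().var(ddof=1)
        for name in self.param_names:
            prior_var = self.model.priors[name].natural_var
            out[name] = float(posterior_contraction(prior_var, sds[name]))
        return out

    def _az_dicts(self, log_likelihood: bool, max_loglik_draws: int = 500):
        posterior = {
            name: self.chain_x[:, :, i] for i, name in enumerate(self.param_names)
        }
        nat = {}
        for i, name in enumerate(self.param_names):
            p = self.model.priors[name]
            arr = self.chain_x[:, :, i]
            nat[name] = np.exp(arr) if p.sampled_on_log_scale else arr
        groups = {"posterior": nat}
        if log_likelihood:
            w, d, nd = self.chain_x.shape
            # thin along draws (same indices per walker) to cap memory/time
            per_walker = max(2, int(np.ceil(max_loglik_draws / w)))
            idx = np.unique(np.linspace(0, d - 1, min(d, per_walker)).astype(int))
            X = self.chain_x[:, idx, :].reshape(-1, nd)
            pw = self.model._pointwise_matrix(X)
            pw = pw.reshape(w, len(idx), -1)
            groups["log_likelihood"] = {"I": pw}
            groups["posterior"] = {k: v[:, idx] for k, v in nat.items()}
        return groups

    def to_inference_data(self, log_likelihood: bool = False):
        import arviz as az

        groups = self._az_dicts(log_likelihood)
        kwargs = {"posterior": groups["posterior"]}
        if log_likelihood:
            kwargs["log_likelihood"] = groups["log_likelihood"]
        with warnings.catch_warnings():
            # walkers-as-chains can outnumber thinned draws; harmless here
            warnings.simplefilter("ignore", UserWarning)
            return az.from_dict(**kwargs)

    def loo(self):
        import arviz as az

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return az.loo(self.to_inference_data(log_likelihood=True), pointwise=True)

    def diagnostics(self) -> FitDiagnostics:
        if "diag" not in self._cache:
            import arviz as az

            idata = self.to_inference_data()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rhat = az.rhat(idata)
                ess = az.ess(idata)
            self._cache["diag"] = FitDiagnostics(
                rhat={n: float(rhat[n].values) for n in self.param_names},
                ess={n: float(ess[n].values) for n in self.param_names},
                acceptance_fraction=self.acceptance_fraction,
                contraction=self.contraction(),
            )
        return self._cache["diag"]

    def summary(self) -> pd.DataFrame:
        """Posterior summary table: moments, 90% CI, diagnostics, contraction."""
        d = self.draws()
        diag = self.diagnostics()
        rows = []
        for name in self.param_names:
            lo, hi = self.credible_interval(name, 0.9)
            rows.append({
                "param": name,
                "mean": d[name].mean(), "sd": d[name].std(ddof=1),
                "median": d[name].median(), "ci5": lo, "ci95": hi,
                "rhat": diag.rhat[name], "ess": diag.ess[name],
                "contraction": diag.contraction[name],
            })
        return pd.DataFrame(rows).set_index("param")

    def save_draws(self, path) -> None:
        df = self.draws().copy()
        df.insert(0, "draw", np.arange(len(df)))
        header = (f"# model_kind={self.model.model_kind} seed={self.seed} "
                  f"walkers={self.chain_x.shape[0]} draws={self.chain_x.shape[1]} "
                  f"warmup={self.n_warmup}\n")
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
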