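"""Zero-inflated negative binomial (ZINB) probability law.

The observation model for yearly per-pixel infestation counts is a mixture of
a structural-zero process and an overdispersed count process:

    P(y = 0) = (1 - pi) + pi * NB(0 | mu, phi)
    P(y > 0) = pi * NB(y | mu, phi)

where ``pi`` is the probability that the pixel is "open" to infestation
(logistic sub-model), and NB is the negative binomial pmf parameterized by
mean ``mu`` and dispersion (size) ``phi``:

    NB(y | mu, phi) = C(y + phi - 1, y) * (mu/(mu+phi))^y * (phi/(mu+phi))^phi.

Under this law E[y] = pi * mu and Var[y] grows with 1/phi; phi -> infinity
recovers a (zero-inflated) Poisson.

The same functions serve both the likelihood during fitting and the sampler
during forward simulation, so the fitted and simulated laws cannot drift
apart.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = ["nb_logpmf", "zinb_logpmf", "zinb_logpmf_core", "zinb_rvs", "zinb_mean", "zinb_var"]


def _validate(pi, mu, phi):
    pi = np.asarray(pi, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("pi must lie in [0, 1]")
    if np.any(mu <= 0):
        raise ValueError("mu must be > 0")
    if np.any(phi <= 0):
        raise ValueError("phi must be > 0")
    return pi, mu, phi


def nb_logpmf(y, mu, phi):
    """Log pmf of the negative binomial in mean/dispersion form.

    The binomial coefficient with non-integer ``phi`` is evaluated through
    log-gamma for numerical stability; stable for counts up to ~1e5.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be a non-negative integer")
    # log C(y+phi-1, y) = lgamma(y+phi) - lgamma(phi) - lgamma(y+1)
    coef = special.gammaln(y + phi) - special.gammaln(phi) - special.gammaln(y + 1.0)
    # use log1p-style stable forms: log(mu/(mu+phi)) and log(phi/(mu+phi))
    log_mu_frac = np.log(mu) - np.log(mu + phi)
    log_phi_frac = np.log(phi) - np.log(mu + phi)
    return coef + y * log_mu_frac + phi * log_phi_frac


def zinb_logpmf_core(y, pi, mu, phi):
    """Unchecked log pmf kernel shared by the likelihood and the simulator.

    Assumes valid, pre-broadcast float arrays; used in the MCMC hot path.
    """
    coef = special.gammaln(y + phi) - special.gammaln(phi) - special.gammaln(y + 1.0)
    log_mu_frac = np.log(mu) - np.log(mu + phi)
    log_phi_frac = np.log(phi) - np.log(mu + phi)
    nb = coef + y * log_mu_frac + phi * log_phi_frac
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log_1mpi = np.log1p(-pi)
    # y == 0: logaddexp(log(1-pi), log(pi) + NB(0)); y > 0: log(pi) + NB(y)
    zero_branch = np.logaddexp(log_1mpi, log_pi + nb)
    pos_branch = log_pi + nb
    return np.where(y == 0, zero_branch, pos_branch)


def zinb_logpmf(y, pi, mu, phi):
    """Log probability of counts under the zero-inflated NB mixture.

    Parameters broadcast elementwise. Returns -inf where a zero-probability
    outcome is requested (e.g. y > 0 with pi = 0).
    """
    pi, mu, phi = _validate(pi, mu, phi)
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be a non-negative integer")
    return zinb_logpmf_core(y, pi, mu, phi)


def zinb_mean(pi, mu, phi=None):
    """E[y] = pi * mu (phi accepted for signature symmetry)."""
    return np.asarray(pi, dtype=float) * np.asarray(mu, dtype=float)


def zinb_var(pi, mu, phi):
    """Var[y] = pi*mu*(1 + mu/phi) + pi*(1-pi)*mu^2."""
    pi, mu, phi = _validate(pi, mu, phi)
    return pi * mu * (1.0 + mu / phi) + pi * (1.0 - pi) * mu**2


def zinb_rvs(pi, mu, phi, rng: np.random.Generator, size=None):
    """Draw ZINB counts: a Bernoulli(pi) gate times an NB(mu, phi) count.

    NB draws use the gamma-Poisson mixture, matching the pmf above exactly.
    """
    pi, mu, phi = _validate(pi, mu, phi)
    shape = np.broadcast_shapes(pi.shape, mu.shape, phi.shape) if size is None else size
    pi, mu, phi = (np.broadcast_to(a, shape) for a in (pi, mu, phi))
    gate = rng.random(shape) < pi
    lam = rng.gamma(shape=phi, scale=mu / phi)
    counts = rng.poisson(lam)
    return np.where(gate, counts, 0)
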