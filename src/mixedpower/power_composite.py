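"""Composite responder endpoint: response probabilities, delta-method
variance, power and sample size.

A composite responder endpoint reduces the K mixed outcomes to one binary
indicator per patient: a responder satisfies ``Y_k <= eta_k`` on every
component (continuous components on the observed scale, discrete components
on the latent scale).  Under the latent multivariate-normal model the
per-arm response probability is a K-dimensional normal rectangle
probability, the treatment effect is the risk difference

    delta* = Phi_K(eta; mu_T*, Sigma) - Phi_K(eta; mu_C*, Sigma),

and its sampling variance follows from a first-order Taylor (delta-method)
expansion around the fitted model parameters.  Power and sample size then
use the standard one-sided two-proportion normal approximation with
``sigma_delta^2 = 2 sigma^2 / n``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._mvn import DEFAULT_ABSEPS, mvn_cdf
from .power_coprimary import InfeasibleDesignError

__all__ = [
    "CompositeEffect",
    "response_prob",
    "composite_effect",
    "delta_method_var",
    "power_composite",
    "samplesize_composite",
    "binary_method_n",
]

FD_REL_STEP = 1e-5  # central finite-difference step (relative)
PSD_TOL = 1e-10  # eigenvalue floor when projecting Cov(theta) to PSD


@dataclass(frozen=True)
class CompositeEffect:
    """Risk difference on the composite responder scale.

    ``var_delta`` is the pilot-scale sampling variance of the estimated risk
    difference (delta method); ``sigma2`` is the per-observation variance
    scale defined through ``sigma_delta^2 = 2 sigma^2 / n`` when the pilot's
    per-group n is known.
    """

    p_T: float
    p_C: float
    delta_star: float
    var_delta: float | None = None
    sigma2: float | None = None


def response_prob(
    mu_star,
    corr,
    eta,
    sd=None,
    m_of_k: int | None = None,
    abseps: float = DEFAULT_ABSEPS,
) -> float:
    """P(Y_1 <= eta_1, ..., Y_K <= eta_K) under one arm's latent normal law.

    ``sd`` carries per-component SDs (continuous components may have
    sigma_k != 1; discrete components are 1).  With ``m_of_k`` set, response
    requires only m of the K components to meet their cuts; the probability
    is assembled by inclusion-exclusion over the count of components above
    their cuts.
    """
    mu = np.atleast_1d(np.asarray(mu_star, dtype=float))
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    corr = np.atleast_2d(np.asarray(corr, dtype=float))
    K = mu.size
    if eta.size != K or corr.shape != (K, K):
        raise ValueError(
            f"dimension mismatch: mu {mu.size}, eta {eta.size}, "
            f"corr {corr.shape}"
        )
    s = np.ones(K) if sd is None else np.atleast_1d(np.asarray(sd, float))
    upper = (eta - mu) / s
    if m_of_k is None or m_of_k >= K:
        val, _ = mvn_cdf(upper, corr, abseps=abseps)
        return val
    if m_of_k < 1:
        raise ValueError("m_of_k must be at least 1")
    # P(at least m of K below cut) via inclusion-exclusion on subsets:
    # sum_{j=m}^{K} (-1)^{j-m} C(j-1, m-1) sum_{|I|=j} P(all of I below)
    from itertools import combinations
    from math import comb

    total = 0.0
    for j in range(m_of_k, K + 1):
        coef = (-1) ** (j - m_of_k) * comb(j - 1, m_of_k - 1)
        for idx in combinations(range(K), j):
            sub = np.asarray(idx)
            v, _ = mvn_cdf(upper[sub], corr[np.ix_(sub, sub)], abseps=abseps)
            total += coef * v
    return float(np.clip(total, 0.0, 1.0))


def composite_effect(
    fit,
    eta,
    m_of_k: int | None = None,
    n_pilot: int | None = None,
    abseps: float = DEFAULT_ABSEPS,
) -> CompositeEffect:
    """Risk difference delta* = p_T - p_C from a fitted latent model.

    ``fit`` is a :class:`mixedpower.estimation.LatentModelFit` (or any object
    exposing ``mu_star(arm)``, ``sds()``, ``corr_matrix()`` and
    ``cov_theta``).  Positive delta* favours treatment (response = all
    components at or below their cuts).  When ``fit.cov_theta`` is available
    the delta-method variance is attached; with ``n_pilot`` (per-group pilot
    size) the per-observation scale sigma^2 = n_pilot * var_delta / 2 is
    derived for use in :func:`samplesize_composite`.
    """
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    corr = fit.corr_matrix()
    sd = fit.sds()
    p_T = response_prob(fit.mu_star("T"), corr, eta, sd, m_of_k, abseps)
    p_C = response_prob(fit.mu_star("C"), corr, eta, sd, m_of_k, abseps)
    var_d = None
    sigma2 = None
    if getattr(fit, "cov_theta", None) is not None:
        var_d = delta_method_var(fit, eta, m_of_k=m_of_k, abseps=abseps)
        if n_pilot is not None:
            sigma2 = n_pilot * var_d / 2.0
    return CompositeEffect(
        p_T=p_T,
        p_C=p_C,
        delta_star=p_T - p_C,
        var_delta=var_d,
        sigma2=sigma2,
    )


def _nearest_psd(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() >= -PSD_TOL:
        return cov
    warnings.warn(
        f"Cov(theta) has negative eigenvalue {vals.min():.3e}; projecting "
        "to the nearest positive-semidefinite matrix",
        stacklevel=3,
    )
    vals = np.clip(vals, 0.0, None)
    return (vecs * vals) @ vecs.T


def delta_method_var(
    fit,
    eta,
    m_of_k: int | None = None,
    abseps: float = DEFAULT_ABSEPS,
) -> float:
    """First-order Taylor variance of the estimated risk difference.

    The gradient of delta*(theta) is computed by central finite differences
    (relative step 1e-5) over the fitted parameter vector, then combined with
    Cov(theta-hat) as ``g' Cov g``.  A non-PSD covariance is projected to the
    nearest PSD matrix with a warning.
    """
    if getattr(fit, "cov_theta", None) is None:
        raise ValueError("fit carries no Cov(theta); delta method unavailable")
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    theta0 = fit.theta_values()

    def delta_of(theta_vec: np.ndarray) -> float:
        f = fit.with_theta(theta_vec)
        p_t = response_prob(
            f.mu_star("T"), f.corr_matrix(), eta, f.sds(), m_of_k, abseps
        )
        p_c = response_prob(
            f.mu_star("C"), f.corr_matrix(), eta, f.sds(), m_of_k, abseps
        )
        return p_t - p_c

    grad = np.zeros_like(theta0)
    for i in range(theta0.size):
        h = FD_REL_STEP * max(abs(theta0[i]), 1.0)
        up = theta0.copy()
        dn = theta0.copy()
        up[i] += h
        dn[i] -= h
        grad[i] = (delta_of(up) - delta_of(dn)) / (2.0 * h)
    cov = _nearest_psd(np.asarray(fit.cov_theta_values(), dtype=float))
    var = float(grad @ cov @ grad)
    return max(var, 0.0)


def power_composite(
    delta_star: float, sigma2: float, n: int, alpha: float = 0.025
) -> float:
    """One-sided power Phi(delta* / sqrt(2 sigma^2 / n) - z_alpha)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if n < 2:
        raise ValueError("n must be at least 2")
    z_a = stats.norm.ppf(1.0 - alpha)
    return float(stats.norm.cdf(delta_star / np.sqrt(2.0 * sigma2 / n) - z_a))


def samplesize_composite(
    delta_star: float,
    sigma2: float,
    alpha: float = 0.025,
    target_power: float = 0.80,
) -> int:
    """Per-group n = ceil(2 sigma^2 (z_{1-beta} + z_alpha)^2 / delta*^2)."""
    if delta_star <= 0:
        raise InfeasibleDesignError(
            f"composite risk difference {delta_star} is not positive"
        )
    z_a = stats.norm.ppf(1.0 - alpha)
    z_b = stats.norm.ppf(target_power)
    return int(np.ceil(2.0 * sigma2 * (z_b + z_a) ** 2 / delta_star**2))


def binary_method_n(
    p_T: float,
    p_C: float,
    alpha: float = 0.025,
    target_power: float = 0.80,
) -> int:
    """Classical two-proportion per-group n (pooled null variance).

    ``ceil((z_a sqrt(2 pbar qbar) + z_{1-beta} sqrt(p_T q_T + p_C q_C))^2
    / (p_T - p_C)^2)`` with ``pbar`` the pooled rate -- the comparator a
    trialist would use when collapsing the composite to an observed binary
    endpoint.
    """
    if p_T == p_C:
        raise InfeasibleDesignError("p_T and p_C must differ")
    z_a = stats.norm.ppf(1.0 - alpha)
    z_b = stats.norm.ppf(target_power)
    pbar = 0.5 * (p_T + p_C)
    num = (
        z_a * np.sqrt(2.0 * pbar * (1.0 - pbar))
        + z_b * np.sqrt(p_T * (1 - p_T) + p_C * (1 - p_C))
    ) ** 2
    return int(np.ceil(num / (p_T - p_C) ** 2))
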