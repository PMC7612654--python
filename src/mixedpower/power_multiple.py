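"""Multiple primary (union-test) power, sample size and FWER.

A multiple-primary endpoint declares success if at least one of the K
one-sided component tests rejects, each performed at a multiplicity-adjusted
level (Bonferroni alpha/K by default).  The overall power is

    P(union_k {Z_k > z_k}) = sum over non-empty subsets I of {1..K} of
                             (-1)^{|I|+1} P(intersection_{k in I} Z_k > z_k),

computed by inclusion-exclusion over multivariate-normal upper-orthant
probabilities, and cross-checked against the complement identity
``1 - Phi_K(z_1, ..., z_K; Gamma)``.

The family-wise error rate under the global null (all effects zero) is
``1 - Phi_K(z_a', ..., z_a'; Gamma)`` with per-test level alpha' (alpha, or
alpha/K under Bonferroni).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from ._mvn import DEFAULT_ABSEPS, mvn_cdf
from .endpoint_model import DesignParams, EndpointSpec, standardized_effects
from .power_coprimary import (
    InfeasibleDesignError,
    PowerResult,
    SampleSizeResult,
    closed_form_n_single,
    search_sample_size,
    shifted_criticals,
)

__all__ = [
    "FwerReport",
    "power_union",
    "samplesize_multiple",
    "fwer_analytic",
    "adjusted_alpha",
]

MAX_K_ENUMERATION = 12
# disagreement between inclusion-exclusion and the complement identity above
# this bound indicates a quadrature failure
CROSSCHECK_TOL = 1e-6


@dataclass(frozen=True)
class FwerReport:
    """Analytic family-wise error rate under the global null."""

    K: int
    corr: np.ndarray
    alpha: float
    adjustment: str
    fwer: float


def adjusted_alpha(alpha: float, K: int, adjustment: str) -> float:
    """Per-test level implied by the multiplicity adjustment."""
    if adjustment == "none":
        return alpha
    if adjustment == "bonferroni":
        return alpha / K
    raise ValueError(
        f"adjustment {adjustment!r} has no fixed per-test level; Holm is "
        "stepwise -- use the simulation module (empirical_power/empirical_fwer)"
    )


def _orthant_upper(z: np.ndarray, corr: np.ndarray, abseps: float) -> float:
    """P(X_k > z_k for all k), X ~ N(0, corr): reflect to a CDF."""
    val, _ = mvn_cdf(-z, corr, abseps=abseps)
    return val


def power_union(
    spec: EndpointSpec,
    n_T: int,
    params: DesignParams,
    abseps: float = DEFAULT_ABSEPS,
) -> PowerResult:
    """Union power by inclusion-exclusion at the adjusted per-test level.

    Raises if K > 12 (2^K subset blow-up); the complement identity
    ``1 - Phi_K(z; Gamma)`` is evaluated as an internal cross-check and a
    numerical error is raised if the two paths disagree beyond tolerance.
    """
    K = spec.K
    if K > MAX_K_ENUMERATION:
        raise ValueError(
            f"K={K} exceeds the inclusion-exclusion cap of "
            f"{MAX_K_ENUMERATION}; use the complement form 1 - Phi_K(z; Gamma)"
        )
    a_each = adjusted_alpha(params.alpha, K, params.adjustment)
    z = shifted_criticals(spec, n_T, params, alpha_each=a_each)
    corr = spec.corr
    total = 0.0
    for size in range(1, K + 1):
        sign = 1.0 if size % 2 == 1 else -1.0
        for idx in combinations(range(K), size):
            sub = np.asarray(idx)
            total += sign * _orthant_upper(
                z[sub], corr[np.ix_(sub, sub)], abseps
            )
    complement, err = mvn_cdf(z, corr, abseps=abseps)
    check = 1.0 - complement
    if abs(total - check) > max(CROSSCHECK_TOL, 10 * abseps):
        raise ArithmeticError(
            "inclusion-exclusion union power disagrees with the complement "
            f"identity: {total:.8f} vs {check:.8f} (K={K}, n_T={n_T})"
        )
    return PowerResult(
        power=float(np.clip(total, 0.0, 1.0)),
        n_per_group=int(n_T),
        shifted_criticals=tuple(float(v) for v in z),
        quadrature_error=max(err, abs(total - check)),
    )


def samplesize_multiple(
    spec: EndpointSpec,
    params: DesignParams,
    abseps: float = DEFAULT_ABSEPS,
) -> SampleSizeResult:
    """Smallest per-group n with union power >= target_power."""
    d = standardized_effects(spec).as_array()
    if np.all(d <= 0):
        raise InfeasibleDesignError(
            "no outcome has a positive standardized effect; union power "
            "cannot reach the target"
        )
    a_each = adjusted_alpha(params.alpha, spec.K, params.adjustment)
    kappa = spec.alloc_ratio
    # union power >= max marginal power, so the single-outcome n for the
    # strongest effect at the adjusted level is an upper bound; start there
    # and let the search bracket downward.
    n_start = closed_form_n_single(
        float(d.max()), a_each, params.target_power, kappa
    )

    def pw(n: int) -> float:
        return power_union(spec, n, params, abseps=abseps).power

    n, p_n, p_prev, curve = search_sample_size(
        pw, n_start, params.target_power
    )
    return SampleSizeResult(
        n_per_group=n,
        achieved_power=p_n,
        power_at_n_minus_1=p_prev,
        n_control=int(np.ceil(kappa * n)),
        curve=curve,
    )


def fwer_analytic(
    K: int,
    corr,
    alpha: float,
    adjustment: str = "none",
    abseps: float = DEFAULT_ABSEPS,
) -> FwerReport:
    """FWER of K one-sided tests under the global null.

    ``corr`` may be a full K x K matrix or a scalar equicorrelation value.
    ``adjustment`` is ``"none"`` or ``"bonferroni"``; Holm has no closed form
    and is directed to the simulation module.
    """
    if np.isscalar(corr):
        rho = float(corr)
        corr_m = np.full((K, K), rho)
        np.fill_diagonal(corr_m, 1.0)
    else:
        corr_m = np.atleast_2d(np.asarray(corr, dtype=float))
        if corr_m.shape != (K, K):
            raise ValueError(
                f"corr shape {corr_m.shape} does not match K={K}"
            )
    a_each = adjusted_alpha(alpha, K, adjustment)
    z = np.full(K, stats.norm.ppf(1.0 - a_each))
    accept_all, _ = mvn_cdf(z, corr_m, abseps=abseps)
    return FwerReport(
        K=K,
        corr=corr_m,
        alpha=alpha,
        adjustment=adjustment,
        fwer=float(np.clip(1.0 - accept_all, 0.0, 1.0)),
    )
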