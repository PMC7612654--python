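"""Co-primary (intersection-test) power and sample size.

A co-primary endpoint declares success only if every one of the K one-sided
component tests rejects.  With standardized effects d_k and per-group sizes
n_T, n_C = kappa * n_T, the vector of shifted test statistics is
asymptotically N_K(0, Gamma), and

    power(n) = Phi_K(-z_1(n), ..., -z_K(n); Gamma),
    z_k(n)   = z_alpha - d_k * sqrt(kappa * n_T / (1 + kappa)),

evaluated by deterministic multivariate-normal quadrature.  The sample-size
search exploits the strict monotonicity of power in n: it starts from the
closed-form single-outcome size for the weakest effect (a valid lower bound,
since intersection power can never exceed any marginal power), brackets
upward exponentially, then bisects on the integer lattice, so the returned n
carries a minimality certificate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._mvn import DEFAULT_ABSEPS, mvn_cdf
from .endpoint_model import DesignParams, EndpointSpec, standardized_effects

__all__ = [
    "PowerResult",
    "SampleSizeResult",
    "InfeasibleDesignError",
    "shifted_criticals",
    "power_coprimary",
    "samplesize_coprimary",
    "closed_form_n_single",
    "search_sample_size",
]

MAX_N = 2**24  # search guard


class InfeasibleDesignError(ValueError):
    """Target power cannot be reached for any sample size."""


@dataclass(frozen=True)
class PowerResult:
    """Power at a given per-group size, with audit fields."""

    power: float
    n_per_group: int
    shifted_criticals: tuple[float, ...]
    quadrature_error: float


@dataclass(frozen=True)
class SampleSizeResult:
    """Smallest adequate per-group n with its minimality certificate."""

    n_per_group: int
    achieved_power: float
    power_at_n_minus_1: float
    n_control: int
    curve: tuple[tuple[int, float], ...] = field(default=())


def shifted_criticals(
    spec: EndpointSpec,
    n_T: int,
    params: DesignParams,
    alpha_each: float | None = None,
) -> np.ndarray:
    """Per-outcome shifted critical values z_k = z_a - d_k sqrt(kappa n_T/(1+kappa))."""
    if n_T < 2:
        raise ValueError("n_T must be at least 2")
    alpha = params.alpha if alpha_each is None else alpha_each
    z_a = stats.norm.ppf(1.0 - alpha)
    d = standardized_effects(spec).as_array()
    kappa = spec.alloc_ratio
    return z_a - d * np.sqrt(kappa * n_T / (1.0 + kappa))


def power_coprimary(
    spec: EndpointSpec,
    n_T: int,
    params: DesignParams,
    abseps: float = DEFAULT_ABSEPS,
) -> PowerResult:
    """Intersection power Phi_K(-z_1, ..., -z_K; Gamma) at per-group size n_T."""
    z = shifted_criticals(spec, n_T, params)
    val, err = mvn_cdf(-z, spec.corr, abseps=abseps)
    return PowerResult(
        power=val,
        n_per_group=int(n_T),
        shifted_criticals=tuple(float(v) for v in z),
        quadrature_error=err,
    )


def closed_form_n_single(
    d: float, alpha: float, target_power: float, kappa: float = 1.0
) -> int:
    """Single-outcome per-group n: ceil((1+kappa)/kappa * (z_a + z_b)^2 / d^2).

    For a continuous outcome d = delta/sigma; for a discrete outcome d is the
    latent effect (unit latent variance).  At kappa=1 this is the familiar
    ``2 (z_a + z_{1-beta})^2 / d^2``.
    """
    if d <= 0:
        raise InfeasibleDesignError(
            f"standardized effect {d} is not positive; target power "
            "unreachable"
        )
    z_a = stats.norm.ppf(1.0 - alpha)
    z_b = stats.norm.ppf(target_power)
    return int(np.ceil((1.0 + kappa) / kappa * (z_a + z_b) ** 2 / d**2))


def search_sample_size(power_fn, n_start: int, target: float):
    """Minimal integer n with power_fn(n) >= target, assuming monotone power.

    Returns ``(n, power(n), power(n-1), curve)`` where ``curve`` records every
    evaluated (n, power) pair.
    """
    curve: list[tuple[int, float]] = []

    def f(n: int) -> float:
        p = power_fn(n)
        curve.append((n, p))
        return p

    n0 = max(2, int(n_start))
    if f(n0) >= target:
        # bracket downward: find lo < n0 with power below target
        hi = n0
        lo = max(2, n0 // 2)
        while f(lo) >= target:
            hi = lo
            if lo == 2:
                lo = 1  # sentinel: n=2 already suffices
                break
            lo = max(2, lo // 2)
    else:
        # bracket upward
        lo, hi = n0, 2 * n0
        while f(hi) < target:
            lo = hi
            hi *= 2
            if hi > MAX_N:
                raise InfeasibleDesignError(
                    f"power {curve[-1][1]:.4f} at n={lo}; target {target} "
                    "unreachable"
                )
    while lo + 1 < hi:
        mid = (lo + hi) // 2
        if f(mid) >= target:
            hi = mid
        else:
            lo = mid
    n = hi
    p_n = power_fn(n)
    p_prev = power_fn(n - 1) if n > 2 else float("nan")
    return n, p_n, p_prev, tuple(curve)


def samplesize_coprimary(
    spec: EndpointSpec,
    params: DesignParams,
    abseps: float = DEFAULT_ABSEPS,
) -> SampleSizeResult:
    """Smallest per-group n with intersection power >= target_power."""
    d = standardized_effects(spec).as_array()
    for o, dk in zip(spec.outcomes, d):
        if dk <= 0:
            raise InfeasibleDesignError(
                f"outcome {o.name or o.kind!r} has non-positive standardized "
                f"effect {dk:.4g}; co-primary power cannot reach the target"
            )
    kappa = spec.alloc_ratio
    n_start = closed_form_n_single(
        float(d.min()), params.alpha, params.target_power, kappa
    )

    def pw(n: int) -> float:
        return power_coprimary(spec, n, params, abseps=abseps).power

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
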