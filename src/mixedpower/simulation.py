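"""Seeded synthetic-trial generation and empirical power / FWER experiments.

Trials are drawn from the K-variate latent normal implied by an
:class:`~mixedpower.endpoint_model.EndpointSpec`: control latent means are
anchored by the stated response probabilities (or at 0 when a design states
latent effects directly), treatment means are shifted by the standardized
effects, discrete outcomes are produced by thresholding, and the latent
values are retained so that tests can be applied on either surface.

Empirical power applies the endpoint-level decision to each simulated
replicate: all K one-sided z tests must reject for a co-primary endpoint, at
least one at the adjusted level for a multiple primary endpoint, and a
two-proportion z test on the responder difference for a composite endpoint.
The default test surface is *latent* (z statistics computed from the latent
values with known unit variance); the *observed* surface re-estimates the
latent means of discrete outcomes from observed response proportions by the
marginal probit transform.

Randomness: a single seed expands into fixed-size replicate blocks through
``numpy.random.SeedSequence.spawn``, so results are reproducible and
independent of how blocks are processed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .endpoint_model import (
    EndpointSpec,
    latent_mean_from_prob,
    standardized_effects,
)
from .estimation import TrialData
from .power_multiple import adjusted_alpha

__all__ = [
    "SimulationPlan",
    "EmpiricalEstimate",
    "simulate_trial",
    "empirical_power",
    "empirical_fwer",
    "control_latent_means",
    "default_thresholds",
]

_BLOCK = 200  # replicates per seed block (fixed: part of the stream layout)


@dataclass(frozen=True)
class SimulationPlan:
    """A fully specified empirical-power experiment."""

    spec: EndpointSpec
    n_per_group: int
    reps: int = 10_000
    seed: int = 0
    test_surface: str = "latent"
    endpoint_type: str = "coprimary"
    adjustment: str = "none"
    alpha: float = 0.025

    def __post_init__(self) -> None:
        if self.reps < 100:
            raise ValueError("reps must be at least 100")
        if self.test_surface not in ("latent", "observed"):
            raise ValueError(f"unknown test_surface {self.test_surface!r}")
        if self.endpoint_type not in ("coprimary", "multiple", "composite"):
            raise ValueError(f"unknown endpoint_type {self.endpoint_type!r}")


@dataclass(frozen=True)
class EmpiricalEstimate:
    """Monte-Carlo estimate with its standard error and provenance."""

    estimate: float
    mc_se: float
    reps: int
    seed: int
    settings: dict = field(default_factory=dict)


def default_thresholds(n_levels: int) -> np.ndarray:
    """Equally spaced quantile cuts: uniform category probabilities at mean 0."""
    w = n_levels - 1
    return stats.norm.ppf(np.arange(1, w + 1) / (w + 1))


def _spec_thresholds(spec: EndpointSpec) -> list[np.ndarray | None]:
    out: list[np.ndarray | None] = []
    for o in spec.outcomes:
        if o.kind == "continuous":
            out.append(None)
        elif o.thresholds is not None:
            out.append(np.asarray(o.thresholds, dtype=float))
        else:
            out.append(default_thresholds(o.n_levels))
    return out


def control_latent_means(spec: EndpointSpec) -> np.ndarray:
    """Control-arm latent means implied by the spec.

    Continuous outcomes are anchored at 0 (only differences matter for
    power).  A discrete outcome with stated response probabilities is
    anchored so that the control response rate -- the probability of
    exceeding the first threshold -- equals ``prob_C``:
    ``mu_C* = tau_1 + Phi^-1(prob_C)``.  Discrete outcomes stated through a
    direct latent effect are anchored at 0.
    """
    thresholds = _spec_thresholds(spec)
    mu = np.zeros(spec.K)
    for k, o in enumerate(spec.outcomes):
        if o.kind != "continuous" and o.prob_C is not None:
            mu[k] = thresholds[k][0] + latent_mean_from_prob(o.prob_C, o.name)
    return mu


def simulate_trial(
    spec: EndpointSpec,
    n_per_group: int,
    seed: int,
    effect_sign: float = 1.0,
) -> TrialData:
    """Draw one two-arm trial from the latent model implied by ``spec``.

    Treatment latent means are the control means shifted by the standardized
    effects (times sigma_k on the observed scale for continuous outcomes);
    ``effect_sign=-1`` flips the shift (used for composite responder
    simulations where benefit lowers the latent scores).  Byte-identical
    across runs with the same seed.
    """
    rng = np.random.default_rng(seed)
    d = standardized_effects(spec).as_array() * effect_sign
    sds = np.asarray(
        [o.sd if o.kind == "continuous" else 1.0 for o in spec.outcomes]
    )
    mu_C = control_latent_means(spec)
    mu_T = mu_C + d * sds
    thresholds = _spec_thresholds(spec)
    n_T = int(n_per_group)
    n_C = int(np.ceil(spec.alloc_ratio * n_per_group))
    L = np.linalg.cholesky(spec.corr)
    lat = []
    for n, mu in ((n_T, mu_T), (n_C, mu_C)):
        z = rng.standard_normal((n, spec.K)) @ L.T
        lat.append(mu + z * sds)
    latent = np.vstack(lat)
    arm = np.concatenate([np.ones(n_T, int), np.zeros(n_C, int)])
    y = latent.copy()
    for k, o in enumerate(spec.outcomes):
        if o.kind == "continuous":
            continue
        y[:, k] = np.searchsorted(thresholds[k], latent[:, k], side="right")
    return TrialData(arm=arm, y=y, latent=latent)


# ---------------------------------------------------------------------------
# Empirical power
# ---------------------------------------------------------------------------


def _block_seeds(seed: int, reps: int) -> list[np.random.SeedSequence]:
    n_blocks = (reps + _BLOCK - 1) // _BLOCK
    return np.random.SeedSequence(seed).spawn(n_blocks)


def _z_statistics_block(
    spec: EndpointSpec,
    n_per_group: int,
    rng: np.random.Generator,
    reps: int,
    surface: str,
) -> np.ndarray:
    """(reps, K) matrix of per-outcome one-sided z statistics."""
    K = spec.K
    d = standardized_effects(spec).as_array()
    sds = np.asarray(
        [o.sd if o.kind == "continuous" else 1.0 for o in spec.outcomes]
    )
    mu_C = control_latent_means(spec)
    mu_T = mu_C + d * sds
    thresholds = _spec_thresholds(spec)
    n_T = int(n_per_group)
    n_C = int(np.ceil(spec.alloc_ratio * n_per_group))
    L = np.linalg.cholesky(spec.corr)
    lat_T = mu_T + (
        rng.standard_normal((reps, n_T, K)) @ L.T
    ) * sds
    lat_C = mu_C + (
        rng.standard_normal((reps, n_C, K)) @ L.T
    ) * sds
    if surface == "latent":
        diff = lat_T.mean(axis=1) - lat_C.mean(axis=1)
        denom = sds * np.sqrt(1.0 / n_T + 1.0 / n_C)
        return diff / denom
    # observed surface: continuous outcomes keep their sample means (known
    # sigma); discrete latent means re-estimated from response proportions by
    # the marginal probit transform, with its delta-method standard error
    # p(1-p) / (n phi(Phi^-1(p))^2) per arm
    z = np.empty((reps, K))
    for k, o in enumerate(spec.outcomes):
        if o.kind == "continuous":
            diff = lat_T[:, :, k].mean(axis=1) - lat_C[:, :, k].mean(axis=1)
            z[:, k] = diff / (sds[k] * np.sqrt(1.0 / n_T + 1.0 / n_C))
        else:
            cut = thresholds[k][0]
            p_T = (lat_T[:, :, k] >= cut).mean(axis=1)
            p_C = (lat_C[:, :, k] >= cut).mean(axis=1)
            p_T = np.clip(p_T, 0.5 / n_T, 1.0 - 0.5 / n_T)
            p_C = np.clip(p_C, 0.5 / n_C, 1.0 - 0.5 / n_C)
            mu_hat_T = stats.norm.ppf(p_T)
            mu_hat_C = stats.norm.ppf(p_C)
            var = p_T * (1 - p_T) / (n_T * stats.norm.pdf(mu_hat_T) ** 2)
            var += p_C * (1 - p_C) / (n_C * stats.norm.pdf(mu_hat_C) ** 2)
            z[:, k] = (mu_hat_T - mu_hat_C) / np.sqrt(var)
    return z


def _composite_reject_block(
    spec: EndpointSpec,
    n_per_group: int,
    rng: np.random.Generator,
    reps: int,
    alpha: float,
) -> np.ndarray:
    """Composite responder z test per replicate (treatment lowers scores).

    Responders are classified on the latent values; for discrete components
    whose cut coincides with a threshold this is identical to classifying on
    the observed levels, and continuous components are observed directly.
    """
    K = spec.K
    eta = np.asarray(
        [
            o.responder_cut if o.responder_cut is not None else 0.0
            for o in spec.outcomes
        ]
    )
    d = standardized_effects(spec).as_array()
    sds = np.asarray(
        [o.sd if o.kind == "continuous" else 1.0 for o in spec.outcomes]
    )
    mu_C = control_latent_means(spec)
    mu_T = mu_C - d * sds  # benefit = lower latent scores (response <= eta)
    n_T = int(n_per_group)
    n_C = int(np.ceil(spec.alloc_ratio * n_per_group))
    L = np.linalg.cholesky(spec.corr)
    z_a = stats.norm.ppf(1.0 - alpha)
    lat_T = mu_T + (rng.standard_normal((reps, n_T, K)) @ L.T) * sds
    lat_C = mu_C + (rng.standard_normal((reps, n_C, K)) @ L.T) * sds
    resp_T = (lat_T <= eta).all(axis=2).mean(axis=1)
    resp_C = (lat_C <= eta).all(axis=2).mean(axis=1)
    var = resp_T * (1 - resp_T) / n_T + resp_C * (1 - resp_C) / n_C
    var = np.maximum(var, 1e-12)
    z = (resp_T - resp_C) / np.sqrt(var)
    return z > z_a


def empirical_power(plan: SimulationPlan) -> EmpiricalEstimate:
    """Monte-Carlo power of the endpoint-level decision rule."""
    spec = plan.spec
    rejections = 0
    done = 0
    z_a_each = None
    if plan.endpoint_type in ("coprimary", "multiple"):
        a_each = (
            plan.alpha
            if plan.endpoint_type == "coprimary"
            else (
                plan.alpha
                if plan.adjustment == "holm"
                else adjusted_alpha(plan.alpha, spec.K, plan.adjustment)
            )
        )
        z_a_each = stats.norm.ppf(1.0 - a_each)
    for ss in _block_seeds(plan.seed, plan.reps):
        b = min(_BLOCK, plan.reps - done)
        rng = np.random.default_rng(ss)
        if plan.endpoint_type == "composite":
            rej = _composite_reject_block(
                spec, plan.n_per_group, rng, b, plan.alpha
            )
        else:
            z = _z_statistics_block(
                spec, plan.n_per_group, rng, b, plan.test_surface
            )
            if plan.endpoint_type == "coprimary":
                rej = (z > z_a_each).all(axis=1)
            elif plan.adjustment == "holm":
                rej = _holm_any_rejection(z, plan.alpha)
            else:
                rej = (z > z_a_each).any(axis=1)
        rejections += int(rej.sum())
        done += b
    est = rejections / plan.reps
    se = float(np.sqrt(est * (1 - est) / plan.reps))
    return EmpiricalEstimate(
        estimate=est,
        mc_se=se,
        reps=plan.reps,
        seed=plan.seed,
        settings={
            "n_per_group": plan.n_per_group,
            "endpoint_type": plan.endpoint_type,
            "test_surface": plan.test_surface,
            "adjustment": plan.adjustment,
            "alpha": plan.alpha,
        },
    )


def _holm_any_rejection(z: np.ndarray, alpha: float) -> np.ndarray:
    """Holm step-down: does at least one hypothesis get rejected?

    For the 'any rejection' event Holm reduces to its first step: the
    smallest p-value against alpha/K (further steps only add rejections).
    """
    K = z.shape[1]
    p_min = stats.norm.sf(z).min(axis=1)
    return p_min <= alpha / K


def _holm_rejections(z: np.ndarray, alpha: float) -> np.ndarray:
    """Full Holm step-down rejection matrix (reps, K)."""
    reps, K = z.shape
    p = stats.norm.sf(z)
    order = np.argsort(p, axis=1)
    rej = np.zeros_like(p, dtype=bool)
    levels = alpha / (K - np.arange(K))
    sorted_p = np.take_along_axis(p, order, axis=1)
    ok = sorted_p <= levels  # candidate rejections in sorted order
    # step-down: stop at the first failure
    keep = np.cumprod(ok, axis=1).astype(bool)
    np.put_along_axis(rej, order, keep, axis=1)
    return rej


def empirical_fwer(
    K: int,
    rho: float,
    alpha: float = 0.025,
    adjustment: str = "none",
    reps: int = 10_000,
    seed: int = 0,
    return_flags: bool = False,
):
    """Monte-Carlo FWER of K one-sided tests under the global null.

    Test statistics are drawn exactly from their null law N_K(0, Gamma) with
    equicorrelation ``rho`` (the sample size cancels under the null).
    Supports none / bonferroni / holm.
    """
    corr = np.full((K, K), float(rho))
    np.fill_diagonal(corr, 1.0)
    L = np.linalg.cholesky(corr)
    flags = np.empty(reps, dtype=bool)
    done = 0
    for ss in _block_seeds(seed, reps):
        b = min(_BLOCK, reps - done)
        rng = np.random.default_rng(ss)
        z = rng.standard_normal((b, K)) @ L.T
        if adjustment == "none":
            rej = (z > stats.norm.ppf(1.0 - alpha)).any(axis=1)
        elif adjustment == "bonferroni":
            rej = (z > stats.norm.ppf(1.0 - alpha / K)).any(axis=1)
        elif adjustment == "holm":
            rej = _holm_any_rejection(z, alpha)
        else:
            raise ValueError(f"unknown adjustment {adjustment!r}")
        flags[done : done + b] = rej
        done += b
    est = float(flags.mean())
    se = float(np.sqrt(est * (1 - est) / reps))
    result = EmpiricalEstimate(
        estimate=est,
        mc_se=se,
        reps=reps,
        seed=seed,
        settings={"K": K, "rho": rho, "alpha": alpha, "adjustment": adjustment},
    )
    if return_flags:
        return result, flags
    return result
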