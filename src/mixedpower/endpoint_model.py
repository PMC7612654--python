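"""Mixed-outcome endpoint data model and observed/latent scale transforms.

A trial endpoint combines K outcomes measured on different scales:
continuous outcomes observed directly, and ordinal/binary outcomes modelled
as threshold-discretised latent Gaussian variables with unit variance
(probit-type model).  Treatment effects on discrete outcomes live on the
latent scale: for a response event with probabilities ``pi_T``/``pi_C`` in
the two arms, the latent mean difference is
``delta* = Phi^-1(pi_T) - Phi^-1(pi_C)``.

Everything downstream (power, sample size, simulation, estimation) consumes
the :class:`EndpointSpec` defined here, so validation is strict and the
error types are distinct.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "OutcomeSpec",
    "EndpointSpec",
    "DesignParams",
    "EffectVector",
    "SpecValidationError",
    "OutcomeOrderError",
    "CorrelationError",
    "ThresholdError",
    "ProbabilityError",
    "VarianceError",
    "latent_mean_from_prob",
    "latent_effect_from_probs",
    "ordinal_category_prob",
    "standardized_effects",
    "validate_spec",
    "load_scenario",
    "dump_scenario",
]

_KINDS = ("continuous", "ordinal", "binary")
_KIND_ORDER = {k: i for i, k in enumerate(_KINDS)}


class SpecValidationError(ValueError):
    """Base class for endpoint-specification problems."""


class OutcomeOrderError(SpecValidationError):
    """Outcomes must be listed continuous, then ordinal, then binary."""


class CorrelationError(SpecValidationError):
    """Correlation matrix is not a valid positive-definite correlation."""


class ThresholdError(SpecValidationError):
    """Ordinal thresholds are missing, mis-sized or not increasing."""


class ProbabilityError(SpecValidationError):
    """A response probability lies outside the open interval (0, 1)."""


class VarianceError(SpecValidationError):
    """A continuous outcome has a missing or non-positive SD."""


@dataclass(frozen=True)
class OutcomeSpec:
    """One component outcome of a mixed endpoint.

    Parameters
    ----------
    kind:
        ``"continuous"``, ``"ordinal"`` or ``"binary"``.
    effect_obs, sd:
        Observed-scale mean difference and SD (continuous only).
    prob_T, prob_C:
        Response probabilities per arm (discrete only); the latent effect is
        derived as ``Phi^-1(prob_T) - Phi^-1(prob_C)``.
    effect_latent:
        Direct latent-scale effect for a discrete outcome.  Takes precedence
        over the probability pair when both are given, so a design can be
        stated in terms of a published standardized effect.
    n_levels:
        Number of ordinal levels (w+1 >= 2).  Binary is fixed at 2.
    thresholds:
        Strictly increasing latent cut-points for an ordinal outcome
        (length ``n_levels - 1``).  Binary is fixed at ``(0.0,)``.
    responder_cut:
        Latent-scale responder threshold eta (composite endpoints only).
    name:
        Optional label used in error messages and reports.
    """

    kind: Literal["continuous", "ordinal", "binary"]
    effect_obs: float | None = None
    sd: float | None = None
    prob_T: float | None = None
    prob_C: float | None = None
    effect_latent: float | None = None
    n_levels: int | None = None
    thresholds: tuple[float, ...] | None = None
    responder_cut: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise SpecValidationError(f"unknown outcome kind {self.kind!r}")
        label = self.name or self.kind
        if self.kind == "continuous":
            if self.sd is None or not self.sd > 0:
                raise VarianceError(f"{label}: continuous outcome needs sd > 0")
            if self.prob_T is not None or self.prob_C is not None:
                raise SpecValidationError(
                    f"{label}: continuous outcome cannot carry response "
                    "probabilities"
                )
            if self.effect_obs is None:
                raise SpecValidationError(f"{label}: effect_obs required")
        else:
            if self.sd is not None:
                raise VarianceError(
                    f"{label}: discrete outcomes have unit latent variance; "
                    "sd must not be set"
                )
            if self.effect_latent is None:
                for p, nm in ((self.prob_T, "prob_T"), (self.prob_C, "prob_C")):
                    if p is None:
                        raise ProbabilityError(
                            f"{label}: discrete outcome needs {nm} (or "
                            "effect_latent)"
                        )
                    if not 0.0 < p < 1.0:
                        raise ProbabilityError(
                            f"{label}: {nm}={p} outside (0, 1)"
                        )
            else:
                for p, nm in ((self.prob_T, "prob_T"), (self.prob_C, "prob_C")):
                    if p is not None and not 0.0 < p < 1.0:
                        raise ProbabilityError(
                            f"{label}: {nm}={p} outside (0, 1)"
                        )
        if self.kind == "binary":
            if self.n_levels not in (None, 2):
                raise ThresholdError(f"{label}: binary outcome has 2 levels")
            if self.thresholds not in (None, (0.0,)):
                raise ThresholdError(
                    f"{label}: binary threshold is fixed at 0"
                )
            object.__setattr__(self, "n_levels", 2)
            object.__setattr__(self, "thresholds", (0.0,))
        if self.kind == "ordinal":
            if self.n_levels is None or self.n_levels < 2:
                raise ThresholdError(
                    f"{label}: ordinal outcome needs n_levels >= 2"
                )
            if self.thresholds is not None:
                thr = tuple(float(t) for t in self.thresholds)
                if len(thr) != self.n_levels - 1:
                    raise ThresholdError(
                        f"{label}: expected {self.n_levels - 1} thresholds, "
                        f"got {len(thr)}"
                    )
                if np.any(np.diff(thr) <= 0):
                    raise ThresholdError(
                        f"{label}: thresholds must be strictly increasing"
                    )
                object.__setattr__(self, "thresholds", thr)


@dataclass(frozen=True)
class EndpointSpec:
    """Full description of a K-outcome mixed endpoint.

    ``outcomes`` must be ordered continuous, ordinal, binary.  ``corr`` is the
    common K x K latent-scale correlation matrix used for both arms;
    ``alloc_ratio`` is kappa = n_C / n_T.
    """

    outcomes: tuple[OutcomeSpec, ...]
    corr: np.ndarray
    alloc_ratio: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcomes", tuple(self.outcomes))
        object.__setattr__(
            self, "corr", np.atleast_2d(np.asarray(self.corr, dtype=float))
        )
        validate_spec(self)

    @property
    def K(self) -> int:
        return len(self.outcomes)

    @property
    def k_m(self) -> int:
        """Number of continuous outcomes."""
        return sum(o.kind == "continuous" for o in self.outcomes)

    @property
    def k_o(self) -> int:
        """Index after the last ordinal outcome."""
        return self.k_m + sum(o.kind == "ordinal" for o in self.outcomes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EndpointSpec):
            return NotImplemented
        return (
            self.outcomes == other.outcomes
            and np.array_equal(self.corr, other.corr)
            and self.alloc_ratio == other.alloc_ratio
        )


@dataclass(frozen=True)
class DesignParams:
    """One-sided significance level, target power and multiplicity rule."""

    alpha: float = 0.025
    target_power: float = 0.80
    adjustment: Literal["none", "bonferroni", "holm"] = "none"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 0.5:
            raise SpecValidationError(f"alpha={self.alpha} outside (0, 0.5]")
        if not 0.0 < self.target_power < 1.0:
            raise SpecValidationError(
                f"target_power={self.target_power} outside (0, 1)"
            )
        if self.adjustment not in ("none", "bonferroni", "holm"):
            raise SpecValidationError(
                f"unknown adjustment {self.adjustment!r}"
            )


@dataclass(frozen=True)
class EffectVector:
    """Standardized effects: delta_k / sigma_k (continuous), delta_k* (discrete)."""

    delta: tuple[float, ...]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.delta)):
            raise SpecValidationError("standardized effects must be finite")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.delta, dtype=float)


# ---------------------------------------------------------------------------
# Scale transforms
# ---------------------------------------------------------------------------

def latent_mean_from_prob(pi: float, name: str | None = None) -> float:
    """Latent mean implied by a response probability: ``Phi^-1(pi)``."""
    if not 0.0 < pi < 1.0:
        label = f" for outcome {name!r}" if name else ""
        raise ProbabilityError(
            f"response probability {pi}{label} outside the open interval "
            "(0, 1); the latent mean is unbounded at the endpoints"
        )
    return float(stats.norm.ppf(pi))


def latent_effect_from_probs(
    pi_T: float, pi_C: float, name: str | None = None
) -> float:
    """Latent-scale treatment effect ``Phi^-1(pi_T) - Phi^-1(pi_C)``."""
    return latent_mean_from_prob(pi_T, name) - latent_mean_from_prob(pi_C, name)


def ordinal_category_prob(
    thresholds: Sequence[float],
    mu_star: float,
    level_set: Sequence[int],
) -> float:
    """Probability that a thresholded latent N(mu*, 1) falls in a level set.

    Levels are ``0..w`` with cut-points ``tau_1 < ... < tau_w`` (tau_0 = -inf,
    tau_{w+1} = +inf); level j occupies ``(tau_j, tau_{j+1}]``.  ``level_set``
    must be a non-empty contiguous range of levels.
    """
    thr = np.asarray(thresholds, dtype=float)
    if thr.size and np.any(np.diff(thr) <= 0):
        raise ThresholdError("thresholds must be strictly increasing")
    w = thr.size  # levels 0..w
    levels = sorted(int(l) for l in level_set)
    if not levels:
        raise SpecValidationError("level_set must be non-empty")
    if levels[0] < 0 or levels[-1] > w:
        raise SpecValidationError(
            f"levels {levels} outside valid range 0..{w}"
        )
    if levels != list(range(levels[0], levels[-1] + 1)):
        raise SpecValidationError(f"level_set {levels} is not contiguous")
    bounds = np.concatenate(([-np.inf], thr, [np.inf]))
    lo, hi = bounds[levels[0]], bounds[levels[-1] + 1]
    return float(stats.norm.cdf(hi - mu_star) - stats.norm.cdf(lo - mu_star))


def standardized_effects(spec: EndpointSpec) -> EffectVector:
    """Per-outcome standardized effects consumed by every power function.

    Continuous: ``effect_obs / sd``.  Discrete: ``effect_latent`` if stated,
    else the probit transform of the response probabilities.
    """
    delta = []
    for o in spec.outcomes:
        if o.kind == "continuous":
            delta.append(float(o.effect_obs) / float(o.sd))
        elif o.effect_latent is not None:
            delta.append(float(o.effect_latent))
        else:
            delta.append(latent_effect_from_probs(o.prob_T, o.prob_C, o.name))
    return EffectVector(tuple(delta))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_spec(spec: EndpointSpec) -> EndpointSpec:
    """Check ordering, correlation validity and per-outcome invariants.

    Returns the spec unchanged on success; raises a distinct
    :class:`SpecValidationError` subclass per violated invariant.
    """
    kinds = [o.kind for o in spec.outcomes]
    if not kinds:
        raise SpecValidationError("endpoint needs at least one outcome")
    order = [_KIND_ORDER[k] for k in kinds]
    if order != sorted(order):
        raise OutcomeOrderError(
            "outcomes must be ordered continuous, ordinal, binary; got "
            + ", ".join(kinds)
        )
    corr = spec.corr
    K = len(kinds)
    if corr.shape != (K, K):
        raise CorrelationError(
            f"correlation matrix shape {corr.shape} does not match K={K}"
        )
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise CorrelationError("correlation matrix is not symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
        raise CorrelationError("correlation matrix diagonal must be 1")
    off = corr[~np.eye(K, dtype=bool)]
    if off.size and (np.any(off <= -1.0) or np.any(off >= 1.0)):
        raise CorrelationError("off-diagonal correlations must lie in (-1, 1)")
    if K > 1 and np.linalg.eigvalsh(corr).min() <= 1e-10:
        raise CorrelationError(
            "correlation matrix is not positive definite "
            f"(min eigenvalue {np.linalg.eigvalsh(corr).min():.2e})"
        )
    if not spec.alloc_ratio > 0:
        raise SpecValidationError(
            f"alloc_ratio={spec.alloc_ratio} must be positive"
        )
    return spec


# ---------------------------------------------------------------------------
# Scenario config files (YAML / JSON)
# ---------------------------------------------------------------------------

def _outcome_to_dict(o: OutcomeSpec) -> dict:
    d = {k: v for k, v in dataclasses.asdict(o).items() if v is not None}
    if "thresholds" in d:
        d["thresholds"] = list(d["thresholds"])
    if o.kind == "binary":
        # fixed by convention; keep files minimal
        d.pop("n_levels", None)
        d.pop("thresholds", None)
    return d


def scenario_to_dict(
    spec: EndpointSpec, params: DesignParams | None = None
) -> dict:
    out: dict = {
        "outcomes": [_outcome_to_dict(o) for o in spec.outcomes],
        "corr": [[float(v) for v in row] for row in spec.corr],
        "alloc_ratio": float(spec.alloc_ratio),
    }
    if params is not None:
        out.update(
            alpha=float(params.alpha),
            target_power=float(params.target_power),
            adjustment=params.adjustment,
        )
    return out


_SCENARIO_KEYS = {
    "outcomes",
    "corr",
    "alloc_ratio",
    "alpha",
    "target_power",
    "adjustment",
}


def scenario_from_dict(d: dict) -> tuple[EndpointSpec, DesignParams]:
    unknown = set(d) - _SCENARIO_KEYS
    if unknown:
        raise SpecValidationError(f"unknown scenario keys: {sorted(unknown)}")
    outcomes = []
    for od in d["outcomes"]:
        od = dict(od)
        if "thresholds" in od and od["thresholds"] is not None:
            od["thresholds"] = tuple(od["thresholds"])
        outcomes.append(OutcomeSpec(**od))
    K = len(outcomes)
    corr = d.get("corr", np.eye(K))
    if isinstance(corr, dict):
        rho = float(corr["rho"])  # equicorrelation shorthand
        corr = np.full((K, K), rho)
        np.fill_diagonal(corr, 1.0)
    spec = EndpointSpec(
        outcomes=tuple(outcomes),
        corr=np.asarray(corr, dtype=float),
        alloc_ratio=float(d.get("alloc_ratio", 1.0)),
    )
    params = DesignParams(
        alpha=float(d.get("alpha", 0.025)),
        target_power=float(d.get("target_power", 0.80)),
        adjustment=d.get("adjustment", "none"),
    )
    return spec, params


def load_scenario(path: str | Path) -> tuple[EndpointSpec, DesignParams]:
    """Load a scenario config (YAML or JSON, by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return scenario_from_dict(data)


def dump_scenario(
    spec: EndpointSpec,
    params: DesignParams,
    path: str | Path,
) -> None:
    """Write a scenario config; ``load -> dump -> load`` is the identity."""
    path = Path(path)
    data = scenario_to_dict(spec, params)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
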