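"""Maximum-likelihood fit of the latent variable model to pilot trial data.

Each patient contributes a mixed density: the multivariate-normal density of
the continuous components times the conditional multivariate-normal
rectangle probability of the observed discrete cells (exact for a latent
MVN).  Identifiability follows the usual probit conventions: discrete latent
variances are 1; ordinal outcomes have control-arm latent mean fixed at 0
and free thresholds; binary outcomes have the threshold fixed at 0 and free
per-arm latent means.  A single correlation matrix is shared by both arms.

The fitted parameter vector theta-hat and the inverse observed information
Cov(theta-hat) feed the composite-endpoint delta method
(:func:`mixedpower.power_composite.delta_method_var`) and design inputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools import numdiff

from ._mvn import batch_rectangle
from .endpoint_model import EndpointSpec, SpecValidationError

__all__ = [
    "TrialData",
    "LatentModelFit",
    "FitError",
    "IdentifiabilityError",
    "fit_latent_model",
    "latent_test_statistics",
]

logger = logging.getLogger(__name__)

_LL_FLOOR = 1e-300  # rectangle probabilities are clipped here before log


class FitError(RuntimeError):
    """Optimizer failed to converge; carries the optimizer trace."""


class IdentifiabilityError(ValueError):
    """A discrete level is unobserved in some arm."""


@dataclass(frozen=True)
class TrialData:
    """Two-arm trial data: arm indicator plus K mixed outcome columns.

    ``y`` holds continuous values, integer ordinal levels (0..w) and 0/1
    binaries as floats, column order matching the endpoint spec.  ``latent``
    optionally carries the underlying latent values (simulated data only).
    """

    arm: np.ndarray
    y: np.ndarray
    latent: np.ndarray | None = None

    def __post_init__(self) -> None:
        arm = np.asarray(self.arm, dtype=int)
        y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if arm.ndim != 1 or y.shape[0] != arm.size:
            raise ValueError("arm and y must align row-wise")
        if not np.isin(arm, (0, 1)).all():
            raise ValueError("arm must be coded 0 (control) / 1 (treatment)")
        object.__setattr__(self, "arm", arm)
        object.__setattr__(self, "y", y)
        if self.latent is not None:
            lat = np.atleast_2d(np.asarray(self.latent, dtype=float))
            if lat.shape != y.shape:
                raise ValueError("latent must match y's shape")
            object.__setattr__(self, "latent", lat)

    @property
    def n_T(self) -> int:
        return int((self.arm == 1).sum())

    @property
    def n_C(self) -> int:
        return int((self.arm == 0).sum())

    @property
    def K(self) -> int:
        return self.y.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {"arm": self.arm}
        for k in range(self.K):
            cols[f"y{k + 1}"] = self.y[:, k]
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialData":
        df = pd.read_csv(path)
        if "arm" not in df.columns:
            raise ValueError("CSV must have an 'arm' column")
        ycols = [c for c in df.columns if c != "arm"]
        n_bad = int(df[["arm", *ycols]].isna().any(axis=1).sum())
        if n_bad:
            logger.info("dropping %d rows with missing entries", n_bad)
            df = df.dropna()
        return cls(arm=df["arm"].to_numpy(), y=df[ycols].to_numpy(float))


# ---------------------------------------------------------------------------
# Parameter bookkeeping
# ---------------------------------------------------------------------------


def _param_names(kinds: tuple[str, ...], n_levels: tuple[int, ...]) -> list[str]:
    names: list[str] = []
    K = len(kinds)
    for k, kind in enumerate(kinds, start=1):
        names.append(f"mu_T[{k}]")
        if kind != "ordinal":  # ordinal control mean fixed at 0
            names.append(f"mu_C[{k}]")
    for k, kind in enumerate(kinds, start=1):
        if kind == "continuous":
            names.append(f"sigma[{k}]")
    for k, kind in enumerate(kinds, start=1):
        if kind == "ordinal":
            for j in range(1, n_levels[k - 1]):
                names.append(f"tau[{k},{j}]")
    for i in range(1, K + 1):
        for j in range(i + 1, K + 1):
            names.append(f"rho[{i},{j}]")
    return names


@dataclass(frozen=True)
class LatentModelFit:
    """Fitted latent model: named theta-hat, Cov(theta-hat) and metadata."""

    names: tuple[str, ...]
    values: np.ndarray
    cov: np.ndarray | None
    kinds: tuple[str, ...]
    n_levels: tuple[int, ...]
    loglik: float
    n_T: int
    n_C: int
    converged: bool

    # -- access helpers ----------------------------------------------------
    @property
    def theta(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names), name="theta")

    @property
    def cov_theta(self) -> pd.DataFrame | None:
        if self.cov is None:
            return None
        return pd.DataFrame(
            self.cov, index=list(self.names), columns=list(self.names)
        )

    def _get(self, name: str, default: float | None = None) -> float:
        try:
            i = self.names.index(name)
        except ValueError:
            if default is None:
                raise KeyError(name) from None
            return default
        return float(self.values[i])

    def mu_star(self, arm: str) -> np.ndarray:
        """Latent mean vector for arm 'T' or 'C' (observed mean for continuous)."""
        arm = arm.upper()
        out = []
        for k, kind in enumerate(self.kinds, start=1):
            if kind == "ordinal" and arm == "C":
                out.append(0.0)
            else:
                out.append(self._get(f"mu_{arm}[{k}]"))
        return np.asarray(out)

    def sds(self) -> np.ndarray:
        return np.asarray(
            [
                self._get(f"sigma[{k}]") if kind == "continuous" else 1.0
                for k, kind in enumerate(self.kinds, start=1)
            ]
        )

    def corr_matrix(self) -> np.ndarray:
        K = len(self.kinds)
        G = np.eye(K)
        for i in range(1, K + 1):
            for j in range(i + 1, K + 1):
                r = self._get(f"rho[{i},{j}]", 0.0)
                G[i - 1, j - 1] = G[j - 1, i - 1] = r
        return G

    def thresholds(self, k: int) -> np.ndarray:
        """Cut-points of outcome k (1-based); binary returns (0.0,)."""
        kind = self.kinds[k - 1]
        if kind == "binary":
            return np.array([0.0])
        if kind != "ordinal":
            raise ValueError(f"outcome {k} is {kind}; no thresholds")
        return np.asarray(
            [
                self._get(f"tau[{k},{j}]")
                for j in range(1, self.n_levels[k - 1])
            ]
        )

    # -- delta-method plumbing ----------------------------------------------
    def theta_values(self) -> np.ndarray:
        return self.values.copy()

    def cov_theta_values(self) -> np.ndarray:
        if self.cov is None:
            raise ValueError("fit carries no covariance")
        return self.cov

    def with_theta(self, values: np.ndarray) -> "LatentModelFit":
        return replace(self, values=np.asarray(values, dtype=float))

    # -- serialisation -------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "theta": {n: float(v) for n, v in zip(self.names, self.values)},
            "cov": None if self.cov is None else self.cov.tolist(),
            "kinds": list(self.kinds),
            "n_levels": list(self.n_levels),
            "loglik": self.loglik,
            "n_T": self.n_T,
            "n_C": self.n_C,
            "converged": self.converged,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LatentModelFit":
        d = json.loads(Path(path).read_text())
        names = tuple(d["theta"].keys())
        return cls(
            names=names,
            values=np.asarray(list(d["theta"].values()), dtype=float),
            cov=None if d["cov"] is None else np.asarray(d["cov"]),
            kinds=tuple(d["kinds"]),
            n_levels=tuple(d["n_levels"]),
            loglik=float(d["loglik"]),
            n_T=int(d["n_T"]),
            n_C=int(d["n_C"]),
            converged=bool(d["converged"]),
        )


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


class _Structure:
    """Maps between the natural theta vector and model matrices."""

    def __init__(self, kinds: tuple[str, ...], n_levels: tuple[int, ...]):
        self.kinds = kinds
        self.n_levels = n_levels
        self.K = len(kinds)
        self.km = sum(k == "continuous" for k in kinds)
        self.names = _param_names(kinds, n_levels)
        self.index = {n: i for i, n in enumerate(self.names)}

    def unpack(self, theta: np.ndarray):
        g = lambda name, default=None: (
            theta[self.index[name]]
            if name in self.index
            else default
        )
        K = self.K
        mu_T = np.zeros(K)
        mu_C = np.zeros(K)
        sd = np.ones(K)
        for k, kind in enumerate(self.kinds, start=1):
            mu_T[k - 1] = g(f"mu_T[{k}]")
            mu_C[k - 1] = 0.0 if kind == "ordinal" else g(f"mu_C[{k}]")
            if kind == "continuous":
                sd[k - 1] = g(f"sigma[{k}]")
        taus = {}
        for k, kind in enumerate(self.kinds, start=1):
            if kind == "ordinal":
                taus[k - 1] = np.asarray(
                    [g(f"tau[{k},{j}]") for j in range(1, self.n_levels[k - 1])]
                )
            elif kind == "binary":
                taus[k - 1] = np.asarray([0.0])
        G = np.eye(K)
        for i in range(1, K + 1):
            for j in range(i + 1, K + 1):
                r = g(f"rho[{i},{j}]", 0.0)
                G[i - 1, j - 1] = G[j - 1, i - 1] = r
        return mu_T, mu_C, sd, taus, G


def _arm_loglik(
    y_c: np.ndarray,
    levels: np.ndarray,
    mu: np.ndarray,
    sd: np.ndarray,
    taus: dict,
    G: np.ndarray,
    km: int,
) -> float:
    K = mu.size
    d = K - km
    Sigma = np.outer(sd, sd) * G
    ll = 0.0
    if km > 0:
        Scc = Sigma[:km, :km]
        ll += float(
            stats.multivariate_normal.logpdf(
                y_c, mean=mu[:km], cov=Scc, allow_singular=False
            ).sum()
        )
    if d == 0:
        return ll
    if km > 0:
        Scc = Sigma[:km, :km]
        Sdc = Sigma[km:, :km]
        B = np.linalg.solve(Scc, Sdc.T).T  # d x km
        cond_cov = Sigma[km:, km:] - B @ Sdc.T
        cond_means = mu[km:] + (y_c - mu[:km]) @ B.T
    else:
        cond_cov = Sigma
        cond_means = np.broadcast_to(mu, (levels.shape[0], K)).copy()
    # rectangle bounds from observed levels
    n = levels.shape[0]
    lower = np.empty((n, d))
    upper = np.empty((n, d))
    for j in range(d):
        k0 = km + j
        bounds = np.concatenate(([-np.inf], taus[k0], [np.inf]))
        lv = levels[:, j].astype(int)
        lower[:, j] = bounds[lv]
        upper[:, j] = bounds[lv + 1]
    probs = batch_rectangle(lower, upper, cond_means, cond_cov)
    return ll + float(np.log(np.clip(probs, _LL_FLOOR, None)).sum())


def _make_loglik(structure: _Structure, data: TrialData):
    km = structure.km
    y_T = data.y[data.arm == 1]
    y_C = data.y[data.arm == 0]

    def loglik(theta: np.ndarray) -> float:
        mu_T, mu_C, sd, taus, G = structure.unpack(theta)
        if np.any(sd <= 0):
            return -np.inf
        for tau in taus.values():
            if tau.size > 1 and np.any(np.diff(tau) <= 0):
                return -np.inf
        if structure.K > 1:
            mineig = np.linalg.eigvalsh(G).min()
            if mineig < 1e-6:
                return -np.inf
        ll = _arm_loglik(
            y_T[:, :km], y_T[:, km:], mu_T, sd, taus, G, km
        )
        ll += _arm_loglik(
            y_C[:, :km], y_C[:, km:], mu_C, sd, taus, G, km
        )
        return ll

    return loglik


# unconstrained internal parameterisation: log(sigma), first threshold +
# log-increments, atanh(rho); keeps L-BFGS iterates feasible.


def _natural_to_free(structure: _Structure, theta: np.ndarray) -> np.ndarray:
    x = theta.copy()
    for n, i in structure.index.items():
        if n.startswith("sigma"):
            x[i] = np.log(theta[i])
        elif n.startswith("rho"):
            x[i] = np.arctanh(np.clip(theta[i], -0.999, 0.999))
    for k, kind in enumerate(structure.kinds, start=1):
        if kind == "ordinal":
            w = structure.n_levels[k - 1] - 1
            idx = [structure.index[f"tau[{k},{j}]"] for j in range(1, w + 1)]
            tau = theta[idx]
            x[idx[0]] = tau[0]
            for j in range(1, w):
                x[idx[j]] = np.log(tau[j] - tau[j - 1])
    return x


def _free_to_natural(structure: _Structure, x: np.ndarray) -> np.ndarray:
    theta = x.copy()
    for n, i in structure.index.items():
        if n.startswith("sigma"):
            theta[i] = np.exp(x[i])
        elif n.startswith("rho"):
            theta[i] = np.tanh(x[i])
    for k, kind in enumerate(structure.kinds, start=1):
        if kind == "ordinal":
            w = structure.n_levels[k - 1] - 1
            idx = [structure.index[f"tau[{k},{j}]"] for j in range(1, w + 1)]
            theta[idx[0]] = x[idx[0]]
            for j in range(1, w):
                theta[idx[j]] = theta[idx[j - 1]] + np.exp(x[idx[j]])
    return theta


def _starting_values(structure: _Structure, data: TrialData) -> np.ndarray:
    km, K = structure.km, structure.K
    y_T = data.y[data.arm == 1]
    y_C = data.y[data.arm == 0]
    theta = np.zeros(len(structure.names))
    idx = structure.index
    for k, kind in enumerate(structure.kinds, start=1):
        col = k - 1
        if kind == "continuous":
            theta[idx[f"mu_T[{k}]"]] = y_T[:, col].mean()
            theta[idx[f"mu_C[{k}]"]] = y_C[:, col].mean()
            theta[idx[f"sigma[{k}]"]] = max(data.y[:, col].std(ddof=1), 1e-3)
        elif kind == "binary":
            for arm_y, nm in ((y_T, "T"), (y_C, "C")):
                p1 = np.clip(arm_y[:, col].mean(), 0.02, 0.98)
                # level 1 is the upper cell: P(Y=1) = Phi(mu)
                theta[idx[f"mu_{nm}[{k}]"]] = stats.norm.ppf(p1)
        else:  # ordinal: control mean 0; thresholds from pooled control cdf
            w = structure.n_levels[col] - 1
            cum = np.clip(
                np.cumsum(
                    [
                        (y_C[:, col] == lv).mean()
                        for lv in range(w)
                    ]
                ),
                0.02,
                0.98,
            )
            tau = stats.norm.ppf(cum)
            tau = np.maximum.accumulate(tau + 1e-6 * np.arange(w))
            for j in range(1, w + 1):
                theta[idx[f"tau[{k},{j}]"]] = tau[j - 1]
            # treatment mean from matching its top-cell rate to Phi(mu - tau_w)
            p_top = np.clip((y_T[:, col] == w).mean(), 0.02, 0.98)
            theta[idx[f"mu_T[{k}]"]] = tau[-1] + stats.norm.ppf(p_top)
    # modest correlation starts from observed Pearson correlations
    if K > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            R = np.corrcoef(data.y, rowvar=False)
        R = np.nan_to_num(R, nan=0.0)
        for i in range(1, K + 1):
            for j in range(i + 1, K + 1):
                theta[idx[f"rho[{i},{j}]"]] = np.clip(
                    R[i - 1, j - 1], -0.6, 0.6
                )
    return theta


def _check_identifiable(structure: _Structure, data: TrialData) -> None:
    km = structure.km
    for k, kind in enumerate(structure.kinds, start=1):
        if kind == "continuous":
            continue
        w = structure.n_levels[k - 1]
        for arm, label in ((1, "treatment"), (0, "control")):
            seen = set(data.y[data.arm == arm, k - 1].astype(int))
            missing = [lv for lv in range(w) if lv not in seen]
            if missing:
                raise IdentifiabilityError(
                    f"outcome {k} ({kind}): level(s) {missing} unobserved in "
                    f"the {label} arm; thresholds/means unidentifiable"
                )


def fit_latent_model(
    data: TrialData,
    spec: EndpointSpec,
    compute_cov: bool = True,
    maxiter: int = 500,
) -> LatentModelFit:
    """Fit the latent variable model by maximum likelihood.

    ``spec`` supplies the outcome kinds and ordinal level counts; all model
    parameters (means, SDs, thresholds, correlations) are estimated from
    ``data``.  ``Cov(theta-hat)`` is the inverse of the numerically
    differentiated observed information at the optimum.
    """
    kinds = tuple(o.kind for o in spec.outcomes)
    n_levels = tuple(o.n_levels or 0 for o in spec.outcomes)
    structure = _Structure(kinds, n_levels)
    if data.K != structure.K:
        raise SpecValidationError(
            f"data has {data.K} outcome columns, spec has {structure.K}"
        )
    if data.n_T < 10 or data.n_C < 10:
        raise ValueError("need at least 10 patients per arm")
    _check_identifiable(structure, data)

    loglik = _make_loglik(structure, data)
    theta0 = _starting_values(structure, data)
    x0 = _natural_to_free(structure, theta0)

    def neg_ll(x: np.ndarray) -> float:
        ll = loglik(_free_to_natural(structure, x))
        return np.inf if not np.isfinite(ll) else -ll

    res = optimize.minimize(
        neg_ll,
        x0,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
    )
    if not res.success and not np.isfinite(res.fun):
        raise FitError(f"latent model fit failed: {res.message}; trace: {res}")
    theta_hat = _free_to_natural(structure, res.x)
    ll_hat = -float(res.fun)

    cov = None
    if compute_cov:
        def nat_neg_ll(theta: np.ndarray) -> float:
            ll = loglik(theta)
            return np.inf if not np.isfinite(ll) else -ll

        H = numdiff.approx_hess1(theta_hat, nat_neg_ll)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        cov = 0.5 * (cov + cov.T)

    return LatentModelFit(
        names=tuple(structure.names),
        values=theta_hat,
        cov=cov,
        kinds=kinds,
        n_levels=n_levels,
        loglik=ll_hat,
        n_T=data.n_T,
        n_C=data.n_C,
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# Latent-scale test statistics
# ---------------------------------------------------------------------------


def latent_test_statistics(
    source: LatentModelFit | TrialData,
    variance_mode: str = "nominal",
    sigmas=None,
) -> np.ndarray:
    """Per-outcome one-sided z statistics on the latent scale.

    For a fitted model, the statistic is
    ``(mu_T_k* - mu_C_k*) / sqrt((1+kappa)/(kappa n_T))`` with unit latent
    variance in nominal mode (continuous outcomes scale by sigma_k), or uses
    the model-based standard error from Cov(theta-hat) in model mode.  For
    simulated :class:`TrialData` carrying latent values, sample means of the
    latent columns are used directly (nominal mode only); ``sigmas`` supplies
    known SDs for continuous components, defaulting to 1.
    """
    if variance_mode not in ("nominal", "model"):
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    if isinstance(source, TrialData):
        if variance_mode != "nominal":
            raise ValueError("TrialData input supports nominal mode only")
        if source.latent is None:
            raise ValueError("TrialData carries no latent values")
        lat_T = source.latent[source.arm == 1]
        lat_C = source.latent[source.arm == 0]
        diff = lat_T.mean(axis=0) - lat_C.mean(axis=0)
        sd = np.ones(source.K) if sigmas is None else np.asarray(sigmas, float)
        denom = sd * np.sqrt(1.0 / source.n_T + 1.0 / source.n_C)
        return diff / denom

    fit = source
    diff = fit.mu_star("T") - fit.mu_star("C")
    kappa = fit.n_C / fit.n_T
    if variance_mode == "nominal":
        denom = fit.sds() * np.sqrt((1.0 + kappa) / (kappa * fit.n_T))
        return diff / denom
    if fit.cov is None:
        raise ValueError("model-mode statistics need Cov(theta-hat)")
    cov = fit.cov_theta
    out = np.empty(len(fit.kinds))
    for k, kind in enumerate(fit.kinds, start=1):
        nm_t, nm_c = f"mu_T[{k}]", f"mu_C[{k}]"
        v = cov.loc[nm_t, nm_t]
        if kind != "ordinal":  # ordinal control mean is fixed, no variance
            v += cov.loc[nm_c, nm_c] - 2.0 * cov.loc[nm_t, nm_c]
        out[k - 1] = diff[k - 1] / np.sqrt(v)
    return out
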