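"""Packaged design scenarios.

``muse_spec`` encodes the four-dimensional systemic lupus erythematosus
endpoint used throughout the worked examples: SLEDAI (continuous), PGA
(continuous), BILAG (five-level ordinal) and an oral-corticosteroid tapering
indicator (binary), with the correlation estimates from the MUSE phase IIb
trial.  The discrete effects are stated directly on the latent scale at the
published two-decimal precision (0.24 and 0.40, the probit transforms of
response probabilities (0.97, 0.95) and (0.54, 0.38)).

``table2_spec`` builds the equicorrelated four-outcome designs (two
continuous with unit SD, one ordinal, one binary) with user-chosen
standardized effects, used for the power/sample-size grids.
"""

from __future__ import annotations

import numpy as np

from .endpoint_model import EndpointSpec, OutcomeSpec

__all__ = ["muse_spec", "muse_corr", "table2_spec", "equicorr"]

# correlation estimates from the MUSE trial dataset
_MUSE_RHO = {
    (1, 2): 0.448,
    (1, 3): 0.521,
    (1, 4): 0.003,
    (2, 3): 0.448,
    (2, 4): -0.031,
    (3, 4): 0.066,
}


def muse_corr() -> np.ndarray:
    G = np.eye(4)
    for (i, j), r in _MUSE_RHO.items():
        G[i - 1, j - 1] = G[j - 1, i - 1] = r
    return G


def equicorr(K: int, rho: float) -> np.ndarray:
    G = np.full((K, K), float(rho))
    np.fill_diagonal(G, 1.0)
    return G


def muse_spec(
    sigma1_sq: float = 18.0,
    sigma2_sq: float = 0.35,
) -> EndpointSpec:
    """The four-outcome SLE endpoint with MUSE correlations.

    ``sigma1_sq``/``sigma2_sq`` are the assumed variances of SLEDAI and PGA
    (the design allows for uncertainty by varying them).
    """
    return EndpointSpec(
        outcomes=(
            OutcomeSpec(
                kind="continuous",
                effect_obs=0.88,
                sd=float(np.sqrt(sigma1_sq)),
                name="SLEDAI",
            ),
            OutcomeSpec(
                kind="continuous",
                effect_obs=0.38,
                sd=float(np.sqrt(sigma2_sq)),
                name="PGA",
            ),
            OutcomeSpec(
                kind="ordinal",
                n_levels=5,
                prob_T=0.97,
                prob_C=0.95,
                effect_latent=0.24,
                name="BILAG",
            ),
            OutcomeSpec(
                kind="binary",
                prob_T=0.54,
                prob_C=0.38,
                effect_latent=0.40,
                name="Taper",
            ),
        ),
        corr=muse_corr(),
    )


def table2_spec(deltas, rho: float) -> EndpointSpec:
    """Equicorrelated 4-outcome design: 2 continuous (sd 1), 1 ordinal, 1 binary."""
    d1, d2, d3, d4 = (float(v) for v in deltas)
    return EndpointSpec(
        outcomes=(
            OutcomeSpec(kind="continuous", effect_obs=d1, sd=1.0, name="Y1"),
            OutcomeSpec(kind="continuous", effect_obs=d2, sd=1.0, name="Y2"),
            OutcomeSpec(
                kind="ordinal", n_levels=5, effect_latent=d3, name="Y3"
            ),
            OutcomeSpec(kind="binary", effect_latent=d4, name="Y4"),
        ),
        corr=equicorr(4, rho),
    )
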