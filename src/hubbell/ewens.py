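"""Ewens sampling formula: likelihood and maximum-likelihood theta.

The Ewens formula gives the probability of observing a species abundance
configuration (n_1..n_S) in a sample of J individuals drawn from a neutral
metacommunity with fundamental biodiversity number theta, assuming no
dispersal limitation (immigration probability m = 1):

    Pr(n | theta, J) = J! theta^S
                       / (prod_i n_i * prod_a phi_a! * prod_{k=1}^{J} (theta + k - 1))

theta bundles the metacommunity size J_M and per-capita speciation rate v as
theta = J_M v / (1 - v); the two are not separately identifiable from a
single sample and are only ever represented through theta.

The species count S is sufficient for theta, and the MLE solves the score
equation S = sum_{k=0}^{J-1} theta / (theta + k), whose left side is strictly
increasing in theta — so a bracketed root find is exact and fast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from .otu_io import AbundanceConfiguration

__all__ = [
    "EwensFit",
    "ewens_log_likelihood",
    "ewens_theta_mle",
    "fit_ewens",
    "expected_richness",
]


@dataclass
class EwensFit:
    """Fitted Ewens parameters for one sample.

    ``degenerate`` marks the boundary cases where theta is not interior:
    S == J (all singletons, theta -> +inf) and S == 1 (monodominance,
    theta -> 0).  In both limits the likelihood tends to 1, so logL = 0.
    """

    theta: float
    logL: float
    J: int
    S: int
    degenerate: bool = False
    sample_id: str = ""


def ewens_log_likelihood(config: AbundanceConfiguration, theta: float) -> float:
    """Natural-log Ewens probability of ``config`` at ``theta``.

    Everything is computed in log space via log-gamma; raw factorials are
    never formed (J can be 10^4).
    """
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    J, S = config.J, config.S
    n = config.abundances.astype(float)
    log_phi_fact = sum(gammaln(count + 1.0) for count in config.phi.values())
    # ln prod_{k=1}^{J} (theta+k-1) = ln Gamma(theta+J) - ln Gamma(theta)
    log_poch = gammaln(theta + J) - gammaln(theta)
    return float(
        gammaln(J + 1.0)
        + S * math.log(theta)
        - np.sum(np.log(n))
        - log_phi_fact
        - log_poch
    )


def expected_richness(theta: float, J: int) -> float:
    """Expected species count in a J-individual Ewens sample:
    E[S] = sum_{k=0}^{J-1} theta / (theta + k)."""
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    if J < 1:
        raise ValueError(f"J must be >= 1, got {J}")
    k = np.arange(J, dtype=float)
    return float(np.sum(theta / (theta + k)))


def ewens_theta_mle(J: int, S: int) -> float:
    """Solve the score equation S = sum_{k=0}^{J-1} theta/(theta+k) for theta.

    Root finding is bracketed on log-theta over [1e-8, 1e8]; the score is
    strictly increasing in theta so the bracket is safe.  Returns +inf for
    S == J and 0.0 for S == 1 with J > 1 (boundary MLEs).
    """
    if not 1 <= S <= J:
        raise ValueError(f"need 1 <= S <= J, got S={S}, J={J}")
    if S == J:
        return math.inf
    if S == 1:
        return 0.0
    k = np.arange(J, dtype=float)

    def score(log_theta: float) -> float:
        t = math.exp(log_theta)
        return float(np.sum(t / (t + k))) - S

    root = brentq(score, math.log(1e-8), math.log(1e8), xtol=1e-12, rtol=1e-14)
    return math.exp(root)


def fit_ewens(config: AbundanceConfiguration) -> EwensFit:
    """Maximum-likelihood Ewens fit for one sample."""
    J, S = config.J, config.S
    theta = ewens_theta_mle(J, S)
    if not math.isfinite(theta) or theta == 0.0:
        # boundary: likelihood tends to 1 in either limit
        return EwensFit(theta=theta, logL=0.0, J=J, S=S, degenerate=True,
                        sample_id=config.sample_id)
    logL = ewens_log_likelihood(config, theta)
    return EwensFit(theta=theta, logL=logL, J=J, S=S, degenerate=False,
                    sample_id=config.sample_id)
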