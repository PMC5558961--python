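"""Etienne dispersal-limited sampling formula and joint (theta, m) MLE.

The Etienne formula generalises the Ewens formula to a local community that
receives immigrants from the metacommunity at per-birth probability m < 1.
With I = m (J - 1) / (1 - m), the probability of an abundance configuration
D = (n_1..n_S) is

    Pr(D | theta, m, J) = J! / (prod_i n_i * prod_a phi_a!)
                          * theta^S / (I)_J
                          * sum_{A=S}^{J} K(D, A) I^A / (theta)_A

where (x)_A is the Pochhammer rising factorial and K(D, A) sums, over all
ways of assigning a_i immigrant ancestors to species i with sum a_i = A,
the products prod_i s(n_i, a_i) s(a_i, 1) / s(n_i, 1) of unsigned Stirling
numbers of the first kind.  As m -> 1 the formula reduces to Ewens.

K(D, A) does not depend on (theta, m), so it is computed once per sample as
a sequential convolution of per-species coefficient vectors

    c_i(a) = ln[ s(n_i, a) (a-1)! / (n_i-1)! ],   a = 1..n_i,

carried out entirely in log space with log-sum-exp: positive summands cannot
underflow there, and the Stirling rows themselves (which overflow double for
n > 170 in linear space) are built by the log-space recurrence
s(n+1, a) = s(n, a-1) + n s(n, a).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .ewens import ewens_theta_mle
from .otu_io import AbundanceConfiguration

__all__ = [
    "EtienneFit",
    "KCoefficients",
    "log_stirling_row",
    "compute_K",
    "etienne_log_likelihood",
    "fit_etienne",
    "m_to_I",
    "I_to_m",
]

_NEG_INF = -np.inf

# cache of requested log-Stirling rows: {n: ln s(n, a) for a=1..n}; a new row
# is grown by the recurrence from the largest cached row below it, so repeated
# calls with related n share work without storing every intermediate row
_stirling_cache: dict[int, np.ndarray] = {1: np.array([0.0])}


def log_stirling_row(n: int) -> np.ndarray:
    """ln of unsigned Stirling numbers of the first kind s(n, a), a = 1..n."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if n in _stirling_cache:
        return _stirling_cache[n]
    m = max(k for k in _stirling_cache if k <= n)
    row = _stirling_cache[m]
    while m < n:
        # s(m+1, a) = s(m, a-1) + m * s(m, a); in log space via logaddexp
        nxt = np.empty(m + 1)
        nxt[0] = math.log(m) + row[0]           # s(m+1, 1) = m * s(m, 1) = m!
        nxt[m] = 0.0                             # s(m+1, m+1) = 1
        if m > 1:
            nxt[1:m] = np.logaddexp(row[:-1], math.log(m) + row[1:])
        row, m = nxt, m + 1
    _stirling_cache[n] = row
    return row


def _log_conv(a: np.ndarray, b: np.ndarray, chunk: int = 4096) -> np.ndarray:
    """Exact log-space linear convolution: out[k] = lse_j(a[k-j] + b[j]).

    Output rows are processed in chunks to bound the temporary matrix.
    """
    if len(b) > len(a):
        a, b = b, a
    La, Lb = len(a), len(b)
    if Lb == 1:
        return a + b[0]
    pad = np.full(Lb - 1, _NEG_INF)
    ap = np.concatenate([pad, a, pad])  # length La + 2(Lb-1)
    b_rev = b[::-1]
    L = La + Lb - 1
    out = np.empty(L)
    for start in range(0, L, chunk):
        stop = min(start + chunk, L)
        idx = np.arange(start, stop)[:, None] + np.arange(Lb)[None, :]
        out[start:stop] = logsumexp(ap[idx] + b_rev[None, :], axis=1)
    return out


@dataclass
class KCoefficients:
    """ln K(D, A) for A = S..J, plus the parameter-free prefactor pieces.

    Depends only on the abundance multiset of the sample, never on (theta, m);
    computed once and reused across all likelihood evaluations during fitting
    and testing.
    """

    logK: np.ndarray  # length J - S + 1, index 0 <-> A = S
    J: int
    S: int
    log_prefactor: float  # ln J! - sum_i ln n_i - sum_a ln phi_a!

    @property
    def A(self) -> np.ndarray:
        return np.arange(self.S, self.J + 1)


def compute_K(config: AbundanceConfiguration) -> KCoefficients:
    """Build the K(D, A) coefficient vector for one sample.

    Species are convolved in descending-abundance order; the result is
    order-independent (convolution commutes) but starting with the longest
    vectors keeps intermediate arrays compact.
    """
    J, S = config.J, config.S
    # prefetch Stirling rows ascending so each extends the previous one
    for n_i in sorted(set(int(v) for v in config.abundances)):
        log_stirling_row(n_i)
    acc: np.ndarray | None = None
    for n_i in config.abundances:  # already sorted descending
        n_i = int(n_i)
        c = log_stirling_row(n_i) + gammaln(np.arange(1, n_i + 1)) - gammaln(n_i)
        acc = c if acc is None else _log_conv(acc, c)
    assert acc is not None and len(acc) == J - S + 1
    log_phi_fact = sum(gammaln(v + 1.0) for v in config.phi.values())
    pref = float(
        gammaln(J + 1.0) - np.sum(np.log(config.abundances.astype(float))) - log_phi_fact
    )
    return KCoefficients(logK=acc, J=J, S=S, log_prefactor=pref)


def m_to_I(m: float, J: int) -> float:
    """Convert immigration probability m to the immigrant-number parameter
    I = m (J - 1) / (1 - m).  m -> 1 maps to +inf."""
    if not 0 < m <= 1:
        raise ValueError(f"m must be in (0, 1], got {m}")
    if J < 2:
        raise ValueError(f"J must be >= 2, got {J}")
    if m == 1.0:
        return math.inf
    return m * (J - 1) / (1.0 - m)


def I_to_m(I: float, J: int) -> float:
    """Inverse of :func:`m_to_I`: m = I / (I + J - 1)."""
    if I <= 0:
        raise ValueError(f"I must be positive, got {I}")
    if J < 2:
        raise ValueError(f"J must be >= 2, got {J}")
    if math.isinf(I):
        return 1.0
    return I / (I + J - 1)


def _log_pochhammer_I(I: float, J: int) -> float:
    # explicit sum of ln(I + k): gammaln differences cancel catastrophically
    # for I ~ 1e12 (m near 1), this stays exact to ~1e-11
    return float(np.sum(np.log(I + np.arange(J, dtype=float))))


def _etienne_loglik_at(K: KCoefficients, theta: float, log_I: float) -> float:
    """Core evaluation at (theta, I) with I given in log form."""
    J, S, A = K.J, K.S, K.A
    log_poch_theta = gammaln(theta + A) - gammaln(theta)
    I = math.exp(log_I)
    lse = logsumexp(K.logK + A * log_I - log_poch_theta)
    return K.log_prefactor + S * math.log(theta) - _log_pochhammer_I(I, J) + lse


def etienne_log_likelihood(
    config: AbundanceConfiguration,
    K: KCoefficients,
    theta: float,
    m: float,
) -> float:
    """Natural-log Etienne probability of ``config`` at (theta, m).

    ``K`` must have been computed from the same abundance configuration.
    """
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    if not 0 < m < 1:
        raise ValueError(f"m must be in (0, 1), got {m}")
    if K.J != config.J or K.S != config.S:
        raise ValueError("K coefficients do not match the configuration")
    if config.J == 1:
        return 0.0
    I = m_to_I(m, config.J)
    return float(_etienne_loglik_at(K, theta, math.log(I)))


@dataclass
class EtienneFit:
    """Joint MLE of (theta, m) under the Etienne formula for one sample."""

    theta: float
    m: float
    I: float
    logL: float
    J: int
    S: int
    converged: bool
    n_restarts_used: int
    weakly_identified: bool = False
    sample_id: str = ""


# optimizer settings: unconstrained (ln theta, logit m) scale; logit m capped
# at +/- 60 to keep I = (J-1) e^x inside double range
_X_CAP = 60.0
_M_STARTS = (0.5, 0.9, 0.999)
_MAXFEV = 2000
_FATOL = 1e-8


def fit_etienne(config: AbundanceConfiguration) -> EtienneFit:
    """Fit (theta, m) by derivative-free simplex search with restarts.

    The negative log-likelihood is minimised over (ln theta, logit m); the
    logit parameterisation also gives ln I = ln(J-1) + logit(m) directly,
    avoiding cancellation as m -> 1.  Three restarts from m0 in
    {0.5, 0.9, 0.999}, theta0 at the Ewens MLE.
    """
    J, S = config.J, config.S
    K = compute_K(config)
    if J == 1:
        return EtienneFit(theta=1.0, m=0.5, I=m_to_I(0.5, 2), logL=0.0, J=J, S=S,
                          converged=True, n_restarts_used=0, weakly_identified=True,
                          sample_id=config.sample_id)

    theta0 = ewens_theta_mle(J, S)
    if not math.isfinite(theta0) or theta0 <= 0:
        theta0 = max(float(S), 1.0)
    log_Jm1 = math.log(J - 1)

    def nll(x: np.ndarray) -> float:
        log_theta = min(max(x[0], math.log(1e-8)), math.log(1e8))
        xm = min(max(x[1], -_X_CAP), _X_CAP)
        return -_etienne_loglik_at(K, math.exp(log_theta), log_Jm1 + xm)

    best = None
    converged = False
    n_used = 0
    for m0 in _M_STARTS:
        n_used += 1
        x0 = np.array([math.log(theta0), math.log(m0 / (1 - m0))])
        res = minimize(
            nll, x0, method="Nelder-Mead",
            options={"maxfev": _MAXFEV, "fatol": _FATOL, "xatol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)

    assert best is not None
    theta_hat = math.exp(min(max(best.x[0], math.log(1e-8)), math.log(1e8)))
    xm = min(max(best.x[1], -_X_CAP), _X_CAP)
    m_hat = 1.0 / (1.0 + math.exp(-xm))
    I_hat = (J - 1) * math.exp(xm)
    return EtienneFit(
        theta=theta_hat, m=m_hat, I=I_hat, logL=float(-best.fun), J=J, S=S,
        converged=converged, n_restarts_used=n_used,
        weakly_identified=(S == 1), sample_id=config.sample_id,
    )
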