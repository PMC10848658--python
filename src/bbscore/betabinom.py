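"""Beta-binomial distribution machinery in the (mu, rho) parameterization.

The per-trial count of correct tokens X out of n is modelled as
``X ~ BetaBinomial(n, mu, rho)`` where ``mu`` is the mean per-token success
probability and ``rho`` is the intraclass correlation among tokens within a
trial.  ``rho = 0`` is the binomial special case; ``rho -> 1`` concentrates
mass on the all-or-nothing outcomes 0 and n.

The (mu, rho) pair maps to the classical Beta(alpha, beta) mixing
distribution through::

    mu  = alpha / (alpha + beta)
    rho = 1 / (alpha + beta + 1)

All probability-mass computations run in log space via log-gamma so that
small rho (large alpha + beta) stays numerically stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, gammaln

__all__ = [
    "BetaBinomialParams",
    "CountDistribution",
    "alpha_beta_to_mu_rho",
    "count_distribution",
    "estimate_mu_rho_moments",
    "logpmf",
    "moments",
    "mu_rho_to_alpha_beta",
    "pmf",
    "sample",
]

# Above this concentration the gammaln differences in the betaln form lose
# precision, so the pmf switches to an exact rising-factorial form (n is small).
_LARGE_CONCENTRATION = 1e4


def mu_rho_to_alpha_beta(mu: float, rho: float) -> tuple[float, float]:
    """Map (mu, rho) to the Beta mixing parameters (alpha, beta).

    Solves ``mu = alpha/(alpha+beta)`` and ``rho = 1/(alpha+beta+1)``.
    ``rho = 0`` has no finite (alpha, beta) image (the binomial limit) and
    raises; callers handle that branch themselves.
    """
    mu = float(mu)
    rho = float(rho)
    if not 0.0 < mu < 1.0:
        raise ValueError(f"mu must lie strictly in (0, 1); got mu={mu}")
    if not 0.0 < rho < 1.0:
        raise ValueError(f"rho must lie strictly in (0, 1) for this map; got rho={rho}")
    concentration = 1.0 / rho - 1.0  # alpha + beta
    return mu * concentration, (1.0 - mu) * concentration


def alpha_beta_to_mu_rho(alpha: float, beta: float) -> tuple[float, float]:
    """Inverse of :func:`mu_rho_to_alpha_beta`."""
    alpha = float(alpha)
    beta = float(beta)
    if alpha <= 0.0:
        raise ValueError(f"alpha must be positive; got alpha={alpha}")
    if beta <= 0.0:
        raise ValueError(f"beta must be positive; got beta={beta}")
    return alpha / (alpha + beta), 1.0 / (alpha + beta + 1.0)


@dataclass(frozen=True)
class BetaBinomialParams:
    """Parameters of one trial-count distribution.

    Attributes
    ----------
    n : int
        Tokens per trial (n >= 1).
    mu : float
        Mean per-token success probability, in (0, 1).
    rho : float
        Intraclass correlation, in [0, 1).  ``rho = 0`` denotes the binomial.
    """

    n: int
    mu: float
    rho: float = 0.0

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"n must be a positive integer; got n={self.n}")
        if not 0.0 < self.mu < 1.0:
            raise ValueError(f"mu must lie strictly in (0, 1); got mu={self.mu}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must lie in [0, 1); got rho={self.rho}")

    @property
    def alpha_beta(self) -> tuple[float, float]:
        """(alpha, beta) of the Beta mixing distribution (requires rho > 0)."""
        return mu_rho_to_alpha_beta(self.mu, self.rho)


@dataclass(frozen=True)
class CountDistribution:
    """Probability mass over k = 0..n correct tokens."""

    n: int
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (self.n + 1,):
            raise ValueError(f"probs must have length n+1={self.n + 1}; got {probs.shape}")
        if np.any(probs < 0.0):
            raise ValueError("probs must be nonnegative")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError(f"probs must sum to 1 within 1e-12; got {probs.sum()!r}")
        object.__setattr__(self, "probs", probs)


def _log_binom_coeff(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def _logpmf_arrays(
    k: np.ndarray, n: np.ndarray, mu: np.ndarray, rho: np.ndarray
) -> np.ndarray:
    """Vectorized beta-binomial log pmf; rho entries of exactly 0 use the
    binomial branch.  Inputs broadcast against each other; n must be small
    integers (token counts per trial)."""
    k, n, mu, rho = np.broadcast_arrays(
        np.asarray(k, dtype=float),
        np.asarray(n, dtype=float),
        np.asarray(mu, dtype=float),
        np.asarray(rho, dtype=float),
    )
    out = np.empty(k.shape, dtype=float)
    logc = _log_binom_coeff(k, n)

    # below ~1e-12 the mixture is indistinguishable from the binomial at
    # double precision, and the exact branch avoids rounding accumulation
    binom = rho < 1e-12
    if np.any(binom):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(k > 0, k * np.log(mu), 0.0) + np.where(
                n - k > 0, (n - k) * np.log1p(-mu), 0.0
            )
        out[binom] = (logc + term)[binom]

    bb = ~binom
    if np.any(bb):
        rho_bb = np.clip(rho, 1e-12, 1.0 - 1e-9)
        conc = 1.0 / rho_bb - 1.0
        a = mu * conc
        b = (1.0 - mu) * conc
        small = bb & (conc <= _LARGE_CONCENTRATION)
        if np.any(small):
            with np.errstate(all="ignore"):
                val = logc + betaln(k + a, n - k + b) - betaln(a, b)
            out[small] = val[small]
        large = bb & (conc > _LARGE_CONCENTRATION)
        if np.any(large):
            # Exact product form: sum_i log(a+i) + sum_j log(b+j) - sum_m log(a+b+m)
            val = logc.copy()
            nmax = int(n[large].max())
            for i in range(nmax):
                val = val + np.where(i < k, np.log(a + i), 0.0)
                val = val + np.where(i < n - k, np.log(b + i), 0.0)
                val = val - np.where(i < n, np.log(a + b + i), 0.0)
            out[large] = val[large]
    return out


def logpmf(k, params: BetaBinomialParams) -> np.ndarray | float:
    """Log probability of k correct tokens (k may be an array)."""
    k_arr = np.asarray(k)
    if np.any((k_arr < 0) | (k_arr > params.n)):
        raise ValueError(f"k must lie in 0..n={params.n}; got k={k}")
    out = _logpmf_arrays(k_arr, params.n, params.mu, params.rho)
    return float(out) if np.isscalar(k) or out.ndim == 0 else out


def pmf(k, params: BetaBinomialParams) -> np.ndarray | float:
    """Probability of k correct tokens (k may be an array)."""
    return np.exp(logpmf(k, params))


def count_distribution(params: BetaBinomialParams) -> CountDistribution:
    """Full probability mass vector over k = 0..n, renormalized to machine
    precision."""
    probs = np.exp(_logpmf_arrays(np.arange(params.n + 1), params.n, params.mu, params.rho))
    return CountDistribution(n=params.n, probs=probs / probs.sum())


def moments(params: BetaBinomialParams) -> tuple[float, float]:
    """Mean and variance of the count: mean = n*mu,
    var = n*mu*(1-mu)*(1 + (n-1)*rho)."""
    n, mu, rho = params.n, params.mu, params.rho
    mean = n * mu
    variance = n * mu * (1.0 - mu) * (1.0 + (n - 1.0) * rho)
    return mean, variance


def sample(
    params: BetaBinomialParams,
    n_trials: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw per-trial counts by the two-stage compositional scheme: one
    per-trial success probability from Beta(alpha, beta), then a binomial
    count given that probability.  ``rho = 0`` samples the binomial directly.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1; got {n_trials}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if params.rho == 0.0:
        return rng.binomial(params.n, params.mu, size=n_trials)
    alpha, beta = params.alpha_beta
    pis = rng.beta(alpha, beta, size=n_trials)
    return rng.binomial(params.n, pis)


def estimate_mu_rho_moments(counts: np.ndarray, n: int) -> tuple[float, float]:
    """Method-of-moments (mu, rho) estimate from counts out of a common n.

    Inverts the variance identity var = n*mu*(1-mu)*(1+(n-1)*rho); rho is
    clipped into [0, 1).  Intended as a rough diagnostic / optimizer start,
    not a substitute for the Bayesian fits.
    """
    counts = np.asarray(counts, dtype=float)
    if n < 1:
        raise ValueError(f"n must be >= 1; got {n}")
    mu_hat = float(np.clip(counts.mean() / n, 1e-9, 1.0 - 1e-9))
    if n == 1 or counts.size < 2:
        return mu_hat, 0.0
    var_hat = counts.var(ddof=1)
    denom = n * mu_hat * (1.0 - mu_hat)
    rho_hat = (var_hat / denom - 1.0) / (n - 1.0) if denom > 0 else 0.0
    return mu_hat, float(np.clip(rho_hat, 0.0, 1.0 - 1e-9))
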