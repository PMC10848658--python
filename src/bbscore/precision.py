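"""Measurement precision of partial-credit scoring vs list length.

The precision metric is the standard deviation, across replicate test
administrations, of mean accuracy (total tokens correct / total tokens).
For W words of n tokens each with per-token accuracy mu and intraclass
correlation rho the closed form is::

    SD(W) = sqrt( mu * (1 - mu) * (1 + (n - 1) * rho) / (n * W) )

and the Monte-Carlo twin draws replicate datasets from the corresponding
binomial (n = 1, whole-word scoring) or beta-binomial distribution.  The
headline planning quantity is the smallest word count whose SD matches a
reference (by default whole-word scoring of 50 words).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from bbscore.betabinom import BetaBinomialParams, mu_rho_to_alpha_beta

__all__ = [
    "PrecisionCurve",
    "analytic_sd_of_mean",
    "list_length_equivalence",
    "min_words_to_match",
    "simulate_sd_of_mean",
]


@dataclass(frozen=True)
class PrecisionCurve:
    """SD of mean accuracy over a grid of word counts, simulated or analytic."""

    n: int
    mu: float
    rho: float
    words_tested: np.ndarray = field(repr=False)
    sd_of_mean: np.ndarray = field(repr=False)
    n_draws: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "words_tested", np.asarray(self.words_tested, dtype=int))
        object.__setattr__(self, "sd_of_mean", np.asarray(self.sd_of_mean, dtype=float))
        if self.words_tested.shape != self.sd_of_mean.shape:
            raise ValueError("words_tested and sd_of_mean must align")
        if np.any(self.sd_of_mean <= 0):
            raise ValueError("sd_of_mean must be strictly positive")


def analytic_sd_of_mean(n: int, mu: float, rho: float, words: int) -> float:
    """Closed-form SD of mean accuracy for ``words`` stimuli of n tokens."""
    if words < 1:
        raise ValueError(f"words must be >= 1; got {words}")
    BetaBinomialParams(n=n, mu=mu, rho=rho)  # validate
    return math.sqrt(mu * (1.0 - mu) * (1.0 + (n - 1.0) * rho) / (n * words))


def analytic_curve(n: int, mu: float, rho: float, words_grid: np.ndarray) -> PrecisionCurve:
    sd = np.array([analytic_sd_of_mean(n, mu, rho, int(w)) for w in np.asarray(words_grid)])
    return PrecisionCurve(n=n, mu=mu, rho=rho, words_tested=np.asarray(words_grid), sd_of_mean=sd)


def simulate_sd_of_mean(
    n: int,
    mu: float,
    rho: float,
    words_grid,
    n_draws: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> PrecisionCurve:
    """Monte-Carlo SD of mean accuracy at each word count in the grid.

    Each of ``n_draws`` replicates draws one dataset of W trials (one
    per-trial success probability from the Beta mixing distribution when
    rho > 0, then a count) and scores mean accuracy as total correct over
    total tokens; the SD is taken across replicates.
    """
    if n_draws < 2:
        raise ValueError(f"n_draws must be >= 2; got {n_draws}")
    BetaBinomialParams(n=n, mu=mu, rho=rho)  # validate
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    words_grid = np.asarray(words_grid, dtype=int)
    if np.any(words_grid < 1):
        raise ValueError("all word counts must be >= 1")
    sds = np.empty(len(words_grid))
    for i, W in enumerate(words_grid):
        if rho == 0.0:
            counts = rng.binomial(n, mu, size=(n_draws, W))
        else:
            alpha, beta = mu_rho_to_alpha_beta(mu, rho)
            pis = rng.beta(alpha, beta, size=(n_draws, W))
            counts = rng.binomial(n, pis)
        accuracy = counts.sum(axis=1) / (n * W)
        sds[i] = accuracy.std(ddof=1)
    return PrecisionCurve(
        n=n,
        mu=mu,
        rho=rho,
        words_tested=words_grid,
        sd_of_mean=sds,
        n_draws=n_draws,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )


def min_words_to_match(target_sd: float, curve_or_params, search_range=(1, 10_000)) -> int:
    """Smallest word count whose SD of mean accuracy is <= ``target_sd``.

    Accepts either a :class:`PrecisionCurve` (first grid point at or below
    the target) or a ``(n, mu, rho)`` tuple, in which case the analytic
    closed form gives ceil(mu*(1-mu)*(1+(n-1)*rho) / (n*target_sd**2)).
    """
    if target_sd <= 0:
        raise ValueError(f"target_sd must be positive; got {target_sd}")
    if isinstance(curve_or_params, PrecisionCurve):
        curve = curve_or_params
        below = curve.sd_of_mean <= target_sd
        if not below.any():
            raise ValueError(
                "no word count in the grid reaches the target SD; closest is "
                f"SD={curve.sd_of_mean.min():.5f} at W={int(curve.words_tested[curve.sd_of_mean.argmin()])}"
            )
        return int(curve.words_tested[np.argmax(below)])
    n, mu, rho = curve_or_params
    BetaBinomialParams(n=n, mu=mu, rho=rho)  # validate
    exact = mu * (1.0 - mu) * (1.0 + (n - 1.0) * rho) / (n * target_sd**2)
    words = max(1, math.ceil(exact - 1e-9))  # guard float fuzz at integer crossings
    lo, hi = search_range
    if not lo <= words <= hi:
        raise ValueError(f"required word count {words} falls outside search range {search_range}")
    return words


def list_length_equivalence(
    rho: float,
    n: int = 3,
    mu: float = 0.5,
    reference_words: int = 50,
    words_grid=None,
    n_draws: int = 10_000,
    seed: int = 0,
) -> dict:
    """Match partial-credit precision to whole-word scoring of a reference list.

    Simulates both scoring modes (whole-word: binomial n=1; token-level:
    beta-binomial) over the word grid, and reports the minimum word count by
    both the Monte-Carlo curves and the analytic closed form, flagging when
    they disagree.
    """
    if words_grid is None:
        words_grid = np.arange(10, 101)
    rng = np.random.default_rng(seed)
    whole = simulate_sd_of_mean(1, mu, 0.0, [reference_words], n_draws=n_draws, seed=rng)
    token = simulate_sd_of_mean(n, mu, rho, words_grid, n_draws=n_draws, seed=rng)
    target_sim = float(whole.sd_of_mean[0])
    target_analytic = analytic_sd_of_mean(1, mu, 0.0, reference_words)
    min_sim = min_words_to_match(target_sim, token)
    min_analytic = min_words_to_match(target_analytic, (n, mu, rho))
    return {
        "n": n,
        "mu": mu,
        "rho": rho,
        "reference_words": reference_words,
        "reference_sd_simulated": target_sim,
        "reference_sd_analytic": target_analytic,
        "min_words_simulated": min_sim,
        "min_words_analytic": min_analytic,
        "agree_within_one_word": abs(min_sim - min_analytic) <= 1,
        "n_draws": n_draws,
        "seed": seed,
        "token_curve": token,
    }
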