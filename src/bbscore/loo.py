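"""Pareto-smoothed importance-sampling leave-one-out cross-validation.

Self-contained estimation of the expected log pointwise predictive density
(ELPD) from a posterior pointwise log-likelihood matrix, plus the pairwise
comparison rule: a model is decisively better only when the ELPD difference
exceeds 4 and its (paired) standard error is smaller than the difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["LooResult", "ComparisonResult", "compare", "elpd_loo", "gpd_fit", "psis_smooth"]

PARETO_K_WARN = 0.7
DELTA_ELPD_THRESHOLD = 4.0


def gpd_fit(exceedances: np.ndarray) -> tuple[float, float]:
    """Fit a generalized Pareto tail shape/scale to positive exceedances.

    Profile-likelihood quasi-Bayesian estimator (Zhang & Stephens 2009 style):
    average the profile likelihood over a deterministic grid of the rate
    parameter, then regularize k weakly toward 0.5.  Returns (k, sigma).
    """
    x = np.sort(np.asarray(exceedances, dtype=float))
    n = len(x)
    if n < 5 or x[-1] <= 0:
        raise ValueError("need at least 5 positive exceedances for a tail fit")
    m_grid = 30 + int(np.sqrt(n))
    j = np.arange(1, m_grid + 1)
    quart = x[int(n / 4 + 0.5) - 1]
    b = 1.0 / x[-1] + (1.0 - np.sqrt(m_grid / (j - 0.5))) / (3.0 * quart)
    # profile log-likelihood at each candidate rate b (k(b) is the profile
    # maximizer of the shape given the rate; heavy tails have b < 0, k > 0)
    k_cand = np.mean(np.log1p(-b[:, None] * x), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_lik = n * (np.log(-(b / k_cand)) - k_cand - 1.0)
    log_lik[~np.isfinite(log_lik)] = -np.inf
    w = np.exp(log_lik - log_lik.max())
    b_hat = float(np.sum(b * w) / np.sum(w))
    k_hat = float(np.mean(np.log1p(-b_hat * x)))
    sigma = -k_hat / b_hat if b_hat != 0 else np.inf
    # weak prior pull toward 0.5 stabilizes small tails
    k_hat = k_hat * n / (n + 10.0) + 0.5 * 10.0 / (n + 10.0)
    return k_hat, float(sigma)


def _gpd_quantiles(p: np.ndarray, k: float, sigma: float) -> np.ndarray:
    if abs(k) < 1e-12:
        return -sigma * np.log1p(-p)
    return sigma * np.expm1(-k * np.log1p(-p)) / k


def psis_smooth(log_ratios: np.ndarray) -> tuple[np.ndarray, float]:
    """Smooth one trial's importance ratios; returns (log weights, pareto k).

    The largest M = min(0.2*S, 3*sqrt(S)) ratios are replaced by expected
    order statistics of a generalized Pareto distribution fit to the tail,
    capped at the raw maximum.  With fewer than 5 usable tail points the
    weights fall back to truncated importance sampling and k is reported as
    NaN (not estimable).
    """
    lr = np.asarray(log_ratios, dtype=float)
    if lr.ndim != 1:
        raise ValueError("log_ratios must be one-dimensional")
    S = len(lr)
    lw = lr - lr.max()
    tail_len = int(np.ceil(min(0.2 * S, 3.0 * np.sqrt(S))))
    if tail_len < 5:
        return _truncate(lw), float("nan")
    order = np.argsort(lw, kind="stable")
    tail_idx = order[S - tail_len :]
    cutoff = lw[order[S - tail_len - 1]] if S > tail_len else lw[order[0]]
    exceedances = np.exp(lw[tail_idx]) - np.exp(cutoff)
    if np.count_nonzero(exceedances > 0) < 5:
        return _truncate(lw), float("nan")
    k_hat, sigma = gpd_fit(exceedances[exceedances > 0])
    probs = (np.arange(1, tail_len + 1) - 0.5) / tail_len
    smoothed_tail = np.log(np.exp(cutoff) + _gpd_quantiles(probs, k_hat, sigma))
    smoothed_tail = np.minimum(smoothed_tail, 0.0)  # cap at the raw maximum
    out = lw.copy()
    out[tail_idx] = smoothed_tail  # tail_idx is sorted by weight, as is smoothed_tail
    return out, float(k_hat)


def _truncate(lw: np.ndarray) -> np.ndarray:
    """Truncated importance sampling: cap weights at mean * sqrt(S)."""
    S = len(lw)
    cap = logsumexp(lw) - np.log(S) + 0.5 * np.log(S)
    return np.minimum(lw, cap)


@dataclass
class LooResult:
    """PSIS-LOO summary for one model fit."""

    elpd_loo: float
    elpd_se: float
    p_loo: float
    p_loo_se: float
    pointwise_elpd: np.ndarray = field(repr=False)
    pareto_k: np.ndarray = field(repr=False)
    n_trials: int = 0
    n_draws: int = 0

    @property
    def frac_k_high(self) -> float:
        """Fraction of trials with Pareto k above the reliability threshold."""
        return float(np.mean(~(self.pareto_k <= PARETO_K_WARN)))


def elpd_loo(pointwise_loglik: np.ndarray) -> LooResult:
    """Estimate ELPD by PSIS-LOO from a (draws x trials) log-likelihood matrix.

    Per trial, importance ratios are the inverse likelihoods; the smoothed
    weights yield elpd_i = log of the weighted mean likelihood.  p_loo is the
    summed gap between the in-sample log predictive density and elpd.
    Standard errors are sqrt(T * var(pointwise)).
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise_loglik must be (draws x trials)")
    bad = ~np.all(np.isfinite(ll), axis=0)
    if np.any(bad):
        raise ValueError(f"non-finite log-likelihood in trial column {int(np.flatnonzero(bad)[0])}")
    S, T = ll.shape
    elpd_i = np.empty(T)
    k_i = np.empty(T)
    lpd_i = logsumexp(ll, axis=0) - np.log(S)
    # Trials with byte-identical likelihood columns (same participant and
    # observed count) share one PSIS computation.
    seen: dict[bytes, tuple[float, float]] = {}
    for i in range(T):
        col = ll[:, i]
        key = col.tobytes()
        if key not in seen:
            lw, k = psis_smooth(-col)
            lw = lw - logsumexp(lw)
            seen[key] = (float(logsumexp(lw + col)), k)
        elpd_i[i], k_i[i] = seen[key]
    p_i = lpd_i - elpd_i
    return LooResult(
        elpd_loo=float(elpd_i.sum()),
        elpd_se=float(np.sqrt(T * np.var(elpd_i, ddof=1))) if T > 1 else 0.0,
        p_loo=float(p_i.sum()),
        p_loo_se=float(np.sqrt(T * np.var(p_i, ddof=1))) if T > 1 else 0.0,
        pointwise_elpd=elpd_i,
        pareto_k=k_i,
        n_trials=T,
        n_draws=S,
    )


@dataclass
class ComparisonResult:
    """Models ranked by ELPD with pairwise differences against the best."""

    names: list[str]
    results: dict[str, LooResult]
    delta_elpd: dict[str, float]
    delta_se: dict[str, float]
    decision: dict[str, str]
    best: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.names:
            r = self.results[name]
            rows.append(
                {
                    "model": name,
                    "elpd_loo": r.elpd_loo,
                    "elpd_loo_se": r.elpd_se,
                    "p_loo": r.p_loo,
                    "p_loo_se": r.p_loo_se,
                    "delta_elpd": self.delta_elpd[name],
                    "delta_elpd_se": self.delta_se[name],
                    "decision": self.decision[name],
                    "frac_pareto_k_high": r.frac_k_high,
                }
            )
        return pd.DataFrame(rows)


def compare(results: dict[str, LooResult]) -> ComparisonResult:
    """Rank models and apply the decision rule against the best model.

    The standard error of each difference comes from the paired pointwise
    ELPD differences, so all models must be evaluated on the identical
    trial set.  decision is "better" when the best model beats this one by
    more than 4 ELPD with SE smaller than the difference, else
    "indistinguishable" (the best model itself is labelled "best").
    """
    if not results:
        raise ValueError("need at least one LooResult")
    sizes = {name: r.n_trials for name, r in results.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"models evaluated on different trial counts: {sizes}")
    ranked = sorted(results, key=lambda name: results[name].elpd_loo, reverse=True)
    best = ranked[0]
    delta_elpd: dict[str, float] = {}
    delta_se: dict[str, float] = {}
    decision: dict[str, str] = {}
    for name in ranked:
        diff = results[name].pointwise_elpd - results[best].pointwise_elpd
        delta_elpd[name] = float(diff.sum())
        T = len(diff)
        delta_se[name] = float(np.sqrt(T * np.var(diff, ddof=1))) if T > 1 and name != best else 0.0
        if name == best:
            decision[name] = "best"
        elif abs(delta_elpd[name]) > DELTA_ELPD_THRESHOLD and delta_se[name] < abs(delta_elpd[name]):
            decision[name] = "better"  # the best model is decisively better than this one
        else:
            decision[name] = "indistinguishable"
    return ComparisonResult(
        names=ranked,
        results=dict(results),
        delta_elpd=delta_elpd,
        delta_se=delta_se,
        decision=decision,
        best=best,
    )
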