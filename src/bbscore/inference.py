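"""Bayesian estimation of the four trial-count models.

Model 1: X_tp ~ Binomial(n_t, mu_p)                  (per-participant mu)
Model 2: X_tp ~ BetaBinomial(n_t, mu_p, rho_p)       (both per participant)
Model 3: X_tp ~ BetaBinomial(n_t, mu_p, rho_group)   (shared rho)
Model 4: X_t  ~ BetaBinomial(n_t, mu_group, rho_group)

All probability parameters get Beta(2, 2) priors (configurable).  Point
estimates come from multi-start optimization of the log posterior on a
logit-transformed scale; full posteriors come from a self-contained adaptive
random-walk Metropolis sampler on the same transform (with the Jacobian
correction), vectorized across chains and across conditionally independent
participant blocks.  Trials are compressed to unique
(participant, n, k) rows with multiplicities, which makes every likelihood
evaluation cheap regardless of trial count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, expit, logit

from bbscore.betabinom import _logpmf_arrays, estimate_mu_rho_moments

__all__ = [
    "ModelSpec",
    "PosteriorFit",
    "fit_map",
    "fit_posterior",
    "log_likelihood",
    "log_prior",
]

_RHO_CAP = 1.0 - 1e-6
_TARGET_ACCEPT = 0.3

_VALID_MODELS = {
    ("binomial", "per_participant", "none"): 1,
    ("betabinomial", "per_participant", "per_participant"): 2,
    ("betabinomial", "per_participant", "group"): 3,
    ("betabinomial", "group", "group"): 4,
}

MODEL_NAMES = {
    "binomial": ("binomial", "per_participant", "none"),
    "bb-individual": ("betabinomial", "per_participant", "per_participant"),
    "bb-shared": ("betabinomial", "per_participant", "group"),
    "bb-pooled": ("betabinomial", "group", "group"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which generative model and its parameter-sharing structure."""

    family: str
    mu_scope: str
    rho_scope: str

    def __post_init__(self) -> None:
        key = (self.family, self.mu_scope, self.rho_scope)
        if key not in _VALID_MODELS:
            raise ValueError(
                f"invalid model {key}; valid combinations: {sorted(_VALID_MODELS)}"
            )

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        if name not in MODEL_NAMES:
            raise ValueError(f"unknown model name {name!r}; choose from {sorted(MODEL_NAMES)}")
        return cls(*MODEL_NAMES[name])

    @property
    def name(self) -> str:
        key = (self.family, self.mu_scope, self.rho_scope)
        return next(n for n, k in MODEL_NAMES.items() if k == key)

    @property
    def number(self) -> int:
        return _VALID_MODELS[(self.family, self.mu_scope, self.rho_scope)]


class _Design:
    """Trial table compressed to unique (participant, n, k) rows."""

    def __init__(self, trials: pd.DataFrame):
        required = ["participant_id", "trial_id", "n_tokens", "n_correct"]
        missing = [c for c in required if c not in trials.columns]
        if missing:
            raise ValueError(f"trial table missing columns {missing}")
        self.participants = sorted(trials["participant_id"].astype(str).unique())
        pid_to_idx = {p: i for i, p in enumerate(self.participants)}
        self.p_idx = trials["participant_id"].astype(str).map(pid_to_idx).to_numpy()
        self.n = trials["n_tokens"].to_numpy(dtype=int)
        self.k = trials["n_correct"].to_numpy(dtype=int)
        if np.any((self.k < 0) | (self.k > self.n)):
            raise ValueError("trial table violates 0 <= n_correct <= n_tokens")
        self.n_trials = len(trials)
        self.n_participants = len(self.participants)

        rows = np.column_stack([self.p_idx, self.n, self.k])
        uniq, inverse, counts = np.unique(rows, axis=0, return_inverse=True, return_counts=True)
        self.u_p = uniq[:, 0]
        self.u_n = uniq[:, 1].astype(float)
        self.u_k = uniq[:, 2].astype(float)
        self.u_count = counts.astype(float)
        self.inverse = inverse
        # (R, P) multiplicity matrix for per-participant likelihood sums
        self.part_matrix = np.zeros((len(uniq), self.n_participants))
        self.part_matrix[np.arange(len(uniq)), self.u_p] = self.u_count
        self.tokens_per_participant = np.bincount(
            self.p_idx, weights=self.n, minlength=self.n_participants
        )
        self.trials_per_participant = np.bincount(self.p_idx, minlength=self.n_participants)


class _Layout:
    """Mapping between the flat unconstrained parameter vector and model roles."""

    def __init__(self, model: ModelSpec, design: _Design):
        self.model = model
        self.design = design
        P = design.n_participants
        names: list[str] = []
        if model.mu_scope == "per_participant":
            self.mu_idx = np.arange(P)
            names += [f"mu[{p}]" for p in design.participants]
        else:
            self.mu_idx = np.array([0])
            names += ["mu_group"]
        off = len(names)
        if model.rho_scope == "per_participant":
            self.rho_idx = off + np.arange(P)
            names += [f"rho[{p}]" for p in design.participants]
        elif model.rho_scope == "group":
            self.rho_idx = np.array([off])
            names += ["rho_group"]
        else:
            self.rho_idx = np.array([], dtype=int)
        self.names = names
        self.dim = len(names)
        # Dims updated in conditionally independent per-participant blocks
        # vs. dims shared across participants (sampled with a full-data step).
        if model.mu_scope == "per_participant":
            self.block_mu = self.mu_idx
            self.block_rho = self.rho_idx if model.rho_scope == "per_participant" else None
            self.global_idx = self.rho_idx if model.rho_scope == "group" else np.array([], int)
        else:
            self.block_mu = None
            self.block_rho = None
            self.global_idx = np.concatenate([self.mu_idx, self.rho_idx])

    def row_params(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Natural-scale (mu, rho) per unique design row; z has shape (..., D)."""
        u_p = self.design.u_p
        mu = expit(z[..., self.mu_idx])
        mu_row = mu[..., u_p] if self.model.mu_scope == "per_participant" else mu
        if self.model.rho_scope == "none":
            rho_row = np.zeros(1)
        else:
            rho = np.clip(expit(z[..., self.rho_idx]), 1e-12, _RHO_CAP)
            rho_row = rho[..., u_p] if self.model.rho_scope == "per_participant" else rho
        return mu_row, rho_row

    def loglik_unique(self, z: np.ndarray) -> np.ndarray:
        """Log pmf at every unique row; shape (..., R)."""
        mu_row, rho_row = self.row_params(z)
        return _logpmf_arrays(self.design.u_k, self.design.u_n, mu_row, rho_row)

    def loglik_total(self, z: np.ndarray) -> np.ndarray:
        return self.loglik_unique(z) @ self.design.u_count

    def params_to_dict(self, z: np.ndarray) -> dict:
        mu = expit(z[self.mu_idx])
        out = {"mu": mu if self.model.mu_scope == "per_participant" else float(mu[0])}
        if self.model.rho_scope == "none":
            out["rho"] = None
        else:
            rho = np.clip(expit(z[self.rho_idx]), 0.0, _RHO_CAP)
            out["rho"] = rho if self.model.rho_scope == "per_participant" else float(rho[0])
        return out

    def dict_to_z(self, params: dict) -> np.ndarray:
        z = np.empty(self.dim)
        z[self.mu_idx] = logit(np.clip(np.atleast_1d(params["mu"]), 1e-9, 1 - 1e-9))
        if len(self.rho_idx):
            z[self.rho_idx] = logit(np.clip(np.atleast_1d(params["rho"]), 1e-9, 1 - 1e-9))
        return z


def _check_params(model: ModelSpec, params: dict, n_participants: int) -> tuple[np.ndarray, np.ndarray | None]:
    mu = np.atleast_1d(np.asarray(params["mu"], dtype=float))
    expected = n_participants if model.mu_scope == "per_participant" else 1
    if mu.shape != (expected,):
        raise ValueError(
            f"model {model.name!r} expects {expected} mu parameter(s); got shape {mu.shape}"
        )
    if model.rho_scope == "none":
        if params.get("rho") is not None:
            raise ValueError(f"model {model.name!r} takes no rho parameter")
        return mu, None
    rho = np.atleast_1d(np.asarray(params["rho"], dtype=float))
    expected = n_participants if model.rho_scope == "per_participant" else 1
    if rho.shape != (expected,):
        raise ValueError(
            f"model {model.name!r} expects {expected} rho parameter(s); got shape {rho.shape}"
        )
    return mu, rho


def log_likelihood(
    model: ModelSpec, params: dict, trials: pd.DataFrame
) -> tuple[float, np.ndarray]:
    """Total and per-trial log-likelihood at natural-scale parameters.

    ``params`` maps "mu" to a scalar (group scope) or length-P array ordered
    by sorted participant id, and "rho" likewise (or None for the binomial).
    Pointwise values follow the trial-table row order.
    """
    design = _Design(trials)
    mu, rho = _check_params(model, params, design.n_participants)
    mu_row = mu[design.p_idx] if model.mu_scope == "per_participant" else mu[0]
    if rho is None:
        rho_row = 0.0
    else:
        rho_row = np.clip(rho[design.p_idx] if model.rho_scope == "per_participant" else rho[0], 0.0, _RHO_CAP)
    pointwise = _logpmf_arrays(design.k, design.n, mu_row, rho_row)
    return float(pointwise.sum()), pointwise


def log_prior(model: ModelSpec, params: dict, prior: tuple[float, float] = (2.0, 2.0)) -> float:
    """Sum of Beta(a, b) log densities over every mu and rho parameter.

    Boundary values map to -inf without numerical faults.
    """
    a, b = prior
    values = np.atleast_1d(np.asarray(params["mu"], dtype=float))
    if params.get("rho") is not None:
        values = np.concatenate([values, np.atleast_1d(np.asarray(params["rho"], dtype=float))])
    if np.any((values < 0.0) | (values > 1.0)):
        raise ValueError("prior parameters must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        logpdf = (a - 1.0) * np.log(values) + (b - 1.0) * np.log1p(-values) - betaln(a, b)
    return float(logpdf.sum())


def _log_sigmoid(z: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -z)


def _logprior_natural_z(z: np.ndarray, prior: tuple[float, float]) -> np.ndarray:
    """Per-dimension Beta(a, b) log density of expit(z) (no Jacobian) — the
    MAP objective's prior term, finite for all finite z."""
    a, b = prior
    return (a - 1.0) * _log_sigmoid(z) + (b - 1.0) * _log_sigmoid(-z) - betaln(a, b)


def _logprior_sampling_z(z: np.ndarray, prior: tuple[float, float]) -> np.ndarray:
    """Per-dimension log density on the logit scale: Beta(a, b) prior plus
    the Jacobian of the logit transform."""
    a, b = prior
    return a * _log_sigmoid(z) + b * _log_sigmoid(-z) - betaln(a, b)


def _initial_guess(layout: _Layout) -> np.ndarray:
    """Empirical start: prior-smoothed token accuracy and method-of-moments rho."""
    design = layout.design
    z = np.zeros(layout.dim)
    correct = np.bincount(design.p_idx, weights=design.k, minlength=design.n_participants)
    tokens = design.tokens_per_participant
    mu0 = (correct + 1.0) / (tokens + 2.0)
    if layout.model.mu_scope == "group":
        mu0 = np.array([(correct.sum() + 1.0) / (tokens.sum() + 2.0)])
    z[layout.mu_idx] = logit(np.clip(mu0, 1e-3, 1 - 1e-3))
    if len(layout.rho_idx):
        rhos = []
        for p in range(design.n_participants):
            mask = design.p_idx == p
            ns = design.n[mask]
            if len(np.unique(ns)) == 1:
                _, r = estimate_mu_rho_moments(design.k[mask], int(ns[0]))
            else:
                r = 0.3
            rhos.append(r)
        rho0 = np.asarray(rhos)
        if layout.model.rho_scope == "group":
            rho0 = np.array([np.median(rho0)])
        z[layout.rho_idx] = logit(np.clip(rho0, 0.02, 0.95))
    return z


def fit_map(
    model: ModelSpec,
    trials: pd.DataFrame,
    seed: int = 0,
    n_starts: int = 8,
    prior: tuple[float, float] = (2.0, 2.0),
) -> dict:
    """Multi-start MAP estimate of the log posterior (natural-scale mode).

    The objective is optimized on the logit transform without a Jacobian
    term, so the returned point is the mode of the posterior density in
    (mu, rho) — e.g. a Beta(2,2)-prior binomial participant lands exactly on
    (successes + 1) / (total + 2).  Raises after ``n_starts`` failed
    optimizations, reporting the best point found.
    """
    design = _Design(trials)
    layout = _Layout(model, design)
    rng = np.random.default_rng([seed, 7])

    def objective(z: np.ndarray) -> float:
        return -(layout.loglik_total(z) + _logprior_natural_z(z, prior).sum())

    starts = [_initial_guess(layout)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(logit(np.clip(rng.beta(2.0, 2.0, size=layout.dim), 1e-3, 1 - 1e-3)))

    best = None
    n_failed = 0
    for z0 in starts:
        res = minimize(objective, z0, method="L-BFGS-B")
        if not res.success and not np.isfinite(res.fun):
            n_failed += 1
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None:
        raise RuntimeError(f"MAP optimization failed in all {n_starts} starts for {model.name}")
    out = layout.params_to_dict(best.x)
    out["log_posterior"] = float(-best.fun)
    out["param_names"] = layout.names
    out["z"] = best.x
    out["n_failed_starts"] = n_failed
    return out


@dataclass
class PosteriorFit:
    """Posterior draws, MAP estimates and diagnostics for one model fit."""

    model: ModelSpec
    param_names: list[str]
    map_estimates: dict
    draws: np.ndarray  # (n_draws_total, n_params), natural scale, chain-major
    draws_by_chain: np.ndarray = field(repr=False)  # (chains, draws, n_params)
    diagnostics: dict = field(default_factory=dict)
    pointwise_loglik: np.ndarray | None = field(default=None, repr=False)  # (draws, trials)
    seed: int = 0

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def summary(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "parameter": self.param_names,
                "mean": self.draws.mean(axis=0),
                "sd": self.draws.std(axis=0, ddof=1),
                "q2.5": np.percentile(self.draws, 2.5, axis=0),
                "q97.5": np.percentile(self.draws, 97.5, axis=0),
                "rhat": self.diagnostics.get("rhat"),
                "ess": self.diagnostics.get("ess"),
            }
        )
        return frame


def _diagnostics(draws_by_chain: np.ndarray, names: list[str]) -> dict:
    """Split-Rhat and bulk ESS per parameter (via arviz)."""
    import arviz as az

    data = {name: draws_by_chain[:, :, j] for j, name in enumerate(names)}
    rhat_ds = az.rhat(az.convert_to_dataset(data), method="split")
    ess_ds = az.ess(az.convert_to_dataset(data), method="bulk")
    rhat = np.array([float(rhat_ds[name]) for name in names])
    ess = np.array([float(ess_ds[name]) for name in names])
    return {
        "rhat": rhat,
        "ess": ess,
        "max_rhat": float(np.nanmax(rhat)),
        "min_ess": float(np.nanmin(ess)),
        "converged": bool(np.all(rhat < 1.01) and np.all(ess > 400)),
        "hard_fail": bool(np.any(rhat >= 1.05)),
    }


def fit_posterior(
    model: ModelSpec,
    trials: pd.DataFrame,
    n_chains: int = 4,
    n_iterations: int = 2500,
    warmup: int = 1000,
    seed: int = 0,
    prior: tuple[float, float] = (2.0, 2.0),
    compute_pointwise: bool = True,
    map_n_starts: int = 4,
) -> PosteriorFit:
    """Adaptive random-walk Metropolis on the logit scale (with Jacobian).

    Chains start from a jittered MAP.  Per-participant parameter blocks are
    conditionally independent given any shared parameter, so all blocks are
    proposed and accepted simultaneously each sweep; shared parameters get a
    separate full-data update.  Per-block proposal scales adapt toward ~0.3
    acceptance during warmup and freeze afterwards.

    A convergence summary (split-Rhat, bulk ESS) is attached to
    ``diagnostics``; Rhat >= 1.05 on any parameter sets the ``hard_fail``
    flag, but the fit is still returned.
    """
    if warmup >= n_iterations:
        raise ValueError("warmup must be smaller than n_iterations")
    design = _Design(trials)
    layout = _Layout(model, design)
    rng = np.random.default_rng([seed, 11])
    C, D = n_chains, layout.dim
    map_fit = fit_map(model, trials, seed=seed, n_starts=map_n_starts, prior=prior)
    z = np.tile(map_fit["z"], (C, 1)) + 0.1 * rng.standard_normal((C, D))

    # Rough curvature-based initial proposal scales, refined by adaptation.
    scales = np.empty((C, D))
    if layout.block_mu is not None:
        scales[:, layout.block_mu] = 2.5 / np.sqrt(np.maximum(design.tokens_per_participant, 4))
        if layout.block_rho is not None:
            scales[:, layout.block_rho] = 2.5 / np.sqrt(
                np.maximum(design.trials_per_participant, 4)
            )
    else:
        scales[:, layout.mu_idx] = 2.5 / np.sqrt(max(design.tokens_per_participant.sum(), 4))
    if model.rho_scope == "group":
        scales[:, layout.rho_idx] = 2.5 / np.sqrt(max(design.n_trials, 4))
    scales = np.clip(scales, 0.02, 2.0)

    has_blocks = layout.block_mu is not None
    g_idx = layout.global_idx
    M = design.part_matrix

    cur_prior = _logprior_sampling_z(z, prior)  # (C, D)
    cur_partlik = layout.loglik_unique(z) @ M  # (C, P)
    cur_total = cur_partlik.sum(axis=1)

    n_keep = n_iterations - warmup
    kept = np.empty((C, n_keep, D))
    acc_block_sum = 0.0
    acc_global_sum = 0.0

    for t in range(n_iterations):
        if has_blocks:
            bdims = layout.block_mu if layout.block_rho is None else np.concatenate(
                [layout.block_mu, layout.block_rho]
            )
            prop_z = z.copy()
            prop_z[:, bdims] = z[:, bdims] + scales[:, bdims] * rng.standard_normal(
                (C, len(bdims))
            )
            prop_prior = _logprior_sampling_z(prop_z, prior)
            prop_partlik = layout.loglik_unique(prop_z) @ M
            delta = prop_partlik - cur_partlik
            delta += prop_prior[:, layout.block_mu] - cur_prior[:, layout.block_mu]
            if layout.block_rho is not None:
                delta += prop_prior[:, layout.block_rho] - cur_prior[:, layout.block_rho]
            accept = np.log(rng.uniform(size=delta.shape)) < delta  # (C, P)
            z[:, layout.block_mu] = np.where(accept, prop_z[:, layout.block_mu], z[:, layout.block_mu])
            cur_prior[:, layout.block_mu] = np.where(
                accept, prop_prior[:, layout.block_mu], cur_prior[:, layout.block_mu]
            )
            if layout.block_rho is not None:
                z[:, layout.block_rho] = np.where(
                    accept, prop_z[:, layout.block_rho], z[:, layout.block_rho]
                )
                cur_prior[:, layout.block_rho] = np.where(
                    accept, prop_prior[:, layout.block_rho], cur_prior[:, layout.block_rho]
                )
            cur_partlik = np.where(accept, prop_partlik, cur_partlik)
            cur_total = cur_partlik.sum(axis=1)
            acc_rate_block = accept.mean()
            acc_block_sum += acc_rate_block if t >= warmup else 0.0
            if t < warmup:
                gamma = (t + 1.0) ** -0.6
                mult = np.exp(gamma * (accept - _TARGET_ACCEPT))
                scales[:, layout.block_mu] *= mult
                if layout.block_rho is not None:
                    scales[:, layout.block_rho] *= mult

        if len(g_idx):
            prop_z = z.copy()
            prop_z[:, g_idx] = z[:, g_idx] + scales[:, g_idx] * rng.standard_normal(
                (C, len(g_idx))
            )
            prop_prior = _logprior_sampling_z(prop_z, prior)
            prop_partlik = layout.loglik_unique(prop_z) @ M
            prop_total = prop_partlik.sum(axis=1)
            delta = (
                prop_total
                - cur_total
                + prop_prior[:, g_idx].sum(axis=1)
                - cur_prior[:, g_idx].sum(axis=1)
            )
            accept = np.log(rng.uniform(size=C)) < delta  # (C,)
            z[accept] = prop_z[accept]
            cur_prior[accept] = prop_prior[accept]
            cur_partlik[accept] = prop_partlik[accept]
            cur_total[accept] = prop_total[accept]
            acc_global_sum += accept.mean() if t >= warmup else 0.0
            if t < warmup:
                gamma = (t + 1.0) ** -0.6
                scales[:, g_idx] *= np.exp(gamma * (accept[:, None] - _TARGET_ACCEPT))

        if t >= warmup:
            kept[:, t - warmup, :] = z

    draws_by_chain = expit(kept)
    if len(layout.rho_idx):
        draws_by_chain[:, :, layout.rho_idx] = np.clip(
            draws_by_chain[:, :, layout.rho_idx], 0.0, _RHO_CAP
        )
    draws = draws_by_chain.reshape(C * n_keep, D)

    diagnostics = _diagnostics(draws_by_chain, layout.names)
    diagnostics["accept_rate_blocks"] = float(acc_block_sum / n_keep) if has_blocks else None
    diagnostics["accept_rate_global"] = float(acc_global_sum / n_keep) if len(g_idx) else None

    pointwise = None
    if compute_pointwise:
        kept_flat = kept.reshape(C * n_keep, D)
        pointwise = np.empty((C * n_keep, design.n_trials))
        for start in range(0, C * n_keep, 512):
            chunk = kept_flat[start : start + 512]
            L_u = layout.loglik_unique(chunk)  # (chunk, R)
            pointwise[start : start + len(chunk)] = L_u[:, design.inverse]

    return PosteriorFit(
        model=model,
        param_names=layout.names,
        map_estimates={k: map_fit[k] for k in ("mu", "rho", "log_posterior")},
        draws=draws,
        draws_by_chain=draws_by_chain,
        diagnostics=diagnostics,
        pointwise_loglik=pointwise,
        seed=seed,
    )
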