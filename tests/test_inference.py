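import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bbscore import betabinom, inference, simulate
from bbscore.inference import ModelSpec, fit_map, fit_posterior, log_likelihood, log_prior

M1 = ModelSpec.from_name("binomial")
M2 = ModelSpec.from_name("bb-individual")
M3 = ModelSpec.from_name("bb-shared")
M4 = ModelSpec.from_name("bb-pooled")


def _one_participant(counts, n=3, pid="A"):
    return pd.DataFrame(
        {
            "participant_id": pid,
            "trial_id": [f"t{i:03d}" for i in range(len(counts))],
            "n_tokens": n,
            "n_correct": counts,
        }
    )


class TestModelSpec:
    def test_four_valid_models(self):
        assert [M1.number, M2.number, M3.number, M4.number] == [1, 2, 3, 4]

    @pytest.mark.parametrize(
        "combo",
        [("binomial", "per_participant", "group"),
         ("binomial", "group", "none"),
         ("betabinomial", "group", "per_participant"),
         ("betabinomial", "per_participant", "none")],
    )
    def test_invalid_combinations(self, combo):
        with pytest.raises(ValueError):
            ModelSpec(*combo)

    def test_name_round_trip(self):
        for name in inference.MODEL_NAMES:
            assert ModelSpec.from_name(name).name == name


class TestLogLikelihood:
    def test_single_binomial_trial(self):
        trials = _one_participant([1])
        total, pointwise = log_likelihood(M1, {"mu": [0.5], "rho": None}, trials)
        assert total == pytest.approx(np.log(0.375))
        assert pointwise == pytest.approx([np.log(0.375)])

    def test_shared_rho_limit_reproduces_binomial(self, small_cohort):
        _, _, trials = small_cohort
        P = trials["participant_id"].nunique()
        mu = np.linspace(0.3, 0.8, P)
        _, pw_binom = log_likelihood(M1, {"mu": mu, "rho": None}, trials)
        _, pw_bb = log_likelihood(M3, {"mu": mu, "rho": 1e-9}, trials)
        assert np.max(np.abs(pw_binom - pw_bb)) < 1e-6

    def test_total_matches_per_trial_oracle(self, small_cohort):
        _, _, trials = small_cohort
        P = trials["participant_id"].nunique()
        participants = sorted(trials["participant_id"].unique())
        mu = np.linspace(0.35, 0.75, P)
        rho = np.linspace(0.1, 0.5, P)
        total, pointwise = log_likelihood(M2, {"mu": mu, "rho": rho}, trials)
        # independent oracle: per-trial pmf recomputed one row at a time
        oracle = []
        for row in trials.itertuples(index=False):
            i = participants.index(row.participant_id)
            params = betabinom.BetaBinomialParams(row.n_tokens, mu[i], rho[i])
            oracle.append(float(betabinom.logpmf(row.n_correct, params)))
        assert np.allclose(pointwise, oracle, atol=1e-10)
        assert total == pytest.approx(sum(oracle))

    def test_shape_mismatch(self, small_cohort):
        _, _, trials = small_cohort
        with pytest.raises(ValueError, match="mu"):
            log_likelihood(M1, {"mu": [0.5, 0.5], "rho": None}, trials)


class TestLogPrior:
    def test_beta22_at_half(self):
        assert log_prior(M4, {"mu": 0.5, "rho": 0.5}) == pytest.approx(2 * np.log(1.5))

    def test_beta22_at_quarter(self):
        assert log_prior(M1, {"mu": [0.25], "rho": None}) == pytest.approx(np.log(1.125))

    def test_boundary_is_neg_inf(self):
        assert log_prior(M1, {"mu": [0.0], "rho": None}) == -np.inf
        assert log_prior(M1, {"mu": [1.0], "rho": None}) == -np.inf

    def test_sums_over_all_parameters(self):
        value = log_prior(M2, {"mu": [0.5, 0.5], "rho": [0.25, 0.5]})
        assert value == pytest.approx(3 * np.log(1.5) + np.log(1.125))


class TestFitMap:
    def test_conjugate_closed_form(self):
        # 300 trials of n=3 with 450/900 tokens correct; Beta(2,2)-prior
        # binomial MAP is (successes + 1) / (total + 2)
        counts = [3] * 50 + [2] * 100 + [1] * 100 + [0] * 50
        fit = fit_map(M1, _one_participant(counts), seed=0)
        assert fit["mu"][0] == pytest.approx(451 / 902, abs=1e-6)

    def test_local_maximum_no_uphill_neighbor(self, small_cohort):
        _, _, trials = small_cohort
        fit = fit_map(M3, trials, seed=0, n_starts=4)

        def objective(mu, rho):
            ll, _ = log_likelihood(M3, {"mu": mu, "rho": rho}, trials)
            return ll + log_prior(M3, {"mu": mu, "rho": rho})

        base = objective(fit["mu"], fit["rho"])
        eps = 1e-4
        for j in range(len(fit["mu"])):
            for sign in (-1, 1):
                mu = fit["mu"].copy()
                mu[j] = np.clip(mu[j] + sign * eps, 1e-6, 1 - 1e-6)
                assert objective(mu, fit["rho"]) <= base + 1e-7
        for sign in (-1, 1):
            assert objective(fit["mu"], fit["rho"] + sign * eps) <= base + 1e-7

    def test_parameter_recovery_shared_rho(self, word_cohort):
        _, params, trials = word_cohort
        fit = fit_map(M3, trials, seed=0, n_starts=4)
        assert fit["rho"] == pytest.approx(0.35, abs=0.05)
        truth = np.array([p.mu_p for p in params])
        assert np.max(np.abs(fit["mu"] - truth)) < 0.06

    def test_degenerate_all_correct(self):
        fit = fit_map(M1, _one_participant([3] * 40), seed=0, n_starts=2)
        # conjugate mode (successes+1)/(total+2) = 121/122
        assert fit["mu"][0] == pytest.approx(121 / 122, abs=1e-4)
        assert np.isfinite(fit["log_posterior"])

    def test_model_nesting(self, small_cohort):
        # Model 2 generalizes Model 3 generalizes Model 4
        _, _, trials = small_cohort
        fits = {m: fit_map(m, trials, seed=1, n_starts=4) for m in (M2, M3, M4)}
        lp = {m: fits[m]["log_posterior"] for m in fits}
        assert lp[M2] >= lp[M3] - 1e-4
        assert lp[M3] >= lp[M4] - 1e-4

        def loglik_at(m):
            fit = fits[m]
            return log_likelihood(m, {"mu": fit["mu"], "rho": fit["rho"]}, trials)[0]

        assert loglik_at(M2) >= loglik_at(M3) - 1e-4
        assert loglik_at(M3) >= loglik_at(M4) - 1e-4

    def test_prior_sensitivity(self, small_cohort):
        _, _, trials = small_cohort
        fit_beta22 = fit_map(M3, trials, seed=0, n_starts=4)
        fit_flat = fit_map(M3, trials, seed=0, n_starts=4, prior=(1.0, 1.0))
        assert abs(fit_beta22["rho"] - fit_flat["rho"]) < 0.02
        assert np.max(np.abs(fit_beta22["mu"] - fit_flat["mu"])) < 0.02


class TestFitPosterior:
    def test_conjugate_beta_posterior(self, single_participant_trials):
        # 20/60 tokens correct under Beta(2,2): posterior is Beta(22, 42)
        fit = fit_posterior(M1, single_participant_trials, seed=1)
        draws = fit.draws[:, 0]
        exact_mean = 22 / 64
        exact_sd = np.sqrt(22 * 42 / (64**2 * 65))
        assert draws.mean() == pytest.approx(exact_mean, abs=0.01)
        assert draws.std(ddof=1) == pytest.approx(exact_sd, rel=0.15)
        # distributional agreement with the closed form
        ks = stats.kstest(draws[::10], stats.beta(22, 42).cdf)
        assert ks.statistic < 0.1

    def test_default_config_convergence(self, single_participant_trials):
        fit = fit_posterior(M1, single_participant_trials, seed=1)
        assert fit.diagnostics["max_rhat"] < 1.01
        assert fit.diagnostics["min_ess"] > 400
        assert fit.diagnostics["converged"]
        assert not fit.diagnostics["hard_fail"]

    def test_determinism(self, single_participant_trials):
        a = fit_posterior(M1, single_participant_trials, n_chains=2, n_iterations=300,
                          warmup=150, seed=7)
        b = fit_posterior(M1, single_participant_trials, n_chains=2, n_iterations=300,
                          warmup=150, seed=7)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.pointwise_loglik, b.pointwise_loglik)

    def test_pointwise_loglik_shape_and_values(self, small_cohort):
        _, _, trials = small_cohort
        fit = fit_posterior(M3, trials, n_chains=2, n_iterations=400, warmup=200, seed=3)
        assert fit.pointwise_loglik.shape == (fit.n_draws, len(trials))
        # spot-check one draw against the likelihood operation
        j = 17
        P = trials["participant_id"].nunique()
        params = {"mu": fit.draws[j, :P], "rho": float(fit.draws[j, P])}
        _, pointwise = log_likelihood(M3, params, trials)
        assert np.allclose(fit.pointwise_loglik[j], pointwise, atol=1e-10)

    def test_map_mode_agreement(self, word_cohort):
        # KDE mode of the rho_group draws close to the MAP point
        _, _, trials = word_cohort
        fit = fit_posterior(M3, trials, n_chains=2, n_iterations=800, warmup=400, seed=5,
                            compute_pointwise=False)
        rho_draws = fit.draws[:, -1]
        kde = stats.gaussian_kde(rho_draws)
        grid = np.linspace(rho_draws.min(), rho_draws.max(), 400)
        mode = grid[np.argmax(kde(grid))]
        assert abs(mode - fit.map_estimates["rho"]) < 0.02

    def test_shared_rho_interval_coverage(self):
        # 95% credible interval for rho_group covers the generating value
        covered = 0
        for seed in range(20):
            spec = simulate.CohortSpec(
                n_participants=8, word_trials=60, sentence_trials=0, rho=0.35, seed=300 + seed
            )
            trials = simulate.generate_trials(simulate.generate_cohort(spec), spec)
            fit = fit_posterior(M3, trials, n_chains=2, n_iterations=700, warmup=350,
                                seed=seed, compute_pointwise=False)
            lo, hi = np.percentile(fit.draws[:, -1], [2.5, 97.5])
            covered += lo <= 0.35 <= hi
        assert covered >= 18

    def test_warmup_validation(self, single_participant_trials):
        with pytest.raises(ValueError, match="warmup"):
            fit_posterior(M1, single_participant_trials, n_iterations=100, warmup=100)
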