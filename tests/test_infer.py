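"""Likelihood, priors, sampler correctness and posterior summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from metasym import (
    HalfNormal,
    MCMCConfig,
    ModelSpec,
    Normal,
    PriorSpec,
    PrevalenceSeries,
    Uniform,
    adaptive_metropolis,
    diagnostics,
    fit_mcmc,
    generate_single_release_dataset,
    log_likelihood,
    log_prior,
    posterior_summary,
    predict_fit,
)


def _one_obs_series(count, n=50, time=2.0):
    df = pd.DataFrame({"replicate": [0], "time": [time], "class": ["infected"],
                       "count": [count], "n_assayed": [n]})
    s = PrevalenceSeries(df)
    s.metadata = {"initial_conditions": [[n - 1, 1, 0, 0]]}
    return s


# ---------------------------------------------------------------------------
# likelihood


def test_certain_event_has_zero_loglik():
    df = pd.DataFrame({"replicate": [0], "time": [0.0], "class": ["infected"],
                       "count": [50], "n_assayed": [50]})
    s = PrevalenceSeries(df)
    s.metadata = {"initial_conditions": [[0, 50, 0, 0]]}  # fraction 1 at t = 0
    total, pw = log_likelihood(s, ModelSpec("si_single"), {"beta": 0.5})
    assert total == pytest.approx(0.0, abs=1e-12)


def test_binomial_loglik_against_lgamma_arithmetic():
    """k = 25 of n = 50 at fraction 1/2: log C(50,25) + 50 log(1/2)."""
    df = pd.DataFrame({"replicate": [0], "time": [0.0], "class": ["infected"],
                       "count": [25], "n_assayed": [50]})
    s = PrevalenceSeries(df)
    s.metadata = {"initial_conditions": [[25, 25, 0, 0]]}  # fraction 0.5 at t=0
    total, _ = log_likelihood(s, ModelSpec("si_single"), {"beta": 0.3})
    expected = (math.lgamma(51) - 2 * math.lgamma(26)) + 50 * math.log(0.5)
    assert total == pytest.approx(expected, rel=1e-10)


def test_impossible_datum_flags_minus_infinity():
    df = pd.DataFrame({"replicate": [0], "time": [0.0], "class": ["infected"],
                       "count": [1], "n_assayed": [50]})
    s = PrevalenceSeries(df)
    s.metadata = {"initial_conditions": [[50, 0, 0, 0]]}  # fraction 0, k = 1
    total, pw = log_likelihood(s, ModelSpec("si_single"), {"beta": 0.5})
    assert total == -np.inf
    assert pw[0] == -np.inf


def test_loglik_decomposes_over_observations():
    series = generate_single_release_dataset(beta=0.5, seed=1)
    total, pw = log_likelihood(series, ModelSpec("si_single"), {"beta": 0.5})
    assert pw.shape == (33,)  # 3 replicates x 11 sampling times
    assert total == pytest.approx(pw.sum())
    assert np.isfinite(total)


# ---------------------------------------------------------------------------
# priors


def test_half_normal_density_at_mode():
    prior = PriorSpec()
    lp = log_prior({"beta": 0.0}, prior)
    assert lp == pytest.approx(math.log(2) - math.log(5 * math.sqrt(2 * math.pi)))


def test_negative_rate_outside_support():
    assert log_prior({"beta": -0.1}, PriorSpec()) == -np.inf


def test_joint_prior_is_sum_of_marginals():
    prior = PriorSpec(priors={"a": HalfNormal(2.0), "b": Normal(1.0, 3.0)})
    joint = log_prior({"a": 0.4, "b": -0.2}, prior)
    assert joint == pytest.approx(HalfNormal(2.0).logpdf(0.4) + Normal(1.0, 3.0).logpdf(-0.2))


def test_unit_interval_parameters_default_to_uniform_prior():
    assert isinstance(PriorSpec().get("phi"), Uniform)
    assert log_prior({"phi": 1.5}, PriorSpec()) == -np.inf


# ---------------------------------------------------------------------------
# sampler core on a conjugate toy


def test_adaptive_metropolis_recovers_beta_binomial_posterior():
    """Binomial k=12 of n=30 with Beta(2,2) prior: posterior is Beta(14, 20).
    The sampler (run on the logit scale with its Jacobian) must reproduce the
    analytic moments within Monte-Carlo error."""
    from scipy.special import expit

    k, n, a, b = 12, 30, 2.0, 2.0

    def logpost(z):
        p = expit(z[0])
        logjac = math.log(p) + math.log1p(-p)
        lp = (k + a - 1) * math.log(p) + (n - k + b - 1) * math.log1p(-p)
        return lp + logjac, None

    cfg = MCMCConfig(n_chains=1, n_warmup=1000, n_iterations=21000, thin=2, seed=0)
    rng = np.random.default_rng(1)
    kept, _, rate = adaptive_metropolis(logpost, np.array([0.0]), cfg, rng)
    draws = expit(kept[:, 0])
    post_a, post_b = k + a, n - k + b
    exact_mean = post_a / (post_a + post_b)
    exact_sd = math.sqrt(post_a * post_b / ((post_a + post_b) ** 2 * (post_a + post_b + 1)))
    ess_floor = draws.size / 20  # conservative for a thinned RW chain
    assert abs(draws.mean() - exact_mean) < 4 * exact_sd / math.sqrt(ess_floor)
    assert draws.std(ddof=1) == pytest.approx(exact_sd, rel=0.1)
    assert 0.2 < rate < 0.7


def test_mcmc_posterior_matches_exact_grid_posterior():
    """End-to-end sampler check: for one release-experiment dataset the MCMC
    quantiles must match the posterior computed by direct numerical
    integration over a fine transmission-rate grid."""
    from scipy.stats import binom as binom_dist
    from scipy.integrate import solve_ivp

    series = generate_single_release_dataset(beta=0.5, seed=0)
    fit = fit_mcmc(series, ModelSpec("si_single"),
                   config=MCMCConfig(n_chains=2, n_warmup=500, n_iterations=3000,
                                     thin=1, seed=0))
    got = posterior_summary(fit).loc["beta"]

    grid = np.linspace(0.3, 0.8, 1001)
    times = np.arange(0, 21, 2.0)
    lp = np.array([HalfNormal(5.0).logpdf(b) for b in grid])
    for j, b in enumerate(grid):
        sol = solve_ivp(lambda t, y: b * y * (50 - y) / 50, (0, 20), [1.0],
                        t_eval=times, rtol=1e-10, atol=1e-12)
        p = np.clip(sol.y[0] / 50, 1e-12, 1 - 1e-12)
        for _, row in series.data.iterrows():
            lp[j] += binom_dist.logpmf(row["count"], row["n_assayed"],
                                       p[int(row["time"] / 2)])
    w = np.exp(lp - lp.max())
    cdf = np.cumsum(w) / w.sum()
    exact = np.interp([0.025, 0.5, 0.975], cdf, grid)
    np.testing.assert_allclose(got.to_numpy(), exact, atol=0.004)


def test_empty_data_recovers_prior():
    series = PrevalenceSeries(pd.DataFrame(columns=["replicate", "time", "class",
                                                    "count", "n_assayed"]))
    fit = fit_mcmc(series, ModelSpec("si_single"),
                   config=MCMCConfig(n_chains=2, n_warmup=1000, n_iterations=9000,
                                     thin=2, seed=4))
    draws = fit.pooled("beta")
    # half-Normal(0, 5): median 5 * Phi^-1(0.75) = 3.372
    assert np.median(draws) == pytest.approx(5 * 0.674489, abs=0.45)
    assert any(f.startswith("wide_posterior") for f in fit.flags)


def test_posterior_narrows_with_more_assays():
    widths = []
    for n_assayed in (20, 200, 2000):
        series = generate_single_release_dataset(beta=0.5, seed=9, n_assayed=n_assayed)
        fit = fit_mcmc(series, ModelSpec("si_single"),
                       config=MCMCConfig(n_chains=2, n_warmup=400, n_iterations=1400,
                                         thin=1, seed=9))
        lo, _, hi = posterior_summary(fit).loc["beta"]
        widths.append(hi - lo)
    assert widths[0] > widths[1] > widths[2]


def test_large_data_consistency():
    """Dense, heavily assayed data pin the transmission rate to within 2%."""
    series = generate_single_release_dataset(beta=0.5, seed=2, n_assayed=5000,
                                             sampling_interval=1.0)
    fit = fit_mcmc(series, ModelSpec("si_single"),
                   config=MCMCConfig(n_chains=2, n_warmup=500, n_iterations=2000,
                                     thin=1, seed=2))
    med = posterior_summary(fit).loc["beta", "q50"]
    assert abs(med - 0.5) / 0.5 < 0.02


# ---------------------------------------------------------------------------
# summaries and diagnostics


def test_posterior_summary_degenerate_sample():
    fit = _fake_fit(np.full((2, 10), 3.3))
    s = posterior_summary(fit)
    assert (s.loc["beta"] == 3.3).all()


def test_posterior_summary_normal_quantile():
    rng = np.random.default_rng(0)
    fit = _fake_fit(rng.standard_normal((1, 10000)))
    s = posterior_summary(fit)
    assert s.loc["beta", "q97.5"] == pytest.approx(1.96, abs=0.05)


def _fake_fit(arr):
    from metasym.infer import FitResult

    C, K = arr.shape
    return FitResult(
        draws={"beta": arr},
        log_lik=np.zeros((C, K, 1)),
        spec=ModelSpec("si_single"),
        prior=PriorSpec(),
        config=MCMCConfig(n_chains=C, n_warmup=0, n_iterations=K, thin=1),
        data_fingerprint="x",
    )


def test_rhat_one_for_identical_chains():
    rng = np.random.default_rng(3)
    chain = rng.standard_normal(2000)
    fit = _fake_fit(np.stack([chain, chain]))
    d = diagnostics(fit)
    assert d.loc["beta", "rhat"] == pytest.approx(1.0, abs=0.01)


def test_rhat_and_ess_for_iid_chains():
    rng = np.random.default_rng(4)
    fit = _fake_fit(rng.standard_normal((4, 2000)))
    d = diagnostics(fit)
    assert d.loc["beta", "rhat"] < 1.01
    assert d.loc["beta", "ess"] == pytest.approx(8000, rel=0.1)


def test_single_chain_rhat_reported_absent():
    rng = np.random.default_rng(5)
    fit = _fake_fit(rng.standard_normal((1, 500)))
    assert np.isnan(diagnostics(fit).loc["beta", "rhat"])


def test_predict_fit_band_contains_initial_fraction():
    series = generate_single_release_dataset(beta=0.5, seed=1)
    fit = fit_mcmc(series, ModelSpec("si_single"),
                   config=MCMCConfig(n_chains=1, n_warmup=300, n_iterations=800,
                                     thin=1, seed=1))
    pred = predict_fit(fit, times=np.arange(0, 21, 2.0), max_draws=50)
    # at t = 0 the fraction is I0/N for every draw: the band collapses to 0.02
    for q in pred["quantiles"].values():
        assert q[0, 0] == pytest.approx(0.02, abs=1e-9)
    assert pred["n_failed"] == 0


def test_fit_requires_initial_conditions_metadata():
    df = pd.DataFrame({"replicate": [0], "time": [0.0], "class": ["infected"],
                       "count": [1], "n_assayed": [50]})
    s = PrevalenceSeries(df)
    with pytest.raises(ValueError, match="initial_conditions"):
        log_likelihood(s, ModelSpec("si_single"), {"beta": 0.5})


def test_fit_result_round_trip(tmp_path):
    series = generate_single_release_dataset(beta=0.5, seed=1)
    fit = fit_mcmc(series, ModelSpec("si_single"),
                   config=MCMCConfig(n_chains=2, n_warmup=100, n_iterations=300,
                                     thin=2, seed=1))
    fit.save(tmp_path / "fit")
    from metasym import FitResult

    back = FitResult.load(tmp_path / "fit")
    np.testing.assert_allclose(back.draws["beta"], fit.draws["beta"])
    np.testing.assert_allclose(back.log_lik, fit.log_lik)
    assert back.data_fingerprint == fit.data_fingerprint


def test_mcmc_config_validation():
    with pytest.raises(ValueError):
        MCMCConfig(n_warmup=10, n_iterations=5)
    with pytest.raises(ValueError):
        MCMCConfig(thin=0)
    assert MCMCConfig().n_kept == 1000  # (5000 - 2000) // 3


def test_model_spec_requires_full_parameter_cover():
    with pytest.raises(ValueError, match="cover"):
        ModelSpec("experiment_two_symbiont", free=("beta_A",))
    spec = ModelSpec("experiment_two_symbiont", free=("beta_A", "beta_B"),
                     fixed={"q": 1.0, "psi": 1.0})
    assert spec.model_params({"beta_A": 0.5, "beta_B": 0.3}).symbiont.q == 1.0
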