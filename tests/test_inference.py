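"""MCMC correctness: log-joint arithmetic, conjugate closed-form oracle,
determinism, convergence, and parameter recovery on a known truth."""

import math

import numpy as np
import pytest
from scipy import stats

from painprior.inference import (ConvergenceError, FitResult, HyperPriors,
                                 McmcConfig, extract_observer, fit_mcmc,
                                 fit_study, log_joint, split_rhat)
from painprior.observer import GaussianBelief, ObserverParams, fuse
from painprior.psychophys import default_map, sensation_mean

MAP = default_map()
HP = HyperPriors()


def _hyper_logpdf(mu, sig, sig_s, hp=HP):
    lp = stats.norm.logpdf(mu, hp.mu_prior_location, hp.mu_prior_scale)
    lp += stats.halfnorm.logpdf(sig, scale=hp.sigma_prior_scale)
    lp += stats.halfnorm.logpdf(sig_s, scale=hp.sigma_s_scale)
    return float(lp)


def test_log_joint_empty_data_is_hyperprior_only():
    got = log_joint((50.0, 10.0, 15.0), [], [], MAP)
    assert got == pytest.approx(_hyper_logpdf(50.0, 10.0, 15.0))


def test_log_joint_single_trial_matches_hand_computation():
    mu, sig, sig_s = 50.0, 10.0, 15.0
    post = fuse(GaussianBelief(mu, sig),
                GaussianBelief(sensation_mean(256, MAP), sig_s))
    expected = (_hyper_logpdf(mu, sig, sig_s)
                + stats.norm.logpdf(60.0, post.mu, post.sigma))
    got = log_joint((mu, sig, sig_s), [60.0], [256], MAP)
    assert got == pytest.approx(expected, rel=1e-12)


def test_log_joint_additivity_in_data():
    params = (45.0, 8.0, 12.0)
    r, w = [30.0, 55.0, 61.0], [64, 256, 256]
    hyper = log_joint(params, [], [], MAP)
    single = log_joint(params, r, w, MAP) - hyper
    double = log_joint(params, r * 2, w * 2, MAP) - hyper
    assert double == pytest.approx(2 * single, rel=1e-12)


def test_log_joint_nonpositive_sigma_is_minus_inf():
    assert log_joint((50.0, -1.0, 15.0), [60.0], [256], MAP) == -math.inf
    assert log_joint((50.0, 10.0, 0.0), [60.0], [256], MAP) == -math.inf


def _conjugate_posterior(ratings, mus, sig, sig_s, hp=HP):
    """Closed-form normal-normal posterior of mu_prior with both sigmas known.

    Each rating r_t ~ N(w*mu + (1-w)*mu_s_t, sigma_post), which is linear-
    Gaussian in mu, so the posterior under the N(m0, s0) hyperprior is normal.
    """
    var_post = 1.0 / (1.0 / sig**2 + 1.0 / sig_s**2)
    w = var_post / sig**2
    prec = 1.0 / hp.mu_prior_scale**2 + len(ratings) * w**2 / var_post
    num = hp.mu_prior_location / hp.mu_prior_scale**2
    num += (w / var_post) * np.sum(ratings - (1.0 - w) * mus)
    return num / prec, math.sqrt(1.0 / prec)


def test_conjugate_subproblem_matches_closed_form(rng):
    sig, sig_s = 10.0, 15.0
    truth_mu = 62.0
    weights = rng.choice([64, 256], size=40)
    mus = sensation_mean(weights, MAP)
    var_post = 1.0 / (1.0 / sig**2 + 1.0 / sig_s**2)
    w = var_post / sig**2
    ratings = rng.normal(w * truth_mu + (1 - w) * mus, math.sqrt(var_post))
    fit = fit_mcmc(ratings, weights, MAP,
                   cfg=McmcConfig(n_chains=4, n_samples=4000, burn_in=1000, seed=7),
                   fix={"sigma_prior": sig, "sigma_s": sig_s})
    cf_mean, cf_sd = _conjugate_posterior(ratings, mus, sig, sig_s)
    draws = fit.samples["mu_prior"]
    ess = fit.ess["mu_prior"]
    mcse_mean = draws.std() / math.sqrt(ess)
    mcse_sd = draws.std() / math.sqrt(2 * ess)
    assert abs(draws.mean() - cf_mean) < 3 * mcse_mean
    assert abs(draws.std() - cf_sd) < 3 * mcse_sd


def test_fixed_seed_gives_bit_identical_draws():
    rng = np.random.default_rng(3)
    weights = rng.choice([64, 256], size=20)
    ratings = rng.normal(50, 10, size=20)
    cfg = McmcConfig(n_chains=2, n_samples=800, burn_in=200, seed=11)
    a = fit_mcmc(ratings, weights, MAP, cfg=cfg)
    b = fit_mcmc(ratings, weights, MAP, cfg=cfg)
    for name in a.samples:
        np.testing.assert_array_equal(a.samples[name], b.samples[name])


def test_overdispersed_chains_converge_on_well_posed_data(rng):
    truth = ObserverParams(prior=GaussianBelief(45, 6), sensory_sigma=15, map=MAP)
    weights = rng.choice([64, 256], size=40)
    post_each = [fuse(truth.prior, GaussianBelief(sensation_mean(w, MAP), 15.0))
                 for w in weights]
    ratings = np.array([rng.normal(p.mu, p.sigma) for p in post_each])
    fit = fit_mcmc(ratings, weights, MAP,
                   cfg=McmcConfig(n_chains=4, n_samples=5000, burn_in=1500, seed=5))
    assert max(fit.rhat.values()) <= 1.05
    assert 0.1 < fit.acceptance_rate < 0.8
    # estimates in a sane region around the truth
    assert abs(fit.point_estimates["mu_prior"] - 45) < 10


def test_credible_intervals_cover_known_truth_in_most_replicates(rng):
    # data simulated from (mu=40, sigma_prior=20, sigma_s=10)
    truth = ObserverParams(prior=GaussianBelief(40, 20), sensory_sigma=10, map=MAP)
    hits = 0
    n_rep = 20
    for rep in range(n_rep):
        weights = rng.choice([64, 256], size=40)
        ratings = np.array([
            rng.normal(*((lambda p: (p.mu, p.sigma))(
                fuse(truth.prior, GaussianBelief(sensation_mean(w, MAP), 10.0)))))
            for w in weights])
        fit = fit_mcmc(ratings, weights, MAP,
                       cfg=McmcConfig(n_chains=2, n_samples=2500, burn_in=800,
                                      seed=100 + rep))
        lo, hi = fit.credible_interval("mu_prior")
        hits += int(lo <= 40.0 <= hi)
    assert hits >= int(0.8 * n_rep)


def test_split_rhat_agrees_with_arviz(rng):
    import arviz as az

    chains = rng.normal(0, 1, size=(4, 500)) + rng.normal(0, 0.3, size=(4, 1))
    mine = float(split_rhat(chains))
    ref = float(az.rhat(az.convert_to_dataset(chains))["x"].values)
    assert mine == pytest.approx(ref, abs=0.01)


def test_extract_observer_projects_point_estimates():
    fit = FitResult(samples={}, point_estimates={"mu_prior": 48.0,
                                                 "sigma_prior": 9.0,
                                                 "sigma_s": 14.0},
                    rhat={"mu_prior": 1.01}, ess={}, log_density=np.empty(0),
                    acceptance_rate=0.4)
    obs = extract_observer(fit, MAP)
    assert obs.prior == GaussianBelief(48.0, 9.0)
    assert obs.sensory_sigma == 14.0


def test_extract_observer_refuses_nonconverged_fit():
    fit = FitResult(samples={}, point_estimates={"mu_prior": 48.0,
                                                 "sigma_prior": 9.0,
                                                 "sigma_s": 14.0},
                    rhat={"mu_prior": 1.5}, ess={}, log_density=np.empty(0),
                    acceptance_rate=0.4)
    with pytest.raises(ConvergenceError):
        extract_observer(fit, MAP)
    assert extract_observer(fit, MAP, force=True).prior.mu == 48.0


def test_empty_data_rejected():
    with pytest.raises(ValueError):
        fit_mcmc([], [], MAP)


def test_joint_study_fit_matches_per_condition_structure(tiny_study):
    sf = fit_study(tiny_study, MAP,
                   cfg=McmcConfig(n_chains=2, n_samples=600, burn_in=200, seed=0))
    assert sf.participants == ["A", "B"]
    est = sf.point_estimates("A")
    assert set(est) == {"mu_prior_doctor", "sigma_prior_doctor",
                        "mu_prior_pharmacy", "sigma_prior_pharmacy", "sigma_s"}
    assert est["sigma_prior_doctor"] > 0 and est["sigma_s"] > 0
    obs = sf.observer("A", "doctor")
    assert obs.prior.sigma > 0
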