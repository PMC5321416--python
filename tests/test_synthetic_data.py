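"""Generator fidelity: schedule contingencies, determinism, population
statistics, and the qualitative variance asymmetry of the paradigm."""

import numpy as np
import pytest

from painprior.observer import FLAT
from painprior.psychophys import sensation_mean
from painprior.synthetic_data import (ConditionPopulation, PopulationConfig,
                                      neutral_config, paper_like_config,
                                      sample_population, simulate_linear_study,
                                      simulate_study)
from painprior.behavior import condition_summaries
from painprior.trial_model import filter_trials


def test_fixed_seed_reproducibility():
    cfg = neutral_config(n_participants=3, seed=9)
    t1 = sample_population(cfg)
    t2 = sample_population(cfg)
    assert t1.participants == t2.participants
    for pid in t1.participants:
        for c in ("doctor", "pharmacy", "control"):
            assert t1.params[pid][c] == t2.params[pid][c]
    d1 = simulate_study(t1, cfg)
    d2 = simulate_study(t2, cfg)
    assert d1 == d2


def test_zero_population_spread_gives_identical_participants():
    cfg = neutral_config(
        n_participants=5,
        doctor=ConditionPopulation(45.0, 0.0, 10.0, 0.0),
        pharmacy=ConditionPopulation(60.0, 0.0, 10.0, 0.0),
        control=None,
        participant_offset_sd=0.0,
        sensory_sigma_scale=0.0,
    )
    truth = sample_population(cfg)
    doctors = {truth.params[p]["doctor"] for p in truth.participants}
    assert len(doctors) == 1
    assert all(truth.params[p]["control"].prior is FLAT
               for p in truth.participants)


def test_population_means_approach_configured_locations():
    cfg = neutral_config(n_participants=10_000, n_conditioning_trials=1,
                         n_test_trials_per_condition=1, seed=4)
    truth = sample_population(cfg)
    mus = truth.true_values("doctor", "mu_prior")
    se = np.sqrt(cfg.doctor.mu_scale**2 + cfg.participant_offset_sd**2) / 100
    assert abs(mus.mean() - cfg.doctor.mu_loc) < 4 * se


def test_generated_dataset_satisfies_all_invariants_and_roundtrips(tmp_path):
    from painprior.trial_model import read_trials, write_trials

    cfg = paper_like_config(n_participants=6, seed=2)
    ds = simulate_study(sample_population(cfg), cfg)
    ds.validate()  # raises on violation
    path = tmp_path / "sim.csv"
    write_trials(ds, path)
    assert read_trials(path) == ds


def test_doctor_stimulus_split_and_choice_rate_within_binomial_bounds():
    cfg = neutral_config(n_participants=250, seed=6)  # 10,000 conditioning trials
    ds = simulate_study(sample_population(cfg), cfg)
    cond = filter_trials(ds, session="conditioning").df
    n_total = len(cond)
    assert n_total == 10_000
    p_doc = (cond.choice == "doctor").mean()
    half = 1.96 * np.sqrt(cfg.p_doctor * (1 - cfg.p_doctor) / n_total)
    assert abs(p_doc - cfg.p_doctor) < half + 1e-12
    doc = cond[cond.choice == "doctor"]
    p64 = (doc.stimulus_weight == 64).mean()
    half64 = 1.96 * np.sqrt(0.25 / len(doc))
    assert abs(p64 - 0.5) < half64
    assert set(cond[cond.choice == "pharmacy"].stimulus_weight) == {256}


def test_noiseless_flat_prior_limit_reproduces_sensation():
    cfg = neutral_config(
        n_participants=2, n_conditioning_trials=6, n_test_trials_per_condition=1,
        doctor=None, pharmacy=None, control=None,
        sensory_sigma_loc=1e-9, sensory_sigma_scale=0.0,
        report_noise_sd=0.0, seed=1,
    )
    truth = sample_population(cfg)
    ds = simulate_study(truth, cfg)
    cond = filter_trials(ds, session="conditioning").df
    expected = sensation_mean(cond.stimulus_weight.to_numpy(float), cfg.map)
    np.testing.assert_allclose(cond.pain_rating.to_numpy(), expected, atol=1e-6)


def test_doctor_condition_has_larger_conditioning_sd_than_pharmacy():
    # the 64/256 stimulus mixture inflates doctor-trial rating spread
    cfg = paper_like_config(seed=3)
    ds = simulate_study(sample_population(cfg), cfg)
    s = condition_summaries(ds)
    wide = s[s.session == "conditioning"].pivot(
        index="participant_id", columns="condition", values="sd_rating").dropna()
    frac = (wide["doctor"] > wide["pharmacy"]).mean()
    assert frac >= 0.9


def test_test_session_condition_means_respect_prior_ordering():
    cfg = paper_like_config(n_participants=40, seed=8)
    ds = simulate_study(sample_population(cfg), cfg)
    test = filter_trials(ds, session="test").df
    means = test.groupby("choice")["pain_rating"].mean()
    assert means["doctor"] < means["control"]
    assert means["pharmacy"] < means["control"]


def test_linear_study_has_no_condition_structure_at_test():
    cfg = paper_like_config(n_participants=40, seed=5)
    ds = simulate_linear_study(cfg, rng=np.random.default_rng(5))
    ds.validate()
    test = filter_trials(ds, session="test").df
    means = test.groupby("choice")["pain_rating"].mean()
    # all conditions share the same 512 mN linear response
    assert np.ptp(means.to_numpy()) < 2.0


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        PopulationConfig(p_doctor=1.5)
    with pytest.raises(ValueError):
        PopulationConfig(n_participants=0)
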