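"""End-to-end orchestration: fit a study, predict the test session,
compare against the linear baseline, and run replicate studies.

Prediction protocol (train/test split): all free parameters are estimated
from conditioning-session trials only; the fitted observers then predict
each participant's test-session ratings at the 512 mN reference
intensity.  Scores (RMSE, BIC) therefore measure genuine out-of-sample
prediction error.

The linear baseline for the doctor condition is fit per participant on
that participant's doctor conditioning trials (two stimulus levels).  The
pharmacy condition delivers a single stimulus level during conditioning,
which leaves the within-condition regression rank-deficient; its baseline
is therefore fit on the participant's full conditioning set (both
choices), the closest well-posed analogue.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior
from .baselines import (LinearBaseline, ModelComparison, compare_models,
                        fit_linear, winner)
from .inference import HyperPriors, McmcConfig, StudyFit, fit_study
from .observer import predict_rating
from .psychophys import PsychMap, default_map
from .synthetic_data import (PopulationConfig, paper_like_config,
                             sample_population, simulate_linear_study,
                             simulate_study)
from .trial_model import StudyDataset, conditioning_arrays, filter_trials

CHOICE_CONDITIONS = ("doctor", "pharmacy")


def _child_seed(seed: int, *path: int) -> int:
    """Deterministic per-stage child seed derivation (documented contract)."""
    ss = np.random.SeedSequence(seed, spawn_key=path)
    return int(ss.generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------

def bayes_predictions(fit: StudyFit, weight: float = 512.0) -> pd.DataFrame:
    """Per participant x condition posterior-mean prediction at ``weight``."""
    rows = []
    for pid in fit.participants:
        for cond in CHOICE_CONDITIONS:
            obs = fit.observer(pid, cond)
            post = predict_rating(obs, weight)
            rows.append(dict(participant_id=pid, condition=cond,
                             predicted=post.mu, predictive_sd=post.sigma))
    return pd.DataFrame(rows)


def linear_predictions(dataset: StudyDataset, pmap: PsychMap,
                       weight: float = 512.0) -> pd.DataFrame:
    """Per participant x condition linear-baseline prediction at ``weight``."""
    rows = []
    for pid in sorted(dataset.participants):
        all_cond = filter_trials(dataset, session="conditioning",
                                 participant=pid).df
        for cond in CHOICE_CONDITIONS:
            if cond == "doctor":
                r, w = conditioning_arrays(dataset, pid, "doctor")
                if len(r) < 3 or len(np.unique(w)) < 2:
                    # degenerate doctor schedule: single realised level
                    r = all_cond["pain_rating"].to_numpy()
                    w = all_cond["stimulus_weight"].to_numpy()
            else:  # single level within condition: fall back to the full set
                r = all_cond["pain_rating"].to_numpy()
                w = all_cond["stimulus_weight"].to_numpy()
            if len(np.unique(w)) < 2:
                # degenerate schedule (every trial at one level): the
                # regression collapses to the intercept-only mean predictor
                base = LinearBaseline(slope=0.0, intercept=float(np.mean(r)),
                                      residual_sd=float(np.std(r, ddof=1)),
                                      n=len(r))
            else:
                base = fit_linear(r, w, pmap)
            rows.append(dict(participant_id=pid, condition=cond,
                             predicted=float(base.predict(weight, pmap)),
                             slope=base.slope, intercept=base.intercept))
    return pd.DataFrame(rows)


def pooled_comparison(dataset: StudyDataset, bayes: pd.DataFrame,
                      linear: pd.DataFrame, k_bayes: int = 3,
                      k_linear: int = 3) -> dict[str, tuple[ModelComparison, ModelComparison]]:
    """Pooled-over-participants test-trial comparison, one pair per condition.

    Each test trial's prediction is its participant's condition prediction;
    both models are scored on the identical trials.
    """
    out = {}
    for cond in CHOICE_CONDITIONS:
        test = filter_trials(dataset, session="test", choice=cond).df
        b_map = bayes.set_index(["participant_id", "condition"])["predicted"]
        l_map = linear.set_index(["participant_id", "condition"])["predicted"]
        pred_b = test["participant_id"].map(lambda p: b_map[(p, cond)]).to_numpy()
        pred_l = test["participant_id"].map(lambda p: l_map[(p, cond)]).to_numpy()
        actual = test["pain_rating"].to_numpy()
        out[cond] = compare_models(pred_b, pred_l, actual,
                                   k_bayes=k_bayes, k_linear=k_linear,
                                   condition=cond)
    return out


def per_participant_comparison(dataset: StudyDataset, bayes: pd.DataFrame,
                               linear: pd.DataFrame) -> pd.DataFrame:
    """Per-participant RMSE decomposition of the pooled comparison."""
    rows = []
    for cond in CHOICE_CONDITIONS:
        for pid in sorted(dataset.participants):
            test = filter_trials(dataset, session="test", choice=cond,
                                 participant=pid).df
            if test.empty:
                continue
            actual = test["pain_rating"].to_numpy()
            for label, frame in (("bayesian", bayes), ("linear", linear)):
                pred = float(frame[(frame.participant_id == pid)
                                   & (frame.condition == cond)]["predicted"].iloc[0])
                err = np.sqrt(np.mean((pred - actual) ** 2))
                rows.append(dict(participant_id=pid, condition=cond,
                                 model=label, rmse=float(err), n=len(actual)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# behavioral statistics bundle
# ---------------------------------------------------------------------------

def behavior_stats(dataset: StudyDataset,
                   predictions: pd.DataFrame | None = None) -> dict:
    """The full behavioral report: choice rates and trend, condition
    summaries, the three test-session paired t-tests, the conditioning
    SD comparison, and (if predictions are given) predicted-vs-actual
    correlations per condition."""
    by_index, overall = behavior.choice_probabilities(dataset)
    trend = behavior.choice_trend(dataset)
    summaries = behavior.condition_summaries(dataset)

    def test_means(cond):
        return behavior.per_participant_test_means(dataset, cond)

    t_tests = {}
    means = {c: test_means(c) for c in ("doctor", "pharmacy", "control")}
    for a, b in (("doctor", "control"), ("pharmacy", "control"),
                 ("doctor", "pharmacy")):
        common = means[a].index.intersection(means[b].index)
        try:
            res = behavior.paired_t(means[a][common], means[b][common])
        except (ValueError, behavior.DegenerateStatisticError):
            res = None
        t_tests[f"{a}_vs_{b}"] = asdict(res) if res else None

    cond_sd = summaries[(summaries.session == "conditioning")]
    sd_wide = cond_sd.pivot(index="participant_id", columns="condition",
                            values="sd_rating")
    try:
        sd_pairs = sd_wide[["doctor", "pharmacy"]].dropna()
        sd_test = behavior.paired_t(sd_pairs["doctor"], sd_pairs["pharmacy"])
    except (KeyError, ValueError, behavior.DegenerateStatisticError):
        sd_test = None

    out = {
        "choice_rate_doctor": overall,
        "choice_rate_pharmacy": 1.0 - overall,
        "choice_trend": asdict(trend),
        "test_session_paired_t": t_tests,
        "conditioning_sd_doctor_vs_pharmacy": asdict(sd_test) if sd_test else None,
        "n_participants": len(dataset.participants),
    }
    if predictions is not None:
        corr = {}
        for cond in CHOICE_CONDITIONS:
            actual = means[cond]
            pred = (predictions[predictions.condition == cond]
                    .set_index("participant_id")["predicted"]
                    .sort_index())
            common = actual.index.intersection(pred.index)
            res = behavior.predicted_vs_actual(pred[common], actual[common])
            corr[cond] = asdict(res)
        out["predicted_vs_actual"] = corr
    return out, by_index, summaries


# ---------------------------------------------------------------------------
# replicate studies
# ---------------------------------------------------------------------------

@dataclass
class PatternStudyResult:
    """Detection rates of the qualitative placebo pattern over replicates."""

    rate_doctor_lt_control: float
    rate_pharmacy_lt_control: float
    frac_participants_sd_doctor_gt_pharmacy: float
    n_replicates: int


def pattern_study(cfg: PopulationConfig | None = None, n_replicates: int = 50,
                  seed: int = 0) -> PatternStudyResult:
    """Replicate simulated studies and score the qualitative pattern:
    significantly lower test-session pain after doctor and pharmacy choices
    than on control trials (paired t, two-sided alpha 0.05, correct sign),
    and larger conditioning-session rating SD after doctor than pharmacy
    choices per participant (driven by the 64/256 stimulus mixture)."""
    cfg = paper_like_config() if cfg is None else cfg
    doc_hits = pha_hits = 0
    sd_greater = sd_total = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(_child_seed(seed, 40, rep))
        truth = sample_population(cfg, rng)
        ds = simulate_study(truth, cfg, rng)
        means = {c: behavior.per_participant_test_means(ds, c)
                 for c in ("doctor", "pharmacy", "control")}
        t_doc = behavior.paired_t(means["doctor"], means["control"])
        t_pha = behavior.paired_t(means["pharmacy"], means["control"])
        doc_hits += int(t_doc.p_two_sided < 0.05 and t_doc.t_stat < 0)
        pha_hits += int(t_pha.p_two_sided < 0.05 and t_pha.t_stat < 0)
        summ = behavior.condition_summaries(ds)
        cond = summ[summ.session == "conditioning"].pivot(
            index="participant_id", columns="condition", values="sd_rating")
        ok = cond[["doctor", "pharmacy"]].dropna()
        sd_greater += int((ok["doctor"] > ok["pharmacy"]).sum())
        sd_total += len(ok)
    return PatternStudyResult(
        rate_doctor_lt_control=doc_hits / n_replicates,
        rate_pharmacy_lt_control=pha_hits / n_replicates,
        frac_participants_sd_doctor_gt_pharmacy=sd_greater / sd_total,
        n_replicates=n_replicates,
    )


@dataclass
class ComparisonStudyResult:
    """Model-comparison win rates over replicate studies."""

    bayes_win_rate: dict[str, float]   # per condition, fraction of replicates
    n_replicates: int
    regime: str                        # generative regime of the data


def model_comparison_study(cfg: PopulationConfig | None = None,
                           mcmc: McmcConfig | None = None,
                           n_replicates: int = 50, seed: int = 0,
                           regime: str = "bayes",
                           linear_noise_sd: float = 8.0) -> ComparisonStudyResult:
    """Replicate simulate -> fit -> predict -> compare and count, per
    condition, how often the Bayesian observer attains the lower pooled BIC.

    ``regime`` selects the generative truth: "bayes" draws ratings from
    the Gaussian-observer model; "linear" from a pure linear response with
    no prior influence (the inversion check).
    """
    cfg = paper_like_config() if cfg is None else cfg
    mcmc = mcmc if mcmc is not None else McmcConfig(n_chains=2, n_samples=2000,
                                                   burn_in=500)
    wins = {c: 0 for c in CHOICE_CONDITIONS}
    for rep in range(n_replicates):
        rng = np.random.default_rng(_child_seed(seed, 50, rep))
        if regime == "bayes":
            truth = sample_population(cfg, rng)
            ds = simulate_study(truth, cfg, rng)
        elif regime == "linear":
            ds = simulate_linear_study(cfg, noise_sd=linear_noise_sd, rng=rng)
        else:
            raise ValueError(f"unknown regime {regime!r}")
        fit = fit_study(ds, cfg.map,
                        cfg=replace(mcmc, seed=_child_seed(seed, 51, rep)))
        bp = bayes_predictions(fit)
        lp = linear_predictions(ds, cfg.map)
        pooled = pooled_comparison(ds, bp, lp)
        for cond, pair in pooled.items():
            if winner(pair) == "bayesian":
                wins[cond] += 1
    return ComparisonStudyResult(
        bayes_win_rate={c: w / n_replicates for c, w in wins.items()},
        n_replicates=n_replicates, regime=regime,
    )


# ---------------------------------------------------------------------------
# single-study analysis bundle (used by the CLI)
# ---------------------------------------------------------------------------

def analyze_study(dataset: StudyDataset, pmap: PsychMap | None = None,
                  hp: HyperPriors = HyperPriors(),
                  mcmc: McmcConfig = McmcConfig()) -> dict:
    """Fit, predict, compare and summarise one study; returns a JSON-able
    report plus the intermediate frames."""
    pmap = default_map() if pmap is None else pmap
    fit = fit_study(dataset, pmap, hp, mcmc)
    bp = bayes_predictions(fit)
    lp = linear_predictions(dataset, pmap)
    pooled = pooled_comparison(dataset, bp, lp)
    per_part = per_participant_comparison(dataset, bp, lp)
    stats, by_index, summaries = behavior_stats(dataset, predictions=bp)
    report = {
        "behavior": stats,
        "comparison": {
            cond: {m.model_label: asdict(m) for m in pair}
            | {"winner": winner(pair)}
            for cond, pair in pooled.items()
        },
        "max_rhat": float(np.nanmax(fit.rhat())),
    }
    return {
        "report": report, "fit": fit, "bayes_predictions": bp,
        "linear_predictions": lp, "per_participant_rmse": per_part,
        "choice_proportions": by_index, "condition_summaries": summaries,
    }


def write_report(report: dict, outdir: str | Path, name: str = "report.json") -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / name
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return path
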