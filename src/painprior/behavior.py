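"""Behavioral statistics: choice probabilities, condition summaries,
paired t-tests, choice-trend check, and predicted-vs-actual correlation.

All tests are two-sided at alpha = 0.05 with no multiple-testing
correction; aggregation is participant-level before testing, so a study of
24 participants yields df = 23.  Sample SDs use the n-1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trial_model import StudyDataset, filter_trials


class DegenerateStatisticError(ValueError):
    """Zero variance where a test statistic needs some."""


@dataclass(frozen=True)
class PairedTestResult:
    t_stat: float
    df: int
    p_two_sided: float
    mean_a: float
    mean_b: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_two_sided: float
    n: int


@dataclass(frozen=True)
class TrendResult:
    slope: float
    p_two_sided: float
    n_indices: int


def choice_probabilities(dataset: StudyDataset) -> tuple[pd.DataFrame, float]:
    """Per-trial-index doctor-choice proportion and the overall proportion.

    Proportions are over conditioning trials; doctor and pharmacy
    proportions sum to one at every index.
    """
    cond = filter_trials(dataset, session="conditioning").df
    if cond.empty:
        raise ValueError("no conditioning trials present")
    by_index = (
        cond.assign(is_doctor=cond["choice"] == "doctor")
        .groupby("trial_index")["is_doctor"]
        .agg(prop_doctor="mean", n="size")
        .reset_index()
    )
    by_index["prop_pharmacy"] = 1.0 - by_index["prop_doctor"]
    overall = float((cond["choice"] == "doctor").mean())
    return by_index, overall


def condition_summaries(dataset: StudyDataset) -> pd.DataFrame:
    """Per participant x session x condition mean and sample SD of ratings.

    Singleton cells get NaN SD (flagged by the caller as needed).
    """
    g = dataset.df.groupby(["participant_id", "session", "choice"])["pain_rating"]
    out = g.agg(n_trials="size", mean_rating="mean", sd_rating="std").reset_index()
    return out.rename(columns={"choice": "condition"})


def paired_t(values_a, values_b) -> PairedTestResult:
    """Paired t-test across participants: t = mean(d) / (sd(d)/sqrt(n))."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 complete pairs of equal length")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise DegenerateStatisticError("zero variance of paired differences")
    res = stats.ttest_rel(a, b)
    return PairedTestResult(
        t_stat=float(res.statistic), df=a.size - 1,
        p_two_sided=float(res.pvalue),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
    )


def predicted_vs_actual(pred, actual) -> CorrelationResult:
    """Pearson correlation of per-participant predicted vs actual test means."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape or pred.size < 3:
        raise ValueError("need >= 3 pairs")
    if np.allclose(pred.std(), 0.0) or np.allclose(actual.std(), 0.0):
        raise DegenerateStatisticError("zero variance in predicted or actual values")
    res = stats.pearsonr(pred, actual)
    return CorrelationResult(r=float(res.statistic),
                             p_two_sided=float(res.pvalue), n=pred.size)


def choice_trend(dataset: StudyDataset) -> TrendResult:
    """OLS slope of per-index doctor-choice proportion on trial index.

    A non-significant slope reproduces the "no change in choice
    probabilities over time" check.
    """
    by_index, _ = choice_probabilities(dataset)
    if len(by_index) < 3:
        raise ValueError("need >= 3 distinct trial indices")
    res = stats.linregress(by_index["trial_index"], by_index["prop_doctor"])
    return TrendResult(slope=float(res.slope), p_two_sided=float(res.pvalue),
                       n_indices=len(by_index))


def per_participant_test_means(dataset: StudyDataset, condition: str) -> pd.Series:
    """Mean test-session rating per participant for one condition,
    indexed by participant_id (sorted)."""
    sub = filter_trials(dataset, session="test", choice=condition).df
    return sub.groupby("participant_id")["pain_rating"].mean().sort_index()
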