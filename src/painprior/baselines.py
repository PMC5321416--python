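"""Linear-regression baseline and BIC/RMSE model-selection machinery.

The baseline regresses the pain rating on the estimated sensory intensity
mu_s(weight) from the same logarithmic psychophysical map the observer
model uses, fit per participant on conditioning trials, then extrapolated
to the test intensity.

Model scores are computed on *test-session prediction residuals*:

    RMSE = sqrt(mean((predicted - actual)^2))
    BIC  = n * ln(SSE / n) + k * ln(n)

This is the Gaussian-error BIC applied to held-out prediction error rather
than training likelihood — an unusual but deliberate scoring rule (the
models are trained on the conditioning session only, so the test session
provides genuine out-of-sample error).  Perfect prediction (SSE = 0) has
no finite BIC under this form and raises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .psychophys import PsychMap, RankDeficiencyError, sensation_mean


class DegenerateFitError(ValueError):
    """SSE is zero: the Gaussian-error BIC is undefined."""


@dataclass(frozen=True)
class LinearBaseline:
    """OLS fit of rating on estimated sensation."""

    slope: float
    intercept: float
    residual_sd: float
    n: int
    exact: bool = False  # True when residuals vanish (residual_sd 0, flagged)

    def predict(self, weight, pmap: PsychMap):
        return self.slope * sensation_mean(weight, pmap) + self.intercept


@dataclass(frozen=True)
class ModelComparison:
    model_label: str
    condition: str
    n_test_trials: int
    rmse: float
    bic: float
    k_params: int


def fit_linear(ratings, weights, pmap: PsychMap) -> LinearBaseline:
    """OLS of rating on sensation_mean(weight); residual sd uses n-2."""
    ratings = np.asarray(ratings, dtype=float)
    x = sensation_mean(np.asarray(weights, dtype=float), pmap)
    if len(ratings) < 3:
        raise ValueError("need >= 3 trials to fit the linear baseline")
    if len(np.unique(x)) < 2:
        raise RankDeficiencyError(
            "all estimated sensations identical; slope not identified"
        )
    res = stats.linregress(x, ratings)
    resid = ratings - (res.slope * x + res.intercept)
    sse = float(np.sum(resid**2))
    resid_sd = math.sqrt(sse / (len(ratings) - 2))
    return LinearBaseline(
        slope=float(res.slope), intercept=float(res.intercept),
        residual_sd=resid_sd, n=len(ratings), exact=sse == 0.0,
    )


def rmse(predicted, actual) -> float:
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape or predicted.size == 0:
        raise ValueError("predicted and actual must have equal nonzero lengths")
    return float(np.sqrt(np.mean((predicted - actual) ** 2)))


def bic(predicted, actual, k_params: int) -> float:
    """Gaussian-error BIC on prediction residuals: n ln(SSE/n) + k ln(n)."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape or predicted.size == 0:
        raise ValueError("predicted and actual must have equal nonzero lengths")
    if k_params < 1:
        raise ValueError("k_params must be >= 1")
    n = predicted.size
    sse = float(np.sum((predicted - actual) ** 2))
    if sse == 0.0:
        raise DegenerateFitError("SSE = 0: BIC of a perfect prediction is -inf")
    return n * math.log(sse / n) + k_params * math.log(n)


def compare_models(bayes_predictions, linear_predictions, actual,
                   k_bayes: int = 3, k_linear: int = 3,
                   condition: str = "all") -> tuple[ModelComparison, ModelComparison]:
    """Score both models on the identical test trials; lower BIC wins.

    Returns (bayes, linear) comparisons; ties are legal and left to the
    caller to break (equal BICs report no winner).
    """
    actual = np.asarray(actual, dtype=float)
    n = actual.size
    b = ModelComparison("bayesian", condition, n,
                        rmse(bayes_predictions, actual),
                        bic(bayes_predictions, actual, k_bayes), k_bayes)
    l = ModelComparison("linear", condition, n,
                        rmse(linear_predictions, actual),
                        bic(linear_predictions, actual, k_linear), k_linear)
    return b, l


def winner(pair: tuple[ModelComparison, ModelComparison]) -> str | None:
    a, b = pair
    if a.bic == b.bic:
        return None
    return a.model_label if a.bic < b.bic else b.model_label
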