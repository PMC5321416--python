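"""Logarithmic stimulus-intensity -> sensation mapping.

The expected sensation produced by a PINPRICK force of ``weight`` mN is
affine in log force::

    mu_s(weight) = a * ln(weight) + b      [rating units, percent of reference]

Natural logarithms are used throughout; any other base is absorbed into
``(a, b)``.  The default map is anchored to the mean conditioning-session
ratings at the two conditioning intensities (7.5 at 64 mN, 57.5 at 256 mN),
which puts the reference intensity at ``mu_s(512) = 82.5``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


class RankDeficiencyError(ValueError):
    """The design has a single distinct stimulus level; the slope is not identified."""


@dataclass(frozen=True)
class PsychMap:
    """Slope/intercept of the log-force -> sensation mapping."""

    slope_a: float
    intercept_b: float


@dataclass(frozen=True)
class CalibrationResult:
    map: PsychMap
    residual_sd: float
    n: int
    slope_stderr: float


#: Anchored so sensation(64)=7.5 and sensation(256)=57.5; sensation(512)=82.5.
DEFAULT_ANCHORS = ((64.0, 7.5), (256.0, 57.5))


def map_from_anchors(anchors=DEFAULT_ANCHORS) -> PsychMap:
    """Exact 2-point map through ``(weight, sensation)`` anchor pairs."""
    (w0, s0), (w1, s1) = anchors
    a = (s1 - s0) / (math.log(w1) - math.log(w0))
    b = s0 - a * math.log(w0)
    return PsychMap(slope_a=a, intercept_b=b)


def default_map() -> PsychMap:
    return map_from_anchors()


def sensation_mean(weight, pmap: PsychMap):
    """Expected sensation mu_s at ``weight`` mN (scalar or array), rating units."""
    w = np.asarray(weight, dtype=float)
    if np.any(w <= 0):
        raise ValueError("stimulus weight must be > 0 mN")
    out = pmap.slope_a * np.log(w) + pmap.intercept_b
    return float(out) if np.isscalar(weight) else out


def calibrate_map(ratings, weights) -> CalibrationResult:
    """Fit (a, b) by ordinary least squares of rating on ln(weight).

    Requires at least two distinct stimulus weights; with exactly two the fit
    passes through the per-level means.
    """
    ratings = np.asarray(ratings, dtype=float)
    x = np.log(np.asarray(weights, dtype=float))
    if len(np.unique(x)) < 2:
        raise RankDeficiencyError("need >= 2 distinct stimulus weights to fit a slope")
    res = stats.linregress(x, ratings)
    fitted = res.slope * x + res.intercept
    dof = max(len(ratings) - 2, 1)
    resid_sd = float(np.sqrt(np.sum((ratings - fitted) ** 2) / dof))
    return CalibrationResult(
        map=PsychMap(slope_a=float(res.slope), intercept_b=float(res.intercept)),
        residual_sd=resid_sd,
        n=len(ratings),
        slope_stderr=float(res.stderr),
    )
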