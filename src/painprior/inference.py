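"""MCMC estimation of per-participant, per-condition prior parameters.

The generative (observation) model for a conditioning trial with stimulus
weight ``w`` and report ``r`` is

    r ~ Normal(mu_post(w), sigma_post)

where ``mu_post`` / ``sigma_post`` come from fusing the condition prior
N(mu_prior, sigma_prior) with the sensory likelihood
N(mu_s(w), sigma_s) — the posterior of the observer model read as a
response distribution.  Free parameters per condition are
(mu_prior, sigma_prior, sigma_s); by default sigma_s is a single sensory
channel shared across the two choice conditions within a participant.

Weakly-informative hyperpriors on the 0-100 magnitude-estimation scale:

    mu_prior     ~ Normal(50, 50)
    sigma_prior  ~ HalfNormal(30)
    sigma_s      ~ HalfNormal(30)   (or fixed by configuration)

Sampling is random-walk Metropolis over the positive-constrained natural
parameterisation (non-positive sigma proposals score -inf and are
rejected).  Chains are vectorised in numpy; proposal scales are adapted
toward ~30% acceptance during burn-in and frozen afterwards, so the kept
draws form a valid Markov chain.  Convergence is summarised by split-R-hat
and (for single fits) effective sample size via arviz.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .observer import GaussianBelief, ObserverParams
from .psychophys import PsychMap, sensation_mean
from .trial_model import StudyDataset, conditioning_arrays, filter_trials

_LOG_2PI = math.log(2.0 * math.pi)
_PARAM_NAMES = ("mu_prior", "sigma_prior", "sigma_s")


class ConvergenceError(RuntimeError):
    """The fit did not converge and no override was given."""


class DegenerateChainError(RuntimeError):
    """The sampler rejected essentially every proposal."""


@dataclass(frozen=True)
class HyperPriors:
    """Hyperprior scales, rating units (percent of reference pain)."""

    mu_prior_location: float = 50.0
    mu_prior_scale: float = 50.0
    sigma_prior_scale: float = 30.0
    sigma_s_scale: float = 30.0
    sigma_s_fixed: float | None = None

    def __post_init__(self) -> None:
        for name in ("mu_prior_scale", "sigma_prior_scale", "sigma_s_scale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class McmcConfig:
    n_chains: int = 4
    n_samples: int = 5000          # total iterations per chain, incl. burn-in
    burn_in: int = 1000
    proposal_scales: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if not self.burn_in < self.n_samples:
            raise ValueError("burn_in must be < n_samples")


@dataclass
class FitResult:
    """Posterior draws and summaries for one participant x condition fit."""

    samples: dict[str, np.ndarray]        # name -> (chain, draw)
    point_estimates: dict[str, float]     # posterior means
    rhat: dict[str, float]
    ess: dict[str, float]
    log_density: np.ndarray               # (chain, draw)
    acceptance_rate: float
    fixed: dict[str, float] = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return max(self.rhat.values(), default=1.0) <= 1.05

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        draws = self.samples[name].ravel()
        lo = (1.0 - level) / 2.0
        return (float(np.quantile(draws, lo)), float(np.quantile(draws, 1.0 - lo)))

    def draws_frame(self):
        """Long-format draws table (chain, draw, parameter, value)."""
        import pandas as pd

        rows = []
        for name, arr in self.samples.items():
            c, d = np.meshgrid(np.arange(arr.shape[0]), np.arange(arr.shape[1]),
                               indexing="ij")
            rows.append(pd.DataFrame({
                "chain": c.ravel(), "draw": d.ravel(),
                "parameter": name, "value": arr.ravel(),
            }))
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# log densities
# ---------------------------------------------------------------------------

def _normal_logpdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - 0.5 * _LOG_2PI


def _halfnormal_logpdf(x, scale):
    return np.where(
        x > 0,
        0.5 * math.log(2.0 / math.pi) - math.log(scale) - 0.5 * (x / scale) ** 2,
        -np.inf,
    )


def _cond_loglik(mu, sig, sig_s, ratings, mus, mask=None):
    """Summed per-trial log-likelihood; parameter arrays broadcast over trials.

    ``mu, sig, sig_s`` have shape (..., 1); ``ratings``/``mus`` broadcastable
    to (..., n).  Invalid sigmas must be screened by the caller.
    """
    var_post = 1.0 / (1.0 / sig**2 + 1.0 / sig_s**2)
    w = var_post / sig**2
    mu_post = w * mu + (1.0 - w) * mus
    ll = _normal_logpdf(ratings, mu_post, np.sqrt(var_post))
    if mask is not None:
        ll = ll * mask
    return ll.sum(axis=-1)


def log_joint(params: Sequence[float], ratings, weights, pmap: PsychMap,
              hp: HyperPriors = HyperPriors()) -> float:
    """Log joint density of (mu_prior, sigma_prior, sigma_s) given one
    participant-condition's conditioning trials.

    Returns -inf (not an exception) for non-positive sigma candidates.
    Zero trials are legal: the result is the hyperprior log-density alone.
    """
    mu, sig, sig_s = (float(p) for p in params)
    if sig <= 0 or sig_s <= 0:
        return -math.inf
    lp = float(_normal_logpdf(mu, hp.mu_prior_location, hp.mu_prior_scale))
    lp += float(_halfnormal_logpdf(sig, hp.sigma_prior_scale))
    if hp.sigma_s_fixed is None:
        lp += float(_halfnormal_logpdf(sig_s, hp.sigma_s_scale))
    ratings = np.asarray(ratings, dtype=float)
    if ratings.size:
        mus = sensation_mean(np.asarray(weights, dtype=float), pmap)
        lp += float(_cond_loglik(
            np.array([[mu]]), np.array([[sig]]), np.array([[sig_s]]),
            ratings, mus,
        )[0])
    return lp


# ---------------------------------------------------------------------------
# random-walk Metropolis core (vectorised over an arbitrary batch of chains)
# ---------------------------------------------------------------------------

def _run_metropolis(logpost: Callable[[np.ndarray], np.ndarray],
                    init: np.ndarray, *, n_samples: int, burn_in: int,
                    base_scales: np.ndarray, rng: np.random.Generator,
                    target_accept: float = 0.4,
                    adapt_window: int = 50):
    """Batched component-wise random-walk Metropolis.

    ``init`` is (B, K): B independent chains over a K-dimensional block.
    Each iteration sweeps the K coordinates in turn (Metropolis within the
    parameter block); per-chain, per-coordinate step sizes are adapted
    toward the target acceptance during burn-in only, so the kept draws
    form a valid Markov chain.  Coordinates with base scale 0 are frozen.
    Returns (draws (B, kept, K), log-density (B, kept), acceptance (B,)).
    """
    B, K = init.shape
    x = init.astype(float).copy()
    lp = logpost(x)
    if not np.all(np.isfinite(lp)):
        raise ValueError("initial states have non-finite log density")
    active = [k for k in range(K) if base_scales[k] > 0]
    mult = np.ones((B, K))
    kept = n_samples - burn_in
    draws = np.empty((B, kept, K))
    lps = np.empty((B, kept))
    acc_window = np.zeros((B, K))
    acc_total = np.zeros(B)
    for it in range(n_samples):
        for k in active:
            old = x[:, k].copy()
            x[:, k] = old + rng.standard_normal(B) * base_scales[k] * mult[:, k]
            lp_prop = logpost(x)
            with np.errstate(invalid="ignore"):
                accept = np.log(rng.random(B)) < lp_prop - lp
            accept &= np.isfinite(lp_prop)
            x[~accept, k] = old[~accept]
            lp[accept] = lp_prop[accept]
            acc_window[:, k] += accept
            if it >= burn_in:
                acc_total += accept
        if it < burn_in:
            if (it + 1) % adapt_window == 0:
                rate = acc_window / adapt_window
                mult *= np.exp(rate - target_accept)
                np.clip(mult, 1e-3, 1e3, out=mult)
                acc_window[:, :] = 0.0
        else:
            j = it - burn_in
            draws[:, j] = x
            lps[:, j] = lp
    acc_rate = acc_total / (kept * max(len(active), 1))
    if np.any(acc_rate < 1e-3):
        raise DegenerateChainError(
            f"chain(s) {np.where(acc_rate < 1e-3)[0].tolist()} rejected essentially "
            f"all proposals; final states: {x[acc_rate < 1e-3]!r}"
        )
    return draws, lps, acc_rate


def split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-R-hat over the last two axes (..., chain, draw)."""
    c, d = chains.shape[-2], chains.shape[-1]
    half = d // 2
    x = np.concatenate(
        [chains[..., :half], chains[..., half: 2 * half]], axis=-2
    )  # (..., 2c, half)
    m = 2 * c
    means = x.mean(axis=-1)
    variances = x.var(axis=-1, ddof=1)
    W = variances.mean(axis=-1)
    B = half * means.var(axis=-1, ddof=1)
    var_plus = (half - 1) / half * W + B / half
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(var_plus / W)
    return np.where(W == 0, 1.0, r)  # frozen coordinates are trivially converged


# ---------------------------------------------------------------------------
# single participant x condition fit
# ---------------------------------------------------------------------------

def fit_mcmc(ratings, weights, pmap: PsychMap,
             hp: HyperPriors = HyperPriors(),
             cfg: McmcConfig = McmcConfig(),
             fix: dict[str, float] | None = None) -> FitResult:
    """Fit (mu_prior, sigma_prior, sigma_s) to one participant-condition's
    conditioning trials by random-walk Metropolis.

    ``fix`` pins any subset of the three parameters to constants (e.g. a
    known sensory noise, or both sigmas for the conjugate sub-problem).
    Reproducible: the same config seed yields bit-identical draws.
    """
    ratings = np.asarray(ratings, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if ratings.size == 0:
        raise ValueError("need at least one conditioning trial")
    fix = dict(fix or {})
    if hp.sigma_s_fixed is not None:
        fix.setdefault("sigma_s", hp.sigma_s_fixed)
    free = [n for n in _PARAM_NAMES if n not in fix]
    if not free:
        raise ValueError("at least one parameter must be free")
    mus = sensation_mean(weights, pmap)
    rng = np.random.default_rng(cfg.seed)

    idx = {n: i for i, n in enumerate(free)}

    # sigmas are sampled on the log scale (multiplicative random walk);
    # the +theta terms below are the change-of-variables Jacobian
    def logpost(theta: np.ndarray) -> np.ndarray:
        def col(name):
            if name in fix:
                return np.full((theta.shape[0], 1), float(fix[name]))
            c = theta[:, idx[name]][:, None]
            return c if name == "mu_prior" else np.exp(c)

        mu, sig, sig_s = col("mu_prior"), col("sigma_prior"), col("sigma_s")
        with np.errstate(over="ignore"):
            lp = _cond_loglik(mu, sig, sig_s, ratings, mus)
            if "mu_prior" in idx:
                lp += _normal_logpdf(mu[:, 0], hp.mu_prior_location,
                                     hp.mu_prior_scale)
            if "sigma_prior" in idx:
                lp += _halfnormal_logpdf(sig[:, 0], hp.sigma_prior_scale)
                lp += np.log(sig[:, 0])
            if "sigma_s" in idx:
                lp += _halfnormal_logpdf(sig_s[:, 0], hp.sigma_s_scale)
                lp += np.log(sig_s[:, 0])
        return np.where(np.isfinite(lp), lp, -np.inf)

    # overdispersed data-informed starting points
    init = np.empty((cfg.n_chains, len(free)))
    for name, j in idx.items():
        if name == "mu_prior":
            init[:, j] = ratings.mean() + rng.normal(0.0, 15.0, cfg.n_chains)
        else:
            init[:, j] = np.log(rng.uniform(5.0, 25.0, cfg.n_chains))
    scales = (np.asarray(cfg.proposal_scales, dtype=float)
              if cfg.proposal_scales is not None
              else np.array([3.0 if n == "mu_prior" else 0.3 for n in free]))

    draws, lps, acc = _run_metropolis(
        logpost, init, n_samples=cfg.n_samples, burn_in=cfg.burn_in,
        base_scales=scales, rng=rng,
    )

    samples = {n: (draws[:, :, idx[n]] if n == "mu_prior"
                   else np.exp(draws[:, :, idx[n]])) for n in free}
    rhat = {n: float(split_rhat(samples[n])) for n in free}
    ess = _ess_per_param(samples)
    if max(rhat.values()) > 1.05:
        warnings.warn(f"R-hat above 1.05: {rhat}", RuntimeWarning, stacklevel=2)
    point = {n: float(samples[n].mean()) for n in free}
    point.update(fix)
    return FitResult(samples=samples, point_estimates=point, rhat=rhat, ess=ess,
                     log_density=lps, acceptance_rate=float(acc.mean()), fixed=fix)


def _ess_per_param(samples: dict[str, np.ndarray]) -> dict[str, float]:
    import arviz as az

    return {n: float(az.ess(az.convert_to_dataset(arr[None] if arr.ndim == 1 else arr))
                     ["x"].values) for n, arr in samples.items()}


def extract_observer(fit: FitResult, pmap: PsychMap,
                     rhat_threshold: float = 1.05,
                     force: bool = False) -> ObserverParams:
    """Build ObserverParams from posterior-mean point estimates.

    Refuses (with diagnostics) when any R-hat exceeds the threshold, unless
    ``force`` is set.
    """
    worst = max(fit.rhat.values(), default=1.0)
    if worst > rhat_threshold and not force:
        raise ConvergenceError(
            f"fit not converged (max R-hat {worst:.3f} > {rhat_threshold}); "
            f"per-parameter: {fit.rhat}. Pass force=True to override."
        )
    p = fit.point_estimates
    return ObserverParams(
        prior=GaussianBelief(mu=p["mu_prior"], sigma=p["sigma_prior"]),
        sensory_sigma=p["sigma_s"],
        map=pmap,
    )


# ---------------------------------------------------------------------------
# whole-study joint fits (shared sensory channel per participant)
# ---------------------------------------------------------------------------

_JOINT_NAMES = ("mu_prior_doctor", "sigma_prior_doctor",
                "mu_prior_pharmacy", "sigma_prior_pharmacy", "sigma_s")


@dataclass
class StudyFit:
    """Joint per-participant fits for a whole study, batched in one sampler run.

    Per participant the block is (mu_prior, sigma_prior) for each choice
    condition plus a shared sigma_s.
    """

    participants: list[str]
    samples: np.ndarray              # (P, K, chain, draw)
    param_names: tuple[str, ...]
    map: PsychMap

    def point_estimates(self, participant: str) -> dict[str, float]:
        i = self.participants.index(participant)
        return {n: float(self.samples[i, k].mean())
                for k, n in enumerate(self.param_names)}

    def rhat(self) -> np.ndarray:
        """(P, K) split-R-hat per participant and parameter."""
        return split_rhat(self.samples)

    def observer(self, participant: str, condition: str) -> ObserverParams:
        p = self.point_estimates(participant)
        return ObserverParams(
            prior=GaussianBelief(mu=p[f"mu_prior_{condition}"],
                                 sigma=p[f"sigma_prior_{condition}"]),
            sensory_sigma=p["sigma_s"],
            map=self.map,
        )

    def credible_interval(self, participant: str, name: str,
                          level: float = 0.95) -> tuple[float, float]:
        i = self.participants.index(participant)
        k = self.param_names.index(name)
        draws = self.samples[i, k].ravel()
        lo = (1.0 - level) / 2.0
        return (float(np.quantile(draws, lo)), float(np.quantile(draws, 1.0 - lo)))


def fit_study(dataset: StudyDataset, pmap: PsychMap,
              hp: HyperPriors = HyperPriors(),
              cfg: McmcConfig = McmcConfig()) -> StudyFit:
    """Fit every participant's doctor and pharmacy priors jointly.

    All participants and chains run as one vectorised Metropolis batch:
    participants are independent, so the joint posterior factorises and the
    batched chains are exact per-participant chains.
    """
    participants = dataset.participants
    P = len(participants)
    if P == 0:
        raise ValueError("dataset has no participants")

    # padded data arrays: (P, Nmax) per condition
    data = {}
    for cond in ("doctor", "pharmacy"):
        rat, mus, mask = [], [], []
        for pid in participants:
            r, w = conditioning_arrays(dataset, pid, cond)
            rat.append(r)
            mus.append(sensation_mean(w, pmap) if len(w) else np.empty(0))
        n_max = max((len(r) for r in rat), default=0)
        n_max = max(n_max, 1)
        R = np.zeros((P, n_max))
        M = np.zeros((P, n_max))
        mask = np.zeros((P, n_max))
        for i, (r, m) in enumerate(zip(rat, mus)):
            R[i, :len(r)] = r
            M[i, :len(r)] = m
            mask[i, :len(r)] = 1.0
        data[cond] = (R, M, mask)

    K = len(_JOINT_NAMES)
    C = cfg.n_chains
    fix_sig_s = hp.sigma_s_fixed

    # sigma coordinates are sampled as log(sigma); Jacobian terms below
    def logpost(theta_flat: np.ndarray) -> np.ndarray:
        th = theta_flat.reshape(-1, P, K)          # (C, P, K)
        with np.errstate(over="ignore"):
            mu_d, sig_d = th[..., 0:1], np.exp(th[..., 1:2])
            mu_p, sig_p = th[..., 2:3], np.exp(th[..., 3:4])
            sig_s = (np.full_like(mu_d, fix_sig_s) if fix_sig_s is not None
                     else np.exp(th[..., 4:5]))
            Rd, Md, kd = data["doctor"]
            Rp, Mp, kp = data["pharmacy"]
            lp = _cond_loglik(mu_d, sig_d, sig_s, Rd, Md, kd)
            lp += _cond_loglik(mu_p, sig_p, sig_s, Rp, Mp, kp)
            lp += _normal_logpdf(mu_d[..., 0], hp.mu_prior_location, hp.mu_prior_scale)
            lp += _normal_logpdf(mu_p[..., 0], hp.mu_prior_location, hp.mu_prior_scale)
            lp += _halfnormal_logpdf(sig_d[..., 0], hp.sigma_prior_scale)
            lp += _halfnormal_logpdf(sig_p[..., 0], hp.sigma_prior_scale)
            lp += np.log(sig_d[..., 0]) + np.log(sig_p[..., 0])
            if fix_sig_s is None:
                lp += _halfnormal_logpdf(sig_s[..., 0], hp.sigma_s_scale)
                lp += np.log(sig_s[..., 0])
        lp = np.where(np.isfinite(lp), lp, -np.inf)
        return lp.reshape(-1)

    rng = np.random.default_rng(cfg.seed)
    init = np.empty((C, P, K))
    for i, pid in enumerate(participants):
        for j, cond in enumerate(("doctor", "pharmacy")):
            r, _ = conditioning_arrays(dataset, pid, cond)
            base = r.mean() if len(r) else hp.mu_prior_location
            init[:, i, 2 * j] = base + rng.normal(0.0, 15.0, C)
            init[:, i, 2 * j + 1] = np.log(rng.uniform(5.0, 25.0, C))
    init[:, :, 4] = (0.0 if fix_sig_s is not None
                     else np.log(rng.uniform(5.0, 25.0, (C, P))))

    scales = np.array([3.0, 0.3, 3.0, 0.3, 0.3])
    if fix_sig_s is not None:
        scales = scales.copy()
        scales[4] = 0.0  # frozen coordinate

    draws, _, _ = _run_metropolis(
        logpost, init.reshape(C * P, K), n_samples=cfg.n_samples,
        burn_in=cfg.burn_in, base_scales=scales, rng=rng,
    )
    kept = draws.shape[1]
    # (C*P, kept, K) -> (P, K, C, kept); sigma coords back to natural scale
    samples = draws.reshape(C, P, kept, K).transpose(1, 3, 0, 2)
    samples[:, 1] = np.exp(samples[:, 1])
    samples[:, 3] = np.exp(samples[:, 3])
    samples[:, 4] = (fix_sig_s if fix_sig_s is not None
                     else np.exp(samples[:, 4]))
    return StudyFit(participants=participants, samples=samples,
                    param_names=_JOINT_NAMES, map=pmap)
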