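"""Maximum-likelihood fitting, KS goodness of fit, and x_min selection.

The estimation step of the pipeline: given the multiset of per-segment token
counts of one language, fit a tail family either to the full data (with
``x_min`` anchored at the smallest observed count, so every observation is in
support) or with ``x_min`` estimated by minimizing the Kolmogorov–Smirnov
distance over candidate cutoffs, refitting the parameters at each candidate.

All four families use truncated likelihoods renormalized over ``x >= x_min``
so that they are compared on identical support — a prerequisite for the
likelihood-ratio comparisons downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .distributions import ALPHA_MAX, TailModel, _as_observations

__all__ = ["FitResult", "fit_mle", "ks_distance", "estimate_xmin"]

log = logging.getLogger(__name__)

#: Minimum tail observations (and distinct values) for a meaningful KS distance.
MIN_TAIL_DEFAULT = 2


@dataclass
class FitResult:
    """A fitted tail model with its goodness-of-fit bookkeeping."""

    model: TailModel
    n_total: int
    n_tail: int
    ks_D: float
    converged: bool
    xmin_estimated: bool = False

    @property
    def prop_fitted(self) -> float:
        """Fraction of the language's observations at or above x_min."""
        return self.n_tail / self.n_total

    def to_row(self, language_id: str | None = None) -> dict:
        row = {} if language_id is None else {"language": language_id}
        row.update(
            family=self.model.family,
            x_min=self.model.x_min,
            n_tail=self.n_tail,
            prop_fitted=self.prop_fitted,
            ks_D=self.ks_D,
            converged=self.converged,
            xmin_estimated=self.xmin_estimated,
        )
        for name, value in zip(self.model.param_names, self.model.params):
            row[name] = value
        return row


def _unique_counts(tail: np.ndarray):
    vals, cnts = np.unique(tail, return_counts=True)
    return vals.astype(float), cnts.astype(float)


def _fit_powerlaw(tail: np.ndarray, x_min: int):
    vals, cnts = _unique_counts(tail)
    n = cnts.sum()
    if vals.size == 1:
        # All observations at a single value: the likelihood increases without
        # bound as alpha grows; report the boundary and flag non-convergence.
        return (ALPHA_MAX,), False
    slog = float(np.sum(cnts * np.log(vals)))

    def nll(alpha):
        return alpha * slog + n * math.log(special.zeta(alpha, x_min))

    res = optimize.minimize_scalar(nll, bounds=(1.0 + 1e-9, ALPHA_MAX), method="bounded",
                                   options={"xatol": 1e-9})
    alpha = float(res.x)
    converged = bool(res.success) and alpha < ALPHA_MAX - 1e-6
    return (alpha,), converged


def _fit_exponential(tail: np.ndarray, x_min: int):
    # Geometric MLE on support {x_min, x_min+1, ...}: theta = n / sum(x - x_min + 1)
    n = tail.size
    theta = n / float(np.sum(tail - x_min + 1))
    if theta >= 1.0:  # all observations exactly at x_min
        return (1.0 - 1e-9,), False
    return (theta,), True


def _fit_poisson(tail: np.ndarray, x_min: int):
    vals, cnts = _unique_counts(tail)
    n = cnts.sum()
    mean = float(np.sum(vals * cnts) / n)
    sum_gammaln = float(np.sum(cnts * special.gammaln(vals + 1)))
    sum_x = float(np.sum(vals * cnts))

    def nll(lam):
        norm = stats.poisson.sf(x_min - 1, lam)
        if norm <= 0:
            return np.inf
        return -(sum_x * math.log(lam) - n * lam - sum_gammaln) + n * math.log(norm)

    hi = max(4.0 * mean, 10.0)
    res = optimize.minimize_scalar(nll, bounds=(1e-8, hi), method="bounded",
                                   options={"xatol": 1e-8 * hi})
    lam = float(res.x)
    converged = bool(res.success) and 1e-6 < lam < hi * (1 - 1e-9)
    return (lam,), converged


def _fit_lognormal(tail: np.ndarray, x_min: int):
    vals, cnts = _unique_counts(tail)
    logs = np.log(tail.astype(float))
    mu0 = float(logs.mean())
    sigma0 = float(max(logs.std(), 0.05))
    bounds = [(-100.0, 100.0), (1e-3, 100.0)]

    def nll(p):
        mu, sigma = p
        dist = stats.lognorm(s=sigma, scale=math.exp(mu))
        num = dist.sf(vals) - dist.sf(vals + 1)
        norm = dist.sf(x_min)
        if norm <= 0 or np.any(num <= 0):
            return 1e12
        return -float(np.sum(cnts * np.log(num))) + cnts.sum() * math.log(norm)

    res = optimize.minimize(nll, x0=np.array([mu0, sigma0]), method="L-BFGS-B",
                            bounds=bounds)
    mu, sigma = (float(res.x[0]), float(res.x[1]))
    at_bound = sigma <= bounds[1][0] * (1 + 1e-6) or sigma >= bounds[1][1] * (1 - 1e-6)
    return (mu, max(sigma, 1e-3)), bool(res.success) and not at_bound


_FITTERS = {
    "powerlaw": _fit_powerlaw,
    "exponential": _fit_exponential,
    "poisson": _fit_poisson,
    "lognormal": _fit_lognormal,
}


def fit_mle(family: str, data, x_min: int = 1) -> FitResult:
    """Fit one tail family to the observations at or above ``x_min``.

    Closed forms are used where they exist (geometric); the power law,
    truncated Poisson and discretized lognormal are maximized numerically
    within generous bounds. Optimizer failure or a boundary solution is
    reported through ``converged=False``, never as an exception.
    """
    if family not in _FITTERS:
        raise ValueError(f"unknown family {family!r}")
    obs = _as_observations(data)
    tail = obs[obs >= x_min]
    if tail.size < 2:
        raise ValueError(
            f"need at least 2 observations >= x_min={x_min} to fit {family}; have {tail.size}"
        )
    params, converged = _FITTERS[family](tail, int(x_min))
    model = TailModel(family, params, int(x_min))
    return FitResult(
        model=model,
        n_total=int(obs.size),
        n_tail=int(tail.size),
        ks_D=ks_distance(model, tail),
        converged=converged,
    )


def ks_distance(model: TailModel, data) -> float:
    """Kolmogorov–Smirnov distance between data and model on the tail.

    The maximum over the observed support of the absolute difference between
    the (right-continuous) empirical CDF and the model CDF; larger is worse.
    """
    tail = _as_observations(data)
    if tail.size == 0:
        raise ValueError("cannot compute a KS distance on an empty tail")
    if tail.min() < model.x_min:
        raise ValueError("all data must lie at or above the model's x_min")
    vals, cnts = np.unique(tail, return_counts=True)
    ecdf = np.cumsum(cnts) / tail.size
    return float(np.max(np.abs(ecdf - model.cdf(vals))))


def estimate_xmin(family: str, data, min_tail: int = MIN_TAIL_DEFAULT) -> FitResult:
    """Select ``x_min`` by KS minimization over the observed unique values.

    For each candidate cutoff (every distinct observed count that leaves at
    least ``min_tail`` observations and two distinct values in the tail), the
    family is refitted by MLE and its KS distance recorded; the candidate with
    the smallest distance wins, ties broken toward the smaller cutoff (more
    data retained). Converged fits are preferred over non-converged ones.
    """
    obs = _as_observations(data)
    candidates = np.unique(obs)
    best: FitResult | None = None
    best_unconverged: FitResult | None = None
    for xmin in candidates:
        tail = obs[obs >= xmin]
        if tail.size < max(min_tail, 2) or np.unique(tail).size < 2:
            continue
        try:
            fit = fit_mle(family, obs, x_min=int(xmin))
        except (ValueError, FloatingPointError):
            continue
        fit.xmin_estimated = True
        if fit.converged:
            if best is None or fit.ks_D < best.ks_D - 1e-15:
                best = fit
        elif best_unconverged is None or fit.ks_D < best_unconverged.ks_D - 1e-15:
            best_unconverged = fit
    if best is None:
        if best_unconverged is not None:
            log.warning("estimate_xmin(%s): only non-converged candidate fits", family)
            return best_unconverged
        raise ValueError(
            f"no admissible x_min candidate for {family} with min_tail={min_tail}"
        )
    return best
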