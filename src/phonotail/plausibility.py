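"""Semi-parametric bootstrap plausibility test for a fitted tail model.

The KS distance of a fitted model has no analytic null distribution once the
parameters (and possibly x_min) have been estimated from the same data, so
the null is calibrated by Monte Carlo: each replicate draws a dataset of the
original size, taking each point from the fitted model (above x_min) with
probability n_tail/n_total and otherwise uniformly from the empirical
observations below x_min; the full estimation pipeline that produced the fit
is re-run on the replicate, and the replicate KS distances form the reference
distribution. The p-value is the fraction of replicate distances at least as
large as the observed one. A model with p <= 0.1 is rejected; p > 0.1 leaves
it plausible (not proven).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .distributions import _as_observations
from .fitting import MIN_TAIL_DEFAULT, FitResult, estimate_xmin, fit_mle

__all__ = ["BootstrapResult", "bootstrap_pvalue", "is_plausible"]

log = logging.getLogger(__name__)

#: Reference replicate count used by the original study.
N_REPS_DEFAULT = 10_000

#: Bootstrap p at or below this threshold rejects the candidate family.
PLAUSIBILITY_THRESHOLD = 0.1


@dataclass
class BootstrapResult:
    fit: FitResult
    n_reps: int
    observed_D: float
    p_value: float
    n_failed: int
    seed: int | None

    def to_row(self, language_id: str | None = None) -> dict:
        row = self.fit.to_row(language_id)
        row.update(p_value=self.p_value, n_reps=self.n_reps, n_failed=self.n_failed,
                   plausible=is_plausible(self))
        return row


def _one_replicate(fit: FitResult, below: np.ndarray, n_total: int,
                   p_tail: float, min_tail: int, rng: np.random.Generator) -> float:
    k = int(rng.binomial(n_total, p_tail)) if below.size else n_total
    parts = [fit.model.sample(k, rng=rng)]
    if n_total - k > 0:
        parts.append(rng.choice(below, size=n_total - k, replace=True))
    rep = np.concatenate(parts)
    if fit.xmin_estimated:
        refit = estimate_xmin(fit.model.family, rep, min_tail=min_tail)
    else:
        refit = fit_mle(fit.model.family, rep, x_min=int(rep.min()))
    if not refit.converged:
        raise ValueError("replicate refit did not converge")
    return refit.ks_D


def bootstrap_pvalue(
    fit: FitResult,
    data,
    n_reps: int = N_REPS_DEFAULT,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    min_tail: int = MIN_TAIL_DEFAULT,
    smoothed: bool = False,
) -> BootstrapResult:
    """Bootstrap p-value for the plausibility of ``fit`` on its language.

    ``data`` must be the full, untruncated observation multiset the fit came
    from. Replicates whose refit fails are dropped and counted in
    ``n_failed`` (warned above 1%). With ``smoothed=True`` the (+1)/(+1)
    estimator is used instead of the raw exceedance fraction; the raw
    fraction counts ties toward plausibility.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not fit.converged:
        raise ValueError("refusing to bootstrap a non-converged fit")
    obs = _as_observations(data)
    if obs.size != fit.n_total:
        raise ValueError("data does not match the fit's n_total; pass the full sample")
    if rng is None:
        rng = np.random.default_rng(seed)
    below = obs[obs < fit.model.x_min]
    p_tail = fit.n_tail / fit.n_total
    ds = np.empty(n_reps)
    n_failed = 0
    n_ok = 0
    for _ in range(n_reps):
        try:
            ds[n_ok] = _one_replicate(fit, below, fit.n_total, p_tail, min_tail, rng)
            n_ok += 1
        except (ValueError, FloatingPointError):
            n_failed += 1
    if n_ok == 0:
        raise ValueError(f"all {n_reps} bootstrap replicates failed to refit "
                         f"({fit.model.family})")
    if n_failed > 0.01 * n_reps:
        log.warning("%s bootstrap: %d/%d replicates failed to refit",
                    fit.model.family, n_failed, n_reps)
    exceed = int(np.sum(ds[:n_ok] >= fit.ks_D))
    p = (exceed + 1) / (n_ok + 1) if smoothed else exceed / n_ok
    return BootstrapResult(fit=fit, n_reps=n_reps, observed_D=fit.ks_D,
                           p_value=float(p), n_failed=n_failed, seed=seed)


def is_plausible(result: BootstrapResult, threshold: float = PLAUSIBILITY_THRESHOLD) -> bool:
    """True iff the bootstrap p-value exceeds the threshold (p <= 0.1 rejects)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return result.p_value > threshold
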