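"""Vuong likelihood-ratio model comparison and Bonferroni correction.

Vuong's test compares two non-nested candidate families on the same data and
the same support: the statistic is the sum of per-observation log-likelihood
ratios normalized by its sample standard deviation and sqrt(n), referred to a
standard normal. Its sign says which family the data favor; the two-sided
p-value says whether the preference is distinguishable from chance.

Because a tail model is only defined above its x_min, two families can only
be compared at a common x_min. When each family estimated its own cutoff, the
comparison is run twice: once imposing A's cutoff (refitting B's parameters
there) and once imposing B's (refitting A) — each direction tagged with the
cutoff's provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .distributions import _as_observations
from .fitting import MIN_TAIL_DEFAULT, FitResult, estimate_xmin, fit_mle

__all__ = ["VuongResult", "vuong_test", "cross_xmin_compare", "bonferroni_adjust"]


@dataclass
class VuongResult:
    family_a: str
    family_b: str
    x_min_used: int
    x_min_source: str  # which family's estimated x_min was imposed ("shared" if equal)
    n_tail: int
    statistic: float  # positive favors family_a
    p_two_sided: float
    favored: str  # family id or "neither" (raw sign, recorded even if not significant)
    significant_bonferroni: bool = False

    def to_row(self, language_id: str | None = None) -> dict:
        row = {} if language_id is None else {"language": language_id}
        row.update(
            pair=f"{self.family_a}_vs_{self.family_b}",
            x_min_source=self.x_min_source,
            x_min=self.x_min_used,
            n_tail=self.n_tail,
            statistic=self.statistic,
            p=self.p_two_sided,
            favored=self.favored,
            significant=self.significant_bonferroni,
        )
        return row


def vuong_test(fit_a: FitResult, fit_b: FitResult, data,
               x_min_source: str = "shared") -> VuongResult:
    """Vuong's normalized log-likelihood-ratio test between two fitted models.

    Both fits must share the same x_min (the test is only meaningful on a
    common support) and have converged. Zero variance of the pointwise
    log-ratios (identical likelihoods) yields statistic 0 and "neither".
    """
    ma, mb = fit_a.model, fit_b.model
    if ma.x_min != mb.x_min:
        raise ValueError(
            f"x_min mismatch ({ma.x_min} vs {mb.x_min}): both distributions must "
            "share the same x_min for a likelihood-ratio comparison"
        )
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both fits must have converged")
    obs = _as_observations(data)
    tail = obs[obs >= ma.x_min]
    r = ma.logpmf(tail) - mb.logpmf(tail)
    n = tail.size
    s_r = float(np.std(r, ddof=1)) if n > 1 else 0.0
    if s_r == 0.0 or not np.isfinite(s_r):
        stat, p = 0.0, 1.0
    else:
        stat = float(np.sum(r) / (s_r * math.sqrt(n)))
        p = float(2.0 * stats.norm.sf(abs(stat)))
    if stat > 0:
        favored = ma.family
    elif stat < 0:
        favored = mb.family
    else:
        favored = "neither"
    return VuongResult(
        family_a=ma.family, family_b=mb.family, x_min_used=ma.x_min,
        x_min_source=x_min_source, n_tail=int(n), statistic=stat,
        p_two_sided=p, favored=favored,
    )


def cross_xmin_compare(family_a: str, family_b: str, data,
                       min_tail: int = MIN_TAIL_DEFAULT):
    """Compare two families that each estimated their own x_min.

    Returns a pair of VuongResults: the first imposes A's estimated x_min on
    B (B's parameters re-estimated there), the second imposes B's on A. A
    direction whose refit fails is returned as None, the other still computed.
    """
    obs = _as_observations(data)
    fit_a = estimate_xmin(family_a, obs, min_tail=min_tail)
    fit_b = estimate_xmin(family_b, obs, min_tail=min_tail)

    def _direction(anchor: FitResult, other_family: str, source: str, flip: bool):
        try:
            refit = fit_mle(other_family, obs, x_min=anchor.model.x_min)
            if not refit.converged:
                return None
            if flip:
                return vuong_test(refit, anchor, obs, x_min_source=source)
            return vuong_test(anchor, refit, obs, x_min_source=source)
        except (ValueError, FloatingPointError):
            return None

    res_a = _direction(fit_a, family_b, source=family_a, flip=False)
    res_b = _direction(fit_b, family_a, source=family_b, flip=True)
    return res_a, res_b


def bonferroni_adjust(p_values, m: int | None = None, alpha: float = 0.05):
    """Family-wise significance mask: significant iff p <= alpha / m."""
    p = list(p_values)
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("m must be >= 1")
    cutoff = alpha / m
    return [pv <= cutoff for pv in p]
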