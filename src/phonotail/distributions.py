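"""Candidate distributions for segment-frequency data.

Two kinds of model live here.

``TailModel`` covers the four families that are fitted by maximum likelihood
to the multiset of per-segment token counts of a single language: the discrete
power law (Hurwitz-zeta normalized), the discretized lognormal, the geometric
distribution (the discrete analog of the exponential), and the Poisson. Every
family carries a lower support bound ``x_min``: the model is defined, and
normalized, over the integers ``{x_min, x_min+1, ...}`` only. Observations
below ``x_min`` are outside the model and have probability zero.

``RankModel`` covers the historical rank–frequency proposals for phoneme
inventories: Zipf's law, Sigurd's geometric series, Good's stick-breaking
expectation, the discretized negative-log approximation to it, and the
Yule–Simon product form ``k^(-alpha) * lambda^k``. These are finite
distributions over the ranks ``1..n`` of an inventory of ``n`` segment types.
They are provided as evaluators and samplers only; no maximum-likelihood
estimator is offered for them (none is established for the Yule–Simon form).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Iterable, Union

import numpy as np
from scipy import special, stats

__all__ = [
    "TAIL_FAMILIES",
    "RANK_FAMILIES",
    "TailModel",
    "RankModel",
    "stick_break_expectation",
    "model_from_json",
]

TAIL_FAMILIES = ("powerlaw", "lognormal", "exponential", "poisson")
RANK_FAMILIES = ("zipf", "sigurd_geometric", "good_stickbreak", "neglog", "yule_simon")

# Number of parameters per tail family (x_min excluded).
N_PARAMS = {"powerlaw": 1, "lognormal": 2, "exponential": 1, "poisson": 1}

#: Upper bound on the power-law exponent used throughout fitting; the largest
#: exponent observed in real inventories is around 6, so 20 is generous.
ALPHA_MAX = 20.0


def _as_observations(data) -> np.ndarray:
    """Coerce a FrequencyTable or an integer multiset to an int array."""
    if hasattr(data, "observations"):
        return data.observations()
    arr = np.asarray(list(data) if isinstance(data, (set, frozenset)) else data)
    return arr.astype(np.int64)


@dataclass(frozen=True)
class TailModel:
    """A candidate distribution over integer counts ``x >= x_min``.

    Parameters
    ----------
    family:
        One of ``powerlaw``, ``lognormal``, ``exponential``, ``poisson``.
    params:
        Family-specific parameter vector:

        - powerlaw: ``(alpha,)`` with scaling exponent ``alpha > 1``;
        - lognormal: ``(mu, sigma)``, log-mean and log-SD (``sigma > 0``);
        - exponential: ``(theta,)`` the per-step decay (geometric success)
          probability, ``0 < theta < 1``;
        - poisson: ``(lam,)`` the Poisson mean, ``lam > 0``.
    x_min:
        Lower support bound (integer >= 1). The pmf is renormalized so it
        sums to one over ``{x_min, x_min+1, ...}``.
    """

    family: str
    params: tuple
    x_min: int = 1

    def __post_init__(self):
        if self.family not in TAIL_FAMILIES:
            raise ValueError(f"unknown tail family {self.family!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        object.__setattr__(self, "x_min", int(self.x_min))
        if self.x_min < 1:
            raise ValueError("x_min must be a positive integer")
        if len(self.params) != N_PARAMS[self.family]:
            raise ValueError(
                f"{self.family} takes {N_PARAMS[self.family]} parameter(s), "
                f"got {len(self.params)}"
            )
        p = self.params
        if self.family == "powerlaw" and p[0] <= 1.0:
            raise ValueError("power-law exponent must exceed 1 for a normalizable pmf")
        if self.family == "lognormal" and p[1] <= 0.0:
            raise ValueError("lognormal sigma must be positive")
        if self.family == "exponential" and not 0.0 < p[0] < 1.0:
            raise ValueError("geometric decay parameter theta must lie in (0, 1)")
        if self.family == "poisson" and p[0] <= 0.0:
            raise ValueError("poisson mean must be positive")

    # -- parameter access -------------------------------------------------

    @property
    def param_names(self) -> tuple:
        return {
            "powerlaw": ("alpha",),
            "lognormal": ("mu", "sigma"),
            "exponential": ("theta",),
            "poisson": ("lam",),
        }[self.family]

    @property
    def primary_param(self) -> float:
        """The family's headline shape parameter (alpha, sigma, theta, lam)."""
        return self.params[1] if self.family == "lognormal" else self.params[0]

    def with_x_min(self, x_min: int) -> "TailModel":
        return replace(self, x_min=int(x_min))

    # -- pmf / cdf ---------------------------------------------------------

    def logpmf(self, x) -> Union[float, np.ndarray]:
        x = np.asarray(x)
        scalar = x.ndim == 0
        x = np.atleast_1d(x).astype(np.int64)
        out = np.full(x.shape, -np.inf, dtype=float)
        ok = x >= self.x_min
        if ok.any():
            out[ok] = self._logpmf_support(x[ok])
        return float(out[0]) if scalar else out

    def pmf(self, x) -> Union[float, np.ndarray]:
        """Probability of observing the integer count ``x``; 0 below x_min."""
        return np.exp(self.logpmf(x))

    def cdf(self, x) -> Union[float, np.ndarray]:
        """P(X <= x) for the truncated model; 0 below x_min, limit 1."""
        x = np.asarray(x)
        scalar = x.ndim == 0
        x = np.atleast_1d(x).astype(np.int64)
        out = np.zeros(x.shape, dtype=float)
        ok = x >= self.x_min
        if ok.any():
            out[ok] = np.clip(self._cdf_support(x[ok]), 0.0, 1.0)
        return float(out[0]) if scalar else out

    def sf(self, x):
        return 1.0 - self.cdf(x)

    def _logpmf_support(self, x: np.ndarray) -> np.ndarray:
        xm = self.x_min
        if self.family == "powerlaw":
            (alpha,) = self.params
            return -alpha * np.log(x) - math.log(special.zeta(alpha, xm))
        if self.family == "exponential":
            (theta,) = self.params
            return math.log(theta) + (x - xm) * math.log1p(-theta)
        if self.family == "poisson":
            (lam,) = self.params
            norm = stats.poisson.sf(xm - 1, lam)
            return stats.poisson.logpmf(x, lam) - math.log(norm)
        # lognormal: unit-interval CDF increments renormalized above x_min
        mu, sigma = self.params
        dist = stats.lognorm(s=sigma, scale=math.exp(mu))
        num = dist.sf(x) - dist.sf(x + 1)
        return np.log(np.clip(num, 1e-320, None)) - math.log(dist.sf(xm))

    def _cdf_support(self, x: np.ndarray) -> np.ndarray:
        xm = self.x_min
        if self.family == "powerlaw":
            (alpha,) = self.params
            return 1.0 - special.zeta(alpha, x + 1.0) / special.zeta(alpha, xm)
        if self.family == "exponential":
            (theta,) = self.params
            return -np.expm1((x - xm + 1) * math.log1p(-theta))
        if self.family == "poisson":
            (lam,) = self.params
            lo = stats.poisson.cdf(xm - 1, lam)
            return (stats.poisson.cdf(x, lam) - lo) / (1.0 - lo)
        mu, sigma = self.params
        dist = stats.lognorm(s=sigma, scale=math.exp(mu))
        return 1.0 - dist.sf(x + 1) / dist.sf(xm)

    # -- likelihood --------------------------------------------------------

    def loglik(self, data) -> float:
        """Sum of log pmf over the observations.

        The caller is responsible for truncating the data to the model's
        support; an observation below ``x_min`` raises, because it signals a
        bookkeeping error rather than a merely poor fit.
        """
        obs = _as_observations(data)
        if obs.size and obs.min() < self.x_min:
            raise ValueError(
                f"datum {obs.min()} lies below x_min={self.x_min}; "
                "truncate the data to the tail before computing the likelihood"
            )
        return float(np.sum(self.logpmf(obs)))

    # -- sampling ----------------------------------------------------------

    def sample(self, n: int, seed=None, rng: np.random.Generator | None = None) -> np.ndarray:
        """Draw ``n`` iid counts from the model (inverse-CDF; seedable)."""
        if n < 0:
            raise ValueError("sample size must be non-negative")
        if rng is None:
            rng = np.random.default_rng(seed)
        if n == 0:
            return np.empty(0, dtype=np.int64)
        xm = self.x_min
        if self.family == "exponential":
            (theta,) = self.params
            return xm - 1 + rng.geometric(theta, size=n).astype(np.int64)
        u = rng.random(n)
        if self.family == "poisson":
            (lam,) = self.params
            lo = stats.poisson.cdf(xm - 1, lam)
            return stats.poisson.ppf(lo + u * (1.0 - lo), lam).astype(np.int64)
        if self.family == "lognormal":
            mu, sigma = self.params
            dist = stats.lognorm(s=sigma, scale=math.exp(mu))
            # smallest integer x >= x_min with sf(x+1) <= (1-u) * sf(x_min)
            q = dist.isf((1.0 - u) * dist.sf(xm))
            return np.maximum(xm, np.ceil(q - 1.0)).astype(np.int64)
        return self._sample_powerlaw(u)

    def _sample_powerlaw(self, u: np.ndarray) -> np.ndarray:
        (alpha,) = self.params
        xm = self.x_min
        z = special.zeta(alpha, xm)
        # Table-based inversion over a doubling horizon; the handful of draws
        # beyond the horizon fall back to bisection on the closed-form CDF.
        horizon = 4096
        grid = np.arange(xm, xm + horizon, dtype=np.int64)
        cdf = 1.0 - special.zeta(alpha, grid + 1.0) / z
        idx = np.searchsorted(cdf, u, side="left")
        out = np.empty(u.shape, dtype=np.int64)
        inside = idx < horizon
        out[inside] = grid[idx[inside]]
        for j in np.nonzero(~inside)[0]:
            out[j] = self._powerlaw_quantile(u[j], z, alpha)
        return out

    def _powerlaw_quantile(self, u: float, z: float, alpha: float) -> int:
        target = (1.0 - u) * z  # want smallest x with zeta(alpha, x+1) <= target
        lo = self.x_min
        hi = max(2 * lo, lo + 1)
        while special.zeta(alpha, hi + 1.0) > target:
            lo, hi = hi, hi * 2
        while lo < hi:
            mid = (lo + hi) // 2
            if special.zeta(alpha, mid + 1.0) <= target:
                hi = mid
            else:
                lo = mid + 1
        return int(lo)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {"kind": "tail", "family": self.family, "params": list(self.params),
             "x_min": self.x_min}
        )


@dataclass(frozen=True)
class RankModel:
    """A finite rank–frequency distribution over ranks ``1..n``.

    ``alpha`` is the power-law exponent (used by ``zipf`` and ``yule_simon``);
    ``lam`` the geometric ratio in (0, 1] (used by ``sigurd_geometric`` and
    ``yule_simon``). ``good_stickbreak`` and ``neglog`` are parameter-free.
    """

    family: str
    n: int
    alpha: float = 1.0
    lam: float = 1.0

    def __post_init__(self):
        if self.family not in RANK_FAMILIES:
            raise ValueError(f"unknown rank family {self.family!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 < self.lam <= 1.0:
            raise ValueError("lam must lie in (0, 1]")

    def probabilities(self) -> np.ndarray:
        """Normalized rank probabilities p(x_1)..p(x_n), descending ranks."""
        k = np.arange(1, self.n + 1, dtype=float)
        if self.family == "zipf":
            w = k ** (-self.alpha)
        elif self.family == "sigurd_geometric":
            w = self.lam ** k
        elif self.family == "good_stickbreak":
            return stick_break_expectation(self.n)
        elif self.family == "neglog":
            w = -np.log(k / (self.n + 1))
        else:  # yule_simon
            w = self.lam ** k / k ** self.alpha
        return w / w.sum()

    def rank_pmf(self, k) -> Union[float, np.ndarray]:
        k_arr = np.atleast_1d(np.asarray(k)).astype(np.int64)
        if k_arr.min() < 1 or k_arr.max() > self.n:
            raise ValueError(f"rank must lie in [1, {self.n}]")
        p = self.probabilities()[k_arr - 1]
        return float(p[0]) if np.ndim(k) == 0 else p

    def sample(self, size: int, seed=None, rng: np.random.Generator | None = None) -> np.ndarray:
        """Draw ``size`` iid ranks from the model."""
        if rng is None:
            rng = np.random.default_rng(seed)
        return rng.choice(np.arange(1, self.n + 1), size=size, p=self.probabilities())

    def to_json(self) -> str:
        return json.dumps(
            {"kind": "rank", "family": self.family, "n": self.n,
             "alpha": self.alpha, "lam": self.lam}
        )


def stick_break_expectation(n: int) -> np.ndarray:
    """Expected sorted part sizes when [0, 1] is broken into ``n`` uniform parts.

    Entry ``k`` (1-based, descending) is ``(1/n) * sum_{i=k..n} 1/i``; the
    vector sums to one exactly and equals the ``good_stickbreak`` rank pmf.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    inv = 1.0 / np.arange(1, n + 1, dtype=float)
    return np.cumsum(inv[::-1])[::-1] / n


def model_from_json(text: str):
    """Inverse of ``TailModel.to_json`` / ``RankModel.to_json``."""
    obj = json.loads(text)
    kind = obj.pop("kind")
    if kind == "tail":
        return TailModel(obj["family"], tuple(obj["params"]), obj["x_min"])
    if kind == "rank":
        return RankModel(obj["family"], obj["n"], obj.get("alpha", 1.0), obj.get("lam", 1.0))
    raise ValueError(f"unknown model kind {kind!r}")
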