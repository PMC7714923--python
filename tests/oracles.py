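"""Independent brute-force oracles used by the tests.

Deliberately naive: dense grid scans, per-point loops and exhaustive
candidate enumeration, kept free of the library's own optimization paths.
"""

import math

import numpy as np
from scipy import special, stats

from phonotail.distributions import TailModel
from phonotail.fitting import fit_mle, ks_distance


def naive_ks(model, data):
    """Max |ecdf - cdf| by explicit loop over the observed unique values."""
    data = np.sort(np.asarray(data))
    n = data.size
    best = 0.0
    for x in np.unique(data):
        ecdf = np.sum(data <= x) / n
        best = max(best, abs(ecdf - model.cdf(int(x))))
    return best


def _loglik(family, params, data, x_min):
    return TailModel(family, params, x_min).loglik(data)


def grid_search_mle(family, data, x_min, resolution=1e-3):
    """Dense grid argmax of the truncated log-likelihood.

    1-parameter families use a single flat grid at the requested resolution;
    the lognormal uses an iteratively refined 2-d grid whose final spacing is
    below the resolution. Returns (params, loglik).
    """
    data = np.asarray(data)
    tail = data[data >= x_min]
    vals, cnts = np.unique(tail, return_counts=True)
    n = cnts.sum()
    if family == "powerlaw":
        grid = np.arange(1.0 + resolution, 20.0, resolution)
        slog = np.sum(cnts * np.log(vals))
        ll = -(grid * slog) - n * np.log(special.zeta(grid, x_min))
        best = grid[np.argmax(ll)]
        return (float(best),), float(ll.max())
    if family == "exponential":
        grid = np.arange(resolution, 1.0, resolution)
        ll = (n * np.log(grid)
              + np.sum(cnts * (vals - x_min)) * np.log1p(-grid))
        best = grid[np.argmax(ll)]
        return (float(best),), float(ll.max())
    if family == "poisson":
        mean = float(np.sum(vals * cnts) / n)
        grid = np.arange(resolution, 4 * mean + 10, resolution)
        sum_x = np.sum(vals * cnts)
        sum_gl = np.sum(cnts * special.gammaln(vals + 1))
        ll = (sum_x * np.log(grid) - n * grid - sum_gl
              - n * np.log(stats.poisson.sf(x_min - 1, grid)))
        best = grid[np.argmax(ll)]
        return (float(best),), float(ll.max())
    if family == "lognormal":
        logs = np.log(tail.astype(float))
        mu_lo, mu_hi = logs.mean() - 3, logs.mean() + 3
        s_lo, s_hi = 1e-2, max(3.0, 3 * logs.std())
        best = None
        for _ in range(5):  # zoom until spacing < resolution
            mus = np.linspace(mu_lo, mu_hi, 41)
            sigmas = np.linspace(s_lo, s_hi, 41)
            scores = np.full((41, 41), -np.inf)
            for i, mu in enumerate(mus):
                for j, sg in enumerate(sigmas):
                    try:
                        scores[i, j] = _loglik(family, (mu, sg), tail, x_min)
                    except (ValueError, FloatingPointError):
                        pass
            i, j = np.unravel_index(np.argmax(scores), scores.shape)
            best = ((float(mus[i]), float(sigmas[j])), float(scores[i, j]))
            dmu, ds = mus[1] - mus[0], sigmas[1] - sigmas[0]
            mu_lo, mu_hi = mus[i] - dmu, mus[i] + dmu
            s_lo, s_hi = max(sigmas[j] - ds, 1e-3), sigmas[j] + ds
            if max(dmu, ds) < resolution:
                break
        return best
    raise ValueError(family)


def scan_xmin(family, data, min_tail=2):
    """Exhaustive x_min scan: refit at every admissible unique value, take min KS."""
    data = np.asarray(data)
    best = None
    for xmin in np.unique(data):
        tail = data[data >= xmin]
        if tail.size < max(min_tail, 2) or np.unique(tail).size < 2:
            continue
        try:
            fit = fit_mle(family, data, x_min=int(xmin))
        except (ValueError, FloatingPointError):
            continue
        if not fit.converged:
            continue
        if best is None or fit.ks_D < best.ks_D - 1e-15:
            best = fit
    return best
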