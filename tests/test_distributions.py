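"""Tail and rank distribution evaluators and samplers."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from phonotail.distributions import (RankModel, TailModel, model_from_json,
                                     stick_break_expectation)

FAMILY_EXAMPLES = {
    "powerlaw": (2.0,),
    "lognormal": (1.0, 0.8),
    "exponential": (0.4,),
    "poisson": (3.0,),
}


def make_model(family, x_min=1):
    return TailModel(family, FAMILY_EXAMPLES[family], x_min)


tail_models = st.builds(
    make_model,
    st.sampled_from(sorted(FAMILY_EXAMPLES)),
    st.integers(min_value=1, max_value=5),
)


# -- pmf / cdf closed forms -------------------------------------------------


def test_powerlaw_pmf_closed_form():
    # at alpha=2, x_min=1 the normalizer is zeta(2) = pi^2 / 6
    m = TailModel("powerlaw", (2.0,), 1)
    assert m.pmf(1) == pytest.approx(6 / math.pi**2, rel=1e-12)
    assert m.pmf(3) == pytest.approx((6 / math.pi**2) / 9, rel=1e-12)


def test_geometric_halving():
    m = TailModel("exponential", (0.5,), 1)
    assert m.pmf([1, 2, 3]) == pytest.approx([0.5, 0.25, 0.125])
    assert m.cdf(3) == pytest.approx(0.875)


@given(tail_models)
def test_pmf_normalizes(model):
    xs = np.arange(model.x_min, model.x_min + 3000)
    total = model.pmf(xs).sum() + model.sf(xs[-1])
    assert total == pytest.approx(1.0, abs=1e-8)


@given(tail_models, st.integers(min_value=0, max_value=50))
def test_cdf_pmf_telescoping(model, offset):
    x = model.x_min + offset
    assert model.cdf(x) - model.cdf(x - 1) == pytest.approx(model.pmf(x), abs=1e-12)
    assert model.cdf(model.x_min - 1) == 0.0


def test_pmf_zero_below_support():
    for family in FAMILY_EXAMPLES:
        m = make_model(family, x_min=4)
        assert m.pmf(3) == 0.0 and np.isinf(m.logpmf(2))


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        TailModel("powerlaw", (1.0,), 1)  # non-normalizable
    with pytest.raises(ValueError):
        TailModel("lognormal", (0.0, -1.0), 1)
    with pytest.raises(ValueError):
        TailModel("exponential", (1.5,), 1)
    with pytest.raises(ValueError):
        TailModel("poisson", (-2.0,), 1)


def test_exponential_shift_property():
    base = TailModel("exponential", (0.35,), 1)
    shifted = TailModel("exponential", (0.35,), 6)
    xs = np.arange(6, 40)
    assert shifted.pmf(xs) == pytest.approx(base.pmf(xs - 5), rel=1e-12)


# -- likelihood -------------------------------------------------------------


def test_loglik_hand_example():
    m = TailModel("exponential", (0.5,), 1)
    assert m.loglik([1, 2]) == pytest.approx(math.log(0.5) + math.log(0.25))
    assert m.loglik([m.x_min]) == pytest.approx(m.logpmf(m.x_min))


@given(tail_models, st.data())
def test_loglik_matches_pointwise_sum(model, data):
    xs = data.draw(st.lists(
        st.integers(model.x_min, model.x_min + 60), min_size=1, max_size=30))
    expected = sum(math.log(model.pmf(x)) for x in xs)
    assert model.loglik(xs) == pytest.approx(expected, rel=1e-10)


def test_loglik_rejects_datum_below_xmin():
    m = TailModel("powerlaw", (2.5,), 3)
    with pytest.raises(ValueError, match="below x_min"):
        m.loglik([2, 3, 4])


# -- sampling ---------------------------------------------------------------


def test_sample_determinism_and_degenerate():
    m = TailModel("powerlaw", (2.5,), 1)
    assert m.sample(0, seed=3).size == 0
    assert np.array_equal(m.sample(50, seed=3), m.sample(50, seed=3))
    with pytest.raises(ValueError):
        m.sample(-1, seed=3)


@pytest.mark.parametrize("family", sorted(FAMILY_EXAMPLES))
def test_sample_matches_pmf(family):
    """Empirical frequencies of 1e5 draws sit within 3 SE of the pmf."""
    model = make_model(family, x_min=2)
    n = 100_000
    draws = model.sample(n, seed=99)
    assert draws.min() >= model.x_min
    for x in range(model.x_min, model.x_min + 6):
        p = model.pmf(x)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(np.mean(draws == x) - p) < 3.5 * se + 1e-9


def test_sample_chi_square_consistency():
    model = TailModel("exponential", (0.3,), 1)
    draws = model.sample(100_000, seed=7)
    hi = 20
    observed = np.bincount(np.minimum(draws, hi), minlength=hi + 1)[1:]
    expected = np.append(model.pmf(np.arange(1, hi)), model.sf(hi - 1)) * draws.size
    _, p = stats.chisquare(observed, expected)
    assert p > 1e-3


def test_powerlaw_heavy_tail_sampling():
    # alpha near 1 exercises the beyond-horizon quantile fallback
    m = TailModel("powerlaw", (1.2,), 1)
    draws = m.sample(2000, seed=11)
    assert draws.min() >= 1 and draws.max() > 10_000


# -- rank models ------------------------------------------------------------


def test_rank_probabilities_sum_to_one():
    for family in ("zipf", "sigurd_geometric", "good_stickbreak", "neglog", "yule_simon"):
        p = RankModel(family, 37, alpha=1.0, lam=0.8).probabilities()
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(p) <= 1e-15)  # non-increasing in rank


def test_stick_break_expectation_small_n():
    assert stick_break_expectation(1) == pytest.approx([1.0])
    assert stick_break_expectation(2) == pytest.approx([0.75, 0.25])
    with pytest.raises(ValueError):
        stick_break_expectation(0)


def test_stick_break_matches_simulated_spacings(rng):
    """Mean sorted uniform spacings follow the (1/n) sum_{i>=k} 1/i vector."""
    n, reps = 8, 40_000
    cuts = np.sort(rng.random((reps, n - 1)), axis=1)
    parts = np.diff(np.concatenate([np.zeros((reps, 1)), cuts, np.ones((reps, 1))], axis=1))
    means = np.sort(parts, axis=1)[:, ::-1].mean(axis=0)
    expect = stick_break_expectation(n)
    se = np.sort(parts, axis=1)[:, ::-1].std(axis=0) / math.sqrt(reps)
    assert np.all(np.abs(means - expect) < 3.5 * se + 1e-12)


def test_yule_simon_reductions():
    for n in (2, 10, 100):
        k = np.arange(1, n + 1)
        ys = RankModel("yule_simon", n, alpha=1.3, lam=1.0)
        zipf = RankModel("zipf", n, alpha=1.3)
        assert ys.rank_pmf(k) == pytest.approx(zipf.rank_pmf(k), abs=1e-12)
        ys0 = RankModel("yule_simon", n, alpha=0.0, lam=0.6)
        geo = RankModel("sigurd_geometric", n, lam=0.6)
        assert ys0.rank_pmf(k) == pytest.approx(geo.rank_pmf(k), abs=1e-12)


def test_good_converges_to_neglog():
    gaps = []
    for n in (10, 100, 1000):
        k = np.arange(1, n + 1)
        good = RankModel("good_stickbreak", n).rank_pmf(k)
        neglog = RankModel("neglog", n).rank_pmf(k)
        gaps.append(np.max(np.abs(good - neglog)))
    assert gaps[0] > gaps[1] > gaps[2]


def test_rank_pmf_domain_errors():
    m = RankModel("zipf", 5)
    with pytest.raises(ValueError):
        m.rank_pmf(0)
    with pytest.raises(ValueError):
        m.rank_pmf(6)


def test_rank_sampler_follows_probabilities():
    m = RankModel("zipf", 4, alpha=1.0)
    draws = m.sample(50_000, seed=5)
    freq = np.bincount(draws, minlength=5)[1:] / draws.size
    assert freq == pytest.approx(m.probabilities(), abs=0.01)


# -- serialization ----------------------------------------------------------


@given(tail_models)
def test_tail_model_json_roundtrip(model):
    assert model_from_json(model.to_json()) == model


def test_rank_model_json_roundtrip():
    m = RankModel("yule_simon", 24, alpha=1.1, lam=0.9)
    assert model_from_json(m.to_json()) == m
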