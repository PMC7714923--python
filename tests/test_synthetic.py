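"""Synthetic corpus generation: counts, corpora, spliced languages."""

import numpy as np
import pytest

from phonotail.corpus_io import read_counts, segment_counts, write_counts
from phonotail.distributions import RankModel, TailModel
from phonotail.fitting import estimate_xmin
from phonotail.synthetic import (CorpusConfig, SplicedModel, generate_corpus,
                                 generate_counts, generate_spliced)


def test_zipf_rank_ratio():
    """At alpha=1 the second-ranked type is about half as frequent as the first."""
    t = generate_counts(RankModel("zipf", 2, alpha=1.0), 2, n_tokens=300_000, seed=3)
    c = sorted(t.counts.values(), reverse=True)
    ratio = c[0] / c[1]
    p1, p2 = 2 / 3, 1 / 3
    se = np.sqrt(p1 * p2 / 300_000)  # binomial SE on the top-rank share
    assert abs(c[0] / 300_000 - p1) < 3.5 * se
    assert ratio == pytest.approx(2.0, rel=0.02)


def test_single_type_inventory():
    t = generate_counts(RankModel("zipf", 1), 1, n_tokens=500, seed=1)
    assert list(t.counts.values()) == [500]


def test_multinomial_frequencies_converge_to_model():
    model = RankModel("sigurd_geometric", 10, lam=0.7)
    probs = model.probabilities()
    kls = []
    for n_tokens in (1000, 100_000):
        t = generate_counts(model, 10, n_tokens=n_tokens, seed=6)
        freq = np.array([t.counts[k] for k in sorted(t.counts)]) / t.n_tokens
        kls.append(float(np.sum(probs * np.log(probs / freq))))
    assert kls[1] < kls[0]


def test_counts_cover_all_types():
    t = generate_counts(RankModel("zipf", 20, alpha=1.5), 20, n_tokens=200, seed=9)
    assert t.n_types == 20 and min(t.counts.values()) >= 1


def test_tail_model_draws_are_counts():
    model = TailModel("exponential", (0.3,), 1)
    t = generate_counts(model, 500, seed=4)
    assert t.n_types == 500
    # iid geometric draws: mean near 1/theta
    assert np.mean(t.observations()) == pytest.approx(1 / 0.3, rel=0.15)
    with pytest.raises(ValueError, match="n_tokens"):
        generate_counts(model, 10, n_tokens=100, seed=4)


def test_generate_corpus_defaults_and_determinism(tmp_path):
    cfg = CorpusConfig(model=RankModel("sigurd_geometric", 24, lam=0.8),
                       n_languages=40, seed=7)
    tables = generate_corpus(cfg)
    sizes = np.array([t.n_types for t in tables])
    words = np.array([t.n_words for t in tables])
    assert sizes.min() >= 16 and sizes.max() <= 37
    assert 23 <= sizes.mean() <= 26
    assert words.min() >= 268 and words.max() <= 8742
    # same seed -> byte-identical corpus file
    again = generate_corpus(cfg)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_counts(tables, p1)
    write_counts(again, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_generate_corpus_empty():
    cfg = CorpusConfig(model=RankModel("zipf", 5), n_languages=0, seed=1)
    assert generate_corpus(cfg) == []


def test_materialized_wordlists_roundtrip_through_counting():
    cfg = CorpusConfig(model=RankModel("zipf", 20, alpha=1.0), n_languages=3, seed=5)
    tables, wordlists = generate_corpus(cfg, materialize=True)
    for table, wl in zip(tables, wordlists):
        recounted = segment_counts(wl)
        assert recounted.counts == table.counts
        assert recounted.n_words == table.n_words
        lens = [len(f) for f in wl.entries]
        assert min(lens) >= 2 and max(lens) <= 10


def test_corpus_roundtrips_through_counts_file(tmp_path):
    cfg = CorpusConfig(model=TailModel("exponential", (0.2,), 1),
                       n_languages=4, seed=2)
    tables = generate_corpus(cfg)
    path = tmp_path / "corpus.csv"
    write_counts(tables, path)
    back = read_counts(path)
    assert [(t.language_id, t.counts) for t in back] == [
        (t.language_id, t.counts) for t in tables
    ]


def test_spliced_pmf_normalizes_and_is_continuous():
    body = TailModel("exponential", (0.25,), 1)
    tail = TailModel("powerlaw", (2.5,), 8)
    m = SplicedModel(body, tail, 8)
    xs = np.arange(1, 30_000)
    assert m.pmf(xs).sum() == pytest.approx(1.0, abs=1e-3)
    # continuity at the junction: spliced pmf at the cut matches the body's shape
    assert m.pmf(8) / m.pmf(7) == pytest.approx(body.pmf(8) / body.pmf(7), rel=1e-9)


def test_degenerate_splice_equals_pure_tail():
    tail = TailModel("powerlaw", (2.5,), 1)
    m = SplicedModel(TailModel("exponential", (0.25,), 5), tail, cut=1)
    xs = np.arange(1, 50)
    assert m.pmf(xs) == pytest.approx(tail.with_x_min(1).pmf(xs), rel=1e-12)


def test_spliced_recovery_of_cut(rng):
    body = TailModel("exponential", (0.25,), 1)
    tail = TailModel("powerlaw", (2.5,), 8)
    hits = 0
    reps = 25
    for _ in range(reps):
        t = generate_spliced(body, tail, cut=8, inventory_size=1000, rng=rng)
        fit = estimate_xmin("powerlaw", t.observations())
        hits += abs(fit.model.x_min - 8) <= 2
    assert hits > reps / 2


def test_null_splice_keeps_xmin_low(rng):
    """Body identical to tail: the estimated cutoff stays near the support minimum."""
    pl = TailModel("powerlaw", (2.5,), 1)
    low = 0
    reps = 20
    for _ in range(reps):
        t = generate_spliced(pl, pl, cut=1, inventory_size=500, rng=rng)
        fit = estimate_xmin("powerlaw", t.observations())
        low += fit.model.x_min <= 3
    assert low >= 0.8 * reps
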