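"""Synthetic corpora with the statistical structure of real wordlist data.

The generator emulates the shape of the study sample the pipeline is designed
for: on the order of 166 languages, inventories of 16–37 segment types (mean
24.5, SD 3.8), and wordlists of 268–8742 lexemes whose forms are 2–10
segments long.

Two kinds of generative model are supported, and they induce counts
differently:

- a finite **rank model** (Zipf, Sigurd geometric, stick-breaking, negative
  log, Yule–Simon) supplies the inventory's type probabilities directly, and
  the observed counts are one multinomial draw of the language's token
  total — reproducing the integer granularity and sampling noise that real
  wordlists impose on an underlying frequency vector;
- a **tail model** (or a spliced two-regime model) specifies the
  distribution of the count *values* themselves, so the observed counts are
  ``inventory_size`` iid draws from it. This is the construction used to
  validate value-distribution inference (plausibility calibration, x_min
  recovery): pushing such draws through an additional multinomial rescaling
  would distort the very value distribution under test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Union

import numpy as np

from .corpus_io import FrequencyTable, Wordlist
from .distributions import RankModel, TailModel

__all__ = [
    "SplicedModel",
    "CorpusConfig",
    "generate_counts",
    "generate_corpus",
    "generate_spliced",
    "materialize_wordlist",
]

log = logging.getLogger(__name__)

_MAX_RETRIES = 1000


@dataclass(frozen=True)
class SplicedModel:
    """Integer distribution with a body regime below ``cut``, tail above.

    The tail model is re-anchored at ``x_min = cut``; its mass is scaled so
    the pmf is continuous at the junction (the spliced pmf equals the body's
    pmf at ``cut``), and the whole is renormalized. With ``cut <= body.x_min``
    the model degenerates to the pure tail.
    """

    body: TailModel
    tail: TailModel
    cut: int

    def __post_init__(self):
        object.__setattr__(self, "tail", self.tail.with_x_min(self.cut))
        if self.cut > self.body.x_min:
            pb, pt = self.body.pmf(self.cut), self.tail.pmf(self.cut)
            if pb <= 0 or pt <= 0:
                raise ValueError("body and tail have no probability at the cut")

    def _weights(self):
        if self.cut <= self.body.x_min:
            return 0.0, 1.0  # pure tail
        scale = self.body.pmf(self.cut) / self.tail.pmf(self.cut)
        w_body = self.body.cdf(self.cut - 1)
        total = w_body + scale
        return w_body / total, scale / total

    def pmf(self, x):
        x = np.atleast_1d(np.asarray(x)).astype(np.int64)
        w_body, w_tail = self._weights()
        body_part = (self.body.pmf(x) / self.body.cdf(self.cut - 1) * w_body
                     if w_body > 0 else np.zeros(x.shape))
        out = np.where(x < self.cut, body_part, self.tail.pmf(x) * w_tail)
        return out if out.size > 1 else float(out[0])

    def sample(self, n: int, seed=None, rng: np.random.Generator | None = None) -> np.ndarray:
        if rng is None:
            rng = np.random.default_rng(seed)
        w_body, _ = self._weights()
        from_body = rng.random(n) < w_body
        out = np.empty(n, dtype=np.int64)
        n_body = int(from_body.sum())
        if n_body:
            support = np.arange(self.body.x_min, self.cut)
            probs = self.body.pmf(support)
            out[from_body] = rng.choice(support, size=n_body, p=probs / probs.sum())
        if n - n_body:
            out[~from_body] = self.tail.sample(n - n_body, rng=rng)
        return out


GenerativeModel = Union[RankModel, TailModel, SplicedModel]


@dataclass
class CorpusConfig:
    """Study conditions for a synthetic corpus.

    Defaults mirror the real sample: inventory sizes from a discretized
    normal (mean 24.5, SD 3.8) clamped to [16, 37]; wordlist sizes
    log-uniform over [268, 8742]; form lengths uniform on 2–10 segments.
    """

    model: GenerativeModel
    n_languages: int = 166
    seed: int = 0
    inventory_mean: float = 24.5
    inventory_sd: float = 3.8
    inventory_range: tuple = (16, 37)
    wordlist_range: tuple = (268, 8742)
    form_length_range: tuple = (2, 10)

    def sample_inventory_size(self, rng: np.random.Generator) -> int:
        lo, hi = self.inventory_range
        size = int(round(rng.normal(self.inventory_mean, self.inventory_sd)))
        return int(np.clip(size, lo, hi))

    def sample_wordlist_size(self, rng: np.random.Generator) -> int:
        lo, hi = self.wordlist_range
        return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def _labels(k: int) -> list:
    return [f"s{i:03d}" for i in range(1, k + 1)]


def generate_counts(model: GenerativeModel, inventory_size: int,
                    n_tokens: int | None = None, seed=None,
                    rng: np.random.Generator | None = None,
                    language_id: str = "synthetic") -> FrequencyTable:
    """One language's segment counts under a generative model.

    A rank model requires ``n_tokens`` and yields one multinomial draw over
    its ``n = inventory_size`` rank probabilities; multinomial draws leaving
    any type unobserved are retried (bounded), keeping counts honest positive
    integers rather than smoothing them. A tail or spliced model yields
    ``inventory_size`` iid count draws directly (``n_tokens`` must be None).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(model, RankModel):
        if n_tokens is None:
            raise ValueError("a rank model needs n_tokens for the multinomial draw")
        if n_tokens < inventory_size:
            raise ValueError("n_tokens must be at least inventory_size")
        if model.n != inventory_size:
            model = replace(model, n=inventory_size)
        probs = model.probabilities()
        for attempt in range(_MAX_RETRIES):
            counts = rng.multinomial(n_tokens, probs)
            if counts.min() > 0:
                if attempt:
                    log.debug("%s: %d redraw(s) to cover all types", language_id, attempt)
                return FrequencyTable(language_id,
                                      dict(zip(_labels(inventory_size), counts)))
        raise ValueError(
            f"could not observe all {inventory_size} types in {n_tokens} tokens "
            f"after {_MAX_RETRIES} draws"
        )
    if n_tokens is not None:
        raise ValueError(
            "a tail/spliced model draws counts directly; n_tokens does not apply"
        )
    draws = model.sample(inventory_size, rng=rng)
    return FrequencyTable(language_id, dict(zip(_labels(inventory_size), draws)))


def generate_corpus(config: CorpusConfig, materialize: bool = False):
    """A corpus of synthetic languages under a single generative model.

    Per-language generators are spawned from the master seed, so the corpus
    is fully reproducible and any single language can be regenerated. Under a
    rank model the token total comes from a sampled wordlist (lexeme count x
    form lengths); under a tail model the token total is whatever the drawn
    counts sum to, and the lexeme count follows from partitioning those
    tokens into forms. With ``materialize=True`` also returns Wordlists whose
    forms partition the token counts, so a corpus round-trips through
    wordlist reading and counting.
    """
    master = np.random.default_rng(config.seed)
    children = master.spawn(config.n_languages)
    lo, hi = config.form_length_range
    tables, wordlists = [], []
    for i, rng in enumerate(children):
        lang = f"lang{i:03d}"
        inv = config.sample_inventory_size(rng)
        if isinstance(config.model, RankModel):
            n_words = config.sample_wordlist_size(rng)
            lengths = rng.integers(lo, hi + 1, size=n_words)
            n_tokens = int(max(lengths.sum(), inv))
            table = generate_counts(config.model, inv, n_tokens, rng=rng,
                                    language_id=lang)
        else:
            table = generate_counts(config.model, inv, rng=rng, language_id=lang)
            lengths = _partition_lengths(table.n_tokens, lo, hi, rng)
        table.n_words = len(lengths)
        tables.append(table)
        if materialize:
            wordlists.append(materialize_wordlist(table, lengths, rng))
    if tables:
        sizes = [t.n_types for t in tables]
        log.info("generated %d languages: inventory %d-%d (mean %.1f)",
                 len(tables), min(sizes), max(sizes), float(np.mean(sizes)))
    return (tables, wordlists) if materialize else tables


def _partition_lengths(n_tokens: int, lo: int, hi: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Form lengths in [lo, hi] summing exactly to n_tokens."""
    lengths = []
    remaining = n_tokens
    while remaining > hi:
        ln = int(rng.integers(lo, hi + 1))
        lengths.append(ln)
        remaining -= ln
    if remaining:
        if remaining < lo and lengths:  # merge the stub into the last form
            lengths[-1] += remaining
        else:
            lengths.append(remaining)
    return np.asarray(lengths, dtype=np.int64)


def materialize_wordlist(table: FrequencyTable, lengths: np.ndarray,
                         rng: np.random.Generator) -> Wordlist:
    """Partition a language's segment tokens into forms with given lengths."""
    pool = np.repeat(list(table.counts.keys()), list(table.counts.values()))
    rng.shuffle(pool)
    if lengths.sum() != pool.size:
        raise ValueError("form lengths must sum to n_tokens")
    forms, start = [], 0
    for ln in lengths:
        forms.append(tuple(pool[start:start + ln]))
        start += int(ln)
    return Wordlist(table.language_id, forms)


def generate_spliced(body_model: TailModel, tail_model: TailModel, cut: int,
                     inventory_size: int, seed=None,
                     rng: np.random.Generator | None = None,
                     language_id: str = "spliced") -> FrequencyTable:
    """Counts from a two-regime distribution: body below ``cut``, tail above.

    The ``inventory_size`` iid draws from the spliced distribution are the
    observed counts themselves — the construction used for x_min-recovery
    experiments, where the estimated cutoff should land near ``cut``.
    """
    model = SplicedModel(body_model, tail_model, int(cut))
    return generate_counts(model, inventory_size, rng=rng, seed=seed,
                           language_id=language_id)
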