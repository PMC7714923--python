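"""Wordlist reading and per-language segment frequency tables.

Input data are delimited wordlists: one row per lexeme, with a language
identifier column and a pre-segmented phonemic form column (segments joined
by a declared delimiter, space by default). Each lexeme is counted exactly
once, so lexemes are weighted equally — these are lexical frequencies, not
discourse frequencies. Beyond NFC unicode normalization, segment labels are
treated as opaque symbols: no case folding, no orthography-profile parsing.
"""

from __future__ import annotations

import logging
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CorpusFormatError",
    "Wordlist",
    "FrequencyTable",
    "read_wordlists",
    "write_wordlists",
    "segment_counts",
    "filter_corpus",
    "read_counts",
    "write_counts",
]

log = logging.getLogger(__name__)

#: Minimum wordlist size retained by default: below ~250 lexemes, segment
#: frequency estimates lose fidelity rapidly.
MIN_WORDS_DEFAULT = 250


class CorpusFormatError(ValueError):
    """Raised for malformed wordlist/counts files or bad column config."""


@dataclass
class Wordlist:
    """One language's lexemes, each a tuple of segment labels."""

    language_id: str
    entries: list  # list[tuple[str, ...]]

    def __post_init__(self):
        for i, form in enumerate(self.entries):
            form = tuple(form)
            if len(form) == 0 or any(not s for s in form):
                raise CorpusFormatError(
                    f"{self.language_id}: entry {i} has an empty form or segment"
                )
            self.entries[i] = form

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class FrequencyTable:
    """Per-language segment token counts — the observations handed to fitting.

    ``counts`` maps segment label to a positive integer token count; the
    values of this map (one observation per segment *type*) are the data the
    tail models are fitted to.
    """

    language_id: str
    counts: dict
    n_words: int = 0

    def __post_init__(self):
        self.counts = {str(k): int(v) for k, v in self.counts.items()}
        if any(v < 1 for v in self.counts.values()):
            raise CorpusFormatError(f"{self.language_id}: counts must be >= 1")

    @property
    def n_types(self) -> int:
        return len(self.counts)

    @property
    def n_tokens(self) -> int:
        return sum(self.counts.values())

    def observations(self) -> np.ndarray:
        """The multiset of token counts as an integer array."""
        return np.fromiter(self.counts.values(), dtype=np.int64, count=len(self.counts))


def _split_form(form: str, segment_sep, row: int) -> tuple:
    form = unicodedata.normalize("NFC", form)
    if segment_sep is None:
        if len(form) > 1:
            raise CorpusFormatError(
                f"row {row}: multi-character form {form!r} but no segment "
                "delimiter is configured"
            )
        return (form,)
    return tuple(s for s in form.split(segment_sep) if s)


def read_wordlists(
    path,
    language_col: str = "language",
    form_col: str = "form",
    sep: str = ",",
    segment_sep: str | None = " ",
) -> list:
    """Read a delimited wordlist file into one ``Wordlist`` per language.

    Entry order is preserved; languages appear in order of first occurrence.
    An empty file yields an empty list with a logged warning.
    """
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        log.warning("wordlist file %s is empty", path)
        return []
    missing = [c for c in (language_col, form_col) if c not in df.columns]
    if missing:
        raise CorpusFormatError(f"{path}: missing column(s) {missing}; have {list(df.columns)}")
    if df.empty:
        log.warning("wordlist file %s has a header but no rows", path)
        return []
    out: dict[str, Wordlist] = {}
    for row, (lang, form) in enumerate(zip(df[language_col], df[form_col])):
        segs = _split_form(form, segment_sep, row)
        if not segs:
            raise CorpusFormatError(f"row {row}: empty form for language {lang!r}")
        out.setdefault(lang, Wordlist(lang, [])).entries.append(segs)
    return list(out.values())


def write_wordlists(
    wordlists: Iterable[Wordlist],
    path,
    language_col: str = "language",
    form_col: str = "form",
    sep: str = ",",
    segment_sep: str = " ",
) -> None:
    rows = [
        {language_col: wl.language_id, form_col: segment_sep.join(form)}
        for wl in wordlists
        for form in wl.entries
    ]
    pd.DataFrame(rows, columns=[language_col, form_col]).to_csv(path, sep=sep, index=False)


def segment_counts(wordlist: Wordlist) -> FrequencyTable:
    """Tally segment tokens across all lexemes, each lexeme counted once."""
    if len(wordlist) == 0:
        raise CorpusFormatError(f"{wordlist.language_id}: no entries to count")
    tally: Counter = Counter()
    for form in wordlist.entries:
        tally.update(form)
    return FrequencyTable(wordlist.language_id, dict(tally), n_words=len(wordlist))


def filter_corpus(tables: Iterable[FrequencyTable], min_words: int = MIN_WORDS_DEFAULT) -> list:
    """Keep only languages with at least ``min_words`` lexemes (order kept)."""
    if min_words < 1:
        raise ValueError("min_words must be >= 1")
    kept = []
    for t in tables:
        if t.n_words >= min_words:
            kept.append(t)
        else:
            log.info("dropping %s: %d words < %d", t.language_id, t.n_words, min_words)
    return kept


def read_counts(path, sep: str = ",") -> list:
    """Read a pre-aggregated long-format counts file (language, segment, count)."""
    try:
        df = pd.read_csv(path, sep=sep, dtype={"language": str, "segment": str})
    except pd.errors.EmptyDataError:
        log.warning("counts file %s is empty", path)
        return []
    missing = [c for c in ("language", "segment", "count") if c not in df.columns]
    if missing:
        raise CorpusFormatError(f"{path}: missing column(s) {missing}")
    tables = []
    for lang, grp in df.groupby("language", sort=False):
        counts = dict(zip(grp["segment"], grp["count"].astype(int)))
        tables.append(FrequencyTable(str(lang), counts))
    return tables


def write_counts(tables: Iterable[FrequencyTable], path, sep: str = ",") -> None:
    rows = [
        {"language": t.language_id, "segment": s, "count": c}
        for t in tables
        for s, c in t.counts.items()
    ]
    pd.DataFrame(rows, columns=["language", "segment", "count"]).to_csv(path, sep=sep, index=False)
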