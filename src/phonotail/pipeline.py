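"""Study orchestration: fits, plausibility and model selection for a corpus.

``run_study`` applies the three-step evaluation to every language of a
corpus: (1) each candidate family is fitted both to the full inventory
(x_min anchored at the smallest observed count) and with an estimated x_min;
(2) every converged fit receives a semi-parametric bootstrap p-value and a
plausibility call at the 0.1 threshold; (3) families are compared pairwise
with Vuong's test — at the shared anchored x_min for the full-inventory
fits, and under the cross-x_min protocol (imposing each family's estimated
cutoff on the other) for the estimated fits — with Bonferroni correction
over the number of languages applied per comparison family.

Failures in a single (language, family) cell are logged and recorded as
missing, never fatal to the study.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus_io import FrequencyTable
from .distributions import TAIL_FAMILIES
from .fitting import MIN_TAIL_DEFAULT, FitResult, estimate_xmin, fit_mle
from .model_selection import VuongResult, bonferroni_adjust, cross_xmin_compare, vuong_test
from .plausibility import (N_REPS_DEFAULT, PLAUSIBILITY_THRESHOLD, BootstrapResult,
                           bootstrap_pvalue, is_plausible)

__all__ = ["StudyConfig", "LanguageRecord", "StudyReport", "run_study", "summarize",
           "loglog_points"]

log = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    families: tuple = TAIL_FAMILIES
    n_reps: int = N_REPS_DEFAULT
    seed: int = 0
    min_tail: int = MIN_TAIL_DEFAULT
    threshold: float = PLAUSIBILITY_THRESHOLD
    alpha: float = 0.05
    estimate_xmin: bool = True  # also run the with-x_min setting
    #: "all": Vuong-compare every family pair; "plausible": skip pairs where
    #: either family was already rejected for (nearly) every language.
    vuong_mode: str = "all"


@dataclass
class LanguageRecord:
    language_id: str
    #: (family, setting) -> FitResult, setting in {"fixed", "estimated"}
    fits: dict = field(default_factory=dict)
    #: (family, setting) -> BootstrapResult
    bootstraps: dict = field(default_factory=dict)
    #: list of VuongResult for this language
    vuong: list = field(default_factory=list)
    failures: list = field(default_factory=list)


@dataclass
class StudyReport:
    config: StudyConfig
    records: list  # list[LanguageRecord]

    @property
    def n_languages(self) -> int:
        return len(self.records)

    def fits_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            for (family, setting), boot in rec.bootstraps.items():
                row = boot.to_row(rec.language_id)
                row["setting"] = setting
                rows.append(row)
        return pd.DataFrame(rows)

    def vuong_frame(self) -> pd.DataFrame:
        rows = [v.to_row(rec.language_id) for rec in self.records for v in rec.vuong]
        df = pd.DataFrame(rows)
        if not df.empty:
            df["setting"] = np.where(df["x_min_source"] == "shared", "fixed", "estimated")
        return df


def _language_seeds(master_seed: int, n: int):
    return np.random.default_rng(master_seed).spawn(n)


def run_study(corpus, config: StudyConfig | None = None) -> StudyReport:
    """Run the full evaluation over a pre-filtered corpus of FrequencyTables."""
    corpus = list(corpus)
    if not corpus:
        raise ValueError("corpus is empty")
    if config is None:
        config = StudyConfig()
    records = []
    for rec_rng, table in zip(_language_seeds(config.seed, len(corpus)), corpus):
        records.append(_run_language(table, config, rec_rng))
    _apply_bonferroni(records, config)
    return StudyReport(config=config, records=records)


def _run_language(table: FrequencyTable, config: StudyConfig,
                  rng: np.random.Generator) -> LanguageRecord:
    rec = LanguageRecord(table.language_id)
    obs = table.observations()
    settings = [("fixed", int(obs.min()))]
    if config.estimate_xmin:
        settings.append(("estimated", None))
    for family in config.families:
        for setting, anchored in settings:
            try:
                if setting == "fixed":
                    fit = fit_mle(family, obs, x_min=anchored)
                else:
                    fit = estimate_xmin(family, obs, min_tail=config.min_tail)
                rec.fits[(family, setting)] = fit
                if fit.converged:
                    rec.bootstraps[(family, setting)] = bootstrap_pvalue(
                        fit, obs, n_reps=config.n_reps, rng=rng.spawn(1)[0],
                        min_tail=config.min_tail)
            except (ValueError, FloatingPointError) as exc:
                log.warning("%s/%s/%s failed: %s", table.language_id, family, setting, exc)
                rec.failures.append((family, setting, str(exc)))
    _run_vuong(rec, obs, config)
    return rec


def _pairs(rec: LanguageRecord, config: StudyConfig, setting: str):
    for fam_a, fam_b in itertools.combinations(config.families, 2):
        if config.vuong_mode == "plausible":
            calls = [rec.bootstraps.get((f, setting)) for f in (fam_a, fam_b)]
            if any(c is None or not is_plausible(c, config.threshold) for c in calls):
                continue
        yield fam_a, fam_b


def _run_vuong(rec: LanguageRecord, obs: np.ndarray, config: StudyConfig) -> None:
    # Full-inventory fits all share the anchored x_min, so a direct test applies.
    for fam_a, fam_b in _pairs(rec, config, "fixed"):
        fa = rec.fits.get((fam_a, "fixed"))
        fb = rec.fits.get((fam_b, "fixed"))
        if fa is None or fb is None or not (fa.converged and fb.converged):
            continue
        try:
            rec.vuong.append(vuong_test(fa, fb, obs))
        except ValueError as exc:
            rec.failures.append((f"{fam_a}~{fam_b}", "fixed", str(exc)))
    if not config.estimate_xmin:
        return
    for fam_a, fam_b in _pairs(rec, config, "estimated"):
        try:
            res_a, res_b = cross_xmin_compare(fam_a, fam_b, obs, min_tail=config.min_tail)
        except (ValueError, FloatingPointError) as exc:
            rec.failures.append((f"{fam_a}~{fam_b}", "estimated", str(exc)))
            continue
        rec.vuong.extend(r for r in (res_a, res_b) if r is not None)


def _apply_bonferroni(records, config: StudyConfig) -> None:
    """Per comparison family (pair x x_min_source), m = number of languages."""
    m = len(records)
    groups: dict = {}
    for rec in records:
        for v in rec.vuong:
            groups.setdefault((v.family_a, v.family_b, v.x_min_source), []).append(v)
    for results in groups.values():
        mask = bonferroni_adjust([v.p_two_sided for v in results], m=m,
                                 alpha=config.alpha)
        for v, sig in zip(results, mask):
            v.significant_bonferroni = bool(sig)


# ---------------------------------------------------------------------------
# Summaries


def _summary_block(df: pd.DataFrame, n_languages: int) -> pd.DataFrame:
    """Per family x setting: shape-parameter, KS and p summaries + plausibility."""
    param_col = {"powerlaw": "alpha", "lognormal": "sigma",
                 "exponential": "theta", "poisson": "lam"}
    rows = []
    for (family, setting), grp in df.groupby(["family", "setting"]):
        shape = grp[param_col[family]]
        n_plaus = int(grp["plausible"].sum())
        rows.append({
            "family": family, "setting": setting, "n_fitted": len(grp),
            "param": param_col[family],
            "param_mean": shape.mean(), "param_sd": shape.std(ddof=1),
            "param_min": shape.min(), "param_max": shape.max(),
            "ks_mean": grp["ks_D"].mean(), "ks_sd": grp["ks_D"].std(ddof=1),
            "ks_min": grp["ks_D"].min(), "ks_max": grp["ks_D"].max(),
            "p_mean": grp["p_value"].mean(), "p_sd": grp["p_value"].std(ddof=1),
            "p_min": grp["p_value"].min(), "p_max": grp["p_value"].max(),
            "n_plausible": n_plaus,
            "pct_plausible": 100.0 * n_plaus / n_languages,
            "mean_prop_fitted": grp["prop_fitted"].mean(),
        })
    out = pd.DataFrame(rows)
    return out.round(2) if not out.empty else out


def _vuong_tally(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (pair, source), grp in df.groupby(["pair", "x_min_source"]):
        fam_a, fam_b = pair.split("_vs_")
        rows.append({
            "pair": pair, "x_min_source": source, "n_tests": len(grp),
            "family_a": fam_a, "family_b": fam_b,
            "favors_a": int((grp["favored"] == fam_a).sum()),
            "favors_b": int((grp["favored"] == fam_b).sum()),
            "n_significant": int(grp["significant"].sum()),
        })
    return pd.DataFrame(rows)


def summarize(report: StudyReport):
    """Aggregate a StudyReport into summary tables and a text rendering.

    Returns ``(tables, text)`` where ``tables`` maps block names to rounded
    DataFrames (sample SD convention, two decimals) and ``text`` is a
    human-readable rendering of the same numbers.
    """
    fits = report.fits_frame()
    blocks = {"fits": fits, "vuong": report.vuong_frame()}
    blocks["summary"] = (_summary_block(fits, report.n_languages)
                         if not fits.empty else pd.DataFrame())
    blocks["vuong_tally"] = (_vuong_tally(blocks["vuong"])
                             if not blocks["vuong"].empty else pd.DataFrame())
    lines = [f"Study over {report.n_languages} language(s), "
             f"{report.config.n_reps} bootstrap reps\n"]
    if not blocks["summary"].empty:
        lines += ["== Per-family summary ==", blocks["summary"].to_string(index=False), ""]
    if not blocks["vuong_tally"].empty:
        lines += ["== Vuong tallies ==", blocks["vuong_tally"].to_string(index=False), ""]
    return blocks, "\n".join(lines)


def loglog_points(table: FrequencyTable, fit_lines: bool = False, drop_lowest: int = 5):
    """Rank–frequency points for the legacy log-log diagnostic plot.

    Returns a DataFrame of descending-sorted (rank, count) pairs with log10
    transforms; ties in count keep a stable order by segment label. With
    ``fit_lines=True`` adds least-squares lines on log10(count) vs
    log10(rank), with and without the ``drop_lowest`` least-frequent
    segments — a visual diagnostic only, known to be unreliable as a test.
    """
    items = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame({
        "segment": [s for s, _ in items],
        "rank": np.arange(1, len(items) + 1),
        "count": [c for _, c in items],
    })
    df["rel_freq"] = df["count"] / table.n_tokens
    df["log10_rank"] = np.log10(df["rank"])
    df["log10_count"] = np.log10(df["count"])
    lines = {}
    if fit_lines:
        for label, sub in (("full", df), ("trimmed", df.iloc[:max(len(df) - drop_lowest, 2)])):
            slope, intercept = np.polyfit(sub["log10_rank"], sub["log10_count"], 1)
            pred = intercept + slope * sub["log10_rank"]
            ss_res = float(np.sum((sub["log10_count"] - pred) ** 2))
            ss_tot = float(np.sum((sub["log10_count"] - sub["log10_count"].mean()) ** 2))
            lines[label] = {"slope": float(slope), "intercept": float(intercept),
                            "r2": 1.0 - ss_res / ss_tot if ss_tot else float("nan")}
    return (df, lines) if fit_lines else df
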