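"""Popularity-proxy transformations and group statistics.

Popularity — how often a code or term appears in the literature and in
curated annotation resources — proxies a fact's exposure during LLM
pretraining. Three proxies are carried per pair: the code's literature
count, the term's literature count, and its annotation count. Counts are
Laplace-smoothed (+1) and log10-transformed before analysis to tame the
long-tail skew: log10(count + 1), so a count of 0 maps to exactly 0.

Analyses mirror the standard report shapes:

* per-category summaries (mean, SD, N per proxy) with a one-way ANOVA
  across outcome categories per proxy;
* Pearson correlation matrices among the three transformed proxies;
* a two-way ANOVA (Terminology x Correctness, Type-II sums of squares)
  on one chosen proxy, with Games–Howell post hoc across terminologies
  when an effect involving terminology is significant (robust to unequal
  variances and group sizes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .errors import DegenerateInputError, ValidationError
from .io import TermCodePair
from .outcomes import OutcomeRecord

#: proxy name -> raw-count column
PROXIES = {"annotation": "annotation_count", "code": "code_count", "term": "term_count"}


def transform_counts(pairs: Sequence[TermCodePair]) -> pd.DataFrame:
    """Laplace-smoothed log10 popularity per pair.

    Columns: pair_id, terminology, raw counts, and log_{proxy} columns
    holding log10(count + 1).
    """
    if not pairs:
        raise ValidationError("no pairs to transform")
    df = pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in pairs],
            "terminology": [p.terminology for p in pairs],
            "annotation_count": [p.annotation_count for p in pairs],
            "code_count": [p.code_count for p in pairs],
            "term_count": [p.term_count for p in pairs],
        }
    )
    for proxy, col in PROXIES.items():
        if (df[col] < 0).any():
            bad = df.loc[df[col] < 0, "pair_id"].iloc[0]
            raise ValidationError(f"negative {col} for pair {bad}")
        df[f"log_{proxy}"] = np.log10(df[col] + 1.0)
    return df


def attach_outcomes(
    popularity: pd.DataFrame,
    outcomes: Sequence[OutcomeRecord],
    pair_of_instance: Mapping[str, str],
) -> pd.DataFrame:
    """Join outcome categories onto the popularity table by pair.

    ``pair_of_instance`` maps instance_id -> pair_id (instances expanded
    from the same pair share its popularity counts).
    """
    rows = []
    for rec in outcomes:
        rows.append(
            {
                "pair_id": pair_of_instance[rec.instance_id],
                "category": rec.category.value,
                "split": rec.split,
                "F": rec.F,
            }
        )
    outcome_df = pd.DataFrame(rows)
    return popularity.merge(outcome_df, on="pair_id", how="inner")


def group_summaries(records: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Mean/SD/N per (category, proxy) plus an all-concepts row.

    The per-proxy one-way ANOVA across categories is run on the
    transformed counts; the table reports raw-count means. Categories
    with no members are simply absent. ``anova_significant`` flags
    proxies whose category means differ at the given alpha.
    """
    if "category" not in records.columns:
        raise ValidationError("records must carry an outcome category column")
    out_rows = []
    categories = [c for c in records["category"].unique()]
    anova_flags: dict[str, Optional[bool]] = {}
    for proxy, col in PROXIES.items():
        groups = [
            records.loc[records["category"] == c, f"log_{proxy}"].to_numpy()
            for c in categories
        ]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) >= 2 and any(np.var(g) > 0 for g in groups):
            _, p = stats.f_oneway(*groups)
            anova_flags[proxy] = bool(p < alpha)
        else:
            anova_flags[proxy] = None  # not applicable
    for category in categories:
        sub = records[records["category"] == category]
        row: dict = {"category": category, "N": len(sub)}
        for proxy, col in PROXIES.items():
            row[f"{proxy}_mean"] = float(sub[col].mean())
            row[f"{proxy}_sd"] = float(sub[col].std(ddof=1)) if len(sub) > 1 else float("nan")
            row[f"{proxy}_anova_significant"] = anova_flags[proxy]
        out_rows.append(row)
    all_row: dict = {"category": "all", "N": len(records)}
    for proxy, col in PROXIES.items():
        all_row[f"{proxy}_mean"] = float(records[col].mean())
        all_row[f"{proxy}_sd"] = float(records[col].std(ddof=1))
        all_row[f"{proxy}_anova_significant"] = anova_flags[proxy]
    out_rows.append(all_row)
    return pd.DataFrame(out_rows)


def proxy_correlations(records: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations among the three log-transformed proxies.

    Computed per terminology when several are present. A zero-variance
    proxy yields NaN in its cells (flagged, not fabricated).
    """
    if len(records) < 3:
        raise ValidationError("need at least 3 records for correlations")
    log_cols = [f"log_{p}" for p in PROXIES]
    frames = []
    for terminology, sub in records.groupby("terminology"):
        corr = sub[log_cols].corr(method="pearson")
        corr.index = pd.MultiIndex.from_product([[terminology], corr.index])
        frames.append(corr)
    return pd.concat(frames)


@dataclass
class TwoWayAnovaReport:
    """Type-II two-way ANOVA table plus optional Games–Howell post hoc."""

    proxy: str
    anova: pd.DataFrame  # index: effect; columns: sum_sq, df, F, PR(>F)
    games_howell: Optional[pd.DataFrame]
    notes: list[str]

    def effect_p(self, effect: str) -> float:
        return float(self.anova.loc[effect, "PR(>F)"])


def games_howell(records: pd.DataFrame, dv: str, between: str) -> pd.DataFrame:
    """Games–Howell all-pairs comparison (Welch df, studentized range)."""
    return pg.pairwise_gameshowell(data=records, dv=dv, between=between)


def two_way_anova_popularity(
    records: pd.DataFrame,
    correctness: Mapping[str, int],
    proxy: str = "code",
    alpha: float = 0.05,
) -> TwoWayAnovaReport:
    """Terminology x Correctness ANOVA on one log-popularity proxy.

    ``correctness`` maps pair_id -> 0/1 (post-fine-tuning match). Both
    factors need at least two observed levels with >= 2 records each.
    Type-II sums of squares are used (standard for unbalanced
    observational designs without interaction emphasis). When the
    terminology main effect or the interaction is significant at alpha,
    Games–Howell compares terminologies pairwise.
    """
    if proxy not in PROXIES:
        raise ValidationError(f"unknown proxy {proxy!r}; choose from {sorted(PROXIES)}")
    df = records.copy()
    df["correct"] = df["pair_id"].map(correctness)
    if df["correct"].isna().any():
        missing = df.loc[df["correct"].isna(), "pair_id"].iloc[0]
        raise ValidationError(f"no correctness bit for pair {missing}")
    df["correct"] = df["correct"].astype(int)
    dv = f"log_{proxy}"
    for factor in ("terminology", "correct"):
        level_counts = df[factor].value_counts()
        if (level_counts >= 2).sum() < 2:
            raise ValidationError(
                f"factor {factor!r} needs >= 2 levels with >= 2 records each"
            )
    if np.var(df[dv].to_numpy()) == 0:
        raise DegenerateInputError(f"{dv} has zero variance; ANOVA is undefined")

    notes: list[str] = []
    cell_sizes = df.groupby(["terminology", "correct"], observed=True).size()
    n_cells_expected = df["terminology"].nunique() * df["correct"].nunique()
    if len(cell_sizes) < n_cells_expected:
        notes.append(
            "unbalanced design with empty cells; Type-II sums of squares applied"
        )

    model = ols(f"{dv} ~ C(terminology) * C(correct)", data=df).fit()
    table = anova_lm(model, typ=2)
    table = table.rename(
        index={
            "C(terminology)": "terminology",
            "C(correct)": "correctness",
            "C(terminology):C(correct)": "terminology:correctness",
            "Residual": "residual",
        }
    )
    gh = None
    p_term = float(table.loc["terminology", "PR(>F)"])
    p_inter = float(table.loc["terminology:correctness", "PR(>F)"])
    if (np.isfinite(p_term) and p_term < alpha) or (
        np.isfinite(p_inter) and p_inter < alpha
    ):
        if df["terminology"].nunique() >= 2:
            gh = games_howell(df, dv=dv, between="terminology")
    return TwoWayAnovaReport(proxy=proxy, anova=table, games_howell=gh, notes=notes)


__all__ = [
    "PROXIES",
    "transform_counts",
    "attach_outcomes",
    "group_summaries",
    "proxy_correlations",
    "games_howell",
    "two_way_anova_popularity",
    "TwoWayAnovaReport",
]
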