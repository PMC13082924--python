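"""Four-way fine-tuning outcome classification and derived metrics.

Each evaluated instance carries two correctness bits: B (baseline) and
F (fine-tuned). The pair (B, F) places the instance in exactly one of
four mutually exclusive categories:

===================  =========  =========
category             B          F
===================  =========  =========
gainer               0          1
loser                1          0
continuing_correct   1          1
continuing_incorrect 0          0
===================  =========  =========

Aggregating by whether the pair was seen during fine-tuning yields the
derived metrics:

* memorization (%)   = gainers on seen instances / N_seen x 100
* generalization (%) = gainers on unseen instances / N_unseen x 100
* degradation (%)    = losers on unseen instances / N_unseen x 100
* derived accuracy   = continuing_correct% + gainer% - loser% on seen

The derived accuracy identity is what makes published category tables and
summary tables mutually checkable; :func:`check_consistency` flags cells
where a reported summary disagrees with the identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import CoverageError, ValidationError
from .scoring import ResponseRecord


class Category(str, Enum):
    GAINER = "gainer"
    LOSER = "loser"
    CONTINUING_CORRECT = "continuing_correct"
    CONTINUING_INCORRECT = "continuing_incorrect"


CATEGORIES = tuple(Category)


def categorize(B: int, F: int) -> Category:
    """Truth table mapping the (baseline, fine-tuned) bits to a category."""
    if B not in (0, 1) or F not in (0, 1):
        raise ValidationError(f"correctness bits must be 0/1, got B={B!r} F={F!r}")
    if B == 0 and F == 1:
        return Category.GAINER
    if B == 1 and F == 0:
        return Category.LOSER
    if B == 1 and F == 1:
        return Category.CONTINUING_CORRECT
    return Category.CONTINUING_INCORRECT


@dataclass(frozen=True)
class OutcomeRecord:
    instance_id: str
    B: int
    F: int
    split: str  # "seen" | "unseen"
    category: Category


def classify_outcomes(
    baseline: Sequence[ResponseRecord],
    finetuned: Sequence[ResponseRecord],
    split_of: Mapping[str, str],
) -> list[OutcomeRecord]:
    """Pair scored baseline and fine-tuned records into outcome records.

    Both conditions must cover exactly the same instance set; ``split_of``
    maps each instance_id to "seen" or "unseen".
    """
    base_by_id = {r.instance_id: r for r in baseline}
    fine_by_id = {r.instance_id: r for r in finetuned}
    missing_fine = sorted(set(base_by_id) - set(fine_by_id))
    missing_base = sorted(set(fine_by_id) - set(base_by_id))
    if missing_fine or missing_base:
        raise CoverageError(
            f"conditions do not cover the same instances; "
            f"missing fine-tuned: {missing_fine[:5]}, missing baseline: {missing_base[:5]}"
        )
    outcomes = []
    for iid, base in base_by_id.items():
        fine = fine_by_id[iid]
        if base.correct is None or fine.correct is None:
            raise ValidationError(f"instance {iid}: records must be scored first")
        split = split_of.get(iid)
        if split not in ("seen", "unseen"):
            raise ValidationError(f"instance {iid}: split must be 'seen' or 'unseen', got {split!r}")
        outcomes.append(
            OutcomeRecord(
                instance_id=iid,
                B=base.correct,
                F=fine.correct,
                split=split,
                category=categorize(base.correct, fine.correct),
            )
        )
    return outcomes


@dataclass
class MetricsSummary:
    """Counts, category percentage table, and the derived metrics."""

    N_seen: int
    N_unseen: int
    counts: pd.DataFrame  # index: category, columns: seen/unseen
    category_pcts: pd.DataFrame
    memorization_pct: Optional[float]
    generalization_pct: Optional[float]
    degraded_pct: Optional[float]
    accuracy_pct: Optional[float]
    pooled_accuracy_pct: Optional[float]
    notes: list[str] = field(default_factory=list)

    def rounded(self) -> dict:
        """Report-time view with percentages rounded to 1 decimal."""

        def r(x: Optional[float]) -> Optional[float]:
            return None if x is None else round(x, 1)

        return {
            "N_seen": self.N_seen,
            "N_unseen": self.N_unseen,
            "memorization_pct": r(self.memorization_pct),
            "generalization_pct": r(self.generalization_pct),
            "degraded_pct": r(self.degraded_pct),
            "accuracy_pct": r(self.accuracy_pct),
            "pooled_accuracy_pct": r(self.pooled_accuracy_pct),
            "category_pcts": self.category_pcts.round(1).to_dict(),
            "notes": list(self.notes),
        }


def summarize_metrics(outcomes: Sequence[OutcomeRecord]) -> MetricsSummary:
    """Aggregate outcome records into the category table and derived metrics.

    An absent split leaves its metrics as None with an explanatory note,
    never a silent zero. The fine-tuned accuracy on seen terms is also
    reported pooled over both splits, since published summaries differ in
    which convention they use.
    """
    if not outcomes:
        raise ValidationError("no outcomes to summarize")
    counts = pd.DataFrame(
        0, index=[c.value for c in CATEGORIES], columns=["seen", "unseen"], dtype=int
    )
    for rec in outcomes:
        counts.loc[rec.category.value, rec.split] += 1
    n_seen = int(counts["seen"].sum())
    n_unseen = int(counts["unseen"].sum())

    pcts = counts.astype(float)
    notes: list[str] = []
    for col, n in (("seen", n_seen), ("unseen", n_unseen)):
        if n > 0:
            pcts[col] = 100.0 * counts[col] / n
        else:
            pcts[col] = float("nan")
            notes.append(f"no {col} instances: {col}-side metrics not available")

    def pct(category: Category, split: str) -> Optional[float]:
        n = n_seen if split == "seen" else n_unseen
        if n == 0:
            return None
        return 100.0 * counts.loc[category.value, split] / n

    memorization = pct(Category.GAINER, "seen")
    generalization = pct(Category.GAINER, "unseen")
    degraded = pct(Category.LOSER, "unseen")
    if n_seen > 0:
        accuracy = (
            pct(Category.CONTINUING_CORRECT, "seen")
            + pct(Category.GAINER, "seen")
            - pct(Category.LOSER, "seen")
        )
    else:
        accuracy = None
    total = n_seen + n_unseen
    ft_correct = int(
        counts.loc[Category.CONTINUING_CORRECT.value].sum()
        + counts.loc[Category.GAINER.value].sum()
    )
    pooled = 100.0 * ft_correct / total if total else None

    return MetricsSummary(
        N_seen=n_seen,
        N_unseen=n_unseen,
        counts=counts,
        category_pcts=pcts,
        memorization_pct=memorization,
        generalization_pct=generalization,
        degraded_pct=degraded,
        accuracy_pct=accuracy,
        pooled_accuracy_pct=pooled,
        notes=notes,
    )


@dataclass(frozen=True)
class DerivedMetrics:
    """Derived summary computed from category percentages alone."""

    memorized: float
    generalized: float
    degraded: float
    accuracy: float

    def rounded(self) -> "DerivedMetrics":
        return DerivedMetrics(
            memorized=round(self.memorized, 1),
            generalized=round(self.generalized, 1),
            degraded=round(self.degraded, 1),
            accuracy=round(self.accuracy, 1),
        )


_PCT_KEYS = {c.value for c in CATEGORIES}


def derive_from_percentages(
    seen_pcts: Mapping[str, float], unseen_pcts: Mapping[str, float]
) -> DerivedMetrics:
    """Apply the derived-metric formulas to published category percentages.

    ``seen_pcts`` / ``unseen_pcts`` map the four category names to their
    percentage of instances in that split. This is the bridge from a
    category table (one row per category x split) to a summary row
    (memorized / generalized / degraded / accuracy).
    """
    for name, pcts in (("seen", seen_pcts), ("unseen", unseen_pcts)):
        missing = _PCT_KEYS - set(pcts)
        if missing:
            raise ValidationError(f"{name} percentages missing categories {sorted(missing)}")
    return DerivedMetrics(
        memorized=float(seen_pcts["gainer"]),
        generalized=float(unseen_pcts["gainer"]),
        degraded=float(unseen_pcts["loser"]),
        accuracy=float(
            seen_pcts["continuing_correct"] + seen_pcts["gainer"] - seen_pcts["loser"]
        ),
    )


def check_consistency(
    derived: DerivedMetrics, reported: Mapping[str, float], tol: float = 0.05
) -> dict[str, bool]:
    """Compare derived metrics against a reported summary row.

    Returns a map metric -> consistent? at printed precision (1 decimal,
    ±0.05). Inconsistent cells are flagged for the caller; nothing is
    forced into agreement.
    """
    rounded = derived.rounded()
    out = {}
    for key in ("memorized", "generalized", "degraded", "accuracy"):
        if key in reported:
            out[key] = abs(getattr(rounded, key) - float(reported[key])) <= tol
    return out


def export_transition_counts(outcomes: Sequence[OutcomeRecord]) -> dict:
    """Baseline-state -> fine-tuned-state flow counts per split.

    The four flows are exactly the four categories; inflow equals outflow
    equals N within each split, so any flow diagram built on these counts
    conserves mass.
    """
    flows: dict[str, dict[str, int]] = {}
    for rec in outcomes:
        split_flows = flows.setdefault(
            rec.split,
            {
                "incorrect->correct": 0,
                "correct->incorrect": 0,
                "correct->correct": 0,
                "incorrect->incorrect": 0,
            },
        )
        source = "correct" if rec.B else "incorrect"
        target = "correct" if rec.F else "incorrect"
        split_flows[f"{source}->{target}"] += 1
    return flows


def write_transition_counts(flows: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(flows, indent=2) + "\n", encoding="utf-8")


__all__ = [
    "Category",
    "CATEGORIES",
    "categorize",
    "OutcomeRecord",
    "classify_outcomes",
    "MetricsSummary",
    "summarize_metrics",
    "DerivedMetrics",
    "derive_from_percentages",
    "check_consistency",
    "export_transition_counts",
    "write_transition_counts",
]
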