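"""Frequency-balanced train / withheld sampling.

Biomedical terminologies are long-tailed: a handful of head codes dominate
literature mentions while most codes occur rarely or never. To probe model
behaviour across the whole frequency range, codes are ranked by their
corpus count, partitioned into contiguous rank bins (default 20), and an
equal number of pairs is drawn from every bin for each split. The withheld
split is matched for popularity *structurally*: both splits receive
exactly ``per_bin`` pairs from each bin, drawn in one pass and alternated.

Codes that never appear in the corpus (count 0) carry no evidence of use
and are excluded from sampling by default.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import SizingError, ValidationError
from .io import TermCodePair, TerminologyTable


@dataclass(frozen=True)
class SamplingPlan:
    """Parameters of the frequency-balanced draw.

    Defaults are the standard design: 20 rank bins x 30 pairs per bin per
    split, i.e. 600-pair train and 600-pair withheld sets.
    """

    n_bins: int = 20
    per_bin: int = 30
    namespace_quota: Optional[dict[str, int]] = None
    exclude_zero_counts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins <= 0 or self.per_bin <= 0:
            raise ValidationError("n_bins and per_bin must be positive")

    @property
    def split_size(self) -> int:
        return self.n_bins * self.per_bin


@dataclass
class SampledSplit:
    """A disjoint train/withheld draw plus bin bookkeeping and provenance."""

    train: list[str]
    withheld: list[str]
    bin_assignment: dict[str, int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.train) & set(self.withheld)
        if overlap:
            raise ValidationError(f"train/withheld overlap: {sorted(overlap)[:5]} ...")

    def split_of(self, pair_id: str) -> str:
        if pair_id in self._train_set:
            return "seen"
        if pair_id in self._withheld_set:
            return "unseen"
        raise KeyError(pair_id)

    @property
    def _train_set(self) -> set[str]:
        return set(self.train)

    @property
    def _withheld_set(self) -> set[str]:
        return set(self.withheld)


def _eligible_rows(table: TerminologyTable, plan: SamplingPlan) -> list[TermCodePair]:
    rows = list(table.rows)
    if plan.exclude_zero_counts:
        rows = [r for r in rows if r.code_count > 0]
    return rows


def rank_and_bin(table: TerminologyTable, plan: SamplingPlan) -> dict[str, int]:
    """Partition eligible pairs into contiguous rank bins.

    Rows are ranked by code_count descending (ties broken by code ascending
    for cross-platform determinism); bin 0 holds the most frequent codes.
    When the eligible count is not divisible by ``n_bins`` the head bins
    absorb the remainder, one extra row each.
    """
    rows = _eligible_rows(table, plan)
    minimum = plan.n_bins * 2 * plan.per_bin
    if len(rows) < minimum:
        raise SizingError(
            f"{len(rows)} eligible rows; the {plan.n_bins}x{plan.per_bin} design "
            f"requires at least {minimum}"
        )
    ranked = sorted(rows, key=lambda r: (-r.code_count, r.code))
    n = len(ranked)
    base, remainder = divmod(n, plan.n_bins)
    assignment: dict[str, int] = {}
    cursor = 0
    for b in range(plan.n_bins):
        size = base + (1 if b < remainder else 0)
        for row in ranked[cursor : cursor + size]:
            assignment[row.pair_id] = b
        cursor += size
    return assignment


def draw_balanced_splits(table: TerminologyTable, plan: SamplingPlan) -> SampledSplit:
    """Draw popularity-matched train and withheld splits.

    From each bin, ``2 * per_bin`` distinct pairs are drawn without
    replacement and alternated into train/withheld, so both splits contain
    exactly ``per_bin`` pairs from every bin. Deterministic per seed.
    """
    assignment = rank_and_bin(table, plan)
    by_bin: dict[int, list[str]] = {b: [] for b in range(plan.n_bins)}
    # keep ranked order within bins so rng.choice indexes a stable sequence
    ranked_ids = sorted(
        assignment, key=lambda pid: (-table[pid].code_count, table[pid].code)
    )
    for pid in ranked_ids:
        by_bin[assignment[pid]].append(pid)

    rng = np.random.default_rng(plan.seed)
    train: list[str] = []
    withheld: list[str] = []
    for b in range(plan.n_bins):
        pool = by_bin[b]
        need = 2 * plan.per_bin
        if len(pool) < need:
            raise SizingError(
                f"bin {b} holds {len(pool)} pairs but {need} are required"
            )
        drawn = rng.choice(len(pool), size=need, replace=False)
        # alternate by popularity rank within the draw so the two splits
        # interleave the bin's frequency range; a coin decides which split
        # leads, keeping the assignment exchangeable across bins
        picked = sorted(drawn.tolist())  # pool is already rank-ordered
        offset = int(rng.random() < 0.5)
        train.extend(pool[i] for i in picked[offset::2])
        withheld.extend(pool[i] for i in picked[1 - offset :: 2])
    return SampledSplit(
        train=train,
        withheld=withheld,
        bin_assignment=assignment,
        provenance={
            "n_bins": plan.n_bins,
            "per_bin": plan.per_bin,
            "exclude_zero_counts": plan.exclude_zero_counts,
            "seed": plan.seed,
            "namespace_quota": plan.namespace_quota,
        },
    )


def _derive_seed(seed: int, tag: str) -> int:
    # stage/namespace-tagged child seed, kept below 2**31
    return (seed + zlib.crc32(tag.encode("utf-8"))) % (2**31 - 1)


def draw_namespace_balanced(table: TerminologyTable, plan: SamplingPlan) -> SampledSplit:
    """Apply the balanced draw independently within each namespace.

    ``plan.namespace_quota`` maps namespace -> total pairs per split (the
    three-hierarchy design: 200 each, totalling 600). Binning is performed
    per namespace so each hierarchy's own frequency range is spanned.
    """
    if not plan.namespace_quota:
        raise ValidationError("namespace_quota must be set for a namespace-balanced draw")
    train: list[str] = []
    withheld: list[str] = []
    assignment: dict[str, int] = {}
    for namespace, quota in plan.namespace_quota.items():
        if quota % plan.n_bins != 0:
            raise ValidationError(
                f"namespace {namespace!r}: quota {quota} is not divisible by "
                f"{plan.n_bins} bins"
            )
        rows = [r for r in table.rows if r.namespace == namespace]
        if not rows:
            raise SizingError(f"namespace {namespace!r} has no rows in the table")
        sub_table = TerminologyTable(rows=rows, source_label=f"{table.source_label}:{namespace}")
        sub_plan = SamplingPlan(
            n_bins=plan.n_bins,
            per_bin=quota // plan.n_bins,
            exclude_zero_counts=plan.exclude_zero_counts,
            seed=_derive_seed(plan.seed, namespace),
        )
        try:
            sub_split = draw_balanced_splits(sub_table, sub_plan)
        except SizingError as exc:
            raise SizingError(f"namespace {namespace!r}: {exc}") from exc
        train.extend(sub_split.train)
        withheld.extend(sub_split.withheld)
        assignment.update(sub_split.bin_assignment)
    return SampledSplit(
        train=train,
        withheld=withheld,
        bin_assignment=assignment,
        provenance={
            "n_bins": plan.n_bins,
            "namespace_quota": dict(plan.namespace_quota),
            "exclude_zero_counts": plan.exclude_zero_counts,
            "seed": plan.seed,
            "per_namespace_binning": True,
        },
    )


def write_split(split: SampledSplit, path: str | Path) -> None:
    """JSONL split file: a provenance header object, then one row per pair."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write(json.dumps({"provenance": split.provenance}) + "\n")
        for name, ids in (("train", split.train), ("withheld", split.withheld)):
            for pid in ids:
                row = {"pair_id": pid, "split": name, "bin": split.bin_assignment.get(pid)}
                handle.write(json.dumps(row) + "\n")


def read_split(path: str | Path) -> SampledSplit:
    path = Path(path)
    provenance: dict = {}
    train: list[str] = []
    withheld: list[str] = []
    bins: dict[str, int] = {}
    with path.open("r", encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            record = json.loads(line)
            if "provenance" in record:
                provenance = record["provenance"]
                continue
            pid = record["pair_id"]
            (train if record["split"] == "train" else withheld).append(pid)
            if record.get("bin") is not None:
                bins[pid] = record["bin"]
    return SampledSplit(train=train, withheld=withheld, bin_assignment=bins, provenance=provenance)


__all__ = [
    "SamplingPlan",
    "SampledSplit",
    "rank_and_bin",
    "draw_balanced_splits",
    "draw_namespace_balanced",
    "write_split",
    "read_split",
]
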