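"""Output normalization and hits@1 exact-match scoring.

Predictions are scored top-1: one greedy-decoded output per instance, and
an answer counts only if it matches the gold answer exactly after a light,
documented normalization. Two matching modes are exposed:

* ``strict`` (default) — the whole normalized output must equal the
  normalized gold answer.
* ``lenient`` — for code answers, a single candidate matching the code's
  surface pattern is first extracted from the output (zero or multiple
  distinct candidates score 0); for term answers the gold term may appear
  as a whole-phrase substring.

Strict correctness implies lenient correctness, never the converse.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .errors import JoinError, ValidationError
from .prompting import EvaluationInstance

logger = logging.getLogger(__name__)

_TERMINAL_PUNCT = ".!?;:,\"'"
_PREFIXED_CODE_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]*)\s*[:_]\s*(\d+)$")
_PREFIXED_FIND_RE = re.compile(r"[A-Za-z][A-Za-z0-9]*\s?[:_]\s?\d+")
_SYMBOL_FIND_RE = re.compile(r"\b[A-Z][A-Z0-9-]{1,14}\b")


def normalize_answer(raw: str, answer_kind: str = "code") -> str:
    """Canonicalize a model output or gold answer for comparison.

    Trims whitespace, strips terminal sentence punctuation, collapses
    internal whitespace runs; terms are case-folded; codes keep their case
    except registry prefixes (HP:, GO:, HGNC:, ...) which are upper-cased,
    and underscore separators (``HP_0001250``) are normalized to colon form.
    Total function: never raises.
    """
    text = raw.strip()
    text = text.rstrip(_TERMINAL_PUNCT).strip()
    text = re.sub(r"\s+", " ", text)
    if answer_kind == "term":
        return text.casefold()
    match = _PREFIXED_CODE_RE.match(text)
    if match:
        prefix, digits = match.groups()
        return f"{prefix.upper()}:{digits}"
    return text


def _extract_code_candidates(text: str, gold_normalized: str) -> set[str]:
    """Find distinct code-shaped substrings, shaped like the gold answer."""
    if ":" in gold_normalized:  # prefixed registry identifier
        found = _PREFIXED_FIND_RE.findall(text)
    else:  # bare symbol: all-caps alphanumeric token
        found = _SYMBOL_FIND_RE.findall(text)
    return {normalize_answer(tok, "code") for tok in found}


@dataclass(frozen=True)
class ResponseRecord:
    """One model answer to one instance under one condition."""

    instance_id: str
    condition: str  # "baseline" | "finetuned"
    raw_output: str
    normalized_output: str = ""
    correct: Optional[int] = None


def is_correct(raw_output: str, gold_answer: str, answer_kind: str, mode: str) -> int:
    """Score a single output against its gold answer. Returns 0 or 1."""
    gold = normalize_answer(gold_answer, answer_kind)
    out = normalize_answer(raw_output, answer_kind)
    if out == gold:
        return 1
    if mode == "strict":
        return 0
    if mode != "lenient":
        raise ValidationError(f"unknown scoring mode {mode!r}")
    if answer_kind == "code":
        candidates = _extract_code_candidates(raw_output, gold)
        if len(candidates) != 1:
            return 0
        return int(candidates.pop() == gold)
    # lenient term match: gold term as a whole-phrase substring
    return int(re.search(rf"(?<!\w){re.escape(gold)}(?!\w)", out) is not None)


def score_responses(
    instances: Sequence[EvaluationInstance],
    responses: Sequence[ResponseRecord],
    mode: str = "strict",
) -> list[ResponseRecord]:
    """Join responses to instances and set per-instance correctness bits.

    One response per (instance, condition) is required — greedy decoding
    yields a single deterministic output — and every response must
    reference a known instance.
    """
    by_id = {inst.instance_id: inst for inst in instances}
    seen_keys: set[tuple[str, str]] = set()
    scored: list[ResponseRecord] = []
    for resp in responses:
        inst = by_id.get(resp.instance_id)
        if inst is None:
            raise JoinError(f"response references unknown instance {resp.instance_id!r}")
        key = (resp.instance_id, resp.condition)
        if key in seen_keys:
            raise JoinError(f"duplicate response for instance/condition {key!r}")
        seen_keys.add(key)
        scored.append(
            replace(
                resp,
                normalized_output=normalize_answer(resp.raw_output, inst.answer_kind),
                correct=is_correct(resp.raw_output, inst.gold_answer, inst.answer_kind, mode),
            )
        )
    return scored


def accuracy(records: Iterable[ResponseRecord]) -> float:
    """hits@1 accuracy in percent (full precision; round only at report time)."""
    bits = [r.correct for r in records]
    if any(b is None for b in bits):
        raise ValidationError("records must be scored before computing accuracy")
    if not bits:
        raise ValidationError("no records to summarize")
    return 100.0 * sum(bits) / len(bits)


#: A responder maps one evaluation instance to a single raw output string.
Responder = Callable[[EvaluationInstance], str]


def run_responder(
    instances: Sequence[EvaluationInstance],
    responder: Responder,
    condition: str,
) -> list[ResponseRecord]:
    """Produce one ResponseRecord per instance from a pluggable responder.

    A responder exception is recorded as an empty output (scored 0) and
    logged, so one bad instance never aborts an evaluation run.
    """
    records = []
    for inst in instances:
        try:
            output = responder(inst)
        except Exception:  # noqa: BLE001 - contract: degrade, don't abort
            logger.exception("responder failed on instance %s", inst.instance_id)
            output = ""
        records.append(
            ResponseRecord(instance_id=inst.instance_id, condition=condition, raw_output=output)
        )
    return records


def playback_responder(recorded: Mapping[str, str]) -> Responder:
    """Replay recorded outputs keyed by instance_id."""

    def respond(inst: EvaluationInstance) -> str:
        try:
            return recorded[inst.instance_id]
        except KeyError as exc:
            raise JoinError(f"no recorded output for instance {inst.instance_id!r}") from exc

    return respond


def write_responses(records: Sequence[ResponseRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        for rec in records:
            row = {
                "instance_id": rec.instance_id,
                "condition": rec.condition,
                "raw_output": rec.raw_output,
            }
            handle.write(json.dumps(row, ensure_ascii=False) + "\n")


def read_responses(path: str | Path) -> list[ResponseRecord]:
    records = []
    with Path(path).open("r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            row = json.loads(line)
            try:
                records.append(
                    ResponseRecord(
                        instance_id=row["instance_id"],
                        condition=row["condition"],
                        raw_output=row["raw_output"],
                    )
                )
            except KeyError as exc:
                raise ValidationError(f"{path}:{lineno}: missing field {exc}") from exc
    return records


__all__ = [
    "ResponseRecord",
    "Responder",
    "normalize_answer",
    "is_correct",
    "score_responses",
    "accuracy",
    "run_responder",
    "playback_responder",
    "write_responses",
    "read_responses",
]
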