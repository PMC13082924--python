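"""Prompt-template expansion and fine-tuning file export.

Each term–code pair is expanded into five fixed natural-language prompt
templates per mapping direction. Forward prompts ask for the code given
the term; reverse prompts mirror the forward wording, swapping the roles
of "term" and "identifier" and substituting the code into the probe slot.
No further prompt engineering is applied: the five templates are fixed a
priori and used verbatim across terminologies and directions.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from math import ceil
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import TemplateError, ValidationError
from .io import CodeType, TermCodePair

#: The five canonical forward templates. [ONTOLOGY] is the terminology
#: label, [TERM] the probed term. Template 2 carries an explicit
#: answer-format instruction on a second line.
DEFAULT_FORWARD_PATTERNS: tuple[str, ...] = (
    "What is the [ONTOLOGY] identifier for the [ONTOLOGY] term [TERM]?",
    "The [ONTOLOGY] term [TERM] has what [ONTOLOGY] identifier?\n"
    "Respond only with the [ONTOLOGY] identifier.",
    "Provide the [ONTOLOGY] identifier for: [TERM]",
    "What is the ontology identifier for [TERM] in [ONTOLOGY]?",
    "Return only the [ONTOLOGY] identifier for the term: [TERM]",
)

#: Requested-object wording per code type: arbitrary codes are asked for
#: as "identifier", mnemonic gene symbols as "gene symbol".
OBJECT_WORDS: dict[CodeType, str] = {
    CodeType.ARBITRARY_ID: "identifier",
    CodeType.LEXICALIZED_SYMBOL: "gene symbol",
}


@dataclass(frozen=True)
class PromptTemplate:
    template_id: int
    pattern: str
    direction: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        slot = "[TERM]" if self.direction == "forward" else "[CODE]"
        if self.direction not in ("forward", "reverse"):
            raise TemplateError(f"unknown direction {self.direction!r}")
        if self.pattern.count(slot) != 1:
            raise TemplateError(
                f"template {self.template_id}: pattern must contain {slot} exactly once"
            )
        if "[ONTOLOGY]" not in self.pattern:
            raise TemplateError(
                f"template {self.template_id}: pattern must contain [ONTOLOGY]"
            )


@dataclass(frozen=True)
class EvaluationInstance:
    """A single (pair, direction, template) probe with its gold answer."""

    instance_id: str
    pair_id: str
    direction: str
    template_id: int
    prompt_text: str
    gold_answer: str
    split: Optional[str] = None  # "seen" | "unseen" | None
    terminology: str = ""
    answer_kind: str = "code"  # "code" | "term"


def default_forward_templates() -> list[PromptTemplate]:
    return [
        PromptTemplate(template_id=i + 1, pattern=p, direction="forward")
        for i, p in enumerate(DEFAULT_FORWARD_PATTERNS)
    ]


_SENTINEL = "\x00"


def _swap_roles(pattern: str) -> str:
    """Swap the standalone words 'identifier' and 'term' in one pass."""
    out = re.sub(r"\bidentifier\b", _SENTINEL, pattern)
    out = re.sub(r"\bterm\b", "identifier", out)
    return out.replace(_SENTINEL, "term")


def mirror_templates(forward: Sequence[PromptTemplate]) -> list[PromptTemplate]:
    """Produce the reverse templates mirroring a forward set.

    The probe slot receives the code and the requested object becomes the
    term: ``Provide the [ONTOLOGY] identifier for: [TERM]`` mirrors to
    ``Provide the [ONTOLOGY] term for: [CODE]``. Applying the mirror twice
    returns a forward-shaped set.
    """
    mirrored = []
    for tpl in forward:
        if tpl.direction == "forward":
            pattern = _swap_roles(tpl.pattern).replace("[TERM]", "[CODE]")
            direction = "reverse"
        else:
            pattern = _swap_roles(tpl.pattern).replace("[CODE]", "[TERM]")
            direction = "forward"
        mirrored.append(
            PromptTemplate(template_id=tpl.template_id, pattern=pattern, direction=direction)
        )
    return mirrored


def default_reverse_templates() -> list[PromptTemplate]:
    return mirror_templates(default_forward_templates())


def render_prompt(template: PromptTemplate, pair: TermCodePair) -> str:
    """Instantiate one template for one pair."""
    text = template.pattern
    object_word = OBJECT_WORDS[pair.code_type]
    if object_word != "identifier":
        text = re.sub(r"\bidentifier\b", object_word, text)
    text = text.replace("[ONTOLOGY]", pair.terminology)
    if template.direction == "forward":
        return text.replace("[TERM]", pair.term)
    return text.replace("[CODE]", pair.code)


def expand_prompts(
    pairs: Sequence[TermCodePair],
    direction: str,
    templates: Optional[Sequence[PromptTemplate]] = None,
    split: Optional[str] = None,
) -> list[EvaluationInstance]:
    """Expand pairs x templates into evaluation instances.

    Ordering is deterministic: pair order (outer) x template order (inner),
    so |output| = |pairs| x |templates|.
    """
    if templates is None:
        templates = (
            default_forward_templates() if direction == "forward" else default_reverse_templates()
        )
    for tpl in templates:
        if tpl.direction != direction:
            raise TemplateError(
                f"template {tpl.template_id} has direction {tpl.direction!r}, "
                f"expected {direction!r}"
            )
    instances = []
    for pair in pairs:
        for tpl in templates:
            gold = pair.code if direction == "forward" else pair.term
            instances.append(
                EvaluationInstance(
                    instance_id=f"{pair.pair_id}:{direction}:{tpl.template_id}",
                    pair_id=pair.pair_id,
                    direction=direction,
                    template_id=tpl.template_id,
                    prompt_text=render_prompt(tpl, pair),
                    gold_answer=gold,
                    split=split,
                    terminology=pair.terminology,
                    answer_kind="code" if direction == "forward" else "term",
                )
            )
    return instances


def export_finetune_file(
    instances: Sequence[EvaluationInstance], path: str | Path
) -> None:
    """Write a supervised fine-tuning file: one {prompt, completion} per line."""
    if not instances:
        raise ValidationError("refusing to export an empty fine-tuning file")
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for inst in instances:
            handle.write(
                json.dumps(
                    {"prompt": inst.prompt_text, "completion": inst.gold_answer},
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_finetune_file(path: str | Path) -> list[dict]:
    with Path(path).open("r", encoding="utf-8") as handle:
        return [json.loads(line) for line in handle if line.strip()]


def write_instances(instances: Sequence[EvaluationInstance], path: str | Path) -> None:
    """One evaluation instance per JSONL row (all fields, verbatim)."""
    with Path(path).open("w", encoding="utf-8") as handle:
        for inst in instances:
            handle.write(json.dumps(inst.__dict__, ensure_ascii=False) + "\n")


def read_instances(path: str | Path) -> list[EvaluationInstance]:
    with Path(path).open("r", encoding="utf-8") as handle:
        return [
            EvaluationInstance(**json.loads(line)) for line in handle if line.strip()
        ]


@dataclass(frozen=True)
class TrainingSteps:
    """Gradient-update count for a fine-tuning run.

    Batches are counted over the pooled example stream (n_examples x
    epochs); when that total is not divisible by the batch size, the
    final partial batch counts as one additional step.
    """

    full_batches: int
    partial_batches: int

    @property
    def total(self) -> int:
        return self.full_batches + self.partial_batches


def training_steps(n_examples: int, epochs: int, batch_size: int) -> TrainingSteps:
    if n_examples <= 0 or epochs <= 0 or batch_size <= 0:
        raise ValidationError("n_examples, epochs and batch_size must all be positive")
    full, rem = divmod(n_examples * epochs, batch_size)
    return TrainingSteps(full_batches=full, partial_batches=1 if rem else 0)


def training_step_count(n_examples: int, epochs: int, batch_size: int) -> int:
    """Total gradient updates: n x epochs / batch, exact when divisible,
    with a trailing partial batch counting as one step otherwise."""
    return training_steps(n_examples, epochs, batch_size).total


__all__ = [
    "DEFAULT_FORWARD_PATTERNS",
    "OBJECT_WORDS",
    "PromptTemplate",
    "EvaluationInstance",
    "default_forward_templates",
    "default_reverse_templates",
    "mirror_templates",
    "render_prompt",
    "expand_prompts",
    "export_finetune_file",
    "read_finetune_file",
    "write_instances",
    "read_instances",
    "TrainingSteps",
    "training_steps",
    "training_step_count",
]
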