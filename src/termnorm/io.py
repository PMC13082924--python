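"""Core data model and tabular I/O for term–code pair tables.

A terminology is represented as a flat table with one row per term–code
pair: the natural-language term (e.g. "Tremor"), its code (an arbitrary
identifier like "HP:0001337" or a lexicalized symbol like "TP53"), and
three popularity proxies — how often the code, the term, and the pair's
curated annotations appear in a literature corpus.

Files are UTF-8 TSV (tab-separated, no quoting; literal tabs inside a
field are a validation error) or JSONL (one object per row). Both formats
round-trip bit-exactly through :func:`read_terminology_table` /
:func:`write_terminology_table`.
"""

from __future__ import annotations

import hashlib
import json
import unicodedata
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .errors import SchemaError, ValidationError


class CodeType(str, Enum):
    """Whether a code is a semantically opaque identifier or a mnemonic symbol."""

    ARBITRARY_ID = "arbitrary_id"
    LEXICALIZED_SYMBOL = "lexicalized_symbol"


#: Column order used by both TSV and JSONL serializations.
FIELD_NAMES = (
    "pair_id",
    "terminology",
    "term",
    "code",
    "code_type",
    "namespace",
    "code_count",
    "term_count",
    "annotation_count",
)

_COUNT_FIELDS = ("code_count", "term_count", "annotation_count")


def stable_pair_id(terminology: str, term: str, code: str) -> str:
    """Deterministic pair key, stable across runs and platforms.

    Lets recorded model responses be joined back to their pairs even when
    the source table carried no explicit ids.
    """
    payload = "\x1f".join((terminology, term, code)).encode("utf-8")
    return hashlib.sha1(payload).hexdigest()[:12]


@dataclass(frozen=True)
class TermCodePair:
    """One term with one code and its popularity counts."""

    term: str
    code: str
    code_type: CodeType
    terminology: str
    pair_id: str = ""
    namespace: Optional[str] = None
    code_count: int = 0
    term_count: int = 0
    annotation_count: int = 0

    def __post_init__(self) -> None:
        term = unicodedata.normalize("NFC", self.term).strip()
        code = unicodedata.normalize("NFC", self.code).strip()
        object.__setattr__(self, "term", term)
        object.__setattr__(self, "code", code)
        if not term:
            raise ValidationError("term is empty after trimming")
        if not code:
            raise ValidationError("code is empty after trimming")
        if "\t" in term or "\t" in code:
            raise ValidationError("literal tab characters are forbidden in term/code")
        object.__setattr__(self, "code_type", CodeType(self.code_type))
        for name in _COUNT_FIELDS:
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool) or value < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {value!r}")
        if not self.pair_id:
            object.__setattr__(
                self, "pair_id", stable_pair_id(self.terminology, term, code)
            )


@dataclass
class TerminologyTable:
    """Ordered collection of :class:`TermCodePair` rows with uniqueness checks."""

    rows: list[TermCodePair] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        seen_ids: set[str] = set()
        seen_triples: set[tuple[str, str, CodeType]] = set()
        for i, row in enumerate(self.rows):
            if row.pair_id in seen_ids:
                raise ValidationError(f"row {i}: duplicate pair_id {row.pair_id!r}")
            triple = (row.term, row.code, row.code_type)
            if triple in seen_triples:
                raise ValidationError(
                    f"row {i}: duplicate (term, code, code_type) {triple!r}"
                )
            seen_ids.add(row.pair_id)
            seen_triples.add(triple)
        self._by_id = {row.pair_id: row for row in self.rows}

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[TermCodePair]:
        return iter(self.rows)

    def __getitem__(self, pair_id: str) -> TermCodePair:
        return self._by_id[pair_id]

    def __contains__(self, pair_id: str) -> bool:
        return pair_id in self._by_id

    def subset(self, pair_ids: Iterable[str], source_label: str = "") -> "TerminologyTable":
        wanted = set(pair_ids)
        return TerminologyTable(
            rows=[r for r in self.rows if r.pair_id in wanted],
            source_label=source_label or self.source_label,
        )

    def namespaces(self) -> list[str]:
        seen: dict[str, None] = {}
        for row in self.rows:
            if row.namespace is not None:
                seen.setdefault(row.namespace, None)
        return list(seen)

    def to_records(self) -> list[dict]:
        return [_row_to_record(r) for r in self.rows]


def _row_to_record(row: TermCodePair) -> dict:
    return {
        "pair_id": row.pair_id,
        "terminology": row.terminology,
        "term": row.term,
        "code": row.code,
        "code_type": row.code_type.value,
        "namespace": row.namespace,
        "code_count": row.code_count,
        "term_count": row.term_count,
        "annotation_count": row.annotation_count,
    }


def _record_to_row(record: dict, where: str) -> TermCodePair:
    missing = [k for k in FIELD_NAMES if k not in record]
    # pair_id / namespace may legitimately be absent or empty
    missing = [k for k in missing if k not in ("pair_id", "namespace")]
    if missing:
        raise SchemaError(f"{where}: missing required fields {missing}")
    counts = {}
    for name in _COUNT_FIELDS:
        raw = record[name]
        try:
            value = int(raw)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{where}: {name}={raw!r} is not an integer") from exc
        if value < 0:
            raise ValidationError(f"{where}: {name}={value} is negative")
        counts[name] = value
    code_type = record["code_type"]
    if code_type not in (ct.value for ct in CodeType):
        raise ValidationError(f"{where}: unknown code_type {code_type!r}")
    namespace = record.get("namespace") or None
    try:
        return TermCodePair(
            pair_id=str(record.get("pair_id") or ""),
            terminology=str(record["terminology"]),
            term=str(record["term"]),
            code=str(record["code"]),
            code_type=CodeType(code_type),
            namespace=namespace,
            **counts,
        )
    except ValidationError as exc:
        raise ValidationError(f"{where}: {exc}") from exc


def read_terminology_table(path: str | Path, format: str = "tsv") -> TerminologyTable:
    """Read and validate a terminology table from TSV or JSONL.

    Every malformed row raises with its row number; rows are never
    silently dropped.
    """
    path = Path(path)
    if format == "tsv":
        rows = list(_read_tsv(path))
    elif format == "jsonl":
        rows = list(_read_jsonl(path))
    else:
        raise ValueError(f"unknown format {format!r}")
    return TerminologyTable(rows=rows, source_label=str(path))


def _read_tsv(path: Path) -> Iterator[TermCodePair]:
    with path.open("r", encoding="utf-8", newline="") as handle:
        header_line = handle.readline()
        if not header_line:
            raise SchemaError(f"{path}: empty file, expected a header row")
        header = header_line.rstrip("\n").split("\t")
        required = [f for f in FIELD_NAMES if f not in ("pair_id", "namespace")]
        missing = [f for f in required if f not in header]
        if missing:
            raise SchemaError(f"{path}: header is missing columns {missing}")
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise SchemaError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(cells)}"
                )
            record = dict(zip(header, cells))
            yield _record_to_row(record, where=f"{path}:{lineno}")


def _read_jsonl(path: Path) -> Iterator[TermCodePair]:
    with path.open("r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            yield _record_to_row(record, where=f"{path}:{lineno}")


def write_terminology_table(
    table: TerminologyTable, path: str | Path, format: str = "tsv"
) -> None:
    """Write a table so that re-reading it reproduces the table exactly."""
    path = Path(path)
    if format == "tsv":
        with path.open("w", encoding="utf-8", newline="") as handle:
            handle.write("\t".join(FIELD_NAMES) + "\n")
            for row in table.rows:
                record = _row_to_record(row)
                record["namespace"] = record["namespace"] or ""
                handle.write(
                    "\t".join(str(record[f]) for f in FIELD_NAMES) + "\n"
                )
    elif format == "jsonl":
        with path.open("w", encoding="utf-8") as handle:
            for row in table.rows:
                handle.write(json.dumps(_row_to_record(row), ensure_ascii=False) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


__all__ = [
    "CodeType",
    "TermCodePair",
    "TerminologyTable",
    "FIELD_NAMES",
    "stable_pair_id",
    "read_terminology_table",
    "write_terminology_table",
    "replace",
]
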