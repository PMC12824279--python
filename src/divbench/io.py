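"""File I/O: response and text corpora (JSONL/CSV), tables, vector files.

Every reader validates its schema and reports the offending line number;
every writer is deterministic (fixed column order, fixed float format,
sorted JSON keys) so identical inputs and seeds produce byte-identical
outputs.
"""

from __future__ import annotations

import json
import re
from typing import Iterable, Sequence

import pandas as pd

from .dat import ParsedResponse, RawResponse
from .embeddings import EmbeddingTable
from .textmetrics import TextSample

__all__ = [
    "SchemaError",
    "read_responses",
    "read_texts",
    "write_responses",
    "write_texts",
    "write_results",
    "write_vectors",
]


class SchemaError(ValueError):
    """An input file is missing required fields or malformed."""


_RESPONSE_FIELDS = ("response_id", "source", "condition", "text")
_WORD_COL_RE = re.compile(r"^(word|w)_?(\d+)$", re.IGNORECASE)


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = str(path).lower().rsplit(".", 1)[-1]
    if suffix in ("jsonl", "json", "ndjson"):
        return "jsonl"
    if suffix == "csv":
        return "csv"
    raise SchemaError(f"cannot infer format from path {path!r}; pass fmt explicitly")


def read_responses(path, fmt: str | None = None) -> list[RawResponse]:
    """Read raw word-list responses.

    JSONL: one object per line with ``response_id, source, condition,
    text``; unknown fields are preserved as metadata and the line number
    is attached for error reporting.  CSV: either a ``text`` column with
    the same id columns, or human-entry mode with 10 word columns
    (``word1..word10``), which are joined into one entry per line so the
    ordinary parser reproduces the tabulated words exactly.
    """
    fmt = _infer_format(path, fmt)
    out: list[RawResponse] = []
    if fmt == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"{path}: line {lineno}: invalid JSON") from exc
                for fld in ("response_id", "source", "text"):
                    if fld not in obj:
                        raise SchemaError(
                            f"{path}: line {lineno}: missing field {fld!r}"
                        )
                meta = {k: v for k, v in obj.items() if k not in _RESPONSE_FIELDS}
                meta["line"] = lineno
                try:
                    out.append(
                        RawResponse(
                            response_id=str(obj["response_id"]),
                            source=str(obj["source"]),
                            condition=str(obj.get("condition", "dat")),
                            text=str(obj["text"]),
                            metadata=meta,
                        )
                    )
                except ValueError as exc:
                    raise SchemaError(f"{path}: line {lineno}: {exc}") from exc
        return out

    df = pd.read_csv(path, dtype=str).fillna("")
    word_cols = sorted(
        (c for c in df.columns if _WORD_COL_RE.match(c)),
        key=lambda c: int(_WORD_COL_RE.match(c).group(2)),
    )
    if "text" not in df.columns and not word_cols:
        raise SchemaError(f"{path}: need a 'text' column or word1..word10 columns")
    for fld in ("response_id", "source"):
        if fld not in df.columns:
            raise SchemaError(f"{path}: missing column {fld!r}")
    for idx, row in df.iterrows():
        lineno = int(idx) + 2  # header is line 1
        if "text" in df.columns and row["text"]:
            text = row["text"]
        else:
            text = "\n".join(w for w in (row[c].strip() for c in word_cols) if w)
        try:
            out.append(
                RawResponse(
                    response_id=row["response_id"],
                    source=row["source"],
                    condition=row.get("condition", "") or "dat",
                    text=text,
                    metadata={"line": lineno},
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: line {lineno}: {exc}") from exc
    return out


def read_texts(path) -> list[TextSample]:
    """Read creative-writing samples from JSONL
    (``text_id, source, task, body`` plus optional ``condition``)."""
    out: list[TextSample] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"{path}: line {lineno}: invalid JSON") from exc
            for fld in ("text_id", "source", "task", "body"):
                if fld not in obj:
                    raise SchemaError(f"{path}: line {lineno}: missing field {fld!r}")
            try:
                out.append(
                    TextSample(
                        text_id=str(obj["text_id"]),
                        source=str(obj["source"]),
                        task=str(obj["task"]),
                        body=str(obj["body"]),
                        condition=obj.get("condition"),
                    )
                )
            except ValueError as exc:
                raise SchemaError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_responses(responses: Iterable[RawResponse], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in responses:
            record = {
                "response_id": r.response_id,
                "source": r.source,
                "condition": r.condition,
                "text": r.text,
            }
            fh.write(json.dumps(record, sort_keys=True) + "\n")


def write_texts(samples: Iterable[TextSample], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in samples:
            record = {
                "text_id": s.text_id,
                "source": s.source,
                "task": s.task,
                "body": s.body,
            }
            if s.condition is not None:
                record["condition"] = s.condition
            fh.write(json.dumps(record, sort_keys=True) + "\n")


def write_results(df: pd.DataFrame, path, allow_empty: bool = False) -> None:
    """Write a result table as UTF-8 CSV with a stable float format."""
    if df.empty and not allow_empty:
        raise ValueError("refusing to write an empty table (pass allow_empty=True)")
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def write_vectors(table: EmbeddingTable, path) -> None:
    """Write a table in the plain-text vector dialect (full precision)."""
    with open(path, "w", encoding="utf-8") as fh:
        for word in sorted(table.vocab):
            comps = " ".join(format(x, ".17g") for x in table.vocab[word])
            fh.write(f"{word} {comps}\n")
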