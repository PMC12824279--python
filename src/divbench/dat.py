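"""Divergent Association Task (DAT) parsing and scoring.

The DAT asks for 10 words that are as different from each other as
possible.  The score is 100 x the mean pairwise cosine distance over the
first 7 valid words of the response, giving a theoretical range of 0
(identical vectors) to 200 (every pair antipodal); responses with fewer
than 10 listed words or fewer than 7 valid words are excluded.

This module turns raw generations (numbered lists, bulleted lists,
comma-separated lines, bare lines) into word lists, applies the validity
and adherence rules, and computes scores, adherence ratios and word-set
frequency tables over whole corpora.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .embeddings import EmbeddingTable, embed_word

__all__ = [
    "RawResponse",
    "ParsedResponse",
    "DATResult",
    "parse_response",
    "select_scoring_words",
    "dat_score",
    "parse_corpus",
    "score_corpus",
    "adherence_ratio",
    "word_set_frequencies",
]

_CONDITION_RE = re.compile(
    r"^(dat|control|strategy:[a-z_]+|temperature:(low|mid|high|default))$"
)


@dataclass
class RawResponse:
    """One raw trial: an unparsed generation or human entry."""

    response_id: str
    source: str
    condition: str = "dat"
    text: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not _CONDITION_RE.match(self.condition):
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class ParsedResponse:
    """A trial after parsing: ordered words plus validity/adherence flags.

    ``valid_flags`` marks, per word, whether it can contribute to scoring
    (single word, not a duplicate, and -- after selection -- present in the
    embedding vocabulary).  ``scoring_words`` is the first-7-valid subset;
    ``adhered`` requires a full 10-entry list *and* 7 scoring words.
    """

    response_id: str
    source: str
    condition: str
    words: list[str]
    valid_flags: list[bool]
    scoring_words: list[str] | None = None
    adhered: bool = False
    excluded_reason: str | None = None


@dataclass
class DATResult:
    score: float
    n_pairs: int
    used_words: list[str]


_NUMBERED_RE = re.compile(r"^\s*\d+\s*[.):\]-]\s*(.*)$")
_BULLET_RE = re.compile(r"^\s*[-*•–—]\s+(.*)$")
_STRIP_CHARS = ".,;:!?\"'()[]{}<>«»“”‘’`"


def _clean_entry(entry: str) -> str:
    entry = entry.strip().strip(_STRIP_CHARS).strip()
    entry = re.sub(r"\s+", " ", entry)
    return entry.lower()


def parse_response(raw: RawResponse) -> ParsedResponse:
    """Extract candidate words from a raw generation.

    List dialect is auto-detected per response: if numbered or bulleted
    lines are present, only those lines are entries (preamble chatter such
    as "Sure! Here is my list:" is dropped) and the majority marker style
    wins; a single comma-separated line is split on commas; otherwise each
    non-empty line is one entry.  Entries are lowercased and stripped of
    surrounding punctuation.  Multiword entries are retained as single
    tokens but flagged invalid, as are duplicates after the first
    occurrence.  Empty text yields ``excluded_reason='unparseable'``.
    """
    text = raw.text or ""
    lines = [ln for ln in text.splitlines() if ln.strip()]

    numbered: list[str] = []
    bulleted: list[str] = []
    bare: list[str] = []
    for ln in lines:
        m = _NUMBERED_RE.match(ln)
        if m:
            numbered.append(m.group(1))
            continue
        m = _BULLET_RE.match(ln)
        if m:
            bulleted.append(m.group(1))
            continue
        bare.append(ln)

    if numbered or bulleted:
        entries = numbered if len(numbered) >= len(bulleted) else bulleted
    elif len(lines) == 1 and "," in lines[0]:
        entries = lines[0].split(",")
    else:
        entries = bare

    words: list[str] = []
    flags: list[bool] = []
    seen: set[str] = set()
    for entry in entries:
        word = _clean_entry(entry)
        if not word:
            continue
        ok = " " not in word and word not in seen
        words.append(word)
        flags.append(ok)
        if ok:
            seen.add(word)

    parsed = ParsedResponse(
        response_id=raw.response_id,
        source=raw.source,
        condition=raw.condition,
        words=words,
        valid_flags=flags,
    )
    if not words:
        parsed.excluded_reason = "unparseable"
    return parsed


def select_scoring_words(
    parsed: ParsedResponse, table: EmbeddingTable
) -> ParsedResponse:
    """Apply the first-7-valid rule and the 10-word adherence rule.

    A word is valid when it survived parsing (single word, non-duplicate)
    and is in the embedding vocabulary; the scoring subset is the first 7
    valid words in listed order, which lets occasional misspellings still
    yield a valid score.  Failures are encoded on the record, never raised.
    """
    flags = [
        bool(ok and embed_word(table, w)[1])
        for w, ok in zip(parsed.words, parsed.valid_flags)
    ]
    valid_words = [w for w, ok in zip(parsed.words, flags) if ok]
    scoring = valid_words[:7]
    out = replace(parsed, valid_flags=flags, scoring_words=scoring)
    out.adhered = len(parsed.words) >= 10 and len(scoring) == 7
    if out.adhered:
        out.excluded_reason = None
    elif parsed.excluded_reason == "unparseable":
        out.excluded_reason = "unparseable"
    elif len(parsed.words) < 10:
        out.excluded_reason = "too_few_words"
    else:
        out.excluded_reason = "too_few_valid"
    return out


def dat_score(words: Sequence[str], table: EmbeddingTable) -> DATResult:
    """Score exactly 7 in-vocabulary words.

    score = 100 x mean over all C(7,2)=21 unordered pairs of
    (1 - cosine similarity); invariant to word order.
    """
    words = list(words)
    if len(words) != 7:
        raise ValueError(f"dat_score requires exactly 7 words, got {len(words)}")
    try:
        mat = table.matrix(words)
    except KeyError as exc:
        raise ValueError(f"out-of-vocabulary word in scoring set: {exc}") from exc
    norms = np.linalg.norm(mat, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("zero-norm vector in scoring set")
    unit = mat / norms[:, None]
    gram = unit @ unit.T
    iu = np.triu_indices(len(words), k=1)
    score = float(100.0 * np.mean(1.0 - gram[iu]))
    return DATResult(score=score, n_pairs=len(iu[0]), used_words=words)


def parse_corpus(
    responses: Iterable[RawResponse], table: EmbeddingTable
) -> list[ParsedResponse]:
    """Parse and select scoring words for every response."""
    return [select_scoring_words(parse_response(r), table) for r in responses]


def score_corpus(
    responses: Sequence[RawResponse],
    table: EmbeddingTable,
    include_excluded: bool = False,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Score a corpus; one row per adhered response plus an exclusion log.

    With ``include_excluded=True`` excluded responses appear as rows with a
    NaN score, which is the layout the CLI writes (the exclusion reason
    travels in its own column either way).
    """
    responses = list(responses)
    if not responses:
        raise ValueError("empty corpus")
    columns = ["response_id", "source", "condition", "score", "adhered", "excluded_reason"]
    rows = []
    exclusions: list[tuple[str, str]] = []
    n_adhered = 0
    for raw in responses:
        parsed = select_scoring_words(parse_response(raw), table)
        if parsed.adhered:
            n_adhered += 1
            result = dat_score(parsed.scoring_words, table)
            rows.append(
                dict(
                    response_id=raw.response_id,
                    source=raw.source,
                    condition=raw.condition,
                    score=result.score,
                    adhered=True,
                    excluded_reason="",
                )
            )
        else:
            exclusions.append((raw.response_id, parsed.excluded_reason or "unknown"))
            if include_excluded:
                rows.append(
                    dict(
                        response_id=raw.response_id,
                        source=raw.source,
                        condition=raw.condition,
                        score=np.nan,
                        adhered=False,
                        excluded_reason=parsed.excluded_reason or "unknown",
                    )
                )
    if n_adhered == 0:
        warnings.warn("all responses were excluded; score table is empty", stacklevel=2)
    table_df = pd.DataFrame(rows, columns=columns)
    return table_df, exclusions


def adherence_ratio(corpus) -> float:
    """Proportion of responses satisfying the task's structural rules.

    Accepts either a list of :class:`ParsedResponse` (from
    :func:`parse_corpus`) or a score table that kept its excluded rows.
    """
    if isinstance(corpus, pd.DataFrame):
        if corpus.empty:
            raise ValueError("empty corpus")
        return float(corpus["adhered"].mean())
    items = list(corpus)
    if not items:
        raise ValueError("empty corpus")
    return sum(bool(p.adhered) for p in items) / len(items)


def word_set_frequencies(responses: Iterable[ParsedResponse]) -> pd.DataFrame:
    """Percentage of response sets containing each word at least once.

    Sorted by descending percentage, ties broken alphabetically.
    """
    parsed = list(responses)
    if not parsed:
        return pd.DataFrame(columns=["word", "percent"])
    counts: Counter[str] = Counter()
    for p in parsed:
        counts.update(set(p.words))
    n = len(parsed)
    df = pd.DataFrame(
        {"word": list(counts.keys()), "percent": [100.0 * c / n for c in counts.values()]}
    )
    df = df.sort_values(
        ["percent", "word"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df
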