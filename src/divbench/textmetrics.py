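"""Creative-writing metrics: DSI, Lempel-Ziv complexity, structure checks.

Divergent Semantic Integration (DSI) extends semantic-distance scoring
from word lists to narratives: stopwords and punctuation are stripped,
each remaining token is embedded with a context-dependent vector (mean of
two hidden layers by default), and the score is the mean cosine distance
over token pairs -- all unordered pairs by default, adjacent pairs in
``successive`` mode.  Higher values mean the text integrates more
semantically remote ideas.

Lempel-Ziv (LZ76) complexity counts the phrases of an exhaustive
left-to-right parse of the character stream; a text full of repeated
substrings parses into few phrases, so the length-normalized count is a
redundancy-free proxy for lexical diversity that needs no embeddings.

Structure checks enforce the low-level form constraints of the writing
tasks: the 5-7-5 syllable pattern for haiku, and strict word caps of 50
for movie synopses and 200 for flash fiction.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from .embeddings import ContextualBackend, contextual_embed, cosine_similarity

__all__ = [
    "TASKS",
    "DEFAULT_STOPWORDS",
    "DEFAULT_WORD_LIMITS",
    "HAIKU_PATTERN",
    "TextSample",
    "DSIResult",
    "LZResult",
    "StructureReport",
    "preprocess_tokens",
    "dsi_score",
    "canonicalize_text",
    "lz_complexity",
    "count_syllables",
    "check_structure",
    "match_length_distributions",
    "concept_similarity",
]

TASKS = ("haiku", "synopsis", "flash_fiction")
DEFAULT_STOPWORDS = frozenset(ENGLISH_STOP_WORDS)
DEFAULT_WORD_LIMITS = {"synopsis": 50, "flash_fiction": 200}
HAIKU_PATTERN = (5, 7, 5)


@dataclass
class TextSample:
    """One creative-writing text with its task type and group label."""

    text_id: str
    source: str
    task: str
    body: str
    condition: str | None = None

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if not self.body:
            raise ValueError("body must be non-empty")


@dataclass
class DSIResult:
    value: float
    n_tokens: int
    n_pairs: int
    mode: str


@dataclass
class LZResult:
    n_phrases: int
    length: int
    normalized: float
    normalization: str


@dataclass
class StructureReport:
    compliant: bool
    per_line_syllables: list[int]
    word_count: int
    limit: int
    violations: list[str]


def preprocess_tokens(body: str, stopwords: Iterable[str] | None = None) -> list[str]:
    """Lowercased alphabetic tokens with punctuation and stopwords removed.

    Order is preserved; a body of only stopwords yields an empty list and
    downstream code decides what that means.
    """
    if not body:
        raise ValueError("body must be non-empty")
    stop = DEFAULT_STOPWORDS if stopwords is None else set(stopwords)
    return [t for t in re.findall(r"[a-z]+", body.lower()) if t not in stop]


def dsi_score(
    sample: TextSample,
    backend: ContextualBackend,
    mode: str = "all_pairs",
    stopwords: Iterable[str] | None = None,
    layer_indices: Sequence[int] = (6, 7),
) -> DSIResult:
    """Divergent Semantic Integration of one text.

    value = mean over the selected token pairs of (1 - cosine similarity)
    on combined-layer contextual token embeddings.  ``all_pairs`` (default)
    uses every unordered token pair across the text; ``successive`` uses
    adjacent pairs only.
    """
    if mode not in ("all_pairs", "successive"):
        raise ValueError(f"unknown mode {mode!r}")
    tokens = preprocess_tokens(sample.body, stopwords)
    if len(tokens) < 2:
        raise ValueError("DSI undefined for fewer than 2 retained tokens")
    embs = contextual_embed(
        sample.body,
        backend,
        layer_indices=layer_indices,
        tokens=tokens,
        text_id=sample.text_id,
    )
    mat = np.vstack([e.vector for e in embs])
    norms = np.linalg.norm(mat, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("zero-norm token vector")
    unit = mat / norms[:, None]
    if mode == "all_pairs":
        gram = unit @ unit.T
        iu = np.triu_indices(len(tokens), k=1)
        dists = 1.0 - gram[iu]
    else:
        dists = 1.0 - np.sum(unit[:-1] * unit[1:], axis=1)
    return DSIResult(
        value=float(np.mean(dists)),
        n_tokens=len(tokens),
        n_pairs=int(dists.size),
        mode=mode,
    )


def canonicalize_text(body: str) -> str:
    """Lowercase and collapse whitespace runs to single spaces."""
    return re.sub(r"\s+", " ", body.lower()).strip()


def _lz76_phrase_count(s: str) -> int:
    # Exhaustive left-to-right LZ76 parse: each phrase is the shortest
    # prefix of the remainder that does not occur inside the preceding
    # history (overlap into the current phrase is allowed, as in the
    # original production-style parse).
    n = len(s)
    i = 0
    count = 0
    while i < n:
        length = 1
        while i + length <= n and s[i : i + length] in s[: i + length - 1]:
            length += 1
        count += 1
        i += length
    return count


def lz_complexity(body: str, normalization: str = "per_char") -> LZResult:
    """Normalized LZ76 phrase count of the canonicalized character stream.

    ``per_char`` (default) divides the phrase count by the text length;
    ``classic`` applies the n x log2(L) / L normalization used when
    comparing against the asymptotic phrase count of random sequences
    (defined as 1.0 at L=1, where the logarithm degenerates).
    """
    if normalization not in ("per_char", "classic"):
        raise ValueError(f"unknown normalization {normalization!r}")
    s = canonicalize_text(body)
    if not s:
        raise ValueError("text is empty after canonicalization")
    n_phrases = _lz76_phrase_count(s)
    length = len(s)
    if normalization == "per_char":
        normalized = n_phrases / length
    else:
        normalized = n_phrases * math.log2(length) / length if length > 1 else 1.0
    return LZResult(
        n_phrases=n_phrases,
        length=length,
        normalized=float(normalized),
        normalization=normalization,
    )


def count_syllables(word: str) -> int:
    """Rule-based syllable count: contiguous vowel groups (a,e,i,o,u,y),
    with a final silent 'e' dropped unless it is the only group; minimum 1.
    """
    if not word or not word.isalpha():
        raise ValueError(f"alphabetic word required, got {word!r}")
    w = word.lower()
    groups = re.findall(r"[aeiouy]+", w)
    n = len(groups)
    if n > 1 and w.endswith("e") and groups[-1] == "e":
        n -= 1
    return max(n, 1)


def check_structure(
    sample: TextSample,
    limits: Mapping[str, int] | None = None,
    syllable_tolerance: int = 0,
    syllable_counter: Callable[[str], int] = count_syllables,
) -> StructureReport:
    """Validate the low-level form of a creative-writing sample.

    Haiku: three non-empty lines whose syllable counts match 5-7-5 within
    ``syllable_tolerance`` per line (strict by default).  Synopsis / flash
    fiction: word count at most the task cap (50 / 200).  Trailing
    whitespace and punctuation never affect the verdict.
    """
    caps = dict(DEFAULT_WORD_LIMITS)
    if limits:
        caps.update(limits)
    violations: list[str] = []
    word_count = len(re.findall(r"\S+", sample.body))

    if sample.task == "haiku":
        lines = [ln.strip() for ln in sample.body.splitlines() if ln.strip()]
        per_line = [
            sum(syllable_counter(tok) for tok in re.findall(r"[a-zA-Z]+", ln))
            for ln in lines
        ]
        if len(lines) != 3:
            violations.append(f"haiku must have 3 non-empty lines, found {len(lines)}")
        else:
            for idx, (got, want) in enumerate(zip(per_line, HAIKU_PATTERN), start=1):
                if abs(got - want) > syllable_tolerance:
                    violations.append(
                        f"line {idx}: {got} syllables, expected {want}"
                    )
        return StructureReport(
            compliant=not violations,
            per_line_syllables=per_line,
            word_count=word_count,
            limit=sum(HAIKU_PATTERN),
            violations=violations,
        )

    cap = caps[sample.task]
    if word_count > cap:
        violations.append(f"word limit {cap} exceeded ({word_count} words)")
    return StructureReport(
        compliant=not violations,
        per_line_syllables=[],
        word_count=word_count,
        limit=cap,
        violations=violations,
    )


def _word_count(sample: TextSample) -> int:
    return len(re.findall(r"\S+", sample.body))


def match_length_distributions(
    corpora: Mapping[str, Sequence[TextSample]],
    tol_mean: float = 2.0,
    tol_sd: float = 2.0,
) -> dict[str, list[TextSample]]:
    """Greedy cross-group word-count matching by subsampling.

    Repeatedly drops the single sample whose removal most reduces the
    maximum cross-group difference in mean word count (ties broken on the
    SD gap, then on input order) until all pairwise mean gaps are at most
    ``tol_mean`` and SD gaps at most ``tol_sd``, or until some group would
    fall below 50% retention, in which case a warning is emitted and the
    best-effort result returned.  Deterministic given input order.
    """
    groups = list(corpora.keys())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    counts = {g: np.array([_word_count(s) for s in corpora[g]], dtype=float) for g in groups}
    keep = {g: list(range(len(corpora[g]))) for g in groups}
    floor = {g: math.ceil(len(corpora[g]) / 2) for g in groups}

    def spread(kept: Mapping[str, list[int]]) -> tuple[float, float]:
        means = [counts[g][kept[g]].mean() for g in groups]
        sds = [
            counts[g][kept[g]].std(ddof=1) if len(kept[g]) > 1 else 0.0 for g in groups
        ]
        dmean = max(
            abs(means[i] - means[j])
            for i in range(len(groups))
            for j in range(i + 1, len(groups))
        )
        dsd = max(
            abs(sds[i] - sds[j])
            for i in range(len(groups))
            for j in range(i + 1, len(groups))
        )
        return dmean, dsd

    while True:
        dmean, dsd = spread(keep)
        if dmean <= tol_mean and dsd <= tol_sd:
            break
        best_key = None
        best_move = None
        for g in groups:
            if len(keep[g]) <= floor[g]:
                continue
            for pos in range(len(keep[g])):
                trial = dict(keep)
                trial[g] = keep[g][:pos] + keep[g][pos + 1 :]
                key = spread(trial)
                if best_key is None or key < best_key:
                    best_key = key
                    best_move = (g, pos)
        if best_move is None:
            warnings.warn(
                "length matching hit the 50% retention floor before reaching "
                "tolerance; returning best-effort subsample",
                stacklevel=2,
            )
            break
        g, pos = best_move
        keep[g] = keep[g][:pos] + keep[g][pos + 1 :]

    return {g: [corpora[g][i] for i in keep[g]] for g in groups}


def concept_similarity(
    sample: TextSample,
    concept: str,
    backend: ContextualBackend,
    stopwords: Iterable[str] | None = None,
    layer_indices: Sequence[int] = (6, 7),
) -> float:
    """Mean cosine similarity between each retained token and a concept word.

    Used to quantify how closely a text orbits a theme (e.g. how much a
    haiku dwells on nature imagery).
    """
    tokens = preprocess_tokens(sample.body, stopwords)
    if not tokens:
        raise ValueError("no retained tokens in sample")
    token_embs = contextual_embed(
        sample.body,
        backend,
        layer_indices=layer_indices,
        tokens=tokens,
        text_id=sample.text_id,
    )
    try:
        concept_emb = contextual_embed(
            concept,
            backend,
            layer_indices=layer_indices,
            tokens=[concept.lower()],
            text_id=f"concept:{concept.lower()}",
        )[0]
    except KeyError as exc:
        raise ValueError(f"concept {concept!r} is out of vocabulary") from exc
    sims = [cosine_similarity(e.vector, concept_emb.vector) for e in token_embs]
    return float(np.mean(sims))
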