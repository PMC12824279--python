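"""Static and contextual word-embedding utilities.

Semantic-distance creativity metrics reduce to cosine geometry over word
vectors.  This module supplies the vector sources used everywhere else in
the package:

* a loader for plain-text word2vec/GloVe vector files (``word v1 ... vd``
  per line), which back the static Divergent Association Task scoring;
* cosine similarity and its distance complement;
* a deterministic hash-based mock embedder, so that every downstream
  metric is testable offline with no model download;
* a pluggable contextual-embedding backend contract.  Contextual token
  vectors (one vector per token, conditioned on the surrounding text) may
  come from a live transformer, from a JSONL cache of precomputed vectors,
  or from a context-free mock.  When several hidden layers are requested
  they are combined by an elementwise mean.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "EmbeddingTable",
    "TokenEmbedding",
    "VectorFormatError",
    "EmbedderConfigError",
    "load_static_table",
    "embed_word",
    "cosine_similarity",
    "semantic_distance",
    "make_hash_embedder",
    "ContextualBackend",
    "HashBackend",
    "StaticTableBackend",
    "CachedVectorBackend",
    "tokenize",
    "contextual_embed",
]


class VectorFormatError(ValueError):
    """A plain-text vector file violates the expected dialect."""


class EmbedderConfigError(RuntimeError):
    """A contextual embedding was requested without a usable backend."""


@dataclass
class EmbeddingTable:
    """Vocabulary -> vector map standing in for a static embedding corpus.

    All vectors share dimension ``dim``; keys are unique, lowercase and
    non-empty; no all-zero vectors survive loading.  ``cluster_of`` is
    populated by the synthetic generator and records which cluster each
    synthetic word was drawn around.
    """

    vocab: dict[str, np.ndarray]
    dim: int
    name: str = ""
    cluster_of: dict[str, int] | None = None

    def __len__(self) -> int:
        return len(self.vocab)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.vocab

    def get(self, word: str) -> np.ndarray | None:
        return self.vocab.get(word.lower())

    def matrix(self, words: Sequence[str]) -> np.ndarray:
        """Stack the vectors of ``words`` (row per word); KeyError on OOV."""
        missing = [w for w in words if w.lower() not in self.vocab]
        if missing:
            raise KeyError(f"words not in vocabulary: {missing}")
        return np.vstack([self.vocab[w.lower()] for w in words])


@dataclass
class TokenEmbedding:
    """One context-dependent token vector with its 0-based position."""

    token: str
    vector: np.ndarray
    position: int


_HEADER_RE = re.compile(r"^\s*\d+\s+\d+\s*$")


def load_static_table(
    path,
    expected_dim: int | None = None,
    name: str | None = None,
) -> EmbeddingTable:
    """Read a plain-text vector file into an :class:`EmbeddingTable`.

    The dialect is the word2vec/GloVe text format: one ``word v1 ... vd``
    per line, whitespace separated, UTF-8.  An optional word2vec-style
    header line ``N d`` is tolerated and skipped.  Words are lowercased;
    duplicates keep the first occurrence and emit a warning.
    """
    vocab: dict[str, np.ndarray] = {}
    dim: int | None = None
    try:
        fh = open(path, encoding="utf-8")
    except OSError as exc:
        raise VectorFormatError(f"cannot read vector file {path!r}: {exc}") from exc
    with fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 and _HEADER_RE.match(line):
                continue
            parts = line.split()
            if not parts:
                continue
            word, *vals = parts
            if not vals:
                warnings.warn(
                    f"{path}: line {lineno} has no vector components; skipped",
                    stacklevel=2,
                )
                continue
            try:
                vec = np.array([float(x) for x in vals], dtype=float)
            except ValueError as exc:
                raise VectorFormatError(
                    f"{path}: line {lineno}: non-numeric vector component"
                ) from exc
            if dim is None:
                dim = vec.size
            elif vec.size != dim:
                raise VectorFormatError(
                    f"{path}: line {lineno}: expected {dim} dimensions, got {vec.size}"
                )
            if not np.any(vec):
                raise VectorFormatError(f"{path}: line {lineno}: all-zero vector")
            key = word.lower()
            if key in vocab:
                warnings.warn(
                    f"{path}: duplicate word {key!r} at line {lineno}; keeping first",
                    stacklevel=2,
                )
                continue
            vocab[key] = vec
    if not vocab or dim is None:
        raise VectorFormatError(f"{path}: no vectors found")
    if expected_dim is not None and dim != expected_dim:
        raise VectorFormatError(
            f"{path}: dimension {dim} does not match expected {expected_dim}"
        )
    return EmbeddingTable(vocab=vocab, dim=int(dim), name=name or str(path))


def embed_word(table: EmbeddingTable, word: str) -> tuple[np.ndarray | None, bool]:
    """Case-insensitive lookup; ``(vector, True)`` iff the word is known.

    Validity is operationalized as vocabulary membership: a word the
    embedding corpus does not know cannot contribute to a semantic-distance
    score.  The lookup is exact after lowercasing -- callers must strip
    punctuation first.
    """
    if not word:
        raise ValueError("word must be non-empty")
    vec = table.get(word)
    return vec, vec is not None


def cosine_similarity(u, v) -> float:
    """Standard cosine similarity; errors on zero-norm or mismatched input."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vectors")
    return float(np.dot(u, v) / (nu * nv))


def semantic_distance(u, v) -> float:
    """1 - cosine similarity: the scale underlying both DAT and DSI."""
    return 1.0 - cosine_similarity(u, v)


def make_hash_embedder(dim: int, seed: int):
    """Deterministic word -> unit-vector function for offline testing.

    Each word's vector is drawn from a Gaussian seeded by a keyed BLAKE2b
    digest of the word, then normalized, so the same ``(word, dim, seed)``
    triple yields bit-identical vectors across processes, and distinct
    words are approximately uncorrelated in high dimension.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    key = (int(seed) & 0xFFFFFFFFFFFFFFFF).to_bytes(8, "little")
    cache: dict[str, np.ndarray] = {}

    def embed(word: str) -> np.ndarray:
        cached = cache.get(word)
        if cached is not None:
            return cached
        digest = hashlib.blake2b(word.encode("utf-8"), digest_size=16, key=key).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "little"))
        vec = rng.standard_normal(dim)
        vec /= np.linalg.norm(vec)
        cache[word] = vec
        return vec

    return embed


class ContextualBackend:
    """Contract for context-dependent token vectors.

    Implementations return, for a token sequence, one ``(n_tokens, dim)``
    array per requested hidden layer.  A live transformer, a cache of
    precomputed vectors, and a context-free mock all satisfy the same
    contract, so the metric code never depends on a model download.
    """

    def layer_vectors(
        self,
        tokens: Sequence[str],
        layers: Sequence[int],
        text_id: str | None = None,
    ) -> Mapping[int, np.ndarray]:
        raise NotImplementedError


class HashBackend(ContextualBackend):
    """Context-free mock backend: every layer returns the hash vector."""

    def __init__(self, dim: int = 64, seed: int = 0):
        self.dim = dim
        self._embed = make_hash_embedder(dim, seed)

    def layer_vectors(self, tokens, layers, text_id=None):
        if tokens:
            mat = np.vstack([self._embed(t) for t in tokens])
        else:
            mat = np.empty((0, self.dim))
        return {layer: mat for layer in layers}


class StaticTableBackend(ContextualBackend):
    """Context-free backend over a static table (layer = the type vector)."""

    def __init__(self, table: EmbeddingTable):
        self.table = table

    def layer_vectors(self, tokens, layers, text_id=None):
        mat = self.table.matrix(list(tokens))
        return {layer: mat for layer in layers}


class CachedVectorBackend(ContextualBackend):
    """Precomputed per-token vectors loaded from JSONL.

    Each line is an object with fields ``text_id``, ``tokens`` (list) and
    ``vectors`` (row-major list of lists, one row per token).  This lets a
    corpus embedded once elsewhere be re-scored here with no model.
    """

    def __init__(self, path):
        self._store: dict[str, tuple[list[str], np.ndarray]] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise VectorFormatError(f"{path}: line {lineno}: bad JSON") from exc
                for fld in ("text_id", "tokens", "vectors"):
                    if fld not in obj:
                        raise VectorFormatError(
                            f"{path}: line {lineno}: missing field {fld!r}"
                        )
                toks = [str(t).lower() for t in obj["tokens"]]
                mat = np.asarray(obj["vectors"], dtype=float)
                if mat.ndim != 2 or mat.shape[0] != len(toks):
                    raise VectorFormatError(
                        f"{path}: line {lineno}: vectors shape does not match tokens"
                    )
                self._store[str(obj["text_id"])] = (toks, mat)

    def layer_vectors(self, tokens, layers, text_id=None):
        if text_id is None or text_id not in self._store:
            raise EmbedderConfigError(
                f"no cached vectors for text_id {text_id!r}"
            )
        cached_tokens, mat = self._store[text_id]
        if list(tokens) != cached_tokens:
            raise ValueError(
                f"token mismatch against cached vectors for text_id {text_id!r}"
            )
        return {layer: mat for layer in layers}


_TOKEN_RE = re.compile(r"[a-z]+")


def tokenize(text: str) -> list[str]:
    """Lowercase alphabetic tokens in order of appearance."""
    return _TOKEN_RE.findall(text.lower())


def contextual_embed(
    text: str,
    backend: ContextualBackend,
    layer_indices: Sequence[int] = (6, 7),
    combiner: str = "mean",
    tokens: Sequence[str] | None = None,
    text_id: str | None = None,
) -> list[TokenEmbedding]:
    """Embed each retained token of ``text``, combining hidden layers.

    When several layers are requested their per-token vectors are combined
    elementwise by the ``mean`` combiner (the only one defined).  Callers
    that have already tokenized (e.g. after stopword removal) may pass
    ``tokens`` to bypass the default alphabetic tokenizer.
    """
    if tokens is None:
        if not text:
            raise ValueError("text must be non-empty")
        tokens = tokenize(text)
    if backend is None:
        raise EmbedderConfigError(
            "no contextual embedder backend configured and no precomputed vectors"
        )
    if combiner != "mean":
        raise ValueError(f"unsupported combiner: {combiner!r}")
    layer_indices = tuple(layer_indices)
    if not layer_indices:
        raise ValueError("at least one layer index is required")
    tokens = list(tokens)
    if not tokens:
        return []
    layered = backend.layer_vectors(tokens, layer_indices, text_id=text_id)
    stacked = np.stack(
        [np.asarray(layered[layer], dtype=float) for layer in layer_indices]
    )
    combined = stacked.mean(axis=0)
    return [
        TokenEmbedding(token=tok, vector=combined[i], position=i)
        for i, tok in enumerate(tokens)
    ]
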