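"""Synthetic embedding spaces, word-list responses and text corpora.

Live model APIs and the deposited human corpus are out of reach for an
offline test suite, so this module generates data whose statistical
structure is known by construction:

* a clustered unit-vector vocabulary (near-orthogonal cluster centers
  with angular noise), standing in for a static embedding corpus;
* 10-word responses whose semantic diversity is governed by a
  cluster-level knob theta (probability that each successive word comes
  from a not-yet-used cluster) -- the synthetic analogue of sampling
  temperature -- with an invalid-word rate rho injecting out-of-vocabulary
  tokens (misspellings / non-compliance);
* control responses drawn uniformly with no diversity pressure;
* short texts (haiku / synopsis / flash fiction) with controllable
  redundancy r (probability of repeating an earlier sentence) and topic
  spread tied to theta.

Everything is bit-reproducible given the same spec, and the module also
carries the brute-force oracles (naive pairwise-distance mean, naive LZ76
parse) used to cross-check the fast implementations.
"""

from __future__ import annotations

import math
import string
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import yaml

from .dat import RawResponse
from .embeddings import EmbeddingTable
from .textmetrics import TextSample

__all__ = [
    "SyntheticSpec",
    "make_cluster_space",
    "gen_word_responses",
    "gen_control_responses",
    "gen_text_corpus",
    "oracle_mean_pairwise_distance",
    "oracle_lz76",
]


@dataclass
class SyntheticSpec:
    """Generator parameters: cluster geometry plus behavioral knobs.

    Defaults describe a moderately clustered vocabulary (8 near-orthogonal
    topics in 64 dimensions, 50 words per topic, mild angular noise) with
    a mostly-divergent responder (theta=0.7), a small invalid-word rate
    mirroring occasional misspellings, and lightly redundant texts.
    """

    n_clusters: int = 8
    dim: int = 64
    sigma: float = 0.15
    vocab_size: int = 400
    diversity: float = 0.7
    invalid_rate: float = 0.02
    redundancy: float = 0.1
    seed: int = 0
    multiword_rate: float = 0.01

    def __post_init__(self):
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.vocab_size < self.n_clusters:
            raise ValueError("vocab_size must be >= n_clusters")
        for fld in ("diversity", "invalid_rate", "redundancy", "multiword_rate"):
            val = getattr(self, fld)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{fld} must lie in [0, 1], got {val}")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


_LETTERS = string.ascii_lowercase


def _word_name(index: int) -> str:
    # Letter-encoded identifiers ("w" + base-26 suffix) keep the synthetic
    # vocabulary purely alphabetic, so the words survive the downstream
    # punctuation-and-digits stripping applied to real text.
    chars = []
    value = index
    for _ in range(4):
        chars.append(_LETTERS[value % 26])
        value //= 26
    return "w" + "".join(reversed(chars))


def _oov_token(rng: np.random.Generator) -> str:
    # 'zq' prefix guarantees no collision with vocabulary words ('w...').
    return "zq" + "".join(_LETTERS[int(i)] for i in rng.integers(0, 26, size=6))


def make_cluster_space(spec: SyntheticSpec, centers=None) -> EmbeddingTable:
    """Build a clustered synthetic vocabulary as an :class:`EmbeddingTable`.

    Cluster centers are mutually orthogonal when n_clusters <= dim
    (columns of a QR factor of a seeded Gaussian matrix), otherwise random
    unit vectors with a warning when sigma=0 makes overlap unavoidable.
    Words are assigned to clusters round-robin; each word vector is its
    center perturbed by isotropic Gaussian noise of scale sigma, then
    re-normalized.  ``centers`` may be passed explicitly (rows) to pin a
    specific geometry, e.g. antipodal pairs.
    """
    rng = np.random.default_rng([spec.seed, 11])
    k, dim = spec.n_clusters, spec.dim
    if centers is None:
        if k <= dim:
            gauss = rng.standard_normal((dim, k))
            q, _ = np.linalg.qr(gauss)
            centers = q.T[:k]
        else:
            if spec.sigma == 0:
                warnings.warn(
                    "more clusters than dimensions: centers cannot be orthogonal",
                    stacklevel=2,
                )
            centers = rng.standard_normal((k, dim))
            centers /= np.linalg.norm(centers, axis=1)[:, None]
    else:
        centers = np.asarray(centers, dtype=float)
        if centers.shape != (k, dim):
            raise ValueError(f"centers must have shape ({k}, {dim})")
        centers = centers / np.linalg.norm(centers, axis=1)[:, None]

    vocab: dict[str, np.ndarray] = {}
    cluster_of: dict[str, int] = {}
    for i in range(spec.vocab_size):
        word = _word_name(i)
        cl = i % k
        vec = centers[cl].copy()
        if spec.sigma > 0:
            # scale by 1/sqrt(dim) so sigma is the expected perturbation
            # magnitude (hence the angular spread) independent of dimension
            vec = vec + spec.sigma * rng.standard_normal(dim) / math.sqrt(dim)
        vec = vec / np.linalg.norm(vec)
        vocab[word] = vec
        cluster_of[word] = cl
    return EmbeddingTable(
        vocab=vocab,
        dim=dim,
        name=f"synthetic-K{k}-d{dim}",
        cluster_of=cluster_of,
    )


def _words_by_cluster(space: EmbeddingTable) -> dict[int, list[str]]:
    if space.cluster_of is None:
        raise ValueError("embedding table lacks cluster assignments")
    out: dict[int, list[str]] = {}
    for word, cl in space.cluster_of.items():
        out.setdefault(cl, []).append(word)
    return {cl: sorted(words) for cl, words in sorted(out.items())}


def _render_list(entries: Sequence[str], style: str, preamble: bool) -> str:
    lines = ["Here is my list:"] if preamble else []
    for idx, entry in enumerate(entries, start=1):
        lines.append(f"{idx}. {entry}" if style == "numbered" else f"- {entry}")
    return "\n".join(lines)


def _corrupt(word: str, rng: np.random.Generator, spec: SyntheticSpec, vocab: list[str]) -> str:
    if rng.random() < spec.invalid_rate:
        return _oov_token(rng)
    if rng.random() < spec.multiword_rate:
        extra = vocab[int(rng.integers(len(vocab)))]
        return f"{word} {extra}"
    return word


def gen_word_responses(
    space: EmbeddingTable,
    spec: SyntheticSpec,
    n: int,
    condition: str = "dat",
) -> list[RawResponse]:
    """Generate ``n`` 10-word responses under diversity pressure theta.

    The first word comes from a random cluster; each later word switches
    to a not-yet-used cluster with probability ``spec.diversity`` and
    reuses an already-visited cluster otherwise.  Words never repeat
    within a response; with probability ``spec.invalid_rate`` a word is
    replaced by an out-of-vocabulary token, and a small fixed rate of
    multiword entries exercises the parser.  Responses alternate between
    numbered and bulleted renderings, some with preamble chatter.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    by_cluster = _words_by_cluster(space)
    cluster_ids = sorted(by_cluster)
    vocab = sorted(space.vocab)
    out: list[RawResponse] = []
    for i in range(n):
        rng = np.random.default_rng([spec.seed, 101, i])
        used_clusters: list[int] = []
        used_words: set[str] = set()
        entries: list[str] = []
        for j in range(10):
            fresh = [c for c in cluster_ids if c not in used_clusters]
            if j == 0:
                cluster = cluster_ids[int(rng.integers(len(cluster_ids)))]
            elif fresh and rng.random() < spec.diversity:
                cluster = fresh[int(rng.integers(len(fresh)))]
            else:
                cluster = used_clusters[int(rng.integers(len(used_clusters)))]
            if cluster not in used_clusters:
                used_clusters.append(cluster)
            candidates = [w for w in by_cluster[cluster] if w not in used_words]
            if not candidates:
                candidates = [w for w in vocab if w not in used_words]
            word = candidates[int(rng.integers(len(candidates)))]
            used_words.add(word)
            entries.append(_corrupt(word, rng, spec, vocab))
        text = _render_list(
            entries,
            style="numbered" if i % 2 == 0 else "bulleted",
            preamble=(i % 7 == 3),
        )
        out.append(
            RawResponse(
                response_id=f"{condition.replace(':', '-')}-{i:05d}",
                source="synthetic",
                condition=condition,
                text=text,
            )
        )
    return out


def gen_control_responses(
    space: EmbeddingTable, spec: SyntheticSpec, n: int
) -> list[RawResponse]:
    """Control condition: 10 words drawn uniformly, no diversity pressure."""
    if n <= 0:
        raise ValueError("n must be positive")
    vocab = sorted(space.vocab)
    out: list[RawResponse] = []
    for i in range(n):
        rng = np.random.default_rng([spec.seed, 202, i])
        idx = rng.choice(len(vocab), size=10, replace=False)
        entries = [_corrupt(vocab[int(k)], rng, spec, vocab) for k in idx]
        text = _render_list(
            entries,
            style="numbered" if i % 2 == 0 else "bulleted",
            preamble=(i % 7 == 3),
        )
        out.append(
            RawResponse(
                response_id=f"control-{i:05d}",
                source="synthetic",
                condition="control",
                text=text,
            )
        )
    return out


_TASK_CODE = {"haiku": 1, "synopsis": 2, "flash_fiction": 3}
# Word budgets stop sentence accretion safely below the task caps
# (a final sentence of at most 9 words can never breach 50 / 200).
_WORD_BUDGET = {"synopsis": 41, "flash_fiction": 185}


def gen_text_corpus(
    space: EmbeddingTable, spec: SyntheticSpec, task: str, n: int
) -> list[TextSample]:
    """Generate ``n`` synthetic texts of the given task form.

    Sentences are runs of words sampled from a topic cluster; a new topic
    is opened with probability ``spec.diversity``, otherwise an earlier
    topic is reused.  With probability ``spec.redundancy`` a sentence is a
    verbatim repeat of an earlier one, lowering LZ complexity.  Haiku are
    three 3-word lines; synopses and flash fiction respect the 50- and
    200-word caps by construction.
    """
    if task not in _TASK_CODE:
        raise ValueError(f"unknown task {task!r}")
    if n <= 0:
        raise ValueError("n must be positive")
    by_cluster = _words_by_cluster(space)
    cluster_ids = sorted(by_cluster)
    out: list[TextSample] = []
    for i in range(n):
        rng = np.random.default_rng([spec.seed, 303, _TASK_CODE[task], i])
        used_clusters: list[int] = []
        sentences: list[str] = []

        def new_sentence(length: int) -> str:
            fresh = [c for c in cluster_ids if c not in used_clusters]
            if not used_clusters or (fresh and rng.random() < spec.diversity):
                pool = fresh if fresh else cluster_ids
                cluster = pool[int(rng.integers(len(pool)))]
            else:
                cluster = used_clusters[int(rng.integers(len(used_clusters)))]
            if cluster not in used_clusters:
                used_clusters.append(cluster)
            words = by_cluster[cluster]
            return " ".join(
                words[int(rng.integers(len(words)))] for _ in range(length)
            )

        if task == "haiku":
            for _ in range(3):
                if sentences and rng.random() < spec.redundancy:
                    sentences.append(sentences[int(rng.integers(len(sentences)))])
                else:
                    sentences.append(new_sentence(3))
            body = "\n".join(sentences)
        else:
            budget = _WORD_BUDGET[task]
            total = 0
            while total < budget:
                if sentences and rng.random() < spec.redundancy:
                    sent = sentences[int(rng.integers(len(sentences)))]
                else:
                    sent = new_sentence(int(rng.integers(6, 10)))
                sentences.append(sent)
                total += len(sent.split())
            body = ". ".join(sentences) + "."
        out.append(
            TextSample(
                text_id=f"{task}-{i:04d}",
                source="synthetic",
                task=task,
                body=body,
            )
        )
    return out


def oracle_mean_pairwise_distance(words: Sequence[str], table: EmbeddingTable) -> float:
    """Brute-force mean pairwise cosine distance (independent oracle).

    An explicit double loop over unordered pairs with hand-written dot
    products; deliberately shares no code with the fast scorers.
    """
    vectors: list[list[float]] = []
    for word in words:
        vec = table.get(word)
        if vec is None:
            raise KeyError(f"word {word!r} not in table")
        vectors.append([float(x) for x in vec])
    total = 0.0
    n_pairs = 0
    for i in range(len(vectors)):
        for j in range(i + 1, len(vectors)):
            dot = 0.0
            norm_i = 0.0
            norm_j = 0.0
            for x, y in zip(vectors[i], vectors[j]):
                dot += x * y
                norm_i += x * x
                norm_j += y * y
            total += 1.0 - dot / math.sqrt(norm_i * norm_j)
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("need at least 2 words")
    return total / n_pairs


def oracle_lz76(s: str) -> int:
    """Naive quadratic exhaustive-history LZ76 phrase count (oracle).

    Character-by-character substring search, no use of Python's fast
    ``in`` operator, so it checks the production parser independently.
    """
    if not s:
        raise ValueError("empty string")
    n = len(s)
    i = 0
    count = 0
    while i < n:
        length = 1
        while i + length <= n:
            found = False
            for start in range(i):
                match = True
                for k in range(length):
                    if s[start + k] != s[i + k]:
                        match = False
                        break
                if match:
                    found = True
                    break
            if not found:
                break
            length += 1
        count += 1
        i += length
    return count
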