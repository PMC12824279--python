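# Methods

## The metrics

**Word-list scoring (DAT).** A response to the divergent-association task
lists 10 words that should be as mutually unrelated as possible. After
parsing, a word is *valid* when it is a single non-duplicate token present
in the static embedding vocabulary (vocabulary membership operationalizes
"properly spelled"; no separate dictionary is consulted). The score is

    score = 100 · mean over all C(7,2) = 21 unordered pairs of (1 − cos(v_i, v_j))

computed over the **first 7 valid words** in listed order, so occasional
misspellings still yield a score. The scale runs from 0 (all seven words
share one vector) to 200 (every pair antipodal); random unit vectors in
high dimension concentrate near 100. A response *adheres* when it lists at
least 10 entries **and** yields 7 valid words; both conditions are tracked
separately because both exclusion rules apply. Repeated words are invalid
after their first occurrence (the task demands words "different from each
other"); multiword entries are retained as tokens but never score. The
"only nouns" instruction is not enforced by the scorer — deliberately, as
no part-of-speech filter belongs to the scoring protocol.

**Divergent semantic integration (DSI).** For free text, the body is
lowercased, stripped of punctuation and stopwords (default list:
scikit-learn's English stopwords; the exact list used by any particular
study is rarely published, so it is a parameter), and each retained token
is embedded with a *contextual* vector: the elementwise mean of two hidden
layers (6 and 7 by default) of whatever backend is configured. DSI is the
mean of (1 − cosine) over token pairs. Two pair sets are defined:
`all_pairs` (default — every unordered token pair across the text,
matching the construct of integrating remote ideas anywhere in the
narrative) and `successive` (adjacent pairs only) behind a flag, because
the two readings coexist in the literature. Values are reported on the
distance scale so that higher = more divergent. Sentence segmentation is
not used to restrict the pair set in `all_pairs` mode.

The contextual backend is a contract, not a model: a transformer can
implement it, but the package ships (a) a keyed-hash mock that returns a
deterministic unit vector per token, (b) a static-table backend that
serves type vectors, and (c) a JSONL cache of precomputed per-token
vectors (`{text_id, tokens, vectors}` per line). The test suite therefore
runs fully offline; scoring a real corpus with a real BERT only requires
wrapping it in the same three-method contract.

**Lempel-Ziv complexity.** The text is canonicalized (lowercase,
whitespace runs collapsed to single spaces) and parsed by the exhaustive
left-to-right LZ76 procedure: each phrase is the shortest prefix of the
remainder not occurring in the preceding history (overlapping matches
allowed, as in the original production parse). The phrase count `c` is
normalized by text length L: `per_char` (default) reports c/L — the
literal "normalized by length" reading — and `classic` reports
c·log2(L)/L, the normalization against the asymptotic random-sequence
phrase count (defined as 1.0 at L=1 where the logarithm degenerates).
Repetitive text parses into few phrases, so lower values mean more
internal redundancy.

**Structure checks.** Haiku must have exactly three non-empty lines whose
syllable counts match 5-7-5; syllables are counted by a rule-based
heuristic (contiguous vowel groups over a-e-i-o-u-y, final silent "e"
dropped unless it is the only group, minimum 1). The counter is a plain
callable parameter, so a hyphenation dictionary can be dropped in where
available; a per-line ±k tolerance mode exists but the default is strict.
The heuristic is wrong on words like "quiet" (one vowel group, two spoken
syllables) — an accepted limitation of dictionary-free counting.
Synopses are capped at 50 words, flash fiction at 200; trailing
whitespace and punctuation never affect a verdict.

**Length matching.** Cross-group word-count matching greedily removes the
single sample whose removal most reduces the maximum cross-group mean gap
(ties: SD gap, then input order) until mean and SD gaps are within
tolerance, stopping at a 50% retention floor with a warning. Deterministic
given input order.

## Group statistics

Contrasts use Welch's two-sided independent-samples t-test (group
variances are visibly unequal across sources; a pooled-variance test would
be anti-conservative). When both groups are constant, p = 1 by convention
if the means agree. Benjamini–Hochberg FDR correction is applied across
the *whole* family of pairwise contrasts of one analysis. Effect sizes are
Cohen's d with pooled (n−1-weighted) SD. Confidence intervals on group
means are t-based (the cheap, standard choice; a bootstrap would also be
defensible). Contrast families are ordered by descending group mean —
ordering by "correlation with the best model" is not operationally defined
and was replaced. Percentile ranks count reference values strictly below
the score. PCA of document embeddings mean-centers but does not scale
(embedding dimensions share units) and fits one model per writing task.

## The synthetic generator

Live model APIs and the deposited human corpus are out of scope, so the
generator produces data whose structure is known by construction. It is
**not** a language model: it emulates exactly the statistical features the
pipeline measures, nothing else.

* **Embedding space** — `vocab_size` words (letter-encoded names,
  purely alphabetic so they survive token filtering) around `n_clusters`
  unit centers, mutually orthogonal when K ≤ dim (QR of a seeded Gaussian
  matrix). Each word is its center plus Gaussian noise of expected
  magnitude `sigma` (scaled by 1/√dim so sigma is an angular spread
  independent of dimension), re-normalized.
* **Responses** — 10 words; the first from a random cluster, each later
  word from a *not-yet-used* cluster with probability θ (`diversity`),
  otherwise from an already-used one. Diversity is modeled at the cluster
  level because the score rewards between-cluster distance; a word-level
  temperature analogue would conflate vocabulary size with diversity. θ
  plays the role sampling temperature plays for a real model: θ=0 pins a
  response to one topic (score ≈ 0 in a noiseless space), θ=1 with K ≥ 10
  orthogonal clusters scores ≈ 100. With probability ρ (`invalid_rate`) a
  word is replaced by an out-of-vocabulary token (misspellings /
  non-compliance); a fixed small `multiword_rate` (0.01) injects
  two-word entries to exercise the parser. Responses alternate numbered
  and bulleted renderings, some with preamble chatter.
* **Control responses** — 10 uniform draws without replacement, no
  diversity pressure, mirroring the "make a list of 10 words" condition.
* **Texts** — sentences are word runs from a topic cluster (new topic
  with probability θ); with probability r (`redundancy`) a sentence is a
  verbatim repeat of an earlier one, lowering LZ complexity. Haiku are
  three 3-word lines; synopses and flash fiction respect the 50/200-word
  caps by construction via word budgets (41/185) that no final sentence
  of ≤ 9 words can breach.

Defaults — K=8, dim=64, sigma=0.15, vocab 400, θ=0.7, ρ=0.02, r=0.1,
seed 0 — describe a moderately clustered vocabulary and a mostly divergent
responder with realistic occasional non-compliance. Every generator is
bit-reproducible given the spec: per-item RNGs are seeded with
`[seed, stream, item index]`.

**What passing tests do and do not show.** The generator emulates cluster
structure, diversity pressure, non-compliance, redundancy and topic
spread; it does not emulate syntax, meaning, polysemy, real
misspelling patterns, or the 5-7-5 syllable compliance of real haiku (its
synthetic haiku satisfy line structure, not syllable counts). Green tests
therefore certify the *measurement pipeline* — parsing, validity rules,
score arithmetic, statistics, determinism — under controlled conditions,
not claims about any particular model's or population's creativity.

## Numerical and design notes

* Cosine similarity errors on zero-norm vectors; loaded tables reject
  all-zero rows at parse time with the offending line number.
* Oracle cross-checks are genuinely independent: the pairwise-distance
  oracle is a hand-written double loop (no numpy, no shared code), the
  LZ oracle a character-by-character quadratic search avoiding Python's
  `in`. Fast paths match them to 1e−10 (distances) and exactly (LZ).
* Scoring uses the raw (un-normalized) stored vectors, normalizing
  on the fly, so cosine invariance under global rotation holds to 1e−8.
* At the default θ=0.7 with K=8 the generated DAT-vs-control gap is
  positive but small: seven uniform draws over eight clusters already
  land in mostly distinct clusters. The contrast is sharp at θ→1 or
  larger K, which is where the task-vs-control comparison is exercised.
* Test problem sizes (e.g. 100 recovery replicates of 300 responses per
  diversity level, 500 null simulations for the FDR false-positive check,
  10,000 bounded-score draws) are the package's chosen verification
  scale; the full suite runs in well under a minute.
* Greedy length matching can remove a sample even when no removal
  improves the objective (it still picks the least-bad one); the
  retention floor guarantees termination.

## Known limitations

* Validity is vocabulary membership: a larger human-study dictionary, if
  one was used originally, would accept words this scorer rejects.
* Exact replication of published human DAT values is pinned to a specific
  (unnamed) static-vector corpus; with a different corpus scores are
  comparable within, not across, studies.
* The syllable heuristic is approximate; the haiku verdict inherits that.
* DSI with the hash mock measures token diversity, not meaning; use a
  cached-vector file from a real contextual model for substantive corpora.
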