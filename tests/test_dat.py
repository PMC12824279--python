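import numpy as np
import pandas as pd
import pytest

from divbench.dat import (
    RawResponse,
    adherence_ratio,
    dat_score,
    parse_corpus,
    parse_response,
    score_corpus,
    select_scoring_words,
    word_set_frequencies,
)
from divbench.embeddings import EmbeddingTable
from divbench.synthetic import (
    SyntheticSpec,
    gen_word_responses,
    make_cluster_space,
    oracle_mean_pairwise_distance,
)


def _raw(text, rid="r1", condition="dat"):
    return RawResponse(response_id=rid, source="test", condition=condition, text=text)


WORDS10 = ["apple", "river", "stone", "cloud", "piano", "ember", "fox", "lens", "moss", "kite"]


class TestParseResponse:
    def test_numbered_list(self):
        text = "\n".join(f"{i + 1}. {w}" for i, w in enumerate(WORDS10))
        parsed = parse_response(_raw(text))
        assert parsed.words == WORDS10
        assert all(parsed.valid_flags)

    def test_preamble_dropped_when_bullets_present(self):
        text = "Sure! Here is my list:\n" + "\n".join(f"- {w}" for w in WORDS10)
        parsed = parse_response(_raw(text))
        assert parsed.words == WORDS10

    def test_multiword_entry_kept_but_invalid(self):
        text = "1. apple\n2. ice cream\n3. river"
        parsed = parse_response(_raw(text))
        assert parsed.words == ["apple", "ice cream", "river"]
        assert parsed.valid_flags == [True, False, True]

    def test_duplicate_invalid_after_first(self):
        parsed = parse_response(_raw("1. apple\n2. apple\n3. river"))
        assert parsed.valid_flags == [True, False, True]

    def test_comma_separated_single_line(self):
        parsed = parse_response(_raw(", ".join(WORDS10)))
        assert parsed.words == WORDS10

    def test_surrounding_punctuation_and_case_stripped(self):
        parsed = parse_response(_raw('1. "Apple!"\n2. (River)'))
        assert parsed.words == ["apple", "river"]

    def test_empty_text_is_unparseable_not_an_exception(self):
        parsed = parse_response(_raw(""))
        assert parsed.words == []
        assert parsed.excluded_reason == "unparseable"

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            _raw("x", condition="freeform")


class TestSelectScoringWords:
    def test_first_seven_valid_words_used(self, ortho_table):
        table, words = ortho_table
        vocab10 = words + ["extra1", "extra2", "extra3"]  # last 3 OOV
        text = "\n".join(f"{i + 1}. {w}" for i, w in enumerate(vocab10))
        parsed = select_scoring_words(parse_response(_raw(text)), table)
        assert parsed.scoring_words == words
        assert parsed.adhered

    def test_misspelling_is_skipped_not_fatal(self, ortho_table):
        table, words = ortho_table
        listed = words[:2] + ["xqzw"] + words[2:] + ["moss", "kite"]
        text = "\n".join(f"{i + 1}. {w}" for i, w in enumerate(listed))
        parsed = select_scoring_words(parse_response(_raw(text)), table)
        assert parsed.scoring_words == words
        assert parsed.adhered

    def test_too_few_valid_words_excluded(self, ortho_table):
        table, words = ortho_table
        listed = words[:6] + ["oov1", "oov2", "oov3", "oov4"]
        text = "\n".join(f"{i + 1}. {w}" for i, w in enumerate(listed))
        parsed = select_scoring_words(parse_response(_raw(text)), table)
        assert not parsed.adhered
        assert parsed.excluded_reason == "too_few_valid"

    def test_fewer_than_ten_entries_excluded(self, ortho_table):
        table, words = ortho_table
        text = "\n".join(f"{i + 1}. {w}" for i, w in enumerate(words))  # only 7
        parsed = select_scoring_words(parse_response(_raw(text)), table)
        assert not parsed.adhered
        assert parsed.excluded_reason == "too_few_words"


class TestDatScore:
    def test_identical_vectors_score_zero(self):
        v = np.array([0.6, 0.8])
        vocab = {f"w{i}": v.copy() for i in range(7)}
        table = EmbeddingTable(vocab=vocab, dim=2)
        assert dat_score(list(vocab), table).score == pytest.approx(0.0, abs=1e-12)

    def test_orthonormal_vectors_score_100(self, ortho_table):
        table, words = ortho_table
        result = dat_score(words, table)
        assert result.score == pytest.approx(100.0, abs=1e-12)
        assert result.n_pairs == 21

    def test_antipodal_pair_term_attains_200(self):
        v = np.array([1.0, 0.0])
        table = EmbeddingTable(vocab={"up": v, "down": -v}, dim=2)
        # single-pair distance term via the oracle: the 0-200 scale anchor
        assert 100 * oracle_mean_pairwise_distance(["up", "down"], table) == pytest.approx(200.0)

    def test_matches_bruteforce_oracle(self, random_table):
        rng = np.random.default_rng(11)
        vocab = list(random_table.vocab)
        for _ in range(200):
            words = [vocab[i] for i in rng.choice(len(vocab), 7, replace=False)]
            fast = dat_score(words, random_table).score
            slow = 100 * oracle_mean_pairwise_distance(words, random_table)
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_permutation_invariant(self, random_table):
        rng = np.random.default_rng(5)
        words = list(random_table.vocab)[:7]
        base = dat_score(words, random_table).score
        for _ in range(50):
            perm = [words[i] for i in rng.permutation(7)]
            assert dat_score(perm, random_table).score == pytest.approx(base, abs=1e-10)

    def test_global_rotation_leaves_scores_unchanged(self, random_table):
        rng = np.random.default_rng(17)
        q, _ = np.linalg.qr(rng.standard_normal((32, 32)))
        rotated = EmbeddingTable(
            vocab={w: q @ v for w, v in random_table.vocab.items()}, dim=32
        )
        words = sorted(random_table.vocab)[:7]
        assert dat_score(words, rotated).score == pytest.approx(
            dat_score(words, random_table).score, abs=1e-8
        )

    def test_scores_bounded_on_random_draws(self):
        rng = np.random.default_rng(23)
        vocab = {f"w{chr(97 + i // 26)}{chr(97 + i % 26)}": None for i in range(100)}
        mat = rng.standard_normal((100, 16))
        mat /= np.linalg.norm(mat, axis=1)[:, None]
        table = EmbeddingTable(
            vocab={w: mat[i] for i, w in enumerate(vocab)}, dim=16
        )
        words = list(table.vocab)
        for _ in range(10_000):
            picks = [words[i] for i in rng.choice(100, 7, replace=False)]
            s = dat_score(picks, table).score
            assert 0.0 <= s <= 200.0

    def test_concentration_near_100_in_high_dim(self):
        rng = np.random.default_rng(31)
        mat = rng.standard_normal((300, 50))
        mat /= np.linalg.norm(mat, axis=1)[:, None]
        words = [f"w{chr(97 + i // 26)}{chr(97 + i % 26)}" for i in range(300)]
        table = EmbeddingTable(vocab=dict(zip(words, mat)), dim=50)
        scores = []
        for _ in range(1000):
            picks = [words[i] for i in rng.choice(300, 7, replace=False)]
            scores.append(dat_score(picks, table).score)
        assert 95.0 <= np.mean(scores) <= 105.0

    def test_wrong_word_count_rejected(self, ortho_table):
        table, words = ortho_table
        with pytest.raises(ValueError):
            dat_score(words[:6], table)

    def test_out_of_vocabulary_rejected(self, ortho_table):
        table, words = ortho_table
        with pytest.raises(ValueError):
            dat_score(words[:6] + ["zzqx"], table)


class TestScoreCorpus:
    def _mixed_corpus(self, table, words):
        good = "\n".join(f"{i + 1}. {w}" for i, w in enumerate(words + ["moss", "kite", "bark"]))
        short = "\n".join(f"{i + 1}. {w}" for i, w in enumerate(words[:5]))
        return [
            _raw(good, "a1"),
            _raw(good, "a2"),
            _raw(good, "a3"),
            _raw(short, "x1"),
            _raw("", "x2"),
        ]

    def test_counts_rows_and_exclusions(self, ortho_table):
        table, words = ortho_table
        df, exclusions = score_corpus(self._mixed_corpus(table, words), table)
        assert len(df) == 3
        assert sorted(rid for rid, _ in exclusions) == ["x1", "x2"]

    def test_identical_responses_give_zero_sd(self, ortho_table):
        table, words = ortho_table
        text = "\n".join(f"{i + 1}. {w}" for i, w in enumerate(words + ["moss", "kite", "bark"]))
        df, _ = score_corpus([_raw(text, f"r{i}") for i in range(5)], table)
        assert df["score"].std() == pytest.approx(0.0)

    def test_all_excluded_warns_with_empty_table(self, ortho_table):
        table, _ = ortho_table
        with pytest.warns(UserWarning, match="excluded"):
            df, exclusions = score_corpus([_raw("", "e1"), _raw("", "e2")], table)
        assert df.empty and len(exclusions) == 2

    def test_empty_corpus_rejected(self, ortho_table):
        table, _ = ortho_table
        with pytest.raises(ValueError):
            score_corpus([], table)

    def test_higher_diversity_scores_higher(self):
        spec_lo = SyntheticSpec(n_clusters=12, vocab_size=240, sigma=0.1,
                                diversity=0.1, invalid_rate=0.0, seed=42)
        spec_hi = SyntheticSpec(n_clusters=12, vocab_size=240, sigma=0.1,
                                diversity=0.9, invalid_rate=0.0, seed=42)
        space = make_cluster_space(spec_lo)
        lo, _ = score_corpus(gen_word_responses(space, spec_lo, 100), space)
        hi, _ = score_corpus(gen_word_responses(space, spec_hi, 100), space)
        assert hi["score"].mean() > lo["score"].mean()


class TestAdherence:
    def test_all_adhered(self, ortho_table):
        table, words = ortho_table
        text = "\n".join(f"{i + 1}. {w}" for i, w in enumerate(words + ["moss", "kite", "bark"]))
        parsed = parse_corpus([_raw(text, f"r{i}") for i in range(4)], table)
        assert adherence_ratio(parsed) == 1.0

    def test_half_adhered(self, ortho_table):
        table, words = ortho_table
        good = "\n".join(f"{i + 1}. {w}" for i, w in enumerate(words + ["moss", "kite", "bark"]))
        corpus = [_raw(good, f"g{i}") for i in range(5)] + [_raw("", f"b{i}") for i in range(5)]
        assert adherence_ratio(parse_corpus(corpus, table)) == 0.5

    def test_decreasing_in_invalid_rate(self):
        ratios = []
        for rho in (0.0, 0.2, 0.5, 0.8):
            spec = SyntheticSpec(invalid_rate=rho, seed=9)
            space = make_cluster_space(spec)
            parsed = parse_corpus(gen_word_responses(space, spec, 150), space)
            ratios.append(adherence_ratio(parsed))
        assert all(a >= b for a, b in zip(ratios, ratios[1:]))
        assert ratios[0] > ratios[-1]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            adherence_ratio([])


class TestWordSetFrequencies:
    def test_percentages_and_tie_breaking(self, ortho_table):
        table, _ = ortho_table
        corpus = [
            _raw("1. apple\n2. river", "r1"),
            _raw("1. apple\n2. stone", "r2"),
        ]
        parsed = [p for p in parse_corpus(corpus, table)]
        freq = word_set_frequencies(parsed)
        assert freq.iloc[0]["word"] == "apple"
        assert freq.iloc[0]["percent"] == 100.0
        # river/stone tie at 50% -> alphabetical
        assert list(freq["word"][1:]) == ["river", "stone"]
        assert list(freq["percent"][1:]) == [50.0, 50.0]

    def test_duplicates_within_a_set_count_once(self, ortho_table):
        table, _ = ortho_table
        parsed = parse_corpus([_raw("1. apple\n2. apple", "r1")], table)
        freq = word_set_frequencies(parsed)
        assert freq.loc[freq["word"] == "apple", "percent"].item() == 100.0
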