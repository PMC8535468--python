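"""Tokenisation, n-gram generation, deduplication and boundary filtering."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinconcept.postag import is_verb_adj_adv, pos_tag_token
from clinconcept.preprocess import (DEFAULT_STOPWORDS, deduplicate,
                                    document_from_text, generate_ngrams,
                                    identify_word_boundaries, pos_filter_bag,
                                    tokenize)
from clinconcept.postag import lemmatize_tokens

WORDS = st.text(alphabet="abcdefghij", min_size=1, max_size=6)


class TestTokenize:
    def test_empty_text_yields_no_sentences(self):
        assert tokenize("") == []

    def test_punctuation_split_from_words(self):
        assert tokenize("The patient has a pelvic fracture.") == [
            ["The", "patient", "has", "a", "pelvic", "fracture", "."]]

    def test_two_line_note_keeps_line_indices(self):
        doc = document_from_text("d", "chest pain today\nno fever now")
        lines = {tok.line_index for s in doc.sentences for tok in s.tokens}
        assert lines == {1, 2}
        # token offsets reconstruct the original token sequence per line
        first = [t.surface for s in doc.sentences for t in s.tokens
                 if t.line_index == 1]
        assert first == ["chest", "pain", "today"]
        assert [t.token_index for s in doc.sentences for t in s.tokens
                if t.line_index == 1] == [0, 1, 2]

    def test_sentence_final_punctuation_splits_within_line(self):
        doc = document_from_text("d", "he was well. she was not.")
        assert len(doc.sentences) == 2
        # token indices keep counting across sentences of the same line
        assert doc.sentences[1].tokens[0].token_index == 4

    def test_clinical_abbreviations_stay_whole(self):
        assert tokenize("aspirin 81 mg/dL q.d. daily") == [
            ["aspirin", "81", "mg/dL", "q.d.", "daily"]]


class TestLemmatize:
    @pytest.mark.parametrize("token,lemma", [
        ("caring", "care"),
        ("fracture", "fracture"),
        ("arteries", "artery"),
        ("was", "be"),
        ("blockers", "blocker"),
    ])
    def test_known_lemmas(self, token, lemma):
        assert lemmatize_tokens([token]) == [lemma]

    def test_out_of_vocabulary_is_lowercased_identity(self):
        assert lemmatize_tokens(["Zzyzx"]) == ["zzyzx"]

    def test_length_preserved_and_tags_accepted(self):
        toks = ["Troponins", "were", "rising"]
        lemmas = lemmatize_tokens(toks, ["NNS", "VBD", "VBG"])
        assert len(lemmas) == len(toks)
        assert lemmas[0] == "troponin"

    def test_mismatched_tags_rejected(self):
        with pytest.raises(ValueError):
            lemmatize_tokens(["a", "b"], ["NN"])


class TestGenerateNgrams:
    def test_enumeration_order(self):
        grams = generate_ngrams(["a", "b", "c"], n_max=2)
        assert [" ".join(g.tokens) for g in grams] == ["a", "b", "c", "a b", "b c"]

    def test_short_sentence(self):
        grams = generate_ngrams(["a"], n_max=4)
        assert [g.tokens for g in grams] == [["a"]]

    def test_six_token_sentence_count(self):
        grams = generate_ngrams(list("abcdef"), n_max=4)
        assert len(grams) == 6 + 5 + 4 + 3

    def test_invalid_n_max(self):
        with pytest.raises(ValueError):
            generate_ngrams(["a"], n_max=0)

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(WORDS, max_size=12), st.integers(min_value=1, max_value=5))
    def test_count_formula(self, tokens, n_max):
        grams = generate_ngrams(tokens, n_max=n_max)
        expected = sum(max(0, len(tokens) - n + 1) for n in range(1, n_max + 1))
        assert len(grams) == expected
        # windows are contiguous and within the sentence
        for g in grams:
            line, start, end = g.location
            assert g.tokens == tokens[start:end + 1]


class TestDeduplicate:
    def test_keeps_first_occurrence(self):
        grams = generate_ngrams(["x", "y", "x"], n_max=1)
        assert [g.tokens for g in deduplicate(grams)] == [["x"], ["y"]]

    def test_empty(self):
        assert deduplicate([]) == []

    def test_case_variants_collapse(self):
        grams = generate_ngrams(["Stress", "stress"], n_max=1)
        assert len(deduplicate(grams)) == 1

    @settings(max_examples=40, derandomize=True)
    @given(st.lists(WORDS, max_size=10))
    def test_idempotent(self, tokens):
        grams = generate_ngrams(tokens, n_max=2) if tokens else []
        once = deduplicate(grams)
        assert deduplicate(once) == once


class TestPosFilterBag:
    def test_keeps_nouns_adjectives_adverbs(self):
        tagged = [("severe", "JJ"), ("atherosclerosis", "NN"), ("was", "VBD")]
        assert pos_filter_bag(tagged) == ["severe", "atherosclerosis"]

    def test_all_verbs_filtered(self):
        assert pos_filter_bag([("was", "VBD"), ("running", "VBG")]) == []

    def test_matches_regex_oracle_on_mixed_sentence(self):
        import re
        tokens = "the very severe chest pain was slowly getting much worse".split()
        tagged = [(t, pos_tag_token(t)) for t in tokens]
        kept = pos_filter_bag(tagged)
        oracle = [t for t, tag in tagged if re.match(r"NN|JJ|RB", tag)]
        assert kept == oracle


def _boundary_oracle(cand, stopwords):
    """Independent per-token check: keep iff any token is a content token."""
    import string
    if any(t and all(ch in string.punctuation for ch in t) for t in cand.tokens):
        return False
    if not cand.normalized:
        return False
    disqualified = 0
    for surf, tag in zip(cand.tokens, cand.pos_tags):
        if surf.lower() in stopwords or is_verb_adj_adv(tag):
            disqualified += 1
    return disqualified != len(cand.tokens)


class TestWordBoundaries:
    @pytest.mark.parametrize("phrase,kept", [
        ("is the", False),           # pure function words
        ("did have of", False),
        ("a pelvic fracture", True),  # interior stopword, noun head
        ("burst of atrial", True),
        ("have burst", True),
        ("good effect", True),        # noun 'effect' qualifies the candidate
        ("of atrial", False),         # stopword + adjective only
    ])
    def test_worked_examples(self, phrase, kept):
        grams = [g for g in generate_ngrams(phrase.split(), n_max=4)
                 if g.n == len(phrase.split())]
        retained = identify_word_boundaries(grams)
        assert bool(retained) is kept

    def test_pure_filter_subset_and_order(self):
        doc = document_from_text("d", "she was given beta blockers for chest pain .")
        grams = generate_ngrams(doc.sentences[0].tokens, n_max=4)
        kept = identify_word_boundaries(grams)
        assert all(g in grams for g in kept)
        indices = [grams.index(g) for g in kept]
        assert indices == sorted(indices)

    def test_fuzzed_candidates_match_oracle(self):
        rng = random.Random(20240917)
        vocab = ("the of and was very severe pain heart rate aspirin good "
                 "effect did have is burst atrial slowly running . , normal").split()
        for _ in range(1000):
            tokens = [rng.choice(vocab) for _ in range(rng.randint(1, 4))]
            grams = generate_ngrams(tokens, n_max=4)
            kept = identify_word_boundaries(grams)
            expected = [g for g in grams if _boundary_oracle(g, DEFAULT_STOPWORDS)]
            assert kept == expected

    def test_retained_candidates_contain_content_token(self, default_corpus):
        for text in default_corpus.notes.values():
            doc = document_from_text("d", text)
            for sent in doc.sentences:
                for cand in identify_word_boundaries(
                        generate_ngrams(sent.tokens, n_max=4)):
                    assert any(
                        surf.lower() not in DEFAULT_STOPWORDS
                        and not is_verb_adj_adv(tag)
                        for surf, tag in zip(cand.tokens, cand.pos_tags))
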