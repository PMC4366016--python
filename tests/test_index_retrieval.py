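from collections import Counter
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from ontosieve.index_retrieval import (
    Annotation,
    ConceptTokenIndex,
    IndexRow,
    annotate,
    build_index,
    exact_match,
    generate_candidates,
    positional_encoding,
    score,
    split_sentences,
)
from ontosieve.lexicon_io import RawConcept, build_profiles


class TestPositionalEncoding:
    def test_two_tokens(self):
        assert positional_encoding(["adenine", "aminase"]) == {
            "adenine": 2, "aminase": 1,
        }

    def test_single_token(self):
        assert positional_encoding(["kinase"]) == {"kinase": 1}

    def test_repeats_accumulate(self):
        values = positional_encoding(["a", "b", "a"])
        assert values == {"a": 4, "b": 2}
        assert sum(values.values()) == 6  # L(L+1)/2

    @given(st.lists(st.sampled_from("abcdef"), min_size=1, max_size=10))
    def test_value_sum_is_triangular(self, tokens):
        L = len(tokens)
        assert sum(positional_encoding(tokens).values()) == L * (L + 1) // 2

    @given(st.lists(st.sampled_from("abcdefgh"), min_size=1, max_size=8, unique=True))
    def test_distinct_tokens_get_permutation(self, tokens):
        values = positional_encoding(tokens)
        assert sorted(values.values()) == list(range(1, len(tokens) + 1))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding([])


class TestBuildIndex:
    def test_single_label_row(self):
        profiles, _ = build_profiles([RawConcept("X:1", ("alpha beta gamma",))])
        index = build_index(profiles)
        assert len(index.rows) == 1
        assert index.rows[0].value_sum == 6
        assert index.max_len == 3

    def test_variant_adds_row(self, suffix_concepts):
        from ontosieve.dfr_gain import compute_gain_table
        from ontosieve.mutual_info import compute_mi_stats
        from ontosieve.variant_generation import VariantParams, generate_variants
        profiles, stats = build_profiles(suffix_concepts)
        table = compute_gain_table(profiles, stats)
        mi = compute_mi_stats(profiles, m=1.0, n=0.5)
        variants = generate_variants(profiles, table, mi, VariantParams(n=0.5))
        plain = build_index(profiles)
        augmented = build_index(profiles, variants)
        assert len(augmented.rows) == len(plain.rows) + len(variants)

    def test_shared_label_ambiguity_kept(self):
        profiles, _ = build_profiles([
            RawConcept("X:1", ("cell",)),
            RawConcept("X:2", ("cell",)),
        ])
        index = build_index(profiles)
        rows = [index.rows[i].concept_id for i in index.postings("cell")]
        assert sorted(rows) == ["X:1", "X:2"]

    def test_inverted_index_complete(self, suffix_concepts):
        profiles, _ = build_profiles(suffix_concepts)
        index = build_index(profiles)
        for row_id, row in enumerate(index.rows):
            for token in row.tokens:
                assert row_id in index.postings(token)

    def test_json_round_trip(self, tmp_path):
        profiles, _ = build_profiles([
            RawConcept("X:1", ("alpha beta", "gamma")),
        ])
        index = build_index(profiles, case_sensitive=True, metadata={"css": 0.5})
        path = tmp_path / "index.json"
        index.save(path)
        loaded = ConceptTokenIndex.load(path)
        assert loaded.case_sensitive is True
        assert loaded.metadata == {"css": 0.5}
        assert [r.tokens for r in loaded.rows] == [r.tokens for r in index.rows]
        assert loaded.inverted == index.inverted


class TestScore:
    def row(self, tokens, cid="X:1"):
        return IndexRow(cid, tuple(tokens), positional_encoding(tokens))

    def test_self_query_scores_one(self):
        row = self.row(["alpha", "beta", "gamma"])
        assert score(["alpha", "beta", "gamma"], row) == 1

    def test_out_of_vocabulary_scores_zero(self):
        row = self.row(["alpha", "beta"])
        assert score(["delta", "epsilon"], row) == 0

    def test_partial_query_hand_value(self):
        row = self.row(["a", "b"])  # values a:2, b:1
        assert score(["a"], row) == Fraction(2, 3)

    def test_permuted_query_scores_one_without_guard(self):
        # score alone cannot tell permutations apart; the exact-match
        # contract relies on the positional-sum + token-count equality
        row = self.row(["a", "b"])
        assert score(["b", "a"], row) == 1
        assert exact_match(["b", "a"], row)

    def test_multiset_collision_blocked_by_count_guard(self):
        # query [a] has row value 3 in row [a,b,c]? no: a maps to 3, the
        # guard rejects the length mismatch even though sums could collide
        row = self.row(["a", "b", "c"])
        assert score(["a"], row) == Fraction(1, 1) * Fraction(3, 6)
        assert not exact_match(["a"], row)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            score([], self.row(["a"]))

    @given(
        row_tokens=st.lists(st.sampled_from("abcde"), min_size=1, max_size=6),
        query=st.lists(st.sampled_from("abcdefg"), min_size=1, max_size=6),
    )
    @settings(max_examples=500)
    def test_exact_match_equals_multiset_equality(self, row_tokens, query):
        row = self.row(row_tokens)
        assert exact_match(query, row) == (Counter(query) == Counter(row_tokens))

    @given(
        row_tokens=st.lists(st.sampled_from("abcde"), min_size=1, max_size=6),
        query=st.lists(st.sampled_from("abcdefg"), min_size=1, max_size=6),
    )
    def test_score_bounded(self, row_tokens, query):
        value = score(query, self.row(row_tokens))
        assert 0 <= value
        assert Fraction(len(query) - sum(
            1 for t in query if t not in set(row_tokens)), len(query)) <= 1


class TestSentenceSplitting:
    def test_basic_split(self):
        spans = split_sentences("First sentence. Second one! Third?")
        assert len(spans) == 3

    def test_abbreviations_not_split(self):
        spans = split_sentences("Known tools, e.g. taggers, help. Second.")
        assert len(spans) == 2

    def test_spans_cover_text(self):
        text = "Alpha beta. Gamma delta."
        spans = split_sentences(text)
        assert spans[0] == (0, 11)
        assert text[spans[1][0]:spans[1][1]].strip() == "Gamma delta."


class TestGenerateCandidates:
    def test_window_combinatorics(self):
        candidates = generate_candidates("alpha beta gamma", max_len=2)
        token_tuples = [c[1].tokens for c in candidates]
        assert len(token_tuples) == 5  # 3 unigrams + 2 bigrams

    def test_span_excludes_stripped_determiner(self):
        text = "the cell"
        candidates = generate_candidates(text, max_len=2)
        spans = {c[0] for c in candidates}
        assert (4, 8) in spans          # "cell"
        assert all(text[s:e].strip() == text[s:e] for s, e in spans)
        assert not any(text[s:e].startswith("the ") for s, e in spans)

    def test_empty_windows_skipped(self):
        candidates = generate_candidates("the of with", max_len=3)
        assert candidates == []

    def test_windows_do_not_cross_sentences(self):
        candidates = generate_candidates("alpha beta. gamma delta", max_len=4)
        for _span, seq in candidates:
            assert not (
                "alpha" in seq.tokens and "gamma" in seq.tokens
            )


class TestAnnotate:
    def make_index(self, *labels, case_sensitive=False):
        concepts = [
            RawConcept(f"X:{i}", (label,)) for i, label in enumerate(labels)
        ]
        profiles, _ = build_profiles(concepts, case_sensitive_mode=case_sensitive)
        return build_index(profiles, case_sensitive=case_sensitive)

    def test_verbatim_label_found_once(self):
        index = self.make_index("epithelial cell")
        text = "Sections showed epithelial cell layers everywhere."
        annotations = annotate("d1", text, index)
        assert len(annotations) == 1
        a = annotations[0]
        assert (a.start, a.end) == (16, 31)
        assert text[a.start:a.end] == "epithelial cell"
        assert a.concept_id == "X:0"

    def test_nested_matches_all_reported(self):
        index = self.make_index("epithelial cell", "cell")
        text = "We counted epithelial cells yesterday."
        annotations = annotate("d1", text, index)
        found = {(a.concept_id, text[a.start:a.end]) for a in annotations}
        assert found == {("X:0", "epithelial cells"), ("X:1", "cells")}

    def test_case_sensitive_homograph(self):
        index = self.make_index("AGE", case_sensitive=True)
        assert annotate("d1", "The age of onset varied.", index) == []
        hits = annotate("d1", "Serum AGE levels rose.", index)
        assert len(hits) == 1
        assert hits[0].concept_id == "X:0"

    def test_duplicate_span_concept_collapsed(self):
        # same concept reachable via two identical normalized sequences
        concepts = [RawConcept("X:1", ("beta cell", "beta cells"))]
        profiles, _ = build_profiles(concepts)
        index = build_index(profiles)
        annotations = annotate("d1", "Islet beta cells were imaged.", index)
        assert len(annotations) == 1

    def test_self_retrieval_all_rows(self, suffix_concepts):
        profiles, _ = build_profiles(suffix_concepts)
        index = build_index(profiles)
        for row in index.rows[:50]:
            text = " ".join(row.tokens)
            annotations = annotate("d", text, index)
            assert any(a.concept_id == row.concept_id for a in annotations)

    def test_annotation_validation(self):
        with pytest.raises(ValueError):
            Annotation("d", 5, 5, "X:1")
        with pytest.raises(ValueError):
            Annotation("d", -1, 3, "X:1")
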