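"""Summarization: edit distance, suggestion routes, map application."""

import random
import string

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from camkit.model import AMBIVALENT, CAMSet
from camkit.summarize import (
    PatternError,
    SummaryMap,
    apply_summary,
    cosine_similarity,
    embedding_suggestions,
    load_synonym_dictionary,
    normalize_text,
    osa_distance,
    search_terms,
    suggest_by_distance,
    synonym_groups,
    unsummarized_overview,
)
from conftest import make_cam
from _oracles import damerau_levenshtein_unrestricted, osa_reference

words = st.text(alphabet=string.ascii_lowercase, max_size=8)


class TestOsaDistance:
    @pytest.mark.parametrize(
        "s,t,expected",
        [
            ("dreams", "dreasm", 1),   # adjacent transposition of the misspelling
            ("abc", "abc", 0),
            ("", "abc", 3),
            ("kitten", "sitting", 3),
            ("ca", "abc", 3),          # OSA; unrestricted DL would give 2
        ],
    )
    def test_known_distances(self, s, t, expected):
        assert osa_distance(s, t) == expected

    def test_osa_exceeds_unrestricted_dl_on_ca_abc(self):
        assert damerau_levenshtein_unrestricted("ca", "abc") == 2
        assert osa_distance("ca", "abc") == 3

    @settings(max_examples=200, derandomize=True)
    @given(words, words)
    def test_matches_reference_and_symmetry(self, s, t):
        d = osa_distance(s, t)
        assert d == osa_reference(s, t)
        assert d == osa_distance(t, s)
        assert (d == 0) == (s == t)


class TestDistanceSuggestions:
    def test_worked_typo_pair_grouped(self):
        groups = suggest_by_distance({"dreams", "dreasm", "tree"}, max_dist=1)
        assert len(groups) == 1
        assert groups[0].members == ("dreams", "dreasm")

    def test_distant_words_not_grouped(self):
        assert suggest_by_distance({"transport", "happiness", "economy"}, max_dist=1) == []

    def test_single_linkage_chain_closure(self):
        # aaaa-aaab at d=1, aaab-aabb at d=1, but aaaa-aabb at d=2
        groups = suggest_by_distance({"aaaa", "aaab", "aabb"}, max_dist=1)
        assert len(groups) == 1 and set(groups[0].members) == {"aaaa", "aaab", "aabb"}

    def test_normalization_merges_case_and_whitespace(self):
        groups = suggest_by_distance({"Heat  Pump", "heat pump", "heat pumps"}, max_dist=1)
        assert len(groups) == 1
        assert set(groups[0].members) == {"heat pump", "heat pumps"}


class TestSearchTerms:
    def test_posix_digit_class(self):
        assert search_terms({"co2 tax", "heat"}, "[[:digit:]]") == ["co2 tax"]

    def test_no_match_empty(self):
        assert search_terms({"aaa", "bbb"}, "zzz") == []

    def test_case_insensitive_default_and_flag(self):
        assert search_terms({"War", "warm"}, "^war$") == ["war"]
        assert search_terms({"War", "warm"}, "^War$", case_sensitive=True) == []

    def test_invalid_pattern_raises_with_position(self):
        with pytest.raises(PatternError):
            search_terms({"x"}, "([unclosed")


class TestSynonyms:
    DICT = load_synonym_dictionary(
        {"war": ["conflict"], "big": ["large"], "tiny": ["small"]}
    )

    def test_war_conflict_grouped(self):
        groups = synonym_groups({"war", "conflict"}, self.DICT)
        assert len(groups) == 1 and set(groups[0].members) == {"conflict", "war"}

    def test_multiword_never_grouped(self):
        assert synonym_groups({"world war", "war"}, self.DICT) == []

    def test_overlap_only_for_linked_words(self):
        groups = synonym_groups({"big", "large", "tiny"}, self.DICT)
        assert len(groups) == 1 and set(groups[0].members) == {"big", "large"}

    def test_dictionary_symmetrized_on_load(self):
        assert "war" in self.DICT["conflict"]


class TestCosine:
    def test_proportional_orthogonal_and_hand_value(self):
        assert cosine_similarity([1, 2], [2, 4]) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cosine_similarity([1, 2, 3], [3, 2, 1]) == pytest.approx(10 / 14)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_similarity([0, 0], [1, 0])

    def test_scipy_cross_check(self):
        from scipy.spatial.distance import cosine as scipy_cos

        rng = np.random.default_rng(4)
        for _ in range(20):
            u, v = rng.normal(size=5), rng.normal(size=5)
            assert cosine_similarity(u, v) == pytest.approx(1 - scipy_cos(u, v))


class TestEmbeddingSuggestions:
    VECS = {
        "car": np.array([1.0, 0.1, 0.0]),
        "auto": np.array([1.0, 0.12, 0.01]),
        "train": np.array([0.0, 1.0, 0.1]),
        "railway": np.array([0.05, 1.0, 0.12]),
    }

    def test_matches_brute_force_all_pairs(self):
        groups, missing = embedding_suggestions(self.VECS, self.VECS, threshold=0.9)
        linked = {
            frozenset((a, b))
            for a in self.VECS
            for b in self.VECS
            if a < b and cosine_similarity(self.VECS[a], self.VECS[b]) >= 0.9
        }
        assert linked == {frozenset(("car", "auto")), frozenset(("train", "railway"))}
        assert {frozenset(g.members) for g in groups} == linked
        assert missing == []

    def test_identical_vectors_group_at_any_threshold(self):
        groups, _ = embedding_suggestions(
            {"a", "b"}, {"a": [1, 0], "b": [2, 0]}, threshold=1.0
        )
        assert len(groups) == 1

    def test_missing_vectors_reported(self):
        _, missing = embedding_suggestions({"a", "zzz"}, {"a": [1.0]}, threshold=0.5)
        assert missing == ["zzz"]


def _cost_set() -> CAMSet:
    cam1 = make_cam("c1", {"a": ("cheap", 2), "b": ("expensive", -2)}, [("a", "b", 1)])
    cam2 = make_cam("c2", {"a": ("cheap", 0), "b": ("fees", AMBIVALENT)}, [("a", "b", 1)])
    return CAMSet(cams=[cam1, cam2])


class TestApplySummary:
    MAP = SummaryMap(
        {"cheap": "Cost", "expensive": "Cost", "fees": "Cost"}, split_by_valence=True
    )

    def test_valence_split_suffixes(self):
        out = apply_summary(_cost_set(), self.MAP)
        texts = sorted(c.text for _, c in out.all_concepts())
        assert texts == ["Cost_ambivalent", "Cost_negative", "Cost_neutral", "Cost_positive"]

    def test_raw_text_preserved_and_structure_untouched(self):
        src = _cost_set()
        out = apply_summary(src, self.MAP)
        assert out["c1"].concept("a").raw_text == "cheap"
        assert out["c1"].connectors == src["c1"].connectors
        assert [c.valence for c in out["c1"].concepts] == [
            c.valence for c in src["c1"].concepts
        ]

    def test_empty_map_is_identity(self):
        src = _cost_set()
        out = apply_summary(src, SummaryMap({}))
        assert list(out) == list(src)

    def test_idempotent(self):
        once = apply_summary(_cost_set(), self.MAP)
        twice = apply_summary(once, self.MAP)
        assert [c.text for _, c in twice.all_concepts()] == [
            c.text for _, c in once.all_concepts()
        ]


class TestUnsummarizedOverview:
    def test_counts_and_ordering(self):
        src = _cost_set()
        out = unsummarized_overview(src, SummaryMap({"cheap": "Cost"}))
        assert list(out.itertuples(index=False, name=None)) == [
            ("expensive", 1),
            ("fees", 1),
        ]

    def test_fully_mapped_empty(self):
        src = _cost_set()
        smap = SummaryMap({"cheap": "Cost", "expensive": "Cost", "fees": "Cost"})
        assert len(unsummarized_overview(src, smap)) == 0

    def test_counts_match_brute_force_tally(self):
        src = _cost_set()
        out = unsummarized_overview(src, SummaryMap({}))
        tally = {}
        for _, c in src.all_concepts():
            tally[normalize_text(c.text)] = tally.get(normalize_text(c.text), 0) + 1
        assert dict(zip(out["raw_text"], out["frequency"])) == tally
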