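"""Sentence relevance, positional weights, document scoring, labelling."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from thyroscore import (SUBTYPES, TITLE, Document, ScoringConfig,
                        ValidationError, baseline_classify, classify,
                        classify_document, match_sentence, positional_weight,
                        score_document, sentence_relevance)
from thyroscore.lexicon import KeywordMatches
from thyroscore.scoring import ScoreVector


def _matches(sk, ak, mk):
    return KeywordMatches(frozenset(sk), ak, mk, ())


class TestSentenceRelevance:
    # Exhaustive 4 x 2 x 2 condition table: the three co-occurrence rules
    # applied independently per subtype.
    @pytest.mark.parametrize("subtype", SUBTYPES)
    @pytest.mark.parametrize("ak, mk, expected", [
        (True, True, 1.0), (True, False, 0.5), (False, True, 0.5),
        (False, False, 0.25),
    ])
    def test_condition_table(self, config, subtype, ak, mk, expected):
        vec = sentence_relevance(_matches({subtype}, ak, mk), config)
        for j in SUBTYPES:
            assert vec.get(j) == (expected if j == subtype else 0.0)

    def test_multiple_subtypes_scored_independently(self, config):
        vec = sentence_relevance(_matches({"PTC", "MTC"}, True, True), config)
        assert vec.s_p == 1.0 and vec.s_m == 1.0
        assert vec.s_a == vec.s_f == 0.0

    def test_one_score_per_subtype_regardless_of_repeats(self, lexicon, config):
        once = sentence_relevance(
            match_sentence("Papillary thyroid cancer.", lexicon), config)
        twice = sentence_relevance(
            match_sentence("Papillary and papillary thyroid cancer.", lexicon), config)
        assert once == twice

    def test_values_always_in_quarter_set(self, lexicon, config):
        for sk, ak, mk in itertools.product([set(), {"PTC"}], [0, 1], [0, 1]):
            vec = sentence_relevance(_matches(sk, bool(ak), bool(mk)), config)
            assert set(vec.as_tuple()) <= {0.0, 0.25, 0.5, 1.0}


class TestPositionalWeight:
    def test_six_sentence_fixture(self, config):
        assert positional_weight(TITLE, 6, config) == 4
        assert [positional_weight(i, 6, config) for i in range(6)] == \
               [2, 1, 0.5, 0.5, 1, 2]

    @pytest.mark.parametrize("index, n, expected", [
        (0, 1, 2),    # single sentence: first and last
        (0, 2, 2), (1, 2, 2),
        (1, 3, 1),    # second and penultimate
        (0, 3, 2),
    ])
    def test_short_abstracts_take_max_category(self, config, index, n, expected):
        assert positional_weight(index, n, config) == expected

    def test_max_of_categories_matches_enumeration_oracle(self, config):
        for n in range(1, 9):
            for i in range(n):
                cats = [0.5]
                if i in (0, n - 1):
                    cats.append(2)
                if i in (1, n - 2):
                    cats.append(1)
                assert positional_weight(i, n, config) == max(cats)

    @pytest.mark.parametrize("index", [-1, 6, 2.5])
    def test_out_of_range_rejected(self, config, index):
        with pytest.raises(ValidationError):
            positional_weight(index, 6, config)


class TestScoreDocument:
    def test_title_only_full_name(self, lexicon, config):
        doc = Document("1", "Papillary thyroid carcinoma.", ())
        assert score_document(doc, lexicon, config) == ScoreVector(4.0, 0, 0, 0)

    def test_hand_computed_weighted_sum(self, lexicon, config):
        doc = Document("1", "Genomic study.", (
            "Papillary thyroid cancer is common.",   # w=2, rel=1
            "We sequenced tumors.",                  # no SK
            "BRAF was mutated.",                     # nothing
            "Papillary cancer has good prognosis.",  # w=2 (last), rel=0.5
        ))
        vec = score_document(doc, lexicon, config)
        assert vec.s_p == 2 * 1 + 2 * 0.5
        assert vec.s_a == vec.s_f == vec.s_m == 0.0

    def test_keyword_free_document_scores_zero(self, lexicon, config):
        doc = Document("1", "A study.", ("No relevant words here.",))
        assert score_document(doc, lexicon, config) == ScoreVector()

    @given(st.integers(0, 3))
    def test_monotone_under_keyword_append(self, lexicon, config, idx):
        base_sentences = ["Alpha beta.", "Gamma delta.", "Epsilon zeta.", "Eta theta."]
        doc = Document("1", "A title.", tuple(base_sentences))
        grown = list(base_sentences)
        grown[idx] = grown[idx] + " Medullary thyroid carcinoma."
        doc2 = Document("1", "A title.", tuple(grown))
        before = score_document(doc, lexicon, config)
        after = score_document(doc2, lexicon, config)
        assert after.s_m >= before.s_m


class TestClassify:
    def test_dominant_score_labels_single_subtype(self, config):
        labels = classify(ScoreVector(7, 0, 0.5, 0), config, True)
        assert labels == {"PTC"}  # 0.5 fails the absolute threshold

    def test_zero_vector_without_relevance_is_non(self, config):
        assert classify(ScoreVector(), config, False) == {"NON"}

    def test_subthreshold_relevance_is_tc(self, config):
        assert classify(ScoreVector(0.5, 0.25, 0, 0), config, True) == {"TC"}

    def test_share_threshold_prunes_minor_components(self, config):
        # FTC clears the absolute threshold but not its 20% share.
        vec = ScoreVector(10, 0, 1.5, 0)
        assert classify(vec, config, True) == {"PTC"}

    def test_multi_label_when_both_clear(self, config):
        vec = ScoreVector(6, 0, 4, 0)
        assert classify(vec, config, True) == {"PTC", "FTC"}

    def test_classify_document_end_to_end(self, lexicon, config):
        doc = Document("1", "Medullary thyroid carcinoma in families.",
                       ("Screening was performed.",))
        result = classify_document(doc, lexicon, config)
        assert result.labels == {"MTC"}
        assert result.scores.s_m == 4.0

    def test_tc_only_document(self, lexicon, config):
        doc = Document("1", "Thyroid cancer epidemiology.", ())
        assert classify_document(doc, lexicon, config).labels == {"TC"}


class TestBaseline:
    @pytest.mark.parametrize("title, expected", [
        ("Papillary thyroid cancer in children", {"PTC"}),
        ("Papillary carcinoma of the thyroid", {"PTC"}),
        ("Thyroid medullary carcinoma study", {"MTC"}),
        ("A completely unrelated title", {"NON"}),
    ])
    def test_full_name_detection(self, lexicon, title, expected):
        assert baseline_classify(Document("1", title, ()), lexicon) == expected

    def test_partial_names_invisible_to_baseline(self, lexicon, config):
        doc = Document("1", "A study.", ("Risk of papillary cancer increased.",))
        assert baseline_classify(doc, lexicon) == {"NON"}
        # ...while the scorer still sees the partial mention
        assert score_document(doc, lexicon, config).s_p == pytest.approx(1.0)


class TestScoringConfig:
    def test_from_file_overrides(self, tmp_path):
        path = tmp_path / "cfg.txt"
        path.write_text("weight_title=5\nmin_share.PTC=0.4\n# comment\n")
        cfg = ScoringConfig.from_file(path)
        assert cfg.weight_title == 5
        assert cfg.min_share["PTC"] == 0.4
        assert cfg.min_share["ATC"] == 0.2  # untouched default

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.txt"
        path.write_text("wibble=1\n")
        with pytest.raises(ValidationError):
            ScoringConfig.from_file(path)

    def test_invalid_share_rejected(self):
        with pytest.raises(ValidationError):
            ScoringConfig(min_share={"PTC": 1.5, "ATC": 0.2, "FTC": 0.2, "MTC": 0.2})
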