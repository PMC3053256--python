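"""Feature extraction, the frequency baseline, per-rank accuracy profiles."""

import io

import pytest

from pprerank.corpus_io import BlockType
from pprerank.ranking import (
    AccuracyProfile,
    FreqScoreModel,
    LinearSvmModel,
    RankedList,
    estimate_rank_accuracy,
    extract_features,
    rank_frequency_baseline,
    rank_with_model,
    read_profile,
    write_profile,
)
from conftest import build_doc


def doc_with_counts(counts: dict[str, int], results_counts: dict[str, int] = {}):
    """One Introduction and one Results BODY block with given mention counts."""
    intro = " ".join(
        f"{ident} was seen." for ident, k in counts.items() for _ in range(k)
    )
    results = " ".join(
        f"{ident} was confirmed." for ident, k in results_counts.items() for _ in range(k)
    )
    return build_doc(
        [
            (BlockType.BODY, ("1 Introduction",), intro),
            (BlockType.BODY, ("3 Results",), results),
            (BlockType.BODY, ("5 Conclusions",), "We are done."),
        ]
    )


class TestFreqBaseline:
    def test_orders_by_article_frequency(self):
        doc = doc_with_counts({"P40337": 45, "P40338": 14, "Q05513": 10, "Q9NPB6": 7})
        assert rank_frequency_baseline(doc).identifiers == [
            "P40337", "P40338", "Q05513", "Q9NPB6",
        ]

    def test_results_section_breaks_ties(self):
        doc = doc_with_counts(
            {"P11111": 1, "P22222": 3}, results_counts={"P11111": 2}
        )
        # both have total frequency 3; P11111 has 2 Results mentions
        assert rank_frequency_baseline(doc).identifiers == ["P11111", "P22222"]

    def test_earlier_mention_breaks_remaining_ties(self):
        doc = build_doc([(BlockType.BODY, ("1 Intro",), "P22222 then P11111 appear.")])
        assert rank_frequency_baseline(doc).identifiers == ["P22222", "P11111"]

    def test_single_identifier(self):
        doc = doc_with_counts({"P11111": 2})
        assert rank_frequency_baseline(doc).identifiers == ["P11111"]

    def test_frequency_non_increasing_along_ranks(self):
        doc = doc_with_counts({"P11111": 5, "P22222": 9, "P33333": 1, "P44444": 9})
        ranked = rank_frequency_baseline(doc)
        counts = [
            sum(1 for m in doc.mentions if m.identifier == x) for x in ranked.identifiers
        ]
        assert counts == sorted(counts, reverse=True)


class TestFeatures:
    def test_abstract_only_identifier(self):
        doc = build_doc(
            [
                (BlockType.ABSTRACT, (), "P11111 was studied."),
                (BlockType.BODY, ("3 Results",), "Other things happened."),
            ]
        )
        fv = extract_features(doc, "P11111")
        assert fv.freq_total == 1
        assert fv.in_abstract
        assert not any(
            [fv.in_title, fv.in_first_section, fv.in_results, fv.in_last_section,
             fv.in_appendix, fv.in_other_section, fv.in_figure_table_caption]
        )

    def test_results_ratio_and_sections(self):
        doc = build_doc(
            [
                (BlockType.BODY, ("1 Introduction",), "P11111 was found."),
                (BlockType.BODY, ("3 Results",), "P11111 binds. P11111 acts. P11111 moves."),
            ]
        )
        fv = extract_features(doc, "P11111")
        assert fv.freq_total == 4
        assert fv.freq_results_ratio == pytest.approx(0.75)
        assert fv.in_first_section and fv.in_results

    def test_keyword_field_and_cooccurrence(self):
        doc = build_doc(
            [
                (BlockType.KEYWORD, (), "P11111; signalling"),
                (BlockType.BODY, ("3 Results",), "P22222 requires signalling input. P33333 acts."),
            ]
        )
        assert extract_features(doc, "P11111").in_keyword_field
        assert extract_features(doc, "P22222").cooccur_keyword
        assert not extract_features(doc, "P33333").cooccur_keyword

    def test_figure_reference_and_indicator_phrase(self):
        doc = build_doc(
            [
                (BlockType.BODY, ("3 Results",),
                 "P11111 binds P22222 (Figure 3). We conclude that P33333 is key."),
            ]
        )
        assert extract_features(doc, "P11111").cooccur_figure_reference
        assert extract_features(doc, "P33333").indicator_phrase
        assert not extract_features(doc, "P33333").cooccur_figure_reference

    def test_section_heading_and_caption(self):
        doc = build_doc(
            [
                (BlockType.BODY, ("3 Results", "3.1 P11111 interacts"), "P11111 binds."),
                (BlockType.FIGURE, (), "Figure 1. P22222 localization."),
            ]
        )
        assert extract_features(doc, "P11111").in_section_heading
        assert extract_features(doc, "P22222").in_figure_table_caption

    def test_unknown_identifier_rejected(self):
        doc = build_doc([(BlockType.BODY, (), "P11111 acts.")])
        with pytest.raises(ValueError, match="Q99999"):
            extract_features(doc, "Q99999")


class TestModelRanking:
    def test_frequency_model_reproduces_baseline(self):
        doc = doc_with_counts({"P11111": 5, "P22222": 9, "P33333": 1})
        features = {x: extract_features(doc, x) for x in doc.identifiers()}
        ranked = rank_with_model(
            FreqScoreModel(), features, baseline=rank_frequency_baseline(doc)
        )
        assert ranked.identifiers == rank_frequency_baseline(doc).identifiers

    def test_scoring_failure_names_identifier(self):
        def broken(fv):
            raise RuntimeError("boom")

        doc = doc_with_counts({"P11111": 1})
        features = {x: extract_features(doc, x) for x in doc.identifiers()}
        with pytest.raises(RuntimeError, match="P11111"):
            rank_with_model(broken, features)

    def test_linear_svm_separates_planted_classes(self):
        pos = [extract_features(doc_with_counts({}, {"P11111": k}), "P11111")
               for k in (3, 4, 5)]
        neg = [extract_features(doc_with_counts({"Q22222": k}), "Q22222")
               for k in (3, 4, 5)]
        model = LinearSvmModel().fit(
            [(fv, True) for fv in pos] + [(fv, False) for fv in neg]
        )
        assert min(model.score(fv) for fv in pos) > max(model.score(fv) for fv in neg)


class TestAccuracyProfile:
    def test_rank1_correct_in_both_articles(self):
        results = [
            (RankedList("a", ["x", "y"]), {"x"}),
            (RankedList("b", ["u", "v"]), {"u", "v"}),
        ]
        profile = estimate_rank_accuracy(results)
        assert profile.acc[1] == 1.0

    def test_counting_over_four_articles(self):
        results = [
            (RankedList("a", ["x", "g"]), {"g"}),
            (RankedList("b", ["x", "y"]), {"z"}),
            (RankedList("c", ["x", "y"]), {"z"}),
            (RankedList("d", ["x", "y"]), {"z"}),
        ]
        profile = estimate_rank_accuracy(results)
        assert profile.acc[2] == pytest.approx(0.25)

    def test_short_lists_excluded_from_denominator(self):
        results = [
            (RankedList("a", ["x"]), {"x"}),
            (RankedList("b", ["u", "g"]), {"g"}),
        ]
        profile = estimate_rank_accuracy(results)
        assert profile.acc[2] == 1.0

    def test_lookup_clamps_beyond_table(self):
        profile = AccuracyProfile(acc={1: 0.9, 2: 0.5})
        assert profile.lookup(99) == 0.5

    def test_floor_applied(self):
        profile = AccuracyProfile(acc={1: 0.0}, floor_epsilon=1e-6)
        assert profile.lookup(1) == 1e-6

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_rank_accuracy([])

    def test_profile_tsv_round_trip(self):
        profile = AccuracyProfile(acc={1: 0.9, 2: 0.45, 3: 0.0}, floor_epsilon=1e-5)
        out = io.StringIO()
        write_profile(profile, out)
        clone = read_profile(io.StringIO(out.getvalue()))
        assert clone == profile
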