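"""Unit and property tests for the band-scoring rubric core."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ninescore import (
    IndicatorValue,
    SystemRating,
    ThresholdBand,
    band_score,
    classify_rating,
    domain_total,
    grade_from_total,
    overall_rating,
    rate_scores,
    score_indicator,
)
from ninescore.errors import (
    InvalidInputError,
    InvalidRatingError,
    InvalidScoreError,
    InvalidTotalError,
    MissingDataError,
)

HALE = ThresholdBand(score3_exclusive=70, score1_exclusive=50)
MI = ThresholdBand(score3_exclusive=95, score1_exclusive=90)
PCT90 = ThresholdBand(score3_exclusive=90, score1_exclusive=50)
OOP = ThresholdBand(score3_exclusive=5, score1_exclusive=7.5, higher_is_better=False)


class TestBandScore:
    @pytest.mark.parametrize(
        "band,value,expected",
        [
            (HALE, 74, 3),       # above the target threshold
            (MI, 92, 2),         # inside the closed middle band
            (PCT90, 90, 2),      # exactly on the score-3 boundary -> middle band
            (PCT90, 49.9, 1),    # strictly below the score-1 boundary
            (PCT90, 50, 2),      # exactly on the score-1 boundary -> middle band
            (OOP, 4, 3),         # inverted band: lower out-of-pocket is better
            (OOP, 8, 1),
            (OOP, 5, 2),         # boundary of inverted band also scores 2
            (OOP, 7.5, 2),
        ],
    )
    def test_banding(self, band, value, expected):
        assert band_score(value, band) == expected

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), float("-inf"), None, "74"])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            band_score(bad, HALE)

    def test_malformed_band_rejected(self):
        with pytest.raises(InvalidInputError):
            ThresholdBand(score3_exclusive=50, score1_exclusive=90)
        with pytest.raises(InvalidInputError):
            ThresholdBand(score3_exclusive=9, score1_exclusive=5, higher_is_better=False)

    @given(st.floats(allow_nan=False, allow_infinity=False, width=32))
    @settings(max_examples=300, derandomize=True)
    def test_every_finite_value_gets_exactly_one_score(self, value):
        assert band_score(value, HALE) in (1, 2, 3)
        assert band_score(value, OOP) in (1, 2, 3)


class TestScoreIndicator:
    def test_direct_score_overrides_raw(self, rubric):
        v = IndicatorValue(indicator_id=4, raw_value=99.0, direct_score=1, provenance="delphi")
        assert score_indicator(v, rubric[4]) == 1

    def test_out_of_pocket_alone(self, rubric):
        v = IndicatorValue(indicator_id=8, alt_raw_value=4.0)
        assert score_indicator(v, rubric[8]) == 3

    def test_dual_criterion_takes_most_favorable(self, rubric):
        # HSA penetration 60% bands to 2, out-of-pocket 8% bands to 1: "or" keeps 2
        v = IndicatorValue(indicator_id=8, raw_value=60.0, alt_raw_value=8.0)
        assert score_indicator(v, rubric[8]) == 2

    def test_research_funding_middle_band(self, rubric):
        v = IndicatorValue(indicator_id=9, raw_value=0.1)
        assert score_indicator(v, rubric[9]) == 2

    def test_missing_cell_raises_for_delphi_referral(self, rubric):
        with pytest.raises(MissingDataError):
            score_indicator(IndicatorValue(indicator_id=7), rubric[7])

    def test_alt_value_without_alt_band_rejected(self, rubric):
        v = IndicatorValue(indicator_id=3, alt_raw_value=4.0)
        with pytest.raises(InvalidInputError):
            score_indicator(v, rubric[3])

    def test_mismatched_definition_rejected(self, rubric):
        v = IndicatorValue(indicator_id=1, raw_value=80.0)
        with pytest.raises(InvalidInputError):
            score_indicator(v, rubric[2])


class TestDomainAggregation:
    @pytest.mark.parametrize(
        "scores,total", [((3, 3, 3), 9), ((1, 1, 1), 3), ((3, 2, 2), 7)]
    )
    def test_domain_total(self, scores, total):
        assert domain_total(scores) == total

    @pytest.mark.parametrize("bad", [(0, 1, 2), (1, 2, 4), (1, 2), (1, 2, 3, 3)])
    def test_domain_total_rejects_bad_scores(self, bad):
        with pytest.raises(InvalidScoreError):
            domain_total(bad)

    def test_grade_lookup_matches_enumerated_oracle(self):
        # independent 27-entry lookup built by hand from the grade cut points
        oracle = {}
        for triple in itertools.product((1, 2, 3), repeat=3):
            t = sum(triple)
            oracle[triple] = "A" if t in (8, 9) else ("B" if t in (5, 6, 7) else "C")
        for triple, expected in oracle.items():
            assert grade_from_total(domain_total(triple)) == expected

    @pytest.mark.parametrize("total,grade", [(9, "A"), (8, "A"), (7, "B"), (5, "B"), (4, "C"), (3, "C")])
    def test_grade_cut_points(self, total, grade):
        assert grade_from_total(total) == grade

    @pytest.mark.parametrize("bad", [2, 10, 0, -1])
    def test_grade_rejects_unattainable_totals(self, bad):
        with pytest.raises(InvalidTotalError):
            grade_from_total(bad)


SORTED_RATINGS = ["AAA", "AAB", "AAC", "ABB", "ABC", "ACC", "BBB", "BBC", "BCC", "CCC"]


class TestRatingComposition:
    @pytest.mark.parametrize(
        "grades,rating",
        [(("A", "B", "A"), "AAB"), (("B", "C", "B"), "BBC"), (("C", "C", "C"), "CCC")],
    )
    def test_rating_is_sorted_best_first(self, grades, rating):
        result = overall_rating(grades)
        assert result.rating == rating
        assert result.grades_by_domain == grades  # unsorted order preserved

    @pytest.mark.parametrize(
        "rating,category",
        [
            ("AAA", "excellent"),
            ("AAB", "above_average"),
            ("ABB", "stable"),
            ("BBB", "stable"),
            ("AAC", "critical"),
            ("ABC", "critical"),
            ("BBC", "critical"),
            ("ACC", "failing"),
            ("BCC", "failing"),
            ("CCC", "failing"),
        ],
    )
    def test_category_total_over_all_ten_ratings(self, rating, category):
        assert classify_rating(rating) == category

    @pytest.mark.parametrize("bad", ["BAA", "ABD", "AB", "CBA", "aab"])
    def test_unsorted_or_invalid_rating_rejected(self, bad):
        with pytest.raises(InvalidRatingError):
            classify_rating(bad)

    def test_rating_closure_over_all_score_vectors(self):
        """Every one of the 3^9 score vectors yields a valid sorted rating
        and a defined category."""
        seen = set()
        for vector in itertools.product((1, 2, 3), repeat=9):
            _, rating = rate_scores(vector)
            assert rating.rating in SORTED_RATINGS
            assert rating.category in ("excellent", "above_average", "stable", "critical", "failing")
            seen.add(rating.rating)
        assert seen == set(SORTED_RATINGS)

    def test_monotonicity_raising_one_score_never_hurts(self):
        """Raising any single indicator score never worsens the domain
        grade, the rating string, or the qualitative category."""
        cat_rank = {"excellent": 0, "above_average": 1, "stable": 2, "critical": 3, "failing": 4}
        for vector in itertools.product((1, 2, 3), repeat=9):
            _, base = rate_scores(vector)
            for pos in range(9):
                if vector[pos] == 3:
                    continue
                raised = vector[:pos] + (vector[pos] + 1,) + vector[pos + 1:]
                _, better = rate_scores(raised)
                assert better.rating <= base.rating  # lexicographic: A < B < C
                assert cat_rank[better.category] <= cat_rank[base.category]
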