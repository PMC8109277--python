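"""Nine-indicator rubric: threshold bands, domain grades, overall rating.

The rating framework scores nine health-system indicators on a 1/2/3
rubric, groups them into three domains (general performance, clinical
outcome, equity & sustainability), grades each domain A/B/C from its
three-indicator total, and renders the three grades as a best-first
sorted rating string (``AAA`` … ``CCC``) with a qualitative category.

Band convention
---------------
Published bands are printed as strict outer inequalities (e.g. ``>90`` /
``50-90`` / ``<50``); accordingly the score-3 and score-1 thresholds are
exclusive and the middle band is the closed interval between them, so a
value sitting exactly on a printed boundary scores 2.  One indicator
(financial protection, id 8) has a second, inverted criterion — the
out-of-pocket share of household income, where *lower* is better — and
the two criteria are joined by "or": the more favorable band score wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .errors import (
    InvalidInputError,
    InvalidRatingError,
    InvalidScoreError,
    InvalidTotalError,
    MissingDataError,
)

__all__ = [
    "ThresholdBand",
    "IndicatorDefinition",
    "IndicatorValue",
    "CountryProfile",
    "DomainScore",
    "SystemRating",
    "Rubric",
    "band_score",
    "score_indicator",
    "domain_total",
    "grade_from_total",
    "overall_rating",
    "classify_rating",
    "score_profile",
    "rate_scores",
    "default_rubric",
    "PROVENANCES",
    "CATEGORIES",
    "RATINGS",
]

#: Allowed provenance tags for an indicator value.
PROVENANCES = ("literature", "official", "delphi")

#: The ten sorted three-letter ratings, best first.
RATINGS = (
    "AAA", "AAB", "AAC", "ABB", "ABC", "ACC", "BBB", "BBC", "BCC", "CCC",
)

#: Qualitative categories from best to worst.
CATEGORIES = ("excellent", "above_average", "stable", "critical", "failing")


@dataclass(frozen=True)
class ThresholdBand:
    """Three-band scoring rule for one indicator criterion.

    Parameters
    ----------
    score3_exclusive
        Threshold the value must strictly beat (exceed, or undercut when
        ``higher_is_better`` is False) to score 3.
    score1_exclusive
        Threshold beyond which (on the unfavorable side) the value
        scores 1.  The closed interval between the two thresholds
        scores 2.
    higher_is_better
        Direction of the criterion.  The out-of-pocket arm of the
        financial-protection indicator is the only shipped band with
        ``higher_is_better=False``.
    """

    score3_exclusive: float
    score1_exclusive: float
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        if self.higher_is_better:
            if not self.score1_exclusive <= self.score3_exclusive:
                raise InvalidInputError(
                    "score-1 threshold must not exceed score-3 threshold "
                    f"({self.score1_exclusive} > {self.score3_exclusive})"
                )
        else:
            if not self.score3_exclusive <= self.score1_exclusive:
                raise InvalidInputError(
                    "inverted band requires score-3 threshold <= score-1 "
                    f"threshold ({self.score3_exclusive} > {self.score1_exclusive})"
                )


def band_score(value: float, band: ThresholdBand, *, indicator: str | int = "?") -> int:
    """Map a raw value to a score in {1, 2, 3} under a threshold band.

    The outer thresholds are strict; exactly hitting either printed
    boundary lands in the closed middle band and scores 2.
    """
    if not isinstance(value, (int, float)) or isinstance(value, bool) or not math.isfinite(value):
        raise InvalidInputError(f"indicator {indicator}: raw value {value!r} is not a finite number")
    if band.higher_is_better:
        if value > band.score3_exclusive:
            return 3
        if value < band.score1_exclusive:
            return 1
    else:
        if value < band.score3_exclusive:
            return 3
        if value > band.score1_exclusive:
            return 1
    return 2


@dataclass(frozen=True)
class IndicatorDefinition:
    """One of the nine rubric indicators with its band(s) and unit."""

    id: int
    name: str
    domain: int
    unit: str
    band: ThresholdBand
    alt_band: Optional[ThresholdBand] = None
    alt_unit: Optional[str] = None

    def __post_init__(self) -> None:
        if self.id not in range(1, 10):
            raise InvalidInputError(f"indicator id must be 1-9, got {self.id}")
        expected_domain = (self.id - 1) // 3 + 1
        if self.domain != expected_domain:
            raise InvalidInputError(
                f"indicator {self.id} must sit in domain {expected_domain}, got {self.domain}"
            )
        if self.alt_band is not None and self.id != 8:
            raise InvalidInputError(
                f"only indicator 8 carries an alternative criterion (got one on {self.id})"
            )


@dataclass(frozen=True)
class IndicatorValue:
    """A country's datum for one indicator.

    Either ``raw_value`` (in the indicator's unit) or ``direct_score``
    (a pre-assigned 1/2/3, e.g. a Delphi consensus) must be present;
    ``direct_score`` wins when both are.  ``alt_raw_value`` holds the
    out-of-pocket share for indicator 8 when the primary value is HSA
    penetration.
    """

    indicator_id: int
    raw_value: Optional[float] = None
    alt_raw_value: Optional[float] = None
    direct_score: Optional[int] = None
    provenance: str = "literature"
    source_note: str = ""

    def __post_init__(self) -> None:
        if self.indicator_id not in range(1, 10):
            raise InvalidInputError(f"indicator id must be 1-9, got {self.indicator_id}")
        if self.direct_score is not None and self.direct_score not in (1, 2, 3):
            raise InvalidScoreError(
                f"indicator {self.indicator_id}: direct score must be 1, 2 or 3, "
                f"got {self.direct_score}"
            )
        if self.provenance not in PROVENANCES:
            raise InvalidInputError(
                f"indicator {self.indicator_id}: unknown provenance {self.provenance!r}"
            )

    @property
    def is_missing(self) -> bool:
        """True when the cell has neither a raw value nor a direct score."""
        return self.raw_value is None and self.alt_raw_value is None and self.direct_score is None


def score_indicator(value: IndicatorValue, definition: IndicatorDefinition) -> int:
    """Score one indicator value under its definition.

    A ``direct_score`` (Delphi or official override) takes precedence.
    Otherwise the raw value is banded; for indicator 8, when both the
    HSA-penetration and the out-of-pocket criteria are supplied, the
    more favorable of the two band scores is returned ("or" rule).
    """
    if value.indicator_id != definition.id:
        raise InvalidInputError(
            f"value for indicator {value.indicator_id} scored against definition {definition.id}"
        )
    if value.direct_score is not None:
        return value.direct_score
    scores = []
    if value.raw_value is not None:
        scores.append(band_score(value.raw_value, definition.band, indicator=definition.id))
    if value.alt_raw_value is not None:
        if definition.alt_band is None:
            raise InvalidInputError(
                f"indicator {definition.id} has no alternative criterion for "
                f"alt value {value.alt_raw_value}"
            )
        scores.append(band_score(value.alt_raw_value, definition.alt_band, indicator=definition.id))
    if not scores:
        raise MissingDataError(
            f"indicator {value.indicator_id}: no raw value or direct score; "
            "refer to Delphi panel"
        )
    return max(scores)


def domain_total(scores: Sequence[int]) -> int:
    """Sum three indicator scores into a domain total in [3, 9]."""
    if len(scores) != 3:
        raise InvalidScoreError(f"a domain holds exactly three scores, got {len(scores)}")
    for s in scores:
        if s not in (1, 2, 3):
            raise InvalidScoreError(f"indicator score must be 1, 2 or 3, got {s}")
    return int(sum(scores))


def grade_from_total(total: int) -> str:
    """Grade a domain total: 8-9 -> A, 5-7 -> B, 3-4 -> C."""
    if total not in range(3, 10):
        raise InvalidTotalError(f"domain total must be in [3, 9], got {total}")
    if total >= 8:
        return "A"
    if total >= 5:
        return "B"
    return "C"


@dataclass(frozen=True)
class DomainScore:
    """Per-domain total and letter grade."""

    domain: int
    total: int
    grade: str

    def __post_init__(self) -> None:
        if grade_from_total(self.total) != self.grade:
            raise InvalidTotalError(
                f"domain {self.domain}: grade {self.grade} inconsistent with total {self.total}"
            )


@dataclass(frozen=True)
class SystemRating:
    """Overall rating: per-domain grades, sorted rating string, category."""

    grades_by_domain: tuple[str, str, str]
    rating: str
    category: str


def overall_rating(grades_by_domain: Sequence[str]) -> SystemRating:
    """Compose three domain grades into a sorted rating and category.

    The rating string is the three letters sorted best-first (A before B
    before C); the unsorted per-domain grades are preserved for
    reporting.
    """
    grades = tuple(grades_by_domain)
    if len(grades) != 3 or any(g not in "ABC" for g in grades):
        raise InvalidRatingError(f"grades must be three letters in {{A,B,C}}, got {grades!r}")
    rating = "".join(sorted(grades))
    return SystemRating(grades_by_domain=grades, rating=rating, category=classify_rating(rating))


def classify_rating(rating: str) -> str:
    """Classify a sorted rating string into its qualitative category.

    AAA -> excellent; AAB -> above_average; BBB and ABB -> stable;
    exactly one C -> critical; two or more C -> failing.  Ratings the
    scheme's authors never enumerated (AAC, ABC, ACC) follow the same
    C-count rule.
    """
    if rating not in RATINGS:
        raise InvalidRatingError(
            f"rating must be one of the ten sorted A/B/C strings, got {rating!r}"
        )
    n_c = rating.count("C")
    if n_c >= 2:
        return "failing"
    if n_c == 1:
        return "critical"
    if rating == "AAA":
        return "excellent"
    if rating == "AAB":
        return "above_average"
    return "stable"  # BBB, ABB


@dataclass(frozen=True)
class CountryProfile:
    """A country's nine indicator values plus its expenditure per capita.

    Total health expenditure per capita per year (US$) is the "#10"
    indicator, used only as a ranking tie-break.
    """

    country: str
    values: tuple[IndicatorValue, ...]
    expenditure_per_capita_usd: float

    def __post_init__(self) -> None:
        ids = sorted(v.indicator_id for v in self.values)
        if ids != list(range(1, 10)):
            raise InvalidInputError(
                f"{self.country}: profile must hold exactly one value per indicator 1-9, "
                f"got ids {ids}"
            )
        if not (isinstance(self.expenditure_per_capita_usd, (int, float))
                and math.isfinite(self.expenditure_per_capita_usd)
                and self.expenditure_per_capita_usd >= 0):
            raise InvalidInputError(
                f"{self.country}: expenditure per capita must be a finite number >= 0, "
                f"got {self.expenditure_per_capita_usd!r}"
            )

    def value_for(self, indicator_id: int) -> IndicatorValue:
        for v in self.values:
            if v.indicator_id == indicator_id:
                return v
        raise KeyError(indicator_id)

    def with_value(self, new_value: IndicatorValue) -> "CountryProfile":
        """Return a copy with one indicator value replaced."""
        values = tuple(
            new_value if v.indicator_id == new_value.indicator_id else v for v in self.values
        )
        return replace(self, values=values)


@dataclass(frozen=True)
class Rubric:
    """The full nine-indicator rubric, one definition per id 1-9."""

    indicators: tuple[IndicatorDefinition, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = sorted(d.id for d in self.indicators)
        if ids != list(range(1, 10)):
            raise InvalidInputError(f"rubric must define exactly indicators 1-9, got ids {ids}")

    def __getitem__(self, indicator_id: int) -> IndicatorDefinition:
        for d in self.indicators:
            if d.id == indicator_id:
                return d
        raise KeyError(indicator_id)

    @classmethod
    def from_mapping(cls, doc: Mapping) -> "Rubric":
        defs = []
        for entry in doc["indicators"]:
            band = ThresholdBand(**entry["band"])
            alt = entry.get("alt_band")
            defs.append(
                IndicatorDefinition(
                    id=int(entry["id"]),
                    name=str(entry["name"]),
                    domain=int(entry["domain"]),
                    unit=str(entry["unit"]),
                    band=band,
                    alt_band=ThresholdBand(**alt) if alt else None,
                    alt_unit=entry.get("alt_unit"),
                )
            )
        return cls(indicators=tuple(defs))

    @classmethod
    def from_yaml(cls, path) -> "Rubric":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def default_rubric() -> Rubric:
    """The packaged rubric reproducing the published band thresholds."""
    text = resources.files("ninescore.data").joinpath("rubric.yaml").read_text(encoding="utf-8")
    return Rubric.from_mapping(yaml.safe_load(text))


def score_profile(profile: CountryProfile, rubric: Optional[Rubric] = None) -> tuple[int, ...]:
    """Score all nine indicators of a profile; returns scores for ids 1..9."""
    rubric = rubric or default_rubric()
    scores = []
    for i in range(1, 10):
        value = profile.value_for(i)
        try:
            scores.append(score_indicator(value, rubric[i]))
        except MissingDataError:
            raise MissingDataError(
                f"({profile.country}, indicator {i}): no raw value or direct score; "
                "refer to Delphi panel"
            ) from None
    return tuple(scores)


def rate_scores(scores: Sequence[int]) -> tuple[tuple[DomainScore, DomainScore, DomainScore], SystemRating]:
    """Aggregate nine indicator scores into domain scores and an overall rating."""
    if len(scores) != 9:
        raise InvalidScoreError(f"expected nine indicator scores, got {len(scores)}")
    domains = []
    for d in range(3):
        total = domain_total(scores[3 * d: 3 * d + 3])
        domains.append(DomainScore(domain=d + 1, total=total, grade=grade_from_total(total)))
    rating = overall_rating(tuple(ds.grade for ds in domains))
    return (domains[0], domains[1], domains[2]), rating
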