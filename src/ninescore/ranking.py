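"""Ordering rated health systems into numeric ranks.

The rating class dominates absolutely: a system rated ``ABB`` outranks
every ``BBB`` system no matter how much either spends.  Within one
rating class the "#10" indicator — total health expenditure per capita
per year (US$) — breaks ties, higher expenditure first.  Exact ties on
expenditure fall back to the sum of the three domain totals (higher
first) and finally to country name, so the order is a deterministic
total order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .errors import InvalidInputError, InvalidRatingError
from .rubric import (
    RATINGS,
    CountryProfile,
    Rubric,
    SystemRating,
    rate_scores,
    score_profile,
)

__all__ = ["RatedSystem", "RankedTable", "rating_key", "rank_systems", "rate_systems"]


def rating_key(rating: str) -> str:
    """Orderable key for a sorted rating string; smaller sorts better.

    With A < B < C, plain lexicographic comparison of the sorted rating
    strings already orders better systems first (AAA < AAB < … < CCC),
    so the key is the validated string itself.
    """
    if rating not in RATINGS:
        raise InvalidRatingError(
            f"rating must be one of the ten sorted A/B/C strings, got {rating!r}"
        )
    return rating


@dataclass(frozen=True)
class RatedSystem:
    """One health system after scoring: rating, totals, expenditure."""

    country: str
    rating: SystemRating
    domain_totals: tuple[int, int, int]
    expenditure_per_capita_usd: float
    indicator_scores: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        from .rubric import grade_from_total  # local to avoid re-export noise

        grades = tuple(grade_from_total(t) for t in self.domain_totals)
        if grades != self.rating.grades_by_domain:
            raise InvalidInputError(
                f"{self.country}: rating {self.rating.grades_by_domain} inconsistent "
                f"with domain totals {self.domain_totals}"
            )
        if self.expenditure_per_capita_usd < 0:
            raise InvalidInputError(
                f"{self.country}: negative expenditure {self.expenditure_per_capita_usd}"
            )


@dataclass(frozen=True)
class RankedTable:
    """Ordered list of (rank, system) with ranks exactly 1..n."""

    entries: tuple[tuple[int, RatedSystem], ...]

    def __post_init__(self) -> None:
        ranks = [r for r, _ in self.entries]
        if ranks != list(range(1, len(ranks) + 1)):
            raise InvalidInputError(f"ranks must be exactly 1..n, got {ranks}")

    @property
    def systems(self) -> tuple[RatedSystem, ...]:
        return tuple(s for _, s in self.entries)

    def rank_of(self, country: str) -> int:
        for rank, system in self.entries:
            if system.country == country:
                return rank
        raise KeyError(country)


def rank_systems(
    systems: Sequence[RatedSystem],
    *,
    pinned: Optional[Mapping[str, int]] = None,
) -> RankedTable:
    """Assign numeric ranks 1..n to rated systems.

    Sort order: rating class first (better letters first), then
    descending expenditure per capita, then descending sum of domain
    totals, then country name.

    ``pinned`` optionally maps country names to priorities that override
    the expenditure tie-break *within* a rating class (lower priority
    number first, pinned countries before un-pinned ones).  This exists
    because an externally imposed within-class order may disagree with
    the expenditure rule; the rating class itself can never be
    overridden.
    """
    if not systems:
        raise InvalidInputError("cannot rank an empty list of systems")
    names = [s.country for s in systems]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise InvalidInputError(f"duplicate country names: {dupes}")
    pinned = pinned or {}

    def key(system: RatedSystem):
        return (
            rating_key(system.rating.rating),
            pinned.get(system.country, float("inf")),
            -system.expenditure_per_capita_usd,
            -sum(system.domain_totals),
            system.country,
        )

    ordered = sorted(systems, key=key)
    return RankedTable(entries=tuple((i + 1, s) for i, s in enumerate(ordered)))


def rate_systems(
    profiles: Sequence[CountryProfile], rubric: Optional[Rubric] = None
) -> list[RatedSystem]:
    """Score and grade a list of country profiles into rated systems."""
    rated = []
    for profile in profiles:
        scores = score_profile(profile, rubric)
        domains, rating = rate_scores(scores)
        rated.append(
            RatedSystem(
                country=profile.country,
                rating=rating,
                domain_totals=tuple(d.total for d in domains),
                expenditure_per_capita_usd=profile.expenditure_per_capita_usd,
                indicator_scores=scores,
            )
        )
    return rated
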