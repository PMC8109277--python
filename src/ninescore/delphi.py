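"""Delphi consensus aggregation for missing indicator cells.

When no published value exists for a (country, indicator) cell, a panel
of public-health experts votes a score in {1, 2, 3}.  The modal vote is
adopted; a frequency tie resolves to the most favorable (highest) tied
score.  The agreement percentage — the adopted score's share of the
votes — doubles as a reliability measure: unanimous (100%) cells are the
most reliable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Collection, Iterable, Sequence

from .errors import ConflictError, InvalidScoreError, NoResponsesError
from .rubric import CountryProfile, IndicatorValue

__all__ = ["DelphiBallot", "DelphiConsensus", "consensus", "fill_missing"]


@dataclass(frozen=True)
class DelphiBallot:
    """Expert votes for one (country, indicator) cell."""

    country: str
    indicator_id: int
    votes: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.votes:
            raise NoResponsesError(
                f"({self.country}, indicator {self.indicator_id}): ballot has no votes"
            )
        for v in self.votes:
            if v not in (1, 2, 3):
                raise InvalidScoreError(
                    f"({self.country}, indicator {self.indicator_id}): vote must be "
                    f"1, 2 or 3, got {v}"
                )


@dataclass(frozen=True)
class DelphiConsensus:
    """Adopted score for one cell with its agreement percentage."""

    country: str
    indicator_id: int
    adopted_score: int
    agreement_pct: float
    unanimous: bool


def consensus(ballot: DelphiBallot) -> DelphiConsensus:
    """Aggregate a ballot: modal vote, favorable tie-break, agreement %.

    The adopted score is the most frequent vote; when two or three
    scores tie in frequency the highest tied score is adopted.  The
    agreement percentage is the adopted score's vote share, rounded to
    one decimal place.
    """
    counts = Counter(ballot.votes)
    top = max(counts.values())
    adopted = max(score for score, n in counts.items() if n == top)
    agreement = round(100.0 * counts[adopted] / len(ballot.votes), 1)
    return DelphiConsensus(
        country=ballot.country,
        indicator_id=ballot.indicator_id,
        adopted_score=adopted,
        agreement_pct=agreement,
        unanimous=len(counts) == 1,
    )


def fill_missing(
    profiles: Sequence[CountryProfile],
    consensuses: Iterable[DelphiConsensus],
    *,
    override: Collection[tuple[str, int]] = (),
) -> list[CountryProfile]:
    """Fill missing indicator cells from Delphi consensus scores.

    Each consensus sets ``direct_score`` (provenance ``delphi``) on the
    matching cell.  Cells that already hold a literature/official value
    are never silently overwritten: a consensus targeting such a cell
    raises :class:`~ninescore.errors.ConflictError` unless the
    (country, indicator) pair is listed in ``override``.

    Consensuses for countries absent from ``profiles`` are ignored, so a
    full survey table can be applied to a subset of countries.
    """
    by_country = {p.country: p for p in profiles}
    override = set(override)
    for cons in consensuses:
        profile = by_country.get(cons.country)
        if profile is None:
            continue
        current = profile.value_for(cons.indicator_id)
        if not current.is_missing and (cons.country, cons.indicator_id) not in override:
            raise ConflictError(
                f"({cons.country}, indicator {cons.indicator_id}) already holds a "
                f"{current.provenance} value; pass override to replace it"
            )
        filled = IndicatorValue(
            indicator_id=cons.indicator_id,
            direct_score=cons.adopted_score,
            provenance="delphi",
            source_note=f"Delphi consensus, agreement {cons.agreement_pct}%",
        )
        by_country[cons.country] = profile.with_value(filled)
    return [by_country[p.country] for p in profiles]
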