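"""Worked-example fixtures and a synthetic country-profile generator.

The packaged fixtures carry the published 11-country worked example:
per-indicator scores with expenditure per capita, and the Delphi survey
consensus cells.  The synthetic generator emits seeded pseudo-random
country profiles spanning all three score bands of every indicator,
optionally with values pinned exactly on band boundaries (to stress the
boundary convention) and with missing cells paired with simulated
expert ballots (to exercise the Delphi fill-in path).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

import numpy as np
import pandas as pd

from .delphi import DelphiBallot, DelphiConsensus
from .errors import InvalidInputError
from .rubric import CountryProfile, IndicatorValue, Rubric, default_rubric

__all__ = [
    "table5_fixture",
    "table6_fixture",
    "SyntheticSpec",
    "SyntheticData",
    "generate_profiles",
]


def _data_text(name: str) -> str:
    return resources.files("ninescore.data").joinpath(name).read_text(encoding="utf-8")


def table5_fixture() -> list[CountryProfile]:
    """The 11-country worked example: direct scores and expenditures."""
    from io import StringIO

    df = pd.read_csv(StringIO(_data_text("table5.csv")))
    profiles = []
    for _, row in df.iterrows():
        values = tuple(
            IndicatorValue(indicator_id=i, direct_score=int(row[f"ind{i}_score"]))
            for i in range(1, 10)
        )
        profiles.append(
            CountryProfile(
                country=str(row["country"]),
                values=values,
                expenditure_per_capita_usd=float(row["expenditure_per_capita_usd"]),
            )
        )
    return profiles


def table6_fixture() -> list[DelphiConsensus]:
    """The Delphi survey consensus cells, one record per surveyed cell."""
    from io import StringIO

    df = pd.read_csv(StringIO(_data_text("table6.csv")))
    return [
        DelphiConsensus(
            country=str(row["country"]),
            indicator_id=int(row["indicator_id"]),
            adopted_score=int(row["adopted_score"]),
            agreement_pct=float(row["agreement_pct"]),
            unanimous=float(row["agreement_pct"]) == 100.0,
        )
        for _, row in df.iterrows()
    ]


#: Plausible raw-value range per indicator, wide enough that every band
#: has positive width.  Units match the rubric (percentages, years,
#: index points, % of GDP).
PLAUSIBLE_RANGES: dict[int, tuple[float, float]] = {
    1: (10.0, 100.0),   # UHC effective coverage, %
    2: (40.0, 90.0),    # female HALE at birth, years
    3: (10.0, 150.0),   # surgical procedures vs. minimum needed, %
    4: (20.0, 100.0),   # overall HAQ index
    5: (20.0, 100.0),   # HAQ index for Hodgkin lymphoma
    6: (80.0, 100.0),   # 30-day MI survival, %
    7: (10.0, 100.0),   # accredited tertiary-care hospitals, %
    8: (0.0, 100.0),    # HSA penetration, %
    9: (0.0, 0.5),      # government health-research funding, % of GDP
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters for the synthetic profile generator.

    band_edge_fraction: share of generated cells whose raw value sits
    exactly on a band boundary (such values score 2 under the closed
    middle band).  missing_fraction: share of cells left blank, each
    paired with a simulated ballot of ``panel_size`` expert votes.
    Generation is a pure function of the spec: the same spec always
    yields the same data.
    """

    n_countries: int
    seed: int
    band_edge_fraction: float = 0.0
    missing_fraction: float = 0.0
    panel_size: int = 7

    def __post_init__(self) -> None:
        if self.n_countries < 0:
            raise InvalidInputError(f"n_countries must be >= 0, got {self.n_countries}")
        for name in ("band_edge_fraction", "missing_fraction"):
            frac = getattr(self, name)
            if not 0.0 <= frac <= 1.0:
                raise InvalidInputError(f"{name} must be in [0, 1], got {frac}")
        if self.panel_size < 1:
            raise InvalidInputError(f"panel_size must be >= 1, got {self.panel_size}")


class SyntheticData(NamedTuple):
    """Generator output: profiles, ballots for missing cells, and the
    generator's own intended score per generated raw value (an oracle
    for band scoring)."""

    profiles: list[CountryProfile]
    ballots: list[DelphiBallot]
    intended_scores: dict[tuple[str, int], int]


def _draw_in_band(rng: np.random.Generator, lo: float, hi: float,
                  band3: float, band1: float, target: int) -> float:
    """Draw a raw value strictly inside the target band's interval."""
    if target == 3:
        a, b = band3, hi
    elif target == 1:
        a, b = lo, band1
    else:
        a, b = band1, band3
    # keep clear of the exclusive edges
    u = rng.random()
    return a + (b - a) * (0.01 + 0.98 * u)


def generate_profiles(spec: SyntheticSpec, rubric: Rubric | None = None) -> SyntheticData:
    """Generate seeded synthetic country profiles and Delphi ballots.

    Each non-missing cell picks a target score uniformly from {1, 2, 3}
    and draws a raw value inside the matching band, so all three bands
    occur for every indicator with positive probability.  Missing cells
    receive no value; a simulated ballot (votes clustered on a latent
    true score) is emitted for each.
    """
    rubric = rubric or default_rubric()
    rng = np.random.default_rng(spec.seed)
    profiles: list[CountryProfile] = []
    ballots: list[DelphiBallot] = []
    intended: dict[tuple[str, int], int] = {}

    for c in range(spec.n_countries):
        country = f"Synthetica-{c:03d}"
        values = []
        for i in range(1, 10):
            if rng.random() < spec.missing_fraction:
                values.append(IndicatorValue(indicator_id=i, source_note="missing"))
                true_score = int(rng.integers(1, 4))
                votes = tuple(
                    true_score if rng.random() < 0.7 else int(rng.integers(1, 4))
                    for _ in range(spec.panel_size)
                )
                ballots.append(DelphiBallot(country=country, indicator_id=i, votes=votes))
                continue
            band = rubric[i].band
            lo, hi = PLAUSIBLE_RANGES[i]
            if rng.random() < spec.band_edge_fraction:
                # exactly on a printed boundary: closed middle band -> score 2
                value = band.score3_exclusive if rng.random() < 0.5 else band.score1_exclusive
                target = 2
            else:
                target = int(rng.integers(1, 4))
                value = float(
                    _draw_in_band(rng, lo, hi, band.score3_exclusive, band.score1_exclusive, target)
                )
            values.append(IndicatorValue(indicator_id=i, raw_value=float(value)))
            intended[(country, i)] = target
        expenditure = float(np.round(rng.uniform(50.0, 11000.0), 1))
        profiles.append(
            CountryProfile(
                country=country,
                values=tuple(values),
                expenditure_per_capita_usd=expenditure,
            )
        )
    return SyntheticData(profiles=profiles, ballots=ballots, intended_scores=intended)
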