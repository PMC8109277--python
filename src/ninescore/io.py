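"""Readers and writers for country-profile tables, Delphi votes, reports.

Input dialect: UTF-8 CSV with a header row and decimal points (JSON is
accepted as an array of flat records with the same keys).  Profile
columns: ``country``, ``expenditure_per_capita_usd``, and per indicator
``i`` any of ``ind{i}_score``, ``ind{i}_raw``, ``ind{i}_provenance``,
``ind{i}_note``; indicator 8 additionally accepts ``ind8_alt_raw`` for
its out-of-pocket criterion.  A row may mix raw values and direct
scores; the direct score takes precedence when both are present.

Malformed cells are reported with (row, column) coordinates and a
machine-readable error code.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .delphi import DelphiBallot, DelphiConsensus
from .errors import NinescoreError, TableFormatError
from .ranking import RankedTable
from .rubric import CountryProfile, IndicatorValue, PROVENANCES

__all__ = [
    "read_country_table",
    "write_country_table",
    "read_vote_table",
    "write_consensus_table",
    "write_rating_report",
]

_IND_COL = re.compile(r"^ind([1-9])_(score|raw|alt_raw|provenance|note)$")

REPORT_FORMATS = ("tsv", "json", "markdown")


def _load_records(path: Path) -> pd.DataFrame:
    if path.suffix.lower() == ".json":
        with open(path, "r", encoding="utf-8") as fh:
            records = json.load(fh)
        return pd.DataFrame.from_records(records)
    return pd.read_csv(path, encoding="utf-8", float_precision="round_trip")


def _cell(row: pd.Series, col: str):
    if col not in row.index:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)) or (isinstance(v, str) and not v.strip()):
        return None
    return v


def read_country_table(path) -> list[CountryProfile]:
    """Read and validate country profiles from a CSV or JSON table.

    Returns an empty list (with no error) for a table with a header but
    no rows.  Raises :class:`TableFormatError` naming the (row, column)
    of the first malformed cell, or on duplicate countries and unknown
    indicator columns.
    """
    path = Path(path)
    try:
        df = _load_records(path)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    known = {"country", "expenditure_per_capita_usd"}
    for col in df.columns:
        if col in known or _IND_COL.match(str(col)):
            continue
        raise TableFormatError(f"{path.name}: unknown column {col!r}")
    for required in ("country", "expenditure_per_capita_usd"):
        if required not in df.columns:
            raise TableFormatError(f"{path.name}: missing required column {required!r}")

    profiles: list[CountryProfile] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # 1-based plus header line
        country = str(_cell(row, "country") or "").strip()
        if not country:
            raise TableFormatError(f"{path.name} row {rowno}: empty country name")
        if country in seen:
            raise TableFormatError(f"{path.name} row {rowno}: duplicate country {country!r}")
        seen.add(country)
        values = []
        for i in range(1, 10):
            kwargs = {"indicator_id": i}
            raw = _cell(row, f"ind{i}_raw")
            if raw is not None:
                kwargs["raw_value"] = _number(raw, path, rowno, f"ind{i}_raw")
            if i == 8:
                alt = _cell(row, "ind8_alt_raw")
                if alt is not None:
                    kwargs["alt_raw_value"] = _number(alt, path, rowno, "ind8_alt_raw")
            score = _cell(row, f"ind{i}_score")
            if score is not None:
                s = _number(score, path, rowno, f"ind{i}_score")
                if s not in (1, 2, 3):
                    raise TableFormatError(
                        f"{path.name} row {rowno} column ind{i}_score: "
                        f"score must be 1, 2 or 3, got {score!r}"
                    )
                kwargs["direct_score"] = int(s)
            prov = _cell(row, f"ind{i}_provenance")
            if prov is not None:
                if str(prov) not in PROVENANCES:
                    raise TableFormatError(
                        f"{path.name} row {rowno} column ind{i}_provenance: "
                        f"unknown provenance {prov!r}"
                    )
                kwargs["provenance"] = str(prov)
            note = _cell(row, f"ind{i}_note")
            if note is not None:
                kwargs["source_note"] = str(note)
            values.append(IndicatorValue(**kwargs))
        exp = _number(_cell(row, "expenditure_per_capita_usd"), path, rowno,
                      "expenditure_per_capita_usd")
        if exp is None or exp < 0:
            raise TableFormatError(
                f"{path.name} row {rowno}: expenditure must be a number >= 0, got {exp!r}"
            )
        profiles.append(
            CountryProfile(country=country, values=tuple(values),
                           expenditure_per_capita_usd=float(exp))
        )
    return profiles


def _number(value, path: Path, rowno: int, col: str) -> float:
    if value is None:
        raise TableFormatError(f"{path.name} row {rowno} column {col}: missing value")
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise TableFormatError(
            f"{path.name} row {rowno} column {col}: not a number: {value!r}"
        ) from None
    if not math.isfinite(out):
        raise TableFormatError(f"{path.name} row {rowno} column {col}: non-finite value")
    return out


def write_country_table(profiles: Sequence[CountryProfile], path) -> None:
    """Write profiles to CSV in the same dialect ``read_country_table`` reads."""
    rows = []
    for p in profiles:
        row: dict = {"country": p.country}
        for i in range(1, 10):
            v = p.value_for(i)
            if v.raw_value is not None:
                row[f"ind{i}_raw"] = v.raw_value
            if v.alt_raw_value is not None:
                row[f"ind{i}_alt_raw"] = v.alt_raw_value
            if v.direct_score is not None:
                row[f"ind{i}_score"] = v.direct_score
            if v.provenance != "literature":
                row[f"ind{i}_provenance"] = v.provenance
            if v.source_note:
                row[f"ind{i}_note"] = v.source_note
        row["expenditure_per_capita_usd"] = p.expenditure_per_capita_usd
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def read_vote_table(path) -> list[DelphiBallot]:
    """Read Delphi votes (columns expert_id, country, indicator_id, vote)
    and group them into one ballot per (country, indicator) cell."""
    path = Path(path)
    try:
        df = _load_records(path)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    required = {"expert_id", "country", "indicator_id", "vote"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path.name}: missing vote columns {sorted(missing)}")
    ballots = []
    for (country, ind), group in df.groupby(["country", "indicator_id"], sort=True):
        votes = tuple(int(v) for v in group["vote"])
        ballots.append(DelphiBallot(country=str(country), indicator_id=int(ind), votes=votes))
    return ballots


def write_consensus_table(consensuses: Sequence[DelphiConsensus], fmt: str = "csv") -> str:
    """Render consensus records as CSV or JSON text."""
    rows = [
        {
            "country": c.country,
            "indicator_id": c.indicator_id,
            "adopted_score": c.adopted_score,
            "agreement_pct": c.agreement_pct,
            "unanimous": c.unanimous,
        }
        for c in consensuses
    ]
    if fmt == "json":
        return json.dumps(rows, indent=2)
    if fmt == "csv":
        return pd.DataFrame(
            rows, columns=["country", "indicator_id", "adopted_score",
                           "agreement_pct", "unanimous"]
        ).to_csv(index=False)
    raise TableFormatError(f"unsupported consensus format {fmt!r}")


def _report_rows(table: RankedTable) -> list[dict]:
    rows = []
    for rank, system in table.entries:
        row: dict = {"rank": rank, "country": system.country}
        scores = system.indicator_scores or ()
        for i, s in enumerate(scores, start=1):
            row[f"ind{i}"] = s
        for d, total in enumerate(system.domain_totals, start=1):
            row[f"domain{d}_total"] = total
        row["rating"] = system.rating.rating
        row["category"] = system.rating.category
        row["expenditure_per_capita_usd"] = round(system.expenditure_per_capita_usd, 1)
        rows.append(row)
    return rows


def write_rating_report(table: RankedTable, fmt: str = "tsv") -> str:
    """Render a ranked table as TSV, JSON, or a Markdown table.

    One row per system: nine indicator scores, three domain totals,
    rating, category, expenditure (one decimal), rank.
    """
    if fmt not in REPORT_FORMATS:
        raise TableFormatError(
            f"unsupported report format {fmt!r}; choose from {REPORT_FORMATS}"
        )
    rows = _report_rows(table)
    if fmt == "json":
        return json.dumps(rows, indent=2)
    df = pd.DataFrame(rows)
    df["expenditure_per_capita_usd"] = df["expenditure_per_capita_usd"].map(
        lambda x: f"{x:.1f}"
    )
    if fmt == "tsv":
        return df.to_csv(sep="\t", index=False)
    # markdown
    headers = list(df.columns)
    lines = ["| " + " | ".join(headers) + " |",
             "| " + " | ".join("---" for _ in headers) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(row[h]) for h in headers) + " |")
    return "\n".join(lines) + "\n"
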