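# ninescore

A scoring and ranking engine for the "nine plus one" multidimensional
health-system rating framework, for health-policy analysts and
population-health researchers who need a simple, reproducible rubric
for comparing national health systems.

## The framework

Nine outcome indicators are grouped into three domains:

| Domain | Indicators |
|---|---|
| I — General performance | UHC effective coverage (%); female HALE at birth (years); surgical procedures performed as % of the minimum needed |
| II — Clinical outcome | Overall HAQ index; HAQ index for Hodgkin lymphoma; 30-day survival after acute MI (%) |
| III — Equity & sustainability | Accredited tertiary-care hospitals (%); financial protection (HSA penetration **or** out-of-pocket share of household income, whichever is more favorable); government health-research funding (% of GDP) |

Each indicator is scored on a three-level threshold band — e.g. an
overall HAQ index **>90** scores 3, **50–90** scores 2, **<50** scores 1.
The outer thresholds are strict, so a value sitting exactly on a printed
boundary falls in the closed middle band and scores 2.  The
out-of-pocket arm of the financial-protection indicator is inverted
(<5% of household income scores 3, >7.5% scores 1).

The three scores in a domain sum to a total in [3, 9], graded

- **A** for a total of 8–9, **B** for 5–7, **C** for 3–4.

The three domain grades, sorted best-first, form the overall rating
(AAA … CCC) with a qualitative category: AAA *excellent*, AAB *above
average*, ABB/BBB *stable*, one C *critical*, two or more C *failing*.
Systems are ranked by rating class first; within one rating class the
"#10" indicator — total health expenditure per capita per year (US$) —
breaks ties, higher expenditure first.

Missing indicator cells are filled by a Delphi survey: each expert on a
panel votes a score in {1, 2, 3}, the modal vote is adopted (frequency
ties resolve to the most favorable score), and the adopted score's vote
share is reported as the agreement percentage.

## Worked example

The package ships the published 11-country worked example as a fixture:

```sh
ninescore fixtures export --dest fx
ninescore rank --input fx/worked_example_profiles.csv
```

```text
rank	country	rating	expenditure_per_capita_usd
1	Switzerland	AAB	9956.3
2	Germany	AAB	5033.5
3	France	AAB	4379.9
4	Japan	AAB	4169.0
5	Singapore	ABB	2618.7
6	UK	BBB	3858.7
7	USA	BBC	10246.1
8	Russia	BBC	585.9
9	China	BBC	440.8
10	Brazil	BCC	928.8
11	India	CCC	69.3
```

No system reaches AAA.  The USA has the highest expenditure in the
table yet ranks 7: its BBC rating (critical — one C domain) is compared
before the expenditure tie-break ever applies.  Within the BBC class
the expenditure tie-break orders USA, Russia, China.  Note that the
published table lists France second and Germany third even though
Germany's printed expenditure is higher; the engine applies the stated
within-class rule (which puts Germany second), and `rank_systems`
accepts a `pinned` priority map to reproduce an externally imposed
within-class order (see `docs/methods.md`).

The same pipeline is available as a library:

```python
import ninescore as ns

profiles = ns.table5_fixture()
table = ns.rank_systems(ns.rate_systems(profiles))
print(table.rank_of("USA"))           # 7
print(ns.overall_rating(("B", "C", "B")).rating)  # 'BBC'
```

`ninescore report --format markdown` renders the full table (indicator
scores, domain totals, rating, category, expenditure, rank), and
`ninescore delphi --votes votes.csv` aggregates a vote table into
consensus scores with agreement percentages.

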