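# Methods

## Model

The rating engine implements a rule-based composite of nine indicators
in three domains.  Every indicator carries a three-band threshold
rubric mapping a raw value to a score in {1, 2, 3}; the three scores of
a domain sum to a total in [3, 9], graded A (8–9), B (5–7) or C (3–4);
the three domain grades, sorted best-first with A < B < C, form the
overall rating string; a qualitative category is a total function of
the rating.  Ranking sorts systems by rating class and breaks ties
within a class by total health expenditure per capita per year
(descending).  There is no weighting beyond the uniform 1/2/3 rubric
and no statistical model: the contribution of the framework is the
rubric itself, so every rule is implemented explicitly and verified by
enumeration (3^9 score vectors, 27 domain triples, all ballots of size
≤ 7) rather than by sampling.

The underlying indices (UHC effective coverage, HALE, HAQ,
surgical-need denominators) are *inputs*; this package does not compute
them.

## Band-boundary convention

The published bands use strict outer inequalities (">90 / 50–90 /
<50"), which leaves exact boundary membership unstated.  The engine
treats both outer thresholds as exclusive and the middle band as the
closed interval between them: a value of exactly 90 (or exactly 50)
scores 2.  This is the only reading consistent with both printed strict
inequalities, and it is stress-tested by the synthetic generator's
`band_edge_fraction` parameter, which pins raw values exactly on
boundaries.  Raw values are banded at full precision; no rounding is
applied before comparison.

## The financial-protection indicator (id 8)

This is the only indicator with two criteria, joined by "or": HSA
penetration (higher is better) or the out-of-pocket share of household
income (lower is better; <5% scores 3, >7.5% scores 1).  When both are
supplied the engine returns the more favorable band score.  The
inverted direction is a flag on the band type rather than a separate
type, so the same banding code and boundary convention apply.

## Score precedence and provenance

An indicator value may carry a raw value, a pre-assigned direct score,
or both.  A direct score — typically a Delphi consensus or an official
assessment — always takes precedence over banding the raw value, and
its provenance (`literature`, `official`, `delphi`) is recorded.  A
cell with neither raises a missing-data error naming the (country,
indicator) pair, which is the signal to refer the cell to a Delphi
panel.  `fill_missing` never silently overwrites an existing value: a
consensus targeting a populated cell is a conflict error unless the
cell is explicitly listed for override.

## Rating categories

The category map is: AAA → excellent, AAB → above average, ABB and
BBB → stable, exactly one C → critical, two or more C → failing.  The
source enumeration omits AAC, ABC and ACC (they do not occur in the
worked example); the engine classifies them by C-count, which is the
unique extension consistent with the enumerated cases and keeps the
category monotone in the grades (verified exhaustively: raising any
single indicator score never worsens the grade, rating, or category).

## Ranking rule and the within-class override

Rank order is: rating class (lexicographic on the sorted rating
string), then descending expenditure per capita, then — for exact
ties, on which the framework is silent — descending sum of the three
domain totals, then country name.  The last two keys are a
determinism choice of this package so that ranking is a total order
and idempotent.

The worked example prints France second and Germany third although
Germany's printed expenditure (5033.5) exceeds France's (4379.9),
contradicting the stated within-class rule.  The engine implements the
rule as stated; `rank_systems(..., pinned={...})` accepts a priority
map that overrides the tie-break *within* a rating class (pinned
countries order by their priority and precede un-pinned ones in the
same class) for reproducing an externally imposed order.  The rating
class itself can never be overridden.

## Delphi aggregation

The adopted score is the modal vote; an exact frequency tie resolves
to the highest (most favorable) tied score.  Agreement is the adopted
score's vote share, rounded to one decimal place to match the reported
format.  Unanimity is exact (all votes equal); with n voters the
attainable agreement values are multiples of 100/n, which with the
7-member panels of the worked example yields exactly
{57.1, 71.4, 85.7, 100.0}.  Panel size is treated as data — the engine
takes ballots as given and assumes nothing about response rates.
Near-ties are not special-cased: anything short of an exact frequency
tie is an ordinary majority.

## Synthetic data generator

`generate_profiles(SyntheticSpec)` emits seeded pseudo-random country
profiles for property testing.  Per cell it picks a target score
uniformly from {1, 2, 3} and draws a raw value strictly inside the
matching band (intersected with a plausible range per indicator:
UHC coverage 10–100%, HALE 40–90 years, surgical ratio 10–150%, HAQ
20–100, MI survival 80–100%, accreditation 10–100%, HSA penetration
0–100%, research funding 0–0.5% of GDP), recording the target as an
oracle for the banding code.  `band_edge_fraction` instead pins the
value exactly on a boundary (intended score 2); `missing_fraction`
leaves cells blank and pairs each with a simulated ballot of
`panel_size` votes clustered (probability 0.7) on a latent true score.
Expenditure is uniform on 50–11000 US$.  Generation is a pure function
of the spec; NumPy's seeded default generator provides stability
within a release.

What the generator does **not** emulate: correlation among indicators
within a country (rich countries score high across the board in real
data), measurement error in the underlying indices, or non-response
structure in expert panels.  Passing tests therefore demonstrate the
correctness of the scoring/ranking/aggregation rules, not the
real-world behavior of the indices feeding them.

## Numerical and degenerate-input choices

- Non-finite raw values (NaN, ±inf) are rejected, never banded.
- Domain totals outside [3, 9], scores outside {1, 2, 3}, unsorted
  rating strings, empty ballots, empty system lists, duplicate country
  names and negative expenditures all raise typed errors with
  machine-readable codes.
- An empty input table (no rows) reads as an empty profile list, not
  an error.
- CSV round-trips are lossless: floats are written at shortest
  round-trip precision and parsed with round-trip float precision.
- Expenditure is assumed to be one consistent US$ series across the
  compared systems; no currency or purchasing-power adjustment.

## Problem sizes

All checks run at desk scale: the worked example is 11 systems, the
exhaustive enumerations cover 19 683 score vectors, 27 domain triples
and 120 ballot multisets, and the property suites use up to a few
hundred synthetic countries.  The full test suite runs in a few
seconds on one CPU.

## Known limitations

- The rubric thresholds are fixed configuration; the engine validates
  but does not derive them.
- Indicator 3's region-specific surgical-need denominator is the
  caller's responsibility: the expected raw value is already the
  performed/needed ratio in percent.
- Delphi reliability is expressed only as the agreement percentage; no
  chance-corrected inter-rater statistic is computed.
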