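# Default nine-indicator rubric: band thresholds as published.
# Outer thresholds are exclusive; the closed middle band scores 2.
indicators:
  - id: 1
    name: UHC effective coverage
    domain: 1
    unit: "% of population"
    band: {score3_exclusive: 90, score1_exclusive: 50}
  - id: 2
    name: Female HALE at birth
    domain: 1
    unit: years
    band: {score3_exclusive: 70, score1_exclusive: 50}
  - id: 3
    name: Surgical procedures performed as % of minimum needed
    domain: 1
    unit: "% (region-specific denominator)"
    band: {score3_exclusive: 90, score1_exclusive: 50}
  - id: 4
    name: Overall HAQ index
    domain: 2
    unit: index points (0-100)
    band: {score3_exclusive: 90, score1_exclusive: 50}
  - id: 5
    name: HAQ index for Hodgkin lymphoma
    domain: 2
    unit: index points (0-100)
    band: {score3_exclusive: 90, score1_exclusive: 50}
  - id: 6
    name: 30-day survival of patients hospitalized with acute MI
    domain: 2
    unit: "% of patients"
    band: {score3_exclusive: 95, score1_exclusive: 90}
  - id: 7
    name: Accredited hospitals providing tertiary care
    domain: 3
    unit: "% of hospitals"
    band: {score3_exclusive: 90, score1_exclusive: 50}
  - id: 8
    name: Financial protection, health care equity and funding sustainability
    domain: 3
    unit: "% of population covered by HSAs"
    band: {score3_exclusive: 90, score1_exclusive: 50}
    # Out-of-pocket arm: lower is better; <5% of household income scores 3,
    # >7.5% scores 1.  Joined to the HSA arm by "or" (most favorable wins).
    alt_unit: "% of household income spent out of pocket"
    alt_band: {score3_exclusive: 5, score1_exclusive: 7.5, higher_is_better: false}
  - id: 9
    name: Government funding for health research
    domain: 3
    unit: "% of GDP"
    band: {score3_exclusive: 0.2, score1_exclusive: 0.05}
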