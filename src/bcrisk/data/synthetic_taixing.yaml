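# Synthetic Taixing-like region.
#
# The incidence and mortality tables are SYNTHETIC: plausible age patterns
# for breast-cancer incidence and non-breast-cancer mortality among women in
# rural eastern China circa 2015, NOT official registry figures (which are
# not redistributed here). The attributable risk 0.78 is the published
# population AR for the Taixing validation cohort. reference_risk_table.csv
# holds the published projected-risk grid (percent) used for the
# interpolation lookup.
name: synthetic_taixing
incidence_table: synthetic_taixing_incidence.csv
mortality_table: synthetic_taixing_mortality.csv
attributable_risk: 0.78
risk_table: reference_risk_table.csv
risk_grid:
  ages: [25, 30, 40, 50, 60, 70]
  durations: [5, 10, 20, 30]
  rr: [1, 5, 10, 15, 20, 25]
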