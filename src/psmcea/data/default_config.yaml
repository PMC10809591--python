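# Packaged base-case run configuration.
#
# Survival inputs are calibrated from published median survival times
# (months); alternative modes per endpoint are `ipd` (CSV of time_days,
# event, arm) and `km` (digitized curve CSV of time_days, survival), both
# fitted across six parametric families with AIC selection.

seed: 1

wtp_per_qaly: 38223.34

cycle_plan:
  cycle_length_days: 21
  horizon_years: 5
  discount: 0.05
  evaluation: midpoint

reference: pembrolizumab
comparator: chemotherapy

survival:
  pembrolizumab:
    os: {mode: median, family: exponential, median_months: 17.2}
    pfs: {mode: median, family: lognormal, median_months: 4.1, sigma: 1.0}
  chemotherapy:
    os: {mode: median, family: exponential, median_months: 15.3}
    pfs: {mode: median, family: lognormal, median_months: 5.5, sigma: 1.0}

background_mortality:
  enabled: true
  start_age_years: 50
  life_table_csv: null   # null -> packaged synthetic life table

treatment_caps:
  pembrolizumab: 35
  chemotherapy: null

dsa:
  enabled: true

psa:
  enabled: true
  n_iterations: 1000
  include_discount: false

scenarios:
  - {name: philanthropic drug donation program, kind: donation}
  - {name: price dropped by 60%, kind: price_reduction, fraction: 0.6}
  - {name: 3% discount, kind: discount, rate: 0.03}
  - {name: 8% discount, kind: discount, rate: 0.08}
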