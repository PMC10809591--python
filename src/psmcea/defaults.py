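"""Base-case parameter values for the packaged analysis (USD, 21-day cycles).

These are the default inputs of the pembrolizumab-versus-chemotherapy
evaluation in platinum-pretreated recurrent/metastatic nasopharyngeal
carcinoma: per-cycle drug acquisition costs, grade >=3 adverse-event
incidences and management costs, monitoring and terminal-care costs,
health-state utilities, the discount rate and the willingness-to-pay
threshold (three times 2022 Chinese per-capita GDP).  Ranges are the
published sensitivity-analysis intervals; parameters without a published
range vary by +/-20% of base.
"""

from __future__ import annotations

WTP_PER_QALY = 38223.34

DISCOUNT_RATE = 0.05
DISCOUNT_RANGE = (0.0, 0.08)

CYCLE_LENGTH_DAYS = 21.0
HORIZON_YEARS = 5.0

START_AGE_YEARS = 50.0

# per-cycle drug acquisition costs, USD
DRUG_COSTS = {
    "pembrolizumab": 5327.90,
    "capecitabine": 36.39,
    "gemcitabine": 44.16,
    "docetaxel": 31.22,
}
DRUG_COST_RANGES = {
    "pembrolizumab": (4262.32, 5327.90),
    "capecitabine": (29.11, 36.39),
    "gemcitabine": (35.33, 44.16),
    "docetaxel": (24.98, 31.22),
}
# upper pembrolizumab price bound quoted in the tornado discussion
PEMBROLIZUMAB_PRICE_UPPER_ALT = 6393.48

# the comparator arm pools three chemotherapy regimens, equal weights
CHEMO_DRUGS = ("capecitabine", "gemcitabine", "docetaxel")
CHEMO_MIX_WEIGHTS = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)

# one-off management cost per adverse event, USD
AE_COSTS = {"anemia": 6562.68, "neutrocytopenia": 475.32}
AE_COST_RANGES = {"anemia": (5250.14, 7875.22), "neutrocytopenia": (380.26, 570.38)}

# grade >=3 incidence by arm (fractions)
AE_PROBS = {
    "pembrolizumab": {"anemia": 0.009, "neutrocytopenia": 0.0},
    "chemotherapy": {"anemia": 0.107, "neutrocytopenia": 0.277},
}

IMAGING_COST = 207.25
IMAGING_COST_RANGE = (165.80, 248.70)
LAB_COST = 11.89
LAB_COST_RANGE = (9.51, 14.27)
TERMINAL_CARE_COST = 1460.30
TERMINAL_CARE_COST_RANGE = (109.23, 1825.38)

# monitoring schedule (cycles between scheduled events, while alive)
LAB_INTERVAL_CYCLES = 1
IMAGING_INTERVAL_CYCLES = 3

UTILITY_PFS = 0.76
UTILITY_PFS_RANGE = (0.61, 0.91)
UTILITY_PD = 0.35
UTILITY_PD_RANGE = (0.28, 0.42)

# pembrolizumab given for at most 35 cycles; chemotherapy to progression
PEMBROLIZUMAB_CAP_CYCLES = 35

# published median survival (months) used for curve calibration
OS_MEDIANS_MONTHS = {"pembrolizumab": 17.2, "chemotherapy": 15.3}
PFS_MEDIANS_MONTHS = {"pembrolizumab": 4.1, "chemotherapy": 5.5}
PFS_LOGNORMAL_SIGMA = 1.0
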