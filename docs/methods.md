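# Methods

## Model structure

The analysis is a three-state partitioned survival model (PSM):
progression-free (PFS), progressed disease (PD), dead. Unlike a Markov
cohort model, a PSM derives state occupancy directly from the two survival
curves — PFS membership is S_PFS(t), death is 1 − S_OS(t), PD is the
remainder — so no transition rates are estimated. The cohort starts fully
progression-free; progression is irreversible.

Cycles are 21 days (the treatment administration interval) over a 5-year
horizon. 5 × 365.25 / 21 = 86.96 cycles is rounded **up** to 87 full
cycles so that no survival benefit inside the stated horizon is truncated.
Half-cycle correction is implemented as midpoint evaluation: memberships
and discount factors are taken at t_k = (k − ½)·21 days. A `boundary`
convention is available for comparison.

Because OS and PFS curves are modelled independently they can cross
(S_PFS > S_OS), which is structurally impossible; occupancy is clamped
cycle-by-cycle (PFS ≤ OS) and the affected time range is reported as a
warning. With the packaged median-calibrated curves the crossing affects
only the first cycle and is numerically negligible.

Background mortality enters as a hazard floor on OS:
h*(t) = max(h_model(t), h_population(age₀ + t)), integrated daily by
trapezoid rule. The floor guarantees extrapolated disease survival never
beats the general population. The cohort starting age defaults to 50
(configurable). The shipped life table is **synthetic** (Gompertz–Makeham,
q(a) = 1 − exp(−(5·10⁻⁴ + 3·10⁻⁵·e^{0.085a}))); at ages 50–55 its annual
mortality (≈0.3%) is far below the disease hazard (≈40%/year), so the
floor never binds in the base case and exists for structural correctness
and for low-hazard applications.

## Survival inputs

Three modes per endpoint and arm:

1. **Median calibration** (packaged default). A published median pins one
   parameter: exponential rate = ln 2 / median; lognormal μ = ln median
   with σ supplied (default 1.0, a deliberately wide but unexceptional
   dispersion for oncology PFS — it is a named configuration field because
   no fitted dispersion is published, and downstream results can be probed
   against it).
2. **IPD fitting.** Censored maximum likelihood
   (Σ_events log f + Σ_censored log S) for six families: exponential,
   Weibull, log-logistic, lognormal, Gompertz, generalized gamma (Prentice
   location–scale–shape form; |Q| < 10⁻⁵ switches to the lognormal limit
   for numerical stability at the interior degenerate point). Optimisation
   is multi-start L-BFGS-B on log-transformed positive parameters, 3
   starts, tolerance 10⁻⁸ on the log-likelihood; non-convergence is
   flagged, never silent. Selection minimises AIC = 2k − 2ℓ or
   BIC = k ln n − 2ℓ with n = subjects (the common convention; events
   would be the alternative). Ties break toward fewer parameters, then
   lexicographic family name, for reproducibility.
3. **Digitized curves.** Pseudo-IPD are reconstructed interval-wise from
   Kaplan–Meier coordinates (Guyot-style): events are allocated from
   survival drops against the running product-limit estimate; with a
   numbers-at-risk table, censorings are inserted at each risk-table
   boundary to reconcile the at-risk count; without one, all censoring is
   placed at the end of follow-up. The reconstruction reproduces the input
   curve within 0.02 sup-norm in the packaged tests.

## Economics

All values USD (source prices fixed at 6.73 RMB/USD, 2022). Per cycle:

| parameter | base | range | PSA distribution |
|---|---|---|---|
| pembrolizumab / cycle | 5327.90 | 4262.32–5327.90 | gamma |
| capecitabine / cycle | 36.39 | 29.11–36.39 | gamma |
| gemcitabine / cycle | 44.16 | 35.33–44.16 | gamma |
| docetaxel / cycle | 31.22 | 24.98–31.22 | gamma |
| anemia management | 6562.68 | 5250.14–7875.22 | gamma |
| neutrocytopenia management | 475.32 | 380.26–570.38 | gamma |
| imaging event | 207.25 | 165.80–248.70 | gamma |
| laboratory event | 11.89 | 9.51–14.27 | gamma |
| terminal care | 1460.30 | 109.23–1825.38 | gamma |
| utility PFS | 0.76 | 0.61–0.91 | beta |
| utility PD | 0.35 | 0.28–0.42 | beta |
| AE incidences | 0.9/0.0 and 10.7/27.7 % | ±20% | beta |

Design choices where the source material is silent or ambiguous:

- The chemotherapy arm pools three regimens; its per-cycle drug cost is
  the **equal-weight mean** (37.26 USD), weights configurable.
- Monitoring frequency: laboratory tests every cycle, imaging every 3rd
  cycle, both while alive; intervals configurable.
- Adverse-event cost is a one-off lump sum (Σ incidence × unit cost)
  charged in cycle 1, on the assumption that grade ≥3 events cluster at
  treatment start. AE disutilities and AE-driven discontinuation are out
  of scope.
- Terminal care cost attaches to each cycle's new deaths and is
  discounted at that cycle.
- Pembrolizumab is capped at 35 treatment cycles; chemotherapy is given
  to progression. Drug cost accrues against PFS occupancy up to the cap.
- Drug dosing is consumed as per-cycle prices (body-surface-area dosing
  is already embedded in them); mg-level dosing is not recomputed.

## Sensitivity analysis

One-way analysis re-evaluates the full model at each parameter's bounds
(published interval, else ±20%), all else at base, and sorts by ICER span.
Note a structural caveat: when the incremental QALY is near zero — as it
is under median-calibrated curves — the ICER denominator can change sign
within a utility parameter's range, producing enormous spans for the
utilities rather than the drug price; the tornado table is therefore most
interpretable alongside the incremental-NMB view.

PSA draws all parameters independently (no correlation structure is
available): gamma for costs, beta for utilities and incidences,
moment-matched so the mean equals the base value and SD = (high − low)/3.92
(interval read as a 95% range); zero-width ranges become point masses.
The discount rate is treated as structural (varied one-way over 0–8% and
in scenarios) and excluded from PSA by default; a flag re-enables it.
Survival parameters are structural throughout — no published basis exists
for their uncertainty. The CEAC reports, per WTP value, the fraction of
iterations with positive incremental net monetary benefit.

## Scenarios

1. **Donation program**: the patient pays cycles 1–2 and 5–6; cycles 3–4
   and 7–35 are donated; no drug beyond cycle 35. "Course" is read as one
   21-day cycle, and the schedule is applied expectation-wise to cohort
   occupancy, not per simulated individual.
2. **Price reduction**: per-cycle pembrolizumab price scaled by (1 − f),
   default f = 0.6.
3. **Discount rates** 3% and 8%, all else unchanged.

## Synthetic data generator

`synthetic_ipd` emulates a two-arm trial whose OS is exponential (medians
17.2 / 15.3 months) and PFS lognormal (medians 4.1 / 5.5 months, σ = 1.0),
with uniform accrual over one year, an administrative cutoff at three
years, and no loss to follow-up (default n = 100/arm, configurable). OS
and latent progression share one uniform per subject (comonotone frailty),
so PFS ≤ OS holds record-by-record **and** both marginal medians match
their calibrated curves; drawing the endpoints independently and taking
the minimum would deflate the observed PFS median by ~20%. What the
generator does **not** emulate: covariates and subgroups, response
endpoints, non-administrative censoring, delayed treatment effects or
non-proportional hazards. Tests passing on these data therefore validate
the pipeline's arithmetic and statistical machinery, not the clinical
fidelity of any particular extrapolation.

Parameter-recovery tests use per-family true parameters chosen in
well-identified regimes (e.g. a steeply rising Gompertz hazard, a
generalized gamma with tight σ), with the administrative cutoff set so
~20% of subjects are censored; in weakly identified regimes (near-flat
Gompertz shape, generalized gamma near its lognormal limit) the sampling
variance of the estimates at n = 1000 genuinely exceeds a 15% relative band —
a property of the families, not of the optimizer.

## Numerical choices

- Time unit internally is days; 1 month = 30.4375 days, 1 year = 365.25
  days. Curves carry an explicit unit tag and convert exactly.
- Membership sums are validated to 1 ± 10⁻¹²; dead occupancy must be
  non-decreasing.
- ICERs with |ΔE| ≤ 10⁻¹² are reported as undefined (NaN) with dominance
  classified by cost.
- Background-mortality integration uses a 1-day trapezoid grid.
- All stochastic components take a `numpy` `Generator` seeded from
  explicit integers; identical seeds give bit-identical outputs.

## Known limitations

- The base case rests on median calibration: the published fitted curves
  and their parameters are not available, so printed base-case totals
  (e.g. 3.96 LY for pembrolizumab over 5 years) are not reproducible from
  first principles; the package's median-calibrated totals are materially
  lower (≈1.7 LY) because an exponential through a 17.2-month median
  decays much faster than the published extrapolation evidently did. The
  headline conclusion — ~$40k incremental cost, negligible QALY gain, 0%
  probability of cost-effectiveness at $38,223/QALY — is insensitive to
  this difference.
- The source's chemotherapy AE probabilities appear under a mislabelled
  table heading; they are used for the chemotherapy arm as the evident
  intent. Its published donation-scenario pembrolizumab total (~$5.8k) is
  hard to reconcile with any literal per-cycle reading of the schedule;
  the schedule is implemented as described and only the published table's
  internal arithmetic is asserted.
- No value-of-information analysis, no correlation between sampled
  parameters, no cure-fraction or spline survival models, no societal
  costs.
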