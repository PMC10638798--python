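# Methods

## Model

`bcscea` implements a six-state Markov cohort model of the long-term
prognosis of women treated surgically for in situ (stage 0) breast cancer,
and a cost-utility comparison of three strategies for the first surgery:
mastectomy, lumpectomy (breast-conserving surgery) without follow-up
irradiation, and lumpectomy with irradiation.

States: **A** cancer-free, **B** loco-regional recurrence, **C** remission
after recurrence, **D** metastasis, **E** remission after metastasis,
**F** death (absorbing).  The graph allows A→{B,D,F}, B→{C,F}, C→{D,F},
D→{E,F}, E→{F} plus self-loops; remission states never revert (repeat
recurrences are modelled as continued occupancy of B or D).  The cohort
enters fully in state A at age 58 and is propagated for 30 one-year cycles
(a lifetime horizon for this entry age).  Successful initial surgery is
assumed; surgical complications are not modelled.

The three strategies share all transition inputs except the cancer-free →
recurrence probability `tpA2B`, which is strategy-specific and
time-dependent: loco-regional recurrence incidence (events per 1000
person-years) is piecewise constant on follow-up windows [0,5), [5,10),
[10,30) years and declines over time.  The mastectomy schedule is not
directly observed in Swedish data; it is transferred from the
lumpectomy-without-irradiation schedule by dividing each period incidence by
the mastectomy : lumpectomy incidence-rate ratio of 1.27 estimated in a US
randomised trial.

## Transition probabilities

All evidence is converted to annual probabilities through the
constant-hazard model `p = 1 − exp(−r t)`:

* incidence rates: `r = rate / 1000` per year, `t = 1` cycle;
* cumulative incidences over a follow-up of `T` years: the rate is first
  recovered as `r = −ln(1 − CI) / T`.

Six probabilities come from cumulative incidences (A→D 0.008, B→C 0.165,
B→F 0.065, C→D 0.230, D→E 0.375, D→F 0.178); stay-probabilities are
complements.  Background all-cause mortality `mor_gp(age)` is looked up in
the life table at the integer age `entry_age + cycle` (no interpolation)
and overlaid on every living state: it *is* the death exit of A, C and E,
and is *added* to the disease-specific death exits of B and D
(`background_mortality_additive`, default on; off treats B→F/D→F as already
all-cause).  If a row's exits ever exceed one (possible only under extreme
sampled inputs or entry ages far beyond the life-table range), death is
capped at 1, the other exits are zeroed and a warning is logged; base-case
inputs never reach this regime.

## Cost and QALY accrual

Each cycle is valued on its end-of-cycle occupancy and discounted by
`1/(1+rate)^(t+1)` (3 %/year for both costs and QALYs).  No half-cycle
correction is applied (`half_cycle_correction` exists as a switch, default
off): the accounting below was chosen to reproduce the published
deterministic cost totals of the analysis this package re-implements, which
show no sign of one.

Healthcare-perspective costs (2020 SEK):

* the arm baseline cost (surgery + hospitalisation: 87,670 mastectomy /
  27,655 lumpectomy / 50,352 lumpectomy+RT) is charged once on entry,
  undiscounted, **and as a running cost for every cycle spent cancer-free**.
  The running State A charge is essential: without it the mastectomy arm —
  which has the *lowest* recurrence — would be the cheapest strategy,
  contradicting the published totals (≈1.18 M SEK for mastectomy vs
  ≈0.63 M for lumpectomy alone), which are only reproducible when the
  baseline cost accrues per cancer-free cycle.  Both charges are governed by
  switches (`charge_entry_cost`, `state_a_running_cost`);
* state B costs 17,680 SEK/cycle after mastectomy (adjuvant therapy) and
  87,670 SEK/cycle after either lumpectomy (recurrence is treated by
  mastectomy); state D costs 499,343 SEK/cycle for all arms; states C, E, F
  are costless.

Societal perspective adds, on top of healthcare costs:

* informal care (10,003 SEK/year; halved to 5,002 for lumpectomy without
  irradiation) as a **flat discounted annuity over all 30 cycles**
  (`informal_care_scope='flat_annuity'`).  This convention was identified
  from the published perspective gaps, which equal the annuity closed form
  `10,003 × a(30y, 3%) = 196,072` to a few SEK; `'all_alive'` and
  `'state_D'` scopes are available and tested;
* minus the productivity gain of the lumpectomy arms (4,104 SEK/year,
  first 10 years) as a flat discounted 10-year annuity
  (`productivity_alive_weighted` optionally weights it by survival).

QALYs: state utilities 0.84 (A, mastectomy), 0.87 (A, either lumpectomy),
0.78 (B), 0.81 (C), 0.69 (D), 0.76 (E), 0 (death).  The remission weights
are the published scalars; they are *not* re-derived as adjacent-state
averages (which would give 0.825/0.78 for the lumpectomy arms).

## Incremental analysis

Average cost-effectiveness ratios are cost/QALY per strategy.  For the
incremental comparison, strategies that are more costly and no more
effective than an alternative are strongly dominated (QALY ties resolved in
favour of the cheaper strategy); among the survivors, ordered by
effectiveness, a strategy whose ICER over its cheaper neighbour exceeds the
next ICER up the ladder is removed as extendedly dominated, iterating until
the ICER sequence increases.  The comparison is done by cross-multiplied
QALY/cost differences with a 1e−9 relative tolerance so exactly collinear
strategies stay on the frontier.  Frontier ICERs are classified against the
Swedish bands: < 100,000 SEK/QALY low; 100,000–499,999 moderate;
500,000–1,000,000 high (inclusive); above 1 million very high.  Negative
ICERs are rejected — dominance must be resolved first.

## Probabilistic sensitivity analysis

1,000 Monte Carlo iterations (the published design; `n_iter` is free).  Per
iteration one joint parameter draw is applied to all three strategies
(common random parameters, so arms are compared within a simulation):

* transition probabilities and utilities: Beta(α, β) with the published
  shape pairs; implied means match the deterministic values to ≤ 0.005;
* costs: Gamma(shape, scale) — the published pairs reproduce each
  deterministic mean as shape × scale to < 0.05 %, which is how the
  printed (α, β) pairs are interpreted;
* entry age: Normal(58, SD 11.8), truncated to [18, 100] by resampling and
  rounded to integer years; mortality lookups clamp to the life-table range.
  Sampling age is what drags PSA mean QALYs below the deterministic values
  (older entries face convexly higher mortality);
* discount rates, background mortality, societal add-ons and complements
  are held fixed; complements are recomputed per draw and draws with an
  infeasible row (B or D exits > 1) are rejected and redrawn (abort after
  1,000 consecutive rejections — never observed with the packaged specs).

The evidence base provides a *single* Beta for `tpA2B` although the model
uses nine period/strategy values.  This package samples one multiplicative
shift — the Beta draw divided by the Beta mean (0.0549, the implied
mastectomy 0–5-year probability) — and scales all nine period incidences by
it, preserving the between-strategy ratios and the time profile.  This
scheme is this package's construction; it treats recurrence uncertainty as
perfectly correlated across arms and periods.

Outputs: per-draw (cost, QALY) per strategy and perspective; means and
empirical 2.5/97.5 percentile intervals; incremental analysis on the PSA
means; CE-plane clouds per pairwise comparison; CEAC curves
`P(NMB_alt > NMB_ref)` with `NMB = λ·QALY − cost` on a willingness-to-pay
grid of 0–2,000,000 SEK/QALY in 100,000 steps.

## Synthetic data

Two inputs of the original analysis are confidential or external and are
replaced by generators (readers for real versions are provided:
`read_lifetable`, `read_registry`).

**Life table.**  A deterministic Gompertz–Makeham schedule
`q(x) = 1 − exp(−(a + b·c^x))` with defaults `a = 5e−4`, `b = 4.42e−6`,
`c = 1.122`, calibrated once to the magnitude of Swedish female all-cause
mortality: q(58) ≈ 0.004, q(85) ≈ 0.08.  It does **not** emulate: the
2020/21 mortality spike, male/female mixing, or deviations of the national
schedule from log-linear ageing.  The packaged schedule is somewhat lighter
than the all-persons WHO schedule used by the source analysis; as a result
deterministic QALYs on the synthetic table run a few percent higher
(≈ 12.0/12.0/12.7 vs the published 11.21/11.24/11.80) and the healthcare
ICER lands at ≈ 376,000 vs the published 402,994 SEK/QALY — the same
"moderate" band, and all dominance conclusions are unchanged.  A
sensitivity sweep scaling the hazard by 1.3–1.6 (both-sexes-like weight)
moves QALYs and the ICER to within ~1–4 % of the published values, so the
residual gap is attributable to the mortality schedule, not the engine.
Exact reproduction requires supplying the real national table via
`read_lifetable`.

**Cost registry.**  96 mastectomy + 629 lumpectomy records with gamma
per-patient costs.  The lumpectomy arm is a two-component mixture (components
centred at 27,655 and 50,352 SEK, mixed 240:389) because the source registry
does not record irradiation status; the arms are recovered downstream by
splitting at the Swedish DRG reference cost of a lumpectomy without
irradiation (36,439 SEK), classifying `cost ≤ DRG` as the cheaper
without-irradiation arm.  Component SDs are moment-matched to the published
standard errors (SD = SE·√n at n = 96/240/389).  The component overlap
around the DRG threshold means the split misclassifies some records
(recovered splits are ≈ 255–270 vs the published 240), biasing the split
counts but leaving arm means within a few percent of their targets; tests
assert 10 %.  The generator does not emulate regional cost variation,
case-mix covariates, or heavy upper tails beyond the gamma.

**Inflation.**  The 2005→2020 CPI factor is hard-coded as 10,003/8,350
(≈ 1.19796), the ratio implied by the published informal-care pair, making
the package self-contained; it reproduces the 499,343 SEK metastasis cost
from its 2005 source (425,174 − 8,350) to < 0.01 %.

## Numerical choices

* Follow-up windows are half-open; cycle t uses the window containing t
  (boundary cycles 5 and 10 belong to the later window).
* Matrix rows are validated to sum to 1 within 1e−12; occupancy
  conservation is tested at 1e−10; a time-homogeneous variant of the engine
  is tested against the matrix-power closed form at 1e−10.
* Death-row and structural zeros are enforced exactly.
* Percentile intervals are plain empirical quantiles (no smoothing).

## What passing tests show — and what they do not

The test suite verifies the conversion formulas against all printed
evidence values, the accounting conventions against the published totals'
closed forms, engine invariants against independent oracles, and the
qualitative economic conclusions (mastectomy strongly dominated in both
perspectives; lumpectomy+RT vs lumpectomy ICER in the moderate band;
CEAC ≈ 1 at 2 M SEK/QALY) on the synthetic inputs at fixed seeds.  They do
not certify the absolute published QALY/cost totals, which depend on the
confidential registry and the exact national mortality table.  One known
knife edge: with the light synthetic schedule, deterministic mastectomy
QALYs end 0.03 % *above* lumpectomy-without-RT (the lower recurrence almost
exactly offsets the lower cancer-free utility); under heavier real-world
mortality, and on PSA means with sampled ages, mastectomy is strictly last,
matching the published ordering.

## Limitations

* Fixed six-state topology; no tunnel states, no cause-of-death partition,
  no complication sub-model.
* The State A running-cost convention reproduces the source accounting but
  is economically unusual (it re-charges the surgery-episode cost
  annually); analysts wanting a conventional episode-cost model can switch
  `state_a_running_cost` off, at the price of leaving the published totals.
* Recurrence uncertainty in the PSA is a single perfectly correlated
  multiplicative shift (see above).
* SEK only; no currency or CPI time-series handling beyond the fixed
  2005→2020 factor.
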