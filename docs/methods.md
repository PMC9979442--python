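# Methods

`btccea` implements a three-state Markov cohort model comparing first-line
durvalumab + gemcitabine/cisplatin ("combo") with gemcitabine/cisplatin alone
("chemo") in advanced biliary tract cancer, from the perspective of the
Chinese healthcare system. This note records the model, its assumptions, the
parameter conventions, and the design choices made where the published
description of the analysis leaves the design open.

## Model structure

States are progression-free survival (PFS), progressed disease (PD) and
Death, with a 21-day cycle matching the treatment schedule, a 10-year horizon
(174 cycles), and 5% annual discounting of costs and QALYs applied per cycle
as `(1 + r)^(−i·21/365.25)`. Utilities are 0.9 (PFS) and 0.4 (PD). The
cost-effectiveness threshold is three times 2021 Chinese per-capita GDP,
$37,663.26/QALY.

Rewards accrue by default on the **post-transition occupancy** of each cycle
(the membership after that cycle's transitions), without half-cycle
correction. Both choices are exposed (`accrual="pre"`,
`half_cycle_correction=True`) because cohort models genuinely differ here and
the choice moves totals by up to one cycle's accrual; the defaults were fixed
once by the reproduction analysis described under *Reproduction of the
published table* below.

## Survival inputs

Each arm's OS and PFS follow Weibull laws `S(t) = exp(−λ t^γ)` with `t` in
model cycles. The packaged base case carries the published `(λ, γ)` per
endpoint and arm.

**Time unit.** The published parameters do not state their time unit. In
cycle units the implied medians, converted at 30.44 days/month, reproduce the
trial-reported medians — combo OS 13.3 vs 12.8 months, chemo OS 11.4 vs 11.7,
combo PFS 6.6 vs 7.2, chemo PFS 5.8 vs 5.7 — all within 10%, whereas month or
day units miss by 40% or more. Cycle units are therefore used throughout (and
asserted in the test suite); a month-unit reinterpretation is available as an
investigation switch (`reporting.apply_conventions(..., time_unit="month")`,
which rescales `λ → λ·(21/30.44)^γ`).

**Refitting from digitized curves.** When survival evidence arrives as
digitized Kaplan–Meier coordinates instead, pseudo individual-patient data
are reconstructed by interval allocation: for each adjacent pair of curve
points, `round(n·ΔS)` event records are placed at the interval midpoint and
survivors of the last point become administratively censored records there;
published numbers-at-risk, when present, rescale the interval counts. This
deterministic scheme (rather than the full Guyot reconstruction) is adequate
for refitting smooth two-parameter laws, which is its only use here. Weibull
and exponential laws are then fitted by right-censored maximum likelihood —
L-BFGS-B on `(log λ, log γ)`, objective tolerance 1e-12, started from the
exponential hazard moment estimate with `γ = 1`; the exponential and
fixed-shape MLEs are closed-form — and compared by AIC (`2k − 2ℓ`), with
ties broken toward the fewer-parameter family. The fitted likelihood is
cross-checked against an independent implementation in the test suite. The
published AIC values depend on unpublished reconstructed data and only their
ordering (Weibull preferred in every row) is used.

## Transition probabilities

The per-cycle probability of leaving the state governed by a curve is the
conditional `p_i = 1 − S(i)/S(i−1)`; for `γ = 1` this reduces to the
constant-hazard conversion `1 − e^{−λ}`. PFS exits follow the PFS curve.
Total deaths each cycle are targeted at the OS hazard applied to the alive
cohort, so the modelled alive fraction tracks the fitted OS curve exactly —
the standard construction of a state-transition model from two marginal
curves. Deaths are supplied first from PFS at the background mortality rate
(annual probability 0.00718, the 2021 Chinese crude death rate, converted by
`1 − (1−p)^{21/365.25}`; the source population is named in the publication
but not the number), then from PD, with any remainder taken from PFS exits
(reducing progressions). All probabilities are clamped to [0, 1]; if
extrapolated curves cross so that the death target cannot be met, the flow is
clamped and a warning logged. With background mortality zero the alive trace
equals `S_OS` to machine precision, which the tests assert at 1e-6 over all
174 cycles.

## Costs

All costs are 2021 USD (6.45 RMB/USD), direct medical only. Dosing uses a
65 kg / 1.72 m² reference patient, linear per-mg pricing and no vial wastage
(prices are quoted per pack but no wastage rule is published).

* Induction (cycles 1–8, while in PFS): gemcitabine 1000 mg/m² and cisplatin
  25 mg/m² on days 1 and 8 ($191.37/cycle), plus durvalumab 1500 mg on day 1
  in the combo arm ($8,415.00).
* Maintenance (cycles > 8, combo arm, while in PFS): durvalumab 1500 mg every
  4 weeks, prorated into the 21-day cycle (×21/28 = $6,311.25/cycle) rather
  than switching cycle length.
* Tests and imaging: $268.22 every cycle alive (applied in PD as well — the
  publication is silent; configurable via `tests_imaging_in_pd`).
* Adverse events: one-time per-arm aggregate at model start ($603.87 combo /
  $591.20 chemo); a detailed incidence×unit-cost mode is available.
* Terminal care: $4,517.85 once, on the cohort fraction entering Death,
  discounted at that cycle.
* Second line (PD state): a configurable regimen mix. FOLFOX costs use
  oxaliplatin 85, leucovorin 400 and fluorouracil 2800 mg/m² fortnightly,
  prorated ×21/14; pembrolizumab 200 mg q3w; targeted therapy averages
  dabrafenib+trametinib and regorafenib at label doses. **Default: 100%
  FOLFOX in both arms.** The trial's second-line proportions are not
  published; a symmetric, chemotherapy-based mix reproduces the published
  incremental cost to +0.3%, whereas an asymmetric mix placing 30% of
  chemo-arm patients on pembrolizumab moves it ~19% — the published cost
  arithmetic is only consistent with second-line costs that are cheap and
  near-symmetric. Alternative mixes are packaged as presets and the mix is
  fully overridable.

**Charity assistance.** The donation programme is modelled as
pay-`k`-administrations-then-free-until-progression, zeroing the durvalumab
component after administration `k`. The published description of the
ES-SCLC programme is ambiguous about `k`; the printed total saving of
$62,405.90 identifies it: `k = 2` reproduces the saving to +1.7% (and the
charity-scenario incremental cost to −4.4%), while `k = 1` and `k = 3`
mismatch by ~35%. `k = 2` is the default; it is a configuration field, not a
constant.

## Economics

Incremental cost and QALYs are exact arm differences; the ICER is their
ratio, with dominance classification when the signs disagree and an
undefined tag (no division) when |ΔQALY| < 1e-12. The break-even durvalumab
price bisects on the unit price — the ICER is monotone increasing in it —
until the ICER matches the threshold to a relative tolerance of 1e-4.

One-way sensitivity analysis re-runs the full pipeline at each parameter's
published lower/upper bound (95% CI or ±25%), all else at base, and sorts by
ICER spread. The PSA (default 1000 draws) samples every cost from a Gamma and
the utilities and discount rate from Beta distributions, moment-matched by
reading each published range as a 95% interval (`sd = (upper − lower)/3.92`);
the PFS-utility upper bound 1.125 is truncated to 1.0 before matching.
Parameters are sampled independently; survival parameters are not sampled
(the published distribution table assigns distributions only to costs,
utilities and the discount rate). The acceptability curve reports the
fraction of draws with nonnegative net monetary benefit over a WTP grid of
$0–150,000 in $1,500 steps plus the exact threshold. All sampling is driven
by a single seeded generator; identical seeds give bit-identical results.

## Synthetic data

`simulate.SimulationSpec` emulates the published observation process: event
times drawn by inverse CDF from a known Weibull law, administrative censoring
at the follow-up horizon (default 35 cycles ≈ 2 years), Kaplan–Meier curves
read off a 30-point grid, and survival rounded to 0.005 to mimic
figure-digitization resolution; arm sizes default to the trial's 341/344.
The generator reproduces sampling noise and digitization coarseness but not
informative censoring, reader bias in curve tracing, or axis-calibration
error — so round-trip tests demonstrate correctness of the reconstruction
and fitting machinery, not the fidelity of any particular published figure.

## Reproduction of the published table

The published base-case table is only partly reconcilable with the published
inputs. Its two ICER / incremental-cost pairs imply a common unrounded
ΔQALY of 0.11623 (an identity the comparison layer reproduces to 4
significant figures), and this model reproduces the incremental costs
(+0.3% / −4.4%) and the charity saving (+1.7%). But the printed QALY totals
(1.68 / 1.80) cannot follow from the published Weibull parameters: in cycle
units — the only unit consistent with the trial medians — the chemo-arm mean
OS is ≈19 cycles ≈ 1.1 years, bounding discounted QALYs near 0.65, and no
accrual convention, half-cycle setting, time-unit reinterpretation, charity
rule or second-line mix closes a 2.5× gap. This model's ΔQALY (0.156)
accordingly exceeds the published implied 0.1162, putting its ICERs ~25–30%
below the published ones while every qualitative conclusion (ICERs far above
the threshold, 0% PSA acceptability without charity, durvalumab price the
dominant parameter, break-even below $0.33/mg) is reproduced.

`reporting.investigate_table3` makes this auditable: it re-runs the model
over the convention grid (half-cycle × accrual × time unit × charity `k` ×
second-line preset) and reports every quantity's relative deviation from the
published table. The reproduction tests assert a ±20% band on these
deviations and the ICER/QALY assertions fail, by design, with messages that
state the deviations — the discrepancy is reported, not calibrated away.

## Numerical choices and limitations

* Optimiser tolerances: 1e-12 (objective) / 1e-10 (gradient); non-convergence
  raises with the final gradient norm. Survival underflow in the hazard ratio
  returns exit probability 1 with a warning.
* Row-stochasticity is enforced to 1e-12; cohort conservation to 1e-10.
* AIC ties select the fewer-parameter family; `round` (banker's) is used in
  IPD allocation, so half-count intervals may round down — degenerate
  reconstructions (no representable events) raise rather than fit.
* Problem sizes used by the packaged analyses: 174 cycles, 1000 PSA draws,
  n = 2000 for parameter-recovery checks, 100,000 draws for sampler moment
  checks.
* Not modelled: tunnel states, time-in-state utilities, individual-level
  simulation, parameter correlation in the PSA, indirect/societal costs,
  vial wastage, EVPI. Second-line drug costs accrue for the whole PD
  occupancy (no duration cap by default; configurable).
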