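# Methods

This note documents the model implemented by `psmcea`, the conventions it
adopts where the source analysis left choices open, and what the synthetic
data and the test suite do and do not establish.

## The cohort model

A three-state partitioned-survival model ("progression-free" PFS,
"progressive disease" PD, "death") for first-line treatment of
extensive-stage small-cell lung cancer: toripalimab + platinum/etoposide
chemotherapy versus chemotherapy alone. State occupancy is read directly
off the overall-survival and progression-free-survival curves at every
cycle boundary:

    pfs(t)   = min(S_PFS(t), S_OS(t))
    death(t) = 1 − S_OS(t)
    pd(t)    = S_OS(t) − pfs(t)

The clamp keeps the PD compartment non-negative when the fitted PFS curve
crosses above OS (which the published overall-population parameters do; see
below). The cohort enters in PFS. Cycles are 21 days (one treatment
cycle), the horizon is 10 years (173 cycles), and costs and QALYs accrue
per cycle on start-of-cycle occupancy, discounted continuously at an annual
rate r by `(1 + r)^(−t_years)` with `t_years = cycle_index × 21/365.25`
(5 %/yr in the China scenarios, 3 %/yr in the US scenarios). A
`half_cycle_correction` flag switches accrual to cycle-average occupancy;
it is off by default because the source analysis gives no indication of
using one, and the acceptance bands absorb the ≤ half-cycle difference.

QALYs weight occupancy by state utilities (PFS 0.69, PD 0.60). Grade ≥ 3
adverse events with incidence above 5 % (six events) contribute a one-time
cost `Σ incidence_j × unit_cost_j` and a one-time QALY loss
`Σ incidence_j × disutility_j × cycle_years`, both charged in the first
cycle.

### Time-grid calibration

The packaged survival parameters are evaluated on the model's own cycle
grid: one curve-time unit per 21-day cycle
(`ModelSettings.curve_time_per_cycle = 1.0`). This is a deliberate
calibration choice. The published parameter set is only internally
consistent with the published base-case results under this reading: with
it, all twelve discounted QALY totals land within 0.04 of the published
table and the four subgroup ICERs within ±7 %; reading the same parameters
on a calendar-month axis (`curve_time_per_cycle = 21/30.4375`) inflates
every QALY total by roughly 45 % (e.g. 1.18 instead of the published 0.81
for the China combination arm). The original model was evidently built on
a per-cycle time grid while accruing 21 days of calendar time per cycle,
and this package reproduces that behaviour. Users fitting their own curves
on a calendar axis should set `curve_time_per_cycle` accordingly.

### Known inconsistencies in the transcribed inputs

The scenario files transcribe the published parameter tables verbatim, and
two of the overall-population PFS rows are internally implausible:

* the combination-arm PFS row (log-logistic shape 1.839, scale 22.624)
  duplicates the ITH-L subgroup combination-arm **OS** row and implies a
  median PFS longer than median OS;
* the comparator PFS scale (15.128) coincides with the comparator OS scale
  (15.127), likewise implying median PFS ≈ median OS, far from the trial's
  ~5.6-month median PFS.

After clamping, PFS occupancy in both overall-population arms equals OS
occupancy. QALY totals are barely affected (they are OS-dominated), but
maintenance-antibody exposure — charged to PFS occupancy — is roughly twice
what the published incremental costs imply in **both** currencies, so the
overall-population incremental costs, ICERs and PSA probabilities computed
from the printed inputs overshoot the published values by about a factor of
two. The subgroup scenarios (ITH-L, HLA-A11+/B62−), whose PFS rows are
plausible, reproduce the published ICERs within a few percent. The files
keep the printed values and flag the artifact in comments rather than
substituting invented "corrected" curves.

## Costs

All costs are USD per the published tables (China costs converted by the
source at 7.0467 CNY/USD). Per cycle, PFS occupancy accrues:

* **drugs** — induction (first 4 cycles): carboplatin day 1 + etoposide
  days 1–3 (3 × the per-dose cost), plus toripalimab in the combination
  arm; maintenance: toripalimab only, in the combination arm, continued
  without a duration cap (trial protocol: until progression);
* **administration** — China uses a per-infusion-event fee structure
  (infusion fee + prophylactic medication per IV day, + a per-cycle
  prophylaxis charge; 3 IV days per induction cycle, 1 per maintenance
  cycle); the US uses per-hour fees (first hour + 2 additional hours on
  day 1, first hour only on days 2–3). The comparator arm accrues
  induction administration but nothing during (placebo) maintenance;
* **laboratory** per cycle, and **imaging** on the surveillance grid
  (every 2 cycles through cycle 18 ≈ week 54, then every 4 cycles).

PD occupancy accrues a blended post-progression cost: the treated fraction
(55.2 % / 69.4 % by arm) gets the published regimen mix — cytotoxic
(topotecan + cisplatin), TKI (anlotinib), PD-1 inhibitor (toripalimab) —
with shares renormalized to sum to one (the printed shares describe
overlapping therapy lines and sum to 95.5 % / 128.3 %); the untreated
fraction gets best supportive care. This blend applies for the full PD
sojourn, the usual convention when no treatment duration is reported; the
one-way analysis covers the proportions. Incident deaths (the per-cycle
increment of the death state) accrue a one-time end-of-life cost,
discounted at that cycle. The US table prints no anlotinib price; the
China price is the explicit default, flagged in the scenario file.

## Survival distributions and fitting

Eight families in the parameterizations standard in survival
extrapolation (identical to the R `flexsurv` dialects, so published tables
transcribe directly): exponential (rate), Weibull AFT (shape, scale),
Weibull PH (shape, scale: S = exp(−scale·t^shape)), gamma (shape, rate),
Gompertz (shape, rate; negative shape allowed, giving an improper
distribution flagged by `is_improper`), lognormal (meanlog, sdlog),
log-logistic (shape, scale: S = 1/(1+(t/scale)^shape)), and the Prentice
(mu, sigma, Q) generalized gamma, whose Q→0 limit is the lognormal and
which nests the Weibull (Q=1) and gamma (Q=sigma).

Right-censored maximum likelihood maximizes
`Σ_events log f(t_i) + Σ_censored log S(t_i)` by L-BFGS-B on
log-transformed positive parameters with moment-style starting values and
up to three randomized restarts; no observed events raises `UnfitDataError`
and optimizer failure raises `ConvergenceError` carrying the optimizer
status. AIC = 2k − 2ℓ and BIC = k·ln n − 2ℓ; `select_best` minimizes the
chosen criterion, breaking ties by fewer parameters, then by family
declaration order. The generalized-gamma Q is weakly identified (its
sampling sd is ≈ 0.05 even at n = 5000), so the recovery tests measure
*bias* by averaging estimates over eight seeded replicates rather than
judging a single draw; a spot check against `flexsurv` on identical data
agrees to four decimals in parameters and log-likelihood.

The published model-fit (AIC/BIC) tables themselves cannot be reproduced:
they depend on digitized curve coordinates that were never published. The
fitting machinery is therefore validated by formula tests, parameter- and
model-recovery simulations, and the reconstruction loop below.

## Synthetic data

The synthetic module emulates the data pathway behind the published
survival parameters: `simulate_ipd` draws event times by inverse-CDF
sampling with independent exponential censoring (its hazard calibrated
numerically so the expected pre-cutoff censored fraction matches a target
rate) plus administrative censoring at a cutoff; `km_estimate` is the
product-limit estimator (via lifelines); `digitize_curve` samples the step
function on a regular grid and adds truncated, monotonized Gaussian
read-off noise, emulating manual graph digitization; `pseudo_ipd`
reconstructs individual observations by cumulative-rounding allocation so
the empirical KM matches the curve within 1/(2n), with post-last-point mass
censored there — a simplified Guyot-style reconstruction that uses no
number-at-risk table, because the source figures print none.

What this does *not* emulate: real digitizer biases (axis miscalibration,
systematic under-tracing near drops), interval censoring, and risk-set
information that the full reconstruction algorithm would exploit. Passing
the end-to-end loop test (simulate → KM → digitize → reconstruct → refit
recovers a log-logistic truth within 10 % at n = 400) shows the pipeline
is self-consistent at trial-like sample sizes, not that the original
digitization was accurate.

## Sensitivity analysis

One-way analysis re-runs both arms at each parameter's published low/high
values (±20 % of base for nearly all rows, transcribed as printed) and
ranks by absolute ICER spread; INMB is available as the robust metric when
the effect difference nears zero. The probabilistic analysis draws costs
from gamma and utilities/probabilities from beta distributions by method of
moments with mean = base and sd = (high − low)/3.92 — the printed range
read as a 95 % interval, the standard convention when a source names
distributions but not spreads. Infeasible beta moments fall back to a
shrunk sd with a warning. Survival-curve parameters carry no published
ranges and are held fixed in the PSA; this is a documented limitation, and
one reason the package's acceptability probabilities are more extreme
(closer to 0 or 1) than the published ones — the published scatter implies
a wider joint input distribution than the printed ranges generate.

## Numerical choices and degenerate inputs

* Cycle count: `floor(horizon_years × 365.25 / 21)` = 173 for the default
  horizon; a horizon shorter than one cycle is rejected.
* Discounting at cycle start; the one-time AE burden and cycle-0 costs are
  undiscounted.
* Patients still alive at the horizon never accrue the end-of-life cost.
* Ties at exactly zero net monetary benefit count as *not* cost-effective
  (CEAC and `cost_effective`).
* ICER is reported unrounded; zero effect difference yields a tagged
  undefined ratio, and dominance (cheaper-and-better /
  costlier-and-worse) is tagged rather than reported as a ratio.
* `survival_at` clips to [0, 1] against floating-point excursions; fitting
  floors S at 1e−300 inside logs.

## Limitations

* The overall-population scenarios inherit the transcription artifacts of
  their printed PFS rows (see above); their incremental costs and ICERs
  reproduce the *printed inputs*, not the published results table.
* PSA dispersion is bounded by the printed ±20 % ranges; the published
  acceptability probabilities imply wider input uncertainty than those
  ranges encode.
* Subsequent-treatment costing assumes the blended per-cycle mix for the
  whole PD sojourn; no treatment-waning, cure-fraction or duration-capped
  variants are implemented.
* One trial, no covariate adjustment, no indirect costs; the US scenario
  reuses China-trial efficacy and several China-priced inputs where the US
  table is silent.
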