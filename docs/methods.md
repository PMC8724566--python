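# Methods

## Decision problem and model structure

The package compares three first-line ICI monotherapies for advanced
NSCLC with PD-L1 ≥ 50% — cemiplimab (350 mg q3w, capped at 36 cycles /
108 weeks), pembrolizumab (200 mg q3w, capped at 35 cycles / 2 years)
and atezolizumab (1200 mg q3w, until progression) — from the US
health-care-sector perspective in 2021 dollars.

Four health states are modelled on a 3-week cycle: progression-free
(PFS), progressive disease (PD, receiving subsequent anticancer
therapy), end-stage disease (best supportive care only), and death.
Although the source framework is usually described as a Markov model,
the published material supplies survival *curves*, not transition
matrices, so occupancy is derived partitioned-survival style:

* `pfs(t) = S_PFS(t)`
* `alive(t) = S_OS(t)` (life-table blended, below)
* progressed pool `alive − pfs`, split between PD and end-stage by the
  `endstage_split` parameter
* `dead(t) = 1 − alive(t)`

Mass conservation is then exact by construction and the model
reproduces the input curves verbatim.  The timing of the PD→end-stage
transition is not identifiable from published information; the constant
split (default 0.5, swept 0.25–0.75 in DSA) reflects trial-reported
subsequent-therapy uptake of roughly half of progressors.

## Survival inputs

The reference (cemiplimab) arm uses log-logistic OS and PFS,
`S(t) = 1/(1 + λ t^κ)`, with (λ=0.02432, κ=1.11748) for OS and
(λ=0.09810, κ=1.14350) for PFS.  Two documented ambiguities of this
parameterization are exposed as configuration switches and resolved as
follows:

* **λ form** (`loglogistic_form`): the shape pair is sometimes printed
  as θ with S(t)=1/(1+exp(θ)t^κ).  Taking λ=exp(0.02432)≈1.02 implies a
  median OS of about one cycle, which contradicts the source trial;
  λ=θ directly gives a median of ≈28 time units, consistent with it.
  Default: `lambda_direct`.
* **time unit of t** (`loglogistic_time_unit`): with t in cycles the
  model understates the published pembrolizumab QALYs by ~15% and
  overstates the cemiplimab–pembrolizumab QALY gap by ~40%; with t in
  months (evaluated on the cycle grid at 0.69 months/cycle) all three
  arm totals and both QALY differences agree with the published
  analysis within ±10%.  Default: `months`, i.e. the published fit is
  read as a months-scale curve applied per cycle.

Comparator arms apply proportional hazards to the reference curves,
S^HR, with HRs (OS 1.17 / PFS 1.21 for pembrolizumab, OS 1.04 / PFS
1.16 for atezolizumab, each vs cemiplimab) taken from a network
indirect comparison as config inputs.  `icicea.nma` reimplements that
step (fixed-effect inverse-variance pooling plus the Bucher contrast)
so users can regenerate HRs from trial summaries; fixed effects were
chosen because with at most two trials per contrast the between-trial
variance is inestimable.

### Life-table blending

Heavy-tailed log-logistic extrapolation is disciplined by a life table:
beyond the end of observed trial follow-up (cycle 36) the per-cycle OS
hazard is `max(parametric hazard, life-table hazard)`.  The bundled
table (`data/synthetic_endstage_life_table.csv`, clearly synthetic) is
a surrogate for a registry extract: it emulates conditional survival of
advanced-NSCLC patients already alive ~2 years after diagnosis, with
annual hazard declining from ~20%/yr to a ~9%/yr floor — magnitudes
consistent with registry conditional-survival studies and, at the
floor, with elderly background mortality.  At these levels the blend
trims the extrapolated tail moderately; a steeply declining
from-diagnosis table (e.g. ~5% survival at 5 years) would instead
collapse mean survival to ~2 life-years and is inconsistent with the
published totals this model reproduces.  Users with a real registry
extract substitute it via `life_table` in the config or
`synthetic.surrogate_life_table`.

The horizon is 1220 cycles (~70 years), at which point the alive
fraction is below 0.1%; a warning is logged if a configuration leaves
more than that alive.

## Treatment exposure and costs

On-treatment occupancy is PFS occupancy thinned by the per-cycle
probability of AE discontinuation, `on(t) = S_PFS(t)·(1−p)^t`, and
truncated at the arm's treatment cap.  Discontinuation affects drug
cost accrual only; survival follows the trial curves, which already
include discontinuers.  Trial-period probabilities convert to per-cycle
values via p = 1−exp(−rt) with r = −ln(1−P)/D.

Drugs are dispensed at cycle starts (discounted at the cycle index);
continuous accruals (follow-up, BSC, QALYs) use mid-cycle occupancy
with half-cycle correction (on by default, toggleable).  Dosing rules:
flat mg, mg/kg (weight 70.32 kg), mg/m² (BSA 1.79 m²), and Calvert AUC
(CrCl 70 mL/min; carboplatin AUC 5, a standard-of-care assumption).
Administration costs $148.30 for the first infusion hour plus $31.40
per additional started hour (1 h/cycle for ICIs, 3 h for
chemotherapy).  AE management is a one-off cost per line started
(per-arm aggregates of incidence × management cost).  Monthly
quantities (physician visit $183.19, BSC $637.00) accrue at ×21/30.44
per cycle and 13-weekly imaging at ×21/91 per cycle, to avoid
cycle-grid artifacts.  A $9,433 terminal-care cost is charged to the
incident dead fraction.

### Subsequent therapy

The arm-specific subsequent regimens behind the published per-arm
totals are not public.  The package models them as explicit regimen
mixes over PD-state occupancy and calibrates the mix proportions once
so that the deterministic per-arm totals match the published figures
(cemiplimab ≈ $231k, pembrolizumab ≈ $208k, atezolizumab ≈ $332k):

* **cemiplimab arm** — continued cemiplimab while in PD within the
  108-week overall window, plus a 4-cycle carboplatin–pemetrexed course
  charged to incident PD entrants;
* **pembrolizumab arm** — ramucirumab+docetaxel 20%, docetaxel 30%,
  pemetrexed 4%, gemcitabine 46%;
* **atezolizumab arm** — nivolumab 15%, ramucirumab+docetaxel 20%,
  docetaxel 30%, pemetrexed 5%, gemcitabine 30%.

These are documented assumptions, exposed in the config for
replacement, not estimates of actual post-progression practice.  PD
entrants are computed as the growth of the progressed pool plus its
occupancy-proportional share of deaths.

## Utilities

Time-to-death banding uses the blended OS curve: at cycle t the alive
cohort splits by conditional survival at +1, +6 and +12 months into
bands valued 0.573 / 0.632 / 0.726 / 0.805.  Per-cycle AE disutilities
(0.006 / 0.014 / 0.005) apply to on-treatment occupancy only — the only
reading consistent with their magnitude.  Whether AE costs were charged
once or per cycle is not stated in the source; once-per-line is used
(the inputs are cumulative by construction).

## Sensitivity analysis

* **DSA** varies one parameter at a time across its stored range (95%
  CIs for HRs and utilities, ±50% otherwise; ±50% is also the fallback
  for user-added parameters without ranges).  ICERs at the bounds are
  mapped to a bounded scale for tornado ordering (dominant → 0,
  dominated → 5×WTP).  Threshold crossings are classified as *ratio*
  crossings (ΔQALY > 0 at both bounds and the ICER passes the WTP) or
  *dominance flips* (the QALY difference changes sign, as happens at
  the OS-HR lower bound); only ratio crossings correspond to "the ICER
  rising above the threshold".  `find_threshold_value` bisects for the
  crossing input value.
* **PSA** samples each parameter from its stated family, moment-matched
  so the mean equals the baseline and (low, high) maps to the central
  95% interval: Normal(μ=baseline, σ=(high−low)/3.92); Gamma with
  shape=(mean/σ)²; Beta by method of moments (range-truncated uniform
  fallback with a warning if the moments are infeasible); LogNormal
  with log-scale σ from the log-range and mean equal to baseline.
  OS and PFS HRs are sampled independently (correlation unavailable;
  a documented limitation).  Each parameter owns a substream spawned
  from the master seed, so adding a parameter does not shuffle other
  draws; invalid draws (e.g. a negative Normal-tail creatinine
  clearance) are rejected and resampled, with the count reported.
  The CEAC reports P(maximal NMB) per strategy on a WTP grid; pairwise
  summaries report the acceptability fraction
  P(NMB_ref ≥ NMB_comparator) and its decomposition into
  "cost-effective (ICER ≤ WTP)" and "dominant" fractions.

## Scenarios

* **Shared subsequent therapy**: all arms adopt the reference arm's
  post-progression regimen.  Because the published variant also shifts
  comparator survival, two readings ship: `adopt_survival=True`
  (default; comparators keep their own PFS but adopt the reference
  arm's post-progression pool) and a costs-only variant.
* **Pembrolizumab + chemotherapy**: adds a combination arm chained off
  pembrolizumab with external-source HR placeholders (OS 0.83, PFS
  0.62 vs pembrolizumab monotherapy) that users must confirm; the
  module never silently invents efficacy.  Its cost side (uncapped
  pemetrexed maintenance) is deliberately conservative.

## Synthetic data

`synthetic.simulate_ipd` draws event times by inverse CDF from
log-logistic, Weibull or exponential families with independent uniform
censoring plus administrative censoring — a stand-in for pseudo-IPD
reconstructed from published Kaplan–Meier figures.  It supports the
parameter-recovery tests (MLE on 2,000 records recovers (λ, κ) within
10%, median over 20 replicates).  What passing those tests shows is
that the fitting and simulation machinery are mutually consistent; they
say nothing about digitization error or non-log-logistic real-world
hazards.  `jitter_config` perturbs all non-structural inputs with
log-normal noise to assert the engine is total over plausible inputs.

## Numerical choices

* Discounting: (1.03)^(−cycle·21/365.25); administrations at cycle
  start, continuous accruals at mid-cycle under half-cycle correction.
* Curve grids extend ~12 months past the horizon so time-to-death
  banding needs no extrapolation; OS rebuilt from accumulated hazards
  during blending (float dust ≤1e−12 tolerated in state identities).
* AIC ties in model selection break by BIC, then by parameter count.
* Gompertz fitting caps the exponent at 500 to keep far-off optimizer
  steps finite; the shape is restricted to increasing hazard.
* PSA rejection-resamples rather than truncates, preserving
  distribution shapes; rejection counts are reported in the manifest.

## Known limitations

* Partitioned survival cannot represent individual time-in-state, so
  duration-limited subsequent therapy is approximated by per-cycle
  charging within a model-cycle window or per-course charging of PD
  entrants.
* The subsequent-therapy mixes are calibrated, not observed; per-arm
  cost conclusions inherit that assumption (QALY results do not).
* OS/PFS hazard-ratio correlation and second-line AE burden are not
  modelled.
* The bundled life table is synthetic; real registry extracts should
  replace it for applied work.
* Deterministic totals here sit ~7–8% above the published per-arm QALYs
  (within the model's stated tolerance); residual differences trace to
  the unpublished regimen table, end-stage split and life-table shape.
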