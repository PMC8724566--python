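# icicea

Cost-effectiveness modelling of first-line immune checkpoint inhibitor
(ICI) monotherapy — cemiplimab, pembrolizumab and atezolizumab — for
advanced non-small-cell lung cancer (NSCLC) with PD-L1 expression of at
least 50%, from the United States health-care-sector perspective.

The package is aimed at health-economics and HTA analysts who want a
fully scripted, testable version of this decision problem: every input
(drug prices, hazard ratios, utilities, unit costs) is a named,
documented parameter, and every published-style output — lifetime
discounted QALYs and costs per arm, pairwise ICERs, tornado diagrams,
cost-effectiveness acceptability curves — is recomputed from those
inputs at run time.

## The model

A four-state cohort model (progression-free survival, progressive
disease, end-stage disease, death) advances in 3-week cycles over a
lifetime horizon, with 3% annual discounting of costs and QALYs and a
willingness-to-pay threshold of $100,000/QALY.

State occupancy is partitioned-survival: the reference arm's OS and PFS
follow log-logistic curves

    S(t) = 1 / (1 + λ t^κ),

with (λ, κ) fitted to trial data (fitting utilities with AIC/BIC model
selection across five parametric families are included).  Comparator
arms are derived under proportional hazards, S_alt(t) = S(t)^HR, with
hazard ratios from a fixed-effect Bucher indirect comparison through the
common chemotherapy control (`icicea.nma`).  Beyond trial follow-up the
extrapolated OS hazard is floored by a registry-style life table
(hazard-max blending), so the tail never outperforms observed long-term
survivors.

QALYs use time-to-death utilities: at each cycle the alive cohort is
partitioned by conditional time until death (≥12, 6–12, 1–6, ≤1 months)
and valued at the corresponding EQ-5D-3L utilities, with per-cycle
disutilities while on first-line treatment.  Costs cover drug
acquisition (flat, per-kg, per-m² and Calvert-AUC dosing), intravenous
administration fees, adverse-event management, routine follow-up, best
supportive care, and terminal care.

Uncertainty is handled by one-way deterministic sensitivity analysis
(tornado ordering, threshold-crossing detection) and probabilistic
sensitivity analysis (moment-matched Beta/Gamma/LogNormal/Normal
sampling, CEAC output, seed-reproducible substreams per parameter).

## Worked example

```python
import icicea

config = icicea.default_config()
results = icicea.run_base_case(config)
print(icicea.reporting.render_summary(results).to_string(index=False))
```

prints

```
     strategy    cost qalys incremental_cost incremental_qalys                    icer
   cemiplimab 232,136  3.33
pembrolizumab 207,852  2.84           24,283              0.49 49,425 (cost-effective)
 atezolizumab 330,742  3.22          -98,606              0.12               Dominated
```

Reading: cemiplimab buys 0.49 extra QALYs over pembrolizumab for an
extra $24,283 — $49,425 per QALY gained, below the $100,000 threshold,
so cemiplimab is cost-effective against pembrolizumab.  Against
atezolizumab it is cheaper *and* more effective, so atezolizumab is
dominated.  One-way sensitivity analysis
(`icicea.run_dsa(config, ("cemiplimab", "pembrolizumab"))`) shows the
two ICI prices are the only single parameters able to push this ICER
above the threshold (cemiplimab above ≈ $31/mg, pembrolizumab below
≈ $42/mg), and a 10,000-draw PSA (`icicea.run_psa(config, 10_000,
seed=42)`) finds cemiplimab cost-effective versus pembrolizumab in
roughly two-thirds of draws at $100,000/QALY.

The same pipeline runs from a shell:

```bash
icicea run                     # base case (+ --scenario variants)
icicea dsa --plot              # tornado CSV + figure
icicea psa --n 10000 --seed 42 # CEAC CSV (+ --plot)
icicea write-config my.yaml    # dump the documented default inputs
```

## Layout

| module | contents |
| --- | --- |
| `icicea.config` | typed parameters/strategies/settings, YAML/JSON IO, bundled defaults |
| `icicea.survival` | log-logistic curves, S(t)^HR adjustment, MLE fitting, AIC/BIC selection |
| `icicea.nma` | inverse-variance pooling, Bucher indirect comparison |
| `icicea.engine` | cohort trace, life-table blending, discounting |
| `icicea.valuation` | dosing, administration/AE/follow-up/BSC/death costs, time-to-death utilities |
| `icicea.outcomes` | ICER, dominance, NMB, summary comparisons |
| `icicea.sensitivity` | one-way DSA, PSA, CEAC |
| `icicea.scenarios` | declarative scenario overrides and bundled scenario builders |
| `icicea.synthetic` | pseudo-IPD simulation, surrogate life tables, config jitter |
| `icicea.reporting` | summary/tornado/CEAC exports with CSV twins |

Methodological details, assumptions and limitations: `docs/methods.md`.
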