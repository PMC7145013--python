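# vteburden

Estimate the 90-day economic burden of postoperative **venous thromboembolism
(VTE)** from a surgical claims cohort.

Hospital-acquired VTE — deep-vein thrombosis and pulmonary embolism after
surgery — drives readmissions, extra outpatient care and excess payments.
Quantifying that burden from administrative claims requires dealing with
strong confounding: VTE cases are older, sicker and concentrated in high-risk
surgery types. This package implements the full observational pipeline for
health-services researchers working with per-episode claims tables:

1. **Cohort building** — eligibility (adults, not pregnant, no anticoagulant
   contraindication), ICD-10 VTE classification within 90 days of surgery
   (PE = I26.x; PTP = I80.1–I80.3, I80.8; VET = I82.x; DVT+PE = deep-vein code
   co-occurring with a PE code), Elixhauser chronic-condition flags, cost
   aggregation and regional wage-index adjustment.
2. **Propensity matching** — a probit model of VTE on sex, age group, surgery
   type, provider region and 30 chronic conditions; greedy 1:1
   nearest-neighbor matching without replacement; standardized-mean-difference
   balance diagnostics.
3. **Effect estimation** — on the matched sample, logistic models for 90-day
   readmission (RMPO) and outpatient visits (OVP), and OLS on log cost with
   **Duan's smearing retransformation**. Adjusted excess estimates use
   recycled predictions: for episode *i* with covariates *x_i*,

   Δ = (1/n) Σᵢ [ ŷᵢ(VTE = 1, x_i) − ŷᵢ(VTE = 0, x_i) ],

   where for costs ŷᵢ(v, x) = φ · exp(x'β̂) with φ = (1/n) Σ exp(ε̂ᵢ) the
   smearing factor. Standard errors come from a seeded matched-pair bootstrap
   (default 500 resamples). Component costs that are zero without the
   triggering event go through a two-part model (logistic "any cost" ×
   log-linear "cost given positive").
4. **Synthetic claims generator** — a fully parameterised cohort simulator
   (probit exposure, log-normal costs with a multiplicative VTE effect,
   logistic outcomes, gamma hospital days) with closed-form truths, so every
   stage is testable without access to any claims database.

## Worked example

```python
import vteburden as vb

cfg = vb.RunConfig(n_episodes=30_000, seed=5, vte_prevalence=0.02, bootstrap=100)
bundle = vb.run_pipeline(cfg, out_dir="scratch/pipeline_demo")
s = bundle["summary"]
print(s["n_matched_pairs"], round(s["excess"]["ALL"]["excess_total_cost"], 1))
```

prints (see `examples/04_full_pipeline.py`):

```
matched pairs: 612
excess total cost (ALL VTE): $1,082.2 (SE 87.1)
adjusted readmission OR by class: {"vte_class[PE]": 5.2, "vte_class[PTP]": 8.69, ...}
cumulative cost gap at day 90: $1,075.6
```

612 of ~600 simulated VTE cases found a nearest-propensity control; toggling
the VTE indicator in the smeared log-cost model attributes about US$1,082 of
the 90-day payment per episode to VTE (the generating truth in this
simulation is ≈US$1,000), and readmission odds are several-fold higher in
every VTE class. The `examples/` directory has one short script per
capability (simulation, classification + matching, excess estimation, full
pipeline); each prints what it computes and what the numbers mean.

A thin CLI mirrors the pipeline stages:

```bash
vteburden simulate --n 30000 --seed 5 --out scratch/sim
vteburden build-cohort --in scratch/sim/episodes.csv --out scratch/cohort.csv
vteburden match --in scratch/cohort.csv --seed 5 --out scratch/matched
vteburden analyze --in scratch/matched/matched_episodes.csv --bootstrap 200 --seed 5 --out scratch/results
vteburden run-all --seed 5 --out scratch/full
```

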