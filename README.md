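# worklife

Multistate estimation of **working life expectancy (WLE)** and **working
years lost (WYL)** for older workers, between ages 50 and 66.

Occupational-health researchers increasingly summarise late working
careers with a single pair of metrics: how many of the 16 years between
50 and 66 a person employed at 50 can expect to spend in paid work
(WLE), and how the remaining years split across exit pathways —
involuntary exit (unemployment, disability benefits), voluntary exit
(economic inactivity, early retirement), and death. Because the
register-linked survey cohorts these analyses run on are access
restricted, this package pairs the full estimation pipeline with a
synthetic-cohort generator that has known ground truth, so every stage
can be validated end to end.

## Model

Monthly labor-market states follow a four-state process — employment
(1), involuntary exit (2), voluntary exit (3), death (4, absorbing) —
with nine allowed transitions (all moves among 1–3, plus each into 4).
For each transition *h → j*, a Cox proportional hazards model on the
**age** time scale (clock forward, delayed entry, Breslow ties) gives

λ_hj(a | x) = λ_hj0(a) · exp(β_hjᵀ x),

with covariates x = gender, education (low/intermediate/high),
chronic-disease status, and top-quartile working-condition exposure
(physical workload, job demands, autonomy, emotional demands, social
support — 5-point items recoded so higher is worse, summed, cut at the
sample P75). The Breslow baseline cumulative hazards feed the
**Aalen–Johansen** product integral

P(s, t) = ∏_{u ∈ (s, t]} ( I + dA(u) ),

and the **expected length of stay** in state j given state h at s is
ELOS_hj = ∫_s^66 P_hj(s, u) du. Then, conditional on employment at 50:

- WLE = ELOS_11,  WYL_invol = ELOS_12,  WYL_vol = ELOS_13,
  WYL_mort = ELOS_14, and WLE + ΣWYL = 16 years exactly.

Uncertainty comes from a percentile bootstrap: persons (with their whole
timelines) are resampled with replacement, the full pipeline re-runs per
replicate, and the 2.5th/97.5th percentiles bound the 95% interval.

## Worked example

```python
import worklife as wl
from worklife.simulate import analytic_wle

cfg = wl.recovery_config(n=5000, seed=3)     # known disease log-HR 0.5
cohort = wl.simulate_cohort(cfg, seed=3)
occ = wl.estimate_wle(cohort, covariates=["chronic_disease"])
```

Running `python examples/04_wle_decomposition.py` (the same pipeline)
prints:

```
reference profile (no chronic disease), start age 50, horizon 66:
  WLE                9.52 years in paid employment
  involuntary WYL    1.63 years (unemployment / disability)
  voluntary WYL      3.81 years (inactivity / early retirement)
  mortality WYL      1.04 years
  sum = 16.000000 years (= the 16-year window, exactly)
matrix-exponential truth for this scenario: WLE 9.460; estimation error +0.057 years
with chronic disease the same model predicts WLE 8.35 (1.17 years lower)
```

A worker employed at 50 in this scenario can expect 9.5 of the next 16
years in paid work; the decomposition attributes the lost years to the
three pathways and sums to the window exactly; the estimate sits within
Monte-Carlo error of the generator's analytic truth.

The other `examples/` scripts walk through scale scoring and cohort
inclusion (01), synthetic-cohort structure and CSV round trips (02),
episode preparation and per-transition Cox fits (03), and bootstrap
intervals with stratified education × disease reports (05). The same
pipeline is scriptable from the shell:

```bash
wle simulate --n 10000 --seed 1 --out data/
wle estimate --persons data/persons.csv --timeline data/timeline.csv \
    --strata education,disease --b 1000 --seed 1 --out results/
```

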