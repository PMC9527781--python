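"""Percentile-bootstrap intervals and a stratified WLE/WYL report.

Resamples persons with replacement (keeping whole timelines), re-runs
the pipeline per replicate, and reads 95% intervals from the 2.5th and
97.5th percentiles; then produces an education x chronic-disease report
in the layout of the standard WLE tables.
"""

import worklife as wl

cohort = wl.simulate_cohort(wl.paper_like_config(n=3000, seed=6))

res = wl.bootstrap_elos(cohort, spec=wl.BootstrapSpec(B=200, seed=1))
print("pooled decomposition with 95% percentile intervals "
      f"(B={res.spec.B}, person-level resampling):")
print(res.summary().round(2).to_string(index=False))

rows = wl.run_stratified_analysis(
    cohort,
    wl.StratumSpec(stratify_by=("education", "chronic_disease"),
                   adjust_for=("female",)),
    spec=wl.BootstrapSpec(B=100, seed=2),
)
print("\nWLE/WYL by education and chronic disease "
      "(profile prediction from one pooled fit, adjusted for gender):")
print(wl.render_report(rows))
print("\nInvoluntary years lost rise with chronic disease inside every "
      "education level; voluntary years barely move.")
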