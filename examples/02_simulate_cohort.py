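"""Simulate a synthetic older-worker cohort and inspect its structure.

The default scenario draws education, chronic disease given education,
gender and working-condition exposure given both, then monthly
labor-market timelines from a continuous-time Markov process. Writing
and re-reading the cohort exercises the CSV schemas.
"""

import tempfile
from collections import Counter

import worklife as wl

cfg = wl.paper_like_config(n=4000, seed=1)
cohort = wl.simulate_cohort(cfg)
print(f"simulated {cohort.n} persons observed inside the 50-66 window")

edu = Counter(r.education for r in cohort.respondents)
print("education mix:", {k: f"{v / cohort.n:.0%}" for k, v in edu.items()})
for level in ("low", "mid", "high"):
    grp = [r for r in cohort.respondents if r.education == level]
    dis = sum(r.chronic_disease for r in grp) / len(grp)
    print(f"  chronic disease | {level} education: {dis:.0%}")

deaths = sum(t.states[-1] == wl.DEAD for t in cohort.timelines)
print(f"deaths during follow-up: {deaths / cohort.n:.1%}")

with tempfile.TemporaryDirectory() as tmp:
    paths = wl.write_cohort(cohort, tmp)
    back = wl.read_cohort(paths["persons"], paths["timeline"])
    print(f"CSV round trip: wrote and re-read {back.n} persons; "
          f"quartile thresholds {back.quartile_thresholds}")
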