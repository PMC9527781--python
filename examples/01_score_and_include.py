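"""Questionnaire scoring, top-quartile exposure, and cohort inclusion.

Builds a handful of respondents by hand, scores a working-condition
scale, dichotomizes at the sample's 75th percentile, and applies the
inclusion rules (self-employment, working-condition availability, the
major-disease rule, and the 50-66 age window).
"""

import numpy as np

import worklife as wl

# Four psychological job-demand items, raw 5-point responses where
# 1='always' .. 5='(almost) never'; the scale is reverse-coded so that
# frequent demands score high.
raw = (1, 2, 1, 3)
score = wl.score_working_condition(raw, wl.SCALES["job_demands"])
print(f"job-demands raw responses {raw} -> sum score {score} "
      f"(range {wl.SCALES['job_demands'].min_score}-"
      f"{wl.SCALES['job_demands'].max_score}, higher = worse)")

scores = np.array([8, 9, 10, 10, 11, 12, 14, 16, 17, 18, 19, 20])
thr, exposed = wl.dichotomize_top_quartile(scores)
print(f"sample P75 = {thr:.2f}; exposed (strictly above): "
      f"{int(exposed.sum())}/{len(scores)} respondents")

for reports in [set(), {"musculoskeletal", "migraine"}, {"migraine"}]:
    print(f"disease reports {sorted(reports) or '{}'} -> "
          f"{wl.classify_chronic_disease(reports)}")

respondents = []
timelines = {}
for i, kwargs in enumerate([
    {},                                            # kept
    {"self_employed": True},                       # dropped: self-employed
    {"disease_reports": frozenset({"epilepsy"})},  # dropped: minor disease only
]):
    rec = wl.RespondentRecord(
        id=f"p{i}", gender="F", education="mid",
        wc_items={"job_demands": raw}, **kwargs,
    )
    respondents.append(rec)
    # employed from age 49 for five years: entry is truncated to 50
    timelines[rec.id] = wl.StateTimeline(
        id=rec.id, start_month=49 * 12, states=np.ones(60, dtype=np.int8)
    )

cohort = wl.apply_inclusion_rules(respondents, timelines)
print("inclusion log (step, before, after):", cohort.log)
print("kept:", [r.id for r in cohort.respondents],
      "entry age:", cohort.respondents[0].entry_age)
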