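"""Scale scoring, quartile dichotomization, disease classification,
inclusion rules and cohort CSV round trips."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import worklife as wl
from worklife.cohort import (
    CohortInputError,
    DISEASE_CHECKLIST,
    EXCLUDED,
    INCLUDED_WITH_DISEASE,
    INCLUDED_WITHOUT_DISEASE,
    MAJOR_DISEASES,
)

from conftest import make_respondent, make_timeline


class TestScaleScoring:
    @pytest.mark.parametrize(
        "scale_name,raw,expected",
        [
            # demand items are reverse-coded: raw 1 ('always') scores 5
            ("physical_workload", (1, 1, 1, 1, 1), 25),
            ("emotional_demands", (5, 5, 5), 3),
            # recoded items (2,3,4,1) on job_demands: raw = 6 - recoded
            ("job_demands", (4, 3, 2, 5), 10),
            # resource scale not reversed: raw 5 ('almost never') is worst
            ("autonomy", (5, 5, 5, 5, 5), 25),
            ("social_support", (1, 1, 1, 1), 4),
        ],
    )
    def test_sum_scores(self, scale_name, raw, expected):
        assert wl.score_working_condition(raw, wl.SCALES[scale_name]) == expected

    def test_wrong_item_count_names_scale(self):
        with pytest.raises(CohortInputError, match="job_demands"):
            wl.score_working_condition((1, 2, 3), wl.SCALES["job_demands"])

    def test_out_of_range_names_item(self):
        with pytest.raises(CohortInputError, match="item 2"):
            wl.score_working_condition((1, 2, 6), wl.SCALES["emotional_demands"])

    @given(
        st.permutations(list(range(5))),
        st.lists(st.integers(1, 5), min_size=5, max_size=5),
    )
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant_when_items_exchangeable(self, perm, items):
        """Scoring is a sum, so item order cannot matter on a scale whose
        items share one recoding direction."""
        scale = wl.SCALES["physical_workload"]
        base = wl.score_working_condition(items, scale)
        shuffled = [items[p] for p in perm]
        assert wl.score_working_condition(shuffled, scale) == base
        assert scale.min_score <= base <= scale.max_score


class TestTopQuartile:
    def test_uniform_scores_give_quarter_prevalence(self):
        scores = np.arange(1, 101)
        thr, exposed = wl.dichotomize_top_quartile(scores)
        assert abs(exposed.sum() - 25) <= 1

    def test_all_identical_nobody_exposed(self):
        thr, exposed = wl.dichotomize_top_quartile(np.full(40, 7.0))
        assert not exposed.any()

    def test_tie_mass_at_threshold_goes_to_referent(self):
        scores = np.array([5, 5, 5, 5, 20, 20, 20, 20])
        thr, exposed = wl.dichotomize_top_quartile(scores)
        assert thr == 20.0
        assert not exposed.any()

    def test_missing_scores_unexposed(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        _, exposed = wl.dichotomize_top_quartile(scores)
        assert not exposed[-1]

    def test_all_missing_errors(self):
        with pytest.raises(CohortInputError):
            wl.dichotomize_top_quartile(np.array([np.nan, np.nan, np.nan, np.nan]))

    @given(
        st.lists(
            st.integers(min_value=3, max_value=15), min_size=4, max_size=200
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_prevalence_bounded_by_quartile_plus_ties(self, scores):
        """Strictly-greater-than-P75 exposure can never exceed 25% of the
        sample plus the mass tied at the threshold, up to one observation
        (the interpolated percentile sits between order statistics)."""
        arr = np.asarray(scores, dtype=float)
        thr, exposed = wl.dichotomize_top_quartile(arr)
        tie_mass = (arr == thr).mean()
        assert exposed.mean() <= 0.25 + tie_mass + 1.0 / arr.size


class TestDiseaseClassification:
    @pytest.mark.parametrize(
        "reports,expected",
        [
            ({"musculoskeletal", "migraine"}, INCLUDED_WITH_DISEASE),
            (set(), INCLUDED_WITHOUT_DISEASE),
            ({"migraine"}, EXCLUDED),
            ({"epilepsy", "skin"}, EXCLUDED),
            ({"diabetes"}, INCLUDED_WITH_DISEASE),
        ],
    )
    def test_classification(self, reports, expected):
        assert wl.classify_chronic_disease(reports) == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(CohortInputError, match="gout"):
            wl.classify_chronic_disease({"gout"})

    @given(
        st.sets(st.sampled_from(sorted(DISEASE_CHECKLIST)), max_size=6)
    )
    @settings(max_examples=200, deadline=None)
    def test_partition_is_exhaustive_and_exclusive(self, reports):
        """Every label subset lands in exactly one of the three groups,
        and the with-disease group is exactly 'has a major disease'."""
        out = wl.classify_chronic_disease(reports)
        assert out in (INCLUDED_WITH_DISEASE, INCLUDED_WITHOUT_DISEASE, EXCLUDED)
        assert (out == INCLUDED_WITH_DISEASE) == bool(reports & MAJOR_DISEASES)
        assert (out == INCLUDED_WITHOUT_DISEASE) == (not reports)


class TestTimelines:
    def test_gap_month_rejected(self):
        with pytest.raises(CohortInputError, match="gap"):
            wl.StateTimeline.from_observations("a", [(600, 1), (602, 1)])

    def test_bad_state_code_rejected(self):
        with pytest.raises(CohortInputError, match="state code 7"):
            wl.StateTimeline.from_observations("a", [(600, 1), (601, 7)])

    def test_resume_after_death_rejected(self):
        with pytest.raises(CohortInputError, match="after death"):
            make_timeline("a", 600, [(1, 5), (4, 1), (1, 3)])

    def test_truncation_window(self):
        t = make_timeline("a", 580, [(1, 300)])
        cut = t.truncate(600, 792)
        assert cut.start_month == 600 and cut.end_month == 792


class TestInclusionRules:
    def _base(self):
        resp = [
            make_respondent("a"),
            make_respondent("b", self_employed=True),
            make_respondent("c", disease_reports=frozenset({"migraine"})),
            make_respondent("d", wc_items={}),
            make_respondent("e", disease_reports=frozenset({"diabetes"})),
        ]
        tls = {r.id: make_timeline(r.id, 600, [(1, 100)]) for r in resp}
        return resp, tls

    def test_each_rule_drops_its_target(self):
        resp, tls = self._base()
        cohort = wl.apply_inclusion_rules(resp, tls)
        ids = [r.id for r in cohort.respondents]
        assert ids == ["a", "e"]
        assert dict((s, (b, a)) for s, b, a in cohort.log)["drop_self_employed"] == (5, 4)

    def test_chronic_flag_set_only_for_included(self):
        resp, tls = self._base()
        cohort = wl.apply_inclusion_rules(resp, tls)
        flags = {r.id: r.chronic_disease for r in cohort.respondents}
        assert flags == {"a": False, "e": True}

    def test_turning_50_in_followup_enters_at_50(self):
        resp = [make_respondent(f"p{i}") for i in range(4)]
        tls = {r.id: make_timeline(r.id, 600, [(1, 60)]) for r in resp}
        # p0 starts observation at 48y; months before 50 are cut
        tls["p0"] = make_timeline("p0", 576, [(1, 90)])
        cohort = wl.apply_inclusion_rules(resp, tls)
        entry = {r.id: r.entry_age for r in cohort.respondents}
        assert entry["p0"] == 50.0

    def test_respondent_without_timeline_errors_with_ids(self):
        resp = [make_respondent("a"), make_respondent("zz")]
        tls = {"a": make_timeline("a", 600, [(1, 10)])}
        with pytest.raises(CohortInputError, match="zz"):
            wl.apply_inclusion_rules(resp, tls)

    def test_observation_outside_window_dropped_entirely(self):
        resp = [make_respondent("a"), make_respondent("b")]
        tls = {
            "a": make_timeline("a", 600, [(1, 10)]),
            "b": make_timeline("b", 792, [(1, 10)]),  # all past 66
        }
        for r in resp[:0]:
            pass
        cohort = wl.apply_inclusion_rules(resp, tls)
        assert [r.id for r in cohort.respondents] == ["a"]


class TestRoundTrip:
    def test_write_then_read_is_identity(self, tmp_path):
        cfg = wl.recovery_config(n=30, seed=3)
        sim = wl.simulate_cohort(cfg, seed=3)
        paths = wl.write_cohort(sim, tmp_path)
        first = wl.read_cohort(paths["persons"], paths["timeline"])
        paths2 = wl.write_cohort(first, tmp_path / "again")
        second = wl.read_cohort(paths2["persons"], paths2["timeline"])

        assert [r.id for r in first.respondents] == [r.id for r in second.respondents]
        for r1, r2 in zip(first.respondents, second.respondents):
            assert r1.gender == r2.gender
            assert r1.education == r2.education
            assert r1.disease_reports == r2.disease_reports
            assert r1.wc_items == r2.wc_items
            assert r1.wc_exposed == r2.wc_exposed
            assert r1.chronic_disease == r2.chronic_disease
            assert r1.entry_age == r2.entry_age
        for t1, t2 in zip(first.timelines, second.timelines):
            assert t1.start_month == t2.start_month
            assert np.array_equal(t1.states, t2.states)
        assert first.quartile_thresholds == second.quartile_thresholds

    def test_timeline_gap_in_csv_rejected(self, tmp_path):
        cfg = wl.recovery_config(n=10, seed=3)
        paths = wl.write_cohort(wl.simulate_cohort(cfg, seed=3), tmp_path)
        import pandas as pd

        tl = pd.read_csv(paths["timeline"])
        tl = tl.drop(index=5)  # punch a hole in the first person's months
        tl.to_csv(paths["timeline"], index=False)
        with pytest.raises(CohortInputError, match="gap"):
            wl.read_cohort(paths["persons"], paths["timeline"])

    def test_missing_scale_kept_all_missing_dropped(self):
        keep = make_respondent(
            "keep", wc_items={"autonomy": (2, 2, 2, 2, 2)}
        )
        drop = make_respondent("drop", wc_items={})
        tls = {
            "keep": make_timeline("keep", 600, [(1, 20)]),
            "drop": make_timeline("drop", 600, [(1, 20)]),
        }
        cohort = wl.apply_inclusion_rules([keep, drop], tls)
        assert [r.id for r in cohort.respondents] == ["keep"]
        assert math.isnan(cohort.respondents[0].wc_scores["physical_workload"])
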