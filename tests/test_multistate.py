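"""Episode expansion, per-transition Cox fits, Breslow/Nelson-Aalen
baselines and proportional-hazards prediction."""

import numpy as np
import pytest

import worklife as wl
from worklife.cohort import CohortInputError
from worklife.states import TRANSITIONS

from conftest import make_respondent, make_timeline


class TestStateSpace:
    def test_structure(self):
        space = wl.build_state_space()
        assert space.n_transitions == 9
        assert space.transition_number(wl.EMPLOYED, wl.DEAD) == 3
        assert space.targets(wl.DEAD) == ()
        for h in (1, 2, 3, 4):
            assert space.transition_number(h, h) == 0

    def test_numbering_is_row_major(self):
        space = wl.build_state_space()
        for q, (h, j) in enumerate(TRANSITIONS, start=1):
            assert space.transition_number(h, j) == q


def _one_person_cohort(runs, start=600):
    rec = make_respondent("x")
    tl = make_timeline("x", start, runs)
    rec.entry_age = start / 12
    return wl.AnalysisCohort(respondents=[rec], timelines=[tl])


class TestEpisodePreparation:
    def test_documented_expansion(self):
        # employed 50-55, involuntary 55-57, dead at 57
        cohort = _one_person_cohort([(1, 60), (2, 24), (4, 1)])
        table = wl.prepare_episodes(cohort, covariates=[])
        df = table.to_frame()
        assert len(df) == 6
        spell1 = df[df["from"] == 1]
        assert set(spell1["trans"]) == {1, 2, 3}
        assert (spell1["Tstart"] == 50.0).all() and (spell1["Tstop"] == 55.0).all()
        assert spell1.set_index("trans")["status"].to_dict() == {1: 1, 2: 0, 3: 0}
        spell2 = df[df["from"] == 2]
        assert (spell2["Tstart"] == 55.0).all() and (spell2["Tstop"] == 57.0).all()
        assert spell2.set_index("trans")["status"].to_dict() == {4: 0, 5: 0, 6: 1}

    def test_administrative_censoring_at_66(self):
        cohort = _one_person_cohort([(1, 192)])
        df = wl.prepare_episodes(cohort, covariates=[]).to_frame()
        assert len(df) == 3
        assert (df["status"] == 0).all()
        assert (df["Tstop"] == 66.0).all()

    def test_person_time_conserved(self, midsize_cohort):
        """Competing rows share the spell interval, so total spell time
        equals observed non-absorbing person-months (counting oracle)."""
        table = wl.prepare_episodes(midsize_cohort, covariates=[])
        months = sum(
            int((t.states != wl.DEAD).sum()) for t in midsize_cohort.timelines
        )
        assert table.person_time_years() == pytest.approx(months / 12, abs=1e-9)
        df = table.to_frame()
        per_spell = df.groupby(["id", "Tstart"])
        assert (per_spell["Tstop"].nunique() == 1).all()

    def test_multiple_reentries_produce_one_spell_each(self):
        cohort = _one_person_cohort([(1, 12), (3, 12), (1, 12), (2, 12)])
        table = wl.prepare_episodes(cohort, covariates=[])
        assert table.n_spells == 4
        assert list(table.from_state) == [1, 3, 1, 2]
        assert list(table.to_state) == [3, 1, 2, 0]


class TestHazardFits:
    def test_no_covariates_baseline_equals_nelson_aalen(self, midsize_cohort):
        """With no covariates the Breslow baseline must coincide with the
        Nelson-Aalen estimator (independent oracle: lifelines with
        left-truncated entry)."""
        from lifelines import NelsonAalenFitter

        table = wl.prepare_episodes(midsize_cohort, covariates=[])
        models = wl.fit_transition_hazards(table, covariates=[])
        for q in (1, 4):  # employment exit and re-entry
            at_risk, status = table.rows_for_transition(q)
            naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
            naf.fit(
                durations=table.m_exit[at_risk] / 12,
                event_observed=status,
                entry=table.m_entry[at_risk] / 12,
            )
            m = models.models[q]
            ours = np.cumsum(m.base_increments)
            theirs = naf.cumulative_hazard_.iloc[:, 0]
            for month, value in zip(m.jump_months, ours):
                assert value == pytest.approx(
                    float(theirs.loc[month / 12]), rel=1e-9
                )

    def test_replication_invariance(self, midsize_cohort):
        """Duplicating every person changes neither coefficients nor the
        baseline cumulative hazard (partial-likelihood invariance)."""
        covs = ["chronic_disease"]
        doubled = midsize_cohort.take(
            list(range(midsize_cohort.n)) * 2, relabel=True
        )
        t1 = wl.prepare_episodes(midsize_cohort, covariates=covs)
        t2 = wl.prepare_episodes(doubled, covariates=covs)
        m1 = wl.fit_transition_hazards(t1, covariates=covs)
        m2 = wl.fit_transition_hazards(t2, covariates=covs)
        for q in (1, 2):
            # equality is exact in theory; slack covers the fitter's
            # iterative convergence tolerance
            assert m1.models[q].beta["chronic_disease"] == pytest.approx(
                m2.models[q].beta["chronic_disease"], abs=1e-4
            )
            assert np.allclose(
                m1.models[q].base_increments, m2.models[q].base_increments,
                rtol=1e-4,
            )

    def test_left_truncation_risk_sets(self):
        """A person entering after another's event must not enter that
        event's risk set: the early increment stays 1/Y of the early
        entrants only."""
        recs = [make_respondent(f"p{i}") for i in range(3)]
        tls = [
            make_timeline("p0", 600, [(1, 12), (2, 12)]),  # event at 51
            make_timeline("p1", 600, [(1, 100)]),
            make_timeline("p2", 660, [(1, 60)]),  # enters at 55
        ]
        for r, t in zip(recs, tls):
            r.entry_age = t.start_month / 12
        cohort = wl.AnalysisCohort(respondents=recs, timelines=tls)
        models = wl.fit_transition_hazards(
            wl.prepare_episodes(cohort, covariates=[]), covariates=[]
        )
        m = models.models[1]
        assert list(m.jump_months) == [612]
        assert m.base_increments[0] == pytest.approx(1 / 2)

    def test_zero_event_transition_warns_not_fails(self):
        cohort = _one_person_cohort([(1, 192)])
        table = wl.prepare_episodes(cohort, covariates=[])
        with pytest.warns(UserWarning, match="zero events"):
            models = wl.fit_transition_hazards(table, covariates=[])
        assert models.models[1].n_events == 0

    def test_known_coefficient_recovered(self, midsize_cohort):
        """Simulated disease log-HR 0.5 on the exit-to-involuntary
        transition is recovered within sampling error."""
        table = wl.prepare_episodes(midsize_cohort, covariates=["chronic_disease"])
        models = wl.fit_transition_hazards(table, covariates=["chronic_disease"])
        assert models.models[1].beta["chronic_disease"] == pytest.approx(
            0.5, abs=0.15
        )


class TestPrediction:
    def test_reference_profile_returns_baseline(self, midsize_cohort):
        table = wl.prepare_episodes(midsize_cohort, covariates=["chronic_disease"])
        models = wl.fit_transition_hazards(table, covariates=["chronic_disease"])
        base = models.predict_cumhaz({})
        ref = models.predict_cumhaz({"chronic_disease": 0.0})
        for q in base:
            assert np.array_equal(base[q][1], ref[q][1])

    def test_jumps_scale_by_exp_beta(self, midsize_cohort):
        table = wl.prepare_episodes(midsize_cohort, covariates=["chronic_disease"])
        models = wl.fit_transition_hazards(table, covariates=["chronic_disease"])
        b = float(models.models[1].beta["chronic_disease"])
        months0, inc0 = models.predict_cumhaz({})[1]
        months1, inc1 = models.predict_cumhaz({"chronic_disease": 1.0})[1]
        assert np.array_equal(months0, months1)
        assert np.allclose(inc1, inc0 * np.exp(b))
        assert (np.diff(np.cumsum(inc1)) >= -1e-12).all()  # still monotone

    def test_unknown_profile_name_rejected(self, midsize_cohort):
        table = wl.prepare_episodes(midsize_cohort, covariates=["chronic_disease"])
        models = wl.fit_transition_hazards(table, covariates=["chronic_disease"])
        with pytest.raises(CohortInputError, match="not among fitted"):
            models.predict_cumhaz({"shoe_size": 1.0})
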