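"""Episode preparation and per-transition hazard estimation on the age scale.

Monthly state timelines are expanded into counting-process spells: each
maximal run of months in a non-absorbing state is one spell, at risk for
the (up to three) competing transitions out of that state, with delayed
entry at the spell's first month and an event dated at the age of the
first month spent in the new state. A Cox proportional hazards model is
fitted separately per transition with age as the time variable (clock
forward), Breslow tie handling, and the Breslow baseline cumulative
hazard recovered on the monthly grid. With no covariates the baseline
reduces to the Nelson-Aalen estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import AnalysisCohort, CohortInputError
from .states import DEAD, MONTHS_PER_YEAR, StateSpace, TRANSITIONS, build_state_space

__all__ = [
    "Episode",
    "EpisodeTable",
    "TransitionModel",
    "TransitionModelSet",
    "design_matrix",
    "prepare_episodes",
    "fit_transition_hazards",
    "predict_cumhaz",
]

#: Covariates derivable from every cohort; working-condition flags are added
#: per scale as ``wc_<scale>``.
BASE_COVARIATES = ("female", "edu_mid", "edu_high", "chronic_disease")


class FitError(RuntimeError):
    """Raised when a per-transition hazard fit fails to converge."""


@dataclass(frozen=True)
class Episode:
    """One at-risk row: a spell paired with one competing transition."""

    id: str
    transition: int
    from_state: int
    to_state: int
    t_entry: float
    t_exit: float
    status: int

    def __post_init__(self) -> None:
        if not self.t_entry < self.t_exit:
            raise ValueError(
                f"episode {self.id}: t_entry {self.t_entry} >= t_exit {self.t_exit}"
            )


@dataclass
class EpisodeTable:
    """Counting-process spells plus person-level covariates.

    Spells are stored compactly (one entry per occupied non-absorbing
    spell); :meth:`to_frame` expands to the long format with one row per
    competing transition per spell, sharing (t_entry, t_exit] within a
    spell with status 1 on at most one row.
    """

    ids: list[str]
    person_idx: np.ndarray  # spell -> respondent index
    from_state: np.ndarray
    to_state: np.ndarray  # 0 when censored
    m_entry: np.ndarray  # months
    m_exit: np.ndarray
    X: np.ndarray  # person-level covariate matrix (n_persons x k)
    covariate_names: list[str]
    space: StateSpace = field(default_factory=build_state_space)

    @property
    def n_spells(self) -> int:
        return int(self.from_state.size)

    def person_time_years(self) -> float:
        """Total person-time in non-absorbing states, in years."""
        return float((self.m_exit - self.m_entry).sum()) / MONTHS_PER_YEAR

    def rows_for_transition(self, q: int) -> tuple[np.ndarray, np.ndarray]:
        """(spell indices at risk, event indicator) for transition number q."""
        h, j = TRANSITIONS[q - 1]
        at_risk = np.flatnonzero(self.from_state == h)
        status = (self.to_state[at_risk] == j).astype(int)
        return at_risk, status

    def to_frame(self) -> pd.DataFrame:
        """Long-format expansion: one row per competing transition per spell."""
        rows = []
        for s in range(self.n_spells):
            h = int(self.from_state[s])
            for j in self.space.targets(h):
                q = self.space.transition_number(h, j)
                rows.append(
                    {
                        "id": self.ids[self.person_idx[s]],
                        "trans": q,
                        "from": h,
                        "to": j,
                        "Tstart": round(self.m_entry[s] / MONTHS_PER_YEAR, 6),
                        "Tstop": round(self.m_exit[s] / MONTHS_PER_YEAR, 6),
                        "status": int(self.to_state[s] == j),
                        **{
                            name: self.X[self.person_idx[s], c]
                            for c, name in enumerate(self.covariate_names)
                        },
                    }
                )
        return pd.DataFrame(rows)


def design_matrix(
    cohort: AnalysisCohort, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Person-level design matrix for the requested covariates.

    Supported names: ``female``, ``edu_mid``, ``edu_high``,
    ``chronic_disease`` and ``wc_<scale>`` (top-quartile exposure flag).
    Reference profile: male, low education, no disease, unexposed.
    """
    cols = []
    for name in covariates:
        if name == "female":
            col = [1.0 if r.gender == "F" else 0.0 for r in cohort.respondents]
        elif name == "edu_mid":
            col = [1.0 if r.education == "mid" else 0.0 for r in cohort.respondents]
        elif name == "edu_high":
            col = [1.0 if r.education == "high" else 0.0 for r in cohort.respondents]
        elif name == "chronic_disease":
            col = [1.0 if r.chronic_disease else 0.0 for r in cohort.respondents]
        elif name.startswith("wc_"):
            scale = name[3:]
            col = [
                1.0 if r.wc_exposed.get(scale) else 0.0 for r in cohort.respondents
            ]
        else:
            raise CohortInputError(f"unknown covariate {name!r}")
        cols.append(col)
    if not cols:
        return np.zeros((cohort.n, 0)), []
    return np.asarray(cols, dtype=float).T, list(covariates)


def prepare_episodes(
    cohort: AnalysisCohort,
    space: StateSpace | None = None,
    covariates: Sequence[str] = BASE_COVARIATES,
) -> EpisodeTable:
    """Expand monthly timelines into counting-process spells.

    Each maximal run of months in a non-absorbing state becomes one
    spell with delayed entry at its first month. A transition observed
    between month m and m+1 is dated at age (m+1)/12; the last spell is
    administratively censored at the end of observation (or 66 years,
    whichever the timeline reaches first, since timelines are already
    truncated to the analysis window).
    """
    space = space or build_state_space()
    X, names = design_matrix(cohort, covariates)

    n = cohort.n
    sizes = np.empty(n, dtype=np.int64)
    start_months = np.empty(n, dtype=np.int64)
    for i, t in enumerate(cohort.timelines):
        sizes[i] = t.states.size
        start_months[i] = t.start_month
    if n == 0 or sizes.sum() == 0:
        raise CohortInputError("no observations in cohort")
    states = np.concatenate([t.states for t in cohort.timelines])
    first_idx = np.concatenate(([0], np.cumsum(sizes)[:-1]))

    change = np.empty(states.size, dtype=bool)
    change[0] = True
    change[1:] = states[1:] != states[:-1]
    change[first_idx] = True

    spell_start = np.flatnonzero(change)
    spell_person = np.searchsorted(first_idx, spell_start, side="right") - 1
    spell_from = states[spell_start]
    # month at flat index i of person p is start_months[p] + (i - first_idx[p])
    spell_m_entry = start_months[spell_person] + spell_start - first_idx[spell_person]
    # end of each spell: start of next spell (same person) or person's end
    same_person = np.empty(spell_start.size, dtype=bool)
    same_person[:-1] = spell_person[:-1] == spell_person[1:]
    same_person[-1] = False
    next_start = np.empty(spell_start.size, dtype=np.int64)
    next_start[:-1] = spell_start[1:]
    next_start[-1] = 0  # placeholder; masked by same_person

    spell_to = np.where(same_person, states[next_start], 0)
    next_entry = np.empty(spell_start.size, dtype=np.int64)
    next_entry[:-1] = spell_m_entry[1:]
    next_entry[-1] = 0
    spell_m_exit = np.where(
        same_person, next_entry, start_months[spell_person] + sizes[spell_person]
    )

    keep = spell_from != DEAD  # death rows carry no risk time
    return EpisodeTable(
        ids=[t.id for t in cohort.timelines],
        person_idx=spell_person[keep],
        from_state=spell_from[keep].astype(int),
        to_state=spell_to[keep].astype(int),
        m_entry=spell_m_entry[keep],
        m_exit=spell_m_exit[keep],
        X=X,
        covariate_names=names,
        space=space,
    )


# ---------------------------------------------------------------------------
# Hazard estimation
# ---------------------------------------------------------------------------

@dataclass
class TransitionModel:
    """Fitted hazard for one transition: log hazard ratios plus the
    Breslow baseline cumulative hazard as a step function of age."""

    transition: int
    beta: pd.Series
    jump_months: np.ndarray
    base_increments: np.ndarray
    n_events: int
    n_at_risk: int
    log_likelihood: float = float("nan")

    def cumhaz_increments(
        self, profile: Mapping[str, float] | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """(jump months, hazard increments) scaled to a covariate profile."""
        if profile is None or len(self.beta) == 0:
            return self.jump_months, self.base_increments
        eta = sum(
            float(self.beta[name]) * float(profile.get(name, 0.0))
            for name in self.beta.index
        )
        return self.jump_months, self.base_increments * np.exp(eta)

    def cumhaz_at(self, t_years: float, profile=None) -> float:
        months, inc = self.cumhaz_increments(profile)
        return float(inc[months <= t_years * MONTHS_PER_YEAR + 1e-9].sum())


@dataclass
class TransitionModelSet:
    """One fitted :class:`TransitionModel` per transition number 1..9."""

    models: dict[int, TransitionModel]
    covariate_names: list[str]
    space: StateSpace = field(default_factory=build_state_space)

    def predict_cumhaz(
        self, profile: Mapping[str, float] | None = None
    ) -> dict[int, tuple[np.ndarray, np.ndarray]]:
        """Per-transition (months, increments) at a covariate profile.

        The profile maps covariate names to values; omitted names default
        to the reference value 0. Unknown names raise an error.
        """
        if profile:
            unknown = set(profile) - set(self.covariate_names)
            if unknown:
                raise CohortInputError(
                    f"profile names {sorted(unknown)} not among fitted covariates "
                    f"{self.covariate_names}"
                )
        return {
            q: m.cumhaz_increments(profile) for q, m in self.models.items()
        }


def _breslow_baseline(
    m_entry: np.ndarray,
    m_exit: np.ndarray,
    status: np.ndarray,
    risk_weight: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Breslow baseline increments d(m) / sum of weights at risk at month m.

    A spell (entry, exit] is at risk at month m iff entry < m <= exit;
    all event times sit on the integer month grid, so the at-risk sums
    are computed with difference arrays in O(rows + grid).
    """
    if status.sum() == 0:
        return np.empty(0, dtype=int), np.empty(0)
    top = int(m_exit.max()) + 2
    diff = np.bincount(m_entry + 1, weights=risk_weight, minlength=top) - np.bincount(
        m_exit + 1, weights=risk_weight, minlength=top
    )
    at_risk = np.cumsum(diff)  # at_risk[m] = weighted size of risk set at month m
    ev_months = m_exit[status == 1]
    d = np.bincount(ev_months, minlength=top)
    jump = np.flatnonzero(d > 0)
    return jump, d[jump] / at_risk[jump]


def fit_transition_hazards(
    table: EpisodeTable,
    space: StateSpace | None = None,
    covariates: Sequence[str] | None = None,
) -> TransitionModelSet:
    """Fit a Cox model per transition on the age time scale.

    ``covariates`` selects a subset of the table's covariate columns;
    None or an empty list fits no regression and the baseline is the
    Nelson-Aalen estimator. Delayed entry is handled through the risk
    sets; ties (heavy on a monthly grid) use the Breslow convention, so
    the baseline is available in closed form given the coefficients.
    Transitions with zero observed events yield a zero hazard and a
    warning rather than an error.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    space = space or table.space
    covariates = list(covariates) if covariates else []
    unknown = set(covariates) - set(table.covariate_names)
    if unknown:
        raise CohortInputError(f"covariates not in episode table: {sorted(unknown)}")
    col_idx = [table.covariate_names.index(c) for c in covariates]

    models: dict[int, TransitionModel] = {}
    for q in range(1, len(TRANSITIONS) + 1):
        at_risk, status = table.rows_for_transition(q)
        m_entry = table.m_entry[at_risk]
        m_exit = table.m_exit[at_risk]
        n_events = int(status.sum())
        if n_events == 0:
            warnings.warn(
                f"transition {q}: zero events; using a zero hazard", stacklevel=2
            )
            models[q] = TransitionModel(
                transition=q,
                beta=pd.Series(dtype=float),
                jump_months=np.empty(0, dtype=int),
                base_increments=np.empty(0),
                n_events=0,
                n_at_risk=at_risk.size,
            )
            continue
        use_covs = list(covariates)
        if covariates:
            Xq_all = table.X[table.person_idx[at_risk]][:, col_idx]
            # a covariate constant across the risk rows is unidentifiable
            # for this transition; drop it (log-HR treated as 0)
            varying = np.ptp(Xq_all, axis=0) > 0
            if not varying.all():
                dropped = [c for c, v in zip(covariates, varying) if not v]
                warnings.warn(
                    f"transition {q}: constant covariates {dropped} dropped",
                    stacklevel=2,
                )
                use_covs = [c for c, v in zip(covariates, varying) if v]
        if use_covs:
            Xq = Xq_all[:, [covariates.index(c) for c in use_covs]]
            df = pd.DataFrame(Xq, columns=use_covs)
            df["start"] = m_entry / MONTHS_PER_YEAR
            df["stop"] = m_exit / MONTHS_PER_YEAR
            df["event"] = status
            cph = CoxPHFitter()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph.fit(
                        df,
                        duration_col="stop",
                        event_col="event",
                        entry_col="start",
                        show_progress=False,
                        fit_options={"precision": 1e-9},
                    )
            except ConvergenceError as exc:
                raise FitError(f"transition {q}: Cox fit did not converge: {exc}")
            beta = cph.params_.astype(float)
            weight = np.exp(Xq @ beta.to_numpy())
            ll = float(cph.log_likelihood_)
        else:
            beta = pd.Series(dtype=float)
            weight = np.ones(at_risk.size)
            ll = float("nan")
        jump, inc = _breslow_baseline(m_entry, m_exit, status, weight)
        models[q] = TransitionModel(
            transition=q,
            beta=beta,
            jump_months=jump,
            base_increments=inc,
            n_events=n_events,
            n_at_risk=at_risk.size,
            log_likelihood=ll,
        )
    return TransitionModelSet(
        models=models, covariate_names=covariates, space=space
    )


def predict_cumhaz(
    models: TransitionModelSet, profile: Mapping[str, float] | None = None
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per-transition cumulative-hazard step functions at a covariate profile."""
    return models.predict_cumhaz(profile)
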