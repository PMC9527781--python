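"""Cohort data model, questionnaire scoring, inclusion rules and CSV I/O.

A cohort couples a baseline-covariate record per respondent (gender,
education, chronic-disease status, five working-condition scales) with a
person-month labor-market state timeline. Working-condition scales are
sums of 5-point items recoded so that a higher score means a worse
condition; adverse exposure is the top quartile of the sum score.
Respondents qualify for analysis when they are observed in the 50-66 age
window, are not self-employed, report at least one complete
working-condition scale, and either have one of six major chronic
diseases or report no disease at all.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .states import DEAD, MONTHS_PER_YEAR

__all__ = [
    "WorkingConditionScale",
    "SCALES",
    "MAJOR_DISEASES",
    "MINOR_DISEASES",
    "DISEASE_CHECKLIST",
    "RespondentRecord",
    "StateTimeline",
    "AnalysisCohort",
    "score_working_condition",
    "dichotomize_top_quartile",
    "classify_chronic_disease",
    "apply_inclusion_rules",
    "read_cohort",
    "write_cohort",
]


class CohortInputError(ValueError):
    """Raised for schema or vocabulary violations in cohort inputs."""


# ---------------------------------------------------------------------------
# Working-condition scales
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WorkingConditionScale:
    """One questionnaire battery scored as a sum of 5-point items.

    Raw responses run 1='always' .. 5='(almost) never'. ``reverse_coded``
    flags items recoded as ``6 - response`` so that after recoding a
    higher score always reflects a worse working condition: on demand
    items (physical workload, job demands, emotional demands) 'always'
    must score 5, on resource items (autonomy, social support)
    '(almost) never' already scores 5.
    """

    name: str
    n_items: int
    reverse_coded: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.reverse_coded) != self.n_items:
            raise ValueError(f"scale {self.name}: reverse_coded length mismatch")

    @property
    def min_score(self) -> int:
        return self.n_items

    @property
    def max_score(self) -> int:
        return 5 * self.n_items


SCALES: dict[str, WorkingConditionScale] = {
    "physical_workload": WorkingConditionScale("physical_workload", 5, (True,) * 5),
    "job_demands": WorkingConditionScale("job_demands", 4, (True,) * 4),
    "autonomy": WorkingConditionScale("autonomy", 5, (False,) * 5),
    "emotional_demands": WorkingConditionScale("emotional_demands", 3, (True,) * 3),
    "social_support": WorkingConditionScale("social_support", 4, (False,) * 4),
}


def score_working_condition(
    responses: Sequence[int], scale: WorkingConditionScale
) -> int:
    """Sum score of one scale after per-item recoding (higher = worse).

    Raises :class:`CohortInputError` naming the scale and offending item
    on a wrong item count or an out-of-range response.
    """
    if len(responses) != scale.n_items:
        raise CohortInputError(
            f"scale {scale.name}: expected {scale.n_items} items, got {len(responses)}"
        )
    total = 0
    for k, (raw, rev) in enumerate(zip(responses, scale.reverse_coded)):
        if not (isinstance(raw, (int, np.integer)) and 1 <= raw <= 5):
            raise CohortInputError(
                f"scale {scale.name}: item {k} response {raw!r} outside 1..5"
            )
        total += (6 - raw) if rev else int(raw)
    return total


def dichotomize_top_quartile(
    scores: Sequence[float] | np.ndarray,
) -> tuple[float, np.ndarray]:
    """Dichotomize sum scores at the sample's 75th percentile.

    The threshold is the empirical 75th percentile (linear interpolation
    between order statistics); a respondent is exposed iff the score is
    strictly greater than the threshold, so ties at the threshold fall in
    the referent (lower-75%) group. Missing scores (NaN) are ignored for
    the threshold and flagged unexposed.

    Returns ``(threshold, exposed)`` where ``exposed`` is a boolean array
    aligned with ``scores``.
    """
    arr = np.asarray(scores, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        raise CohortInputError("dichotomize_top_quartile: all scores missing")
    if finite.size < 4:
        raise CohortInputError(
            f"dichotomize_top_quartile: need >=4 non-missing scores, got {finite.size}"
        )
    threshold = float(np.percentile(finite, 75))
    exposed = np.zeros(arr.shape, dtype=bool)
    ok = np.isfinite(arr)
    exposed[ok] = arr[ok] > threshold
    return threshold, exposed


# ---------------------------------------------------------------------------
# Chronic disease
# ---------------------------------------------------------------------------

MAJOR_DISEASES = frozenset(
    {
        "diabetes",
        "cardiovascular",
        "digestive",
        "psychological",
        "musculoskeletal",
        "respiratory",
    }
)
MINOR_DISEASES = frozenset(
    {"migraine", "skin", "hearing", "eye", "epilepsy", "life_threatening", "other"}
)
DISEASE_CHECKLIST = MAJOR_DISEASES | MINOR_DISEASES

INCLUDED_WITH_DISEASE = "included_with_disease"
INCLUDED_WITHOUT_DISEASE = "included_without_disease"
EXCLUDED = "excluded"


def classify_chronic_disease(disease_reports: Iterable[str]) -> str:
    """Partition a set of reported conditions into the three analysis groups.

    Any major disease (diabetes, cardiovascular, digestive, psychological,
    musculoskeletal, respiratory) puts the respondent in the chronic-disease
    group regardless of co-reported minor conditions; an empty report is the
    disease-free group; reports containing only minor conditions (migraine,
    skin/hearing/eye problems, epilepsy, life-threatening or other unknown
    diseases) are excluded from analysis.
    """
    reports = set(disease_reports)
    unknown = reports - DISEASE_CHECKLIST
    if unknown:
        raise CohortInputError(f"unknown disease labels: {sorted(unknown)}")
    if reports & MAJOR_DISEASES:
        return INCLUDED_WITH_DISEASE
    if not reports:
        return INCLUDED_WITHOUT_DISEASE
    return EXCLUDED


# ---------------------------------------------------------------------------
# Records and timelines
# ---------------------------------------------------------------------------

@dataclass
class RespondentRecord:
    """Baseline covariates and derived exposure flags for one person.

    ``wc_items`` holds raw 1..5 responses per scale (None when the scale
    is missing); ``wc_scores`` the recoded sum scores (NaN when missing);
    ``wc_exposed`` the binary top-quartile flags. ``chronic_disease`` is
    defined only after the inclusion rules have run.
    """

    id: str
    gender: str  # 'M' or 'F'
    education: str  # 'low' | 'mid' | 'high'
    disease_reports: frozenset[str] = frozenset()
    self_employed: bool = False
    wc_items: dict[str, tuple[int, ...] | None] = field(default_factory=dict)
    wc_scores: dict[str, float] = field(default_factory=dict)
    wc_exposed: dict[str, bool] = field(default_factory=dict)
    chronic_disease: bool | None = None
    entry_age: float | None = None

    def __post_init__(self) -> None:
        if self.gender not in ("M", "F"):
            raise CohortInputError(f"respondent {self.id}: gender {self.gender!r}")
        if self.education not in ("low", "mid", "high"):
            raise CohortInputError(
                f"respondent {self.id}: education {self.education!r}"
            )

    def score_scales(self) -> None:
        """(Re)compute sum scores from raw items for every known scale."""
        for name, scale in SCALES.items():
            items = self.wc_items.get(name)
            if items is None:
                self.wc_scores[name] = math.nan
            else:
                self.wc_scores[name] = float(score_working_condition(items, scale))

    @property
    def n_scales_present(self) -> int:
        return sum(
            1 for v in self.wc_scores.values() if v is not None and math.isfinite(v)
        )


@dataclass
class StateTimeline:
    """Monthly labor-market state sequence for one person.

    States are stored as a dense int array over consecutive months
    starting at ``start_month`` (age in months), which makes the
    no-gap invariant structural. DEAD may appear only as the final
    observation.
    """

    id: str
    start_month: int
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 1 or self.states.size == 0:
            raise CohortInputError(f"timeline {self.id}: empty state sequence")
        bad = ~np.isin(self.states, (1, 2, 3, 4))
        if bad.any():
            k = int(np.flatnonzero(bad)[0])
            raise CohortInputError(
                f"timeline {self.id}: invalid state code "
                f"{int(self.states[k])} at month {self.start_month + k}"
            )
        dead = np.flatnonzero(self.states == DEAD)
        if dead.size and dead[0] != self.states.size - 1:
            raise CohortInputError(
                f"timeline {self.id}: observations continue after death"
            )

    @classmethod
    def from_observations(
        cls, id: str, observations: Sequence[tuple[int, int]]
    ) -> "StateTimeline":
        """Build from (age_in_months, state) pairs; months must be consecutive."""
        if not observations:
            raise CohortInputError(f"timeline {id}: no observations")
        months = np.asarray([m for m, _ in observations], dtype=int)
        gaps = np.flatnonzero(np.diff(months) != 1)
        if gaps.size:
            raise CohortInputError(
                f"timeline {id}: gap or disorder after month {int(months[gaps[0]])}"
            )
        states = np.asarray([s for _, s in observations], dtype=np.int8)
        return cls(id=id, start_month=int(months[0]), states=states)

    @property
    def months(self) -> np.ndarray:
        return self.start_month + np.arange(self.states.size)

    @property
    def end_month(self) -> int:
        """One past the last observed month."""
        return self.start_month + self.states.size

    def truncate(self, low_month: int, high_month: int) -> "StateTimeline | None":
        """Restrict to months in [low_month, high_month); None if empty."""
        lo = max(self.start_month, low_month)
        hi = min(self.end_month, high_month)
        if lo >= hi:
            return None
        a = lo - self.start_month
        return StateTimeline(
            id=self.id, start_month=lo, states=self.states[a : hi - self.start_month]
        )

    def state_at(self, month: int) -> int:
        """State at a given age month; DEAD persists past the recorded death."""
        if month < self.start_month:
            raise CohortInputError(f"timeline {self.id}: month {month} before entry")
        k = month - self.start_month
        if k >= self.states.size:
            if self.states[-1] == DEAD:
                return DEAD
            raise CohortInputError(
                f"timeline {self.id}: month {month} past end of observation"
            )
        return int(self.states[k])


@dataclass
class AnalysisCohort:
    """Matched respondent records and state timelines ready for analysis."""

    respondents: list[RespondentRecord]
    timelines: list[StateTimeline]
    quartile_thresholds: dict[str, float] = field(default_factory=dict)
    log: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.respondents) != len(self.timelines):
            raise CohortInputError("respondents and timelines differ in length")
        for r, t in zip(self.respondents, self.timelines):
            if r.id != t.id:
                raise CohortInputError(f"id mismatch: {r.id} vs {t.id}")

    @property
    def n(self) -> int:
        return len(self.respondents)

    def take(self, indices: Sequence[int], relabel: bool = True) -> "AnalysisCohort":
        """Sub-cohort (with repeats allowed) for resampling.

        State arrays are shared, not copied; ids are suffixed to stay
        unique when ``relabel`` and an index repeats.
        """
        resp, tls = [], []
        for k, i in enumerate(indices):
            r, t = self.respondents[i], self.timelines[i]
            if relabel:
                r = dataclasses.replace(r, id=f"{r.id}#{k}")
                t2 = StateTimeline.__new__(StateTimeline)
                t2.id = r.id
                t2.start_month = t.start_month
                t2.states = t.states
                t = t2
            resp.append(r)
            tls.append(t)
        out = AnalysisCohort.__new__(AnalysisCohort)
        out.respondents = resp
        out.timelines = tls
        out.quartile_thresholds = dict(self.quartile_thresholds)
        out.log = []
        return out

    def frame(self) -> pd.DataFrame:
        """Respondent-level covariates as a DataFrame (one row per person)."""
        rows = []
        for r in self.respondents:
            row: dict[str, object] = {
                "id": r.id,
                "gender": r.gender,
                "education": r.education,
                "chronic_disease": r.chronic_disease,
                "entry_age": r.entry_age,
            }
            for s in SCALES:
                row[f"wc_{s}_score"] = r.wc_scores.get(s, math.nan)
                row[f"wc_{s}_exposed"] = r.wc_exposed.get(s)
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Inclusion rules
# ---------------------------------------------------------------------------

def apply_inclusion_rules(
    respondents: Sequence[RespondentRecord],
    timelines: Mapping[str, StateTimeline] | Sequence[StateTimeline],
    age_window: tuple[float, float] = (50.0, 66.0),
) -> AnalysisCohort:
    """Apply the cohort inclusion rules and assemble an analysis cohort.

    Steps (each logged as ``(step, n_before, n_after)``): drop the
    self-employed; drop respondents with no complete working-condition
    scale; drop respondents whose disease reports contain only minor
    conditions; truncate timelines to the age window and drop respondents
    never observed inside it. Quartile thresholds and exposure flags are
    computed once on the final sample. Entry age is months/12 at the first
    retained month.
    """
    if not isinstance(timelines, Mapping):
        timelines = {t.id: t for t in timelines}
    missing = [r.id for r in respondents if r.id not in timelines]
    if missing:
        raise CohortInputError(f"respondents without timeline: {missing}")

    log: list[tuple[str, int, int]] = []
    current = list(respondents)

    def step(name: str, keep) -> None:
        nonlocal current
        before = len(current)
        current = [r for r in current if keep(r)]
        log.append((name, before, len(current)))

    log.append(("loaded", len(current), len(current)))
    step("drop_self_employed", lambda r: not r.self_employed)

    for r in current:
        r.score_scales()
    step("require_working_condition", lambda r: r.n_scales_present >= 1)

    for r in current:
        r.chronic_disease = None
    kept = []
    before = len(current)
    for r in current:
        cls = classify_chronic_disease(r.disease_reports)
        if cls == EXCLUDED:
            continue
        r.chronic_disease = cls == INCLUDED_WITH_DISEASE
        kept.append(r)
    current = kept
    log.append(("disease_rule", before, len(current)))

    low_m = int(round(age_window[0] * MONTHS_PER_YEAR))
    high_m = int(round(age_window[1] * MONTHS_PER_YEAR))
    before = len(current)
    resp_out: list[RespondentRecord] = []
    tl_out: list[StateTimeline] = []
    for r in current:
        t = timelines[r.id].truncate(low_m, high_m)
        if t is None:
            continue
        r.entry_age = t.start_month / MONTHS_PER_YEAR
        resp_out.append(r)
        tl_out.append(t)
    log.append(("age_window", before, len(resp_out)))

    thresholds: dict[str, float] = {}
    for name in SCALES:
        scores = np.array([r.wc_scores.get(name, math.nan) for r in resp_out])
        if np.isfinite(scores).sum() >= 4:
            thr, exposed = dichotomize_top_quartile(scores)
            thresholds[name] = thr
            for r, e in zip(resp_out, exposed):
                r.wc_exposed[name] = bool(e)
    return AnalysisCohort(
        respondents=resp_out,
        timelines=tl_out,
        quartile_thresholds=thresholds,
        log=log,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _item_columns() -> list[tuple[str, str, int]]:
    cols = []
    for name, scale in SCALES.items():
        for k in range(1, scale.n_items + 1):
            cols.append((f"wc_{name}_item{k}", name, k))
    return cols


def read_cohort(
    persons_path: str | Path,
    timeline_path: str | Path,
    age_window: tuple[float, float] = (50.0, 66.0),
) -> AnalysisCohort:
    """Read persons.csv and timeline.csv and apply the inclusion rules.

    persons.csv: ``id, gender {M,F}, education {low,mid,high},
    self_employed {0,1}``, one 0/1 ``disease_<label>`` column per
    checklist label, and ``wc_<scale>_item<k>`` integer columns (blank =
    missing). timeline.csv: ``id, age_months, state`` with one row per
    person-month. Schema violations raise errors naming column and row.
    """
    persons = pd.read_csv(persons_path, dtype={"id": str})
    required = {"id", "gender", "education", "self_employed"}
    if not required.issubset(persons.columns):
        raise CohortInputError(
            f"persons file missing columns: {sorted(required - set(persons.columns))}"
        )
    if persons["id"].duplicated().any():
        dup = persons.loc[persons["id"].duplicated(), "id"].iloc[0]
        raise CohortInputError(f"duplicate person id {dup!r}")

    respondents = []
    for i, row in persons.iterrows():
        reports = set()
        for label in DISEASE_CHECKLIST:
            col = f"disease_{label}"
            if col in persons.columns and row[col] == 1:
                reports.add(label)
        wc_items: dict[str, tuple[int, ...] | None] = {}
        for name, scale in SCALES.items():
            vals = []
            complete = True
            for k in range(1, scale.n_items + 1):
                col = f"wc_{name}_item{k}"
                v = row.get(col)
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    complete = False
                    break
                if float(v) != int(v) or not 1 <= int(v) <= 5:
                    raise CohortInputError(
                        f"persons row {i} column {col}: response {v!r} outside 1..5"
                    )
                vals.append(int(v))
            wc_items[name] = tuple(vals) if complete else None
        try:
            rec = RespondentRecord(
                id=str(row["id"]),
                gender=str(row["gender"]),
                education=str(row["education"]),
                disease_reports=frozenset(reports),
                self_employed=bool(row["self_employed"]),
                wc_items=wc_items,
            )
        except CohortInputError as exc:
            raise CohortInputError(f"persons row {i}: {exc}") from None
        respondents.append(rec)

    tl = pd.read_csv(timeline_path, dtype={"id": str})
    for col in ("id", "age_months", "state"):
        if col not in tl.columns:
            raise CohortInputError(f"timeline file missing column {col}")
    timelines = {}
    for pid, grp in tl.groupby("id", sort=False):
        obs = list(zip(grp["age_months"].astype(int), grp["state"].astype(int)))
        timelines[pid] = StateTimeline.from_observations(str(pid), obs)
    return apply_inclusion_rules(respondents, timelines, age_window=age_window)


def write_cohort(cohort: AnalysisCohort, directory: str | Path) -> dict[str, Path]:
    """Write persons.csv, timeline.csv and cohort.log; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in cohort.respondents:
        row: dict[str, object] = {
            "id": r.id,
            "gender": r.gender,
            "education": r.education,
            "self_employed": int(r.self_employed),
        }
        for label in sorted(DISEASE_CHECKLIST):
            row[f"disease_{label}"] = int(label in r.disease_reports)
        for col, name, k in _item_columns():
            items = r.wc_items.get(name)
            row[col] = items[k - 1] if items is not None else ""
        rows.append(row)
    persons_path = directory / "persons.csv"
    pd.DataFrame(rows).to_csv(persons_path, index=False)

    tl_frames = []
    for t in cohort.timelines:
        tl_frames.append(
            pd.DataFrame(
                {"id": t.id, "age_months": t.months, "state": t.states.astype(int)}
            )
        )
    timeline_path = directory / "timeline.csv"
    pd.concat(tl_frames, ignore_index=True).to_csv(timeline_path, index=False)

    log_path = directory / "cohort.log"
    with open(log_path, "w") as fh:
        for name, before, after in cohort.log:
            fh.write(f"{name}: {before} -> {after}\n")
    return {"persons": persons_path, "timeline": timeline_path, "log": log_path}
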