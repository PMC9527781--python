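"""Percentile-bootstrap uncertainty, stratified analyses, and report tables.

Uncertainty for WLE and the WYL decomposition comes from resampling
persons (each with their whole timeline) with replacement, re-running
the full estimation pipeline per replicate, and reading the 2.5th and
97.5th percentiles of the replicate distribution. Stratified analyses
produce one report row per stratum (gender, education, chronic disease)
or per education x working-condition exposure cell, formatted like the
standard WLE/WYL tables.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import AnalysisCohort, SCALES
from .multistate import fit_transition_hazards, prepare_episodes
from .occupancy import OccupancyResult, aalen_johansen, elos

__all__ = [
    "BootstrapSpec",
    "StratumSpec",
    "WleReportRow",
    "BootstrapResult",
    "estimate_wle",
    "bootstrap_elos",
    "run_stratified_analysis",
    "render_report",
    "rows_to_frame",
    "plot_wle_rows",
]

QUANTITIES = ("wle", "wyl_involuntary", "wyl_voluntary", "wyl_mortality")


@dataclass(frozen=True)
class BootstrapSpec:
    """Percentile-bootstrap settings: B person-level n-out-of-n resamples
    with a fixed master seed spawning one substream per replicate."""

    B: int = 1000
    seed: int = 0
    ci: tuple[float, float] = (2.5, 97.5)

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        lo, hi = self.ci
        if not (0.0 < lo < hi < 100.0):
            raise ValueError("ci percentiles must satisfy 0 < lower < upper < 100")


@dataclass(frozen=True)
class StratumSpec:
    """Which cohort variables define report strata.

    ``stratify_by`` is a subset of {gender, education, chronic_disease};
    ``exposure`` optionally names a working-condition scale whose
    top-quartile flag is contrasted within each stratum; ``adjust_for``
    lists covariates kept in the model without defining strata.
    """

    stratify_by: tuple[str, ...] = ("gender", "education", "chronic_disease")
    exposure: str | None = None
    adjust_for: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        allowed = {"gender", "education", "chronic_disease"}
        bad = set(self.stratify_by) - allowed
        if bad:
            raise ValueError(f"cannot stratify by {sorted(bad)}")
        if self.exposure is not None and self.exposure not in SCALES:
            raise ValueError(f"unknown working-condition scale {self.exposure!r}")


@dataclass
class WleReportRow:
    """One stratum's WLE and WYL decomposition with percentile CIs."""

    labels: dict[str, str]
    estimates: dict[str, tuple[float, float, float]]  # quantity -> (pt, lo, hi)
    n: int = 0
    flagged: bool = False
    note: str = ""


def estimate_wle(
    cohort: AnalysisCohort,
    covariates: Sequence[str] = (),
    profile: Mapping[str, float] | None = None,
    s: float = 50.0,
    horizon: float = 66.0,
) -> OccupancyResult:
    """The standard pipeline: episodes -> per-transition hazards ->
    Aalen-Johansen -> ELOS, at a covariate profile (reference by default)."""
    table = prepare_episodes(cohort, covariates=list(covariates))
    models = fit_transition_hazards(table, covariates=list(covariates))
    grid = aalen_johansen(models.predict_cumhaz(profile or {}), s=s, horizon=horizon)
    return elos(grid)


@dataclass
class BootstrapResult:
    """Point estimate, replicate draws, and percentile intervals."""

    point: OccupancyResult
    replicates: pd.DataFrame  # one row per replicate, columns QUANTITIES
    ci: dict[str, tuple[float, float]]
    spec: BootstrapSpec
    n_failed: int = 0

    def summary(self) -> pd.DataFrame:
        rows = []
        for qty in QUANTITIES:
            lo, hi = self.ci[qty]
            rows.append(
                {
                    "quantity": qty,
                    "estimate": getattr(self.point, qty),
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
        return pd.DataFrame(rows)


def bootstrap_elos(
    cohort: AnalysisCohort,
    pipeline: Callable[[AnalysisCohort], OccupancyResult] | None = None,
    spec: BootstrapSpec = BootstrapSpec(),
) -> BootstrapResult:
    """Percentile bootstrap of the WLE/WYL decomposition.

    Persons are resampled with replacement n-out-of-n, keeping each
    person's entire timeline intact, and the full pipeline is re-run per
    replicate. Replicates whose fit fails outright are logged as warnings
    and excluded from the percentiles (degenerate-but-computable fits,
    e.g. transitions with zero resampled events, are retained via the
    zero-hazard rule); if every replicate fails an error is raised. A
    fixed seed makes the intervals bit-identical across runs.
    """
    pipeline = pipeline or estimate_wle
    point = pipeline(cohort)
    streams = np.random.SeedSequence(spec.seed).spawn(spec.B)
    rows = []
    n_failed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(spec.B):
            rng = np.random.default_rng(streams[b])
            idx = rng.integers(0, cohort.n, cohort.n)
            boot = cohort.take(idx, relabel=False)
            try:
                occ = pipeline(boot)
                rows.append({q: getattr(occ, q) for q in QUANTITIES})
            except Exception as exc:  # degenerate replicate
                n_failed += 1
                rows.append({q: np.nan for q in QUANTITIES})
                warnings.warn_explicit(
                    f"bootstrap replicate {b} failed: {exc}",
                    UserWarning,
                    __file__,
                    0,
                )
    reps = pd.DataFrame(rows)
    if reps[QUANTITIES[0]].notna().sum() == 0:
        raise RuntimeError("all bootstrap replicates failed")
    if n_failed:
        warnings.warn(f"bootstrap: {n_failed}/{spec.B} replicates failed")
    ci = {
        q: tuple(np.nanpercentile(reps[q], spec.ci))  # type: ignore[arg-type]
        for q in QUANTITIES
    }
    return BootstrapResult(
        point=point, replicates=reps, ci=ci, spec=spec, n_failed=n_failed
    )


# ---------------------------------------------------------------------------
# Stratified analyses
# ---------------------------------------------------------------------------

_LEVELS = {
    "gender": ("M", "F"),
    "education": ("low", "mid", "high"),
    "chronic_disease": (False, True),
}
_DUMMIES = {
    ("gender", "F"): {"female": 1.0},
    ("gender", "M"): {"female": 0.0},
    ("education", "low"): {"edu_mid": 0.0, "edu_high": 0.0},
    ("education", "mid"): {"edu_mid": 1.0, "edu_high": 0.0},
    ("education", "high"): {"edu_mid": 0.0, "edu_high": 1.0},
    ("chronic_disease", True): {"chronic_disease": 1.0},
    ("chronic_disease", False): {"chronic_disease": 0.0},
}


def _stratum_members(cohort: AnalysisCohort, combo: dict[str, object]) -> np.ndarray:
    keep = np.ones(cohort.n, dtype=bool)
    for var, level in combo.items():
        if var == "gender":
            vals = np.array([r.gender for r in cohort.respondents])
        elif var == "education":
            vals = np.array([r.education for r in cohort.respondents])
        elif var == "chronic_disease":
            vals = np.array([bool(r.chronic_disease) for r in cohort.respondents])
        else:  # exposure flag
            vals = np.array(
                [bool(r.wc_exposed.get(var)) for r in cohort.respondents]
            )
        keep &= vals == level
    return keep


def _model_covariates(strata: StratumSpec) -> list[str]:
    covs: list[str] = []
    for var in strata.stratify_by:
        for lvl in _LEVELS[var]:
            covs.extend(
                c for c in _DUMMIES[(var, lvl)] if c not in covs
            )
    if strata.exposure:
        covs.append(f"wc_{strata.exposure}")
    for c in strata.adjust_for:
        if c not in covs:
            covs.append(c)
    return covs


def _profiles(strata: StratumSpec):
    """Yield (labels, covariate profile) per stratum/exposure combination."""
    axes = [[(var, lvl) for lvl in _LEVELS[var]] for var in strata.stratify_by]
    if strata.exposure:
        axes.append(
            [(strata.exposure, False), (strata.exposure, True)]
        )
    if not axes:
        yield {}, {}, {}
        return
    for combo in itertools.product(*axes):
        labels: dict[str, str] = {}
        profile: dict[str, float] = {}
        member_combo: dict[str, object] = {}
        for var, lvl in combo:
            if var in _LEVELS:
                labels[var] = str(lvl)
                profile.update(_DUMMIES[(var, lvl)])
                member_combo[var] = lvl
            else:  # exposure scale
                labels[var] = "exposed" if lvl else "lower75"
                profile[f"wc_{var}"] = 1.0 if lvl else 0.0
                member_combo[var] = lvl
        yield labels, profile, member_combo


def run_stratified_analysis(
    cohort: AnalysisCohort,
    strata: StratumSpec = StratumSpec(),
    spec: BootstrapSpec | None = None,
    s: float = 50.0,
    horizon: float = 66.0,
) -> list[WleReportRow]:
    """WLE/WYL per stratum with optional percentile-bootstrap intervals.

    The stratification variables (plus the exposure flag and any
    adjustment covariates) enter one pooled per-transition Cox model;
    each report row is the occupancy predicted at that stratum's
    covariate profile (adjustment covariates held at their reference
    value). Empty strata are flagged rather than dropped. With no
    stratification variables and no exposure the single row equals the
    pooled covariate-free analysis.
    """
    covs = _model_covariates(strata)

    def all_rows(c: AnalysisCohort) -> dict[tuple, dict[str, float]]:
        table = prepare_episodes(c, covariates=covs)
        models = fit_transition_hazards(table, covariates=covs)
        out = {}
        for labels, profile, _ in _profiles(strata):
            grid = aalen_johansen(
                models.predict_cumhaz(profile), s=s, horizon=horizon
            )
            occ = elos(grid)
            out[tuple(labels.items())] = {q: getattr(occ, q) for q in QUANTITIES}
        return out

    point = all_rows(cohort)
    boots: list[dict[tuple, dict[str, float]]] = []
    if spec is not None:
        streams = np.random.SeedSequence(spec.seed).spawn(spec.B)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for b in range(spec.B):
                rng = np.random.default_rng(streams[b])
                idx = rng.integers(0, cohort.n, cohort.n)
                try:
                    boots.append(all_rows(cohort.take(idx, relabel=False)))
                except Exception:
                    continue

    rows = []
    for labels, profile, member_combo in _profiles(strata):
        key = tuple(labels.items())
        n_members = int(_stratum_members(cohort, member_combo).sum())
        est = {}
        for q in QUANTITIES:
            pt = point[key][q]
            if boots:
                draws = np.array([b[key][q] for b in boots])
                lo, hi = (
                    np.percentile(draws, spec.ci) if draws.size else (np.nan, np.nan)
                )
            else:
                lo = hi = float("nan")
            est[q] = (pt, float(lo), float(hi))
        rows.append(
            WleReportRow(
                labels=labels,
                estimates=est,
                n=n_members,
                flagged=n_members == 0,
                note="empty stratum" if n_members == 0 else "",
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def rows_to_frame(rows: Sequence[WleReportRow]) -> pd.DataFrame:
    """Long-format report: stratum columns, quantity, estimate, ci bounds."""
    out = []
    for row in rows:
        for q in QUANTITIES:
            pt, lo, hi = row.estimates[q]
            out.append(
                {
                    **row.labels,
                    "n": row.n,
                    "quantity": q,
                    "estimate": pt,
                    "ci_low": lo,
                    "ci_high": hi,
                    "flagged": row.flagged,
                }
            )
    return pd.DataFrame(out)


def render_report(rows: Sequence[WleReportRow], dash: str = "–") -> str:
    """Plain-text table: 2-decimal years with CIs in parentheses."""
    header_labels = list(rows[0].labels) if rows else []
    headers = header_labels + [
        "WLE (95% CI)",
        "Involuntary WYL (95% CI)",
        "Voluntary WYL (95% CI)",
        "Mortality WYL (95% CI)",
    ]
    lines = ["\t".join(headers)]
    for row in rows:
        cells = [str(row.labels[k]) for k in header_labels]
        for q in QUANTITIES:
            pt, lo, hi = row.estimates[q]
            if np.isfinite(lo) and np.isfinite(hi):
                cells.append(f"{pt:.2f} ({lo:.2f}{dash}{hi:.2f})")
            else:
                cells.append(f"{pt:.2f}")
        if row.flagged:
            cells.append(f"[{row.note}]")
        lines.append("\t".join(cells))
    return "\n".join(lines)


def plot_wle_rows(rows: Sequence[WleReportRow], path: str) -> None:
    """Bar chart of WLE per stratum (with CI whiskers when available)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [" / ".join(str(v) for v in r.labels.values()) or "pooled" for r in rows]
    pts = [r.estimates["wle"][0] for r in rows]
    los = [r.estimates["wle"][1] for r in rows]
    his = [r.estimates["wle"][2] for r in rows]
    yerr = None
    if all(np.isfinite(los)) and all(np.isfinite(his)):
        yerr = [
            np.array(pts) - np.array(los),
            np.array(his) - np.array(pts),
        ]
    fig, ax = plt.subplots(figsize=(max(6, 0.8 * len(rows)), 4))
    ax.bar(range(len(rows)), pts, yerr=yerr, capsize=3, color="#4878a8")
    ax.set_xticks(range(len(rows)))
    ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("Working life expectancy at 50 (years)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
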