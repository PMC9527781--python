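"""Aalen-Johansen transition probabilities, expected length of stay, and
the working-life-expectancy decomposition.

The product-integral of the cumulative-hazard increments over the pooled
jump ages gives transition-probability matrices P(s, t); integrating
P(s, .) over the 50-66 window gives the expected length of stay (ELOS)
in each state conditional on the state at the start age. WLE is the
ELOS in employment conditional on employment at s; working years lost
(WYL) are the ELOS in the involuntary, voluntary and death states, and
the three pathways plus WLE always add up to the window length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import CohortInputError, StateTimeline
from .states import (
    DEAD,
    EMPLOYED,
    INVOLUNTARY,
    MONTHS_PER_YEAR,
    StateSpace,
    TRANSITIONS,
    VOLUNTARY,
    build_state_space,
)

__all__ = [
    "TransitionProbabilityGrid",
    "OccupancyResult",
    "aalen_johansen",
    "elos",
    "empirical_occupancy",
    "EmpiricalOccupancy",
]


@dataclass
class TransitionProbabilityGrid:
    """P(s, t) on the grid of jump ages in (s, horizon].

    ``P[k]`` is the 4x4 row-stochastic matrix P(s, times[k]) (1-based
    states occupy a 5x5 array with index 0 unused). P(s, .) is
    right-continuous and constant between jump ages.
    """

    s: float
    horizon: float
    times: np.ndarray  # jump ages in years, strictly increasing, in (s, horizon]
    P: np.ndarray  # (len(times), 5, 5)
    n_truncated_rows: int = 0

    def __post_init__(self) -> None:
        rows = self.P[:, 1:, 1:]
        if rows.size:
            sums = rows.sum(axis=2)
            if not np.allclose(sums, 1.0, atol=1e-8):
                raise ValueError("transition probability rows do not sum to 1")
            if rows.min() < -1e-12 or rows.max() > 1 + 1e-12:
                raise ValueError("transition probabilities outside [0, 1]")

    def at(self, t: float) -> np.ndarray:
        """P(s, t) for s <= t <= horizon (right-continuous step function)."""
        if t < self.s - 1e-12:
            raise ValueError(f"t={t} before start age {self.s}")
        k = int(np.searchsorted(self.times, t + 1e-9)) - 1
        if k < 0:
            return np.eye(5)
        return self.P[k]


@dataclass
class OccupancyResult:
    """ELOS matrix over [s, horizon] and the WLE/WYL decomposition.

    ``elos[h, j]`` is the expected number of years spent in state j over
    the window given state h at the start age; every row sums to the
    window length. WLE and the three WYL pathways are read from the
    employment row.
    """

    s: float
    horizon: float
    elos: np.ndarray  # (5, 5), index 0 unused

    @property
    def window(self) -> float:
        return self.horizon - self.s

    @property
    def wle(self) -> float:
        return float(self.elos[EMPLOYED, EMPLOYED])

    @property
    def wyl_involuntary(self) -> float:
        return float(self.elos[EMPLOYED, INVOLUNTARY])

    @property
    def wyl_voluntary(self) -> float:
        return float(self.elos[EMPLOYED, VOLUNTARY])

    @property
    def wyl_mortality(self) -> float:
        return float(self.elos[EMPLOYED, DEAD])

    @property
    def wyl_total(self) -> float:
        return self.window - self.wle

    def summary(self) -> dict[str, float]:
        return {
            "wle": self.wle,
            "wyl_involuntary": self.wyl_involuntary,
            "wyl_voluntary": self.wyl_voluntary,
            "wyl_mortality": self.wyl_mortality,
            "wyl_total": self.wyl_total,
        }


def aalen_johansen(
    cumhaz: dict[int, tuple[np.ndarray, np.ndarray]],
    space: StateSpace | None = None,
    s: float = 50.0,
    horizon: float = 66.0,
) -> TransitionProbabilityGrid:
    """Product-integral of per-transition cumulative-hazard increments.

    ``cumhaz`` maps transition numbers to (jump months, increments) step
    functions, as returned by ``TransitionModelSet.predict_cumhaz``. At
    every pooled jump age u in (s, horizon] the increment matrix dA(u)
    has entry (h, j) equal to the jump of the h->j cumulative hazard and
    diagonal minus the row sum; P(s, t) is the ordered product of
    (I + dA(u)). A row whose increments sum above 1 (possible in sparse
    strata) is rescaled to sum 1 so each factor stays stochastic; such
    truncations are counted and warned about.
    """
    space = space or build_state_space()
    if s >= horizon:
        raise ValueError(f"start age {s} must be below horizon {horizon}")
    s_m = s * MONTHS_PER_YEAR
    h_m = horizon * MONTHS_PER_YEAR

    all_m: list[np.ndarray] = []
    all_h: list[np.ndarray] = []
    all_j: list[np.ndarray] = []
    all_v: list[np.ndarray] = []
    for q, (months, inc) in cumhaz.items():
        months = np.asarray(months)
        inc = np.asarray(inc, dtype=float)
        if (inc < -1e-12).any():
            raise ValueError(f"transition {q}: decreasing cumulative hazard")
        sel = (months > s_m + 1e-9) & (months <= h_m + 1e-9)
        h, j = TRANSITIONS[q - 1]
        m_sel = months[sel]
        all_m.append(m_sel)
        all_h.append(np.full(m_sel.size, h))
        all_j.append(np.full(m_sel.size, j))
        all_v.append(inc[sel])
    m_arr = np.concatenate(all_m) if all_m else np.empty(0, dtype=int)
    h_arr = np.concatenate(all_h) if all_h else np.empty(0, dtype=int)
    j_arr = np.concatenate(all_j) if all_j else np.empty(0, dtype=int)
    v_arr = np.concatenate(all_v) if all_v else np.empty(0)
    uniq = np.unique(m_arr)

    times = uniq.astype(float)
    T = uniq.size
    # all product factors I + dA(u) assembled at once
    k_idx = np.searchsorted(uniq, m_arr)
    factors = np.zeros((T, 5, 5))
    factors[k_idx, h_arr, j_arr] = v_arr
    rowsum = factors.sum(axis=2)
    over = rowsum > 1.0
    n_trunc = int(over.sum())
    if n_trunc:
        factors[over] /= rowsum[over][:, None]
        rowsum[over] = 1.0
    diag = np.arange(5)
    factors[:, diag, diag] = 1.0 - rowsum
    out = np.empty((T, 5, 5))
    P = np.eye(5)
    for k in range(T):
        np.matmul(P, factors[k], out=out[k])
        P = out[k]
    if n_trunc:
        warnings.warn(
            f"aalen_johansen: rescaled {n_trunc} increment rows exceeding "
            "total mass 1 to preserve stochasticity",
            stacklevel=2,
        )
    return TransitionProbabilityGrid(
        s=s,
        horizon=horizon,
        times=times / MONTHS_PER_YEAR,
        P=out,
        n_truncated_rows=n_trunc,
    )


def elos(
    grid: TransitionProbabilityGrid, horizon: float | None = None
) -> OccupancyResult:
    """Expected length of stay: integral of P(s, u) over u in [s, horizon].

    P(s, .) is piecewise constant between jump ages and right-continuous,
    so the integral is an exact step-function sum, including the segment
    from the last jump to the horizon.
    """
    horizon = grid.horizon if horizon is None else horizon
    if grid.horizon < horizon - 1e-9:
        raise ValueError(
            f"grid reaches {grid.horizon}, short of requested horizon {horizon}"
        )
    edges = np.concatenate(([grid.s], grid.times, [horizon]))
    widths = np.diff(edges)
    mats = np.concatenate((np.eye(5)[None], grid.P))  # value on [edge_k, edge_k+1)
    E = np.tensordot(widths, mats, axes=(0, 0))
    return OccupancyResult(s=grid.s, horizon=horizon, elos=E)


@dataclass
class EmpiricalOccupancy:
    """Counted state-occupancy fractions among persons employed at s."""

    s: float
    horizon: float
    months: np.ndarray
    fractions: np.ndarray  # (len(months), 5); column 0 unused
    n: int

    def elos(self) -> OccupancyResult:
        """Mean person-years per state (each month contributes 1/12 year)."""
        E = np.zeros((5, 5))
        E[EMPLOYED, 1:] = self.fractions[:, 1:].sum(axis=0) / MONTHS_PER_YEAR
        # rows other than EMPLOYED are not defined by this counting oracle
        for h in (INVOLUNTARY, VOLUNTARY, DEAD):
            E[h, h] = self.horizon - self.s
        return OccupancyResult(s=self.s, horizon=self.horizon, elos=E)


def empirical_occupancy(
    timelines: list[StateTimeline], s: float = 50.0, horizon: float = 66.0
) -> EmpiricalOccupancy:
    """Brute-force occupancy fractions on fully observed timelines.

    Requires every timeline to be uncensored over [s, horizon): observed
    through the final month of the window or ending in death. Among the
    persons employed at the start age, the fraction occupying each state
    at every month is counted directly (death persists after the recorded
    death month). On such data the Aalen-Johansen estimator with no
    covariates reproduces these fractions exactly.
    """
    s_m = int(round(s * MONTHS_PER_YEAR))
    h_m = int(round(horizon * MONTHS_PER_YEAR))
    for t in timelines:
        if t.states[-1] != DEAD and t.end_month < h_m:
            raise CohortInputError(
                f"timeline {t.id}: censored before the horizon; the counting "
                "oracle requires uncensored data"
            )
    sub = [
        t
        for t in timelines
        if t.start_month <= s_m
        and t.end_month > s_m
        and t.state_at(s_m) == EMPLOYED
    ]
    if not sub:
        raise CohortInputError(f"no persons employed at start age {s}")
    months = np.arange(s_m, h_m)
    counts = np.zeros((months.size, 5))
    for t in sub:
        for k, m in enumerate(months):
            counts[k, t.state_at(int(m))] += 1
    return EmpiricalOccupancy(
        s=s,
        horizon=horizon,
        months=months,
        fractions=counts / len(sub),
        n=len(sub),
    )
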