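"""Labor-market state space for the multistate model.

Four mutually exclusive states are tracked on a monthly grid: paid
employment, involuntary exit (unemployment or disability benefits),
voluntary exit (economic inactivity or early retirement), and death.
Death is absorbing; the other three states communicate, giving nine
allowed transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EMPLOYED = 1
INVOLUNTARY = 2
VOLUNTARY = 3
DEAD = 4

STATE_NAMES = {
    EMPLOYED: "employed",
    INVOLUNTARY: "involuntary_exit",
    VOLUNTARY: "voluntary_exit",
    DEAD: "dead",
}

#: Allowed (from, to) pairs in row-major order; index+1 is the transition number.
TRANSITIONS: tuple[tuple[int, int], ...] = (
    (EMPLOYED, INVOLUNTARY),
    (EMPLOYED, VOLUNTARY),
    (EMPLOYED, DEAD),
    (INVOLUNTARY, EMPLOYED),
    (INVOLUNTARY, VOLUNTARY),
    (INVOLUNTARY, DEAD),
    (VOLUNTARY, EMPLOYED),
    (VOLUNTARY, INVOLUNTARY),
    (VOLUNTARY, DEAD),
)

#: Months per year; ages are stored as integer months internally.
MONTHS_PER_YEAR = 12


@dataclass(frozen=True)
class StateSpace:
    """The fixed 4-state / 9-transition structure.

    ``tmat[h, j]`` holds the transition number (1..9) for an allowed move
    from state ``h`` to state ``j`` and 0 otherwise (states are 1-based;
    row/column 0 of the matrix is unused padding).
    """

    states: tuple[int, ...] = (EMPLOYED, INVOLUNTARY, VOLUNTARY, DEAD)
    tmat: np.ndarray = field(default_factory=lambda: _build_tmat())

    @property
    def n_transitions(self) -> int:
        return int((self.tmat > 0).sum())

    def transition_number(self, from_state: int, to_state: int) -> int:
        """Transition number for (from, to), or 0 if the move is disallowed."""
        return int(self.tmat[from_state, to_state])

    def targets(self, from_state: int) -> tuple[int, ...]:
        """Competing destination states reachable from ``from_state``."""
        return tuple(int(j) for j in np.flatnonzero(self.tmat[from_state]) if j)


def _build_tmat() -> np.ndarray:
    tmat = np.zeros((5, 5), dtype=int)
    for q, (h, j) in enumerate(TRANSITIONS, start=1):
        tmat[h, j] = q
    tmat.flags.writeable = False
    return tmat


def build_state_space() -> StateSpace:
    """Return the fixed employment / involuntary / voluntary / death structure."""
    return StateSpace()
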