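import warnings

import numpy as np
import pytest

import worklife as wl


@pytest.fixture(autouse=True)
def _quiet_zero_event_warnings():
    """Sparse fixtures legitimately leave some transitions event-free."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="transition .*zero events")
        warnings.filterwarnings("ignore", message="bootstrap")
        yield


@pytest.fixture(scope="session")
def small_uncensored_cohort():
    """40 persons entering employed at exactly 50, followed to 66 or death."""
    cfg = wl.recovery_config(n=40, seed=9)
    return wl.simulate_cohort(cfg, seed=9)


@pytest.fixture(scope="session")
def midsize_cohort():
    """n=2000 time-homogeneous cohort with a known disease effect."""
    return wl.simulate_cohort(wl.recovery_config(n=2000, seed=21), seed=21)


def make_timeline(pid, start_month, state_runs):
    """Timeline from (state, n_months) runs starting at start_month."""
    states = np.concatenate(
        [np.full(n, s, dtype=np.int8) for s, n in state_runs]
    )
    return wl.StateTimeline(id=pid, start_month=start_month, states=states)


def make_respondent(pid, **kw):
    defaults = dict(
        id=pid,
        gender="M",
        education="low",
        disease_reports=frozenset(),
        self_employed=False,
        wc_items={"physical_workload": (3, 3, 3, 3, 3)},
        chronic_disease=False,
    )
    defaults.update(kw)
    rec = wl.RespondentRecord(**defaults)
    rec.score_scales()
    return rec
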