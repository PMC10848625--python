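"""Age-structured three-state Markov cohort engine.

The fleet is a cohort of expected counts indexed by state — Functioning (F),
Breakdown (B), Beyond Economic Repair (E) — and integer age in completed
years (a new ambulance is age 1 in its first modelled year).  One cycle is
one year.  Within a cycle, under the default start-of-cycle timing:

1. *Scheduled replacement*: every ambulance whose age has reached the
   strategy's replacement age, in any state, is replaced by a new
   Functioning ambulance of age 1.
2. *BER re-entry*: every remaining BER ambulance is likewise replaced by a
   new Functioning ambulance of age 1 (BER vehicles are immobile and are
   replaced the following year).
3. *Transitions*: the surviving F and B sub-cohorts move between states with
   the probabilities of their start-of-cycle age band, and age by one year.

New entrants (steps 1-2) do not transition in the cycle they are bought;
they first transition the following year at age 1.  Total fleet size is
conserved analytically because each transition row sums to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .parameters import ModelConfig, StrategySpec, TransitionMatrix, band_index

__all__ = [
    "F_STATE",
    "B_STATE",
    "E_STATE",
    "STATE_LABELS",
    "FleetState",
    "TransitionFlows",
    "Trace",
    "step",
    "run",
]

F_STATE, B_STATE, E_STATE = 0, 1, 2
STATE_LABELS = ("functioning", "breakdown", "ber")

_CONS_TOL = 1e-6


@dataclass
class FleetState:
    """Fleet counts at one cycle: array of shape ``(3 states, max_age + 1)``.

    Column ``a`` holds the expected number of ambulances of age ``a``; column
    0 is unused (ages start at 1).  Counts may be fractional (cohort
    expectations).
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 3:
            raise ValueError(f"counts must have shape (3, max_age+1), got {self.counts.shape}")
        if np.any(self.counts < -1e-12):
            raise ValueError("fleet counts must be non-negative")
        if np.any(self.counts[:, 0] != 0):
            raise ValueError("age-0 column must be empty; ages start at 1")

    @property
    def max_age(self) -> int:
        return self.counts.shape[1] - 1

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def f(self) -> float:
        return float(self.counts[F_STATE].sum())

    @property
    def b(self) -> float:
        return float(self.counts[B_STATE].sum())

    @property
    def e(self) -> float:
        return float(self.counts[E_STATE].sum())

    def band_totals(self) -> np.ndarray:
        """Counts aggregated to shape ``(3 states, 3 age bands)``."""
        ages = np.arange(self.counts.shape[1])
        bidx = band_index(ages)
        out = np.zeros((3, 3))
        for k in range(3):
            mask = (bidx == k) & (ages >= 1)
            out[:, k] = self.counts[:, mask].sum(axis=1)
        return out

    def resized(self, max_age: int) -> "FleetState":
        """Copy with the age axis widened (never truncating occupied ages)."""
        if max_age < self.max_age:
            occupied = np.nonzero(self.counts.any(axis=0))[0]
            top = int(occupied.max()) if occupied.size else 1
            if max_age < top:
                raise ValueError(f"cannot shrink below occupied age {top}")
        out = np.zeros((3, max_age + 1))
        keep = min(self.max_age, max_age)
        out[:, : keep + 1] = self.counts[:, : keep + 1]
        return FleetState(counts=out)

    def copy(self) -> "FleetState":
        return FleetState(counts=self.counts.copy())

    def to_frame(self) -> pd.DataFrame:
        """Tidy view: one row per (age, state) with a positive count."""
        rows = [
            {"age": a, "state": STATE_LABELS[s], "count": self.counts[s, a]}
            for s in range(3)
            for a in range(1, self.max_age + 1)
            if self.counts[s, a] > 0
        ]
        return pd.DataFrame(rows, columns=["age", "state", "count"])


@dataclass(frozen=True)
class TransitionFlows:
    """Replacement flows realised during one cycle.

    ``r_sched`` counts scheduled (age-policy) replacements in any state,
    ``r_ber`` counts BER vehicles replaced through the BER re-entry rule and
    ``sched_ber`` is the BER portion of the scheduled replacements, so that
    ``ber_retired`` is every BER vehicle taken out of service this cycle.
    """

    r_sched: float
    r_ber: float
    sched_ber: float = 0.0

    @property
    def r_total(self) -> float:
        """All replacements R this cycle (scheduled + BER re-entry)."""
        return self.r_sched + self.r_ber

    @property
    def ber_retired(self) -> float:
        """BER vehicles retired this cycle (eligible for resale by default)."""
        return self.r_ber + self.sched_ber


@dataclass
class Trace:
    """States at cycles 0..n and the flows of each of the n steps."""

    states: list[FleetState] = field(default_factory=list)
    flows: list[TransitionFlows] = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return len(self.flows)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for t, st in enumerate(self.states):
            df = st.to_frame()
            df.insert(0, "cycle", t)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def flows_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(1, self.n_cycles + 1),
                "replacements_scheduled": [fl.r_sched for fl in self.flows],
                "replacements_ber": [fl.r_ber for fl in self.flows],
                "replacements_total": [fl.r_total for fl in self.flows],
                "ber_retired": [fl.ber_retired for fl in self.flows],
            }
        )


def _transition(counts: np.ndarray, surv: np.ndarray, pf: np.ndarray,
                pb: np.ndarray, max_age: int) -> np.ndarray:
    """Move surviving F/B cohorts one year forward; returns new (3, M+1) array."""
    f_s = counts[F_STATE] * surv
    b_s = counts[B_STATE] * surv
    contrib = f_s[:, None] * pf + b_s[:, None] * pb  # (age, destination)
    new = np.zeros_like(counts)
    new[:, 1:] += contrib[:-1].T
    new[:, max_age] += contrib[max_age]  # cap: oldest age bucket absorbs
    return new


def step(
    state: FleetState,
    tm: TransitionMatrix,
    strategy: StrategySpec,
    timing: str = "start",
) -> tuple[FleetState, TransitionFlows]:
    """Advance the cohort one cycle; returns the new state and its flows."""
    counts = state.counts
    m = state.max_age
    ages = np.arange(m + 1)
    pf_rows, pb_rows = tm.row_arrays()
    bidx = band_index(ages)
    pf = pf_rows[bidx]  # (age, dest)
    pb = pb_rows[bidx]
    a = strategy.replacement_age

    if timing == "start":
        sched = (ages >= a) & (ages >= 1)
        r_sched = float(counts[:, sched].sum())
        sched_ber = float(counts[E_STATE, sched].sum())
        surv = (~sched) & (ages >= 1)
        r_ber = float(counts[E_STATE, surv].sum())
        new = _transition(counts, surv, pf, pb, m)
        new[F_STATE, 1] += r_sched + r_ber
    elif timing == "end":
        surv = ages >= 1
        r_ber = float(counts[E_STATE].sum())
        new = _transition(counts, surv, pf, pb, m)
        new[F_STATE, 1] += r_ber
        over = ages > a
        r_sched = float(new[:, over].sum())
        sched_ber = float(new[E_STATE, over].sum())
        new[:, over] = 0.0
        new[F_STATE, 1] += r_sched
    else:
        raise ValueError(f"timing must be 'start' or 'end', got {timing!r}")

    if abs(new.sum() - counts.sum()) > _CONS_TOL * max(1.0, counts.sum()):
        raise AssertionError(
            f"fleet not conserved in step: {counts.sum()} -> {new.sum()}"
        )
    flows = TransitionFlows(r_sched=r_sched, r_ber=r_ber, sched_ber=sched_ber)
    return FleetState(counts=new), flows


def run(
    initial: FleetState,
    tm: TransitionMatrix,
    strategy: StrategySpec,
    config: ModelConfig,
    max_age: Optional[int] = None,
) -> Trace:
    """Propagate the cohort for ``config.n_cycles`` cycles (deterministic)."""
    timing = config.replacement_timing
    if max_age is None:
        # Room for every reachable age: under the replacement policy ages stay
        # below the replacement age (+1 under end-of-cycle timing); without an
        # effective policy they grow by at most one year per cycle.
        reachable = initial.max_age + config.n_cycles
        policy_cap = strategy.replacement_age + (1 if timing == "end" else 0)
        max_age = max(initial.max_age, min(policy_cap, reachable))
    state = initial.resized(max_age)
    trace = Trace(states=[state])
    for _ in range(config.n_cycles):
        state, flows = step(state, tm, strategy, timing=timing)
        trace.states.append(state)
        trace.flows.append(flows)
    return trace
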