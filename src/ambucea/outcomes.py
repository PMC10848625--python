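"""Effectiveness outcomes and the cost-effectiveness comparison.

Every ambulance is expected to deliver the optimum number of trips per year
(the utilization achieved by ambulances aged five years or less).  Older
functioning ambulances deliver fewer trips, broken-down ambulances deliver
half their band's trips, and BER ambulances are immobile and deliver none.
The shortfall relative to the fleet-wide optimum is the number of missed
trips (non-conveyances); each missed trip carries a fixed probability of
death.  Lives saved by an intervention strategy are the deaths it averts
relative to the comparator, and the ICER is the incremental cost per life
saved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .costing import CycleLedger, cycle_ledger, ledger_frame
from .engine import B_STATE, F_STATE, FleetState, Trace, run
from .parameters import EffectivenessInputs, Parameters, StrategySpec

__all__ = [
    "OutcomeRecord",
    "StrategyResult",
    "CEComparison",
    "cycle_outcomes",
    "evaluate_strategy",
    "ce_from_summary",
    "compare_strategies",
]

log = logging.getLogger(__name__)

_ZERO_TOL = 1e-9


@dataclass(frozen=True)
class OutcomeRecord:
    """Trips delivered, missed trips and deaths for one cycle."""

    trips_delivered: float
    missed_trips: float
    deaths: float


def cycle_outcomes(
    state: FleetState,
    effectiveness: EffectivenessInputs,
    clamp_negative: bool = False,
) -> OutcomeRecord:
    """Outcomes for one cycle from the fleet state occupying that year.

    Missed trips are the fleet-wide demand target (total fleet x optimum
    utilization) minus the trips actually delivered.  A negative missed-trip
    count can only arise from a misconfiguration in which some band's
    utilization exceeds the optimum; it is warned about and clamped to zero
    only when ``clamp_negative`` is set.
    """
    bt = state.band_totals()
    util = effectiveness.utilization_array()
    trips = float(((bt[F_STATE] + 0.5 * bt[B_STATE]) * util).sum())
    missed = state.total * effectiveness.optimum_utilization - trips
    if missed < -_ZERO_TOL:
        log.warning(
            "negative missed trips (%s): a band utilization exceeds the optimum",
            missed,
        )
        if clamp_negative:
            missed = 0.0
    deaths = missed * effectiveness.mortality_without_ambulance
    return OutcomeRecord(trips_delivered=trips, missed_trips=missed, deaths=deaths)


@dataclass
class StrategyResult:
    """One strategy's trace, per-cycle ledgers and outcomes, with horizon means.

    Horizon means average cycles 1..n (the initial placement cycle 0 incurs
    no cost), discounted at the configured annual rate (default 0).
    """

    strategy: StrategySpec
    trace: Trace
    ledgers: list[CycleLedger]
    outcomes: list[OutcomeRecord]
    discount_rate: float = 0.0

    @property
    def label(self) -> str:
        return self.strategy.label

    @property
    def n_cycles(self) -> int:
        return len(self.ledgers)

    def _weights(self) -> np.ndarray:
        t = np.arange(1, self.n_cycles + 1)
        return (1.0 + self.discount_rate) ** -(t - 1)

    def _mean(self, values: list[float]) -> float:
        w = self._weights()
        return float((w * np.asarray(values)).sum() / self.n_cycles)

    @property
    def mean_annual_cost(self) -> float:
        return self._mean([led.total for led in self.ledgers])

    def mean_annual_cost_components(self) -> dict[str, float]:
        return {
            "operating": self._mean([led.operating for led in self.ledgers]),
            "maintenance": self._mean([led.maintenance for led in self.ledgers]),
            "repair": self._mean([led.repair for led in self.ledgers]),
            "replacement": self._mean([led.replacement for led in self.ledgers]),
            "resale": self._mean([led.resale for led in self.ledgers]),
            "total": self.mean_annual_cost,
        }

    @property
    def mean_annual_missed_trips(self) -> float:
        return self._mean([o.missed_trips for o in self.outcomes])

    @property
    def mean_annual_deaths(self) -> float:
        return self._mean([o.deaths for o in self.outcomes])

    def outcomes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(1, self.n_cycles + 1),
                "trips_delivered": [o.trips_delivered for o in self.outcomes],
                "missed_trips": [o.missed_trips for o in self.outcomes],
                "deaths": [o.deaths for o in self.outcomes],
            }
        )

    def ledger_frame(self) -> pd.DataFrame:
        return ledger_frame(self.ledgers)


def evaluate_strategy(
    params: Parameters,
    initial: FleetState,
    strategy: StrategySpec,
) -> StrategyResult:
    """Run the cohort model for one strategy and attach ledgers and outcomes."""
    cfg = params.config
    trace = run(initial, params.transitions, strategy, cfg)
    ledgers = []
    outs = []
    for t in range(1, cfg.n_cycles + 1):
        ledgers.append(
            cycle_ledger(
                trace.states[t],
                trace.flows[t - 1],
                params.costs,
                params.effectiveness,
                params.maintenance,
                resale_on_scheduled=cfg.resale_on_scheduled,
            )
        )
        outs.append(
            cycle_outcomes(trace.states[t], params.effectiveness,
                           clamp_negative=cfg.clamp_missed_trips)
        )
    return StrategyResult(
        strategy=strategy,
        trace=trace,
        ledgers=ledgers,
        outcomes=outs,
        discount_rate=cfg.discount_rate,
    )


@dataclass(frozen=True)
class CEComparison:
    """Two-strategy cost-effectiveness summary (intervention vs comparator).

    ``decision`` is one of ``"cost-effective"``, ``"not cost-effective"``,
    ``"dominant"`` (cheaper and more effective), ``"dominated"`` (costlier
    and less effective), ``"equivalent"``, or the trade-off labels for the
    remaining cost-effectiveness-plane quadrants.  ``icer`` is ``None``
    whenever incremental lives saved is not positive.
    """

    comparator: str
    intervention: str
    cost_comparator: float
    cost_intervention: float
    missed_comparator: Optional[float]
    missed_intervention: Optional[float]
    deaths_comparator: float
    deaths_intervention: float
    incremental_cost: float
    lives_saved: float
    icer: Optional[float]
    wtp: float
    decision: str
    cost_effective: bool

    @property
    def missed_trip_reduction(self) -> Optional[float]:
        if self.missed_comparator is None or self.missed_intervention is None:
            return None
        return self.missed_comparator - self.missed_intervention

    def to_dict(self) -> dict:
        return {
            "comparator": self.comparator,
            "intervention": self.intervention,
            "cost_comparator": self.cost_comparator,
            "cost_intervention": self.cost_intervention,
            "missed_trips_comparator": self.missed_comparator,
            "missed_trips_intervention": self.missed_intervention,
            "missed_trip_reduction": self.missed_trip_reduction,
            "deaths_comparator": self.deaths_comparator,
            "deaths_intervention": self.deaths_intervention,
            "incremental_cost": self.incremental_cost,
            "lives_saved": self.lives_saved,
            "icer": self.icer,
            "wtp": self.wtp,
            "decision": self.decision,
            "cost_effective": self.cost_effective,
        }


def ce_from_summary(
    cost_comparator: float,
    cost_intervention: float,
    deaths_comparator: float,
    deaths_intervention: float,
    wtp: float,
    missed_comparator: Optional[float] = None,
    missed_intervention: Optional[float] = None,
    comparator: str = "comparator",
    intervention: str = "intervention",
) -> CEComparison:
    """Cost-effectiveness arithmetic from per-strategy annual summaries.

    Lives saved are deaths averted by the intervention; the ICER is reported
    only when the intervention is both costlier and more effective.
    """
    inc_cost = cost_intervention - cost_comparator
    lives = deaths_comparator - deaths_intervention
    icer: Optional[float] = None
    if abs(inc_cost) <= _ZERO_TOL and abs(lives) <= _ZERO_TOL:
        decision, ce = "equivalent", True
    elif lives > _ZERO_TOL and inc_cost <= _ZERO_TOL:
        decision, ce = "dominant", True
    elif lives < -_ZERO_TOL and inc_cost >= -_ZERO_TOL:
        decision, ce = "dominated", False
    elif lives > _ZERO_TOL:
        icer = inc_cost / lives
        ce = icer <= wtp
        decision = "cost-effective" if ce else "not cost-effective"
    elif lives < -_ZERO_TOL:  # cheaper but less effective: a genuine trade-off
        decision, ce = "tradeoff-southwest", False
    else:  # no effect difference
        decision = "equal-effect-cheaper" if inc_cost < 0 else "equal-effect-costlier"
        ce = inc_cost < 0
    return CEComparison(
        comparator=comparator,
        intervention=intervention,
        cost_comparator=cost_comparator,
        cost_intervention=cost_intervention,
        missed_comparator=missed_comparator,
        missed_intervention=missed_intervention,
        deaths_comparator=deaths_comparator,
        deaths_intervention=deaths_intervention,
        incremental_cost=inc_cost,
        lives_saved=lives,
        icer=icer,
        wtp=wtp,
        decision=decision,
        cost_effective=ce,
    )


def compare_strategies(
    comparator: StrategyResult,
    intervention: StrategyResult,
    wtp: float,
) -> CEComparison:
    """Compare two strategy runs on horizon-mean annual costs and outcomes.

    Both runs must share the horizon and the initial fleet; incrementals are
    intervention minus comparator.
    """
    if comparator.n_cycles != intervention.n_cycles:
        raise ValueError("strategy runs must share the same horizon")
    t0_c = comparator.trace.states[0].total
    t0_i = intervention.trace.states[0].total
    if abs(t0_c - t0_i) > 1e-6 * max(1.0, t0_c):
        raise ValueError("strategy runs must start from the same fleet size")
    return ce_from_summary(
        cost_comparator=comparator.mean_annual_cost,
        cost_intervention=intervention.mean_annual_cost,
        deaths_comparator=comparator.mean_annual_deaths,
        deaths_intervention=intervention.mean_annual_deaths,
        wtp=wtp,
        missed_comparator=comparator.mean_annual_missed_trips,
        missed_intervention=intervention.mean_annual_missed_trips,
        comparator=comparator.label,
        intervention=intervention.label,
    )
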