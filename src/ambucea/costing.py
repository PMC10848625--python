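"""Per-cycle cost ledger for the ambulance fleet.

Annual cost components, all in MYR:

* operating       ``TC_o = sum_band U x (C_p + C_f) x (F + 0.5 B)``
* maintenance     ``TC_m = C_mi x M_mi + C_ma x M_ma`` with
  ``M_mi = (F + 0.5 B) x N_mi`` (band-wise) and ``M_ma = F + B``
* repair          ``TC_w = C_w x B``
* replacement     ``TC_r = R x (C_a + C_e)`` over all replacements
* resale credit   ``TS = S x E`` for the BER vehicles retired in the cycle
  (optionally also crediting scheduled non-BER retirements)
* total           ``TC = TC_o + TC_m + TC_w + TC_r - TS``

The half-cycle factor 0.5 on breakdown counts reflects that a broken-down
ambulance spends part of the year in the workshop and so delivers half the
trips and minor maintenance of a fully functional one; it applies only to
operating cost and minor maintenance.  Repair cost uses the full breakdown
count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import B_STATE, F_STATE, FleetState, TransitionFlows
from .parameters import (
    CostInputs,
    EffectivenessInputs,
    MaintenanceSchedule,
)

__all__ = [
    "CycleLedger",
    "operating_cost",
    "maintenance_cost",
    "repair_cost",
    "replacement_and_resale",
    "total_cost",
    "cycle_ledger",
    "ledger_frame",
]

_IDENTITY_TOL = 0.01  # MYR


@dataclass(frozen=True)
class CycleLedger:
    """All cost components for one cycle, in MYR."""

    operating: float
    maintenance: float
    minor_count: float
    major_count: float
    repair: float
    replacement: float
    resale: float
    total: float

    def __post_init__(self) -> None:
        for name in ("operating", "maintenance", "minor_count", "major_count",
                     "repair", "replacement", "resale"):
            if getattr(self, name) < 0:
                raise ValueError(f"ledger component {name} must be non-negative")
        ident = (self.operating + self.maintenance + self.repair
                 + self.replacement - self.resale)
        if abs(self.total - ident) > _IDENTITY_TOL:
            raise ValueError(
                f"ledger identity violated: total={self.total} vs components={ident}"
            )


def operating_cost(
    f_by_band: np.ndarray,
    b_by_band: np.ndarray,
    utilization: np.ndarray,
    personnel_per_trip: float,
    fuel_per_trip: float,
) -> float:
    """Annual operating cost: trips delivered x (personnel + fuel) per trip.

    Breakdown ambulances deliver half a functional ambulance's trips.
    All arrays are per age band, ordered as :data:`~ambucea.parameters.BANDS`.
    """
    per_trip = personnel_per_trip + fuel_per_trip
    eff_count = np.asarray(f_by_band, float) + 0.5 * np.asarray(b_by_band, float)
    return float((np.asarray(utilization, float) * per_trip * eff_count).sum())


def maintenance_cost(
    f_by_band: np.ndarray,
    b_by_band: np.ndarray,
    schedule: MaintenanceSchedule,
    minor_cost: float,
    major_cost: float,
) -> tuple[float, float, float]:
    """Annual maintenance cost and the minor/major maintenance counts.

    Minor maintenance scales with the band schedule and applies the
    half-cycle factor to breakdowns; every ambulance in F or B receives the
    scheduled major maintenances in full.
    """
    n_mi = schedule.minor_array()
    f = np.asarray(f_by_band, float)
    b = np.asarray(b_by_band, float)
    m_mi = float(((f + 0.5 * b) * n_mi).sum())
    m_ma = float((f + b).sum()) * schedule.major_per_year
    cost = minor_cost * m_mi + major_cost * m_ma
    return cost, m_mi, m_ma


def repair_cost(b_total: float, repair_per_breakdown_year: float) -> float:
    """Annual repair cost: full breakdown count x unit repair cost."""
    if b_total < 0:
        raise ValueError("breakdown count must be non-negative")
    return repair_per_breakdown_year * b_total


def replacement_and_resale(
    flows: TransitionFlows,
    ambulance_price: float,
    equipment_price: float,
    resale_value: float,
    credit_scheduled: bool = False,
) -> tuple[float, float]:
    """Replacement cost and resale credit for one cycle.

    Every replacement (scheduled or BER re-entry) buys a new ambulance plus
    medical equipment.  By default only retired BER vehicles are credited
    with the resale value; ``credit_scheduled`` extends the credit to every
    replaced vehicle.
    """
    tc_r = flows.r_total * (ambulance_price + equipment_price)
    resold = flows.r_total if credit_scheduled else flows.ber_retired
    ts = resale_value * resold
    return tc_r, ts


def total_cost(operating: float, maintenance: float, repair: float,
               replacement: float, resale: float) -> float:
    """Total annual cost: all components less the resale credit."""
    return operating + maintenance + repair + replacement - resale


def cycle_ledger(
    state: FleetState,
    flows: TransitionFlows,
    costs: CostInputs,
    effectiveness: EffectivenessInputs,
    schedule: MaintenanceSchedule,
    resale_on_scheduled: bool = False,
) -> CycleLedger:
    """Full cost ledger for the cycle that produced ``state`` via ``flows``."""
    bt = state.band_totals()
    f_by_band, b_by_band = bt[F_STATE], bt[B_STATE]
    util = effectiveness.utilization_array()
    tc_o = operating_cost(f_by_band, b_by_band, util,
                          costs.personnel_per_trip, costs.fuel_per_trip)
    tc_m, m_mi, m_ma = maintenance_cost(f_by_band, b_by_band, schedule,
                                        costs.minor_maintenance, costs.major_maintenance)
    tc_w = repair_cost(float(b_by_band.sum()), costs.repair_per_breakdown_year)
    tc_r, ts = replacement_and_resale(flows, costs.ambulance_price,
                                      costs.equipment_price, costs.resale_value,
                                      credit_scheduled=resale_on_scheduled)
    return CycleLedger(
        operating=tc_o,
        maintenance=tc_m,
        minor_count=m_mi,
        major_count=m_ma,
        repair=tc_w,
        replacement=tc_r,
        resale=ts,
        total=total_cost(tc_o, tc_m, tc_w, tc_r, ts),
    )


def ledger_frame(ledgers: list[CycleLedger]) -> pd.DataFrame:
    """Per-cycle ledger table (cycles 1..n)."""
    return pd.DataFrame(
        {
            "cycle": np.arange(1, len(ledgers) + 1),
            "operating": [led.operating for led in ledgers],
            "maintenance": [led.maintenance for led in ledgers],
            "minor_count": [led.minor_count for led in ledgers],
            "major_count": [led.major_count for led in ledgers],
            "repair": [led.repair for led in ledgers],
            "replacement": [led.replacement for led in ledgers],
            "resale": [led.resale for led in ledgers],
            "total": [led.total for led in ledgers],
        }
    )
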