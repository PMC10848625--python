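"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way DSA perturbs each uncertain input by a fixed fraction (default
+/-20%) of its base value, re-runs the full two-strategy comparison and
records the ICER swing; ranking the absolute swings gives the tornado
ordering.  Probability parameters are clipped to [0, 1] and their transition
row is renormalised proportionally (see
:meth:`ambucea.parameters.Parameters.with_overrides`).

PSA jointly samples every uncertain input from its assigned distribution —
Beta where alpha/beta are published, otherwise a Gamma moment-matched to
the point value with the published range treated as a 95% interval — and
re-runs both strategies with the same sampled vector (common random
numbers), yielding the incremental cost/effect cloud on the CE plane and
the cost-effectiveness acceptability curve (CEAC): the probability of a
positive net monetary benefit as a function of willingness to pay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import FleetState
from .outcomes import compare_strategies, evaluate_strategy
from .parameters import (
    ParameterError,
    Parameters,
    StrategySpec,
    UncertaintySpec,
)

__all__ = [
    "DsaRow",
    "DsaResult",
    "PsaResult",
    "one_way_dsa",
    "sample_overrides",
    "run_psa",
    "DEFAULT_WTP_GRID",
]

#: WTP grid for the CEAC: 0 to three times GDP per capita (MYR 120,000).
DEFAULT_WTP_GRID = np.arange(0, 120_001, 2_000)

#: z-score mapping the published +/-20% range to a 95% interval.
_Z95 = 1.959963984540054


def _icer_value(comparison) -> float:
    """ICER as a ranking scalar; dominance maps to 0 (intervention wins at any WTP)."""
    if comparison.icer is not None:
        return comparison.icer
    if comparison.decision in ("dominant", "equivalent"):
        return 0.0
    return math.nan


@dataclass(frozen=True)
class DsaRow:
    """One tornado bar: ICER at the low and high perturbation of one input."""

    name: str
    base_value: float
    low_value: float
    high_value: float
    icer_low: float
    icer_high: float

    @property
    def icer_range(self) -> float:
        return abs(self.icer_high - self.icer_low)


@dataclass
class DsaResult:
    """Tornado table: rows sorted by absolute ICER swing, largest first."""

    base_icer: float
    fraction: float
    rows: list[DsaRow] = field(default_factory=list)

    def rank(self, name: str) -> int:
        """0-based tornado rank of a parameter (0 = widest swing)."""
        for i, row in enumerate(self.rows):
            if row.name == name:
                return i
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": [r.name for r in self.rows],
                "base_value": [r.base_value for r in self.rows],
                "low_value": [r.low_value for r in self.rows],
                "high_value": [r.high_value for r in self.rows],
                "icer_low": [r.icer_low for r in self.rows],
                "icer_high": [r.icer_high for r in self.rows],
                "icer_range": [r.icer_range for r in self.rows],
            }
        )


def _compare(params: Parameters, initial: FleetState,
             comparator: StrategySpec, intervention: StrategySpec):
    res_c = evaluate_strategy(params, initial, comparator)
    res_i = evaluate_strategy(params, initial, intervention)
    return compare_strategies(res_c, res_i, wtp=params.config.wtp)


def one_way_dsa(
    params: Parameters,
    initial: FleetState,
    comparator: StrategySpec,
    intervention: StrategySpec,
    names: Optional[Sequence[str]] = None,
    fraction: Optional[float] = None,
) -> DsaResult:
    """One-way deterministic sensitivity analysis over the uncertain inputs.

    ``names`` defaults to every parameter with an uncertainty distribution
    plus the optimum utilization.  Each is varied to base x (1 -/+ fraction)
    in isolation and the two-strategy model is re-run.
    """
    if fraction is None:
        fraction = params.uncertainty.dsa_fraction
    if names is None:
        names = list(params.uncertainty.names()) + ["optimum_utilization"]
    base = _icer_value(_compare(params, initial, comparator, intervention))
    rows = []
    for name in names:
        point = params.point_value(name)
        low, high = point * (1.0 - fraction), point * (1.0 + fraction)
        icer_lo = _icer_value(
            _compare(params.with_overrides({name: low}), initial, comparator, intervention)
        )
        icer_hi = _icer_value(
            _compare(params.with_overrides({name: high}), initial, comparator, intervention)
        )
        rows.append(DsaRow(name=name, base_value=point, low_value=low,
                           high_value=high, icer_low=icer_lo, icer_high=icer_hi))
    rows.sort(key=lambda r: (-r.icer_range if not math.isnan(r.icer_range) else math.inf))
    return DsaResult(base_icer=base, fraction=fraction, rows=rows)


def _gamma_moments(point: float, low: float, high: float) -> tuple[float, float]:
    """Shape and scale of a Gamma matched to mean=point, 95% range=(low, high)."""
    sd = (high - low) / (2.0 * _Z95)
    if sd <= 0 or point <= 0:
        raise ParameterError(
            f"cannot moment-match a Gamma with mean {point} and range ({low}, {high})"
        )
    shape = (point / sd) ** 2
    return shape, point / shape


def sample_overrides(
    params: Parameters,
    spec: UncertaintySpec,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Draw one joint parameter vector from the uncertainty distributions."""
    overrides: dict[str, float] = {}
    for u in spec.parameters:
        point = params.point_value(u.name)
        if u.dist == "beta":
            overrides[u.name] = float(rng.beta(u.alpha, u.beta))
        elif u.dist == "gamma":
            shape, scale = _gamma_moments(point, u.low, u.high)
            overrides[u.name] = float(rng.gamma(shape, scale))
        elif u.dist == "fixed":
            overrides[u.name] = point
        else:  # pragma: no cover - validated at construction
            raise ParameterError(f"{u.name}: unknown distribution {u.dist!r}")
    return overrides


def _validate_spec(params: Parameters, spec: UncertaintySpec) -> None:
    for u in spec.parameters:
        params.point_value(u.name)  # raises for unknown names
        if u.dist == "gamma":
            _gamma_moments(params.point_value(u.name), u.low, u.high)


@dataclass
class PsaResult:
    """PSA products: per-iteration samples, CEAC, and quadrant fractions.

    ``samples`` has one row per iteration with the sampled parameter vector,
    the incremental cost and effect (intervention minus comparator), and the
    CE-plane quadrant (1=NE: costlier & more effective, 2=NW, 3=SW, 4=SE).
    """

    samples: pd.DataFrame
    ceac: pd.DataFrame
    wtp_grid: np.ndarray

    @property
    def n_iter(self) -> int:
        return len(self.samples)

    def quadrant_fractions(self) -> dict[int, float]:
        counts = self.samples["quadrant"].value_counts()
        return {q: float(counts.get(q, 0)) / self.n_iter for q in (1, 2, 3, 4)}

    def ceac_probability(self, wtp: float) -> float:
        """CEAC value at an arbitrary WTP by linear interpolation."""
        return float(np.interp(wtp, self.ceac["wtp"], self.ceac["probability"]))

    def ceac_crossing(self, probability: float = 0.5) -> Optional[float]:
        """Smallest WTP on the grid at which the CEAC reaches ``probability``."""
        hit = self.ceac[self.ceac["probability"] >= probability]
        if hit.empty:
            return None
        return float(hit["wtp"].iloc[0])


def run_psa(
    params: Parameters,
    initial: FleetState,
    comparator: StrategySpec,
    intervention: StrategySpec,
    n_iter: int = 10_000,
    seed: int = 0,
    wtp_grid: Optional[np.ndarray] = None,
) -> PsaResult:
    """Probabilistic sensitivity analysis with common random numbers.

    Every iteration draws one joint parameter vector, applies it to both
    strategies, and records the incremental cost and lives saved (horizon-
    mean annual).  The CEAC is the fraction of iterations with positive net
    monetary benefit ``wtp x lives_saved - incremental_cost`` at each WTP on
    the grid.  Deterministic for a fixed seed.
    """
    if n_iter < 1:
        raise ParameterError("n_iter must be >= 1")
    spec = params.uncertainty
    _validate_spec(params, spec)
    if wtp_grid is None:
        wtp_grid = DEFAULT_WTP_GRID
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    rng = np.random.default_rng(seed)

    names = list(spec.names())
    records = []
    d_cost = np.empty(n_iter)
    d_eff = np.empty(n_iter)
    for i in range(n_iter):
        overrides = sample_overrides(params, spec, rng)
        cmp = _compare(params.with_overrides(overrides), initial,
                       comparator, intervention)
        d_cost[i] = cmp.incremental_cost
        d_eff[i] = cmp.lives_saved
        records.append(overrides)

    quadrant = np.where(
        d_eff > 0,
        np.where(d_cost > 0, 1, 4),
        np.where(d_cost > 0, 2, 3),
    )
    samples = pd.DataFrame(records, columns=names)
    samples.insert(0, "iteration", np.arange(n_iter))
    samples["incremental_cost"] = d_cost
    samples["lives_saved"] = d_eff
    samples["quadrant"] = quadrant

    nmb = wtp_grid[:, None] * d_eff[None, :] - d_cost[None, :]
    ceac = pd.DataFrame(
        {"wtp": wtp_grid, "probability": (nmb > 0).mean(axis=1)}
    )
    return PsaResult(samples=samples, ceac=ceac, wtp_grid=wtp_grid)
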