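"""Synthetic initial-fleet generation.

The published analysis placed a real cohort of 1,891 ambulances into the
model by age, but the underlying age distribution is not available in
machine-readable form.  This module generates stand-in initial age
distributions: a neutral uniform spread, young- or old-skewed geometric
profiles, or fully custom per-age weights.  All generated fleets start in
the Functioning state, as scheduled replacement and breakdowns only unfold
once the model runs.

Cohort fleets hold expected (fractional) counts; :func:`integerize` converts
a fleet to whole ambulances by largest-remainder rounding for use in
per-ambulance microsimulation.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np

from .engine import F_STATE, FleetState
from .parameters import ParameterError

__all__ = ["generate_fleet", "integerize", "SCHEMES"]

SCHEMES = ("uniform", "young_skewed", "old_skewed", "custom")

#: Geometric decay per year of age for the skewed schemes.
_SKEW_RATIO = 0.85


def _weights(scheme: str, max_age: int,
             custom_weights: Optional[Sequence[float] | Mapping[int, float]]) -> np.ndarray:
    ages = np.arange(1, max_age + 1)
    if scheme == "uniform":
        w = np.ones(max_age)
    elif scheme == "young_skewed":
        w = _SKEW_RATIO ** (ages - 1.0)
    elif scheme == "old_skewed":
        w = _SKEW_RATIO ** (max_age - ages.astype(float))
    elif scheme == "custom":
        if custom_weights is None:
            raise ParameterError("scheme 'custom' requires custom_weights")
        if isinstance(custom_weights, Mapping):
            w = np.zeros(max_age)
            for age, weight in custom_weights.items():
                if not 1 <= int(age) <= max_age:
                    raise ParameterError(f"custom weight age {age} outside 1..{max_age}")
                w[int(age) - 1] = float(weight)
        else:
            w = np.asarray(custom_weights, dtype=float)
            if w.shape != (max_age,):
                raise ParameterError(
                    f"custom_weights must have length max_age={max_age}, got {w.shape}"
                )
    else:
        raise ParameterError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if np.any(w < 0):
        raise ParameterError("fleet weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ParameterError("fleet weights must sum to a positive value")
    return w / total


def generate_fleet(
    fleet_size: int,
    scheme: str = "uniform",
    max_age: int = 15,
    seed: Optional[int] = None,
    custom_weights: Optional[Sequence[float] | Mapping[int, float]] = None,
    jitter: float = 0.0,
) -> FleetState:
    """Generate an initial fleet of ``fleet_size`` Functioning ambulances.

    Parameters
    ----------
    fleet_size:
        Total number of ambulances; conserved exactly in the output.
    scheme:
        ``"uniform"`` spreads the fleet evenly over ages 1..max_age;
        ``"young_skewed"`` / ``"old_skewed"`` apply a geometric tilt;
        ``"custom"`` uses ``custom_weights`` (per-age, 1-indexed).
    max_age:
        Oldest initial age (inclusive).
    seed:
        Seeds the Dirichlet jitter; ignored when ``jitter`` is 0 (the
        deterministic schemes need no randomness).
    jitter:
        Optional scenario noise: weights are resampled from a Dirichlet
        centred on the scheme profile with concentration ``1/jitter``.
    """
    if fleet_size < 1:
        raise ParameterError(f"fleet_size must be >= 1, got {fleet_size}")
    if max_age < 1:
        raise ParameterError(f"max_age must be >= 1, got {max_age}")
    w = _weights(scheme, max_age, custom_weights)
    if jitter > 0.0:
        rng = np.random.default_rng(seed)
        alpha = np.maximum(w / jitter, 1e-12)
        w = rng.dirichlet(alpha)
    counts = np.zeros((3, max_age + 1))
    counts[F_STATE, 1:] = fleet_size * w
    # Conservation is exact by construction up to float rounding; pin it.
    counts[F_STATE, 1:] *= fleet_size / counts.sum()
    return FleetState(counts=counts)


def integerize(state: FleetState, seed: Optional[int] = None) -> FleetState:
    """Round a fractional cohort fleet to whole ambulances.

    Uses largest-remainder rounding over all (state, age) cells so the total
    is preserved exactly.  Ties in the remainders are broken by cell order;
    ``seed`` shuffles tie order for scenario generation.
    """
    counts = state.counts
    floors = np.floor(counts)
    short = int(round(counts.sum() - floors.sum()))
    remainders = (counts - floors).ravel()
    order = np.argsort(-remainders, kind="stable")
    if seed is not None:
        rng = np.random.default_rng(seed)
        # reshuffle within equal-remainder groups
        keys = -remainders + 1e-12 * rng.random(remainders.size)
        order = np.argsort(keys, kind="stable")
    out = floors.ravel().copy()
    out[order[:short]] += 1
    return FleetState(counts=out.reshape(counts.shape))
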