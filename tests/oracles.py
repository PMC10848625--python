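"""Independent oracles for checking the cohort engine.

The microsimulation here follows individual ambulances with integer states
and sampled transitions, written directly from the model rules rather than
via the cohort code: replaced/re-entered vehicles become Functioning at age
1 and sit out the cycle's transition; surviving Functioning and Breakdown
vehicles draw their destination from their start-of-cycle age band and age
one year.  Averaged over replicates it estimates the same expectations the
cohort engine computes analytically.
"""

from __future__ import annotations

import numpy as np

F, B, E = 0, 1, 2


def _band(ages: np.ndarray) -> np.ndarray:
    return (ages > 5).astype(np.intp) + (ages > 10)


def microsimulate(
    init_ages: np.ndarray,
    tm_rows: dict[str, np.ndarray],
    replacement_age: int,
    n_cycles: int,
    n_reps: int,
    seed: int,
) -> dict[str, np.ndarray]:
    """Monte-Carlo per-ambulance simulation.

    Parameters
    ----------
    init_ages:
        Integer ages of the initial (all-Functioning) fleet, shape (n_amb,).
    tm_rows:
        ``{"from_f": (3 bands, 3 dests), "from_b": (3 bands, 3 dests)}``
        transition probabilities with destination order (F, B, E).
    replacement_age:
        Vehicles at or above this age are replaced at the start of a cycle.

    Returns
    -------
    dict with per-cycle arrays of shape ``(n_reps, n_cycles + 1)`` holding
    the F/B/E totals of every replicate, plus ``"total"``.
    """
    rng = np.random.default_rng(seed)
    n_amb = len(init_ages)
    state = np.zeros((n_reps, n_amb), dtype=np.int8)
    age = np.tile(np.asarray(init_ages, dtype=np.int32), (n_reps, 1))

    cum_f = np.cumsum(tm_rows["from_f"], axis=1)
    cum_b = np.cumsum(tm_rows["from_b"], axis=1)

    out = {k: np.zeros((n_reps, n_cycles + 1)) for k in ("F", "B", "E")}

    def record(t: int) -> None:
        out["F"][:, t] = (state == F).sum(axis=1)
        out["B"][:, t] = (state == B).sum(axis=1)
        out["E"][:, t] = (state == E).sum(axis=1)

    record(0)
    for t in range(1, n_cycles + 1):
        replaced = (age >= replacement_age) | (state == E)
        surv = ~replaced
        band = _band(age)
        u = rng.random(state.shape)
        # destination thresholds depend on (state, band) of survivors
        cum = np.where((state == F)[:, :, None], cum_f[band], cum_b[band])
        dest = (u[:, :, None] > cum).sum(axis=2).astype(np.int8)
        state = np.where(surv, dest, F)
        age = np.where(surv, age + 1, 1)
        record(t)

    out["total"] = out["F"] + out["B"] + out["E"]
    return out


def stationary_distribution(row_f: np.ndarray, row_b: np.ndarray) -> np.ndarray:
    """Stationary distribution of one band's 3-state chain with BER re-entry.

    The chain is F/B/E with rows ``row_f``, ``row_b`` and deterministic
    E -> F replacement.  Solved as the left eigenvector of the transition
    matrix for eigenvalue 1.
    """
    p = np.vstack([row_f, row_b, [1.0, 0.0, 0.0]])
    w, v = np.linalg.eig(p.T)
    k = np.argmin(np.abs(w - 1.0))
    pi = np.real(v[:, k])
    return pi / pi.sum()
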