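"""Kinetic Monte Carlo trajectory generation on a Markov state model.

Discrete-time kinetic Monte Carlo: from state i, a pseudorandom number
u ~ Uniform[0, 1) is drawn and the next state is the first index n whose
cumulative row sum S_n = sum_{j<=n} T_ij reaches u.  Iterating produces
an arbitrarily long state-to-state trajectory at the model's lag time,
revealing long-timescale dynamics at negligible cost compared to running
the underlying molecular simulations.

The single-walker functions are the reference implementation; the
``*_ensemble`` variant advances many independent replicates per vectorized
step and is the workhorse behind the adaptive-sampling benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import SaxsGuideError
from .msm import DiscreteTrajectory, MarkovModel

__all__ = ["KMCRun", "kmc_trajectory", "first_passage", "first_passage_ensemble"]

#: sentinel returned when a walker never reaches the target
NOT_REACHED = -1

#: name of the pseudorandom generator backing all runs (recorded in metadata)
GENERATOR = "numpy.random.PCG64"


@dataclass(frozen=True)
class KMCRun:
    """One kinetic Monte Carlo trajectory and the seed that produced it."""

    trajectory: DiscreteTrajectory
    seed: Optional[int]
    start_state: int
    generator: str = GENERATOR


def _check_start(model: MarkovModel, start: int) -> None:
    if not 0 <= start < model.n_states:
        raise SaxsGuideError(
            f"start state {start} outside the active set [0, {model.n_states})"
        )


def _cumulative(model: MarkovModel) -> np.ndarray:
    cum = np.cumsum(model.transition_matrix, axis=1)
    cum[:, -1] = 1.0  # guard against accumulated rounding
    return cum


def step_states(cum: np.ndarray, states: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Advance a vector of walkers one step given cumulative rows and uniforms.

    The next state of walker w is the smallest n with cum[state_w, n] >= u_w,
    i.e. the number of cumulative entries strictly below u_w.
    """
    nxt = (cum[states] < u[:, None]).sum(axis=1)
    return np.minimum(nxt, cum.shape[1] - 1)


def kmc_trajectory(
    model: MarkovModel,
    start: int,
    n_steps: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> KMCRun:
    """Generate a state trajectory of ``n_steps`` transitions from ``start``.

    Each entry of the returned trajectory is separated by one lag time tau.
    Identical seeds give identical trajectories.
    """
    _check_start(model, start)
    if n_steps < 0:
        raise SaxsGuideError("n_steps must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    cum = _cumulative(model)
    states = np.empty(n_steps + 1, dtype=int)
    states[0] = start
    s = start
    u = rng.random(n_steps)
    for t in range(n_steps):
        row = cum[s]
        s = int(np.searchsorted(row, u[t], side="left"))
        if s >= row.size:
            s = row.size - 1
        states[t + 1] = s
    return KMCRun(
        trajectory=DiscreteTrajectory(states, frame_interval=model.lag_time),
        seed=seed,
        start_state=start,
    )


def first_passage(
    model: MarkovModel,
    start: int,
    target,
    seed: Optional[int] = None,
    max_steps: int = 1_000_000,
    rng: Optional[np.random.Generator] = None,
) -> int:
    """Number of tau-steps until the walker first enters ``target``.

    Returns :data:`NOT_REACHED` (-1) if the target is not entered within
    ``max_steps``; starting inside the target returns 0.
    """
    _check_start(model, start)
    target = frozenset(int(t) for t in (target if np.iterable(target) else [target]))
    if start in target:
        return 0
    if rng is None:
        rng = np.random.default_rng(seed)
    cum = _cumulative(model)
    s = start
    steps = 0
    block = 4096
    while steps < max_steps:
        u = rng.random(min(block, max_steps - steps))
        for x in u:
            row = cum[s]
            s = int(np.searchsorted(row, x, side="left"))
            if s >= row.size:
                s = row.size - 1
            steps += 1
            if s in target:
                return steps
    return NOT_REACHED


def first_passage_ensemble(
    model: MarkovModel,
    start: int,
    target,
    n_replicates: int,
    max_steps: int = 1_000_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """First-passage step counts for many independent walkers.

    All replicates are advanced together, one vectorized transition per
    step; walkers that have hit the target stop consuming random numbers.
    Entries are :data:`NOT_REACHED` for walkers still outside the target
    after ``max_steps``.
    """
    _check_start(model, start)
    target = np.asarray(
        sorted(int(t) for t in (target if np.iterable(target) else [target])), dtype=int
    )
    mask = np.zeros(model.n_states, dtype=bool)
    mask[target] = True
    out = np.full(n_replicates, NOT_REACHED, dtype=int)
    if mask[start]:
        out[:] = 0
        return out
    if rng is None:
        rng = np.random.default_rng(seed)
    cum = _cumulative(model)
    states = np.full(n_replicates, start, dtype=int)
    alive = np.arange(n_replicates)
    for step in range(1, max_steps + 1):
        u = rng.random(alive.size)
        states[alive] = step_states(cum, states[alive], u)
        hit = mask[states[alive]]
        if hit.any():
            out[alive[hit]] = step
            alive = alive[~hit]
            if alive.size == 0:
                break
    return out
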