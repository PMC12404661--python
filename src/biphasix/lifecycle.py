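"""Discrete biphasic life-cycle model of a two-member community.

The community alternates between two habitats each cycle: it first colonizes
the host (worm) up to the host carrying capacity ``K_W``, then re-seeds and
grows in the free-living environment (agar plate) up to the plate carrying
capacity ``K_P``.  Both habitats are assumed saturated at the end of their
phase, so the state of the system is fully described by the proportion of
species A in each phase.  Selection within a phase acts through a single
relative-fitness parameter per habitat (``w_W_A`` in worms, ``w_P_A`` on
plates), with species B's fitness equal to the complement.

Three update modes are provided:

``replicator`` (default)
    One phase of selection maps the proportion ``p`` of A through the
    two-type replicator update ``p -> p*w / (p*w + (1-p)*(1-w))``, i.e. the
    odds of A are multiplied by ``w/(1-w)``.  This is the normalized reading
    of "abundances weighted by relative fitness" under a fixed carrying
    capacity, and it reproduces the qualitative serial-passage outcome
    (the plate competitor sweeps both habitats over ~10 cycles).

``literal``
    The unnormalized product form ``n_A(t+1) = p(t) * w * K`` with
    ``n_B(t+1) = K - n_A(t+1)``.  Whenever both fitnesses are below 1 this
    shrinks A's proportion every cycle regardless of rank order, so it is
    retained for transparency only.

``stochastic``
    The replicator skeleton with demographic noise: binomial founder
    sampling at host colonization and a binomial transfer bottleneck
    (default 10% of the community) between cycles, emulating a
    serial-passage evolution experiment.
"""

from __future__ import annotations

import dataclasses
import math
from typing import List, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "FitnessParameters",
    "Trajectory",
    "StochasticEnsemble",
    "initialize_plate",
    "replicator_update",
    "step_cycle",
    "simulate",
    "simulate_stochastic",
    "milestone",
]

#: proportions within this distance of 0 or 1 are treated as fixed
FIXATION_TOL = 1e-12

Mode = Literal["replicator", "literal", "stochastic"]


class FitnessParameters(BaseModel):
    """Parameter set of the biphasic model.

    ``w_W_A``: relative fitness of species A within the host (B gets
    ``1 - w_W_A``); estimated from co-culture proportions during short-term
    persistence.  ``w_P_A``: relative fitness of A in the free-living
    environment; estimated from co-culture proportions on agar after 3 days.
    ``K_W`` / ``K_P``: carrying capacities (CFU per worm / per plate),
    assumed reached every phase.  ``prop_A_initial``: proportion of A in the
    experimental inoculum that seeds the cycle-0 plate.
    """

    model_config = ConfigDict(frozen=True)

    w_W_A: float = Field(ge=0.0, le=1.0)
    w_P_A: float = Field(ge=0.0, le=1.0)
    K_W: float = Field(gt=0.0, default=1e4)
    K_P: float = Field(gt=0.0, default=1e9)
    prop_A_initial: float = Field(ge=0.0, le=1.0, default=0.5)


@dataclasses.dataclass
class Trajectory:
    """Per-cycle, per-phase state of the community.

    ``prop_P_A`` has length ``n_cycles + 1`` with index 0 holding the
    pre-cycle inoculated plate; ``prop_W_A`` has length ``n_cycles`` and is
    1-based in cycle terms (``prop_W_A[t-1]`` is the worm phase of cycle t).
    Milestones quoted as "after four cycles" refer to this 1-based index.
    """

    prop_P_A: np.ndarray
    prop_W_A: np.ndarray
    K_P: float
    K_W: float
    mode: str

    @property
    def n_cycles(self) -> int:
        return len(self.prop_W_A)

    @property
    def n_P_A(self) -> np.ndarray:
        return self.prop_P_A * self.K_P

    @property
    def n_P_B(self) -> np.ndarray:
        return (1.0 - self.prop_P_A) * self.K_P

    @property
    def n_W_A(self) -> np.ndarray:
        return self.prop_W_A * self.K_W

    @property
    def n_W_B(self) -> np.ndarray:
        return (1.0 - self.prop_W_A) * self.K_W

    def phase_proportions(self, phase: str) -> np.ndarray:
        """Proportion of A per 1-based cycle for ``phase`` in {worm, plate}."""
        if phase == "worm":
            return self.prop_W_A
        if phase == "plate":
            return self.prop_P_A[1:]
        raise ValueError(f"unknown phase {phase!r}")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: cycle, phase, n_A, n_B, prop_A (cycle 0 is the
        initial plate; worm rows start at cycle 1)."""
        rows = []
        for t in range(len(self.prop_P_A)):
            if t >= 1:
                pw = self.prop_W_A[t - 1]
                rows.append(
                    {
                        "cycle": t,
                        "phase": "worm",
                        "n_A": pw * self.K_W,
                        "n_B": (1 - pw) * self.K_W,
                        "prop_A": pw,
                    }
                )
            pp = self.prop_P_A[t]
            rows.append(
                {
                    "cycle": t,
                    "phase": "plate",
                    "n_A": pp * self.K_P,
                    "n_B": (1 - pp) * self.K_P,
                    "prop_A": pp,
                }
            )
        return pd.DataFrame(rows, columns=["cycle", "phase", "n_A", "n_B", "prop_A"])


@dataclasses.dataclass
class StochasticEnsemble:
    """Ensemble of stochastic trajectories: arrays of shape (n_runs, ...)."""

    prop_P_A: np.ndarray  # (n_runs, n_cycles + 1)
    prop_W_A: np.ndarray  # (n_runs, n_cycles)
    K_P: float
    K_W: float

    @property
    def n_runs(self) -> int:
        return self.prop_P_A.shape[0]

    def trajectories(self) -> List[Trajectory]:
        return [
            Trajectory(
                prop_P_A=self.prop_P_A[i].copy(),
                prop_W_A=self.prop_W_A[i].copy(),
                K_P=self.K_P,
                K_W=self.K_W,
                mode="stochastic",
            )
            for i in range(self.n_runs)
        ]

    def mean_trajectory(self) -> Trajectory:
        return Trajectory(
            prop_P_A=self.prop_P_A.mean(axis=0),
            prop_W_A=self.prop_W_A.mean(axis=0),
            K_P=self.K_P,
            K_W=self.K_W,
            mode="stochastic-mean",
        )


def initialize_plate(params: FitnessParameters) -> tuple[float, float]:
    """Abundances (n_P_A, n_P_B) of the actively inoculated cycle-0 plate,
    assumed to sit at the plate carrying capacity."""
    n_a = params.prop_A_initial * params.K_P
    return n_a, params.K_P - n_a


def _clamp(p: float) -> float:
    if p < FIXATION_TOL:
        return 0.0
    if p > 1.0 - FIXATION_TOL:
        return 1.0
    return p


def replicator_update(p: float, w: float) -> float:
    """One phase of two-type selection: p -> p*w / (p*w + (1-p)*(1-w)).

    Equivalent to multiplying the odds of A by w/(1-w).  p in {0, 1} is
    absorbing; with interior p, w in {0, 1} jumps to w's absorbing endpoint.
    """
    if not (0.0 <= p <= 1.0 and 0.0 <= w <= 1.0):
        raise ValueError(f"p and w must lie in [0, 1]; got p={p}, w={w}")
    if p <= 0.0 or p >= 1.0:
        return p
    denom = p * w + (1.0 - p) * (1.0 - w)
    if denom == 0.0:  # unreachable for interior p, kept as a guard
        return p
    return _clamp(p * w / denom)


def step_cycle(
    prop_P: float, params: FitnessParameters, mode: Mode = "replicator"
) -> tuple[float, float]:
    """Advance one full cycle from a plate proportion of A.

    Returns ``(prop_W_next, prop_P_next)``: first the plate community
    colonizes worms under the within-host fitness, then the worm community
    re-seeds the plate under the free-living fitness.  Both habitats end the
    phase at carrying capacity, so only proportions propagate.
    """
    if mode == "replicator":
        prop_w = replicator_update(prop_P, params.w_W_A)
        prop_p = replicator_update(prop_w, params.w_P_A)
    elif mode == "literal":
        # unnormalized product form; proportion of A is p*w, B takes the rest
        prop_w = _clamp(prop_P * params.w_W_A)
        prop_p = _clamp(prop_w * params.w_P_A)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return prop_w, prop_p


def simulate(
    params: FitnessParameters, n_cycles: int = 10, mode: Mode = "replicator"
) -> Trajectory:
    """Deterministic trajectory over ``n_cycles`` biphasic cycles."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    prop_P = np.empty(n_cycles + 1)
    prop_W = np.empty(n_cycles)
    n_a, _ = initialize_plate(params)
    prop_P[0] = n_a / params.K_P
    for t in range(1, n_cycles + 1):
        prop_W[t - 1], prop_P[t] = step_cycle(prop_P[t - 1], params, mode=mode)
    return Trajectory(
        prop_P_A=prop_P, prop_W_A=prop_W, K_P=params.K_P, K_W=params.K_W, mode=mode
    )


def simulate_stochastic(
    params: FitnessParameters,
    n_cycles: int = 10,
    transfer_fraction: float = 0.1,
    n_worm_founders: int = 1000,
    seed: int = 0,
    n_runs: int = 1,
) -> StochasticEnsemble:
    """Stochastic serial-passage ensemble.

    Each cycle: (i) worm colonization founds a finite population of
    ``n_worm_founders`` individuals whose species-A count is binomial with
    success probability ``replicator_update(prop_P, w_W_A)``; (ii) a
    bottleneck transfers ``round(transfer_fraction * n_worm_founders)``
    individuals, sampled binomially from the worm community, to seed the
    next plate; (iii) plate growth applies the deterministic replicator
    update with ``w_P_A``.  Extinction is absorbing.  As founder counts grow
    the ensemble mean converges to the deterministic replicator trajectory.
    """
    if not (0.0 < transfer_fraction <= 1.0):
        raise ValueError("transfer_fraction must be in (0, 1]")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if n_worm_founders < 1:
        raise ValueError("n_worm_founders must be >= 1")
    n_transfer = max(1, int(round(transfer_fraction * n_worm_founders)))
    rng = np.random.default_rng(seed)
    prop_P = np.empty((n_runs, n_cycles + 1))
    prop_W = np.empty((n_runs, n_cycles))
    prop_P[:, 0] = params.prop_A_initial
    p = np.full(n_runs, params.prop_A_initial)
    for t in range(1, n_cycles + 1):
        # (i) binomial founding of the host population
        p_col = np.array([replicator_update(pi, params.w_W_A) for pi in p])
        founders_a = rng.binomial(n_worm_founders, p_col)
        p_w = founders_a / n_worm_founders
        prop_W[:, t - 1] = p_w
        # (ii) transfer bottleneck
        transferred_a = rng.binomial(n_transfer, p_w)
        p_seed = transferred_a / n_transfer
        # (iii) deterministic plate-phase selection
        p = np.array([replicator_update(pi, params.w_P_A) for pi in p_seed])
        prop_P[:, t] = p
    return StochasticEnsemble(
        prop_P_A=prop_P, prop_W_A=prop_W, K_P=params.K_P, K_W=params.K_W
    )


def milestone(
    traj: Trajectory,
    phase: Literal["worm", "plate"],
    threshold: float,
    direction: Literal["exceeds", "falls_below"] = "exceeds",
) -> Optional[int]:
    """Smallest 1-based cycle index where the phase proportion of A strictly
    crosses ``threshold`` in the stated direction, or ``None``."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly between 0 and 1")
    props = traj.phase_proportions(phase)
    for t, p in enumerate(props, start=1):
        if direction == "exceeds" and p > threshold:
            return t
        if direction == "falls_below" and p < threshold:
            return t
    return None
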