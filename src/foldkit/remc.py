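"""Replica-Exchange Monte Carlo over coarse-grained chain conformations.

Twenty replicas by default, spread geometrically between t_max and t_min
(dimensionless model temperatures).  Each cycle runs one Metropolis
sweep per replica (one proposed move per residue) followed by an
exchange sweep over alternating adjacent pairs.  The trajectory records,
at fixed intervals, the conformation of whichever replica currently has
the lowest total energy, together with its energy, radius of gyration
and end-to-end distance.

Randomness: each replica owns an RNG stream derived from the master
seed, so changing the replica count does not reshuffle the randomness of
the remaining replicas; exchange decisions use a separate stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chain import MoveParams, propose_move
from .geometry import end_to_end, radius_of_gyration


class LadderError(ValueError):
    pass


@dataclass(frozen=True)
class TemperatureLadder:
    """Non-increasing positive temperatures, one per replica."""

    temperatures: tuple[float, ...]

    def __post_init__(self) -> None:
        ts = self.temperatures
        if len(ts) < 1 or any(t <= 0 for t in ts):
            raise LadderError("temperatures must be positive and non-empty")
        if any(a < b for a, b in zip(ts, ts[1:])):
            raise LadderError("temperatures must be non-increasing")

    def __len__(self) -> int:
        return len(self.temperatures)


@dataclass
class ReplicaState:
    coords: np.ndarray
    energy: float
    rng: np.random.Generator
    n_proposed: int = 0
    n_accepted: int = 0

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else 0.0


@dataclass
class Trajectory:
    """Recorded lowest-energy-replica snapshots and their observables."""

    snapshots: list[np.ndarray] = field(default_factory=list)
    energies: list[float] = field(default_factory=list)
    rg: list[float] = field(default_factory=list)
    end_to_end: list[float] = field(default_factory=list)
    #: per-recording-point energies of every replica (diagnostics)
    replica_energies: list[list[float]] = field(default_factory=list)
    swap_log: list[tuple[int, int, bool]] = field(default_factory=list)
    acceptance_rates: list[float] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.snapshots)


def make_ladder(t_max: float, t_min: float, n_replicas: int) -> TemperatureLadder:
    """Geometric temperature ladder from t_max down to t_min.

    Endpoints are exact; a flat range (t_max == t_min) yields a constant
    ladder, and a single replica sits at t_max.
    """
    if t_min <= 0 or t_max < t_min:
        raise LadderError(f"need t_max >= t_min > 0, got ({t_max}, {t_min})")
    if n_replicas < 1:
        raise LadderError("need at least one replica")
    if n_replicas == 1:
        return TemperatureLadder((float(t_max),))
    ratio = (t_min / t_max) ** (1.0 / (n_replicas - 1))
    ts = [t_max * ratio ** k for k in range(n_replicas)]
    ts[0], ts[-1] = float(t_max), float(t_min)
    return TemperatureLadder(tuple(ts))


def metropolis_accept(delta_e: float, temperature: float, u: float) -> bool:
    """Metropolis rule: accept iff u < min(1, exp(-dE/T))."""
    if delta_e <= 0:
        return True
    return u < math.exp(-delta_e / temperature)


def metropolis_sweep(state: ReplicaState, temperature: float, energy_fn,
                     move_params: MoveParams = MoveParams()) -> ReplicaState:
    """One sweep: n proposed local moves (n = chain length), in place."""
    n = len(state.coords)
    for _ in range(n):
        cand, _kind = propose_move(state.coords, state.rng, move_params)
        e_new = energy_fn(cand)
        state.n_proposed += 1
        if metropolis_accept(e_new - state.energy, temperature,
                             float(state.rng.random())):
            state.coords = cand
            state.energy = e_new
            state.n_accepted += 1
    return state


def exchange_sweep(replicas: list[ReplicaState], ladder: TemperatureLadder,
                   rng: np.random.Generator, phase: int = 0,
                   log: list | None = None) -> None:
    """Attempt swaps between adjacent temperature slots of one parity.

    A swap between slots a (T_a) and b (T_b) is accepted with probability
    min(1, exp((1/T_a - 1/T_b) (E_a - E_b))); on acceptance the slots
    exchange conformations (and energies), keeping their temperatures.
    """
    if len(replicas) != len(ladder):
        raise LadderError("replica count must equal ladder length")
    for a in range(phase % 2, len(replicas) - 1, 2):
        b = a + 1
        ta, tb = ladder.temperatures[a], ladder.temperatures[b]
        arg = (1.0 / ta - 1.0 / tb) * (replicas[a].energy - replicas[b].energy)
        accept = arg >= 0 or float(rng.random()) < math.exp(arg)
        if accept:
            replicas[a].coords, replicas[b].coords = (
                replicas[b].coords, replicas[a].coords)
            replicas[a].energy, replicas[b].energy = (
                replicas[b].energy, replicas[a].energy)
        if log is not None:
            log.append((a, b, accept))


def run_simulation(start: np.ndarray, ladder: TemperatureLadder, energy_fn,
                   n_cycles: int, record_every: int, seed: int,
                   move_params: MoveParams = MoveParams()) -> Trajectory:
    """Full REMC run; fully deterministic for a given seed and config.

    Every replica starts from ``start``.  Each cycle performs one
    Metropolis sweep per replica, then one exchange sweep with
    alternating pairing parity.  The start and every ``record_every``-th
    cycle contribute a snapshot of the lowest-total-energy replica.
    """
    start = np.asarray(start, float)
    replicas = [
        ReplicaState(coords=start.copy(), energy=float(energy_fn(start)),
                     rng=np.random.default_rng([seed, k]))
        for k in range(len(ladder))
    ]
    swap_rng = np.random.default_rng([seed, 1_000_003])
    traj = Trajectory(metadata={
        "seed": seed,
        "temperatures": list(ladder.temperatures),
        "n_cycles": n_cycles,
        "record_every": record_every,
    })

    def record() -> None:
        best = min(replicas, key=lambda r: r.energy)
        traj.snapshots.append(best.coords.copy())
        traj.energies.append(best.energy)
        traj.rg.append(radius_of_gyration(best.coords))
        traj.end_to_end.append(end_to_end(best.coords))
        traj.replica_energies.append([r.energy for r in replicas])

    record()
    for cycle in range(1, n_cycles + 1):
        for k, rep in enumerate(replicas):
            metropolis_sweep(rep, ladder.temperatures[k], energy_fn,
                             move_params)
        exchange_sweep(replicas, ladder, swap_rng, phase=cycle,
                       log=traj.swap_log)
        if cycle % record_every == 0:
            record()
    traj.acceptance_rates = [r.acceptance_rate for r in replicas]
    return traj
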