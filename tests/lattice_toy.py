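"""Exactly enumerable 4-bead lattice chain for Monte Carlo validation.

A synthetic toy system, not a protein model: four beads on the cubic
lattice, bead 0 pinned at the origin, the chain encoded by three unit
steps (6 directions each).  States where beads collide are forbidden.
The energy is -1 per non-bonded contact (pairs (0,2), (0,3), (1,3) at
unit lattice distance), giving a non-uniform Boltzmann distribution that
is computable by exhaustive enumeration — the independent oracle against
which the sampler's long-run histogram is compared.

The sampler itself delegates every accept/reject decision to
``foldkit.remc.metropolis_accept`` so the production Metropolis rule is
the code path under test.
"""

import itertools

import numpy as np

from foldkit.remc import metropolis_accept

DIRECTIONS = np.array([
    [1, 0, 0], [-1, 0, 0],
    [0, 1, 0], [0, -1, 0],
    [0, 0, 1], [0, 0, -1],
])

NON_BONDED_PAIRS = ((0, 2), (0, 3), (1, 3))
CONTACT_ENERGY = -1.0


def positions(state: tuple[int, int, int]) -> np.ndarray:
    pos = np.zeros((4, 3), dtype=int)
    for k, d in enumerate(state, start=1):
        pos[k] = pos[k - 1] + DIRECTIONS[d]
    return pos


def state_energy(state) -> float | None:
    """Energy of a direction triple, or None if beads collide."""
    pos = positions(state)
    if len({tuple(p) for p in pos}) < 4:
        return None
    e = 0.0
    for a, b in NON_BONDED_PAIRS:
        if np.abs(pos[a] - pos[b]).sum() == 1:
            e += CONTACT_ENERGY
    return e


def enumerate_states():
    """All valid states with their energies (exhaustive)."""
    out = {}
    for state in itertools.product(range(6), repeat=3):
        e = state_energy(state)
        if e is not None:
            out[state] = e
    return out


def exact_boltzmann(temperature: float) -> dict[tuple, float]:
    states = enumerate_states()
    weights = {s: np.exp(-e / temperature) for s, e in states.items()}
    z = sum(weights.values())
    return {s: w / z for s, w in weights.items()}


def run_chain(n_steps: int, temperature: float, seed: int) -> dict[tuple, int]:
    """Metropolis chain over the toy states; returns visit counts.

    Proposal: redraw one of the three step directions uniformly
    (symmetric); proposals into colliding states are rejected.
    """
    energies = enumerate_states()
    state = next(iter(sorted(energies)))
    e_cur = energies[state]
    rng = np.random.default_rng(seed)
    ks = rng.integers(0, 3, size=n_steps)
    ds = rng.integers(0, 6, size=n_steps)
    us = rng.random(size=n_steps)
    counts: dict[tuple, int] = {}
    for k, d, u in zip(ks, ds, us):
        proposal = list(state)
        proposal[k] = d
        proposal = tuple(proposal)
        e_new = energies.get(proposal)
        if e_new is not None and metropolis_accept(e_new - e_cur,
                                                   temperature, float(u)):
            state, e_cur = proposal, e_new
        counts[state] = counts.get(state, 0) + 1
    return counts


def total_variation(counts: dict[tuple, int],
                    exact: dict[tuple, float]) -> float:
    n = sum(counts.values())
    return 0.5 * sum(abs(counts.get(s, 0) / n - p) for s, p in exact.items())
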