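"""Coarse-grained C-alpha chain model.

A conformation is an (n, 3) array of C-alpha positions in Angstrom, one
bead per query residue.  The module builds starting structures (random
coil, or template coordinates with coil-bridged gaps), proposes local
Monte Carlo moves, and evaluates a surrogate internal energy:

* harmonic virtual-bond term around 3.8 Angstrom;
* pseudo-bond-angle bias toward secondary-structure-dependent targets
  (H -> 91 deg, E -> 120 deg, C unbiased);
* soft-core repulsion between non-adjacent beads below 4.0 Angstrom.

Energies and temperatures are dimensionless model units; only relative
energies are meaningful.  This internal energy is this package's own
coarse-grained surrogate — it is deliberately simple, and the restraint
term (see :mod:`foldkit.restraints`) carries the template information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform

from .bioio import SecondaryStructure, Template
from .constants import (
    BOND_WINDOW,
    CA_BOND_LENGTH,
    HARD_CLASH_DISTANCE,
    HELIX_PSEUDO_ANGLE_DEG,
    STRAND_PSEUDO_ANGLE_DEG,
)


class ChainError(ValueError):
    pass


class GrowthError(ChainError):
    """Random-coil growth failed after bounded retries."""


class BridgeError(ChainError):
    """A template gap could not be bridged with a coil segment."""


@dataclass(frozen=True)
class ChainParams:
    """Surrogate energy constants (model units)."""

    k_bond: float = 25.0
    k_angle: float = 5.0
    k_rep: float = 25.0
    bond_length: float = CA_BOND_LENGTH
    clash_distance: float = HARD_CLASH_DISTANCE
    angle_targets_deg: tuple[float, float] = (
        HELIX_PSEUDO_ANGLE_DEG,
        STRAND_PSEUDO_ANGLE_DEG,
    )


@dataclass(frozen=True)
class MoveParams:
    """Local-move mixture: displacement / crankshaft / terminal pivot."""

    p_displace: float = 0.5
    p_crankshaft: float = 0.3
    p_pivot: float = 0.2
    max_displacement: float = 0.7
    max_crank_angle_deg: float = 25.0
    max_pivot_angle_deg: float = 30.0


@dataclass(frozen=True)
class EnergyBreakdown:
    local: float
    excluded_volume: float
    restraint: float

    @property
    def total(self) -> float:
        return self.local + self.excluded_volume + self.restraint


def check_conformation(coords: np.ndarray,
                       bond_window: tuple[float, float] = BOND_WINDOW,
                       clash: float = HARD_CLASH_DISTANCE) -> list[str]:
    """Audit hard invariants; returns a list of violation messages."""
    coords = np.asarray(coords, float)
    issues = []
    if not np.all(np.isfinite(coords)):
        return ["non-finite coordinates"]
    if len(coords) >= 2:
        bonds = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        for k in np.flatnonzero((bonds < bond_window[0] - 1e-6)
                                | (bonds > bond_window[1] + 1e-6)):
            issues.append(f"bond {k + 1}-{k + 2} length {bonds[k]:.3f} outside "
                          f"[{bond_window[0]}, {bond_window[1]}]")
    if len(coords) >= 3:
        dm = squareform(pdist(coords))
        iu = np.triu_indices(len(coords), k=2)
        bad = dm[iu] < clash - 1e-6
        for a, b in zip(iu[0][bad], iu[1][bad]):
            issues.append(f"clash {a + 1}-{b + 1} at {dm[a, b]:.3f} A")
    return issues


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def random_coil(n: int, seed: int,
                params: ChainParams = ChainParams()) -> np.ndarray:
    """Self-avoiding random coil with 3.8 Angstrom bonds; deterministic per seed.

    Beads are grown one at a time with clash rejection; dead ends trigger
    limited backtracking and finally a full reseeded restart.
    """
    if not 1 <= n <= 900:
        raise ChainError(f"chain length {n} outside 1..900")
    for attempt in range(40):
        rng = np.random.default_rng([seed, attempt])
        coords = np.zeros((n, 3))
        k = 1
        steps = 0
        failed = False
        while k < n:
            placed = False
            for _ in range(80):
                cand = coords[k - 1] + params.bond_length * _random_unit(rng)
                if k >= 2:
                    d = np.linalg.norm(coords[: k - 1] - cand, axis=1)
                    if d.min() < params.clash_distance:
                        continue
                coords[k] = cand
                placed = True
                break
            if placed:
                k += 1
            else:
                k = max(1, k - 5)  # backtrack out of the dead end
            steps += 1
            if steps > 50 * n:
                failed = True
                break
        if not failed:
            return coords
    raise GrowthError(f"could not grow a {n}-bead self-avoiding coil")


# --- geometry relaxation -------------------------------------------------

def _relax_objective(x: np.ndarray, n: int, free: np.ndarray,
                     base: np.ndarray, params: ChainParams,
                     clash_margin: float):
    coords = base.copy()
    coords[free] = x.reshape(-1, 3)
    grad = np.zeros_like(coords)
    # bonds
    b = np.diff(coords, axis=0)
    lb = np.linalg.norm(b, axis=1)
    lb = np.where(lb < 1e-12, 1e-12, lb)
    dev = lb - params.bond_length
    f = float((dev ** 2).sum())
    gb = (2 * dev / lb)[:, None] * b
    np.add.at(grad, np.arange(1, n), gb)
    np.add.at(grad, np.arange(0, n - 1), -gb)
    # clashes (non-adjacent), with a small margin so minima sit inside
    if n >= 3:
        dm = squareform(pdist(coords))
        target = params.clash_distance + clash_margin
        iu, ju = np.triu_indices(n, k=2)
        d = dm[iu, ju]
        mask = d < target
        if mask.any():
            ii, jj, dd = iu[mask], ju[mask], np.where(d[mask] < 1e-12, 1e-12,
                                                      d[mask])
            pen = target - dd
            f += float((pen ** 2).sum())
            gv = (-2 * pen / dd)[:, None] * (coords[jj] - coords[ii])
            np.add.at(grad, jj, gv)
            np.add.at(grad, ii, -gv)
    return f, grad[free].ravel()


def relax_geometry(coords: np.ndarray, fixed: np.ndarray | None = None,
                   params: ChainParams = ChainParams(),
                   max_iter: int = 500,
                   clash_margin: float = 0.1) -> np.ndarray:
    """Push a trace back inside the bond window and out of clashes.

    Minimizes a smooth bond/clash objective over the non-fixed beads
    (L-BFGS with analytic gradients).  Used to repair averaged cluster
    structures and to shape coil bridges between template anchors.
    """
    coords = np.array(coords, float)
    n = len(coords)
    if n < 2:
        return coords
    free = np.ones(n, bool) if fixed is None else ~np.asarray(fixed, bool)
    if not free.any():
        return coords
    res = minimize(
        _relax_objective, coords[free].ravel(), jac=True,
        args=(n, free, coords, params, clash_margin),
        method="L-BFGS-B", options={"maxiter": max_iter},
    )
    out = coords.copy()
    out[free] = res.x.reshape(-1, 3)
    return out


def build_start_from_templates(templates: list[Template], n: int,
                               seed: int,
                               params: ChainParams = ChainParams()) -> np.ndarray:
    """Starting structure: template coordinates with coil-bridged gaps.

    Covered residues take coordinates from the first template covering
    them; interior gaps are bridged by relaxed coil segments between the
    flanking anchors and uncovered tails are grown as coil.  With no
    templates this degenerates to :func:`random_coil`.
    """
    if not templates:
        return random_coil(n, seed, params)
    coords = np.full((n, 3), np.nan)
    covered = np.zeros(n, bool)
    for template in templates:
        trace = template.trace
        for resid, xyz in zip(trace.resids, trace.coords):
            idx = int(resid) - 1
            if not covered[idx]:
                coords[idx] = xyz
                covered[idx] = True
    if covered.all():
        return coords
    rng = np.random.default_rng([seed, 977])
    idx_cov = np.flatnonzero(covered)
    first_cov, last_cov = idx_cov[0], idx_cov[-1]
    # interior gaps
    gaps = []
    prev = first_cov
    for idx in idx_cov[1:]:
        if idx > prev + 1:
            gaps.append((prev, idx))
        prev = idx
    for left, right in gaps:
        g = right - left - 1
        A, B = coords[left], coords[right]
        span = float(np.linalg.norm(B - A))
        if span > BOND_WINDOW[1] * (g + 1):
            raise BridgeError(
                f"gap {left + 2}..{right} ({g} residues) cannot bridge "
                f"anchors {span:.1f} A apart; review template coverage"
            )
        ts = np.arange(1, g + 1) / (g + 1)
        seg = A + ts[:, None] * (B - A)
        # bulge sideways so short chords still get near-3.8 A steps
        perp = np.cross(B - A if span > 1e-9 else np.array([1.0, 0, 0]),
                        _random_unit(rng))
        nrm = np.linalg.norm(perp)
        perp = perp / nrm if nrm > 1e-9 else np.array([0.0, 0, 1.0])
        arc_needed = max(0.0, params.bond_length * (g + 1) - span)
        seg = seg + np.sin(np.pi * ts)[:, None] * perp * (0.6 * arc_needed + 0.5)
        seg += rng.normal(scale=0.1, size=seg.shape)
        coords[left + 1:right] = seg
    fixed = covered.copy()
    coords = _fill_tails(coords, first_cov, last_cov, rng, params)
    if gaps:
        coords = relax_geometry(coords, fixed=fixed, params=params)
    return coords


def _fill_tails(coords, first_cov, last_cov, rng, params):
    n = len(coords)
    for idx in range(first_cov - 1, -1, -1):
        coords[idx] = _grow_bead(coords, idx + 1, idx, rng, params)
    for idx in range(last_cov + 1, n):
        coords[idx] = _grow_bead(coords, idx - 1, idx, rng, params)
    return coords


def _grow_bead(coords, anchor_idx, new_idx, rng, params):
    known = np.flatnonzero(np.all(np.isfinite(coords), axis=1))
    others = known[np.abs(known - new_idx) >= 2]
    for _ in range(200):
        cand = coords[anchor_idx] + params.bond_length * _random_unit(rng)
        if len(others) == 0 or np.linalg.norm(
                coords[others] - cand, axis=1).min() >= params.clash_distance:
            return cand
    raise GrowthError(f"could not grow tail bead {new_idx + 1}")


# --- energy ---------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=64)
def _nonadjacent_mask(n: int) -> np.ndarray:
    iu, ju = np.triu_indices(n, k=1)
    return ju - iu >= 2


@lru_cache(maxsize=64)
def _ss_masks(states: str) -> tuple[np.ndarray, np.ndarray]:
    arr = np.frombuffer(states.encode(), dtype=np.uint8)[1:-1]
    return arr == ord("H"), arr == ord("E")


def pseudo_angles(coords: np.ndarray) -> np.ndarray:
    """Interior C-alpha pseudo-bond angles (radians), length n - 2."""
    u = coords[:-2] - coords[1:-1]
    v = coords[2:] - coords[1:-1]
    cosang = (u * v).sum(axis=1) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def internal_energy(coords: np.ndarray, ss: SecondaryStructure,
                    params: ChainParams = ChainParams(),
                    restraint: float = 0.0) -> EnergyBreakdown:
    """Surrogate internal energy with local and excluded-volume parts.

    ``restraint`` is passed through into the breakdown so callers can
    report a single total.
    """
    coords = np.asarray(coords, float)
    n = len(coords)
    if len(ss) != n:
        raise ChainError(
            f"secondary structure length {len(ss)} != chain length {n}")
    local = 0.0
    if n >= 2:
        bonds = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        local += params.k_bond * float(((bonds - params.bond_length) ** 2).sum())
    if n >= 3:
        ang = pseudo_angles(coords)
        t_h, t_e = np.deg2rad(params.angle_targets_deg)
        is_h, is_e = _ss_masks(ss.states)
        local += params.k_angle * float(((ang[is_h] - t_h) ** 2).sum())
        local += params.k_angle * float(((ang[is_e] - t_e) ** 2).sum())
    excl = 0.0
    if n >= 3:
        d = pdist(coords)
        dn = d[_nonadjacent_mask(n)]
        pen = np.maximum(params.clash_distance - dn, 0.0)
        excl = params.k_rep * float((pen ** 2).sum())
    return EnergyBreakdown(local=local, excluded_volume=excl,
                           restraint=float(restraint))


# --- moves ----------------------------------------------------------------

def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def propose_move(coords: np.ndarray, rng: np.random.Generator,
                 move_params: MoveParams = MoveParams()) -> tuple[np.ndarray, str]:
    """One local move; returns (new coords, move kind).

    Kinds: ``displace`` (one bead, uniform in a 0.7 A ball),
    ``crankshaft`` (the two beads between anchors i and i+3 rotated about
    the anchor chord), ``pivot`` (a terminal bead rotated about a random
    axis through its neighbour).  Each kind is self-inverse in
    distribution, so forward and reverse proposal densities match and the
    plain Metropolis rule is valid.
    """
    coords = np.asarray(coords, float)
    n = len(coords)
    if n < 3:
        raise ChainError("moves need a chain of >= 3 beads")
    u = rng.random()
    if u >= move_params.p_displace and n < 4:
        u = 0.0  # crankshaft infeasible on n=3; fall back to displacement
    new = coords.copy()
    if u < move_params.p_displace:
        k = int(rng.integers(n))
        delta = _random_unit(rng) * move_params.max_displacement * \
            rng.random() ** (1.0 / 3.0)
        new[k] = coords[k] + delta
        return new, "displace"
    if u < move_params.p_displace + move_params.p_crankshaft:
        i = int(rng.integers(n - 3))
        axis = coords[i + 3] - coords[i]
        if np.linalg.norm(axis) < 1e-9:
            axis = np.array([1.0, 0.0, 0.0])
        angle = np.deg2rad(move_params.max_crank_angle_deg) * \
            (2 * rng.random() - 1)
        R = _rotation_about_axis(axis, angle)
        for k in (i + 1, i + 2):
            new[k] = coords[i] + R @ (coords[k] - coords[i])
        return new, "crankshaft"
    end = 0 if rng.random() < 0.5 else n - 1
    pivot = 1 if end == 0 else n - 2
    angle = np.deg2rad(move_params.max_pivot_angle_deg) * (2 * rng.random() - 1)
    R = _rotation_about_axis(_random_unit(rng), angle)
    new[end] = coords[pivot] + R @ (coords[end] - coords[pivot])
    return new, "pivot"
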