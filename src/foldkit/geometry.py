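"""Superposition and similarity metrics on C-alpha traces.

Provides least-squares rigid superposition (Kabsch), RMSD, GDT_TS on the
standard 1/2/4/8 Angstrom cutoffs (reported as a fraction in [0, 1]), and
the two shape observables recorded along trajectories: radius of gyration
and end-to-end distance.

Two traces are always compared on the intersection of their residue
indices, which requires at least three common residues.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .bioio import CaTrace
from .constants import GDT_THRESHOLDS


class InsufficientOverlapError(ValueError):
    """Raised when two traces share fewer than three residues."""


class UndefinedQuantityError(ValueError):
    """Raised when an observable is undefined for the given input."""


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform of b onto a and the resulting RMSD.

    The transform maps a point x of b to ``rotation @ x + translation``.
    The rotation is proper (det = +1): reflections are never returned.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


@dataclass(frozen=True)
class SimilarityScore:
    gdt_ts: float


def as_trace(obj) -> CaTrace:
    """Coerce an (n, 3) array or CaTrace to a CaTrace with 1-based resids."""
    if isinstance(obj, CaTrace):
        return obj
    arr = np.asarray(obj, dtype=float)
    return CaTrace(coords=arr, resids=np.arange(1, len(arr) + 1))


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares proper rotation/translation mapping points Q onto P.

    Returns ``(R, t, rmsd)`` with ``Q @ R.T + t`` optimally aligned to P.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - cq).T @ (P - cp)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    diff = (Q @ R.T + t) - P
    rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
    return R, t, rmsd


def _common(a: CaTrace, b: CaTrace) -> tuple[np.ndarray, np.ndarray]:
    shared, ia, ib = np.intersect1d(a.resids, b.resids, return_indices=True)
    if len(shared) < 3:
        raise InsufficientOverlapError(
            f"traces share only {len(shared)} residues; need >= 3"
        )
    return a.coords[ia], b.coords[ib]


def superpose(a, b) -> SuperpositionResult:
    """Optimal rigid superposition of trace b onto trace a.

    Comparison runs over the common-residue intersection; RMSD is reported
    over those residues.
    """
    A, B = _common(as_trace(a), as_trace(b))
    R, t, rmsd = kabsch(A, B)
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def rmsd(a, b) -> float:
    """Superposed RMSD (Angstrom) over the common residues of a and b."""
    return superpose(a, b).rmsd


def _gdt_seeds(n: int) -> list[np.ndarray]:
    # Small instances seed from every subset of size >= 3, which makes
    # the search exact there; larger ones use contiguous 3/5/7 windows.
    if n <= 8:
        return [np.array(c) for size in range(3, n + 1)
                for c in itertools.combinations(range(n), size)]
    seeds = [np.arange(n)]
    for w in (3, 5, 7):
        seeds.extend(np.arange(s, s + w) for s in range(0, n - w + 1))
    return seeds


def gdt_fraction(A: np.ndarray, B: np.ndarray, threshold: float) -> float:
    """Maximal fraction of paired points superposable within ``threshold``.

    Iterative seed-extension search: superpose on a seed subset, collect
    the points within the cutoff, re-superpose on them, repeat to a fixed
    point; the best fraction over all seeds and iterations is returned.
    """
    n = len(A)
    best = 0.0
    for seed in _gdt_seeds(n):
        subset = seed
        seen: set[frozenset] = set()
        for _ in range(20):
            R, t, _ = kabsch(A[subset], B[subset])
            d = np.linalg.norm(A - (B @ R.T + t), axis=1)
            inside = d <= threshold
            best = max(best, inside.mean())
            nxt = np.flatnonzero(inside)
            key = frozenset(nxt.tolist())
            if len(nxt) < 3 or key in seen:
                break
            seen.add(key)
            subset = nxt
    return float(best)


def gdt_ts(a, b, thresholds=GDT_THRESHOLDS) -> SimilarityScore:
    """Global Distance Test Total Score between two traces, in [0, 1].

    Mean over the distance cutoffs of the maximal common-residue fraction
    superposable within each cutoff.
    """
    A, B = _common(as_trace(a), as_trace(b))
    score = float(np.mean([gdt_fraction(A, B, t) for t in thresholds]))
    return SimilarityScore(gdt_ts=score)


def radius_of_gyration(coords) -> float:
    """Root-mean-square distance of beads from their centroid (Angstrom)."""
    arr = np.asarray(coords, float)
    if arr.ndim != 2 or len(arr) < 1:
        raise UndefinedQuantityError("radius of gyration needs >= 1 bead")
    centred = arr - arr.mean(axis=0)
    return float(np.sqrt((centred ** 2).sum() / len(arr)))


def end_to_end(coords) -> float:
    """Euclidean distance between the first and last bead (Angstrom)."""
    arr = np.asarray(coords, float)
    if arr.ndim != 2 or len(arr) < 2:
        raise UndefinedQuantityError("end-to-end distance needs >= 2 beads")
    return float(np.linalg.norm(arr[-1] - arr[0]))
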