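"""Synthetic toy proteins and perturbed template sets.

The generator builds idealized C-alpha geometries (helix, beta-hairpin,
random coil) with a random but reproducible amino-acid sequence, then
emits noisy, optionally coverage-masked copies as templates.  The helix
solves its radius and rise numerically so the ideal geometry sits
exactly on the chain model's bond-length and helical pseudo-angle
targets; the hairpin is built from extended strands and relaxed into the
bond window.  Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import fsolve

from .bioio import (CaTrace, ProteinSequence, SecondaryStructure, Template,
                    write_ca_pdb)
from .chain import ChainParams, pseudo_angles, random_coil, relax_geometry
from .constants import CA_BOND_LENGTH, HELIX_PSEUDO_ANGLE_DEG

_AA = "ACDEFGHIKLMNPQRSTVWY"

FIXTURE_KINDS = ("helix", "hairpin", "random")


@dataclass
class Fixture:
    sequence: ProteinSequence
    ss: SecondaryStructure
    ideal: np.ndarray
    templates: list[Template]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write seq.fasta, ss.txt and template_*.pdb; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        seq_path = out / "seq.fasta"
        seq_path.write_text(f">{self.sequence.id}\n{self.sequence.residues}\n")
        paths["sequence"] = seq_path
        ss_path = out / "ss.txt"
        ss_path.write_text(self.ss.states + "\n")
        paths["ss"] = ss_path
        for k, template in enumerate(self.templates, start=1):
            p = out / f"template_{k}.pdb"
            write_ca_pdb(template.trace, p, sequence=self.sequence)
            paths[f"template_{k}"] = p
        return paths


def _helix_params(bond: float = CA_BOND_LENGTH,
                  angle_deg: float = HELIX_PSEUDO_ANGLE_DEG,
                  twist_deg: float = 100.0) -> tuple[float, float]:
    """Solve helix radius and rise hitting the bond/pseudo-angle targets."""
    omega = np.deg2rad(twist_deg)

    def eqs(x):
        r, h = x
        pts = np.array([[r * np.cos(k * omega), r * np.sin(k * omega), k * h]
                        for k in range(3)])
        b = np.linalg.norm(pts[1] - pts[0])
        ang = np.rad2deg(pseudo_angles(pts)[0])
        return [b - bond, ang - angle_deg]

    r, h = fsolve(eqs, x0=[2.3, 1.5], full_output=False)
    return float(r), float(h)


def helix_trace(n: int) -> np.ndarray:
    """Ideal C-alpha helix, bond 3.8 A and helical pseudo-angles."""
    r, h = _helix_params()
    omega = np.deg2rad(100.0)
    k = np.arange(n)
    return np.column_stack([r * np.cos(k * omega), r * np.sin(k * omega),
                            k * h])


def hairpin_trace(n: int) -> np.ndarray:
    """Two antiparallel extended strands joined by a short turn."""
    m = (n - 2) // 2
    coords = np.zeros((n, 3))
    step = CA_BOND_LENGTH * np.sin(np.deg2rad(60.0))
    zig = CA_BOND_LENGTH * np.cos(np.deg2rad(60.0))
    for i in range(m):
        coords[i] = (i * step, (i % 2) * zig, 0.0)
    sep = 4.8
    n_turn = n - 2 * m
    for t in range(n_turn):
        frac = (t + 1) / (n_turn + 1)
        coords[m + t] = ((m - 1) * step + 2.5 * np.sin(np.pi * frac),
                         zig / 2.0, sep * frac)
    for i in range(m):
        j = n - 1 - i
        coords[j] = (i * step, ((i + 1) % 2) * zig, sep)
    return relax_geometry(coords, params=ChainParams())


def _make_ss(kind: str, n: int) -> str:
    if kind == "helix":
        return "H" * n
    if kind == "hairpin":
        m = (n - 2) // 2
        return "E" * m + "C" * (n - 2 * m) + "E" * m
    return "C" * n


def generate_fixture(kind: str, n: int, perturbation: float, seed: int,
                     n_templates: int = 2,
                     coverage: list[tuple[int, int] | None] | None = None
                     ) -> Fixture:
    """Build a toy protein plus perturbed template copies.

    ``perturbation`` is the standard deviation (Angstrom) of isotropic
    Gaussian noise added independently to each template's coordinates.
    ``coverage`` optionally gives per-template 1-based residue windows
    (None = full coverage).
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"choose from {FIXTURE_KINDS}")
    if not 3 <= n <= 900:
        raise ValueError("fixture size must be in 3..900")
    rng = np.random.default_rng([seed, 7919])
    residues = "".join(rng.choice(list(_AA)) for _ in range(n))
    seq = ProteinSequence(residues=residues, id=f"{kind}{n}")
    ss = SecondaryStructure(_make_ss(kind, n))
    if kind == "helix":
        ideal = helix_trace(n)
    elif kind == "hairpin":
        ideal = hairpin_trace(n)
    else:
        ideal = random_coil(n, seed=seed)
    templates = []
    for t in range(n_templates):
        coords = ideal + rng.normal(scale=perturbation, size=ideal.shape)
        window = coverage[t] if coverage is not None else None
        resids = np.arange(1, n + 1)
        if window is not None:
            lo, hi = window
            mask = (resids >= lo) & (resids <= hi)
            coords, resids = coords[mask], resids[mask]
        templates.append(
            Template(trace=CaTrace(coords=coords, resids=resids),
                     source=f"{kind}_template_{t + 1}")
        )
    return Fixture(sequence=seq, ss=ss, ideal=ideal, templates=templates)
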