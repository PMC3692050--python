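"""Input/output for sequences, secondary structure and C-alpha PDB files.

The toolkit exchanges four external formats: FASTA or plain-text amino-acid
sequences, a per-residue H/E/C secondary-structure string, PDB files
carrying at least one CA atom per residue (templates), and multi-MODEL
C-alpha PDB files (trajectories and selected models).  Template residue
numbers must refer to positions in the query sequence, i.e. templates are
expected to be pre-aligned to the query.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser

from .constants import DENOVO_LENGTH_RECOMMENDATION, MAX_SEQUENCE_LENGTH

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
SS_STATES = set("HEC")

_THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


class SequenceError(ValueError):
    """Raised for malformed or over-long query sequences."""


class SecondaryStructureError(ValueError):
    """Raised for secondary-structure strings that do not fit the query."""


class TemplateError(ValueError):
    """Raised for template PDB files that cannot be mapped to the query."""


class PDBWriteError(ValueError):
    """Raised when a structure cannot be serialized to PDB."""


@dataclass(frozen=True)
class ProteinSequence:
    """Query amino-acid sequence (one-letter codes, 1..900 residues)."""

    residues: str
    id: str = "query"

    def __post_init__(self) -> None:
        bad = set(self.residues) - AMINO_ACIDS
        if not self.residues or bad:
            raise SequenceError(
                f"invalid sequence: illegal residue codes {sorted(bad)!r}"
                if bad else "invalid sequence: empty"
            )
        if len(self.residues) > MAX_SEQUENCE_LENGTH:
            raise SequenceError(
                f"sequence length {len(self.residues)} exceeds the "
                f"{MAX_SEQUENCE_LENGTH} AA maximum"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SecondaryStructure:
    """Per-residue states over {H, E, C}; same length as the query."""

    states: str

    def __post_init__(self) -> None:
        bad = set(self.states) - SS_STATES
        if bad:
            raise SecondaryStructureError(
                f"illegal secondary-structure symbols {sorted(bad)!r}; "
                "expected H, E or C"
            )

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class CaTrace:
    """Ordered C-alpha coordinates with 1-based residue indices.

    ``resids`` are strictly increasing positions in the query sequence;
    a trace may cover only part of the query (templates) or all of it
    (conformations written to disk).
    """

    coords: np.ndarray
    resids: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        resids = np.asarray(self.resids, dtype=int)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "resids", resids)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if resids.shape != (coords.shape[0],):
            raise ValueError("coords and resids must have equal length")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if len(resids) and (resids[0] < 1 or np.any(np.diff(resids) <= 0)):
            raise ValueError("resids must be 1-based and strictly increasing")

    def __len__(self) -> int:
        return len(self.resids)

    @property
    def coverage(self) -> set[int]:
        return set(int(r) for r in self.resids)


@dataclass(frozen=True)
class Template:
    """A partial C-alpha trace aligned to query numbering."""

    trace: CaTrace
    source: str = "<template>"


@dataclass
class ValidationReport:
    """Accumulated errors and warnings for one run's inputs."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def parse_sequence(text: str) -> ProteinSequence:
    """Parse a FASTA or plain-text amino-acid sequence.

    A leading ``>`` header supplies the id; otherwise the id defaults to
    ``"query"``.  Whitespace is stripped and residues are upper-cased.
    """
    if not text or not text.strip():
        raise SequenceError("invalid sequence: empty input")
    stripped = text.lstrip()
    if stripped.startswith(">"):
        record = SeqIO.read(io.StringIO(stripped), "fasta")
        seq_id = record.id or "query"
        residues = str(record.seq)
    else:
        seq_id = "query"
        residues = "".join(text.split())
    return ProteinSequence(residues=residues.upper(), id=seq_id)


def parse_secondary_structure(
    text: str | None, seq: ProteinSequence
) -> SecondaryStructure:
    """Parse an H/E/C string for ``seq``; absent input defaults to all-coil.

    The all-coil default reflects the advice that over-predicting regular
    structure harms models more than under-predicting it; a warning is
    emitted so the default is visible.
    """
    if text is None or not text.strip():
        warnings.warn(
            "no secondary structure provided; defaulting to all-coil (C)",
            stacklevel=2,
        )
        return SecondaryStructure("C" * len(seq))
    states = "".join(text.split()).upper()
    ss = SecondaryStructure(states)
    if len(ss) != len(seq):
        raise SecondaryStructureError(
            f"secondary structure length {len(ss)} does not match "
            f"sequence length {len(seq)}"
        )
    return ss


def read_template_pdb(path: str | Path, seq: ProteinSequence) -> Template:
    """Read one template (first model of a PDB file) as a C-alpha trace.

    Only CA atoms are used; backbone and side-chain atoms are ignored.
    Residue numbers index the query sequence, so any residue numbered
    outside ``1..len(seq)`` is a numbering mismatch.  Insertion codes are
    rejected; for disordered atoms the first altloc is kept.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:  # pragma: no cover - empty file
        raise TemplateError(f"{path}: no models in PDB file") from None

    entries: dict[int, np.ndarray] = {}
    for residue in model.get_residues():
        hetflag, resid, icode = residue.id
        if "CA" not in residue:
            continue
        if icode.strip():
            raise TemplateError(
                f"{path}: residue {resid}{icode} carries an insertion code; "
                "templates must map cleanly onto query numbering"
            )
        if resid < 1 or resid > len(seq):
            raise TemplateError(
                f"{path}: residue number {resid} outside query range "
                f"1..{len(seq)}; residue numbering must correspond to the "
                "query sequence order"
            )
        atom = residue["CA"]
        if atom.is_disordered():
            atom = atom.disordered_get_list()[0]
        entries.setdefault(int(resid), np.asarray(atom.coord, dtype=float))

    if not entries:
        raise TemplateError(f"{path}: no CA atoms found")
    resids = np.array(sorted(entries), dtype=int)
    coords = np.array([entries[r] for r in resids], dtype=float)
    return Template(trace=CaTrace(coords=coords, resids=resids), source=path.name)


def _atom_line(serial: int, resname: str, resid: int, xyz: np.ndarray) -> str:
    return (
        f"ATOM  {serial:>5}  CA  {resname:<3} A{resid:>4}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
    )


def write_ca_pdb(
    snapshots,
    path: str | Path,
    resids: np.ndarray | None = None,
    sequence: ProteinSequence | None = None,
) -> None:
    """Write one or more C-alpha snapshots as a (multi-MODEL) PDB file.

    ``snapshots`` may be a single (n, 3) array, a :class:`CaTrace`, or a
    sequence of either; more than one snapshot produces MODEL/ENDMDL
    blocks.  Residue names come from ``sequence`` when given, else ALA.
    """
    if isinstance(snapshots, CaTrace) or (
        isinstance(snapshots, np.ndarray) and snapshots.ndim == 2
    ):
        snapshots = [snapshots]
    frames = []
    for snap in snapshots:
        if isinstance(snap, CaTrace):
            frames.append((snap.coords, snap.resids))
        else:
            arr = np.asarray(snap, dtype=float)
            rid = resids if resids is not None else np.arange(1, len(arr) + 1)
            frames.append((arr, np.asarray(rid, dtype=int)))
    for coords, _ in frames:
        if not np.all(np.isfinite(coords)):
            raise PDBWriteError("refusing to write non-finite coordinates")

    def resname(resid: int) -> str:
        if sequence is not None and 1 <= resid <= len(sequence):
            return _THREE_LETTER[sequence.residues[resid - 1]]
        return "ALA"

    lines: list[str] = []
    multi = len(frames) > 1
    for imodel, (coords, rid) in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {imodel:>4}")
        for serial, (resid, xyz) in enumerate(zip(rid, coords), start=1):
            lines.append(_atom_line(serial, resname(int(resid)), int(resid), xyz))
        lines.append("ENDMDL" if multi else "TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ca_trajectory(path: str | Path, seq: ProteinSequence) -> list[CaTrace]:
    """Read every model of a multi-MODEL C-alpha PDB as a list of traces."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(Path(path).stem, str(path))
    frames = []
    for model in structure.get_models():
        entries = {}
        for residue in model.get_residues():
            if "CA" in residue:
                entries[residue.id[1]] = np.asarray(residue["CA"].coord, float)
        resids = np.array(sorted(entries), dtype=int)
        coords = np.array([entries[r] for r in resids], dtype=float)
        frames.append(CaTrace(coords=coords, resids=resids))
    if not frames:
        raise TemplateError(f"{path}: no CA models found")
    return frames


def validate_input(
    seq: ProteinSequence,
    ss: SecondaryStructure | None,
    templates: list[Template],
    mode: str,
) -> ValidationReport:
    """Cross-check a run's inputs; the report carries errors and warnings.

    Pure function of its arguments: errors block a run (consensus mode
    without templates, secondary-structure length mismatch, template
    residues outside the query); the de novo length recommendation is a
    warning only.
    """
    report = ValidationReport()
    if mode not in ("denovo", "consensus"):
        report.errors.append(f"unknown mode {mode!r}")
        return report
    if ss is not None and len(ss) != len(seq):
        report.errors.append(
            f"secondary structure length {len(ss)} != sequence length {len(seq)}"
        )
    if mode == "consensus" and not templates:
        report.errors.append("consensus mode requires at least one template")
    if mode == "denovo" and len(seq) > DENOVO_LENGTH_RECOMMENDATION:
        report.warnings.append(
            f"sequence length {len(seq)} exceeds the ~"
            f"{DENOVO_LENGTH_RECOMMENDATION}-residue recommendation for "
            "de novo modeling"
        )
    for template in templates:
        resids = template.trace.resids
        if len(resids) and resids[-1] > len(seq):
            report.errors.append(
                f"template {template.source}: residue {int(resids[-1])} "
                f"outside query range 1..{len(seq)}"
            )
    return report
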