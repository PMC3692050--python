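"""Consensus distance restraints from structural templates.

Templates aligned to the query define allowed C-alpha pair-distance
ranges.  Which ranges are used depends on how similar the templates are
to one another:

* if the minimum pairwise template GDT_TS is >= 0.3, a pair's range is
  the [min, max] of the distances observed across templates;
* if any template pair falls below 0.3, the observed-distance
  distribution is used instead: [mean - sigma, mean + sigma].

A single template is a separate regime: covered pairs are restrained to a
narrow band around the template distance and uncovered residues stay
free, so template-free fragments are modeled de novo.

During simulation a flat-bottom harmonic penalty applies whenever a
restrained distance leaves its range.  Users can edit the generated set
with a small directive language: ``A i j dmin dmax`` adds a restraint and
``D 55,58,120-160`` deletes every restraint touching the listed residues.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .bioio import Template
from .constants import GDT_REGIME_GATE
from .geometry import gdt_ts

logger = logging.getLogger(__name__)

#: Lower floor (Angstrom) for distribution-regime range bounds.
MIN_PHYSICAL_DISTANCE = 3.0


class RestraintError(ValueError):
    pass


class DirectiveError(ValueError):
    """Raised for malformed restraint-edit directives."""


@dataclass(frozen=True)
class RestraintConfig:
    """Knobs for restraint generation.

    s_min: minimum sequence separation |i - j| of restrained pairs.
    d_cap: pairs whose mean observed distance exceeds this (Angstrom)
        are skipped; very long distances carry little signal.
    tau: half-width (Angstrom) of single-template restraint bands.
    weight: penalty prefactor of generated restraints.
    sigma_convention: "population" (divide by n) or "sample" (n - 1).
    """

    s_min: int = 5
    d_cap: float = 25.0
    tau: float = 1.0
    weight: float = 1.0
    sigma_convention: str = "population"


@dataclass(frozen=True)
class ConsensusDistanceStats:
    """Observed C-alpha distance statistics for one residue pair."""

    i: int
    j: int
    d_min: float
    d_max: float
    mean: float
    sigma: float
    n_obs: int


@dataclass(frozen=True)
class DistanceRestraint:
    """Allowed distance range [dmin, dmax] for the (i, j) C-alpha pair."""

    i: int
    j: int
    dmin: float
    dmax: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise RestraintError(f"require i < j, got ({self.i}, {self.j})")
        if not (0 < self.dmin <= self.dmax):
            raise RestraintError(
                f"require 0 < dmin <= dmax, got [{self.dmin}, {self.dmax}]"
            )
        if self.weight <= 0:
            raise RestraintError("weight must be positive")


@dataclass
class RestraintSet:
    """At most one restraint per residue pair, with per-pair provenance."""

    restraints: dict[tuple[int, int], DistanceRestraint] = field(
        default_factory=dict
    )
    provenance: dict[tuple[int, int], str] = field(default_factory=dict)
    _arrays: tuple | None = field(default=None, repr=False, compare=False)

    def add(self, r: DistanceRestraint, tag: str) -> None:
        self.restraints[(r.i, r.j)] = r
        self.provenance[(r.i, r.j)] = tag
        self._arrays = None

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(sorted(self.restraints.values(), key=lambda r: (r.i, r.j)))

    def as_arrays(self):
        """(i_idx0, j_idx0, dmin, dmax, weight) arrays for vector math."""
        if self._arrays is not None:
            return self._arrays
        rs = list(self)
        if not rs:
            z = np.zeros(0)
            self._arrays = (z.astype(int), z.astype(int), z, z, z)
        else:
            self._arrays = (
                np.array([r.i - 1 for r in rs]),
                np.array([r.j - 1 for r in rs]),
                np.array([r.dmin for r in rs]),
                np.array([r.dmax for r in rs]),
                np.array([r.weight for r in rs]),
            )
        return self._arrays

    def counts_by_provenance(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for tag in self.provenance.values():
            out[tag] = out.get(tag, 0) + 1
        return out

    def to_tsv(self, path) -> None:
        lines = ["i\tj\tdmin\tdmax\tweight\tprovenance"]
        for r in self:
            tag = self.provenance[(r.i, r.j)]
            lines.append(
                f"{r.i}\t{r.j}\t{r.dmin:.4f}\t{r.dmax:.4f}\t{r.weight:.4f}\t{tag}"
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def collect_pair_stats(
    templates: list[Template],
    min_obs: int = 1,
    config: RestraintConfig = RestraintConfig(),
) -> list[ConsensusDistanceStats]:
    """Per-pair distance statistics across a template set.

    For every residue pair (i < j) covered by at least ``min_obs``
    templates, records the min, max, mean and sigma of the C-alpha
    distances over the covering templates.
    """
    if not templates:
        raise RestraintError("need at least one template")
    ddof = 0 if config.sigma_convention == "population" else 1
    observed: dict[tuple[int, int], list[float]] = {}
    for template in templates:
        trace = template.trace
        n = len(trace)
        diffs = trace.coords[:, None, :] - trace.coords[None, :, :]
        dist = np.sqrt((diffs ** 2).sum(axis=-1))
        for a in range(n):
            for b in range(a + 1, n):
                key = (int(trace.resids[a]), int(trace.resids[b]))
                observed.setdefault(key, []).append(float(dist[a, b]))
    out = []
    for (i, j), ds in sorted(observed.items()):
        if len(ds) < min_obs:
            continue
        arr = np.array(ds)
        sigma = float(arr.std(ddof=ddof)) if len(arr) > ddof else 0.0
        out.append(
            ConsensusDistanceStats(
                i=i, j=j,
                d_min=float(arr.min()), d_max=float(arr.max()),
                mean=float(arr.mean()), sigma=sigma, n_obs=len(arr),
            )
        )
    return out


def select_regime(templates: list[Template]) -> str:
    """Choose the consensus regime from pairwise template similarity.

    Returns ``"minmax"`` when the minimum pairwise GDT_TS is at or above
    the 0.3 gate, ``"distribution"`` otherwise.  A single template is a
    distinct regime and must go through
    :func:`generate_single_template_restraints`.
    """
    if len(templates) < 2:
        raise RestraintError(
            "regime selection needs >= 2 templates; use the "
            "single-template path for one template"
        )
    min_gdt = min(
        gdt_ts(templates[a].trace, templates[b].trace).gdt_ts
        for a in range(len(templates))
        for b in range(a + 1, len(templates))
    )
    return "minmax" if min_gdt >= GDT_REGIME_GATE else "distribution"


def _eligible(stats: ConsensusDistanceStats, config: RestraintConfig) -> bool:
    return stats.j - stats.i >= config.s_min and stats.mean <= config.d_cap


def generate_consensus_restraints(
    templates: list[Template], config: RestraintConfig = RestraintConfig()
) -> tuple[RestraintSet, str]:
    """Restraints from >= 2 templates; returns the set and regime used.

    minmax regime: range = [observed min, observed max]; only pairs
    covered by every template are restrained, so a partial subset never
    silently narrows a range.  distribution regime: range =
    [mean - sigma, mean + sigma] (floored at 3.0 Angstrom) over pairs
    covered by at least two templates.
    """
    regime = select_regime(templates)
    min_obs = len(templates) if regime == "minmax" else 2
    rs = RestraintSet()
    for stats in collect_pair_stats(templates, min_obs=min_obs, config=config):
        if not _eligible(stats, config):
            continue
        if regime == "minmax":
            dmin, dmax = stats.d_min, stats.d_max
        else:
            dmin = max(MIN_PHYSICAL_DISTANCE, stats.mean - stats.sigma)
            dmax = max(dmin, stats.mean + stats.sigma)
        rs.add(
            DistanceRestraint(stats.i, stats.j, dmin, dmax, config.weight),
            f"consensus-{regime}",
        )
    return rs, regime


def generate_single_template_restraints(
    template: Template, config: RestraintConfig = RestraintConfig()
) -> RestraintSet:
    """Restraints enforcing one template on its covered fragments.

    Every eligible covered pair gets the band [d - tau, d + tau] around
    the template distance; uncovered residues acquire no restraints and
    are therefore modeled de novo.
    """
    rs = RestraintSet()
    for stats in collect_pair_stats([template], min_obs=1, config=config):
        if not _eligible(stats, config):
            continue
        d = stats.mean
        dmin = max(MIN_PHYSICAL_DISTANCE, d - config.tau)
        rs.add(
            DistanceRestraint(stats.i, stats.j, dmin, d + config.tau, config.weight),
            "single-template",
        )
    return rs


@dataclass(frozen=True)
class AddDirective:
    restraint: DistanceRestraint


@dataclass(frozen=True)
class DeleteDirective:
    residues: frozenset[int]


_RANGE_RE = re.compile(r"^(\d+)\s*[-–]\s*(\d+)$")


def parse_edit_directives(text: str) -> list[AddDirective | DeleteDirective]:
    """Parse restraint-edit lines.

    ``A i j dmin dmax`` adds the restraint [dmin, dmax] between residues
    i and j (order normalized to i < j).  ``D`` followed by
    comma-separated residues and ranges (hyphen or en-dash) deletes all
    restraints touching those residues.  Blank lines and ``#`` comments
    are ignored.
    """
    directives: list[AddDirective | DeleteDirective] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        kind, _, rest = line.partition(" ")
        try:
            if kind.upper() == "A":
                parts = rest.split()
                if len(parts) != 4:
                    raise DirectiveError("expected 'A i j dmin dmax'")
                i, j = int(parts[0]), int(parts[1])
                dmin, dmax = float(parts[2]), float(parts[3])
                if dmin > dmax:
                    raise DirectiveError(f"dmin {dmin} > dmax {dmax}")
                if i == j:
                    raise DirectiveError("i and j must differ")
                if i > j:
                    i, j = j, i
                directives.append(
                    AddDirective(DistanceRestraint(i, j, dmin, dmax))
                )
            elif kind.upper() == "D":
                residues: set[int] = set()
                tokens = [t.strip() for t in rest.split(",")]
                if not rest.strip():
                    raise DirectiveError("empty delete set")
                for token in tokens:
                    m = _RANGE_RE.match(token)
                    if m:
                        lo, hi = int(m.group(1)), int(m.group(2))
                        if lo > hi:
                            raise DirectiveError(f"bad range {token!r}")
                        residues.update(range(lo, hi + 1))
                    elif token.isdigit():
                        residues.add(int(token))
                    else:
                        raise DirectiveError(f"bad residue token {token!r}")
                directives.append(DeleteDirective(frozenset(residues)))
            else:
                raise DirectiveError(f"unknown directive kind {kind!r}")
        except DirectiveError as exc:
            raise DirectiveError(f"line {lineno}: {exc}") from None
        except ValueError as exc:
            raise DirectiveError(f"line {lineno}: {exc}") from None
    return directives


def apply_edits(
    rs: RestraintSet, directives: list[AddDirective | DeleteDirective]
) -> RestraintSet:
    """Apply user edits: deletions first, then additions, in file order.

    Deleting residues with no matching restraint is a logged no-op.
    Adding on an occupied pair replaces the existing restraint; user
    additions are tagged ``user``.
    """
    out = RestraintSet(dict(rs.restraints), dict(rs.provenance))
    for d in directives:
        if isinstance(d, DeleteDirective):
            doomed = [
                key for key in out.restraints
                if key[0] in d.residues or key[1] in d.residues
            ]
            if not doomed:
                logger.info("delete directive matched no restraints: %s",
                            sorted(d.residues)[:10])
            for key in doomed:
                del out.restraints[key]
                del out.provenance[key]
    for d in directives:
        if isinstance(d, AddDirective):
            out.add(replace(d.restraint), "user")
    out._arrays = None
    return out


def restraint_distances(coords: np.ndarray, rs: RestraintSet) -> np.ndarray:
    i, j, _, _, _ = rs.as_arrays()
    coords = np.asarray(coords, float)
    if len(i) and (i.max() >= len(coords) or j.max() >= len(coords)):
        raise RestraintError("restrained residue index outside conformation")
    return np.linalg.norm(coords[j] - coords[i], axis=1)


def restraint_energy(coords: np.ndarray, rs: RestraintSet) -> float:
    """Flat-bottom harmonic penalty, summed over restraints.

    Zero while a distance sits inside its [dmin, dmax] range; outside,
    weight * (distance beyond the nearest bound)^2.
    """
    if len(rs) == 0:
        return 0.0
    i, j, dmin, dmax, w = rs.as_arrays()
    d = restraint_distances(coords, rs)
    below = np.maximum(dmin - d, 0.0)
    above = np.maximum(d - dmax, 0.0)
    return float((w * (below ** 2 + above ** 2)).sum())


def satisfaction_fraction(coords: np.ndarray, rs: RestraintSet) -> float:
    """Fraction of restraints whose distance lies inside its range."""
    if len(rs) == 0:
        warnings.warn("satisfaction of an empty restraint set is vacuous (1.0)",
                      stacklevel=2)
        return 1.0
    _, _, dmin, dmax, _ = rs.as_arrays()
    d = restraint_distances(coords, rs)
    return float(((d >= dmin) & (d <= dmax)).mean())
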