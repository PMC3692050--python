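"""End-to-end orchestration: inputs -> restraints -> REMC -> models.

Two modes mirror the documented protocol: ``denovo`` starts from a
random coil with no template restraints (default ladder 3.5-1.0), and
``consensus`` builds restraints and the starting structure from
templates (default ladder 2.0-1.0).  With two or more templates the
restraint regime is chosen by the pairwise GDT_TS gate; a single
template takes the dedicated single-template path and never computes the
gate.  Runs are deterministic per seed: identical config and seed give
byte-identical TSV/JSON outputs and coordinate-identical PDBs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import bioio, modelsel, remc, restraints as rst
from .bioio import ProteinSequence, SecondaryStructure, Template
from .chain import (ChainParams, MoveParams, build_start_from_templates,
                    internal_energy, random_coil)
from .constants import (CONSENSUS_TEMP_RANGE, DENOVO_TEMP_RANGE,
                        N_REPLICAS_DEFAULT)

logger = logging.getLogger(__name__)

STAGES = ("validate", "restraints", "start", "simulate", "cluster",
          "select", "write")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    mode: str = "denovo"
    seed: int = 1
    t_max: float | None = None
    t_min: float | None = None
    n_replicas: int = N_REPLICAS_DEFAULT
    n_cycles: int = 2000
    record_every: int = 20
    k_clusters: int = 10
    n_models: int = 5
    restraints: rst.RestraintConfig = field(default_factory=rst.RestraintConfig)
    chain: ChainParams = field(default_factory=ChainParams)
    moves: MoveParams = field(default_factory=MoveParams)

    def temperature_range(self) -> tuple[float, float]:
        default = (DENOVO_TEMP_RANGE if self.mode == "denovo"
                   else CONSENSUS_TEMP_RANGE)
        return (self.t_max if self.t_max is not None else default[0],
                self.t_min if self.t_min is not None else default[1])


@dataclass
class RunReport:
    mode: str
    regime: str
    validation_warnings: list[str]
    restraint_counts: dict[str, int]
    n_snapshots: int
    model_table: list[dict]
    seed: int
    progress: list[dict] = field(default_factory=list)


class ProgressLogger:
    """Structured stage/fraction progress records (timestamps to log only)."""

    def __init__(self) -> None:
        self.records: list[dict] = []

    def __call__(self, stage: str, fraction: float) -> dict:
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        record = {"stage": stage, "fraction": float(fraction)}
        logger.info("progress %s %.2f (t=%.3f)", stage, fraction, time.time())
        self.records.append(record)
        return record


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def _write_outputs(out_dir: Path, seq, traj, rs, model_set, cluster_rank,
                   report: RunReport) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bioio.write_ca_pdb(traj.snapshots, out_dir / "trajectory.pdb",
                       sequence=seq)
    lines = ["snapshot\tenergy\trg\tend_to_end"]
    for k in range(len(traj)):
        lines.append(f"{k}\t{_fmt(traj.energies[k])}\t{_fmt(traj.rg[k])}"
                     f"\t{_fmt(traj.end_to_end[k])}")
    (out_dir / "analysis.tsv").write_text("\n".join(lines) + "\n")
    lines = ["slot_a\tslot_b\taccepted"]
    for a, b, acc in traj.swap_log:
        lines.append(f"{a}\t{b}\t{int(acc)}")
    (out_dir / "swaps.tsv").write_text("\n".join(lines) + "\n")
    rs.to_tsv(out_dir / "restraints.tsv")
    models_dir = out_dir / "models"
    models_dir.mkdir(exist_ok=True)
    for rank, model in enumerate(model_set.models, start=1):
        bioio.write_ca_pdb(model.coords, models_dir / f"model_{rank}.pdb",
                           sequence=seq)
    clusters = [
        {"rank": rank, "label": c.label, "size": len(c.members),
         "avg_rmsd": round(c.avg_rmsd, 6), "density": round(c.density, 6)}
        for rank, c in enumerate(cluster_rank, start=1)
    ]
    (out_dir / "clusters.json").write_text(
        json.dumps(clusters, indent=1, sort_keys=True) + "\n")
    k = len(model_set.models)
    lines = ["# pairwise RMSD (A) over ranked models"]
    header = "\t".join(f"model_{m + 1}" for m in range(k))
    lines.append("\t" + header)
    for a in range(k):
        row = "\t".join(_fmt(model_set.rmsd_matrix[a, b]) for b in range(k))
        lines.append(f"model_{a + 1}\t{row}")
    lines.append("# pairwise GDT_TS over ranked models")
    lines.append("\t" + header)
    for a in range(k):
        row = "\t".join(_fmt(model_set.gdt_matrix[a, b]) for b in range(k))
        lines.append(f"model_{a + 1}\t{row}")
    (out_dir / "matrices.tsv").write_text("\n".join(lines) + "\n")
    (out_dir / "report.json").write_text(
        json.dumps(dataclasses.asdict(report), indent=1, sort_keys=True)
        + "\n")


def run_pipeline(config: RunConfig,
                 seq: ProteinSequence,
                 ss: SecondaryStructure | None = None,
                 templates: list[Template] | None = None,
                 edit_text: str | None = None,
                 out_dir: str | Path = "fold_out") -> RunReport:
    """Run the full modeling pipeline and write its output files.

    Outputs under ``out_dir``: trajectory.pdb (multi-MODEL C-alpha),
    analysis.tsv (energy/Rg/end-to-end per lowest-energy-replica
    snapshot), swaps.tsv, restraints.tsv, models/model_*.pdb in density
    rank order, clusters.json, matrices.tsv (cross-analysis) and
    report.json.  A stage failure writes a FAILED marker naming the
    stage and re-raises.
    """
    out_dir = Path(out_dir)
    templates = list(templates or [])
    progress = ProgressLogger()
    stage = "validate"
    try:
        progress(stage, 0.0)
        ss_defaulted = ss is None
        if ss_defaulted:
            ss = SecondaryStructure("C" * len(seq))
        report_v = bioio.validate_input(seq, ss, templates, config.mode)
        if ss_defaulted:
            report_v.warnings.append(
                "no secondary structure provided; defaulting to all-coil")
        if not report_v.ok:
            raise PipelineError(stage, "; ".join(report_v.errors))
        progress(stage, 1.0)

        stage = "restraints"
        progress(stage, 0.0)
        if config.mode == "denovo":
            rs, regime = rst.RestraintSet(), "none"
        elif len(templates) == 1:
            rs = rst.generate_single_template_restraints(
                templates[0], config.restraints)
            regime = "single-template"
        else:
            rs, regime = rst.generate_consensus_restraints(
                templates, config.restraints)
        if edit_text:
            rs = rst.apply_edits(rs, rst.parse_edit_directives(edit_text))
        progress(stage, 1.0)

        stage = "start"
        progress(stage, 0.0)
        if config.mode == "denovo":
            start = random_coil(len(seq), config.seed, config.chain)
        else:
            start = build_start_from_templates(templates, len(seq),
                                               config.seed, config.chain)
        progress(stage, 1.0)

        stage = "simulate"
        progress(stage, 0.0)
        t_max, t_min = config.temperature_range()
        ladder = remc.make_ladder(t_max, t_min, config.n_replicas)

        def energy_fn(coords: np.ndarray) -> float:
            e = internal_energy(coords, ss, config.chain,
                                restraint=rst.restraint_energy(coords, rs))
            return e.total

        traj = remc.run_simulation(start, ladder, energy_fn,
                                   n_cycles=config.n_cycles,
                                   record_every=config.record_every,
                                   seed=config.seed,
                                   move_params=config.moves)
        progress(stage, 1.0)

        stage = "cluster"
        progress(stage, 0.0)
        k = min(config.k_clusters, len(traj))
        features = modelsel.featurize(traj.snapshots)
        cs = modelsel.kmeans_cluster(features, k, config.seed)
        progress(stage, 1.0)

        stage = "select"
        progress(stage, 0.0)
        ranked = modelsel.rank_clusters(cs, traj.snapshots, traj.energies)
        model_set = modelsel.select_models(
            cs, traj.snapshots, traj.energies,
            n_models=min(config.n_models, len(ranked)),
            chain_params=config.chain)
        progress(stage, 1.0)

        stage = "write"
        progress(stage, 0.0)
        report = RunReport(
            mode=config.mode,
            regime=regime,
            validation_warnings=list(report_v.warnings),
            restraint_counts=rs.counts_by_provenance(),
            n_snapshots=len(traj),
            model_table=[
                {"rank": rank, "cluster": m.cluster_label,
                 "size": m.cluster_size, "avg_rmsd": round(m.avg_rmsd, 6),
                 "mode": m.mode}
                for rank, m in enumerate(model_set.models, start=1)
            ],
            seed=config.seed,
            progress=progress.records,
        )
        _write_outputs(out_dir, seq, traj, rs, model_set, ranked, report)
        progress(stage, 1.0)
        return report
    except PipelineError:
        _flush_failed(out_dir, stage)
        raise
    except Exception as exc:
        _flush_failed(out_dir, stage)
        raise PipelineError(stage, str(exc)) from exc


def _flush_failed(out_dir: Path, stage: str) -> None:
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "FAILED").write_text(f"stage: {stage}\n")
    except OSError:  # pragma: no cover
        logger.exception("could not write FAILED marker")
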