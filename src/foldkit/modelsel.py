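"""Trajectory clustering and representative-model selection.

Snapshots are clustered with K-means on a rotation/translation-invariant
feature (inter-residue distances at sequence separation >= 3).  Each
cluster yields one representative: the medoid when the cluster is
diffuse (average pairwise RMSD above 2.15 Angstrom), otherwise the
coordinate average of the members superposed onto the medoid — averaging
tight clusters gives more accurate models, but averaging diverse ones
produces unphysical traces, hence the switch.  Averaged traces are
repaired back into the bond window by local geometry relaxation.
Clusters are ranked by density (members per unit of spread); ranked
representatives get a pairwise RMSD / GDT_TS cross-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .chain import ChainParams, relax_geometry
from .constants import REPRESENTATIVE_RMSD_SWITCH
from .geometry import gdt_ts, kabsch, rmsd


class ClusterError(ValueError):
    pass


@dataclass
class ClusterInfo:
    label: int
    members: list[int]
    avg_rmsd: float = 0.0
    density: float = 0.0
    mean_energy: float = 0.0


@dataclass
class ClusterSet:
    assignments: np.ndarray
    k: int
    clusters: list[ClusterInfo] = field(default_factory=list)


@dataclass
class Model:
    coords: np.ndarray
    cluster_label: int
    cluster_size: int
    avg_rmsd: float
    mode: str  # "average" | "medoid"


@dataclass
class ModelSet:
    models: list[Model]
    rmsd_matrix: np.ndarray
    gdt_matrix: np.ndarray


def featurize(snapshots: list[np.ndarray], min_separation: int = 3) -> np.ndarray:
    """Per-snapshot vectors of inter-residue distances (|i - j| >= 3)."""
    if not snapshots:
        raise ClusterError("need at least one snapshot")
    n = len(snapshots[0])
    iu, ju = np.triu_indices(n, k=min_separation)
    rows = [
        np.linalg.norm(np.asarray(s)[ju] - np.asarray(s)[iu], axis=1)
        for s in snapshots
    ]
    return np.asarray(rows)


def kmeans_cluster(features: np.ndarray, k: int, seed: int) -> ClusterSet:
    """K-means partition of snapshot features (k-means++ init, fixed seed)."""
    features = np.asarray(features, float)
    if k < 1:
        raise ClusterError("k must be >= 1")
    if k > len(features):
        raise ClusterError(f"k={k} exceeds snapshot count {len(features)}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                random_state=int(seed) % (2 ** 31))
    labels = km.fit_predict(features)
    cs = ClusterSet(assignments=labels, k=k)
    for label in range(k):
        members = np.flatnonzero(labels == label).tolist()
        if members:
            cs.clusters.append(ClusterInfo(label=label, members=members))
    return cs


def _pair_indices(m: int, max_pairs: int, seed: int) -> list[tuple[int, int]]:
    pairs = [(a, b) for a in range(m) for b in range(a + 1, m)]
    if len(pairs) <= max_pairs:
        return pairs
    rng = np.random.default_rng([seed, m])
    chosen = rng.choice(len(pairs), size=max_pairs, replace=False)
    return [pairs[c] for c in sorted(chosen)]


def cluster_rmsd_stats(members: list[int], snapshots: list[np.ndarray],
                       max_members_exact: int = 200, seed: int = 0) -> float:
    """Average pairwise superposed RMSD among a cluster's members.

    Exact over all pairs up to ``max_members_exact`` members; beyond
    that, a fixed-seed uniform subsample of pairs.
    """
    m = len(members)
    if m < 2:
        return 0.0
    cap = (max_members_exact * (max_members_exact - 1)) // 2
    pairs = _pair_indices(m, cap, seed)
    vals = [rmsd(snapshots[members[a]], snapshots[members[b]])
            for a, b in pairs]
    return float(np.mean(vals))


def _medoid_index(members: list[int], snapshots: list[np.ndarray]) -> int:
    # member whose summed RMSD to all other members is minimal
    m = len(members)
    if m == 1:
        return 0
    dm = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            d = rmsd(snapshots[members[a]], snapshots[members[b]])
            dm[a, b] = dm[b, a] = d
    return int(dm.sum(axis=1).argmin())


def select_representative(members: list[int], snapshots: list[np.ndarray],
                          threshold: float = REPRESENTATIVE_RMSD_SWITCH,
                          chain_params: ChainParams = ChainParams(),
                          avg_rmsd: float | None = None,
                          repair: bool = True) -> tuple[np.ndarray, str]:
    """Cluster representative: average structure or medoid.

    If the average intra-cluster RMSD exceeds ``threshold`` the medoid is
    returned; otherwise members are superposed onto the medoid and
    averaged, and the averaged trace is relaxed back to physical bond
    lengths.  Singletons return their only member (mode "medoid").
    """
    if not members:
        raise ClusterError("empty cluster")
    if avg_rmsd is None:
        avg_rmsd = cluster_rmsd_stats(members, snapshots)
    mi = _medoid_index(members, snapshots)
    medoid = np.asarray(snapshots[members[mi]], float)
    if len(members) == 1 or avg_rmsd > threshold:
        return medoid.copy(), "medoid"
    acc = np.zeros_like(medoid)
    for idx in members:
        s = np.asarray(snapshots[idx], float)
        R, t, _ = kabsch(medoid, s)
        acc += s @ R.T + t
    avg = acc / len(members)
    if repair:
        avg = relax_geometry(avg, params=chain_params)
    return avg, "average"


def rank_clusters(cs: ClusterSet, snapshots: list[np.ndarray],
                  energies: list[float] | None = None) -> list[ClusterInfo]:
    """Annotate clusters and sort by density, densest first.

    Density = member count / (1 + average intra-cluster RMSD); ties break
    by larger size, then lower mean energy, then label.
    """
    if not cs.clusters:
        raise ClusterError("no clusters to rank")
    for c in cs.clusters:
        c.avg_rmsd = cluster_rmsd_stats(c.members, snapshots)
        c.density = len(c.members) / (1.0 + c.avg_rmsd)
        if energies is not None:
            c.mean_energy = float(np.mean([energies[m] for m in c.members]))
    return sorted(
        cs.clusters,
        key=lambda c: (-c.density, -len(c.members), c.mean_energy, c.label),
    )


def cross_analysis(models: list[Model]) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise RMSD and GDT_TS matrices over ranked representatives."""
    if not models:
        raise ClusterError("need at least one model")
    k = len(models)
    rm = np.zeros((k, k))
    gm = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            rm[a, b] = rm[b, a] = rmsd(models[a].coords, models[b].coords)
            gm[a, b] = gm[b, a] = gdt_ts(models[a].coords,
                                         models[b].coords).gdt_ts
    return rm, gm


def select_models(cs: ClusterSet, snapshots: list[np.ndarray],
                  energies: list[float] | None = None,
                  n_models: int = 5,
                  threshold: float = REPRESENTATIVE_RMSD_SWITCH,
                  chain_params: ChainParams = ChainParams()) -> ModelSet:
    """Rank clusters, take representatives of the top ``n_models``."""
    ranked = rank_clusters(cs, snapshots, energies)
    models = []
    for c in ranked[:n_models]:
        coords, mode = select_representative(
            c.members, snapshots, threshold=threshold,
            chain_params=chain_params, avg_rmsd=c.avg_rmsd)
        models.append(Model(coords=coords, cluster_label=c.label,
                            cluster_size=len(c.members),
                            avg_rmsd=c.avg_rmsd, mode=mode))
    rm, gm = cross_analysis(models)
    return ModelSet(models=models, rmsd_matrix=rm, gdt_matrix=gm)
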