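"""Conformational analysis: pairwise-RMSD matrices, clustering, RMSF.

Two clusterers are provided.  Agglomerative (hierarchical) clustering of
a pairwise RMSD matrix serves model/experimental structure sets, where
the user picks the number of groups from the heatmap.  GROMOS-style
neighbor-count clustering serves MD trajectories: the frame with the
most neighbors within an RMSD cutoff seeds a cluster, the cluster is
removed, and the scheme repeats until no frames remain; the seeding
"middle" frame is the cluster representative and becomes a docking
receptor candidate.

Both clusterers report the same tightness statistic: the minimum over
members of the mean RMSD from that member to the rest of the cluster
(0 for singletons).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .geometry import ResidueSelection, kabsch_superpose, pairwise_superposed_rmsd
from .structio import Structure, Trajectory

logger = logging.getLogger(__name__)


@dataclass
class RmsdMatrix:
    """Symmetric matrix of pairwise minimum RMSDs (Å) with item labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("RMSD matrix is not symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("RMSD matrix diagonal must be exactly zero")
        if np.any(self.values < 0):
            raise ValueError("RMSD values must be nonnegative")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "RmsdMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(labels=[str(c) for c in df.columns], values=df.to_numpy(float))


@dataclass(frozen=True)
class Cluster:
    members: tuple
    representative: object
    size: int
    tightness_rmsd: float


@dataclass
class ClusterResult:
    """A partition of items into clusters, in emission order."""

    clusters: list[Cluster]
    method: str
    params: dict

    def sizes(self) -> list[int]:
        return [c.size for c in self.clusters]

    def assignments(self) -> dict:
        """item -> cluster index (0-based, emission order)."""
        return {m: i for i, c in enumerate(self.clusters) for m in c.members}

    def partition(self) -> set[frozenset]:
        return {frozenset(c.members) for c in self.clusters}

    def to_json(self, path=None) -> str:
        payload = {
            "method": self.method,
            "params": self.params,
            "clusters": [
                {
                    "members": list(c.members),
                    "representative": c.representative,
                    "size": c.size,
                    "tightness_rmsd": c.tightness_rmsd,
                }
                for c in self.clusters
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_tsv(self, path=None, header_comment: str | None = None) -> str:
        """Cluster table: cluster number, size, representative, tightness."""
        lines = []
        if header_comment:
            lines.append(f"# {header_comment}")
        lines.append("cluster\tsize\trepresentative\ttightness_rmsd")
        for i, c in enumerate(self.clusters, start=1):
            lines.append(f"{i}\t{c.size}\t{c.representative}\t{c.tightness_rmsd:.3f}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class CompositionSummary:
    """Per-cluster variant composition (size, tightness, %WT, %mutant)."""

    rows: list[dict]

    def to_tsv(self, path=None) -> str:
        lines = ["cluster\tsize\ttightness_rmsd\tpct_wt\tpct_mutant"]
        for i, row in enumerate(self.rows, start=1):
            lines.append(
                f"{i}\t{row['size']}\t{row['tightness_rmsd']:.3f}"
                f"\t{row['pct_wt']:.1f}\t{row['pct_mutant']:.1f}"
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class RmsfProfile:
    """Per-residue Cα root-mean-square fluctuation over a trajectory."""

    resnums: list[int]
    rmsf: np.ndarray
    annotations: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if self.rmsf.shape != (len(self.resnums),):
            raise ValueError("rmsf length must equal residue count")
        if np.any(self.rmsf < 0):
            raise ValueError("rmsf values must be nonnegative")

    def annotate(self, sites: Mapping[int, str]) -> None:
        unknown = set(sites) - set(self.resnums)
        if unknown:
            logger.warning("annotations for absent residues ignored: %s", sorted(unknown))
        self.annotations.update({k: v for k, v in sites.items() if k in set(self.resnums)})

    def to_tsv(self, path=None) -> str:
        lines = ["resnum\trmsf\tannotation"]
        for n, v in zip(self.resnums, self.rmsf):
            lines.append(f"{n}\t{v:.4f}\t{self.annotations.get(n, '')}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# Pairwise RMSD matrices


def _common_selection_indices(
    items: Sequence[Structure], selection: ResidueSelection | None
) -> list[np.ndarray]:
    common = set(items[0].resnums)
    for s in items[1:]:
        common &= set(s.resnums)
    if selection is not None:
        common &= set(selection.resnums)
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} residues shared by all structures"
            f"{' within the selection' if selection else ''}; need >= 3"
        )
    ordered = sorted(common)
    return [np.array([s.index_of(n) for n in ordered]) for s in items]


def pairwise_rmsd(
    items: Sequence[Structure], selection: ResidueSelection | None = None
) -> RmsdMatrix:
    """Pairwise superposed Cα RMSD over the residues shared by all items.

    Each pair is superposed on the (shared) selection residues, so a
    rigid motion of any input leaves the matrix unchanged.
    """
    if len(items) < 2:
        raise ValueError("need at least 2 structures")
    idx = _common_selection_indices(items, selection)
    coords = np.stack([s.coords[i] for s, i in zip(items, idx)])
    values = pairwise_superposed_rmsd(coords)
    return RmsdMatrix(labels=[s.id for s in items], values=values)


def _tightness(values: np.ndarray, member_idx: Sequence[int]) -> tuple[float, int]:
    """Min over members of mean RMSD to the rest; returns (value, argmin member)."""
    member_idx = list(member_idx)
    if len(member_idx) == 1:
        return 0.0, member_idx[0]
    sub = values[np.ix_(member_idx, member_idx)]
    means = sub.sum(axis=1) / (len(member_idx) - 1)
    k = int(np.argmin(means))
    return float(means[k]), member_idx[k]


# ---------------------------------------------------------------------------
# Hierarchical clustering (model/experimental structure sets)


def hierarchical_cluster(
    m: RmsdMatrix, k: int, linkage: str = "complete"
) -> ClusterResult:
    """Agglomerative clustering of an RMSD matrix, tree cut at ``k`` groups.

    The representative of each cluster is the member with the lowest
    mean RMSD to the rest (its tightness statistic).  Clusters are
    ordered by dendrogram leaf order, matching left-to-right reading of
    a clustered heatmap.
    """
    n = len(m.labels)
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if linkage not in ("complete", "average", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")

    z = scipy_linkage(squareform(m.values, checks=False), method=linkage)
    flat = fcluster(z, t=k, criterion="maxclust")
    leaf_order = leaves_list(z)

    seen: list[int] = []
    for leaf in leaf_order:
        cid = flat[leaf]
        if cid not in seen:
            seen.append(cid)

    clusters = []
    for cid in seen:
        member_idx = [i for i in range(n) if flat[i] == cid]
        tight, rep = _tightness(m.values, member_idx)
        clusters.append(
            Cluster(
                members=tuple(m.labels[i] for i in member_idx),
                representative=m.labels[rep],
                size=len(member_idx),
                tightness_rmsd=tight,
            )
        )
    return ClusterResult(clusters=clusters, method="hierarchical",
                         params={"k": k, "linkage": linkage})


def composition(
    c: ClusterResult, labels: Mapping[object, str]
) -> CompositionSummary:
    """Variant composition of each cluster (percent WT vs mutant).

    ``labels`` maps every member to ``"WT"`` or ``"mutant"``; an
    unlabeled member raises.  Raw fractions are retained next to the
    percentages.
    """
    rows = []
    for cl in c.clusters:
        missing = [m for m in cl.members if m not in labels]
        if missing:
            raise ValueError(f"unlabeled cluster members: {missing}")
        bad = {labels[m] for m in cl.members} - {"WT", "mutant"}
        if bad:
            raise ValueError(f"labels must be 'WT' or 'mutant', got {sorted(bad)}")
        n_wt = sum(1 for m in cl.members if labels[m] == "WT")
        frac_wt = n_wt / cl.size
        rows.append(
            {
                "size": cl.size,
                "tightness_rmsd": cl.tightness_rmsd,
                "frac_wt": frac_wt,
                "frac_mutant": 1.0 - frac_wt,
                "pct_wt": 100.0 * frac_wt,
                "pct_mutant": 100.0 * (1.0 - frac_wt),
            }
        )
    return CompositionSummary(rows=rows)


# ---------------------------------------------------------------------------
# GROMOS trajectory clustering


def gromos_cluster(
    t: Trajectory,
    cutoff: float,
    selection: ResidueSelection | None = None,
) -> ClusterResult:
    """GROMOS neighbor-count clustering of trajectory frames.

    All pairwise frame RMSDs are computed after per-pair superposition
    over the selection (default: whole topology).  Repeatedly, the frame
    with the most neighbors within ``cutoff`` (ties: lowest frame index)
    becomes a cluster center; the center plus its neighbors form a
    cluster and are removed; neighbor counts are recomputed on the
    remainder.  Clusters are emitted in discovery order and their
    members are integer frame indices; the representative is the center.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if t.n_frames < 1:
        raise ValueError("trajectory has no frames")

    if selection is None:
        idx = np.arange(len(t.topology))
    else:
        idx = np.array([t.topology.index_of(n) for n in sorted(selection.resnums)])
        if idx.size < 3:
            raise ValueError("selection must cover at least 3 residues")
    coords = t.frames[:, idx, :]
    values = pairwise_superposed_rmsd(coords)
    return gromos_cluster_from_matrix(values, cutoff)


def gromos_cluster_from_matrix(values: np.ndarray, cutoff: float) -> ClusterResult:
    """GROMOS clustering on a precomputed RMSD matrix (frame indices as items)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    within = values <= cutoff
    np.fill_diagonal(within, False)

    remaining = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while remaining.any():
        counts = np.where(remaining, (within & remaining[None, :]).sum(axis=1), -1)
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = [center] + [
            j for j in np.nonzero(within[center] & remaining)[0] if j != center
        ]
        members.sort()
        tight, _ = _tightness(values, members)
        clusters.append(
            Cluster(
                members=tuple(int(j) for j in members),
                representative=center,
                size=len(members),
                tightness_rmsd=tight,
            )
        )
        remaining[members] = False
    return ClusterResult(clusters=clusters, method="gromos", params={"cutoff": cutoff})


# ---------------------------------------------------------------------------
# RMSF


def rmsf(t: Trajectory, superpose_to: str = "mean") -> RmsfProfile:
    """Per-residue Cα RMSF about the mean position over superposed frames.

    Each frame is rigid-body fitted (whole-topology Cα) to the reference
    — frame 0, or the iterated mean structure (default).  RMSF_i is the
    root-mean-square deviation of residue i's Cα from its mean position
    across the aligned frames.  A single-frame trajectory is rejected:
    a fluctuation over one frame is undefined, and returning zeros would
    silently masquerade as rigidity.
    """
    if superpose_to not in ("mean", "frame0"):
        raise ValueError("superpose_to must be 'mean' or 'frame0'")
    if t.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")

    def _align_all(ref: np.ndarray) -> np.ndarray:
        return np.stack(
            [kabsch_superpose(f, ref).apply(f) for f in t.frames]
        )

    aligned = _align_all(t.frames[0])
    if superpose_to == "mean":
        # one fixed-point refinement of the mean reference is ample here
        for _ in range(2):
            aligned = _align_all(aligned.mean(axis=0))
    mean = aligned.mean(axis=0)
    dev = aligned - mean[None]
    vals = np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0))
    return RmsfProfile(resnums=t.topology.resnums, rmsf=vals)
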