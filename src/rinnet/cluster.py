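"""RMSD-based conformational clustering of a structural ensemble.

Pipeline: all-versus-all RMSD matrix (each pair of states independently
superposed with the Kabsch algorithm over shared backbone anchors, CA for
amino acids and C1' for nucleotides by default) -> agglomerative hierarchical
clustering -> dendrogram cut at a height cutoff in Å -> flat cluster
assignment in time order -> medoid representative per cluster.

Pairwise-optimal superposition is the default because it is reference-free;
``mode="reference"`` instead superposes every state onto one reference and
measures deviations between the aligned coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import squareform

from .geometry import kabsch
from .structures import Ensemble, ResidueKey, SelectionError, coordinate_matrix

DEFAULT_SELECTION = frozenset({"CA", "C1'"})


@dataclass
class RMSDMatrix:
    """Symmetric, zero-diagonal matrix of pairwise RMSD values (Å)."""

    matrix: np.ndarray
    selection: frozenset[str] = DEFAULT_SELECTION

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    def validate(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("RMSD matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-8):
            raise ValueError("RMSD matrix must have zero diagonal")
        if (m < -1e-12).any():
            raise ValueError("RMSD matrix must be non-negative")

    def write_tsv(self, path: str | Path) -> None:
        labels = [f"state_{i}" for i in range(self.n_states)]
        pd.DataFrame(self.matrix, index=labels, columns=labels).to_csv(
            path, sep="\t")


@dataclass
class Dendrogram:
    """Binary merge tree from agglomerative clustering.

    Wraps a scipy linkage matrix: row k merges clusters ``Z[k,0]`` and
    ``Z[k,1]`` at height ``Z[k,2]`` (Å). Leaves are state indices.
    """

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    n_leaves: int
    method: str = "average"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def root_height(self) -> float:
        return float(self.heights[-1]) if len(self.linkage) else 0.0

    def to_newick(self) -> str:
        """Newick string; branch lengths = parent height − child height (Å)."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        label = {i: f"state_{i}" for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            node = n + k
            height[node] = float(h)
            la = f"{label[a]}:{float(h) - height[a]:.6f}"
            lb = f"{label[b]}:{float(h) - height[b]:.6f}"
            label[node] = f"({la},{lb})"
        return label[n + len(self.linkage) - 1] + ";" if len(self.linkage) \
            else f"{label[0]};"


@dataclass
class ClusterAssignment:
    """state index -> 1-based cluster id, ids ordered by first occurrence."""

    labels: list[int]
    cutoff_used: float

    @property
    def n_clusters(self) -> int:
        return max(self.labels)

    def members(self, cluster_id: int) -> list[int]:
        return [i for i, c in enumerate(self.labels) if c == cluster_id]

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame({
            "state": range(len(self.labels)),
            "time_order": range(len(self.labels)),
            "cluster": self.labels,
        }).to_csv(path, sep="\t", index=False)


@dataclass
class RepresentativeSet:
    """cluster id -> medoid state index, with its mean intra-cluster RMSD (Å)."""

    medoids: dict[int, int]
    mean_rmsd: dict[int, float]


def rmsd_matrix(ensemble: Ensemble,
                selection: Iterable[str] = DEFAULT_SELECTION,
                mode: str = "pairwise",
                reference: int = 0) -> RMSDMatrix:
    """All-versus-all RMSD over the selected atoms common to every state.

    ``pairwise``: every pair of states independently superposed (Kabsch) —
    reference-free. ``reference``: all states first superposed onto the
    reference state, then plain RMSD between the aligned coordinates.
    """
    if mode not in ("pairwise", "reference"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(ensemble) < 2:
        raise ValueError("need at least 2 states for an RMSD matrix")
    sels = [coordinate_matrix(st, selection) for st in ensemble.states]
    common = set(zip(sels[0].keys, sels[0].atom_names))
    for s in sels[1:]:
        common &= set(zip(s.keys, s.atom_names))
    if len(common) < 3:
        raise SelectionError(
            f"selection {sorted(selection)} yields {len(common)} atoms "
            "common to all states; need >= 3")
    coords = []
    for s in sels:
        rows = [i for i, ka in enumerate(zip(s.keys, s.atom_names))
                if ka in common]
        coords.append(s.coords[rows])

    n = len(coords)
    m = np.zeros((n, n))
    if mode == "pairwise":
        for i in range(n):
            for j in range(i + 1, n):
                _, r = kabsch(coords[i], coords[j])
                m[i, j] = m[j, i] = r
    else:
        aligned = []
        for c in coords:
            tr, _ = kabsch(coords[reference], c)
            aligned.append(tr.apply(c))
        for i in range(n):
            for j in range(i + 1, n):
                d = aligned[i] - aligned[j]
                m[i, j] = m[j, i] = float(np.sqrt((d ** 2).sum() / len(d)))
    return RMSDMatrix(matrix=m, selection=frozenset(selection))


def hierarchical_cluster(matrix: RMSDMatrix,
                         linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of the RMSD matrix (average/complete/single)."""
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    matrix.validate()
    condensed = squareform(matrix.matrix, checks=False)
    z = _scipy_linkage(condensed, method=linkage)
    return Dendrogram(linkage=z, n_leaves=matrix.n_states, method=linkage)


def cut_dendrogram(dendrogram: Dendrogram, cutoff: float) -> ClusterAssignment:
    """Flat clusters from the merge tree: merges with height < cutoff join,
    merges at height >= cutoff split. Cluster ids are 1-based in order of
    first occurrence along the state (time) axis.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = dendrogram.n_leaves
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (a, b, h, _) in enumerate(dendrogram.linkage):
        if h < cutoff:
            node = n + k
            parent[find(int(a))] = node
            parent[find(int(b))] = node

    relabel: dict[int, int] = {}
    labels = []
    for i in range(n):
        root = find(i)
        if root not in relabel:
            relabel[root] = len(relabel) + 1
        labels.append(relabel[root])
    return ClusterAssignment(labels=labels, cutoff_used=cutoff)


def representatives(assignment: ClusterAssignment,
                    matrix: RMSDMatrix) -> RepresentativeSet:
    """Medoid of each cluster: the member state minimizing summed RMSD to the
    other members (ties -> lowest state index)."""
    if len(assignment.labels) != matrix.n_states:
        raise ValueError("assignment and matrix disagree on state count")
    medoids: dict[int, int] = {}
    means: dict[int, float] = {}
    for cid in range(1, assignment.n_clusters + 1):
        members = assignment.members(cid)
        sub = matrix.matrix[np.ix_(members, members)]
        sums = sub.sum(axis=1)
        best = int(np.argmin(sums))  # argmin takes the first (lowest) index
        medoids[cid] = members[best]
        means[cid] = float(sums[best] / (len(members) - 1)) \
            if len(members) > 1 else 0.0
    return RepresentativeSet(medoids=medoids, mean_rmsd=means)


def cluster_timeline(assignment: ClusterAssignment
                     ) -> tuple[list[tuple[int, int]], int]:
    """(state, cluster) series in time order plus the transition count."""
    series = list(enumerate(assignment.labels))
    transitions = sum(
        1 for i in range(len(assignment.labels) - 1)
        if assignment.labels[i] != assignment.labels[i + 1]
    )
    return series, transitions
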