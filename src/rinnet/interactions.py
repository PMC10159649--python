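"""Typed non-covalent interaction detection and residue-interaction networks.

Contacts between residues are inferred from atomic coordinates by geometric
rules, one rule family per interaction type:

HBOND      donor heavy atom D to acceptor A with d(D,A) <= cutoff and the
           angle at the donor (antecedent—D—A, or D—H—A when an explicit
           hydrogen is present) at least the configured minimum; each donor
           keeps only its closest acceptor.
IONIC      centroid of an anionic group within cutoff of the centroid of a
           cationic group (nucleotide phosphates count as anionic).
PIPISTACK  aromatic ring centroids within cutoff and inter-plane angle,
           folded to [0°, 90°], either near-parallel or near-perpendicular
           (T-shaped).
PICATION   cationic-group centroid within cutoff of a ring centroid and
           within the configured cone around the ring normal.
VDW        heavy-atom pair closer than the sum of van der Waals radii plus a
           slack, unless the residue pair is already explained by an HBOND or
           IONIC edge.
SSBOND     cysteine SG–SG within cutoff (exempt from the sequence-separation
           filter).

All thresholds live in :class:`GeometricCriteria` and are configuration, not
claims about any particular reference tool. Residue pairs closer in sequence
than ``min_seq_separation`` (same chain) are never considered, except for
disulfides. Per residue pair and type only the geometrically best instance
(smallest distance) is kept unless ``keep_multiple`` is set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chemistry import ChemistryTable, default_chemistry
from .geometry import (
    GeometryError,
    angle_deg,
    fit_ring_plane,
    folded_angle_deg,
    neighbor_pairs,
)
from .structures import Ensemble, Residue, ResidueKey, State

logger = logging.getLogger(__name__)


class InteractionType(str, Enum):
    HBOND = "HBOND"
    IONIC = "IONIC"
    PIPISTACK = "PIPISTACK"
    PICATION = "PICATION"
    VDW = "VDW"
    SSBOND = "SSBOND"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


@dataclass(frozen=True)
class GeometricCriteria:
    """Distance/angle thresholds of the detection rules (Å and degrees).

    Defaults follow common geometric-rule practice; every value is meant to be
    overridden freely, and the test fixtures place atoms relative to whatever
    the active thresholds are.
    """

    hbond_max_da: float = 3.5
    hbond_min_angle: float = 90.0
    ionic_max_dist: float = 4.0
    pipi_max_centroid: float = 6.5
    pipi_max_planar_angle: float = 30.0
    pication_max_dist: float = 5.0
    pication_max_angle: float = 45.0
    vdw_slack: float = 0.5
    ssbond_max_ss: float = 2.5
    min_seq_separation: int = 2
    keep_multiple: bool = False

    def __post_init__(self) -> None:
        for name in ("hbond_max_da", "ionic_max_dist", "pipi_max_centroid",
                     "pication_max_dist", "ssbond_max_ss"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("hbond_min_angle", "pipi_max_planar_angle",
                     "pication_max_angle"):
            if not 0.0 <= getattr(self, name) <= 180.0:
                raise ValueError(f"{name} must be in [0, 180] degrees")
        if self.min_seq_separation < 1:
            raise ValueError("min_seq_separation must be >= 1")


@dataclass(frozen=True)
class Edge:
    """One typed interaction between two residues in one state.

    ``source < target`` under the ResidueKey total order (canonical
    orientation), so an edge set never contains both directions.
    """

    source: ResidueKey
    target: ResidueKey
    type: InteractionType
    source_atom: str
    target_atom: str
    distance: float
    angle: float | None = None
    state_index: int = 0

    def pair(self) -> tuple[ResidueKey, ResidueKey]:
        return (self.source, self.target)

    def identity(self) -> tuple[ResidueKey, ResidueKey, InteractionType]:
        return (self.source, self.target, self.type)


@dataclass
class InteractionNetwork:
    """All nodes and typed edges of one state."""

    state_index: int
    nodes: list[ResidueKey]
    edges: list[Edge]

    def edges_of(self, type: InteractionType) -> list[Edge]:
        return [e for e in self.edges if e.type == type]

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiGraph()
        g.add_nodes_from(str(k) for k in self.nodes)
        for e in self.edges:
            g.add_edge(str(e.source), str(e.target), key=e.type.value,
                       type=e.type.value, distance=e.distance, angle=e.angle,
                       atoms=(e.source_atom, e.target_atom))
        return g


# ---------------------------------------------------------------------------
# per-state residue context


class _ResidueContext:
    """Pre-resolved chemistry for one residue (groups, centroids, planes)."""

    def __init__(self, idx: int, res: Residue, chem: ChemistryTable,
                 first_in_chain: bool):
        self.idx = idx
        self.res = res
        self.key = res.key
        self.donors = chem.donor_pairs(res)
        self.acceptors = chem.acceptor_atoms(res)
        self.cations = [self._group(g) for g in
                        chem.cation_groups(res, first_in_chain)]
        self.anions = [self._group(g) for g in chem.anion_groups(res)]
        self.rings = []
        for g in chem.ring_groups(res):
            coords = res.coords_of(sorted(g))
            try:
                plane = fit_ring_plane(coords, sorted(g))
            except GeometryError:
                continue  # degenerate ring geometry: not a candidate
            self.rings.append((sorted(g), coords, plane))
        self.hydrogens = [a for a in res.atoms if a.element.upper() == "H"]
        self.heavy = [a for a in res.atoms if a.element.upper() != "H"]

    def _group(self, names: frozenset[str]) -> tuple[list[str], np.ndarray]:
        atoms = sorted(names)
        coords = self.res.coords_of(atoms)
        return (atoms, coords)


def _contexts(state: State, chem: ChemistryTable) -> list[_ResidueContext]:
    out = []
    idx = 0
    for chain_id, residues in state.chains.items():
        for pos, res in enumerate(residues):
            out.append(_ResidueContext(idx, res, chem, first_in_chain=pos == 0))
            idx += 1
    return out


def _candidate_pairs(ctxs: list[_ResidueContext], cutoff: float
                     ) -> list[tuple[int, int]]:
    """Residue index pairs with any heavy-atom pair within ``cutoff``."""
    coords = []
    owner = []
    for c in ctxs:
        for a in c.heavy:
            coords.append(a.coords)
            owner.append(c.idx)
    if not coords:
        return []
    coords = np.array(coords)
    seen: set[tuple[int, int]] = set()
    for i, j, _ in neighbor_pairs(coords, coords, cutoff):
        ri, rj = owner[i], owner[j]
        if ri < rj:
            seen.add((ri, rj))
    return sorted(seen)


def _sequence_excluded(a: Residue, b: Residue, min_sep: int) -> bool:
    return a.chain_id == b.chain_id and abs(a.number - b.number) < min_sep


def _orient(ki: ResidueKey, ai: str, kj: ResidueKey, aj: str
            ) -> tuple[ResidueKey, str, ResidueKey, str]:
    if ki <= kj:
        return ki, ai, kj, aj
    return kj, aj, ki, ai


def _reduce_best(cands: list[Edge], keep_multiple: bool) -> list[Edge]:
    """Keep the smallest-distance instance per (pair, type)."""
    if keep_multiple:
        return sorted(cands, key=lambda e: (e.source, e.target, e.type.value,
                                            e.distance, e.source_atom,
                                            e.target_atom))
    best: dict[tuple, Edge] = {}
    for e in sorted(cands, key=lambda e: (e.distance, e.source_atom,
                                          e.target_atom)):
        best.setdefault(e.identity(), e)
    return sorted(best.values(),
                  key=lambda e: (e.source, e.target, e.type.value))


# ---------------------------------------------------------------------------
# detectors


def detect_hbond(state: State, criteria: GeometricCriteria | None = None,
                 chemistry: ChemistryTable | None = None) -> list[Edge]:
    """Hydrogen bonds; each donor atom keeps only its closest acceptor."""
    crit = criteria or GeometricCriteria()
    chem = chemistry or default_chemistry()
    ctxs = _contexts(state, chem)
    return _hbond_from_ctx(ctxs, crit, state.index)


def _hbond_from_ctx(ctxs, crit, state_index) -> list[Edge]:
    pairs = _candidate_pairs(ctxs, crit.hbond_max_da)
    raw: list[tuple[tuple, Edge]] = []  # (donor id, candidate edge)
    for ri, rj in pairs:
        ci, cj = ctxs[ri], ctxs[rj]
        if _sequence_excluded(ci.res, cj.res, crit.min_seq_separation):
            continue
        for don_ctx, acc_ctx in ((ci, cj), (cj, ci)):
            for d_name, ante_name in don_ctx.donors:
                d = don_ctx.res.atom(d_name)
                ante = don_ctx.res.atom(ante_name)
                hyds = [h for h in don_ctx.hydrogens
                        if np.linalg.norm(h.coords - d.coords) <= 1.3]
                for a_name in acc_ctx.acceptors:
                    a = acc_ctx.res.atom(a_name)
                    dist = float(np.linalg.norm(d.coords - a.coords))
                    if dist > crit.hbond_max_da:
                        continue
                    if hyds:
                        ang = max(angle_deg(d.coords, h.coords, a.coords)
                                  for h in hyds)
                    else:
                        ang = angle_deg(ante.coords, d.coords, a.coords)
                    if ang < crit.hbond_min_angle:
                        continue
                    s, sa, t, ta = _orient(don_ctx.key, d_name,
                                           acc_ctx.key, a_name)
                    raw.append(((don_ctx.idx, d_name),
                                Edge(s, t, InteractionType.HBOND, sa, ta,
                                     dist, ang, state_index)))
    # per donor keep the closest acceptor
    best_per_donor: dict[tuple, Edge] = {}
    for donor_id, e in sorted(raw, key=lambda r: (r[1].distance,
                                                  r[1].source_atom,
                                                  r[1].target_atom)):
        best_per_donor.setdefault(donor_id, e)
    return _reduce_best(list(best_per_donor.values()), crit.keep_multiple)


def detect_ionic(state: State, criteria: GeometricCriteria | None = None,
                 chemistry: ChemistryTable | None = None) -> list[Edge]:
    """Salt bridges: charged-group centroids within the ionic cutoff."""
    crit = criteria or GeometricCriteria()
    chem = chemistry or default_chemistry()
    return _ionic_from_ctx(_contexts(state, chem), crit, state.index)


def _group_edge(ci, gi, cj, gj, dist, itype, state_index, angle=None) -> Edge:
    """Edge between two groups; atoms = group member closest to partner centroid."""
    atoms_i, coords_i = gi
    atoms_j, coords_j = gj
    cen_i = coords_i.mean(axis=0)
    cen_j = coords_j.mean(axis=0)
    ai = atoms_i[int(np.argmin(np.linalg.norm(coords_i - cen_j, axis=1)))]
    aj = atoms_j[int(np.argmin(np.linalg.norm(coords_j - cen_i, axis=1)))]
    s, sa, t, ta = _orient(ci.key, ai, cj.key, aj)
    return Edge(s, t, itype, sa, ta, dist, angle, state_index)


def _ionic_from_ctx(ctxs, crit, state_index) -> list[Edge]:
    pairs = _candidate_pairs(ctxs, crit.ionic_max_dist + 3.0)
    cands: list[Edge] = []
    for ri, rj in pairs:
        ci, cj = ctxs[ri], ctxs[rj]
        if _sequence_excluded(ci.res, cj.res, crit.min_seq_separation):
            continue
        for cat_ctx, an_ctx in ((ci, cj), (cj, ci)):
            for cg in cat_ctx.cations:
                for ag in an_ctx.anions:
                    dist = float(np.linalg.norm(cg[1].mean(axis=0)
                                                - ag[1].mean(axis=0)))
                    if dist <= crit.ionic_max_dist:
                        cands.append(_group_edge(cat_ctx, cg, an_ctx, ag, dist,
                                                 InteractionType.IONIC,
                                                 state_index))
    return _reduce_best(cands, crit.keep_multiple)


def detect_pipistack(state: State, criteria: GeometricCriteria | None = None,
                     chemistry: ChemistryTable | None = None) -> list[Edge]:
    """π–π stacking: close ring centroids, near-parallel or T-shaped planes."""
    crit = criteria or GeometricCriteria()
    chem = chemistry or default_chemistry()
    return _pipi_from_ctx(_contexts(state, chem), crit, state.index)


def _pipi_from_ctx(ctxs, crit, state_index) -> list[Edge]:
    pairs = _candidate_pairs(ctxs, crit.pipi_max_centroid + 3.0)
    cands: list[Edge] = []
    for ri, rj in pairs:
        ci, cj = ctxs[ri], ctxs[rj]
        if not ci.rings or not cj.rings:
            continue
        if _sequence_excluded(ci.res, cj.res, crit.min_seq_separation):
            continue
        for atoms_i, coords_i, plane_i in ci.rings:
            for atoms_j, coords_j, plane_j in cj.rings:
                dist = float(np.linalg.norm(plane_i.centroid - plane_j.centroid))
                if dist > crit.pipi_max_centroid:
                    continue
                ang = folded_angle_deg(plane_i.normal, plane_j.normal)
                if (ang <= crit.pipi_max_planar_angle
                        or ang >= 90.0 - crit.pipi_max_planar_angle):
                    cands.append(_group_edge(ci, (atoms_i, coords_i),
                                             cj, (atoms_j, coords_j),
                                             dist, InteractionType.PIPISTACK,
                                             state_index, angle=ang))
    return _reduce_best(cands, crit.keep_multiple)


def detect_pication(state: State, criteria: GeometricCriteria | None = None,
                    chemistry: ChemistryTable | None = None) -> list[Edge]:
    """π–cation: cationic group over an aromatic ring face."""
    crit = criteria or GeometricCriteria()
    chem = chemistry or default_chemistry()
    return _pication_from_ctx(_contexts(state, chem), crit, state.index)


def _pication_from_ctx(ctxs, crit, state_index) -> list[Edge]:
    pairs = _candidate_pairs(ctxs, crit.pication_max_dist + 3.0)
    cands: list[Edge] = []
    for ri, rj in pairs:
        ci, cj = ctxs[ri], ctxs[rj]
        if _sequence_excluded(ci.res, cj.res, crit.min_seq_separation):
            continue
        for cat_ctx, ring_ctx in ((ci, cj), (cj, ci)):
            for cg in cat_ctx.cations:
                cat_cen = cg[1].mean(axis=0)
                for atoms_r, coords_r, plane in ring_ctx.rings:
                    sep = cat_cen - plane.centroid
                    dist = float(np.linalg.norm(sep))
                    if dist > crit.pication_max_dist or dist == 0.0:
                        continue
                    ang = folded_angle_deg(sep, plane.normal)
                    if ang > crit.pication_max_angle:
                        continue
                    cands.append(_group_edge(cat_ctx, cg, ring_ctx,
                                             (atoms_r, coords_r), dist,
                                             InteractionType.PICATION,
                                             state_index, angle=ang))
    return _reduce_best(cands, crit.keep_multiple)


def detect_ssbond(state: State, criteria: GeometricCriteria | None = None,
                  chemistry: ChemistryTable | None = None) -> list[Edge]:
    """Disulfide bridges (Cys SG–SG); exempt from sequence separation."""
    crit = criteria or GeometricCriteria()
    chem = chemistry or default_chemistry()
    return _ssbond_from_ctx(_contexts(state, chem), crit, state.index)


def _ssbond_from_ctx(ctxs, crit, state_index) -> list[Edge]:
    cands: list[Edge] = []
    cys = [c for c in ctxs if c.res.name == "CYS"
           and c.res.atom("SG") is not None]
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            a = cys[i].res.atom("SG")
            b = cys[j].res.atom("SG")
            dist = float(np.linalg.norm(a.coords - b.coords))
            if dist <= crit.ssbond_max_ss:
                s, sa, t, ta = _orient(cys[i].key, "SG", cys[j].key, "SG")
                cands.append(Edge(s, t, InteractionType.SSBOND, sa, ta, dist,
                                  None, state_index))
    return _reduce_best(cands, crit.keep_multiple)


def detect_vdw(state: State, criteria: GeometricCriteria | None = None,
               chemistry: ChemistryTable | None = None,
               exclude_pairs: set[tuple[ResidueKey, ResidueKey]] | None = None,
               ) -> list[Edge]:
    """van der Waals contacts between heavy atoms.

    Residue pairs listed in ``exclude_pairs`` (canonically oriented) are
    skipped; when it is None, the exclusion set is computed from this state's
    own HBOND and IONIC edges, per the rule that vdW never duplicates a pair
    already explained by those types.
    """
    crit = criteria or GeometricCriteria()
    chem = chemistry or default_chemistry()
    ctxs = _contexts(state, chem)
    if exclude_pairs is None:
        exclude_pairs = {e.pair() for e in _hbond_from_ctx(ctxs, crit,
                                                           state.index)}
        exclude_pairs |= {e.pair() for e in _ionic_from_ctx(ctxs, crit,
                                                            state.index)}
    return _vdw_from_ctx(ctxs, crit, chem, state.index, exclude_pairs)


def _vdw_from_ctx(ctxs, crit, chem, state_index, exclude_pairs) -> list[Edge]:
    max_r = max(chem.vdw_radii.values()) if chem.vdw_radii else 2.0
    pairs = _candidate_pairs(ctxs, 2 * max_r + crit.vdw_slack)
    cands: list[Edge] = []
    for ri, rj in pairs:
        ci, cj = ctxs[ri], ctxs[rj]
        if _sequence_excluded(ci.res, cj.res, crit.min_seq_separation):
            continue
        ki, kj = (ci.key, cj.key) if ci.key <= cj.key else (cj.key, ci.key)
        if (ki, kj) in exclude_pairs:
            continue
        for a in ci.heavy:
            ra = chem.vdw_radius(a.element)
            for b in cj.heavy:
                dist = float(np.linalg.norm(a.coords - b.coords))
                if dist <= ra + chem.vdw_radius(b.element) + crit.vdw_slack:
                    s, sa, t, ta = _orient(ci.key, a.name, cj.key, b.name)
                    cands.append(Edge(s, t, InteractionType.VDW, sa, ta, dist,
                                      None, state_index))
    return _reduce_best(cands, crit.keep_multiple)


# ---------------------------------------------------------------------------
# assembly


def detect_interactions(state: State,
                        criteria: GeometricCriteria | None = None,
                        chemistry: ChemistryTable | None = None,
                        ) -> InteractionNetwork:
    """Run every detector on one state and assemble the network.

    Unknown residue names are simply not candidates for the typed rules (they
    still contribute vdW contacts through their heavy atoms); they are logged,
    never fatal.
    """
    crit = criteria or GeometricCriteria()
    chem = chemistry or default_chemistry()
    ctxs = _contexts(state, chem)

    unknown = sorted({c.res.name for c in ctxs
                      if c.res.polymer_class == "other"
                      and not (c.cations or c.anions)})
    if unknown:
        logger.warning("residues without typed chemistry (vdW only): %s",
                       ", ".join(unknown))

    hbond = _hbond_from_ctx(ctxs, crit, state.index)
    ionic = _ionic_from_ctx(ctxs, crit, state.index)
    explained = {e.pair() for e in hbond} | {e.pair() for e in ionic}
    edges = (
        hbond
        + ionic
        + _pipi_from_ctx(ctxs, crit, state.index)
        + _pication_from_ctx(ctxs, crit, state.index)
        + _vdw_from_ctx(ctxs, crit, chem, state.index, explained)
        + _ssbond_from_ctx(ctxs, crit, state.index)
    )
    edges.sort(key=lambda e: (e.source, e.target, e.type.value, e.distance))
    return InteractionNetwork(state_index=state.index,
                              nodes=[c.key for c in ctxs], edges=edges)


def network_for_ensemble(ensemble: Ensemble,
                         criteria: GeometricCriteria | None = None,
                         chemistry: ChemistryTable | None = None,
                         ) -> list[InteractionNetwork]:
    """Detect interactions independently in every state, in state order."""
    return [detect_interactions(st, criteria, chemistry)
            for st in ensemble.states]


def filter_network(network: InteractionNetwork,
                   scope: str = "all",
                   types: Iterable[InteractionType] | None = None,
                   ) -> InteractionNetwork:
    """Restrict a network by chain scope and/or interaction types.

    scope: ``all`` | ``intra_chain`` | ``inter_chain``. Nodes are pruned to
    the endpoints of the surviving edges.
    """
    if scope not in ("all", "intra_chain", "inter_chain"):
        raise ValueError(f"unknown scope {scope!r}")
    wanted = set(types) if types is not None else set(InteractionType)
    edges = []
    for e in network.edges:
        if e.type not in wanted:
            continue
        same = e.source.chain_id == e.target.chain_id
        if scope == "intra_chain" and not same:
            continue
        if scope == "inter_chain" and same:
            continue
        edges.append(e)
    keep = {e.source for e in edges} | {e.target for e in edges}
    nodes = [k for k in network.nodes if k in keep]
    return InteractionNetwork(network.state_index, nodes, edges)


# ---------------------------------------------------------------------------
# writers (RING-style tab formats)

EDGE_COLUMNS = ["NodeId1", "Interaction", "NodeId2", "Atom1", "Atom2",
                "Distance", "Angle", "State"]


def edges_frame(networks: Sequence[InteractionNetwork]) -> pd.DataFrame:
    rows = [
        {
            "NodeId1": str(e.source),
            "Interaction": e.type.value,
            "NodeId2": str(e.target),
            "Atom1": e.source_atom,
            "Atom2": e.target_atom,
            "Distance": round(e.distance, 3),
            "Angle": round(e.angle, 2) if e.angle is not None else "",
            "State": e.state_index,
        }
        for net in networks for e in net.edges
    ]
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def nodes_frame(networks: Sequence[InteractionNetwork]) -> pd.DataFrame:
    """Node table with per-type degrees, aggregated over the given networks."""
    keys: list[ResidueKey] = []
    seen = set()
    for net in networks:
        for k in net.nodes:
            if k not in seen:
                seen.add(k)
                keys.append(k)
    deg = {k: {t.value: 0 for t in InteractionType} for k in keys}
    for net in networks:
        for e in net.edges:
            deg[e.source][e.type.value] += 1
            deg[e.target][e.type.value] += 1
    rows = [
        {"NodeId": str(k), "Chain": k.chain_id,
         **{f"Degree_{t.value}": deg[k][t.value] for t in InteractionType},
         "Degree_total": sum(deg[k].values())}
        for k in keys
    ]
    return pd.DataFrame(rows)


def write_edges_tsv(networks: Sequence[InteractionNetwork],
                    path: str | Path) -> None:
    edges_frame(networks).to_csv(path, sep="\t", index=False)


def write_nodes_tsv(networks: Sequence[InteractionNetwork],
                    path: str | Path) -> None:
    nodes_frame(networks).to_csv(path, sep="\t", index=False)
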