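"""Independent reference implementations used as test oracles.

Everything here is deliberately naive: exhaustive double loops over residue
pairs, eigen-decomposition plane fits, no cell lists, no shared helper code
with the package's detectors. The detectors must reproduce these results
exactly on arbitrary coordinates.
"""

from __future__ import annotations

import numpy as np

from rinnet.chemistry import ChemistryTable
from rinnet.interactions import GeometricCriteria, InteractionType
from rinnet.structures import State


def brute_force_pairs(coords_a, coords_b, cutoff):
    """O(n*m) double loop reference for neighbor_pairs."""
    a = np.asarray(coords_a, float).reshape(-1, 3)
    b = np.asarray(coords_b, float).reshape(-1, 3)
    out = []
    for i in range(len(a)):
        for j in range(len(b)):
            d = float(np.sqrt(((a[i] - b[j]) ** 2).sum()))
            if d <= cutoff:
                out.append((i, j, d))
    return out


# ---------------------------------------------------------------------------
# exhaustive detectors


def _flat_residues(state: State):
    """(residue, first_in_chain) in state order."""
    out = []
    for chain in state.chains.values():
        for pos, res in enumerate(chain):
            out.append((res, pos == 0))
    return out


def _angle(a, b, c):
    u = a - b
    v = c - b
    cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return np.degrees(np.arccos(np.clip(cos, -1, 1)))


def _plane(coords):
    """Centroid and unit normal via covariance eigen-decomposition."""
    c = coords.mean(axis=0)
    cov = (coords - c).T @ (coords - c)
    w, v = np.linalg.eigh(cov)
    n = v[:, 0]
    return c, n / np.linalg.norm(n)


def _folded(u, v):
    cos = abs(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return np.degrees(np.arccos(np.clip(cos, 0, 1)))


def _seq_ok(r1, r2, min_sep):
    return r1.chain_id != r2.chain_id or abs(r1.number - r2.number) >= min_sep


def _edge_tuple(r1, a1, r2, a2, itype, dist):
    k1, k2 = r1.key, r2.key
    if k1 <= k2:
        return (str(k1), str(k2), itype, a1, a2, round(dist, 6))
    return (str(k2), str(k1), itype, a2, a1, round(dist, 6))


def _admissible_pairs(state: State, max_reach: float):
    """All distinct residue pairs, pruned only by a provably safe bounding-
    sphere test (centers further apart than the sum of residue radii plus the
    maximum rule distance cannot satisfy any rule)."""
    flat = _flat_residues(state)
    centers = []
    radii = []
    for res, _ in flat:
        xyz = np.array([a.coords for a in res.atoms])
        c = xyz.mean(axis=0)
        centers.append(c)
        radii.append(float(np.linalg.norm(xyz - c, axis=1).max()))
    pairs = []
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            gap = np.linalg.norm(centers[i] - centers[j])
            if gap <= radii[i] + radii[j] + max_reach:
                pairs.append((flat[i], flat[j]))
    return pairs


def _max_reach(crit: GeometricCriteria, chem: ChemistryTable) -> float:
    max_r = max(chem.vdw_radii.values())
    return max(crit.hbond_max_da, crit.ionic_max_dist, crit.pipi_max_centroid,
               crit.pication_max_dist, 2 * max_r + crit.vdw_slack,
               crit.ssbond_max_ss)


def oracle_hbond(state: State, crit: GeometricCriteria,
                 chem: ChemistryTable) -> set:
    cands = []  # (donor identity, edge tuple, distance)
    for (r1, _), (r2, _) in _admissible_pairs(state, _max_reach(crit, chem)):
        if not _seq_ok(r1, r2, crit.min_seq_separation):
            continue
        for don, acc in ((r1, r2), (r2, r1)):
            for d_name, ante_name in chem.donor_pairs(don):
                d_at = don.atom(d_name)
                ante = don.atom(ante_name)
                hyds = [h for h in don.atoms if h.element.upper() == "H"
                        and np.linalg.norm(h.coords - d_at.coords) <= 1.3]
                for a_name in chem.acceptor_atoms(acc):
                    a_at = acc.atom(a_name)
                    dist = float(np.linalg.norm(d_at.coords - a_at.coords))
                    if dist > crit.hbond_max_da:
                        continue
                    if hyds:
                        ang = max(_angle(d_at.coords, h.coords, a_at.coords)
                                  for h in hyds)
                    else:
                        ang = _angle(ante.coords, d_at.coords, a_at.coords)
                    if ang < crit.hbond_min_angle:
                        continue
                    cands.append(((str(don.key), d_name),
                                  _edge_tuple(don, d_name, acc, a_name,
                                              InteractionType.HBOND, dist),
                                  dist))
    best_per_donor = {}
    for donor_id, tup, dist in sorted(cands, key=lambda t: (t[2], t[1])):
        best_per_donor.setdefault(donor_id, tup)
    return _best_per_pair(best_per_donor.values())


def _best_per_pair(tuples) -> set:
    best = {}
    for tup in sorted(tuples, key=lambda t: (t[5], t[3], t[4])):
        best.setdefault((tup[0], tup[1], tup[2]), tup)
    return set(best.values())


def oracle_ionic(state, crit, chem) -> set:
    cands = []
    for (r1, f1), (r2, f2) in _admissible_pairs(state,
                                                _max_reach(crit, chem)):
        if not _seq_ok(r1, r2, crit.min_seq_separation):
            continue
        for (cat, fc), (an, _) in (((r1, f1), (r2, f2)), ((r2, f2), (r1, f1))):
            for cg in chem.cation_groups(cat, first_in_chain=fc):
                cg_coords = np.array([cat.atom(n).coords for n in sorted(cg)])
                cen_c = cg_coords.mean(axis=0)
                for ag in chem.anion_groups(an):
                    ag_coords = np.array([an.atom(n).coords
                                          for n in sorted(ag)])
                    cen_a = ag_coords.mean(axis=0)
                    dist = float(np.linalg.norm(cen_c - cen_a))
                    if dist > crit.ionic_max_dist:
                        continue
                    a1 = sorted(cg)[int(np.argmin(
                        np.linalg.norm(cg_coords - cen_a, axis=1)))]
                    a2 = sorted(ag)[int(np.argmin(
                        np.linalg.norm(ag_coords - cen_c, axis=1)))]
                    cands.append(_edge_tuple(cat, a1, an, a2,
                                             InteractionType.IONIC, dist))
    return _best_per_pair(cands)


def _rings_of(res, chem):
    out = []
    for g in chem.ring_groups(res):
        coords = np.array([res.atom(n).coords for n in sorted(g)])
        cen, nrm = _plane(coords)
        out.append((sorted(g), coords, cen, nrm))
    return out


def oracle_pipistack(state, crit, chem) -> set:
    cands = []
    for (r1, _), (r2, _) in _admissible_pairs(state, _max_reach(crit, chem)):
        if not _seq_ok(r1, r2, crit.min_seq_separation):
            continue
        for g1, c1, cen1, n1 in _rings_of(r1, chem):
            for g2, c2, cen2, n2 in _rings_of(r2, chem):
                dist = float(np.linalg.norm(cen1 - cen2))
                if dist > crit.pipi_max_centroid:
                    continue
                ang = _folded(n1, n2)
                if not (ang <= crit.pipi_max_planar_angle
                        or ang >= 90.0 - crit.pipi_max_planar_angle):
                    continue
                a1 = g1[int(np.argmin(np.linalg.norm(c1 - cen2, axis=1)))]
                a2 = g2[int(np.argmin(np.linalg.norm(c2 - cen1, axis=1)))]
                cands.append(_edge_tuple(r1, a1, r2, a2,
                                         InteractionType.PIPISTACK, dist))
    return _best_per_pair(cands)


def oracle_pication(state, crit, chem) -> set:
    cands = []
    for (r1, f1), (r2, f2) in _admissible_pairs(state,
                                                _max_reach(crit, chem)):
        if not _seq_ok(r1, r2, crit.min_seq_separation):
            continue
        for (cat, fc), (ar, _) in (((r1, f1), (r2, f2)), ((r2, f2), (r1, f1))):
            for cg in chem.cation_groups(cat, first_in_chain=fc):
                cg_coords = np.array([cat.atom(n).coords for n in sorted(cg)])
                cen_c = cg_coords.mean(axis=0)
                for g, c, cen_r, nrm in _rings_of(ar, chem):
                    sep = cen_c - cen_r
                    dist = float(np.linalg.norm(sep))
                    if dist > crit.pication_max_dist or dist == 0.0:
                        continue
                    if _folded(sep, nrm) > crit.pication_max_angle:
                        continue
                    a1 = sorted(cg)[int(np.argmin(
                        np.linalg.norm(cg_coords - cen_r, axis=1)))]
                    a2 = g[int(np.argmin(np.linalg.norm(c - cen_c, axis=1)))]
                    cands.append(_edge_tuple(cat, a1, ar, a2,
                                             InteractionType.PICATION, dist))
    return _best_per_pair(cands)


def oracle_ssbond(state, crit, chem) -> set:
    flat = [r for r, _ in _flat_residues(state)]
    cands = []
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            r1, r2 = flat[i], flat[j]
            if r1.name != "CYS" or r2.name != "CYS":
                continue
            a, b = r1.atom("SG"), r2.atom("SG")
            if a is None or b is None:
                continue
            dist = float(np.linalg.norm(a.coords - b.coords))
            if dist <= crit.ssbond_max_ss:
                cands.append(_edge_tuple(r1, "SG", r2, "SG",
                                         InteractionType.SSBOND, dist))
    return _best_per_pair(cands)


def oracle_vdw(state, crit, chem) -> set:
    explained = {(t[0], t[1]) for t in oracle_hbond(state, crit, chem)}
    explained |= {(t[0], t[1]) for t in oracle_ionic(state, crit, chem)}
    cands = []
    for (r1, _), (r2, _) in _admissible_pairs(state, _max_reach(crit, chem)):
        if not _seq_ok(r1, r2, crit.min_seq_separation):
            continue
        if r1.key <= r2.key:
            k1, k2 = str(r1.key), str(r2.key)
        else:
            k1, k2 = str(r2.key), str(r1.key)
        if (k1, k2) in explained:
            continue
        heavy1 = [a for a in r1.atoms if a.element.upper() != "H"]
        heavy2 = [a for a in r2.atoms if a.element.upper() != "H"]
        for a in heavy1:
            for b in heavy2:
                dist = float(np.linalg.norm(a.coords - b.coords))
                limit = (chem.vdw_radius(a.element)
                         + chem.vdw_radius(b.element) + crit.vdw_slack)
                if dist <= limit:
                    cands.append(_edge_tuple(r1, a.name, r2, b.name,
                                             InteractionType.VDW, dist))
    return _best_per_pair(cands)


ORACLES = {
    InteractionType.HBOND: oracle_hbond,
    InteractionType.IONIC: oracle_ionic,
    InteractionType.PIPISTACK: oracle_pipistack,
    InteractionType.PICATION: oracle_pication,
    InteractionType.VDW: oracle_vdw,
    InteractionType.SSBOND: oracle_ssbond,
}


def edge_tuples(edges) -> set:
    """Package edges -> comparable tuples matching the oracle's output."""
    return {(str(e.source), str(e.target), e.type, e.source_atom,
             e.target_atom, round(e.distance, 6)) for e in edges}


# ---------------------------------------------------------------------------
# naive agglomerative clustering


def naive_agglomerative(dist: np.ndarray, method: str = "average"):
    """O(n^3) reference producing the sorted sequence of merge heights."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []

    def linkage_dist(a, b):
        vals = [dist[i, j] for i in clusters[a] for j in clusters[b]]
        if method == "average":
            return sum(vals) / len(vals)
        if method == "complete":
            return max(vals)
        return min(vals)

    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                d = linkage_dist(ids[x], ids[y])
                if best is None or d < best[0]:
                    best = (d, ids[x], ids[y])
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights
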