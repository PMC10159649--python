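"""Synthetic structures and ensembles with known ground truth.

Every test input is generated programmatically: an ideal α-helix whose
backbone geometry guarantees the (i, i+4) hydrogen-bond ladder, minimal
interacting residue pairs placed relative to the *active* detection
thresholds (at 0.85× the cutoff when an interaction is "on" and at ≥ 2× when
"off", so the suite stays valid if defaults change), multi-basin ensembles
for the clustering pipeline, and scripted-contact ensembles whose on/off
pattern drives the downstream frequency and correlation statistics.

Generators are deterministic: the only randomness is Gaussian coordinate
noise drawn from an explicitly passed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .interactions import GeometricCriteria, InteractionType
from .structures import Atom, Ensemble, Residue, ResidueKey, State

# idealized backbone internal coordinates (Å / degrees)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7
_ANG_CA_C_O = 120.8
_PHI_HELIX = -63.0
_PSI_HELIX = -43.0


@dataclass
class GroundTruth:
    """What the generator put into the coordinates.

    expected_edges: per state, the set of (source_key, target_key, type)
    triples the detection rules must find — exact up to incidental van der
    Waals contacts, which close atom placements can always add (compare on
    the non-VDW edge set). basin_labels: per-state basin index for
    clustering fixtures. script: interaction-name -> per-state on/off
    booleans for scripted-contact ensembles.
    """

    expected_edges: list[set[tuple[str, str, InteractionType]]] = field(
        default_factory=list)
    basin_labels: list[int] = field(default_factory=list)
    script: dict[str, list[bool]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# internal-coordinate placement


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position a fourth atom from three predecessors and internal coords
    (natural extension reference frame)."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _residue(chain: str, number: int, name: str, atoms: dict[str, np.ndarray],
             serial_start: int = 1) -> Residue:
    elements = {n: (n[:1] if n[:1] in "NCOSP" else "C") for n in atoms}
    return Residue(
        chain_id=chain, number=number, insertion="", name=name,
        polymer_class="amino_acid",
        atoms=[Atom(serial=serial_start + i, name=n, element=elements[n],
                    coords=xyz)
               for i, (n, xyz) in enumerate(atoms.items())],
    )


def _key(chain: str, number: int, name: str) -> str:
    return str(ResidueKey(chain, number, "", name))


# ---------------------------------------------------------------------------
# ideal helix


def make_ideal_helix(n_res: int,
                     criteria: GeometricCriteria | None = None,
                     ) -> tuple[Ensemble, GroundTruth]:
    """Ideal α-helix backbone (N, CA, C, O per residue), single state.

    Torsions φ=-63°, ψ=-43°, ω=180° give the canonical ~1.5 Å rise and
    ~100°/turn twist; every (i, i+4) N(i+4)–O(i) distance lands inside the
    hydrogen-bond cutoff (3.04 Å with standard bond geometry), closer than
    any competing acceptor. Deterministic — no randomness at all.

    The ground truth lists the guaranteed (i, i+4) hydrogen-bond ladder; the
    two N-terminal donors that have no (i−4) partner may additionally bond
    to their nearest admissible acceptor, and van der Waals contacts between
    backbone atoms are expected — but no ionic or π edge can occur.
    """
    if n_res < 6:
        raise ValueError("need at least 6 residues for a helix")
    crit = criteria or GeometricCriteria()

    coords: list[dict[str, np.ndarray]] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = np.radians(_ANG_N_CA_C)
    c = ca + _BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res):
        if i > 0:
            prev_n, prev_ca, prev_c = n, ca, c
            n = _place_atom(prev_n, prev_ca, prev_c, _BOND_C_N,
                            _ANG_CA_C_N, _PSI_HELIX)
            ca = _place_atom(prev_ca, prev_c, n, _BOND_N_CA,
                             _ANG_C_N_CA, 180.0)
            c = _place_atom(prev_c, n, ca, _BOND_CA_C,
                            _ANG_N_CA_C, _PHI_HELIX)
        o = _place_atom(n, ca, c, _BOND_C_O, _ANG_CA_C_O, _PSI_HELIX + 180.0)
        coords.append({"N": n, "CA": ca, "C": c, "O": o})

    residues = [
        _residue("A", i + 1, "ALA", coords[i], serial_start=4 * i + 1)
        for i in range(n_res)
    ]
    state = State(index=0, chains={"A": residues})
    ensemble = Ensemble(states=[state], source_path="", format="pdb")

    truth = GroundTruth()
    expected = {
        (_key("A", i + 1, "ALA"), _key("A", i + 5, "ALA"),
         InteractionType.HBOND)
        for i in range(n_res - 4)
    }
    truth.expected_edges = [expected]
    return ensemble, truth


# ---------------------------------------------------------------------------
# minimal interacting pairs


def _salt_bridge_unit(origin: np.ndarray, on: bool, crit: GeometricCriteria,
                      chains: tuple[str, str]) -> list[tuple[str, Residue]]:
    """LYS NZ cation vs GLU carboxylate; centroid distance 0.85× or 2.2× cutoff."""
    d = (0.85 if on else 2.2) * crit.ionic_max_dist
    lys = _residue(chains[0], 1, "LYS", {"NZ": origin + [0.0, 0.0, 0.0]})
    glu = _residue(chains[1], 1, "GLU", {
        "OE1": origin + [d, 1.1, 0.0],
        "OE2": origin + [d, -1.1, 0.0],
    })
    return [(chains[0], lys), (chains[1], glu)]


def _stacked_rings_unit(origin: np.ndarray, on: bool,
                        crit: GeometricCriteria,
                        chains: tuple[str, str]) -> list[tuple[str, Residue]]:
    """Two parallel PHE rings, centroids at 0.85× or 2.2× the π–π cutoff."""
    d = (0.85 if on else 2.2) * crit.pipi_max_centroid
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    ring = {
        nm: np.array([1.39 * np.cos(np.radians(60 * k)),
                      1.39 * np.sin(np.radians(60 * k)), 0.0])
        for k, nm in enumerate(names)
    }
    r1 = _residue(chains[0], 1, "PHE",
                  {nm: origin + xyz for nm, xyz in ring.items()})
    r2 = _residue(chains[1], 1, "PHE",
                  {nm: origin + xyz + [0.0, 0.0, d] for nm, xyz in ring.items()})
    return [(chains[0], r1), (chains[1], r2)]


def _pication_unit(origin: np.ndarray, on: bool, crit: GeometricCriteria,
                   chains: tuple[str, str],
                   axial: bool = True) -> list[tuple[str, Residue]]:
    """PHE ring with a LYS NZ cation on the ring axis (or, with axial=False,
    in the ring plane, which must fail the angle gate)."""
    d = (0.85 if on else 2.2) * crit.pication_max_dist
    ring_parts = _stacked_rings_unit(origin, True, crit, (chains[0], "x"))
    phe = ring_parts[0][1]
    offset = np.array([0.0, 0.0, d]) if axial else np.array([d, 0.0, 0.0])
    lys = _residue(chains[1], 1, "LYS", {"NZ": origin + offset})
    return [(chains[0], phe), (chains[1], lys)]


def _hbond_unit(origin: np.ndarray, on: bool, crit: GeometricCriteria,
                chains: tuple[str, str]) -> list[tuple[str, Residue]]:
    """Backbone N–H···O=C pair at 0.85× or 2.2× the donor–acceptor cutoff,
    with a 150° antecedent angle."""
    d = (0.85 if on else 2.2) * crit.hbond_max_da
    ca = _BOND_N_CA * np.array([np.cos(np.radians(150.0)),
                                np.sin(np.radians(150.0)), 0.0])
    donor = _residue(chains[0], 1, "ALA",
                     {"N": origin + [0.0, 0.0, 0.0], "CA": origin + ca})
    acceptor = _residue(chains[1], 1, "ALA", {
        "O": origin + [d, 0.0, 0.0],
        "C": origin + [d + _BOND_C_O, 0.0, 0.0],
    })
    return [(chains[0], donor), (chains[1], acceptor)]


def make_salt_bridge(criteria: GeometricCriteria | None = None,
                     on: bool = True) -> tuple[Ensemble, GroundTruth]:
    crit = criteria or GeometricCriteria()
    parts = _salt_bridge_unit(np.zeros(3), on, crit, ("A", "B"))
    return _single_state(parts, {
        (_key("A", 1, "LYS"), _key("B", 1, "GLU"), InteractionType.IONIC)
    } if on else set())


def make_stacked_rings(criteria: GeometricCriteria | None = None,
                       on: bool = True) -> tuple[Ensemble, GroundTruth]:
    crit = criteria or GeometricCriteria()
    parts = _stacked_rings_unit(np.zeros(3), on, crit, ("A", "B"))
    return _single_state(parts, {
        (_key("A", 1, "PHE"), _key("B", 1, "PHE"), InteractionType.PIPISTACK)
    } if on else set())


def make_pication_pair(criteria: GeometricCriteria | None = None,
                       on: bool = True,
                       axial: bool = True) -> tuple[Ensemble, GroundTruth]:
    crit = criteria or GeometricCriteria()
    parts = _pication_unit(np.zeros(3), on, crit, ("A", "B"), axial=axial)
    expected = {
        (_key("A", 1, "PHE"), _key("B", 1, "LYS"), InteractionType.PICATION)
    } if (on and axial) else set()
    return _single_state(parts, expected)


def _single_state(parts: list[tuple[str, Residue]],
                  expected: set) -> tuple[Ensemble, GroundTruth]:
    chains: dict[str, list[Residue]] = {}
    for chain_id, res in parts:
        chains.setdefault(chain_id, []).append(res)
    ens = Ensemble(states=[State(index=0, chains=chains)])
    return ens, GroundTruth(expected_edges=[expected])


# ---------------------------------------------------------------------------
# scripted-contact ensembles

_UNIT_BUILDERS = {
    "ionic": (_salt_bridge_unit, ("A", "B"), "LYS", "GLU",
              InteractionType.IONIC),
    "pipi": (_stacked_rings_unit, ("C", "D"), "PHE", "PHE",
             InteractionType.PIPISTACK),
    "hbond": (_hbond_unit, ("E", "F"), "ALA", "ALA", InteractionType.HBOND),
}
_UNIT_SPACING = 60.0  # Å between units: far beyond any detection cutoff


def make_scripted_contact_ensemble(
    script: dict[str, list[bool]],
    seed: int = 0,
    criteria: GeometricCriteria | None = None,
) -> tuple[Ensemble, GroundTruth]:
    """Multi-state ensemble whose contacts follow an explicit on/off script.

    ``script`` maps interaction names (subset of {"ionic", "pipi", "hbond"})
    to per-state booleans, all the same length. Each interaction is one
    isolated residue pair, 60 Å from the others; "on" places the partners at
    0.85× the relevant cutoff, "off" at 2.2×. The seed is part of the
    interface for symmetry with the noisy generators; this construction is
    fully deterministic.
    """
    if not script:
        raise ValueError("script must name at least one interaction")
    unknown = set(script) - set(_UNIT_BUILDERS)
    if unknown:
        raise ValueError(f"unknown interactions {sorted(unknown)}; "
                         f"choose from {sorted(_UNIT_BUILDERS)}")
    lengths = {len(v) for v in script.values()}
    if len(lengths) != 1:
        raise ValueError("all script rows must have the same length")
    (n_states,) = lengths
    if n_states < 1:
        raise ValueError("script must cover at least one state")

    names = sorted(script)
    truth = GroundTruth(script={k: list(map(bool, v))
                                for k, v in script.items()})
    states = []
    for s in range(n_states):
        chains: dict[str, list[Residue]] = {}
        expected: set[tuple[str, str, InteractionType]] = set()
        for u, name in enumerate(names):
            builder, chain_pair, res1, res2, itype = _UNIT_BUILDERS[name]
            origin = np.array([0.0, u * _UNIT_SPACING, 0.0])
            on = bool(script[name][s])
            for chain_id, res in builder(origin, on,
                                         criteria or GeometricCriteria(),
                                         chain_pair):
                chains.setdefault(chain_id, []).append(res)
            if on:
                k1 = _key(chain_pair[0], 1, res1)
                k2 = _key(chain_pair[1], 1, res2)
                expected.add((k1, k2, itype))
        states.append(State(index=s, chains=chains))
        truth.expected_edges.append(expected)
    ens = Ensemble(states=states)
    ens.validate_consistency()
    return ens, truth


# ---------------------------------------------------------------------------
# two-basin ensembles


def _ca_trace(n_res: int) -> np.ndarray:
    """Deterministic open helical CA trace (rise 1.5 Å, radius 2.3 Å)."""
    t = np.arange(n_res) * np.radians(100.0)
    return np.stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n_res)],
                    axis=1)


def _hinge_variant(base: np.ndarray, angle_deg_: float) -> np.ndarray:
    """Rotate the second half of the trace about a hinge at the midpoint."""
    out = base.copy()
    mid = len(base) // 2
    pivot = base[mid]
    theta = np.radians(angle_deg_)
    # hinge axis perpendicular to the trace's long (z) axis, so the rotation
    # bends the chain rather than spinning it
    rot = np.array([
        [1.0, 0.0, 0.0],
        [0.0, np.cos(theta), -np.sin(theta)],
        [0.0, np.sin(theta), np.cos(theta)],
    ])
    out[mid:] = (base[mid:] - pivot) @ rot.T + pivot
    return out


def make_two_basin_ensemble(
    n_states: int,
    basin_shift: float = 6.0,
    noise_sd: float = 0.3,
    switch_script: list[int] | None = None,
    seed: int = 0,
    n_res: int = 20,
) -> tuple[Ensemble, GroundTruth]:
    """Ensemble hopping between two conformational basins.

    Basin 0 is a fixed CA trace; basin 1 is the same trace with its second
    half rotated about a midpoint hinge, the hinge angle solved so the
    pairwise-optimal RMSD between the two references equals ``basin_shift``
    (Å). Each state is its basin's reference plus iid Gaussian noise of
    ``noise_sd`` Å per coordinate. ``switch_script`` gives the basin of each
    state (default: first half 0, second half 1).
    """
    if n_states < 2:
        raise ValueError("need at least 2 states")
    if basin_shift <= 0:
        raise ValueError("basin_shift must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    from .geometry import kabsch

    base = _ca_trace(n_res)

    def rmsd_at(angle: float) -> float:
        return kabsch(base, _hinge_variant(base, angle))[1]

    lo, hi = 0.0, 179.0
    if rmsd_at(hi) < basin_shift:
        raise ValueError(f"basin_shift {basin_shift} Å unreachable; "
                         f"max is {rmsd_at(hi):.2f} Å for n_res={n_res}")
    for _ in range(60):
        midpt = 0.5 * (lo + hi)
        if rmsd_at(midpt) < basin_shift:
            lo = midpt
        else:
            hi = midpt
    refs = [base, _hinge_variant(base, 0.5 * (lo + hi))]

    labels = switch_script if switch_script is not None else \
        [0] * (n_states // 2) + [1] * (n_states - n_states // 2)
    if len(labels) != n_states:
        raise ValueError("switch_script length must equal n_states")
    if not set(labels) <= {0, 1}:
        raise ValueError("switch_script entries must be 0 or 1")

    rng = np.random.default_rng(seed)
    states = []
    for s in range(n_states):
        coords = refs[labels[s]] + rng.normal(0.0, noise_sd, (n_res, 3))
        residues = [
            _residue("A", i + 1, "ALA", {"CA": coords[i]}, serial_start=i + 1)
            for i in range(n_res)
        ]
        states.append(State(index=s, chains={"A": residues}))
    ens = Ensemble(states=states)
    return ens, GroundTruth(basin_labels=list(labels))


# ---------------------------------------------------------------------------
# random decoy states (for detector-vs-oracle equivalence testing)

_DECOY_RESIDUES: dict[str, list[str]] = {
    "ALA": ["N", "CA", "C", "O", "CB"],
    "SER": ["N", "CA", "C", "O", "CB", "OG"],
    "LYS": ["N", "CA", "C", "O", "CB", "CE", "NZ"],
    "ARG": ["N", "CA", "C", "O", "CB", "NE", "CZ", "NH1", "NH2"],
    "ASP": ["N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"],
    "GLU": ["N", "CA", "C", "O", "CB", "CD", "OE1", "OE2"],
    "ASN": ["N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"],
    "PHE": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2",
            "CZ", "OH"],
    "TRP": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1", "CE2",
            "CE3", "CZ2", "CZ3", "CH2"],
    "HIS": ["N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "CYS": ["N", "CA", "C", "O", "CB", "SG"],
    "THR": ["N", "CA", "C", "O", "CB", "OG1"],
    "MET": ["N", "CA", "C", "O", "CB", "SD"],
}


def make_decoy_state(n_res: int, seed: int, box: float = 35.0,
                     jitter: float = 1.6) -> State:
    """Random 'residues' for stress-testing the detectors against an oracle.

    Residue centers are uniform in a cubic box; each residue's atoms are the
    standard names of a randomly chosen residue type, scattered within
    ``jitter`` Å of the center. The geometry is intentionally unphysical —
    the point is that every rule fires on arbitrary coordinates exactly as an
    exhaustive reference implementation says it should.
    """
    rng = np.random.default_rng(seed)
    names = sorted(_DECOY_RESIDUES)
    residues = []
    serial = 1
    for i in range(n_res):
        rname = names[rng.integers(len(names))]
        center = rng.uniform(0.0, box, 3)
        atoms = {}
        for an in _DECOY_RESIDUES[rname]:
            atoms[an] = center + rng.uniform(-jitter, jitter, 3)
        res = _residue("A", i + 1, rname, atoms, serial_start=serial)
        serial += len(atoms)
        residues.append(res)
    return State(index=0, chains={"A": residues})
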