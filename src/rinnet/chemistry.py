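"""Per-residue interaction chemistry: donors, acceptors, charged groups, rings.

The tables below encode which atoms of the standard amino acids and
nucleotides can participate in each interaction type. Bases contribute
aromatic rings, phosphates contribute anionic groups, base N/O atoms donate
and accept hydrogen bonds; sugar atoms participate only in van der Waals
contacts. Hydrogens are never required: hydrogen-bond geometry falls back to
the donor's antecedent heavy atom when no explicit hydrogen is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .structures import Residue

# element -> van der Waals radius, Å (Bondi-style values)
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.70

# Backbone donors/acceptors shared by all amino acids (PRO has no N-H).
_BB_DONOR = {"N": "CA"}
_BB_ACCEPTORS = {"O", "OXT"}

# residue -> {donor atom: antecedent heavy atom}
_AA_DONORS: dict[str, dict[str, str]] = {
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TYR": {"OH": "CZ"},
    "CYS": {"SG": "CB"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
    "LYS": {"NZ": "CE"},
    "ARG": {"NE": "CZ", "NH1": "CZ", "NH2": "CZ"},
    "HIS": {"ND1": "CG", "NE2": "CE1"},
    "TRP": {"NE1": "CD1"},
}

_AA_ACCEPTORS: dict[str, set[str]] = {
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "MET": {"SD"},
    "CYS": {"SG"},
}

_AA_CATIONS: dict[str, list[frozenset[str]]] = {
    "LYS": [frozenset({"NZ"})],
    "ARG": [frozenset({"NE", "CZ", "NH1", "NH2"})],
}
_HIS_CATION = frozenset({"ND1", "NE2"})

_AA_ANIONS: dict[str, list[frozenset[str]]] = {
    "ASP": [frozenset({"OD1", "OD2"})],
    "GLU": [frozenset({"OE1", "OE2"})],
}

_AA_RINGS: dict[str, list[frozenset[str]]] = {
    "PHE": [frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"})],
    "TYR": [frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"})],
    "TRP": [
        frozenset({"CG", "CD1", "CD2", "NE1", "CE2"}),
        frozenset({"CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
    ],
    "HIS": [frozenset({"CG", "ND1", "CD2", "CE1", "NE2"})],
}

_PURINES = {"A", "G", "DA", "DG", "I", "DI"}
_PYRIMIDINES = {"C", "U", "T", "DC", "DT", "DU"}

_NT_RINGS: dict[str, list[frozenset[str]]] = {
    **{n: [
        frozenset({"N1", "C2", "N3", "C4", "C5", "C6"}),
        frozenset({"C4", "C5", "N7", "C8", "N9"}),
    ] for n in _PURINES},
    **{n: [frozenset({"N1", "C2", "N3", "C4", "C5", "C6"})]
       for n in _PYRIMIDINES},
}

_NT_DONORS: dict[str, dict[str, str]] = {
    **{n: {"N6": "C6"} for n in ("A", "DA")},
    **{n: {"N1": "C2", "N2": "C2"} for n in ("G", "DG")},
    **{n: {"N4": "C4"} for n in ("C", "DC")},
    **{n: {"N3": "C2"} for n in ("U", "T", "DT", "DU")},
}

_NT_ACCEPTORS: dict[str, set[str]] = {
    **{n: {"N1", "N3", "N7"} for n in ("A", "DA")},
    **{n: {"O6", "N3", "N7"} for n in ("G", "DG")},
    **{n: {"O2", "N3"} for n in ("C", "DC")},
    **{n: {"O2", "O4"} for n in ("U", "T", "DT", "DU")},
}

_PHOSPHATE_ANION = frozenset({"OP1", "OP2"})

# monoatomic ions commonly seen as HETATM
_CATION_IONS = {"NA", "K", "MG", "CA", "ZN", "MN", "FE", "LI"}
_ANION_IONS = {"CL", "BR", "IOD", "F"}


@dataclass
class ChemistryTable:
    """Atom-level interaction chemistry, queried per residue.

    Groups are returned as lists of atom-name frozensets; a group only counts
    when every member atom is present in the residue (rings, carboxylates) —
    charged single-atom groups need only their one atom.
    """

    donors: dict[str, dict[str, str]] = field(default_factory=dict)
    acceptors: dict[str, set[str]] = field(default_factory=dict)
    cations: dict[str, list[frozenset[str]]] = field(default_factory=dict)
    anions: dict[str, list[frozenset[str]]] = field(default_factory=dict)
    rings: dict[str, list[frozenset[str]]] = field(default_factory=dict)
    vdw_radii: dict[str, float] = field(default_factory=dict)
    his_cationic: bool = False
    cterm_anion: frozenset[str] = frozenset({"O", "OXT"})

    # -- queries ----------------------------------------------------------

    def vdw_radius(self, element: str) -> float:
        return self.vdw_radii.get(element.upper(), DEFAULT_VDW_RADIUS)

    def donor_pairs(self, res: Residue) -> list[tuple[str, str]]:
        """(donor atom, antecedent atom) pairs present in this residue."""
        table = dict(self.donors.get(res.name, {}))
        if res.polymer_class == "amino_acid" and res.name != "PRO":
            table.update(_BB_DONOR)
        have = res.atom_names()
        return [(d, a) for d, a in sorted(table.items())
                if d in have and a in have]

    def acceptor_atoms(self, res: Residue) -> list[str]:
        names = set(self.acceptors.get(res.name, set()))
        if res.polymer_class == "amino_acid":
            names |= _BB_ACCEPTORS
        return sorted(names & res.atom_names())

    def cation_groups(self, res: Residue, first_in_chain: bool = False
                      ) -> list[frozenset[str]]:
        groups = list(self.cations.get(res.name, []))
        if self.his_cationic and res.name == "HIS":
            groups.append(_HIS_CATION)
        if (res.polymer_class == "amino_acid" and first_in_chain
                and res.name != "PRO"):
            groups.append(frozenset({"N"}))  # N-terminal amine
        if res.polymer_class == "other" and res.name in _CATION_IONS:
            groups.append(frozenset(res.atom_names()))
        return [g for g in groups if g <= res.atom_names()]

    def anion_groups(self, res: Residue) -> list[frozenset[str]]:
        groups = list(self.anions.get(res.name, []))
        if res.polymer_class == "nucleotide":
            groups.append(_PHOSPHATE_ANION)
        if res.polymer_class == "amino_acid" and "OXT" in res.atom_names():
            groups.append(self.cterm_anion)  # C-terminal carboxylate
        if res.polymer_class == "other" and res.name in _ANION_IONS:
            groups.append(frozenset(res.atom_names()))
        return [g for g in groups if g <= res.atom_names()]

    def ring_groups(self, res: Residue) -> list[frozenset[str]]:
        return [g for g in self.rings.get(res.name, [])
                if g <= res.atom_names()]


def default_chemistry(his_cationic: bool = False) -> ChemistryTable:
    """The standard table covering the 20 amino acids and RNA/DNA nucleotides."""
    donors = {**_AA_DONORS, **_NT_DONORS}
    acceptors = {**_AA_ACCEPTORS, **_NT_ACCEPTORS}
    return ChemistryTable(
        donors=donors,
        acceptors=acceptors,
        cations=dict(_AA_CATIONS),
        anions=dict(_AA_ANIONS),
        rings={**_AA_RINGS, **_NT_RINGS},
        vdw_radii=dict(VDW_RADII),
        his_cationic=his_cationic,
    )
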