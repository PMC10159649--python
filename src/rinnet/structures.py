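"""Uniform in-memory representation of single- and multi-model structures.

PDB and mmCIF files are read through gemmi and flattened into a small
``Ensemble -> State -> Chain -> Residue -> Atom`` hierarchy. Every model of a
multi-model file becomes one State; all States of an Ensemble are required to
carry the same residue sequence (same ResidueKeys in the same order), which is
what makes per-position ensemble statistics well defined.

Conventions (all configurable where it matters):

* author residue numbering, never re-indexed;
* waters dropped by default;
* for alternate locations the highest-occupancy conformer is kept
  (ties broken by alphabetical altloc id);
* hydrogens kept when present but never required downstream;
* coordinates in Å throughout.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
NUCLEOTIDES = {"A", "C", "G", "U", "T", "I", "DA", "DC", "DG", "DT", "DU", "DI"}


class StructureParseError(ValueError):
    """Unreadable or syntactically invalid coordinate file."""


class EnsembleConsistencyError(ValueError):
    """Models of one file do not share the same residue sequence."""


class SelectionError(ValueError):
    """Atom selection matched nothing usable."""


def polymer_class_of(name: str) -> str:
    if name in AMINO_ACIDS:
        return "amino_acid"
    if name in NUCLEOTIDES:
        return "nucleotide"
    return "other"


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Canonical residue identity ``chain:number[insertion]:name``.

    Ordering is by ``(chain_id, number, insertion, name)`` — numeric on the
    residue number, so ``A:2`` sorts before ``A:10``.
    """

    chain_id: str
    number: int
    insertion: str
    name: str

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.number}{self.insertion}:{self.name}"

    @classmethod
    def parse(cls, text: str) -> "ResidueKey":
        m = re.fullmatch(r"([^:]+):(-?\d+)([A-Za-z]?):([^:]+)", text)
        if m is None:
            raise ValueError(f"not a residue key: {text!r}")
        chain, num, ins, name = m.groups()
        return cls(chain_id=chain, number=int(num), insertion=ins, name=name)


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # (3,) float, Å
    altloc: str = ""
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    chain_id: str
    number: int
    insertion: str
    name: str
    polymer_class: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.number, self.insertion, self.name)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def atom_names(self) -> set[str]:
        return {a.name for a in self.atoms}

    def coords_of(self, names: Iterable[str]) -> np.ndarray | None:
        """Coordinates of the named atoms, or None if any is missing."""
        got = []
        for n in names:
            a = self.atom(n)
            if a is None:
                return None
            got.append(a.coords)
        return np.array(got)


@dataclass
class State:
    """One conformation (model / MD frame); chains hold residues in file order."""

    index: int
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    def residue_keys(self) -> list[ResidueKey]:
        return [r.key for r in self.residues()]

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def find(self, key: ResidueKey) -> Residue | None:
        for r in self.chains.get(key.chain_id, ()):
            if r.key == key:
                return r
        return None


@dataclass
class Ensemble:
    states: list[State]
    source_path: str = ""
    format: str = "pdb"

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("an Ensemble needs at least one State")

    def __len__(self) -> int:
        return len(self.states)

    def residue_keys(self) -> list[ResidueKey]:
        return self.states[0].residue_keys()

    def validate_consistency(self) -> None:
        ref = self.states[0].residue_keys()
        for st in self.states[1:]:
            keys = st.residue_keys()
            if keys != ref:
                for a, b in zip(ref, keys):
                    if a != b:
                        raise EnsembleConsistencyError(
                            f"state {st.index} differs from state 0 at {b} "
                            f"(expected {a})"
                        )
                raise EnsembleConsistencyError(
                    f"state {st.index} has {len(keys)} residues, "
                    f"state 0 has {len(ref)}"
                )


@dataclass
class CoordinateSelection:
    """Row-parallel output of :func:`coordinate_matrix`."""

    coords: np.ndarray  # (n, 3)
    keys: list[ResidueKey]  # residue of each row
    atom_names: list[str]  # atom name of each row
    skipped: list[ResidueKey]  # residues contributing no selected atom


# ---------------------------------------------------------------------------
# parsing


def _pick_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties -> first altloc."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for n in order:
        group = sorted(by_name[n], key=lambda a: (-a.occupancy, a.altloc))
        out.append(group[0])
    return out


def _gemmi_format(fmt: str) -> gemmi.CoorFormat:
    return {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }[fmt]


def parse_structure(
    path: str | Path,
    format: str = "auto",
    keep_waters: bool = False,
) -> Ensemble:
    """Parse a (possibly multi-model) PDB or mmCIF file into an Ensemble.

    One State per model; single-model files yield a one-state Ensemble.
    Raises :class:`StructureParseError` on unreadable input and
    :class:`EnsembleConsistencyError` when models disagree on the residue
    sequence.
    """
    path = Path(path)
    if format not in ("pdb", "mmcif", "auto"):
        raise ValueError(f"unknown format {format!r}")
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_gemmi_format(format))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models found")

    fmt = format
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"

    states: list[State] = []
    for mi, model in enumerate(st):
        state = State(index=mi)
        for chain in model:
            residues: list[Residue] = []
            for res in chain:
                if not keep_waters and res.name in WATER_NAMES:
                    continue
                atoms = [
                    Atom(
                        serial=a.serial,
                        name=a.name,
                        element=a.element.name,
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        altloc=a.altloc if a.altloc != "\x00" else "",
                        occupancy=a.occ,
                        is_hetero=res.het_flag == "H",
                    )
                    for a in res
                ]
                residues.append(
                    Residue(
                        chain_id=chain.name,
                        number=res.seqid.num,
                        insertion=(res.seqid.icode or "").strip(),
                        name=res.name,
                        polymer_class=polymer_class_of(res.name),
                        atoms=_pick_altlocs(atoms),
                    )
                )
            if residues:
                state.chains.setdefault(chain.name, []).extend(residues)
        states.append(state)

    ens = Ensemble(states=states, source_path=str(path), format=fmt)
    ens.validate_consistency()
    return ens


# ---------------------------------------------------------------------------
# writing


def _to_gemmi(states: Sequence[State]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "rinnet"
    for state in states:
        model = gemmi.Model(state.index + 1)
        for chain_id, residues in state.chains.items():
            chain = gemmi.Chain(chain_id)
            for res in residues:
                gres = gemmi.Residue()
                gres.name = res.name
                gres.seqid = gemmi.SeqId(res.number, res.insertion or " ")
                gres.het_flag = "H" if res.polymer_class == "other" else "A"
                for atom in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element)
                    ga.pos = gemmi.Position(*atom.coords)
                    ga.occ = atom.occupancy
                    ga.serial = atom.serial
                    if atom.altloc:
                        ga.altloc = atom.altloc
                    chain_res = gres
                    chain_res.add_atom(ga)
                chain.add_residue(gres)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def write_state(state: State, path: str | Path, format: str = "pdb") -> None:
    """Write one State; output re-parses to an equal State at format precision."""
    write_ensemble(Ensemble(states=[dataclasses.replace(state, index=0)]),
                   path, format=format)


def write_ensemble(ensemble: Ensemble, path: str | Path, format: str = "pdb") -> None:
    """Write all states as a multi-model PDB (MODEL/ENDMDL) or mmCIF file."""
    path = Path(path)
    st = _to_gemmi(ensemble.states)
    try:
        if format == "pdb":
            st.write_pdb(str(path))
        elif format == "mmcif":
            st.make_mmcif_document().write_file(str(path))
        else:
            raise ValueError(f"unsupported output format {format!r}")
    except (OSError, RuntimeError) as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# selections


def coordinate_matrix(
    state: State, selection: Iterable[str]
) -> CoordinateSelection:
    """Stacked coordinates of the selected atom names, in residue order.

    Rows are ordered by (chain, residue, atom name). Residues contributing no
    selected atom are skipped and reported in the result's ``skipped`` list.
    Union semantics: each residue contributes whichever of the selected atoms
    it has (e.g. CA from proteins, C1' from nucleotides).
    """
    names = set(selection)
    if not names:
        raise SelectionError("empty atom selection")
    rows: list[np.ndarray] = []
    keys: list[ResidueKey] = []
    atom_names: list[str] = []
    skipped: list[ResidueKey] = []
    for res in state.residues():
        hit = sorted(n for n in names if res.atom(n) is not None)
        if not hit:
            skipped.append(res.key)
            continue
        for n in hit:
            rows.append(res.atom(n).coords)
            keys.append(res.key)
            atom_names.append(n)
    if not rows:
        raise SelectionError(f"selection {sorted(names)} matched no atoms")
    return CoordinateSelection(
        coords=np.array(rows), keys=keys, atom_names=atom_names, skipped=skipped
    )
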