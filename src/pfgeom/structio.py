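"""Macromolecular coordinate I/O and atom selection.

Reads PDB and mmCIF files (via gemmi) into a small hierarchical model
(:class:`Structure` -> :class:`Chain` -> :class:`Residue` -> :class:`Atom`)
suited to geometry work: one position per atom (highest-occupancy altloc),
author residue numbering, and explicit polymer/heteroatom flags.  A
fixed-column PDB v3.3 writer round-trips coordinates to 0.001 A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "Selection",
    "AtomSet",
    "read_structure",
    "write_pdb",
    "select",
    "sequence_of",
    "vdw_radius",
    "electron_count",
    "VDW_RADII",
    "ELECTRON_COUNTS",
    "AA3TO1",
]

# Bondi-style van der Waals radii (A); heavy atoms only.  H included for
# completeness, never used by default (crystal structures here have no H).
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "MG": 1.73,
    "ZN": 1.39,
    "CA": 2.31,
    "NA": 2.27,
    "K": 2.75,
    "CL": 1.75,
    "F": 1.47,
    "FE": 1.63,
    "MN": 1.61,
}
DEFAULT_VDW_RADIUS = 1.70

ELECTRON_COUNTS: dict[str, int] = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12, "P": 15,
    "S": 16, "CL": 17, "K": 19, "CA": 20, "MN": 25, "FE": 26, "ZN": 30,
    "SE": 34,
}

AA3TO1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}


def vdw_radius(element: str) -> float:
    """Van der Waals radius (A) for an element symbol; warns and falls back
    to the carbon radius for unknown elements."""
    el = element.strip().upper()
    r = VDW_RADII.get(el)
    if r is None:
        warnings.warn(
            f"unknown element {element!r}: using default radius "
            f"{DEFAULT_VDW_RADIUS} A",
            stacklevel=2,
        )
        return DEFAULT_VDW_RADIUS
    return r


def electron_count(element: str) -> int:
    """Electron count for a neutral atom of the given element (carbon
    fallback for unknowns)."""
    return ELECTRON_COUNTS.get(element.strip().upper(), 6)


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    altloc: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    position: np.ndarray  # (3,) A
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.strip().upper() in ("H", "D")


@dataclass
class Residue:
    name: str
    number: int
    insertion_code: str
    atoms: list[Atom] = field(default_factory=list)
    is_polymer: bool = True

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_water(self) -> bool:
        return self.name in _WATER_NAMES

    def one_letter(self) -> str:
        return AA3TO1.get(self.name, "X")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_polymer]

    @property
    def is_polymer(self) -> bool:
        return any(r.is_polymer for r in self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        available = ", ".join(c.chain_id for c in self.chains)
        raise KeyError(f"no chain {chain_id!r}; available chains: {available}")

    def polymer_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.is_polymer]

    def atoms(self) -> Iterator[Atom]:
        for c in self.chains:
            for r in c.residues:
                yield from r.atoms

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def copy(self) -> "Structure":
        import copy as _copy

        return _copy.deepcopy(self)


@dataclass
class Selection:
    """Chain + inclusive residue ranges + optional atom-name filter.

    ``atom_names=None`` keeps every atom; geometry code typically passes
    ``("CA",)``.  ``residue_ranges=None`` selects the whole chain.
    """

    chain_id: str
    residue_ranges: Sequence[tuple[int, int]] | None = None
    atom_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.residue_ranges is not None:
            self.residue_ranges = [tuple(r) for r in self.residue_ranges]
            for start, end in self.residue_ranges:
                if start > end:
                    raise ValueError(f"empty residue range [{start}, {end}]")

    def covers(self, residue_number: int) -> bool:
        if self.residue_ranges is None:
            return True
        return any(s <= residue_number <= e for s, e in self.residue_ranges)


@dataclass
class AtomSet:
    """Ordered atom list with an (N, 3) coordinate matrix."""

    atoms: list[Atom]

    @property
    def positions(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def residue_numbers(self) -> list[int]:
        return [a.residue_number for a in self.atoms]

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    def centroid(self) -> np.ndarray:
        if not self.atoms:
            raise ValueError("centroid of empty AtomSet")
        return self.positions.mean(axis=0)


def _clean_altloc(raw: str) -> str:
    return (raw or "").replace("\x00", "").strip()


def _pick_conformers(gres) -> list:
    """One atom per name: highest occupancy wins, ties go to altloc 'A'."""
    best: dict[str, object] = {}
    for gatom in gres:
        prev = best.get(gatom.name)
        if prev is None:
            best[gatom.name] = gatom
            continue
        if (gatom.occ, -ord(_clean_altloc(gatom.altloc) or "z")) > (
            prev.occ, -ord(_clean_altloc(prev.altloc) or "z")
        ):
            best[gatom.name] = gatom
    # preserve file order of first appearance
    seen: list = []
    names: set[str] = set()
    for gatom in gres:
        if gatom.name not in names:
            names.add(gatom.name)
            seen.append(best[gatom.name])
    return seen


def _from_gemmi(st: gemmi.Structure, structure_id: str) -> Structure:
    st.setup_entities()
    model = st[0]
    out = Structure(id=structure_id)
    serial = 0
    for gchain in model:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            info = gemmi.find_tabulated_residue(gres.name)
            is_poly = bool(info) and (info.is_amino_acid() or info.is_nucleic_acid())
            res = Residue(
                name=gres.name,
                number=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                is_polymer=is_poly,
            )
            for gatom in _pick_conformers(gres):
                serial += 1
                res.atoms.append(
                    Atom(
                        serial=serial,
                        name=gatom.name,
                        element=gatom.element.name,
                        altloc=_clean_altloc(gatom.altloc),
                        residue_name=gres.name,
                        chain_id=gchain.name,
                        residue_number=gres.seqid.num,
                        insertion_code=(gres.seqid.icode or "").strip(),
                        position=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                        occupancy=float(gatom.occ),
                        b_factor=float(gatom.b_iso),
                    )
                )
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            out.chains.append(chain)
    return out


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Alternate conformations are collapsed to the highest-occupancy one
    (ties resolved to altloc 'A'); author residue numbering is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"cannot parse {path}: no models found")
    return _from_gemmi(st, structure_id=st.name or path.stem)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write fixed-column PDB v3.3 ATOM/HETATM records (plus TER/END)."""
    lines: list[str] = []
    serial = 0
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                x, y, z = atom.position
                if max(abs(x), abs(y), abs(z)) >= 10000.0:
                    raise ValueError(
                        f"atom {atom.serial}: coordinate overflow for fixed-column PDB"
                    )
                serial += 1
                record = "ATOM  " if res.is_polymer else "HETATM"
                name = atom.name
                # PDB atom-name alignment: 1-char elements start in column 14
                if len(name) < 4 and len(atom.element.strip()) < 2:
                    name = " " + name
                lines.append(
                    f"{record}{serial % 100000:5d} {name:<4s}{atom.altloc or ' ':1s}"
                    f"{atom.residue_name:>3s} {chain.chain_id[:1]:1s}"
                    f"{atom.residue_number:4d}{atom.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}"
                    f"{atom.b_factor:6.2f}          {atom.element.strip():>2s}"
                )
        if chain.residues and chain.residues[-1].is_polymer:
            serial += 1
            last = chain.residues[-1]
            lines.append(
                f"TER   {serial % 100000:5d}      {last.name:>3s} "
                f"{chain.chain_id[:1]:1s}{last.number:4d}"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def select(structure: Structure, selection: Selection) -> AtomSet:
    """Resolve a :class:`Selection` to an ordered :class:`AtomSet`.

    Atoms come back in residue order; an out-of-range residue window yields
    an empty set (an unknown chain raises).  Waters are always excluded.
    """
    chain = structure.chain(selection.chain_id)
    names = set(selection.atom_names) if selection.atom_names is not None else None
    out: list[Atom] = []
    for res in chain.residues:
        if res.is_water:
            continue
        if not selection.covers(res.number):
            continue
        for atom in res.atoms:
            if atom.is_hydrogen:
                continue
            if names is not None and atom.name not in names:
                continue
            out.append(atom)
    return AtomSet(out)


def select_ca(structure: Structure, chain_id: str,
              residue_ranges: Sequence[tuple[int, int]] | None = None) -> AtomSet:
    """Shorthand for a Calpha-only selection."""
    return select(structure, Selection(chain_id, residue_ranges, atom_names=("CA",)))


def sequence_of(chain: Chain) -> str:
    """One-letter sequence over the chain's polymer residues ('X' for
    nonstandard residues)."""
    return "".join(r.one_letter() for r in chain.polymer_residues())
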