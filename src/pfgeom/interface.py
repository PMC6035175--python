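"""Solvent-accessible surface area and interface analysis.

Shrake-Rupley SASA with a deterministic golden-spiral dot sphere, buried
interface area as the SASA lost on complex formation, and distance-based
contact mapping with salt-bridge / hydrogen-bond candidate classification.
Hydrogens are ignored throughout; waters are never part of a selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structio import Atom, AtomSet, Selection, Structure, select, vdw_radius

__all__ = [
    "SphereSet",
    "SASAResult",
    "ContactPair",
    "InterfaceReport",
    "sasa",
    "buried_area",
    "contacts",
    "sphere_points",
]

DEFAULT_PROBE = 1.4  # A, water probe
DEFAULT_N_POINTS = 960

# basic-residue nitrogens and acidic-residue oxygens for salt-bridge calls
_BASIC_N = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
            ("HIS", "ND1"), ("HIS", "NE2")}
_ACIDIC_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}

SALT_BRIDGE_CUTOFF = 4.0  # A
HBOND_CUTOFF = 3.5  # A


@dataclass
class SphereSet:
    """Atom spheres: centers (N,3), vdW radii (N,), atom back-references."""

    centers: np.ndarray
    radii: np.ndarray
    labels: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if np.any(self.radii <= 0):
            raise ValueError("all radii must be positive")

    @classmethod
    def from_atoms(cls, atoms: AtomSet | list[Atom],
                   radii: dict[str, float] | None = None) -> "SphereSet":
        alist = list(atoms)
        heavy = [a for a in alist if not a.is_hydrogen]
        centers = np.array([a.position for a in heavy], dtype=float)
        if radii:
            rr = np.array([radii.get(a.element.strip().upper(), vdw_radius(a.element))
                           for a in heavy])
        else:
            rr = np.array([vdw_radius(a.element) for a in heavy])
        return cls(centers, rr, heavy)

    def __len__(self) -> int:
        return len(self.radii)


@dataclass
class SASAResult:
    per_atom_area: np.ndarray  # A^2
    probe_radius: float
    n_points: int

    @property
    def total_area(self) -> float:
        return float(self.per_atom_area.sum())


@dataclass
class ContactPair:
    atom_a: Atom
    atom_b: Atom
    distance: float
    kind: str  # contact | hbond_candidate | salt_bridge_candidate


@dataclass
class InterfaceReport:
    buried_area: float  # A^2, interface area = delta-SASA / 2
    buried_area_total: float  # A^2, delta-SASA
    contact_pairs: list[ContactPair] = field(default_factory=list)
    probe_radius: float = DEFAULT_PROBE
    n_points: int = DEFAULT_N_POINTS

    def to_dict(self) -> dict:
        return {
            "buried_area_A2": self.buried_area,
            "buried_area_total_A2": self.buried_area_total,
            "n_contacts": len(self.contact_pairs),
            "probe_radius_A": self.probe_radius,
            "contacts": [
                {
                    "atom_a": f"{c.atom_a.chain_id}/{c.atom_a.residue_name}"
                              f"{c.atom_a.residue_number}/{c.atom_a.name}",
                    "atom_b": f"{c.atom_b.chain_id}/{c.atom_b.residue_name}"
                              f"{c.atom_b.residue_number}/{c.atom_b.name}",
                    "distance_A": round(c.distance, 3),
                    "class": c.kind,
                }
                for c in self.contact_pairs
            ],
        }


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere dots (golden-section spiral)."""
    if n < 1:
        raise ValueError("need at least one dot")
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def sasa(
    spheres: SphereSet,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> SASAResult:
    """Shrake-Rupley accessible surface area.

    Dots are placed on each probe-expanded sphere; a dot counts as
    accessible iff it lies outside every other expanded sphere.  Per-atom
    area is the accessible fraction of 4 pi (r + probe)^2.
    """
    n_atoms = len(spheres)
    if n_atoms == 0:
        raise ValueError("empty sphere set")
    dots = sphere_points(n_points)
    expanded = spheres.radii + probe_radius
    tree = cKDTree(spheres.centers)
    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        ri = expanded[i]
        surface = spheres.centers[i] + ri * dots
        neighbors = [j for j in tree.query_ball_point(spheres.centers[i], ri + expanded.max())
                     if j != i]
        if neighbors:
            nc = spheres.centers[neighbors]
            nr = expanded[neighbors]
            d2 = ((surface[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nr**2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * ri**2
    return SASAResult(per_atom_area=areas, probe_radius=probe_radius, n_points=n_points)


def _resolve_group(structure: Structure, group: Selection | list[Selection]) -> list[Atom]:
    sels = group if isinstance(group, list) else [group]
    out: list[Atom] = []
    for s in sels:
        out.extend(a for a in select(structure, s) if not a.is_hydrogen)
    return out


def buried_area(
    structure: Structure,
    group_a: Selection | list[Selection],
    group_b: Selection | list[Selection],
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> InterfaceReport:
    """Interface burial between two disjoint heavy-atom groups.

    buried_area_total = SASA(A) + SASA(B) - SASA(A u B); the headline
    ``buried_area`` halves it (one-interface convention).  Both values are
    reported so either convention can be compared.
    """
    atoms_a = _resolve_group(structure, group_a)
    atoms_b = _resolve_group(structure, group_b)
    if not atoms_a or not atoms_b:
        raise ValueError("both groups must be non-empty")
    ids_a = {id(a) for a in atoms_a}
    if any(id(b) in ids_a for b in atoms_b):
        raise ValueError("groups overlap; interface burial is undefined")
    sa = sasa(SphereSet.from_atoms(atoms_a), probe_radius, n_points).total_area
    sb = sasa(SphereSet.from_atoms(atoms_b), probe_radius, n_points).total_area
    sab = sasa(SphereSet.from_atoms(atoms_a + atoms_b), probe_radius, n_points).total_area
    delta = sa + sb - sab
    return InterfaceReport(
        buried_area=delta / 2.0,
        buried_area_total=delta,
        probe_radius=probe_radius,
        n_points=n_points,
    )


def _classify(a: Atom, b: Atom, dist: float) -> str:
    ka = (a.residue_name, a.name)
    kb = (b.residue_name, b.name)
    if dist <= SALT_BRIDGE_CUTOFF and (
        (ka in _BASIC_N and kb in _ACIDIC_O) or (kb in _BASIC_N and ka in _ACIDIC_O)
    ):
        return "salt_bridge_candidate"
    ea = a.element.strip().upper()
    eb = b.element.strip().upper()
    if dist <= HBOND_CUTOFF and ea in ("N", "O") and eb in ("N", "O"):
        return "hbond_candidate"
    return "contact"


def contacts(
    structure: Structure,
    group_a: Selection | list[Selection],
    group_b: Selection | list[Selection],
    cutoff: float = 4.0,
) -> InterfaceReport:
    """All heavy-atom pairs across the interface within ``cutoff`` A,
    classified as plain contact, H-bond candidate (N/O vs N/O <= 3.5 A) or
    salt-bridge candidate (basic N vs acidic O <= 4.0 A)."""
    atoms_a = _resolve_group(structure, group_a)
    atoms_b = _resolve_group(structure, group_b)
    if not atoms_a or not atoms_b:
        raise ValueError("both groups must be non-empty")
    pa = np.array([a.position for a in atoms_a])
    pb = np.array([b.position for b in atoms_b])
    tree = cKDTree(pb)
    pairs: list[ContactPair] = []
    for i, a in enumerate(atoms_a):
        for j in tree.query_ball_point(pa[i], cutoff):
            dist = float(np.linalg.norm(pa[i] - pb[j]))
            if dist <= cutoff:
                pairs.append(ContactPair(a, atoms_b[j], dist, _classify(a, atoms_b[j], dist)))
    pairs.sort(key=lambda c: c.distance)
    return InterfaceReport(
        buried_area=0.0, buried_area_total=0.0, contact_pairs=pairs
    )
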