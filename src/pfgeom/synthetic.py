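"""Synthetic coordinate fixtures with known ground truth.

Rigid pseudo-subunit filaments with programmed per-interface bend, twist
and axial rise (plus optional Gaussian coordinate noise) emulate a
head-to-tail tubulin protofilament with controllable curvature, so every
geometry operation can be validated by parameter recovery.  Two-body
constructions at a prescribed surface gap serve the interface module.

Pseudo-subunits are Calpha-only (element carbon) with deterministic
pseudo-sequences; identical seeds give bitwise-identical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structio import Atom, Chain, Residue, Structure, vdw_radius

__all__ = ["FilamentSpec", "make_subunit", "build_filament", "make_two_body"]

_AA_NAMES = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"


@dataclass
class FilamentSpec:
    """Recipe for a rigid pseudo-subunit filament.

    ``bend_per_interface`` / ``twist_per_interface`` are degrees, scalar
    (same at every interface) or one value per interface
    (``n_subunits - 1`` values).  ``rise`` is the centroid-to-centroid
    step in A; ``noise_sigma`` the per-coordinate Gaussian noise in A.
    """

    n_subunits: int = 4
    atoms_per_subunit: int = 120
    bend_per_interface: float | Sequence[float] = 0.0
    twist_per_interface: float | Sequence[float] = 0.0
    rise: float = 42.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subunits < 2:
            raise ValueError("a filament needs at least 2 subunits")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")

    def _per_interface(self, value: float | Sequence[float]) -> list[float]:
        n = self.n_subunits - 1
        if np.isscalar(value):
            return [float(value)] * n
        vals = [float(v) for v in value]
        if len(vals) != n:
            raise ValueError(f"expected {n} per-interface values, got {len(vals)}")
        return vals

    @property
    def bends(self) -> list[float]:
        return self._per_interface(self.bend_per_interface)

    @property
    def twists(self) -> list[float]:
        return self._per_interface(self.twist_per_interface)


def _rot(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    th = np.deg2rad(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def _subunit_coords(n_atoms: int, seed: int) -> np.ndarray:
    """Three mutually skew right-handed helical arcs; chiral and with
    distinct principal moments of inertia, so superposition is
    well-conditioned and mirror-unambiguous."""
    rng = np.random.default_rng(seed)
    sizes = [n_atoms // 3, n_atoms // 3, n_atoms - 2 * (n_atoms // 3)]
    coords = []
    for arc, size in enumerate(sizes):
        # helix with per-arc random orientation and offset
        t = np.arange(size) * (100.0 / 28.0)  # ~alpha-helix rise per residue
        radius = 2.3 + 1.5 * arc
        pitch = np.deg2rad(99.0 + 7.0 * arc)
        local = np.column_stack([
            radius * np.cos(pitch * np.arange(size)),
            radius * np.sin(pitch * np.arange(size)),
            1.5 * t / (100.0 / 28.0),
        ])
        R = _rot(rng.normal(size=3), float(rng.uniform(0, 360)))
        offset = rng.uniform(-8, 8, size=3) + np.array([6.0 * arc, -4.0 * arc, 2.0 * arc])
        coords.append(local @ R.T + offset)
    out = np.vstack(coords)
    return out - out.mean(axis=0)


def _pseudo_sequence(n: int, seed: int) -> list[str]:
    rng = np.random.default_rng(seed + 7919)
    return [_AA_NAMES[i] for i in rng.integers(0, len(_AA_NAMES), size=n)]


def _structure_from_chains(chains_coords: list[np.ndarray],
                           res_names: list[str],
                           structure_id: str) -> Structure:
    st = Structure(id=structure_id)
    serial = 0
    for ci, coords in enumerate(chains_coords):
        cid = _CHAIN_IDS[ci % len(_CHAIN_IDS)]
        chain = Chain(chain_id=cid)
        for i, pos in enumerate(coords):
            serial += 1
            res = Residue(name=res_names[i], number=i + 1, insertion_code="")
            res.atoms.append(
                Atom(serial=serial, name="CA", element="C", altloc="",
                     residue_name=res_names[i], chain_id=cid,
                     residue_number=i + 1, insertion_code="",
                     position=pos.copy())
            )
            chain.residues.append(res)
        st.chains.append(chain)
    return st


def make_subunit(atoms_per_subunit: int = 120, seed: int = 0) -> Structure:
    """One rigid Calpha-only pseudo-domain as a single-chain Structure."""
    if atoms_per_subunit < 10:
        raise ValueError("need at least 10 atoms per subunit")
    coords = _subunit_coords(atoms_per_subunit, seed)
    names = _pseudo_sequence(atoms_per_subunit, seed)
    return _structure_from_chains([coords], names, f"subunit-seed{seed}")


def build_filament(spec: FilamentSpec) -> tuple[Structure, list[tuple[float, float, float]]]:
    """Head-to-tail filament of rigid copies of one pseudo-subunit.

    Subunit i+1 is subunit i rotated about its own centroid by
    twist (about the current filament axis) then bend (about a
    perpendicular axis), and stepped by ``rise`` along the current axis.
    Gaussian noise is added per coordinate afterwards.  Returns the
    structure (chains A, B, C, ...) and the programmed ground truth, one
    (bend, twist, rise) triple per interface.
    """
    template = _subunit_coords(spec.atoms_per_subunit, spec.seed)
    names = _pseudo_sequence(spec.atoms_per_subunit, spec.seed)
    bends, twists = spec.bends, spec.twists

    axis = np.array([0.0, 0.0, 1.0])  # current filament axis
    normal = np.array([1.0, 0.0, 0.0])  # bend axis, perpendicular to axis
    coords = template.copy()
    chains = [coords]
    truth: list[tuple[float, float, float]] = []
    for bend, twist in zip(bends, twists):
        c = chains[-1].mean(axis=0)
        R = _rot(normal, bend) @ _rot(axis, twist)
        nxt = (chains[-1] - c) @ R.T + c + spec.rise * axis
        chains.append(nxt)
        truth.append((bend, twist, spec.rise))
        # advance the frame by the interface rotation
        axis = R @ axis
        normal = R @ normal
        axis /= np.linalg.norm(axis)
        normal -= (normal @ axis) * axis
        normal /= np.linalg.norm(normal)
    if spec.noise_sigma > 0:
        noise_rng = np.random.default_rng([spec.seed, 1])
        chains = [c + noise_rng.normal(0.0, spec.noise_sigma, size=c.shape)
                  for c in chains]
    st = _structure_from_chains(chains, names, f"filament-seed{spec.seed}")
    return st, truth


def make_two_body(separation: float = 10.0, seed: int = 0,
                  atoms_per_body: int = 60) -> Structure:
    """Two copies of a pseudo-domain at a prescribed minimum surface gap.

    The second copy is translated along +x until the smallest
    atom-surface-to-atom-surface distance (vdW radii subtracted) equals
    ``separation``; separation 0 means just touching.
    """
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    coords = _subunit_coords(atoms_per_body, seed)
    names = _pseudo_sequence(atoms_per_body, seed)
    r = vdw_radius("C")

    def min_gap(shift: float) -> float:
        moved = coords + np.array([shift, 0.0, 0.0])
        d = np.linalg.norm(coords[:, None, :] - moved[None, :, :], axis=2)
        return float(d.min()) - 2.0 * r

    lo, hi = 0.0, 4.0 * (np.abs(coords).max() + separation + 2 * r)
    while min_gap(hi) < separation:
        hi *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if min_gap(mid) < separation:
            lo = mid
        else:
            hi = mid
    shift = 0.5 * (lo + hi)
    moved = coords + np.array([shift, 0.0, 0.0])
    return _structure_from_chains([coords, moved], names,
                                  f"two-body-sep{separation:g}")
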