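"""Protofilament curvature and motif-displacement analysis.

Measures the rotation relating consecutive tubulin subunits along a
protofilament by Calpha superposition (the "total" curvature angle),
splits it into bend (perpendicular to the filament axis) and twist (about
the axis) by an exact swing-twist decomposition, extends protofilaments by
repeated application of the dimer-to-dimer transform, and quantifies motif
movement (RMSD / maximum Calpha displacement) between structures after a
frame superposition that excludes the motif itself.

Conventions
-----------
* The headline curvature number is the TOTAL rotation angle of the
  subunit-to-subunit superposition transform; bend and twist are
  supplementary components.
* The default decomposition axis at each interface is the local rise
  direction (unit vector between consecutive subunit centroids); a global
  least-squares filament axis is available as an alternative.
* ``rise`` in a :class:`BendReport` is the centroid step projected on the
  decomposition axis; the screw translation (translation along the
  rotation axis itself) is reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import AtomSet, Selection, Structure, select, Chain, Residue, Atom
from .superpose import (
    AxisAngle,
    CorrespondenceMap,
    RigidTransform,
    align_sequences,
    axis_angle,
    iterative_superpose,
    kabsch,
)

__all__ = [
    "SubunitModel",
    "ProtofilamentModel",
    "BendReport",
    "MotifComparison",
    "subunit_rotation",
    "filament_axis",
    "decompose_bend_twist",
    "extend_protofilament",
    "motif_rmsd",
    "helix_rotation",
    "curvature_profile",
]


@dataclass
class SubunitModel:
    """One rigid subunit of a protofilament model."""

    role: str  # alpha | beta | kinesin | darpin | pseudo
    chain_id: str
    core_selection: Selection | None = None

    def selection(self) -> Selection:
        if self.core_selection is not None:
            return self.core_selection
        return Selection(self.chain_id, None, atom_names=("CA",))


@dataclass
class ProtofilamentModel:
    """Ordered subunits, minus to plus end (alpha1, beta1, alpha2, beta2
    for a two-dimer tubulin complex)."""

    subunits: list[SubunitModel]

    def __post_init__(self) -> None:
        if len(self.subunits) < 2:
            raise ValueError("a protofilament model needs at least 2 subunits")
        tub = {"alpha", "beta"}
        for a, b in zip(self.subunits, self.subunits[1:]):
            if a.role in tub and b.role in tub and a.role == b.role:
                raise ValueError("tubulin subunit roles must alternate alpha/beta")

    @classmethod
    def from_chains(
        cls, chain_ids: Sequence[str], roles: Sequence[str] | None = None
    ) -> "ProtofilamentModel":
        if roles is None:
            roles = ["alpha" if i % 2 == 0 else "beta" for i in range(len(chain_ids))]
        return cls([SubunitModel(r, c) for r, c in zip(roles, chain_ids)])


@dataclass
class BendReport:
    """Per-interface curvature record."""

    pair_label: str
    total_angle: float  # degrees
    bend_component: float  # degrees, about an axis perpendicular to the reference
    twist_component: float  # degrees, about the reference axis
    rotation_axis: np.ndarray  # unit vector of the total rotation
    rise: float  # A, centroid step along the decomposition axis
    screw_translation: float  # A, translation along the rotation axis
    pairs_used: int
    rmsd: float  # A, of the superposition

    def to_dict(self) -> dict:
        return {
            "pair_label": self.pair_label,
            "total_angle_deg": self.total_angle,
            "bend_deg": self.bend_component,
            "twist_deg": self.twist_component,
            "rotation_axis": [float(x) for x in self.rotation_axis],
            "rise_A": self.rise,
            "screw_translation_A": self.screw_translation,
            "pairs_used": self.pairs_used,
            "rmsd_A": self.rmsd,
        }


@dataclass
class MotifComparison:
    """Motif displacement between two structures after frame superposition."""

    rmsd: float
    max_displacement: float
    per_residue_displacements: list[tuple[int, float]] = field(default_factory=list)
    frame_rmsd: float = 0.0
    frame_pairs_used: int = 0

    def to_dict(self) -> dict:
        return {
            "motif_rmsd_A": self.rmsd,
            "max_displacement_A": self.max_displacement,
            "per_residue": [[int(n), float(d)] for n, d in self.per_residue_displacements],
            "frame_rmsd_A": self.frame_rmsd,
            "frame_pairs_used": self.frame_pairs_used,
        }


def _ca_records(structure: Structure, selection: Selection):
    """Residue numbers, Calpha coordinates and one-letter sequence for the
    selected residues that actually carry a CA atom, in chain order."""
    sel = Selection(selection.chain_id, selection.residue_ranges, atom_names=("CA",))
    atoms = select(structure, sel)
    numbers = [a.residue_number for a in atoms]
    coords = atoms.positions
    chain = structure.chain(selection.chain_id)
    one = {}
    for r in chain.residues:
        one[(r.number, r.insertion_code)] = r.one_letter()
    seq = "".join(one.get((a.residue_number, a.insertion_code), "X") for a in atoms)
    return numbers, coords, seq


def _paired_coords(
    structure_a: Structure,
    sel_a: Selection,
    structure_b: Structure,
    sel_b: Selection,
) -> tuple[np.ndarray, np.ndarray, CorrespondenceMap, list[tuple[int, int]]]:
    """Correspondence-matched Calpha coordinate pairs between two selections.

    Identical sequences pair one-to-one; homologous ones go through a
    global sequence alignment.  Returns (P, Q, map, residue-number pairs).
    """
    num_a, P, seq_a = _ca_records(structure_a, sel_a)
    num_b, Q, seq_b = _ca_records(structure_b, sel_b)
    if len(seq_a) == 0 or len(seq_b) == 0:
        raise ValueError("empty Calpha selection; cannot build correspondence")
    cmap = align_sequences(seq_a, seq_b)
    idx_a = [i for i, _ in cmap.pairs]
    idx_b = [j for _, j in cmap.pairs]
    res_pairs = [(num_a[i], num_b[j]) for i, j in cmap.pairs]
    return P[idx_a], Q[idx_b], cmap, res_pairs


def decompose_bend_twist(
    aa: AxisAngle, reference_axis: np.ndarray
) -> tuple[float, float]:
    """Exact swing-twist split of a rotation about a reference axis.

    The rotation is written as swing . twist where twist is a rotation
    about ``reference_axis`` and swing is about an axis perpendicular to
    it; both angles are returned in degrees as magnitudes (bend, twist).
    Recomposition reproduces the input rotation to machine precision.
    """
    a = np.asarray(reference_axis, dtype=float)
    norm = np.linalg.norm(a)
    if not np.isclose(norm, 1.0, atol=1e-6):
        raise ValueError("reference axis must be a unit vector")
    a = a / norm
    if aa.degenerate or aa.angle == 0.0:
        return 0.0, 0.0
    q = Rotation.from_matrix(aa.to_rotation_matrix()).as_quat()  # (x, y, z, w)
    v, w = q[:3], q[3]
    proj = float(v @ a)
    twist_q = np.array([*(proj * a), w])
    n = np.linalg.norm(twist_q)
    if n < 1e-12:
        # 180 deg rotation about an axis exactly perpendicular to the
        # reference: pure swing
        return float(aa.angle), 0.0
    twist_q /= n
    twist = 2.0 * np.arctan2(np.linalg.norm(twist_q[:3]), abs(twist_q[3]))
    twist_rot = Rotation.from_quat(twist_q)
    swing_rot = Rotation.from_quat(q) * twist_rot.inv()
    swing_q = swing_rot.as_quat()
    bend = 2.0 * np.arctan2(np.linalg.norm(swing_q[:3]), abs(swing_q[3]))
    return float(np.rad2deg(bend)), float(np.rad2deg(twist))


def swing_twist_matrices(
    rotation: np.ndarray, reference_axis: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Return (swing, twist) rotation matrices with rotation = swing @ twist."""
    a = np.asarray(reference_axis, dtype=float)
    a = a / np.linalg.norm(a)
    q = Rotation.from_matrix(rotation).as_quat()
    v, w = q[:3], q[3]
    proj = float(v @ a)
    twist_q = np.array([*(proj * a), w])
    n = np.linalg.norm(twist_q)
    if n < 1e-12:
        return rotation.copy(), np.eye(3)
    twist_q /= n
    twist_rot = Rotation.from_quat(twist_q)
    swing_rot = Rotation.from_quat(q) * twist_rot.inv()
    return swing_rot.as_matrix(), twist_rot.as_matrix()


def filament_axis(structure: Structure, model: ProtofilamentModel) -> np.ndarray:
    """Least-squares line direction through subunit Calpha centroids,
    oriented from minus end (first subunit) to plus end (last)."""
    centroids = np.array(
        [select(structure, su.selection()).centroid() for su in model.subunits]
    )
    centered = centroids - centroids.mean(axis=0)
    if np.allclose(centered, 0.0, atol=1e-9):
        raise ValueError("subunit centroids are coincident; no filament axis")
    _, _, Vt = np.linalg.svd(centered)
    axis = Vt[0]
    if axis @ (centroids[-1] - centroids[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def subunit_rotation(
    structure: Structure,
    su_i: SubunitModel,
    su_j: SubunitModel,
    reference_axis: np.ndarray | None = None,
    max_cycles: int = 5,
    reject_factor: float = 2.0,
    pair_label: str | None = None,
    structure_j: Structure | None = None,
) -> BendReport:
    """Rotation relating subunit i to subunit j by Calpha superposition.

    Builds a residue correspondence between the two core selections,
    superposes subunit i onto subunit j (iterative outlier rejection), and
    reports the axis-angle of the resulting transform.  The bend/twist
    split uses ``reference_axis``, defaulting to the local rise direction
    (the unit centroid-to-centroid vector).
    """
    st_j = structure_j if structure_j is not None else structure
    P, Q, cmap, _ = _paired_coords(structure, su_i.selection(), st_j, su_j.selection())
    if len(P) < 3:
        raise ValueError("fewer than 3 corresponding Calpha pairs")
    transform, rmsd, n_used = iterative_superpose(P, Q, max_cycles, reject_factor)
    aa = axis_angle(transform)
    ci = select(structure, su_i.selection()).centroid()
    cj = select(st_j, su_j.selection()).centroid()
    step = cj - ci
    step_norm = np.linalg.norm(step)
    if reference_axis is None:
        if step_norm < 1e-9:
            reference_axis = np.array([0.0, 0.0, 1.0])
        else:
            reference_axis = step / step_norm
    reference_axis = np.asarray(reference_axis, dtype=float)
    reference_axis = reference_axis / np.linalg.norm(reference_axis)
    bend, twist = decompose_bend_twist(aa, reference_axis)
    return BendReport(
        pair_label=pair_label or f"{su_i.chain_id}-{su_j.chain_id}",
        total_angle=aa.angle,
        bend_component=bend,
        twist_component=twist,
        rotation_axis=aa.axis,
        rise=float(step @ reference_axis),
        screw_translation=aa.screw_translation,
        pairs_used=n_used,
        rmsd=rmsd,
    )


def curvature_profile(
    structure: Structure,
    model: ProtofilamentModel,
    axis_mode: Literal["local", "global"] = "local",
    max_cycles: int = 5,
    reject_factor: float = 2.0,
) -> list[BendReport]:
    """One :class:`BendReport` per consecutive subunit pair, labelled
    intra/inter by dimer boundaries (alpha->beta is intra-dimer,
    beta->alpha is the inter-dimer interface)."""
    ref = filament_axis(structure, model) if axis_mode == "global" else None
    reports: list[BendReport] = []
    for k, (si, sj) in enumerate(zip(model.subunits, model.subunits[1:])):
        if si.role == "alpha" and sj.role == "beta":
            kind = "intra"
        elif si.role == "beta" and sj.role == "alpha":
            kind = "inter"
        else:
            kind = "pair"
        label = f"{si.role}{k // 2 + 1}-{sj.role}{(k + 1) // 2 + 1} {kind}" \
            if si.role in ("alpha", "beta") else f"{si.chain_id}-{sj.chain_id} {kind}"
        reports.append(
            subunit_rotation(
                structure, si, sj,
                reference_axis=ref,
                max_cycles=max_cycles,
                reject_factor=reject_factor,
                pair_label=label,
            )
        )
    return reports


_CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def extend_protofilament(
    structure: Structure, model: ProtofilamentModel, n_copies: int
) -> Structure:
    """Append ``n_copies`` further dimer copies along the protofilament.

    The rigid transform mapping dimer 1 (first two subunits) onto dimer 2
    (next two) is computed over their concatenated matched Calpha sets and
    applied iteratively to the last dimer; appended chains get fresh ids.
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    if len(model.subunits) < 4:
        raise ValueError("need at least two dimers (4 subunits) to extend")
    d1 = model.subunits[0:2]
    d2 = model.subunits[2:4]
    Ps, Qs = [], []
    for si, sj in zip(d1, d2):
        P, Q, _, _ = _paired_coords(structure, si.selection(), structure, sj.selection())
        Ps.append(P)
        Qs.append(Q)
    transform, _ = kabsch(np.vstack(Ps), np.vstack(Qs))

    out = structure.copy()
    used = {c.chain_id for c in out.chains}
    fresh = (c for c in _CHAIN_ALPHABET if c not in used)

    seed_ids = [su.chain_id for su in d2]
    prev_chains = [out.chain(cid) for cid in seed_ids]
    for _ in range(n_copies):
        new_chains = []
        for ch in prev_chains:
            try:
                new_id = next(fresh)
            except StopIteration as exc:
                raise ValueError("ran out of chain identifiers") from exc
            nc = Chain(chain_id=new_id)
            for res in ch.residues:
                nr = Residue(res.name, res.number, res.insertion_code,
                             is_polymer=res.is_polymer)
                for a in res.atoms:
                    nr.atoms.append(
                        Atom(
                            serial=a.serial,
                            name=a.name,
                            element=a.element,
                            altloc=a.altloc,
                            residue_name=a.residue_name,
                            chain_id=new_id,
                            residue_number=a.residue_number,
                            insertion_code=a.insertion_code,
                            position=transform.apply(a.position),
                            occupancy=a.occupancy,
                            b_factor=a.b_factor,
                        )
                    )
                nc.residues.append(nr)
            out.chains.append(nc)
            new_chains.append(nc)
        prev_chains = new_chains
    return out


def motif_rmsd(
    struct_a: Structure,
    struct_b: Structure,
    frame: tuple[Selection, Selection],
    motif: tuple[Selection, Selection],
    max_cycles: int = 5,
    reject_factor: float = 2.0,
) -> MotifComparison:
    """Motif RMSD and maximum Calpha displacement after frame superposition.

    Structure B is superposed onto A over the frame Calpha pairs; motif
    displacements are then measured without refitting.  The caller is
    responsible for excluding the motif from the frame selection.
    """
    Pf, Qf, _, _ = _paired_coords(struct_a, frame[0], struct_b, frame[1])
    if len(Pf) < 3:
        raise ValueError("frame selection yields fewer than 3 Calpha pairs")
    # transform maps B coordinates into A's frame
    t_b_to_a, frame_rmsd, n_used = iterative_superpose(Qf, Pf, max_cycles, reject_factor)
    Pm, Qm, _, res_pairs = _paired_coords(struct_a, motif[0], struct_b, motif[1])
    if len(Pm) == 0:
        raise ValueError("motif selection yields no corresponding Calpha pairs")
    moved = t_b_to_a.apply(Qm)
    disp = np.linalg.norm(Pm - moved, axis=1)
    return MotifComparison(
        rmsd=float(np.sqrt(np.mean(disp**2))),
        max_displacement=float(disp.max()),
        per_residue_displacements=[(ra, float(d)) for (ra, _), d in zip(res_pairs, disp)],
        frame_rmsd=frame_rmsd,
        frame_pairs_used=n_used,
    )


def helix_rotation(
    struct_a: Structure,
    struct_b: Structure,
    frame: tuple[Selection, Selection],
    helices: tuple[Selection, Selection],
    max_cycles: int = 5,
    reject_factor: float = 2.0,
) -> float:
    """Rotation angle (degrees) of a helix group between two structures
    after superposing on a reference frame (e.g. the P-loop).

    B is brought into A's frame; the rigid transform best mapping A's
    helix Calpha set onto B's (now frame-aligned) is computed and its
    rotation angle returned.
    """
    Pf, Qf, _, _ = _paired_coords(struct_a, frame[0], struct_b, frame[1])
    if len(Pf) < 3:
        raise ValueError("frame selection yields fewer than 3 Calpha pairs")
    t_b_to_a, _, _ = iterative_superpose(Qf, Pf, max_cycles, reject_factor)
    Ph, Qh, _, _ = _paired_coords(struct_a, helices[0], struct_b, helices[1])
    if len(Ph) < 3:
        raise ValueError("helix selection yields fewer than 3 Calpha pairs")
    transform, _ = kabsch(Ph, t_b_to_a.apply(Qh))
    return axis_angle(transform).angle
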