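"""Rigid-body superposition and axis-angle analysis.

Weighted Kabsch superposition (SVD, reflection-corrected), axis-angle /
screw decomposition of the resulting transform, sequence-based residue
correspondence between homologous chains, and iterative outlier-rejecting
superposition in the style of interactive-graphics ``align`` commands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "RigidTransform",
    "AxisAngle",
    "CorrespondenceMap",
    "kabsch",
    "axis_angle",
    "align_sequences",
    "iterative_superpose",
]


@dataclass
class RigidTransform:
    """A proper rotation plus translation: ``x -> R @ x + t``."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation is improper (det < 0)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self . other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


@dataclass
class AxisAngle:
    """Axis-angle (screw) form of a rigid transform.

    ``screw_translation`` is the component of the translation along the
    rotation axis (the rise, for a filament interface).  ``degenerate`` is
    set when the rotation is (numerically) the identity, in which case the
    axis is the zero vector.
    """

    axis: np.ndarray
    angle: float  # degrees, in [0, 180]
    screw_translation: float = 0.0
    degenerate: bool = False

    def to_rotation_matrix(self) -> np.ndarray:
        if self.degenerate:
            return np.eye(3)
        return _rodrigues(self.axis, np.deg2rad(self.angle))


def _rodrigues(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def kabsch(
    P: np.ndarray, Q: np.ndarray, weights: np.ndarray | None = None
) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of paired point sets.

    Returns the proper-rotation transform minimizing the weighted RMSD of
    ``R @ P + t`` against ``Q``, and that RMSD (A).  Reflections are
    excluded by flipping the smallest singular vector when needed.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (N, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 point pairs, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be nonnegative, not all zero")
    wsum = w.sum()
    pc = (w[:, None] * P).sum(axis=0) / wsum
    qc = (w[:, None] * Q).sum(axis=0) / wsum
    P0 = P - pc
    Q0 = Q - qc
    H = (w[:, None] * P0).T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # degenerate (collinear/coincident) point sets leave the rotation
    # underdetermined about the degenerate direction
    if S[1] < 1e-10 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear or coincident) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((w * (diff**2).sum(axis=1)).sum() / wsum))
    return RigidTransform(R, t), rmsd


def axis_angle(transform: RigidTransform) -> AxisAngle:
    """Axis-angle decomposition of a rigid transform.

    The angle equals ``arccos((tr R - 1)/2)`` in degrees (evaluated via
    atan2 for numerical stability), oriented into [0, 180] by the choice
    of axis sign.  Near 180 deg the skew part of R vanishes, so the axis
    is recovered from the dominant column of R + I.
    """
    R = transform.rotation
    vec = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    sin_theta = np.linalg.norm(vec) / 2.0
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    # atan2 keeps full precision for small angles, unlike arccos
    theta = float(np.arctan2(sin_theta, cos_theta))
    if theta < 1e-12:
        return AxisAngle(np.zeros(3), 0.0, 0.0, degenerate=True)
    if theta < np.pi - 1e-6:
        axis = vec / (2.0 * sin_theta)
    else:
        # angle ~= 180: axis from the dominant column of R + I
        M = R + np.eye(3)
        col = int(np.argmax(np.linalg.norm(M, axis=0)))
        axis = M[:, col]
    axis = axis / np.linalg.norm(axis)
    screw = float(axis @ transform.translation)
    return AxisAngle(axis, float(np.rad2deg(theta)), screw)


@dataclass
class CorrespondenceMap:
    """Matched residue-index pairs between two chains (0-based indices into
    each chain's polymer residue list); strictly increasing in both."""

    pairs: list[tuple[int, int]] = field(default_factory=list)
    identity_fraction: float = 0.0
    method: str = "sequence"  # "sequence" | "one-to-one"

    def __post_init__(self) -> None:
        prev_a, prev_b = -1, -1
        for a, b in self.pairs:
            if a <= prev_a or b <= prev_b:
                raise ValueError("correspondence pairs must be strictly increasing")
            prev_a, prev_b = a, b

    def __len__(self) -> int:
        return len(self.pairs)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    # BLOSUM62 lacks some one-letter codes we emit for nonstandard residues
    aligner.wildcard = "X"
    return aligner


def align_sequences(seqA: str, seqB: str) -> CorrespondenceMap:
    """Global alignment (BLOSUM62, affine gaps) returning matched residue
    pairs only.  Identical sequences short-circuit to one-to-one pairing."""
    if not seqA or not seqB:
        raise ValueError("sequences must be non-empty")
    if seqA == seqB:
        pairs = [(i, i) for i in range(len(seqA))]
        return CorrespondenceMap(pairs, 1.0, method="one-to-one")
    aln = _make_aligner().align(seqA, seqB)[0]
    pairs: list[tuple[int, int]] = []
    n_ident = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((i, j))
            if seqA[i] == seqB[j]:
                n_ident += 1
    ident = n_ident / len(pairs) if pairs else 0.0
    return CorrespondenceMap(pairs, ident, method="sequence")


def iterative_superpose(
    P: np.ndarray,
    Q: np.ndarray,
    max_cycles: int = 5,
    reject_factor: float = 2.0,
) -> tuple[RigidTransform, float, int]:
    """Kabsch with iterative outlier rejection.

    Repeats {fit; drop pairs whose residual exceeds ``reject_factor`` times
    the current RMSD} until no pair is dropped or ``max_cycles`` is reached.
    Returns the final transform, its RMSD over surviving pairs, and the
    number of pairs used.  ``reject_factor = inf`` degenerates to a single
    Kabsch call.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    keep = np.ones(P.shape[0], dtype=bool)
    transform, rmsd = kabsch(P, Q)
    if not np.isfinite(reject_factor):
        return transform, rmsd, P.shape[0]
    for _ in range(max_cycles):
        residuals = np.linalg.norm(transform.apply(P[keep]) - Q[keep], axis=1)
        if rmsd <= 1e-12:
            break
        bad = residuals > reject_factor * rmsd
        if not bad.any():
            break
        new_keep = keep.copy()
        new_keep[np.flatnonzero(keep)[bad]] = False
        if new_keep.sum() < 3:
            raise ValueError("fewer than 3 pairs survive outlier rejection")
        keep = new_keep
        transform, rmsd = kabsch(P[keep], Q[keep])
    return transform, rmsd, int(keep.sum())
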