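"""Optimal superposition and screw-axis geometry between rigid bodies.

Superposition is the least-squares proper rotation + translation (the
Kabsch algorithm, via SVD with a reflection-sign correction).  A relative
placement of one rigid body with respect to another
is summarized as a screw axis: the unique line about which the placement is
a rotation plus a translation along the line (Chasles' theorem).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GeometryError, NoRotationError
from .structio import ResidueSelection, StructureModel

_ATOM_SETS = ("CA", "all_heavy")

#: rotations with |rotvec| below this are treated as the identity
IDENTITY_ANGLE_RAD = 1e-12


@dataclass(frozen=True)
class RigidTransform:
    """x -> R x + t with R a proper rotation (det = +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise GeometryError(f"rotation determinant {np.linalg.det(R):.12f}"
                                " != +1 (improper or non-orthogonal)")
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-9:
            raise GeometryError("rotation matrix is not orthogonal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        pts = np.asarray(coords, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self ∘ other)(x) = self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation
                              + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


class ScrewAxis:
    """Axis-angle(-translation) summary of a rigid placement.

    ``angle_deg`` is the rotation magnitude in (0, 180]; ``direction`` the
    unit axis vector and ``point`` a point on the axis, both raising
    :class:`NoRotationError` for the identity placement.
    """

    def __init__(self, angle_deg: float,
                 direction: Optional[np.ndarray],
                 point: Optional[np.ndarray],
                 translation_along_axis: float) -> None:
        self.angle_deg = float(angle_deg)
        self.translation_along_axis = float(translation_along_axis)
        self._direction = (None if direction is None
                           else np.asarray(direction, dtype=float) /
                           np.linalg.norm(direction))
        self._point = None if point is None else np.asarray(point, dtype=float)

    @property
    def is_identity(self) -> bool:
        return self._direction is None

    @property
    def direction(self) -> np.ndarray:
        if self._direction is None:
            raise NoRotationError("no rotation: axis direction is undefined")
        return self._direction

    @property
    def point(self) -> np.ndarray:
        if self._point is None:
            raise NoRotationError("no rotation: axis point is undefined")
        return self._point

    def __repr__(self) -> str:
        if self.is_identity:
            return "ScrewAxis(identity)"
        d = ", ".join(f"{x:.4f}" for x in self.direction)
        return (f"ScrewAxis(angle={self.angle_deg:.3f} deg, direction=({d}), "
                f"axial translation={self.translation_along_axis:.3f} A)")


# ---------------------------------------------------------------------------
# Coordinate-level operations
# ---------------------------------------------------------------------------

def _check_nondegenerate(pts: np.ndarray) -> None:
    if len(pts) < 3:
        raise GeometryError(f"need >=3 matched atom pairs, got {len(pts)}")
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise GeometryError("matched atoms are collinear or coincident")


def superpose_coords(mobile: np.ndarray, reference: np.ndarray
                     ) -> Tuple[RigidTransform, float]:
    """Least-squares rigid fit of *mobile* onto *reference* (paired rows).

    Kabsch algorithm: SVD of the covariance of the centered point sets,
    with the sign of the smallest singular direction flipped when needed so
    the result is a proper rotation (never a reflection).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape:
        raise GeometryError(f"point sets differ in shape {P.shape} vs {Q.shape}")
    _check_nondegenerate(P)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    U, _, Vt = np.linalg.svd(Pc.T @ Qc)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    resid = Qc - Pc @ R.T
    rmsd = float(np.sqrt((resid * resid).sum(axis=1).mean()))
    return RigidTransform(R, t), rmsd


def rmsd_between(a: np.ndarray, b: np.ndarray) -> float:
    d = np.asarray(a) - np.asarray(b)
    return float(np.sqrt((d * d).sum(axis=1).mean()))


# ---------------------------------------------------------------------------
# Model-level pairing
# ---------------------------------------------------------------------------

def paired_coords(mobile: StructureModel, reference: StructureModel,
                  selection: ResidueSelection, atom_set: str = "CA",
                  on_mismatch: str = "error",
                  selection_reference: Optional[ResidueSelection] = None,
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Matched coordinate arrays over a selection of both models.

    Residues are paired by (author number, insertion code, atom name); the
    chain id is taken from each model's own selection, so the same numbering
    can be matched across differently named chains (``selection_reference``).
    ``on_mismatch='error'`` reports unmatched residues; ``'intersect'`` keeps
    the common subset, which is the practical choice when comparing deposited
    structures with different modelled termini.
    """
    if atom_set not in _ATOM_SETS:
        raise GeometryError(f"atom_set must be one of {_ATOM_SETS}")
    sel_ref = selection_reference if selection_reference is not None else selection

    def atom_map(model: StructureModel, sel: ResidueSelection):
        amap = {}
        for chain, res in sel.resolve(model):
            for atom in res.atoms:
                if atom_set == "CA" and atom.name != "CA":
                    continue
                if atom_set == "all_heavy" and atom.is_hydrogen:
                    continue
                amap[(res.seqid, res.icode, atom.name)] = atom.coord
        return amap

    map_m = atom_map(mobile, selection)
    map_r = atom_map(reference, sel_ref)
    common = sorted(set(map_m) & set(map_r))
    if on_mismatch == "error":
        miss = sorted({(k[0], k[1]) for k in
                       set(map_m).symmetric_difference(map_r)})
        if miss:
            raise GeometryError(
                "mismatched atom sets between models; unmatched residues: "
                + ", ".join(f"{n}{i}" for n, i in miss[:20])
                + ("..." if len(miss) > 20 else ""))
    elif on_mismatch != "intersect":
        raise ValueError("on_mismatch must be 'error' or 'intersect'")
    if not common:
        raise GeometryError("no matched atoms between the two selections")
    P = np.vstack([map_m[k] for k in common])
    Q = np.vstack([map_r[k] for k in common])
    return P, Q


def superpose(mobile: StructureModel, reference: StructureModel,
              selection: ResidueSelection, atom_set: str = "CA",
              on_mismatch: str = "error",
              selection_reference: Optional[ResidueSelection] = None,
              ) -> Tuple[RigidTransform, float]:
    """Optimal rigid fit of *mobile* onto *reference* over a selection.

    Returns the proper rotation + translation and the post-fit RMSD (A).
    """
    P, Q = paired_coords(mobile, reference, selection, atom_set,
                         on_mismatch, selection_reference)
    return superpose_coords(P, Q)


# ---------------------------------------------------------------------------
# Screw decomposition
# ---------------------------------------------------------------------------

def rotation_to_axis_angle(t: RigidTransform,
                           reference_point: Optional[np.ndarray] = None
                           ) -> ScrewAxis:
    """Screw decomposition of a rigid transform.

    The axis point is the minimum-norm point of the screw line, or the point
    on the line nearest ``reference_point`` when given.  The identity
    rotation yields a flagged no-rotation result.
    """
    rotvec = Rotation.from_matrix(t.rotation).as_rotvec()
    angle = np.linalg.norm(rotvec)
    if angle <= IDENTITY_ANGLE_RAD:
        return ScrewAxis(0.0, None, None,
                         float(np.linalg.norm(t.translation)))
    d = rotvec / angle
    v = t.translation
    axial = float(v @ d)
    v_perp = v - axial * d
    # point p on the axis satisfies (I - R) p = v_perp; the system is rank 2
    p, *_ = np.linalg.lstsq(np.eye(3) - t.rotation, v_perp, rcond=None)
    if reference_point is not None:
        ref = np.asarray(reference_point, dtype=float)
        p = p + ((ref - p) @ d) * d
    return ScrewAxis(np.degrees(angle), d, p, axial)


def screw_to_transform(axis: ScrewAxis) -> RigidTransform:
    """Recompose a screw axis into the rigid transform it describes."""
    if axis.is_identity:
        return RigidTransform.identity()
    R = Rotation.from_rotvec(np.radians(axis.angle_deg)
                             * axis.direction).as_matrix()
    p = axis.point
    t = p - R @ p + axis.translation_along_axis * axis.direction
    return RigidTransform(R, t)


def screw_axis_between(conf_a: StructureModel, conf_b: StructureModel,
                       fixed_body: ResidueSelection,
                       moving_body: ResidueSelection,
                       atom_set: str = "CA",
                       on_mismatch: str = "intersect") -> ScrewAxis:
    """Inter-domain rotation axis between two conformers.

    Conformer *b* is first superposed onto conformer *a* over the fixed
    body; the residual rigid transform carrying *a*'s moving body onto the
    fixed-body-aligned copy of *b*'s moving body is then screw-decomposed.
    The reported axis point is the point of the screw line nearest the
    moving body's centroid, so a rendered axis passes through the molecule.
    """
    t_fix, _ = superpose(conf_b, conf_a, fixed_body, atom_set, on_mismatch)
    P_mov, Q_mov = paired_coords(conf_a, conf_b, moving_body, atom_set,
                                 on_mismatch)
    Q_aligned = t_fix.apply(Q_mov)
    t_res, _ = superpose_coords(P_mov, Q_aligned)
    return rotation_to_axis_angle(t_res, reference_point=P_mov.mean(axis=0))


# ---------------------------------------------------------------------------
# Axis visualization helper
# ---------------------------------------------------------------------------

def axis_pseudoatoms(axis: ScrewAxis, half_length: float = 30.0
                     ) -> StructureModel:
    """A two-pseudoatom model tracing a screw axis, for visualization."""
    from .structio import Atom, Chain, Residue  # local to avoid clutter

    p0 = axis.point - half_length * axis.direction
    p1 = axis.point + half_length * axis.direction
    chain = Chain(id="X", residues=[
        Residue(name="AXS", seqid=1, atoms=[Atom("C1", "C", p0, is_het=True)],
                is_het=True),
        Residue(name="AXS", seqid=2, atoms=[Atom("C2", "C", p1, is_het=True)],
                is_het=True),
    ])
    return StructureModel(id="axis", chains=[chain])
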