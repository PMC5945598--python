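"""Helical symmetry: filament construction, axis fitting, twist conversions.

An actin-like filament is a one-start helix: subunit k is the protomer
rotated by k x (genetic twist) about the filament axis and translated by
k x rise along it.  The genetic twist is signed with the right-hand rule
about the rise direction, so a negative twist (e.g. -162.1 deg) describes a
left-handed one-start helix.  Adjacent subunits on one long-pitch strand are
two steps apart along the one-start helix, giving the strand rotation
delta-phi = 2 x twist + 360, normalized into (-180, 180].
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GeometryError, StructureError
from .geometry import RigidTransform, paired_coords, superpose_coords
from .structio import ResidueSelection, StructureModel

#: single-character chain ids available for filament subunits (PDB limit)
CHAIN_ALPHABET = (string.ascii_uppercase + string.ascii_lowercase
                  + string.digits)

_ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                "P": 30.974, "S": 32.06, "MG": 24.305, "CA": 40.078,
                "K": 39.098, "NA": 22.990, "CL": 35.45, "FE": 55.845,
                "ZN": 65.38}


def normalize_angle(deg: float) -> float:
    """Map an angle in degrees into (-180, 180]."""
    r = deg % 360.0
    if r > 180.0:
        r -= 360.0
    return r


@dataclass(frozen=True)
class HelicalSymmetry:
    """Genetic twist (deg/subunit, signed), rise (A/subunit) and axis."""

    genetic_twist_deg: float
    rise_ang: float
    axis_direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    axis_point: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        d = np.asarray(self.axis_direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise GeometryError("axis direction must be non-zero")
        object.__setattr__(self, "axis_direction", d / n)
        object.__setattr__(self, "axis_point",
                           np.asarray(self.axis_point, dtype=float).reshape(3))
        if self.rise_ang <= 0:
            raise GeometryError("helical rise must be positive")
        if not (-180.0 < self.genetic_twist_deg <= 180.0):
            raise GeometryError("genetic twist must lie in (-180, 180]")

    def step_transform(self, k: int = 1) -> RigidTransform:
        """Rigid transform carrying subunit 0 onto subunit k."""
        R = Rotation.from_rotvec(
            np.radians(k * self.genetic_twist_deg) * self.axis_direction
        ).as_matrix()
        p = self.axis_point
        t = p - R @ p + k * self.rise_ang * self.axis_direction
        return RigidTransform(R, t)


@dataclass(frozen=True)
class StrandRotation:
    """Rotation angle between adjacent subunits on one long-pitch strand."""

    delta_phi_deg: float


@dataclass
class HelicalFit:
    """Fitted symmetry plus per-step residuals from consecutive subunits."""

    symmetry: HelicalSymmetry
    step_twists_deg: List[float]
    step_rises_ang: List[float]
    step_rmsds: List[float]

    @property
    def twist_spread_deg(self) -> float:
        return float(np.ptp(self.step_twists_deg))


def strand_rotation_from_genetic(genetic_twist_deg: float) -> StrandRotation:
    """Convert a one-start (genetic) twist to the long-pitch strand rotation.

    delta-phi = normalize(2 x twist + 360) into (-180, 180]; e.g. a genetic
    twist of -162.1 deg corresponds to delta-phi = 35.8 deg.  The straight
    ladder limit (-180 deg, delta-phi = 0) is admitted.
    """
    if not (-180.0 <= genetic_twist_deg <= 180.0):
        raise GeometryError("genetic twist must lie in [-180, 180]")
    return StrandRotation(normalize_angle(2.0 * genetic_twist_deg + 360.0))


# ---------------------------------------------------------------------------
# Filament construction
# ---------------------------------------------------------------------------

def subunit_chain_ids(n_protomer_chains: int, n_subunits: int
                      ) -> List[List[str]]:
    """Deterministic chain renaming for a built filament.

    Returns, per subunit, the list of new chain ids (one per protomer
    chain), drawn in order from A-Z, a-z, 0-9.
    """
    needed = n_protomer_chains * n_subunits
    if needed > len(CHAIN_ALPHABET):
        raise StructureError(
            f"chain-name exhaustion: {needed} chains needed but only "
            f"{len(CHAIN_ALPHABET)} single-character ids are available")
    it = iter(CHAIN_ALPHABET)
    return [[next(it) for _ in range(n_protomer_chains)]
            for _ in range(n_subunits)]


def build_filament(protomer: StructureModel, sym: HelicalSymmetry,
                   n_subunits: int) -> StructureModel:
    """Generate a helical filament from one protomer.

    Subunit k is the protomer rotated by k x twist about the axis and
    translated by k x rise along it; chains are renamed uniquely per
    subunit.  Subunits at even and odd k form the two long-pitch strands.
    """
    if n_subunits < 1:
        raise StructureError("n_subunits must be >= 1")
    names = subunit_chain_ids(len(protomer.chains), n_subunits)
    out = StructureModel(id=f"{protomer.id}_filament",
                         source_format=protomer.source_format)
    for k in range(n_subunits):
        t = sym.step_transform(k)
        copy = protomer.copy()
        copy.transform(t.rotation, t.translation)
        for chain, new_id in zip(copy.chains, names[k]):
            chain.id = new_id
            out.chains.append(chain)
    return out


# ---------------------------------------------------------------------------
# Axis fitting and measurements
# ---------------------------------------------------------------------------

def _signed_screw(t: RigidTransform) -> Tuple[np.ndarray, float, float,
                                              np.ndarray]:
    """(direction, signed angle deg, rise, axis point) with rise > 0."""
    rotvec = Rotation.from_matrix(t.rotation).as_rotvec()
    angle = np.linalg.norm(rotvec)
    if angle < 1e-12:
        raise GeometryError("consecutive subunits are identically placed: "
                            "no helical step to fit")
    d = rotvec / angle
    rise = float(t.translation @ d)
    if rise < 0:
        d, angle, rise = -d, -angle, -rise
    v_perp = t.translation - (t.translation @ d) * d
    p, *_ = np.linalg.lstsq(np.eye(3) - t.rotation, v_perp, rcond=None)
    return d, float(np.degrees(angle)), rise, p


def fit_helical_axis(filament: StructureModel,
                     subunit_map: Sequence[ResidueSelection],
                     atom_set: str = "CA",
                     angle_spread_warning_deg: float = 5.0) -> HelicalFit:
    """Recover helical symmetry from a filament by consecutive superposition.

    Each subunit k is superposed onto subunit k+1 (matching residues by
    author number across the two selections); the per-step screw transforms
    are averaged into a single twist/rise/axis.  The axis direction is
    oriented so the rise is positive and the twist carries the handedness
    sign.  A spread of per-step twists above ``angle_spread_warning_deg``
    triggers a warning; per-step values are always reported.
    """
    if len(subunit_map) < 3:
        raise GeometryError("helical fit needs >=3 subunits")
    dirs, twists, rises, points, rmsds = [], [], [], [], []
    for k in range(len(subunit_map) - 1):
        P, Q = paired_coords(filament, filament, subunit_map[k], atom_set,
                             on_mismatch="intersect",
                             selection_reference=subunit_map[k + 1])
        t, rmsd = superpose_coords(P, Q)
        d, tw, rise, p = _signed_screw(t)
        if dirs and d @ dirs[0] < 0:  # keep one orientation across steps
            d, tw, rise = -d, -tw, -rise
        dirs.append(d)
        twists.append(normalize_angle(tw))
        rises.append(rise)
        points.append(p)
        rmsds.append(rmsd)
    mean_dir = np.mean(dirs, axis=0)
    mean_dir /= np.linalg.norm(mean_dir)
    mean_rise = float(np.mean(rises))
    if mean_rise < 0:
        mean_dir = -mean_dir
        twists = [normalize_angle(-t) for t in twists]
        rises = [-r for r in rises]
        mean_rise = -mean_rise
    mean_twist = normalize_angle(float(np.mean(twists)))
    spread = float(np.ptp(twists))
    if spread > angle_spread_warning_deg:
        warnings.warn(
            f"inconsistent inter-subunit transforms: twist spread "
            f"{spread:.2f} deg over {len(twists)} steps", stacklevel=2)
    sym = HelicalSymmetry(mean_twist, mean_rise, mean_dir,
                          np.mean(points, axis=0))
    return HelicalFit(sym, twists, rises, rmsds)


def centroid_axis_distance(model: StructureModel,
                           sym: HelicalSymmetry,
                           selection: Optional[ResidueSelection] = None,
                           exclude: Optional[ResidueSelection] = None,
                           ca_only: bool = False,
                           mass_weighted: bool = False) -> float:
    """Perpendicular distance from a selection's centroid to the helix axis.

    The centroid is over non-hydrogen atoms ("center of gravity" of a
    deposited model without hydrogens); CA-only and mass-weighted variants
    are available.  ``exclude`` removes residues (e.g. disordered termini
    and the D-loop, residues 1-6 and 41-49 of actin) before averaging.
    """
    pts, weights = [], []
    for chain, res in model.iter_residues():
        if selection is not None and not selection.contains(chain.id, res.seqid):
            continue
        if exclude is not None and exclude.contains(chain.id, res.seqid):
            continue
        for atom in res.atoms:
            if atom.is_hydrogen:
                continue
            if ca_only and atom.name != "CA":
                continue
            pts.append(atom.coord)
            weights.append(_ATOMIC_MASS.get(atom.element.upper(), 12.0)
                           if mass_weighted else 1.0)
    if not pts:
        raise GeometryError("selection is empty after exclusions")
    centroid = np.average(np.vstack(pts), axis=0, weights=np.array(weights))
    rel = centroid - sym.axis_point
    perp = rel - (rel @ sym.axis_direction) * sym.axis_direction
    return float(np.linalg.norm(perp))
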