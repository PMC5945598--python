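"""Interface and steric-collision detection with van-der-Waals criteria.

Two atoms a, b of different molecules form an interface pair when
d(a, b) < interface_factor x (r_a + r_b) with the default factor 1.1, and a
collision pair when both are non-hydrogen and
d(a, b) < collision_factor x (r_a + r_b) with the default factor 0.5;
both comparisons are strict.  Radii default to the Bondi (1964) table and
are fully overridable.  A k-d tree prunes the pair search; results are
identical to the all-pairs double loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ContactError
from .structio import ResidueKey, StructureModel

#: Bondi (1964) van der Waals radii, A
BONDI_RADII: Dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "MG": 1.73, "NA": 2.27,
    "K": 2.75, "CA": 2.31, "ZN": 1.39, "FE": 2.05, "MN": 2.05,
}


@dataclass(frozen=True)
class ContactConfig:
    """Radii table and the interface/collision distance factors."""

    radii_table: Dict[str, float] = field(
        default_factory=lambda: dict(BONDI_RADII))
    interface_factor: float = 1.1
    collision_factor: float = 0.5
    collision_excludes_hydrogen: bool = True
    default_radius: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.collision_factor < self.interface_factor):
            raise ContactError(
                "factors must satisfy 0 < collision_factor < interface_factor")

    def radius(self, element: str, atom_label: str = "?") -> float:
        r = self.radii_table.get(element.upper())
        if r is None:
            r = self.default_radius
        if r is None:
            raise ContactError(
                f"no van der Waals radius for element '{element}' "
                f"(atom {atom_label}) and no default radius configured")
        return r


@dataclass(frozen=True)
class AtomRef:
    """Identifies one atom: residue key + residue name + atom name."""

    chain: str
    seqid: int
    icode: str
    resname: str
    atom: str
    element: str

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain, self.seqid, self.icode)

    def __str__(self) -> str:
        return f"{self.chain}/{self.resname}{self.seqid}{self.icode}/{self.atom}"


ContactPair = Tuple[AtomRef, AtomRef, float]


@dataclass
class ContactCounts:
    n_interface_pairs: int
    n_collision_pairs: int
    n_colliding_atoms_a: int
    n_colliding_atoms_b: int


@dataclass
class ContactReport:
    """Interface and collision pairs between two molecules."""

    interface_pairs: List[ContactPair]
    collision_pairs: List[ContactPair]

    @property
    def interface_residues_a(self) -> Set[ResidueKey]:
        return {a.residue_key for a, _, _ in self.interface_pairs}

    @property
    def interface_residues_b(self) -> Set[ResidueKey]:
        return {b.residue_key for _, b, _ in self.interface_pairs}

    @property
    def colliding_atoms_a(self) -> Set[AtomRef]:
        return {a for a, _, _ in self.collision_pairs}

    @property
    def colliding_atoms_b(self) -> Set[AtomRef]:
        return {b for _, b, _ in self.collision_pairs}

    @property
    def counts(self) -> ContactCounts:
        return ContactCounts(
            n_interface_pairs=len(self.interface_pairs),
            n_collision_pairs=len(self.collision_pairs),
            n_colliding_atoms_a=len(self.colliding_atoms_a),
            n_colliding_atoms_b=len(self.colliding_atoms_b),
        )

    @property
    def n_colliding_atoms(self) -> int:
        """Distinct colliding atoms over both molecules."""
        c = self.counts
        return c.n_colliding_atoms_a + c.n_colliding_atoms_b


def _flatten(model: StructureModel, config: ContactConfig
             ) -> Tuple[List[AtomRef], np.ndarray, np.ndarray, np.ndarray]:
    refs: List[AtomRef] = []
    coords: List[np.ndarray] = []
    radii: List[float] = []
    is_h: List[bool] = []
    for chain, res in model.iter_residues():
        for atom in res.atoms:
            ref = AtomRef(chain.id, res.seqid, res.icode, res.name,
                          atom.name, atom.element)
            refs.append(ref)
            coords.append(atom.coord)
            radii.append(config.radius(atom.element, str(ref)))
            is_h.append(atom.is_hydrogen)
    if not refs:
        raise ContactError(f"molecule '{model.id}' contains no atoms")
    return refs, np.vstack(coords), np.array(radii), np.array(is_h)


def find_contacts(mol_a: StructureModel, mol_b: StructureModel,
                  config: Optional[ContactConfig] = None) -> ContactReport:
    """All interface and collision atom pairs between two molecules.

    The interface criterion is applied to every atom present; the collision
    criterion only to non-hydrogen pairs (configurable).  A k-d tree on the
    larger molecule prunes candidates; the report equals the exhaustive
    all-pairs result.
    """
    config = config or ContactConfig()
    refs_a, xyz_a, rad_a, h_a = _flatten(mol_a, config)
    refs_b, xyz_b, rad_b, h_b = _flatten(mol_b, config)
    cutoff = config.interface_factor * (rad_a.max() + rad_b.max())
    tree_b = cKDTree(xyz_b)
    neighbor_lists = cKDTree(xyz_a).query_ball_tree(tree_b, cutoff)
    interface: List[ContactPair] = []
    collision: List[ContactPair] = []
    for i, neighbors in enumerate(neighbor_lists):
        for j in sorted(neighbors):
            d = float(np.linalg.norm(xyz_a[i] - xyz_b[j]))
            vdw_sum = rad_a[i] + rad_b[j]
            if d < config.interface_factor * vdw_sum:
                interface.append((refs_a[i], refs_b[j], d))
                if d < config.collision_factor * vdw_sum and not (
                        config.collision_excludes_hydrogen
                        and (h_a[i] or h_b[j])):
                    collision.append((refs_a[i], refs_b[j], d))
    return ContactReport(interface, collision)


def interface_residue_table(report: ContactReport) -> pd.DataFrame:
    """Per-residue rollup of the interface pairs of both molecules.

    One row per participating residue with the number of interface pairs it
    joins and the partner residues on the other molecule.
    """
    rows = []
    for side, take_self, take_other in (
            ("A", lambda p: p[0], lambda p: p[1]),
            ("B", lambda p: p[1], lambda p: p[0])):
        per_res: Dict[ResidueKey, Dict] = {}
        for pair in report.interface_pairs:
            me, other = take_self(pair), take_other(pair)
            entry = per_res.setdefault(me.residue_key, {
                "molecule": side, "chain": me.chain, "residue": me.seqid,
                "icode": me.icode, "resname": me.resname, "n_pairs": 0,
                "partners": set()})
            entry["n_pairs"] += 1
            entry["partners"].add(f"{other.chain}:{other.seqid}{other.icode}")
        rows.extend(per_res.values())
    df = pd.DataFrame(rows, columns=["molecule", "chain", "residue", "icode",
                                     "resname", "n_pairs", "partners"])
    if len(df):
        df["partners"] = df["partners"].map(lambda s: ",".join(sorted(s)))
        df = df.sort_values(["molecule", "chain", "residue", "icode"],
                            ignore_index=True)
    return df


def min_ca_distance(pairs: Sequence[Tuple[ResidueKey, ResidueKey]],
                    model: StructureModel) -> float:
    """Minimum CA-CA distance over a list of residue pairs of one model."""
    if not pairs:
        raise ContactError("empty residue pair list")
    dists = []
    for key_a, key_b in pairs:
        for key in (key_a, key_b):
            res = model.residue(tuple(key))
            if res is None:
                raise ContactError(f"residue {key} not found in model "
                                   f"'{model.id}'")
            if res.ca is None:
                raise ContactError(f"residue {key} has no CA atom")
        ca_a = model.residue(tuple(key_a)).ca.coord
        ca_b = model.residue(tuple(key_b)).ca.coord
        dists.append(float(np.linalg.norm(ca_a - ca_b)))
    return min(dists)
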