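"""Synthetic structures with known ground truth for every pipeline stage.

Three generators emulate the study conditions of the real data:

* a multi-conformer ensemble of a two-domain protein with a planted rigid
  core, a planted hinge rotation (axis + per-conformer angle) and optional
  flexible residues carrying 5x noise — the stand-in for an ensemble of
  actin conformers with two rigid bodies and a disordered loop;
* a helical filament built from a compact protomer by twist/rise, optionally
  decorated with a small cofilin-like chain bridging subunits k and k+2 of
  one strand (placed clear of any van-der-Waals contact);
* a two-chain configuration with exact, requested numbers of interface and
  colliding atom pairs.

Protein geometry is a CA-trace plus one pseudo-side-chain atom per residue:
all downstream analysis is purely coordinate- and element-based, so no
stereochemistry is needed.  Every generator is deterministic in its seed and
returns machine-readable ground truth alongside the coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .contacts import find_contacts
from .errors import FilaxisError
from .helical import HelicalSymmetry, build_filament, subunit_chain_ids
from .structio import (Atom, Chain, Residue, StructureModel, write_structure)

#: default per-conformer hinge angles: eight conformers spanning 0-20 deg
DEFAULT_HINGE_ANGLES = tuple(np.linspace(0.0, 20.0, 8))

#: flexible residues carry this multiple of the baseline coordinate noise
FLEXIBLE_NOISE_FACTOR = 5.0


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise FilaxisError("zero vector cannot be normalized")
    return v / n


def _perpendicular(axis: np.ndarray) -> np.ndarray:
    e = np.array([1.0, 0.0, 0.0])
    if abs(axis @ e) > 0.9:
        e = np.array([0.0, 1.0, 0.0])
    return _unit(e - (e @ axis) * axis)


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    return Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()


def _make_residues(ca_positions: np.ndarray, cb_offsets: np.ndarray,
                   first_seqid: int, resname: str = "ALA") -> List[Residue]:
    residues = []
    for i, (ca, cb_off) in enumerate(zip(ca_positions, cb_offsets)):
        residues.append(Residue(
            name=resname, seqid=first_seqid + i,
            atoms=[Atom("CA", "C", ca.copy()),
                   Atom("CB", "C", (ca + cb_off).copy())]))
    return residues


# ---------------------------------------------------------------------------
# Two-domain hinge ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoDomainSpec:
    """A two-rigid-body protein with a hinge between the bodies.

    Body A (residues 1..n_a) is the fixed rigid core; body B is rotated per
    conformer by ``angles_deg[k]`` about ``hinge_axis`` through the hinge
    point (the origin); flexible residues sit between the bodies and carry
    5x the baseline noise.  ``absent`` optionally removes an inclusive
    residue range from one member, emulating a disordered region that was
    not modelled.
    """

    n_residues_body_a: int = 120
    n_residues_body_b: int = 40
    n_flexible: int = 0
    hinge_axis: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    angles_deg: Tuple[float, ...] = DEFAULT_HINGE_ANGLES
    noise_sd: float = 0.2
    seed: int = 0
    absent: Optional[Mapping[int, Tuple[int, int]]] = None


def make_two_domain_ensemble(spec: TwoDomainSpec
                             ) -> Tuple[List[StructureModel], Dict]:
    """Generate hinge-rotated conformers plus their ground truth.

    Body B residues are kept at a perpendicular distance of at least 12 A
    from the hinge axis, so any planted rotation difference across members
    moves them by a resolvable lever arm.
    """
    rng = np.random.default_rng(spec.seed)
    axis = _unit(np.array(spec.hinge_axis))
    u = _perpendicular(axis)
    n_a, n_b, n_f = (spec.n_residues_body_a, spec.n_residues_body_b,
                     spec.n_flexible)
    if n_a < 3 or n_b < 3:
        raise FilaxisError("each body needs at least 3 residues")

    ca_a = -20.0 * u + rng.normal(scale=6.0, size=(n_a, 3))
    ca_f = -5.0 * u + rng.normal(scale=3.0, size=(n_f, 3))
    center_b = 22.0 * u
    ca_b = np.empty((n_b, 3))
    for i in range(n_b):
        while True:
            p = center_b + rng.uniform(-7.0, 7.0, size=3)
            perp = p - (p @ axis) * axis
            if np.linalg.norm(perp) >= 12.0:
                ca_b[i] = p
                break
    cb = np.vstack([_unit(rng.normal(size=3)) * 1.5
                    for _ in range(n_a + n_f + n_b)])

    body_a = (1, n_a)
    flexible = (n_a + 1, n_a + n_f) if n_f else None
    body_b = (n_a + n_f + 1, n_a + n_f + n_b)
    absent = dict(spec.absent or {})

    models: List[StructureModel] = []
    for k, angle in enumerate(spec.angles_deg):
        R = _rotation_about(axis, angle)
        ca_b_k = ca_b @ R.T
        cas = np.vstack([ca_a, ca_f.reshape(-1, 3), ca_b_k])
        if spec.noise_sd > 0:
            noise = rng.normal(scale=spec.noise_sd, size=(len(cas), 3))
        else:
            noise = np.zeros((len(cas), 3))
        if n_f:
            noise[n_a:n_a + n_f] *= FLEXIBLE_NOISE_FACTOR
        residues = _make_residues(cas + noise, cb, first_seqid=1)
        if k in absent:
            lo, hi = absent[k]
            residues = [r for r in residues if not lo <= r.seqid <= hi]
        chain = Chain(id="A", residues=residues)
        models.append(StructureModel(id=f"conformer_{k}", chains=[chain]))

    truth = {
        "body_a_residues": list(body_a),
        "body_b_residues": list(body_b),
        "flexible_residues": list(flexible) if flexible else None,
        "hinge_point": [0.0, 0.0, 0.0],
        "hinge_axis": axis.tolist(),
        "angles_deg": [float(a) for a in spec.angles_deg],
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "absent": {str(k): list(v) for k, v in absent.items()},
    }
    return models, truth


# ---------------------------------------------------------------------------
# Decorated filaments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilamentSpec:
    """A helical filament, optionally decorated with cofilin-like chains.

    Defaults follow the cofilin-decorated filament geometry (-162.1 deg
    twist, 27.6 A rise); a bare actin-like filament uses -166.6 deg /
    27.5 A.  When ``decorated``, one compact dummy chain bridges subunits
    k and k+2 (adjacent on one long-pitch strand) for every k, placed with
    radial clearance so it makes no van-der-Waals contact at default radii.
    """

    protomer_size: int = 40
    genetic_twist_deg: float = -162.1
    rise_ang: float = 27.6
    n_subunits: int = 6
    decorated: bool = True
    noise_sd: float = 0.0
    seed: int = 0


def make_protomer(rng: np.random.Generator, n_residues: int,
                  radial_offset: float = 16.0) -> StructureModel:
    """A compact dummy protomer whose centroid sits off the z-axis."""
    ca = np.array([radial_offset, 0.0, 0.0]) \
        + rng.normal(scale=5.0, size=(n_residues, 3))
    cb = np.vstack([_unit(rng.normal(size=3)) * 1.5
                    for _ in range(n_residues)])
    chain = Chain(id="A", residues=_make_residues(ca, cb, first_seqid=1))
    return StructureModel(id="protomer", chains=[chain])


def make_decorated_filament(spec: FilamentSpec
                            ) -> Tuple[StructureModel, Dict]:
    """Build a (decorated) filament and its ground-truth annotation."""
    rng = np.random.default_rng(spec.seed)
    protomer = make_protomer(rng, spec.protomer_size)
    sym = HelicalSymmetry(spec.genetic_twist_deg, spec.rise_ang)
    filament = build_filament(protomer, sym, spec.n_subunits)
    actin_chains = [ids[0] for ids in
                    subunit_chain_ids(1, spec.n_subunits)]

    cofilin_map: Dict[str, List[str]] = {}
    if spec.decorated and spec.n_subunits >= 3:
        coords = filament.coords()
        r_max = float(np.linalg.norm(coords[:, :2], axis=1).max())
        cof_center_radius = r_max + 6.5
        taken = list(actin_chains)
        centroids = {}
        for cid in actin_chains:
            chain = filament.chain(cid)
            centroids[cid] = np.vstack(
                [a.coord for r in chain.residues for a in r.atoms]
            ).mean(axis=0)
        for k in range(spec.n_subunits - 2):
            b_chain, p_chain = actin_chains[k], actin_chains[k + 2]
            mid = 0.5 * (centroids[b_chain] + centroids[p_chain])
            w = mid.copy()
            w[2] = 0.0
            w = _unit(w)
            center = w * cof_center_radius
            center[2] = mid[2]
            ca = np.empty((6, 3))
            for i in range(6):
                while True:
                    p = center + rng.normal(scale=1.2, size=3)
                    if np.linalg.norm(p - center) <= 2.5:
                        ca[i] = p
                        break
            cb = np.vstack([_unit(rng.normal(size=3)) * 1.0
                            for _ in range(6)])
            cof_id = next(c for c in
                          "abcdefghijklmnopqrstuvwxyz0123456789"
                          if c not in taken)
            taken.append(cof_id)
            chain = Chain(id=cof_id,
                          residues=_make_residues(ca, cb, first_seqid=1,
                                                  resname="COF"))
            filament.chains.append(chain)
            cofilin_map[cof_id] = [b_chain, p_chain]
        for cof_id in cofilin_map:
            others = filament.subset(
                [c.id for c in filament.chains if c.id != cof_id])
            report = find_contacts(filament.subset([cof_id]), others)
            if report.collision_pairs:
                raise FilaxisError(
                    "internal error: decorated chain placed with collisions")

    if spec.noise_sd > 0:
        for _, _, atom in filament.iter_atoms():
            atom.coord = atom.coord + rng.normal(scale=spec.noise_sd, size=3)

    truth = {
        "genetic_twist_deg": spec.genetic_twist_deg,
        "rise_ang": spec.rise_ang,
        "axis_direction": [0.0, 0.0, 1.0],
        "axis_point": [0.0, 0.0, 0.0],
        "n_subunits": spec.n_subunits,
        "protomer_size": spec.protomer_size,
        "actin_chains": actin_chains,
        "strand_of_subunit": {c: ("A" if i % 2 == 0 else "B")
                              for i, c in enumerate(actin_chains)},
        "cofilin_map": cofilin_map,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return filament, truth


# ---------------------------------------------------------------------------
# Clash fixtures
# ---------------------------------------------------------------------------

def make_clash_fixture(n_interface: int, n_collide: int, seed: int = 0
                       ) -> Tuple[StructureModel, Dict]:
    """Two chains with exactly the requested contact counts.

    Carbon atom pairs (Bondi r = 1.70 A) are laid out 10 A apart along x so
    pairs do not interact with each other; colliding pairs sit at 1.6 A
    (< 0.5 x 3.40) and interface-only pairs at 3.6 A (< 1.1 x 3.40 but
    >= 0.5 x 3.40).  The seed is accepted for API uniformity; the layout is
    fully determined by the counts.
    """
    if n_collide > n_interface:
        raise FilaxisError(
            f"infeasible: n_collide ({n_collide}) > n_interface "
            f"({n_interface}); every colliding pair is also an interface pair")
    if n_interface < 0 or n_collide < 0:
        raise FilaxisError("counts must be non-negative")
    res_x, res_y = [], []
    for i in range(max(n_interface, 1)):
        x = 10.0 * i
        if i < n_interface:
            dy = 1.6 if i < n_collide else 3.6
        else:  # placeholder far-apart atoms for the (0, 0) request
            dy = 100.0
        res_x.append(Residue(name="CLS", seqid=i + 1,
                             atoms=[Atom("C1", "C", np.array([x, 0.0, 0.0]))]))
        res_y.append(Residue(name="CLS", seqid=i + 1,
                             atoms=[Atom("C1", "C", np.array([x, dy, 0.0]))]))
    model = StructureModel(id=f"clash_{n_interface}_{n_collide}",
                           chains=[Chain("X", res_x), Chain("Y", res_y)])
    truth = {"n_interface_pairs": n_interface, "n_collision_pairs": n_collide,
             "n_colliding_atoms_per_molecule": n_collide,
             "chains": ["X", "Y"], "seed": seed}
    return model, truth


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_fixture(outdir, models, truth: Dict, stem: str = "synth") -> Dict:
    """Write model(s) as PDB plus a ground-truth JSON; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(models, StructureModel):
        models = [models]
    paths = []
    for i, model in enumerate(models):
        suffix = f"_{i}" if len(models) > 1 else ""
        path = outdir / f"{stem}{suffix}.pdb"
        write_structure(model, path)
        paths.append(str(path))
    truth_path = outdir / f"{stem}_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    return {"structures": paths, "truth": str(truth_path)}
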