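"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from filaxis.structio import Atom, Chain, Residue, StructureModel
from filaxis.synth import (FilamentSpec, TwoDomainSpec,
                           make_decorated_filament, make_two_domain_ensemble)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134   1.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      12.560   6.351   1.200  1.00  0.00           C
ATOM      3  C   ALA A   1      13.020   7.770   1.500  1.00  0.00           C
END
"""


def model_from_points(points, chain_id: str = "A", first_seqid: int = 1,
                      element: str = "C", atom_name: str = "CA",
                      model_id: str = "toy") -> StructureModel:
    """One single-atom residue per point; the workhorse toy model."""
    residues = [Residue(name="ALA", seqid=first_seqid + i,
                        atoms=[Atom(atom_name, element, np.asarray(p, float))])
                for i, p in enumerate(np.atleast_2d(points))]
    return StructureModel(id=model_id, chains=[Chain(chain_id, residues)])


def brute_force_contacts(mol_a, mol_b, config):
    """All-pairs double-loop contact oracle, independent of the k-d tree path.

    Returns (interface, collision) lists of (index_a, index_b, distance)
    over atom enumeration order.
    """
    atoms_a = [(i, a) for i, (_, _, a) in enumerate(mol_a.iter_atoms())]
    atoms_b = [(j, b) for j, (_, _, b) in enumerate(mol_b.iter_atoms())]
    interface, collision = [], []
    for i, a in atoms_a:
        ra = config.radius(a.element)
        for j, b in atoms_b:
            rb = config.radius(b.element)
            d = float(np.linalg.norm(a.coord - b.coord))
            if d < config.interface_factor * (ra + rb):
                interface.append((i, j, d))
                if d < config.collision_factor * (ra + rb) and not (
                        config.collision_excludes_hydrogen
                        and (a.is_hydrogen or b.is_hydrogen)):
                    collision.append((i, j, d))
    return interface, collision


def random_molecule(rng, n_atoms: int, chain_id: str = "A",
                    box: float = 8.0, elements=("C", "N", "O", "S")):
    residues = []
    for i in range(n_atoms):
        el = elements[rng.integers(len(elements))]
        residues.append(Residue(
            name="UNK", seqid=i + 1,
            atoms=[Atom("X1", el, rng.uniform(0, box, 3))]))
    return StructureModel(id=f"rand_{chain_id}",
                          chains=[Chain(chain_id, residues)])


@pytest.fixture(scope="session")
def hinge_ensemble():
    """Eight conformers, planted rigid body 1-120, hinge-rotated 121-160."""
    models, truth = make_two_domain_ensemble(TwoDomainSpec(seed=1))
    return models, truth


@pytest.fixture(scope="session")
def decorated_filament():
    """Cofilin-decorated helical filament (-162.1 deg / 27.6 A, 6 subunits)."""
    return make_decorated_filament(FilamentSpec(seed=3))


@pytest.fixture(scope="session")
def bare_filament():
    """Bare filament with canonical actin-like twist (-166.6 deg / 27.5 A)."""
    return make_decorated_filament(FilamentSpec(
        seed=3, decorated=False, genetic_twist_deg=-166.6, rise_ang=27.5))


@pytest.fixture()
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path
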