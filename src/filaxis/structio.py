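"""Atomic-model I/O, residue selection and conformer correspondence.

The in-memory model is a light chain/residue/atom hierarchy holding author
numbering, element symbols and coordinates in angstroms.  Parsing and writing
of PDB and mmCIF files is delegated to gemmi; only the first model of a file
is kept and alternate locations are collapsed to the highest-occupancy
conformer, so that all downstream geometry operates on a single conformer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import gemmi
import numpy as np

from .errors import EnsembleError, FormatError, SelectionError, StructureError

#: (chain id, author sequence number, insertion code)
ResidueKey = Tuple[str, int, str]

_HYDROGEN = {"H", "D", "T"}


@dataclass
class Atom:
    """A single atom: name, element symbol and coordinates in angstroms."""

    name: str
    element: str
    coord: np.ndarray
    is_het: bool = False
    occupancy: float = 1.0
    b_iso: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float).reshape(3)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coord.copy(),
                    self.is_het, self.occupancy, self.b_iso)


@dataclass
class Residue:
    name: str
    seqid: int
    icode: str = ""
    atoms: List[Atom] = field(default_factory=list)
    is_het: bool = False

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[Atom]:
        return self.atom("CA")

    def copy(self) -> "Residue":
        return Residue(self.name, self.seqid, self.icode,
                       [a.copy() for a in self.atoms], self.is_het)


@dataclass
class Chain:
    id: str
    residues: List[Residue] = field(default_factory=list)

    def residue(self, seqid: int, icode: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.seqid == seqid and r.icode == icode:
                return r
        return None

    def copy(self) -> "Chain":
        return Chain(self.id, [r.copy() for r in self.residues])


@dataclass
class StructureModel:
    """Hierarchical atomic model (chains -> residues -> atoms)."""

    id: str
    chains: List[Chain] = field(default_factory=list)
    source_format: str = "PDB"

    # -- traversal -----------------------------------------------------
    def chain(self, chain_id: str) -> Optional[Chain]:
        for c in self.chains:
            if c.id == chain_id:
                return c
        return None

    def iter_residues(self) -> Iterator[Tuple[Chain, Residue]]:
        for c in self.chains:
            for r in c.residues:
                yield c, r

    def iter_atoms(self) -> Iterator[Tuple[Chain, Residue, Atom]]:
        for c, r in self.iter_residues():
            for a in r.atoms:
                yield c, r, a

    def residue_keys(self) -> List[ResidueKey]:
        return [(c.id, r.seqid, r.icode) for c, r in self.iter_residues()]

    def residue(self, key: ResidueKey) -> Optional[Residue]:
        c = self.chain(key[0])
        return c.residue(key[1], key[2]) if c is not None else None

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for _, r in self.iter_residues())

    # -- geometry helpers ----------------------------------------------
    def coords(self, heavy_only: bool = False) -> np.ndarray:
        pts = [a.coord for _, _, a in self.iter_atoms()
               if not (heavy_only and a.is_hydrogen)]
        if not pts:
            return np.empty((0, 3))
        return np.vstack(pts)

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> None:
        """Apply x -> R x + t in place to every atom."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float).reshape(3)
        for _, _, a in self.iter_atoms():
            a.coord = R @ a.coord + t

    def copy(self) -> "StructureModel":
        return StructureModel(self.id, [c.copy() for c in self.chains],
                              self.source_format)

    def subset(self, chain_ids: Iterable[str]) -> "StructureModel":
        wanted = list(chain_ids)
        chains = [c.copy() for c in self.chains if c.id in wanted]
        return StructureModel(self.id, chains, self.source_format)

    def validate(self) -> None:
        if self.n_atoms == 0:
            raise StructureError(f"model '{self.id}' contains no atoms")
        seen: Dict[ResidueKey, str] = {}
        for c, r in self.iter_residues():
            key = (c.id, r.seqid, r.icode)
            if key in seen:
                raise StructureError(
                    f"duplicate residue id {key} in model '{self.id}' "
                    f"({seen[key]} vs {r.name})")
            seen[key] = r.name


# ---------------------------------------------------------------------------
# Residue selections
# ---------------------------------------------------------------------------

_RANGE_RE = re.compile(r"^(-?\d+)(?:-(-?\d+))?$")


def _merge_ranges(ranges: Iterable[Tuple[int, int]]) -> Tuple[Tuple[int, int], ...]:
    rs = sorted(ranges)
    merged: List[Tuple[int, int]] = []
    for lo, hi in rs:
        if lo > hi:
            raise SelectionError(f"empty range {lo}-{hi}")
        if merged and lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return tuple(merged)


@dataclass(frozen=True)
class ResidueSelection:
    """Inclusive residue-number ranges per chain.

    An entry with an empty range tuple selects the whole chain.  Overlapping
    or adjacent ranges within a chain are merged on construction.
    """

    spec: Tuple[Tuple[str, Tuple[Tuple[int, int], ...]], ...]

    @classmethod
    def from_ranges(cls, chain_id: str,
                    ranges: Sequence[Tuple[int, int]]) -> "ResidueSelection":
        return cls(((chain_id, _merge_ranges(ranges)),))

    @classmethod
    def whole_chain(cls, chain_id: str) -> "ResidueSelection":
        return cls(((chain_id, ()),))

    @classmethod
    def from_string(cls, text: str) -> "ResidueSelection":
        """Parse selections like ``"A:138-336,A:7-35,B"``."""
        per_chain: Dict[str, List[Tuple[int, int]]] = {}
        whole: List[str] = []
        for token in text.split(","):
            token = token.strip()
            if not token:
                continue
            if ":" in token:
                chain_id, _, rng = token.partition(":")
                chain_id = chain_id.strip()
                rng = rng.strip()
                if not chain_id:
                    raise SelectionError(f"missing chain id in '{token}'")
                if not rng:
                    whole.append(chain_id)
                    continue
                m = _RANGE_RE.match(rng)
                if not m:
                    raise SelectionError(f"bad residue range '{rng}'")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                per_chain.setdefault(chain_id, []).append((lo, hi))
            else:
                whole.append(token)
        entries: List[Tuple[str, Tuple[Tuple[int, int], ...]]] = []
        for chain_id in whole:
            entries.append((chain_id, ()))
        for chain_id, ranges in per_chain.items():
            if chain_id in whole:
                continue
            entries.append((chain_id, _merge_ranges(ranges)))
        if not entries:
            raise SelectionError(f"empty selection string '{text}'")
        return cls(tuple(entries))

    def to_string(self) -> str:
        parts = []
        for chain_id, ranges in self.spec:
            if not ranges:
                parts.append(chain_id)
            else:
                for lo, hi in ranges:
                    parts.append(f"{chain_id}:{lo}" if lo == hi
                                 else f"{chain_id}:{lo}-{hi}")
        return ",".join(parts)

    def on_chain(self, chain_id: str) -> "ResidueSelection":
        """The same residue ranges re-targeted at a different chain."""
        ranges: List[Tuple[int, int]] = []
        whole = False
        for _, rs in self.spec:
            if not rs:
                whole = True
            ranges.extend(rs)
        if whole:
            return ResidueSelection.whole_chain(chain_id)
        return ResidueSelection.from_ranges(chain_id, ranges)

    def contains(self, chain_id: str, seqid: int) -> bool:
        for cid, ranges in self.spec:
            if cid != chain_id:
                continue
            if not ranges:
                return True
            for lo, hi in ranges:
                if lo <= seqid <= hi:
                    return True
        return False

    def resolve(self, model: StructureModel) -> List[Tuple[Chain, Residue]]:
        """Residues of *model* covered by this selection, in model order."""
        out = [(c, r) for c, r in model.iter_residues()
               if self.contains(c.id, r.seqid)]
        if not out:
            raise SelectionError(
                f"selection '{self.to_string()}' matches no residue of "
                f"model '{model.id}'")
        return out

    def residue_keys(self, model: StructureModel) -> List[ResidueKey]:
        return [(c.id, r.seqid, r.icode) for c, r in self.resolve(model)]


def selection_from_keys(keys: Iterable[ResidueKey]) -> ResidueSelection:
    """Compact a set of residue keys into per-chain inclusive ranges."""
    per_chain: Dict[str, List[int]] = {}
    for cid, seqid, _ in keys:
        per_chain.setdefault(cid, []).append(seqid)
    entries = []
    for cid in sorted(per_chain):
        nums = sorted(set(per_chain[cid]))
        ranges: List[Tuple[int, int]] = []
        lo = hi = nums[0]
        for n in nums[1:]:
            if n == hi + 1:
                hi = n
            else:
                ranges.append((lo, hi))
                lo = hi = n
        ranges.append((lo, hi))
        entries.append((cid, tuple(ranges)))
    if not entries:
        raise SelectionError("cannot build a selection from zero residues")
    return ResidueSelection(tuple(entries))


# ---------------------------------------------------------------------------
# File I/O (gemmi backed)
# ---------------------------------------------------------------------------

def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt.upper().replace("MMCIF", "mmCIF") if fmt.lower() in (
            "pdb", "mmcif") else fmt
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmCIF"
    return "PDB"


def _from_gemmi(st: gemmi.Structure, source_format: str) -> StructureModel:
    if len(st) == 0:
        raise StructureError(f"'{st.name}': file contains no model")
    gmodel = st[0]
    model = StructureModel(id=st.name or "model", source_format=source_format)
    for gchain in gmodel:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            res = Residue(name=gres.name, seqid=gres.seqid.num,
                          icode=(gres.seqid.icode or "").strip(),
                          is_het=(gres.het_flag == "H"))
            # collapse altlocs: highest occupancy wins per atom name
            best: Dict[str, gemmi.Atom] = {}
            for ga in gres:
                cur = best.get(ga.name)
                if cur is None or ga.occ > cur.occ:
                    best[ga.name] = ga
            for ga in gres:
                if best.get(ga.name) is not ga:
                    continue
                res.atoms.append(Atom(
                    name=ga.name,
                    element=ga.element.name,
                    coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    is_het=res.is_het,
                    occupancy=ga.occ,
                    b_iso=ga.b_iso,
                ))
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            model.chains.append(chain)
    model.validate()
    return model


def read_structure(path, fmt: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    HETATM records (nucleotide, metal ions, ...) are retained and flagged.
    Alternate locations are collapsed to the highest-occupancy conformer.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    resolved = _detect_format(path, fmt)
    try:
        if resolved == "mmCIF":
            st = gemmi.read_structure(str(path),
                                      format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path} as {resolved}: {exc}") from exc
    st.setup_entities()
    model = _from_gemmi(st, resolved)
    if model.id in ("", "model"):
        model.id = path.stem
    return model


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.id
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seqid, res.icode or " ")
            gres.het_flag = "H" if res.is_het else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coord)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_iso
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path, fmt: str = "auto") -> None:
    """Write a model as PDB or mmCIF (chosen by extension when ``auto``)."""
    path = Path(path)
    resolved = _detect_format(path, fmt)
    st = _to_gemmi(model)
    if resolved == "mmCIF":
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Conformer ensembles
# ---------------------------------------------------------------------------

@dataclass
class ConformerEnsemble:
    """N conformers with an explicit residue correspondence.

    ``correspondence`` maps each canonical residue key to the per-member
    residue key, or ``None`` where the member lacks the residue.  The shared
    core is the set of canonical residues present in every member with a CA
    atom; ensemble statistics are defined on the shared core only.
    """

    members: List[StructureModel]
    correspondence: Dict[ResidueKey, List[Optional[ResidueKey]]]
    excluded: Dict[ResidueKey, str] = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def shared_core(self) -> List[ResidueKey]:
        return sorted(k for k, v in self.correspondence.items()
                      if all(m is not None for m in v))

    def core_ca_coords(self, keys: Optional[Sequence[ResidueKey]] = None
                       ) -> np.ndarray:
        """(n_members, n_keys, 3) CA coordinates over shared-core residues."""
        if keys is None:
            keys = self.shared_core
        out = np.empty((self.n_members, len(keys), 3))
        for j, key in enumerate(keys):
            for i, member in enumerate(self.members):
                mk = self.correspondence[key][i]
                res = member.residue(mk)
                out[i, j] = res.ca.coord
        return out


def build_ensemble(models: Sequence[StructureModel],
                   mode: str = "by_author_number") -> ConformerEnsemble:
    """Build a residue correspondence across conformers by author numbering.

    Residues are paired by (chain id, author residue number, insertion code);
    residues missing in any member, or lacking a CA atom anywhere, are
    excluded from the shared core and reported in ``excluded``.
    """
    if mode != "by_author_number":
        raise ValueError(f"unknown correspondence mode '{mode}'")
    if len(models) < 2:
        raise EnsembleError("an ensemble needs at least two members")
    for m in models:
        m.validate()
    canonical: Dict[ResidueKey, List[Optional[ResidueKey]]] = {}
    keys_per_member = [set(m.residue_keys()) for m in models]
    all_keys = set().union(*keys_per_member)
    excluded: Dict[ResidueKey, str] = {}
    for key in sorted(all_keys):
        row: List[Optional[ResidueKey]] = []
        missing_in = []
        no_ca_in = []
        for i, m in enumerate(models):
            if key in keys_per_member[i]:
                res = m.residue(key)
                if res.ca is None:
                    no_ca_in.append(m.id)
                    row.append(None)
                else:
                    row.append(key)
            else:
                missing_in.append(m.id)
                row.append(None)
        canonical[key] = row
        if missing_in:
            excluded[key] = "missing in " + ", ".join(missing_in)
        elif no_ca_in:
            excluded[key] = "no CA atom in " + ", ".join(no_ca_in)
    ens = ConformerEnsemble(list(models), canonical, excluded)
    if not ens.shared_core:
        raise EnsembleError("shared core is empty: no residue with a CA atom "
                            "is present in every member")
    return ens
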