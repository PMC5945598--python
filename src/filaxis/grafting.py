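"""Rigid-body grafting of cofilin onto filaments and hybrid two-strand models.

A graft positions a donor complex (one actin subunit plus its bound cofilin,
extracted from a cofilin-decorated filament) onto a target filament by
superposing one of the donor actin's rigid bodies (SD1 or the inner domain)
onto the matching body of a target subunit; only the cofilin chain is then
merged into the target model — the donor actin is a positioning jig.

A hybrid filament replaces a stretch of one long-pitch strand of a bare
filament with the corresponding cofilin-bound stretch, aligned via the inner
domain of the center subunit of the stretch; the opposite strand is left
untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .contacts import ContactConfig, find_contacts
from .errors import GraftError
from .geometry import RigidTransform, superpose
from .helical import CHAIN_ALPHABET
from .structio import ResidueSelection, StructureModel

SITES = ("F", "Gi", "Go")

#: which rigid body aligns which subunit for each binding site:
#: F-site -> SD1 of the B-subunit; Gi -> inner domain of the P-subunit;
#: Go -> SD1 of the P-subunit.
SITE_RULES: Dict[str, Tuple[str, str]] = {
    "F": ("SD1", "B"),
    "Gi": ("ID", "P"),
    "Go": ("SD1", "P"),
}


@dataclass
class FilamentAnnotation:
    """Chain roles of a (possibly decorated) filament model.

    ``actin_chains`` lists the actin subunit chains in axial order from the
    barbed end (B-end) to the pointed end (P-end); the position in the list
    is the subunit index along the one-start helix.  ``cofilin_map`` maps
    each cofilin chain to its (B-subunit, P-subunit) actin chain pair.
    """

    actin_chains: List[str]
    cofilin_map: Dict[str, Tuple[str, str]] = field(default_factory=dict)

    @property
    def cofilin_chains(self) -> List[str]:
        return list(self.cofilin_map)

    def subunit_index(self, chain_id: str) -> int:
        try:
            return self.actin_chains.index(chain_id)
        except ValueError:
            raise GraftError(f"chain '{chain_id}' is not an annotated actin "
                             "subunit") from None


def _chain_centroid(model: StructureModel, chain_id: str) -> np.ndarray:
    chain = model.chain(chain_id)
    pts = [a.coord for r in chain.residues for a in r.atoms]
    return np.vstack(pts).mean(axis=0)


def annotate_filament(model: StructureModel,
                      actin_chains: Optional[Sequence[str]] = None,
                      cofilin_chains: Optional[Sequence[str]] = None,
                      ) -> FilamentAnnotation:
    """Derive chain roles and axial order for a filament model.

    Without explicit roles, chains are classified by residue count (actin
    subunits are the larger class).  The filament axis is taken as the
    principal axis of the actin-chain centroids, oriented from the first to
    the last actin chain in model order; actins are then sorted along it
    (B-end first) and each cofilin is assigned the two nearest actins as its
    (B, P) subunit pair.  For deposited models, verify the polarity or pass
    explicit chain lists.
    """
    chain_ids = [c.id for c in model.chains]
    if actin_chains is None or cofilin_chains is None:
        sizes = {c.id: len(c.residues) for c in model.chains}
        lo, hi = min(sizes.values()), max(sizes.values())
        if actin_chains is None:
            if hi == lo:
                actin_chains = list(chain_ids)
            else:
                cut = (lo + hi) / 2.0
                actin_chains = [i for i in chain_ids if sizes[i] >= cut]
        if cofilin_chains is None:
            cofilin_chains = [i for i in chain_ids if i not in actin_chains]
    for cid in list(actin_chains) + list(cofilin_chains):
        if model.chain(cid) is None:
            raise GraftError(f"chain '{cid}' not present in model "
                             f"'{model.id}'; chains found: {chain_ids}")
    centroids = {cid: _chain_centroid(model, cid) for cid in actin_chains}
    if len(actin_chains) >= 2:
        pts = np.vstack([centroids[c] for c in actin_chains])
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
        head_tail = centroids[actin_chains[-1]] - centroids[actin_chains[0]]
        if axis @ head_tail < 0:
            axis = -axis
        order = sorted(actin_chains, key=lambda c: float(centroids[c] @ axis))
    else:
        order = list(actin_chains)
        axis = np.array([0.0, 0.0, 1.0])
    cofilin_map: Dict[str, Tuple[str, str]] = {}
    for cof in cofilin_chains:
        cc = _chain_centroid(model, cof)
        nearest = sorted(order,
                         key=lambda c: float(np.linalg.norm(centroids[c] - cc))
                         )[:2]
        if len(nearest) < 2:
            raise GraftError(f"cofilin chain '{cof}' cannot be assigned two "
                             "actin subunits")
        b, p = sorted(nearest, key=lambda c: float(centroids[c] @ axis))
        cofilin_map[cof] = (b, p)
    return FilamentAnnotation(order, cofilin_map)


# ---------------------------------------------------------------------------
# Site-complex extraction
# ---------------------------------------------------------------------------

def extract_site_complex(cofilactin: StructureModel, site: str,
                         cofilin_chain: Optional[str] = None,
                         annotation: Optional[FilamentAnnotation] = None,
                         ) -> StructureModel:
    """Extract one actin + one bound cofilin from a decorated filament.

    ``site='F'`` pairs the cofilin with its B-subunit (the subunit it binds
    through the F-site); ``site='G'`` with its P-subunit.
    """
    if site not in ("F", "G"):
        raise GraftError("site must be 'F' or 'G' for extraction")
    if annotation is None:
        annotation = annotate_filament(cofilactin)
    if not annotation.cofilin_map:
        raise GraftError(
            f"no cofilin chain identified in model '{cofilactin.id}'; "
            f"chains found: {[c.id for c in cofilactin.chains]}")
    if cofilin_chain is None:
        cofilin_chain = annotation.cofilin_chains[0]
    if cofilin_chain not in annotation.cofilin_map:
        raise GraftError(f"chain '{cofilin_chain}' is not an annotated "
                         "cofilin chain")
    b_sub, p_sub = annotation.cofilin_map[cofilin_chain]
    actin = b_sub if site == "F" else p_sub
    out = cofilactin.subset([actin, cofilin_chain])
    out.id = f"{cofilactin.id}_{site}site_{cofilin_chain}"
    return out


# ---------------------------------------------------------------------------
# Rigid-body grafting
# ---------------------------------------------------------------------------

@dataclass
class GraftRecipe:
    """How to place a donor actin+cofilin complex onto a target filament.

    ``align_body`` holds the rigid-body residue ranges (chain-agnostic; they
    are re-targeted at the donor and target chains), typically the SD1 or
    inner-domain rigid body from the rigid-body search.
    """

    donor_complex: StructureModel
    align_body: ResidueSelection
    donor_actin_chain: str
    donor_cofilin_chain: str
    target_chain: str
    site: str = "F"

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise GraftError(f"site must be one of {SITES}")


@dataclass
class GraftResult:
    model: StructureModel
    transform: RigidTransform
    alignment_rmsd: float
    grafted_chain: str


def _free_chain_id(taken: Sequence[str]) -> str:
    for cid in CHAIN_ALPHABET:
        if cid not in taken:
            return cid
    raise GraftError("chain-name exhaustion while merging the grafted chain")


def graft_by_rigid_body(recipe: GraftRecipe, factin: StructureModel,
                        atom_set: str = "CA") -> GraftResult:
    """Graft the donor cofilin onto a filament by rigid-body superposition.

    The donor actin's alignment body is superposed onto the same residue
    ranges of the target subunit; the whole donor complex is moved by that
    transform and only the cofilin chain is merged into a copy of the
    target filament (renamed if its id collides).
    """
    donor_sel = recipe.align_body.on_chain(recipe.donor_actin_chain)
    target_sel = recipe.align_body.on_chain(recipe.target_chain)
    transform, rmsd = superpose(recipe.donor_complex, factin, donor_sel,
                                atom_set=atom_set, on_mismatch="intersect",
                                selection_reference=target_sel)
    moved = recipe.donor_complex.copy()
    moved.transform(transform.rotation, transform.translation)
    cof = moved.chain(recipe.donor_cofilin_chain)
    if cof is None:
        raise GraftError(f"donor complex has no chain "
                         f"'{recipe.donor_cofilin_chain}'")
    out = factin.copy()
    taken = [c.id for c in out.chains]
    new_id = cof.id if cof.id not in taken else _free_chain_id(taken)
    cof.id = new_id
    out.chains.append(cof)
    out.id = f"{factin.id}_{recipe.site}graft"
    return GraftResult(out, transform, rmsd, new_id)


# ---------------------------------------------------------------------------
# Hybrid two-strand filaments
# ---------------------------------------------------------------------------

@dataclass
class HybridSpec:
    """Replace ``span`` subunits of one strand around ``center_subunit``.

    ``center_subunit`` is a one-start subunit index of the target filament
    and must lie on ``strand`` ('A' = even indices, 'B' = odd).  For even
    spans the center is the P-end-side subunit of the two middle ones.
    """

    span: int
    center_subunit: int
    strand: str = "A"


@dataclass
class HybridResult:
    model: StructureModel
    replaced_chains: List[str]
    donor_actin_chains: List[str]
    donor_cofilin_chains: List[str]
    alignment_rmsd: float


def _strand_indices(n_subunits: int, strand: str) -> List[int]:
    if strand not in ("A", "B"):
        raise GraftError("strand must be 'A' or 'B'")
    offset = 0 if strand == "A" else 1
    return [i for i in range(n_subunits) if i % 2 == offset]


def build_hybrid_filament(cofilactin: StructureModel,
                          factin: StructureModel,
                          spec: HybridSpec,
                          id_body: ResidueSelection,
                          cofilactin_annotation: Optional[FilamentAnnotation]
                          = None,
                          factin_annotation: Optional[FilamentAnnotation]
                          = None,
                          allow_any_span: bool = False,
                          atom_set: str = "CA") -> HybridResult:
    """Build a two-strand hybrid: one cofilin-bound and one bare strand.

    A stretch of ``spec.span`` subunits (with the cofilins bound entirely
    within it) is taken from one strand of the decorated filament and
    aligned onto the bare filament by superposing the inner-domain rigid
    body (``id_body`` residue ranges) of the stretch's center subunit onto
    the corresponding target subunit; the replaced target subunits are
    removed and the opposite strand is untouched.
    """
    if not allow_any_span and not (2 <= spec.span <= 5):
        raise GraftError(f"span {spec.span} outside 2-5; pass "
                         "allow_any_span=True to override")
    if spec.span < 1:
        raise GraftError("span must be >= 1")
    if cofilactin_annotation is None:
        cofilactin_annotation = annotate_filament(cofilactin)
    if factin_annotation is None:
        factin_annotation = annotate_filament(factin)

    f_strand = _strand_indices(len(factin_annotation.actin_chains),
                               spec.strand)
    if spec.center_subunit not in f_strand:
        raise GraftError(f"center subunit {spec.center_subunit} is not on "
                         f"strand {spec.strand}")
    pos = f_strand.index(spec.center_subunit)
    start = pos - spec.span // 2 if spec.span % 2 == 0 \
        else pos - (spec.span - 1) // 2
    if start < 0 or start + spec.span > len(f_strand):
        raise GraftError("target filament too short for the requested span")
    target_idx = f_strand[start:start + spec.span]
    target_chains = [factin_annotation.actin_chains[i] for i in target_idx]

    c_actins = cofilactin_annotation.actin_chains
    if max(target_idx) >= len(c_actins):
        raise GraftError("decorated filament too short for the requested span")
    donor_chains = [c_actins[i] for i in target_idx]
    donor_set = set(donor_chains)
    donor_cofs = [cof for cof, (b, p)
                  in cofilactin_annotation.cofilin_map.items()
                  if b in donor_set and p in donor_set]

    center_donor = c_actins[spec.center_subunit]
    center_target = factin_annotation.actin_chains[spec.center_subunit]
    donor_sel = id_body.on_chain(center_donor)
    target_sel = id_body.on_chain(center_target)
    transform, rmsd = superpose(cofilactin, factin, donor_sel,
                                atom_set=atom_set, on_mismatch="intersect",
                                selection_reference=target_sel)
    stretch = cofilactin.subset(donor_chains + donor_cofs)
    stretch.transform(transform.rotation, transform.translation)

    out = factin.copy()
    out.chains = [c for c in out.chains if c.id not in target_chains]
    out.id = f"{factin.id}_hybrid_span{spec.span}{spec.strand}"
    taken = [c.id for c in out.chains]
    renames: Dict[str, str] = {}
    for donor_chain, tgt in zip(donor_chains, target_chains):
        renames[donor_chain] = tgt  # replaced subunit inherits the old id
    for chain in stretch.chains:
        new_id = renames.get(chain.id)
        if new_id is None:
            new_id = chain.id if chain.id not in taken \
                else _free_chain_id(taken)
        chain.id = new_id
        taken.append(new_id)
        out.chains.append(chain)
    return HybridResult(
        model=out,
        replaced_chains=target_chains,
        donor_actin_chains=[renames[c] for c in donor_chains],
        donor_cofilin_chains=[c.id for c in stretch.chains
                              if c.id not in renames.values()],
        alignment_rmsd=rmsd,
    )


# ---------------------------------------------------------------------------
# Collision-count comparison
# ---------------------------------------------------------------------------

def colliding_atom_count(model: StructureModel,
                         chain_pairs: Sequence[Tuple[str, str]],
                         config: Optional[ContactConfig] = None,
                         metric: str = "atoms") -> int:
    """Distinct colliding atoms (or collision pairs) between chain pairs."""
    if metric not in ("atoms", "pairs"):
        raise ValueError("metric must be 'atoms' or 'pairs'")
    atoms = set()
    n_pairs = 0
    for ca, cb in chain_pairs:
        report = find_contacts(model.subset([ca]), model.subset([cb]), config)
        n_pairs += len(report.collision_pairs)
        for ref_a, ref_b, _ in report.collision_pairs:
            atoms.add((ca, ref_a))
            atoms.add((cb, ref_b))
    return len(atoms) if metric == "atoms" else n_pairs


def compare_collision_counts(model_a: StructureModel,
                             model_b: StructureModel,
                             chain_pairs: Sequence[Tuple[str, str]],
                             config: Optional[ContactConfig] = None,
                             metric: str = "atoms") -> float:
    """Percent reduction of colliding atoms in model A relative to model B.

    Returns ``100 x (1 - count_a / count_b)``; raises when model B has no
    collisions (the reference of the reduction is undefined).
    """
    count_a = colliding_atom_count(model_a, chain_pairs, config, metric)
    count_b = colliding_atom_count(model_b, chain_pairs, config, metric)
    if count_b == 0:
        raise GraftError("reference model has zero colliding atoms: "
                         "reduction is undefined")
    return 100.0 * (1.0 - count_a / count_b)
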