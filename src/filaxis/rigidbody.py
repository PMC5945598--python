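"""Per-residue positional variability and the two-pass rigid-body search.

Given an ensemble of conformers of the same protein, a rigid body is a set
of residues whose CA atoms keep fixed relative positions across all
conformers.  The search aligns the ensemble on a seed region, scores every
residue by the spread of its CA position across members, and keeps residues
below a threshold; a second alignment on the putative body with a tighter
threshold gives the final body.  The default thresholds are 1.0 A for the
first pass and 0.7 A for the second, applied as strict "<" comparisons.

The per-residue statistic is the root-mean-square distance of the member CA
positions from their mean — a single pooled 3D standard deviation with a
population (divisor N) normalization; a sample (N-1) variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .errors import EnsembleError
from .geometry import superpose_coords
from .structio import (ConformerEnsemble, ResidueKey, ResidueSelection,
                       selection_from_keys)

#: residues whose SD falls within this margin of a threshold are flagged
BORDERLINE_MARGIN = 0.05


@dataclass(frozen=True)
class ResidueSD:
    """Positional spread of one residue's CA across ensemble members."""

    key: ResidueKey
    sd: float
    n_members: int


@dataclass
class RigidBodyDefinition:
    """Result of the two-pass rigid-body search."""

    member_residues: ResidueSelection
    per_residue_sd: List[ResidueSD]
    thresholds_used: Tuple[float, float]
    converged: bool
    putative_residues: ResidueSelection
    borderline: List[ResidueSD] = field(default_factory=list)
    n_passes: int = 2

    @property
    def member_keys(self) -> List[ResidueKey]:
        return [s.key for s in self.per_residue_sd
                if self.member_residues.contains(s.key[0], s.key[1])]


def _aligned_core_coords(ensemble: ConformerEnsemble,
                         align_keys: Sequence[ResidueKey],
                         core_keys: Sequence[ResidueKey]) -> np.ndarray:
    """CA coords of core residues after fitting every member onto member 1.

    Alignment uses the CA atoms of ``align_keys``; returns an array of shape
    (n_members, n_core, 3) in the frame of the first member.
    """
    if not align_keys:
        raise EnsembleError("alignment region resolves to no shared residue")
    ca_align = ensemble.core_ca_coords(list(align_keys))
    ca_core = ensemble.core_ca_coords(list(core_keys))
    out = np.empty_like(ca_core)
    out[0] = ca_core[0]
    for m in range(1, ensemble.n_members):
        t, _ = superpose_coords(ca_align[m], ca_align[0])
        out[m] = t.apply(ca_core[m])
    return out


def per_residue_sd(ensemble: ConformerEnsemble,
                   align_on: ResidueSelection,
                   divisor: str = "n") -> List[ResidueSD]:
    """Pooled 3D positional SD of every shared-core residue's CA.

    All members are superposed (CA) onto the first member over ``align_on``;
    for each residue, ``sd = sqrt(mean_i |r_i - rbar|^2)`` over the member
    positions (divisor N by default, N-1 with ``divisor='n-1'``).
    """
    if ensemble.n_members < 2:
        raise EnsembleError("per-residue SD needs >=2 members")
    if divisor not in ("n", "n-1"):
        raise ValueError("divisor must be 'n' or 'n-1'")
    core = ensemble.shared_core
    align_keys = [k for k in core if align_on.contains(k[0], k[1])]
    coords = _aligned_core_coords(ensemble, align_keys, core)
    mean = coords.mean(axis=0)
    sq = ((coords - mean) ** 2).sum(axis=2)  # (members, residues)
    n = ensemble.n_members
    denom = n if divisor == "n" else n - 1
    sds = np.sqrt(sq.sum(axis=0) / denom)
    return [ResidueSD(k, float(s), n) for k, s in zip(core, sds)]


def rigid_body_search(ensemble: ConformerEnsemble,
                      initial_region: ResidueSelection,
                      pass1_threshold: float = 1.0,
                      pass2_threshold: float = 0.7,
                      iterate: bool = False,
                      max_iterations: int = 20,
                      divisor: str = "n") -> RigidBodyDefinition:
    """Two-pass rigid-body search over an aligned conformer ensemble.

    Pass 1 aligns on ``initial_region`` and keeps the residues *within* that
    region whose SD is strictly below ``pass1_threshold`` (the putative
    body).  Pass 2 re-aligns on the putative body and keeps all shared-core
    residues strictly below ``pass2_threshold`` (the final body) — membership
    outside the initial region is therefore visible.  With ``iterate=True``
    the second pass is repeated until membership is stable.

    Residues whose final SD lies within ±0.05 A of the pass-2 threshold are
    reported as borderline.
    """
    sds1 = per_residue_sd(ensemble, initial_region, divisor=divisor)
    putative = [s.key for s in sds1
                if initial_region.contains(s.key[0], s.key[1])
                and s.sd < pass1_threshold]
    if not putative:
        raise EnsembleError(
            f"pass 1: no residue of the initial region has SD < "
            f"{pass1_threshold} A")

    def one_pass(body_keys: List[ResidueKey]
                 ) -> Tuple[List[ResidueSD], List[ResidueKey]]:
        sds = per_residue_sd(ensemble, selection_from_keys(body_keys),
                             divisor=divisor)
        final = [s.key for s in sds if s.sd < pass2_threshold]
        return sds, final

    sds2, final = one_pass(putative)
    n_passes = 2
    converged = not iterate
    if iterate:
        prev = set(final)
        for _ in range(max_iterations):
            if not final:
                break
            sds2, final = one_pass(final)
            n_passes += 1
            if set(final) == prev:
                converged = True
                break
            prev = set(final)
    if not final:
        raise EnsembleError(
            f"pass 2: no residue has SD < {pass2_threshold} A")
    borderline = [s for s in sds2
                  if abs(s.sd - pass2_threshold) <= BORDERLINE_MARGIN]
    return RigidBodyDefinition(
        member_residues=selection_from_keys(final),
        per_residue_sd=sds2,
        thresholds_used=(pass1_threshold, pass2_threshold),
        converged=converged,
        putative_residues=selection_from_keys(putative),
        borderline=borderline,
        n_passes=n_passes,
    )


def sd_table(sds: Sequence[ResidueSD]):
    """Per-residue SDs as a pandas DataFrame (chain, residue, sd, n)."""
    import pandas as pd

    return pd.DataFrame(
        [{"chain": s.key[0], "residue": s.key[1], "icode": s.key[2],
          "sd_A": s.sd, "n_members": s.n_members} for s in sds])
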