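# Methods

This note records the models, conventions and numerical choices behind
`filaxis`, and what the synthetic fixtures do and do not establish about
real data.

## Structure model and correspondence

Coordinate files (PDB v3.3 and mmCIF, parsed and written through gemmi) are
held as a chain → residue → atom hierarchy with author numbering, element
symbols and coordinates in Å. Only the first model of a file is kept;
alternate locations are collapsed to the highest-occupancy conformer so all
downstream geometry sees a single conformer. Heteroatoms (nucleotide, metal
ions) are retained and flagged. Duplicate residue identifiers (chain,
author number, insertion code) are an error.

Conformer ensembles pair residues across members **by author numbering
within matching chain ids** — the actin structures being compared share
actin numbering, and the published procedure specifies alignment regions as
residue ranges, which presumes exactly this correspondence. There is no
sequence-alignment fallback. The *shared core* is the set of residues
present in every member with a Cα atom; ensemble statistics are defined on
it only, and all exclusions are reported with their reason. Residue ranges
are inclusive on both ends ("138–336" includes both boundaries).

## Superposition and screw axes

Optimal superposition is the least-squares proper rotation + translation
(Kabsch). The rotation is computed by direct SVD of the covariance of the
centered point sets with a determinant sign correction, which is accurate
to ~1e-15 and never returns a reflection; scipy's `Rotation` is used for
axis-angle algebra around it. Degenerate inputs (fewer than three pairs, or
collinear points, detected by the second singular value) are errors, as are
mismatched atom sets in strict mode; an `intersect` mode keeps the common
atoms, which is the practical choice when comparing deposited structures
with different modelled termini.

A relative rigid placement is summarized as a screw axis: unit direction,
a point on the axis, rotation angle in (0, 180°], and translation along the
axis. The axis point solves (I − R) p = t⊥ by minimum-norm least squares;
when a reference point is given (the moving body's centroid), the reported
point is the point of the screw line nearest it, so a rendered axis passes
through the molecule. Rotations with |rotvec| ≤ 1e-12 are flagged as
"no rotation"; accessing the direction or point of such a result raises.

The inter-domain axis between two conformers is computed by (1) superposing
conformer B onto conformer A over the fixed body, (2) fitting the residual
transform that carries A's moving body onto the aligned copy of B's moving
body, (3) screw-decomposing it. This is a pure rotation decomposition
between given rigid bodies — no hinge auto-detection or residue clustering
is attempted; the bodies come from the rigid-body search or the user.
Swapping the conformers preserves the angle exactly (the two fits are exact
inverses); the axis direction is expressed in each conformer's own
fixed-body frame, so on noisy data the two directions agree only up to the
noise-driven frame rotation (≲ 0.2° at σ = 0.2 Å on the fixtures). Angles
are reported in degrees with 0.1° display precision.

## Rigid-body search

The per-residue statistic is the pooled 3D positional spread of the Cα
across N members after alignment onto the first member:
sd = sqrt((1/N) Σ |r_i − r̄|²). The divisor is N (population) by default
and configurable to N−1; for isotropic per-coordinate noise σ the expected
value is σ·sqrt(3(N−1)/N), which the generator-based tests confirm within
10 %. The statistic is nearly — not exactly — independent of which member
anchors the alignment: pairwise fitting (rather than a generalized
Procrustes mean) leaves a frame dependence of order 1e-4 Å on the fixtures,
negligible against the 0.7 Å threshold.

The search runs exactly two passes by default: align on the initial region
and keep its residues with sd strictly below 1.0 Å (putative body); realign
on the putative body and keep **all** shared-core residues strictly below
0.7 Å (final body), so membership outside the initial region is visible.
Strict "<" at both thresholds; residues within ±0.05 Å of the final
threshold are flagged as borderline. An optional iterate-to-convergence
mode repeats pass 2 until membership stabilizes (off by default). Raising
the pass-2 threshold can only grow the final body (property-tested), and
the search is idempotent on noise-free data.

The initial region should be the *assumed domain* (boundary at the hinge),
e.g. actin residues 138–336 for the inner domain. Seeding with a region
that contains the entire moving body makes pass 1's least-squares alignment
a compromise between the bodies and mixes the membership — this is inherent
to the method, not an implementation artifact.

## Helical symmetry

A filament is generated from a protomer by the one-start screw: subunit k
is rotated by k·ω about the axis (right-hand rule about the rise direction)
and translated by k·h along it. Negative ω is a left-handed one-start
helix; the decorated-filament default is ω = −162.1°, h = 27.6 Å and the
bare-filament default ω = −166.6°, h = 27.5 Å. Chains are renamed uniquely
per subunit from A–Z, a–z, 0–9 (exhaustion is an error); even and odd
subunits form the two long-pitch strands. The strand rotation is
Δϕ = (2ω + 360°) normalized into (−180°, 180°]; the conversion accepts the
closed interval [−180°, 180°] so the straight-ladder limit −180° → 0 is
representable.

Fitting inverts this: consecutive subunits are superposed (residues matched
by author number across chains), each step is screw-decomposed with the
axis oriented so the rise is positive (the twist then carries the
handedness sign), and twist/rise/axis are averaged with per-step residuals
reported. At least three subunits are required; a per-step twist spread
above 5° triggers a warning. On noise-free built filaments the generating
parameters are recovered to machine precision.

Centroid-to-axis distance uses the geometric centroid of non-hydrogen
atoms: deposited models carry no hydrogens and no masses, and the
mass-weighted variant (available behind a flag, with standard atomic
masses) differs by < 0.1 Å on a protein-sized selection. The exclusion
set is a parameter; for actin comparisons the convention is to drop
residues 1–6 and 41–49 (termini and D-loop, disordered in the decorated
filament). A Cα-only variant is provided since the published value does not
state the atom set.

## Grafting and hybrids

The binding-site geometry pairs each site with an alignment body and a
subunit: the F-site with SD1 of the B-subunit (barbed-end side of the bound
cofilin), the Gi-site with the inner domain of the P-subunit, and the
Go-site with SD1 of the P-subunit. A graft superposes the donor actin's
alignment body onto the same residue ranges of the target subunit and
merges **only the cofilin chain** into the target model — the donor actin
is a positioning jig. Grafting is exactly equivariant under rigid motions
of the target and preserves the grafted chain's internal geometry; both are
tested at 1e-9.

Hybrid two-strand models replace a stretch of 2–5 subunits of one strand
(spans outside 2–5 require an explicit override) with the cofilin-bound
structure, aligned via the inner-domain body of the stretch's center
subunit. For even spans the "center" is the P-end-side subunit of the two
middle ones (the severing analysis focuses on the P-end boundary); a flag
switches it. Cofilins travel with the stretch only when both their actins
lie inside it. The opposite strand is never touched (bitwise-equal
coordinates, tested).

Chain roles in a filament are either supplied explicitly or derived:
chains are classified by residue count (actin subunits are the larger
class), the axis is the principal axis of the actin centroids oriented from
the first to the last actin chain in model order, actins are sorted along
it (barbed end first), and each cofilin is assigned its two nearest actins
as (B, P). For deposited models the polarity should be verified or given
explicitly.

The cooperative-binding comparison reports
100·(1 − collisions_A / collisions_B) with collisions counted as distinct
atoms appearing in ≥ 1 collision pair per molecule (a pair-count variant is
also available, since "number of colliding atoms" is ambiguous); a zero
reference count is an error, not 100 %.

## Contacts

Interface: d < 1.1 × (r_a + r_b) over all atoms present. Collision:
d < 0.5 × (r_a + r_b) over non-hydrogen atoms (configurable). Both strict.
Radii default to the Bondi (1964) table (C 1.70, N 1.55, O 1.52, S 1.80,
P 1.80, Mg 1.73, H 1.20 Å …) and are fully overridable; an unknown element
without a declared default radius is an error naming the atom. A k-d tree
prunes candidate pairs at the maximal possible interface cutoff; the tests
verify exact equality with an exhaustive all-pairs double loop on random
configurations, and that collisions are always a subset of interfaces.

## Synthetic data

The generators define the study conditions and are deterministic in their
seed, emitting machine-readable ground truth beside the coordinates.

*Two-domain ensembles*: a 120-residue rigid core, a 40-residue moving body
rotated per conformer about a planted hinge axis through the origin, eight
conformers with angles spread over 0–20°, and isotropic Gaussian noise of
0.2 Å per coordinate (5× on flexible residues, mimicking a disordered loop
qualitatively). Moving-body residues are kept at ≥ 12 Å perpendicular
distance from the hinge axis so the planted rotation has a resolvable lever
arm. Geometry is a Cα trace plus one pseudo-side-chain carbon per residue;
all downstream mathematics is coordinate- and element-based, so no
stereochemistry is modelled.

*Filaments*: a 40-residue compact protomer centered ~16 Å off the axis,
six subunits, decorated by a small dummy chain bridging subunits k and k+2
of one strand for every k, placed radially outward with ≥ 4 Å clearance so
it makes no van-der-Waals contact (asserted at generation time).

*Clash fixtures*: isolated carbon-pair columns 10 Å apart, at 1.6 Å for
colliding pairs and 3.6 Å for interface-only pairs, achieving exactly the
requested counts.

What passing on these fixtures does **not** show: recovery of the published
rigid-body membership, rotation angles or centroid distances from deposited
coordinates (different atom content, real side chains, genuinely borderline
residues), nor anything about map-space refinement — the refined symmetry
and resolution are treated as fixed inputs throughout. The real-data path
is exercised only when the user fetches the released accessions
(`filaxis fetch`), which the default build and test runs never do. One
ensemble member of the published eight (an unpublished crystal structure)
is not retrievable at all, so the printed rigid-body membership is
reproducible only qualitatively.

## Problem sizes and tolerances

Tests run entirely on synthetic fixtures: 1,000 random placements for the
superposition/screw round trips (1e-9), 100 random configurations for the
contact oracle, 50 random generator settings for threshold monotonicity,
six-subunit filaments and eight-member ensembles elsewhere; the suite
completes in a few seconds on one CPU. Exact recoveries are asserted at
1e-9 (1e-6 for angles through noise-free ensembles), noisy recoveries at
1° (axes, σ = 0.3 Å) and 0.5° (filament twist, σ = 0.2 Å), both implied by
the noise level and lever arms, not tuned.
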