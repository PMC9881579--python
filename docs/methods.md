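# Methods

This note documents the models, numerical choices and deliberate
simplifications behind each module, in the order a docking run uses them.
Everything operates on backbone + CB coordinates; sequence design,
sidechain packing and flexible-backbone refinement are outside the scope
of the package.

## Coordinate model and geometry

Structures are ordered chains of residues of named atoms, 1-based residue
indices, coordinates in Å. PDB reading/writing is delegated to gemmi
(ATOM/TER/END subset; HETATM and waters skipped, altloc A kept, residues
with missing backbone flagged rather than dropped). Superposition is the
Kabsch least-squares solution via scipy's `Rotation.align_vectors`, with
reflections always corrected to proper rotations so chirality is
preserved; the test suite cross-checks it against an independently
implemented quaternion-eigenvalue solver to 1e-9 Å. Rank-deficient
(collinear) point sets still return a minimizing transform, with a
warning.

## Backbone hydrogen bonds and secondary structure

Amide hydrogens are reconstructed geometrically: the N-H unit vector of
residue i is anti-parallel to the C=O vector of residue i−1 (first
residues and prolines have no donor). Secondary structure uses the
Kabsch–Sander electrostatic criterion, E = 0.084·332·(1/d_ON + 1/d_CH −
1/d_OH − 1/d_CN) kcal/mol with a bond below −0.5 kcal/mol; helices from
two consecutive i→i+4 turns, strands from parallel/antiparallel bridge
patterns. Two consequences worth knowing:

* a lone extended strand has no bridge partner and is labelled loop —
  the strand definition is bridge-based by choice;
* terminal residues fray (the first residue of a chain cannot donate),
  so a 5-residue ideal hairpin labels its three interior residues E.

Assignment is deterministic and invariant under rigid motion.

## Solvent accessibility

Shrake–Rupley areas are computed by biotite's SASA routine with 960
deterministic sphere points per atom (configurable), probe 1.4 Å, radii
C 1.70 / N 1.55 / O 1.52 / S 1.80 Å, unknown elements 1.70 Å with a
warning. Edge-strand exposure is the mean per-residue summed area of
backbone N and O: a strand H-bonded on both faces buries these atoms
(~12 Å²/residue on the fixtures), an exposed edge does not
(~17–33 Å²/residue); the default gate of 15 Å²/residue sits between the
two populations. Absolute SASA values are implementation-defined, which
is why every SASA-derived threshold is configuration, not constant.

## Edge-strand docking

The dock motif is an ideal two-stranded sheet built by the fixtures
module (below). Its first strand's CA trace is aligned to the edge strand
at a chosen register offset; every offset pairing at least 3 residues is
enumerated — for strand lengths m, n that is m+n−5 offsets per
orientation, and 2·(2L−5) homodimer docks for edge length L. A pleated CA
trace is nearly two-fold symmetric about the strand axis, so the
alignment leaves a genuine two-fold ambiguity: the partner strand can
land on either face of the edge, including the face already occupied by
the sheet's interior. When the host scaffold is supplied, the placement
farther from it (the exposed face) is selected; the alternate placement
is the sheet-lattice image translated across the edge by twice the
perpendicular inter-strand offset, which is the exact lattice relation
for ideal sheets.

Trimming removes terminal dock-strand residues with heavy atoms within
2.8 Å of the scaffold until clash-free; candidates shorter than 3
residues, or with untrimmable interior clashes, are flagged rejected
rather than raised.

The docking score is a smooth well per N-H···O=C pair: Gaussian in the
H···O distance (optimum 1.9 Å, σ 0.3 Å), times cos² of the deviation
from linearity, zero beyond 3.2 Å or past 90° of bend. The weight is
chosen so one ideal bond scores ≈ −1; the default acceptance gate of −4
therefore demands four good bonds, which is the intended meaning of the
gate rather than any absolute energy. Rigid-body minimization of the dock
strand is a bounded (±1.5 Å, ±15°) Powell search on that score; it never
returns a pose worse than its input, and warns when no H-bond basin is in
reach (flat landscape).

Grafting superimposes every same-length window of every exposed edge
strand of every library scaffold onto the dock strand; placements within
the graft tolerance (default 0.75 Å) and free of inter-scaffold clashes
(< 2.8 Å heavy-atom) become heterodimer docks. Interface metrics:
buried surface area as (SASA_A + SASA_B − SASA_AB)/2; a shape
complementarity proxy as the Gaussian-weighted mean of −n̂_A·n̂_B over
close surface pairs (σ 1.5 Å, atom normals approximated from local
centroids); unsatisfied buried polar atoms as backbone N/O exposed in the
monomer, buried in the complex, and lacking any polar partner within
3.2 Å; packing as heavy-atom pairs within 4.5 Å. The "binding energy"
reported is the H-bond score plus a small packing reward and is labelled
a proxy throughout.

## Homodimer self-docking (implicit negative design)

For each orientation and offset the second copy of the protomer is
superimposed by its own edge strand onto the disembodied strand, both
copies are stripped to polyglycine (all sidechain atoms removed), and the
inter-copy repulsion Σ k·(r_clash − d)² (r_clash 3.2 Å, k 100 Å⁻²) gates
the dock. The gate default of 250 is kept for continuity with common
practice but is a different scale from any packaged force field; what the
test suite pins is the behavior that matters — on the paired fixtures the
blocked scaffold's best dock scores more than 10× the gate while the open
scaffold has docks passing comfortably, so the classification is not
threshold-sensitive. Survivors are rigid-body minimized (cross-copy
backbone H-bond score with a soft-sphere penalty, same bounds as docking)
and scored with the interface metrics. A protomer is homodimer-prone iff
some survivor combines proxy ≤ −3 with buried area ≥ 200 Å². The area
cutoff is calibrated for backbone+CB models, which bury systematically
less surface than full-atom interfaces: a full-length backbone
sheet-extension homodimer buries ≈ 220 Å² here, a marginal three-residue
dock well under 150 Å². Both cutoffs are configurable.

## Fusion and cyclic closure

Repeat windows are found by self-superposition over all start phases;
consecutive windows must align below 1.0 Å. Splicing superimposes window
i_b of structure b onto window i_a of a and concatenates a's prefix with
b's transformed suffix at a junction (repeat-window boundary by default),
renumbering from 1; a clash check (< 2.8 Å) outside a two-residue
junction window rejects bad fusions with the offending distance in the
message. Fusion-point sampling tries the first three windows of each
partner, so the designed binding interface is never consumed by the
splice.

Closure of a Cn ring decomposes the subunit transform into rotation angle
(from the rotation matrix), axis, and axial translation (translation
component along the axis). Closed means |angle − 360/n| ≤ 5° and axial
translation ≤ 1.5 Å; both tolerances are package parameters, exposed in
configuration, since no published values exist for this check. A
composition test (Tⁿ applied to a probe set) is reported alongside; by
the triangle inequality its displacement is bounded by n times the
single-step errors. Ring assembly snaps the transform to an exact Cn step
(angle exactly 360/n about the original axis through the original axis
point, axial translation zeroed) and reports, but does not reject,
inter-subunit clashes.

## Assembly combinatorics

Interfaces are assumed perfectly orthogonal: a site binds exactly its
cognate (same interface, opposite side), and a self-complementary side
("S") models connectors that homodimerize. Enumeration grows connected
assemblies instance by instance, optionally closing cycles between free
cognate sites, and deduplicates by labelled multigraph isomorphism
(component names on nodes, interface names on edges) within cheap
invariant buckets. Hubs are single nodes of valency k that count as k
chains in stoichiometry strings. The search is verified against a naive
generate-then-filter oracle on 200 seeded random inventories, and is
guarded at 8 component instances — beyond that the isomorphism
deduplication is the bottleneck and the tool is not intended for it.
Geometric compatibility (whether an enumerated assembly can exist without
clashes) deliberately lives in the fusion layer, not here.

## Binding models

The ternary ODE system has one rate pair per interface: A binds B and BC
with (k1, k−1); C binds B and AB with (k2, k−2). The mass balance of the
six printed rate equations requires the ABC loss term in d[ABC]/dt to be
k−1·[ABC]; the implementation uses that conservative form, and every
trajectory is checked against the three linear invariants (A_T, B_T,
C_T). Integration uses LSODA with rtol 1e-8 and atol 1e-12 times the
largest total; tiny negative undershoot is clipped at −1e-12 relative.
Steady states are computed twice — by long-time integration until
derivatives vanish below 1e-10 of the concentration scale, and by
algebraic solution of the coupled equilibrium (nested monotone 1-D root
finding in free B, then free A with C eliminated) — and must agree to
1e-6 relative; disagreement is an error, not a warning.

The two-state bound fraction uses the conjugate form
fAB = 2·B_T / (A_T+B_T+Kd + sqrt((A_T+B_T+Kd)² − 4·A_T·B_T)),
exact for Kd = 0 and stable when A_T ≪ B_T; it matches a bisection root
of the mass-action quadratic to 1e-10 over 1000 seeded draws. In the
titration fit the a2 and S2 correction terms of the signal model are not
separately identifiable (they enter only as a product with B_T) and are
fitted as one lumped slope. Exponential fits are initialized from the
tail baseline and a log-linear rate estimate, run on a normalized signal
so tolerances behave at any unit scale, support a dead-time offset added
to the time axis, and flag (never raise on) flat or non-decaying data.
Hill fits parametrize the midpoint on a log scale with the coefficient
bounded positive. The pseudo-first-order relation k_obs = k_on·[excess] +
k_off is cross-validated by fitting a simulated trace; note the relation
assumes the limiting partner is far below the excess one (at a 1:10
ratio, depletion of the excess shifts k_obs by ~10%, which is a property
of the approximation, not of the fit).

## Fixtures: what they emulate and what they do not

All fixtures are deterministic. Backbones are built from ideal internal
coordinates (NeRF chain extension; poly-alanine with CB placed at the
CCD-consistent improper torsion so polyglycine conversion is a real
operation). The inter-strand placement of ideal sheets is found once per
(length, orientation): a fixed grid over discrete flips and in-plane
offsets scored by Kabsch–Sander bond count (preferring registers whose
bonds can all reciprocate), refined by a bounded Powell minimization of
the same smooth H-bond well the docking score uses — so ideal sheets sit
at the scoring optimum (≈ −1 per bond) by construction. The DHR analog
repeats a fixed helix-loop-helix dihedral block, giving exact repeat
symmetry with a gentle (≈ 39°, 16 Å) inter-repeat twist; its loop
dihedrals were selected once for compactness and clash-freedom.

The mixed alpha/beta scaffold is a four-stranded antiparallel sheet
(8-residue strands) threaded into a single chain with a core helix packed
underneath and a flanking helix covering one edge; the other edge is left
exposed, covered (edge-buried variant), or flanked by two blocking
helices placed above and below the plane beyond the edge
(homodimer-blocked variant) at positions chosen so that any second copy
docked by sheet extension clashes with them by more than an order of
magnitude over the gate. Connecting loops are geometric arcs with
approximate internal geometry — adequate because no pipeline property
depends on loop realism, which is an explicit non-goal.

What passing on these fixtures does not show: behavior on real,
irregular sheets (beta bulges, twisted sheets, non-ideal registers),
sequence effects on homodimerization, or absolute energies comparable to
any force field. The fixtures pin the logic — enumeration completeness,
face selection, clash discrimination, closure geometry, counting rules —
not the energetics of real proteins.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run at desk scale by choice:
sheets up to 4×10 residues, scaffolds of 74–118 residues, edge lengths
3–8, assemblies to 5 components over ≤ 4-interface inventories, 100
random-rate trajectories, 1000 equilibrium draws, 100 noise replicates
per fit study. All complete in about a minute on one CPU.
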