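# Methods

This note documents the models, conventions and numerical choices behind
fibrilkit, and what the synthetic test data do and do not establish.

## Model containers and PDB conventions

A model is an ordered stack of M chains with identical residue count N and
identical sequence. Chains are held as Cα traces; when the source PDB
provides a full backbone, per-residue N/CA/C/O arrays are carried in
parallel (hydrogens are never read — they are placed geometrically when
needed). Reading goes through Bio.PDB: one model per MODEL record,
highest-occupancy alternate locations, hetero records skipped. Insertion
codes are rejected with an explicit error — internal indexing is
positional, and the short peptides this package targets do not need them.
On output, chain IDs are reassigned by position through the 62-character
alphabet A–Z, a–z, 0–9 (a 30-chain fibril uses A…Z then a…d); more chains
than that is an error instructing the user to split the output.
Coordinates are written with 3 decimals, so a read→write→read cycle is
stable to 10⁻³ Å.

Ensemble averaging (used to build a single reference from an NMR-style
ensemble) superposes every conformer onto the *first* conformer by an
all-Cα Kabsch fit and then averages atomwise. The first-frame reference is
a deliberate choice over an iterated mean frame: it is deterministic and
adequate for small ensembles; for isotropic noise the two differ only by a
rigid motion of the result.

## Superposition

All fitting is proper-rotation Kabsch (SciPy's `align_vectors`, which
corrects the sign of the smallest singular value), so reflections can
never be introduced — peptide chirality is preserved even for near-planar
point sets. Fits require ≥ 3 points and reject collinear inputs (relative
singular-value spread ≤ 10⁻¹²), where the rotation about the line is
undetermined. The test suite checks the fit against two independent
routes: a hand-written SVD Kabsch and a quaternion-multistart numeric
minimization over rotations.

Model–model comparisons use all Cα atoms of all chains. Because fibril
chains carry no intrinsic labels, a candidate-vs-reference comparison
tries both the given chain order and its reversal and keeps the lower
RMSD. Representative-frame ("centroid") selection minimizes the mean
RMSD-after-fit to all other frames; ties break to the lowest index.

## pcaRMSD

The symmetry score is the mean pairwise post-superposition Cα RMSD over
all chain pairs, written with a 1/(M²−M) prefactor over the ordered double
sum; the diagonal contributes zero and RMSD is symmetric, so this equals
the unordered-pair mean (the two forms agree to 10⁻¹⁰ Å in tests). Every
Cα of each chain enters the pairwise fit — no core selection — and each
pair is fitted independently, which makes the score invariant under global
rigid motions, per-chain rigid motions and chain permutations. Ranking is
ascending with stable ties.

## Fibril assembly

The overlap step fits chains 1…overlap of a fresh protofilament copy
jointly onto chains M−overlap+1…M of the fixed model (defaults: overlap
M−1, central extracted chain ⌈M/2⌉, 30 iterations; indices are 1-based in
the configuration to match how such stacking procedures are usually
described). The step transform is computed **once** and composed, rather
than re-fitted against accumulating copies: for a rigid identical building
block the two are mathematically identical, and composition avoids
floating-point drift from repeated fitting. Iteration 1 contributes the
untransformed central chain, so n iterations yield exactly n chains; this
base-case convention is the package's own. For an exactly helical input
the assembled fibril is exactly helical with the generator's rise and
twist (verified to 10⁻⁶ Å against the closed-form screw construction).

## Geometry

* **Axis**: first principal component of the per-chain Cα centers of mass
  — one global axis per model, since the twist is defined against a single
  plane perpendicular to the long axis. The sign follows increasing chain
  order. Centers of mass weight Cα atoms equally (trace models carry no
  masses).
* **Length d**: Euclidean distance between the first and last chain
  centers after ordering chains by axial projection.
* **Twist α**: angle between adjacent chains' Cα(a)→Cα(b) segments
  (defaults a=3, b=9, the extended-strand region of a 13-residue hairpin)
  projected onto the plane perpendicular to the axis; computed with the
  atan2 form, which is stable near 0°. Angles are reported as unsigned
  magnitudes in [0°, 180°], with handedness reported separately as the
  sign of the axis-aligned cross-product component. A segment parallel to
  the axis (projection < 10⁻⁶ Å) is an error naming the chain.
* **Pitch**: `(360/α) × rise`. The default rise convention is `d/n`
  (with `d/(n−1)` available as `per-interface`): for d = 134.13 Å, n = 30,
  α = 9.0° the default gives 178.8 Å ≈ 17.9 nm and 40 chains per turn,
  whereas `d/(n−1)` gives 18.5 nm. When measuring synthetic fibrils against
  generator parameters, the `per-interface` convention is the faithful
  one, since a generator with rise r places n chains over a length of
  (n−1)·r. An untwisted stack (α = 0) reports infinite pitch as a
  distinguished result rather than raising.
* Per-model aggregation pools all M−1 interfaces of a model (mean ± sd);
  multi-model inputs are reported per model so either pooling can be
  applied downstream.

## Secondary structure

Amide hydrogens are placed 1.0 Å from N along the preceding residue's O→C
direction; the N-terminal residue and prolines carry none. The
Kabsch–Sander energy uses the standard 0.084·332 coupling and the
−0.5 kcal/mol bond cutoff; distances under 0.1 Å are clamped so
overlapping atoms give a large finite repulsion. Self-bonds and
sequence-neighbor bonds (|i−j| < 2 within a chain) are never recorded.

β-bridges follow the DSSP parallel/antiparallel patterns, with
`Hbond(a, b)` read in the original acceptor-first sense ("the C=O of a
accepts the N-H of b") — with the opposite reading an ideal in-register
parallel sheet yields no bridges at all. Within a chain, bridge partners
must be ≥ 3 positions apart. "β content" counts residues in any bridge
(isolated bridges included by default, excludable via a flag, since the
assignment convention for isolated bridges varies between tools). The
fraction and count are two views of one number, so they are mutually
consistent by construction. Cα-only models cannot be scored and raise a
clear error.

The amide-I correction is pure arithmetic on fitted band components:
corrected fraction = (I_c/w_c) / Σ (I_k/w_k), where w is a component's
relative molar extinction coefficient. With a β component at 74% intensity
and w_β/w_turn = 2 the corrected β fraction is 58.7%. Peak fitting itself
is out of scope; only the correction is implemented.

## Synthetic generator

The generator emulates a cross-β amyloid built from a 13-residue β-hairpin
peptide (two strands joined by a two-residue U-turn, the fold adopted by
short disulfide-constrained amyloidogenic peptides). The monomer backbone
is built from canonical internal coordinates (N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å, C–O 1.231 Å; trans peptide); arm residues are fully extended
(φ = ψ = 180°) and the two turn residues use type-I′ torsions. The chain
is oriented with its first strand along x and that strand's carbonyls
along ±z, so that stacking along z hydrogen-bonds chain to chain exactly
as in a cross-β spine; the default 13-residue sequence is GIVEQCAASVCSL.
Chain t of a fibril is the monomer under the screw motion (t·twist about
z, t·rise along z), with the template centered on the axis so the chain
centers lie exactly on it.

Defaults are a 30-chain stack with 4.625 Å rise (end-to-end length
≈ 134 Å) and 9° per-chain twist, amyloid-like values for a short-peptide
fibril. Noise is isotropic per-atom Gaussian applied after the screw
motion — the simplest perturbation that makes symmetry scoring and
parameter-recovery nontrivial — and is reproducible bit-for-bit from the
seed. What the synthetic data do **not** emulate: side chains, pleating
and sequence-specific conformational preferences, correlated thermal
motion (bending, breathing) of a real trajectory, and solvent effects.
Passing parameter-recovery tests therefore demonstrates correctness of the
measurement operations, not accuracy of any physical prediction.

Restraint tables for coarse-grained docking place one side-chain–side-chain
restraint per residue per adjacent chain pair (n_residues × (n_chains−1)
rows; defaults 5 Å, weight 1), encouraging in-register parallel packing,
plus optionally one intra-chain Cα–Cα disulfide restraint per chain (e.g.
Cys6–Cys11 at 6.5 Å). The file format is a neutral commented 6-column TSV
rather than any docking tool's private dialect, which is version-dependent;
a header comment documents the mapping.

## Problem sizes in the test suite

Property tests use 5-chain protofilaments and 30-chain fibrils of
13-residue chains; ensemble tests use up to 50 frames. These sizes match
the intended application scale, and every suite completes in seconds.

## Known limitations

* No mmCIF, hetero-atoms or side-chain handling; one letter per chain ID
  caps a single file at 62 chains.
* Secondary-structure assignment implements only the β states (bridge /
  extended); helix, turn and bend states are out of scope.
* The fibril axis is global; strongly bent fibrils (large thermal
  excursions) would need a local-axis treatment that is not implemented.
* The assembly step assumes a rigid identical building block; it does not
  re-optimize chain packing.
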