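# Methods

## The interaction-field model

`mifkit` computes molecular interaction fields (MIFs): for a target
ring molecule and a small probe, the interaction energy of the
target–probe dimer is sampled on a spherical grid around the target and
normalized into a [0, 1] field whose value 1 marks the most stable
geometry found. The field is then contracted into a closed-form
Cartesian Gaussian expansion that can be evaluated anywhere — in
particular inside a protein binding site after superposing the ligand's
ring substructure onto the reference molecule.

The package deliberately separates the *geometry* of the method (frame,
grid, probe posing, normalization, contraction, projection) from the
*energy model*. Any callable mapping a posed dimer to an energy in
kcal/mol can serve as the backend. The packaged classical backend
(pairwise Lennard-Jones plus Coulomb, Lorentz–Berthelot combining,
k_e = 332.0637 kcal·Å/mol·e², zero default charges) is a deterministic
desk-scale engine: it reproduces the geometric structure of weak-
hydrogen-bond fields (minima on the ring normal, repulsive walls near
atoms) but not electronic effects such as dispersion anisotropy or
lone-pair directionality, so absolute energies and CH/π-vs-CH/N
orderings from it carry no quantitative meaning. For quantitative
fields, `write_cp_inputs` emits two-fragment counterpoise single-point
job text for an external electronic-structure engine; running and
parsing such jobs is outside the package's scope, though
`cp_interaction_energy` combines three user-supplied energies.

## Frame and grid conventions

- Origin = centroid of the ring atoms; **w** = least-squares plane
  normal of the ring atoms (singular-vector construction). For
  non-planar rings the least-squares plane, not a three-atom plane, is
  used. The normal's sign is fixed deterministically (largest-magnitude
  component positive); since **v** = **w** × **u**, either sign yields
  a right-handed frame, and for planar symmetric targets the field is
  mirror-symmetric in *w* so the choice is physically immaterial.
- **u** points from the origin toward a user-chosen heavy atom,
  projected into the ring plane first so orthogonality is exact even
  for atoms slightly out of plane.
- Spherical convention: polar angle from +**w**, azimuth from +**u**
  toward +**v**. Grid ordering is radius-major, then polar, then
  azimuth. Coincident points are merged (tolerance 1e-8 Å): each pole
  keeps its azimuth-0 instance and azimuth 360° ≡ 0°. The default spec
  (2–7 Å / 0.2 Å, 10° steps) gives 26 · (17·36 + 2) = 15,964 points.
- Units are Å and kcal/mol throughout; atom indices are 0-based in
  memory, 1-based in file formats.

## Probe posing

Probe monomers use standard experimental geometries (methane r(CH)
1.087 Å tetrahedral; ethylene r(CC) 1.339 Å, r(CH) 1.086 Å, HCC
121.3°; benzene r(CC) 1.391 Å, r(CH) 1.080 Å; acetylene r(CC) 1.203 Å,
r(CH) 1.063 Å). The donor vector **M** lies along one C–H bond — all
candidate bonds are symmetry-equivalent per probe, and the first by
index is used. The donor *carbon* is placed exactly on the grid point,
making the grid-point ↔ donor-carbon correspondence explicit (contact-
density maps based on donor carbons are then directly comparable with
the scan grid).

**G**ₙ points from the grid point to the nearest interaction site;
sites are the real atoms plus one dummy per aromatic-flagged ring at
its centroid (fused bicyclics get one per flagged ring). Exact ties
break to the lowest site index, real atoms ordered before dummies. The
probe is rotated by the minimal rotation taking **M** to **G**ₙ; the
antiparallel case rotates 180° about normalize(**M** × **e**) with
**e** the lab axis least aligned with **M**.

The rotation about the aligned axis is a genuinely free parameter. It
is fixed by rotating the probe's secondary reference vector (methane: a
second C–H difference; ethylene: the C=C axis; benzene: the ring
normal; acetylene: any perpendicular) as close as possible to a
caller-supplied "up" direction — the target frame's **w** during scans.
This is a package convention chosen for determinism, not a physical
optimum; for near-spherical probes like methane its energetic effect
under the classical backend is small.

## Normalization

E_MIF,n = E(raw)ₙ / min(E(raw)) when E(raw)ₙ < 0, else 0. Failed
backend evaluations (exceptions, or atom overlaps closer than 0.1 Å)
record a NaN marker and normalize to 0, the same clamp applied to
repulsive points. Δe_max = min(E(raw)) is reported only when at least
one point is attractive; an all-repulsive scan yields an all-zero field
with Δe_max = None.

## Contraction

Basis: all Cartesian monomial shapes uᵏvˡwᵐ with k+l+m ≤ 7 (types s–j),
each crossed with every peak distance r_max. α = n/(2 r_max²) places
the maximum of the optimal-direction radial profile rⁿ exp(−α r²)
exactly at r_max for n ≥ 1; s-type terms (n = 0, no radial maximum off
the origin) reuse the n = 1 rule so they share the p decay scale — a
documented convention. Defaults r_max ∈ {2.4, 3.0, 3.6, 4.2, 4.8} Å
bracket typical weak-hydrogen-bond optima (≈3.4 Å for CH/N, ≈3.6 Å for
CH/π measured ring-center to donor carbon) and are fully configurable.

Weights: w(E) = d + (a−d)/(1 + exp(−b(E−c))), defaults a=5, b=15,
c=0.5, d=1, up-weighting the most attractive half of the field about
five-fold. Any positive callable on [0, 1] is accepted.

Solver: A_ji = Σₙ wₙ gⱼ(rₙ) gᵢ(rₙ) (+ λ on the diagonal), B_j =
Σₙ wₙ gⱼ(rₙ) Eₙ; symmetric solve with a pseudo-inverse fallback at
relative rank tolerance 1e-10. The full 600-term basis on a 15,964-
point field is severely ill-conditioned (cond(A) ~ 1e21); a small ridge
(λ ≈ 1e-8) stabilizes coefficients with negligible loss of fit and is
exposed but off by default. Evaluations are not clamped; a [0, 1] clamp
is available as a display option. Lattice evaluation processes points
in chunks of 262,144 to bound memory; the canonical 161³ lattice
(0.1 Å, ±8 Å inclusive) of a 600-term function evaluates in about a
minute on one CPU.

## Density maps

Voxels are origin-anchored and half-open [edge, edge+spacing); a point
exactly on a boundary goes to the higher-index voxel. Binning conserves
the in-box count exactly. Smoothing replaces each node by the mean of
itself and its up-to-26 neighbors; boundary nodes average over existing
neighbors (zero-padding optional). Percent-of-max rescales the maximum
to 100; iso masks at 75/50/25 (survey style) or 80/50 (comparison
style) are monotone nested by construction. Symmetry expansion
replicates scatter positions under user-supplied orthogonal frame-space
operations before binning; crystallographic (unit-cell) symmetry is out
of scope. The map extent is a user parameter. A seeded subsampling
utility supports surveys that cap the number of structures (e.g. 500
per target).

## Complex projection

Superposition is the Kabsch SVD construction with the determinant
forced to +1 — mirror images are never matched by a reflection. When no
explicit atom correspondence is supplied, same-element assignments are
enumerated and the lowest-RMSD one kept (recorded in the scene);
symmetric ligands are therefore resolved by geometry. Contact reports
evaluate the fitted function *exactly at heavy-atom positions*
transformed into the molecular frame — never interpolated from a
lattice; the visualization lattice (200³ at 0.1 Å, centered on the
ligand-substructure centroid, which sits half a spacing off-node for
even counts) exists only for export. The one lattice-derived quantity
in a report is the annotation "distance to the nearest node at or above
the top threshold", computed on a 0.2 Å frame-space lattice within
±8 Å; since it is measured in frame coordinates it is invariant under
rigid motion of the scene. Crystal structures usually lack hydrogens,
so reports use heavy-atom positions; typical donor-carbon shifts from
the formable-area boundary are shorter than a C–H bond, and an
idealized-H extension is deliberately not applied by default.

## Synthetic data

The fixtures module generates every input shape the pipeline consumes:

- `synthetic_field` — normalized values clip(Σ c·g(rₙ) + noise, 0, 1)
  from known coefficients, with ground truth attached. The default
  spec is an s + d(w²) pair at r_max 3.6 Å with coefficients (0.04,
  0.20), chosen so the field peaks at ≈0.98 on the ring normal at
  |w| ≈ 3.6 Å — the shape of a real normalized CH/π field.
- `synthetic_scatter` — two Gaussian lobes at |w| = 3.6 Å (σ 0.5 Å)
  mimicking CH/π contact clouds.
- `toy_ring_molecule`, `toy_complex` — ideal ring geometries and
  randomly posed scenes with the true transform returned.

These emulate the *structure* of scan fields, survey scatters and
complexes, not the statistics of real crystallographic populations or
electronic-structure energetics: passing tests demonstrate the
machinery (geometry, algebra, bookkeeping) is correct, not that any
particular chemical conclusion holds.

## Problem sizes and determinism

Tests and the acceptance script use reduced problem sizes chosen to
exercise every code path while completing in seconds: coarse scan grids
(15°–90° steps) for fits and oracles, ≤50-point grids for exhaustive
scan comparison, 500 random poses for alignment properties, and
9³–27³ density grids. All randomness flows through
`numpy.random.default_rng` seeded from a single integer.

## Known limitations

- The classical backend is qualitative; quantitative fields require an
  external quantum-chemistry engine via the counterpoise job writer.
- Aromatic-ring perception is not automatic: ring atom sets and
  aromatic flags are supplied by the caller (or by the simple fixtures).
- The automatic ligand-correspondence search enumerates same-element
  permutations and is practical only for substructures up to ~8 atoms
  per element; larger cases need an explicit mapping.
- Non-linear optimization of Gaussian exponents, basis pruning, and
  coefficient uncertainties are out of scope.
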