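# Methods

`durasim` studies how the dura mater — the thin, poorly conducting
meningeal layer between the CSF and the skull — changes EEG scalp
potentials, using voxelized multi-layer head phantoms, a finite-volume
volume-conductor solver, and topography comparison statistics.  This note
documents the model, the numerical choices, and what the synthetic
phantoms can and cannot show about real heads.

## Physical model

At EEG frequencies capacitive and inductive effects are negligible
(quasi-static approximation) and the electric potential obeys

    div( sigma(r) grad phi(r) ) = div J_p(r)

where `sigma` is the tissue conductivity map and `J_p` the primary
(neuronal) current density.  Cortical activity is modeled as one current
dipole per gray-matter voxel — a ~1 mm³ patch of cortex (about one
hypercolumn, ~10⁵ neurons) acts as a single equivalent dipole — oriented
along the local white→gray surface normal, with magnitudes drawn i.i.d.
uniform on [0, 0.4] mA·m.  The head is surrounded by air, which carries no
current (homogeneous Neumann boundary), so the potential is defined up to
a constant; the gauge is fixed by a zero mean over conductive voxels, and
all surface maps are common-average referenced before comparison.

Two paired models are compared in every experiment: a reference model with
the dura layer, and a test model in which the dura voxels are relabeled as
CSF.  Both share the identical phantom geometry and dipole field; only the
conductivity assignment differs.  Topographies are compared with

* `RDM*` — Euclidean distance between the two unit-normalized potential
  vectors: 0 for identical shapes, 2 for sign-flipped ones;
* `MAG` — ratio of root-sum-square magnitudes, test over reference.  With
  the dura-bearing model as reference, MAG > 1 means the dura attenuates;
* histograms, empirical CDFs, and the two-sample Kolmogorov–Smirnov test
  (asymptotic p-value, effective sample size `n_x n_y/(n_x+n_y)`).

## Synthetic phantom

Real segmented-MRI head models are subject-specific and not redistributable,
so the generator builds nested spherical shells that preserve the layer
topology driving the dura effect: white matter (outer radius 40 mm),
cortical gray ribbon (44 mm), CSF (47 mm), a one-voxel dura shell, hard
skull (53 mm), soft skull (55 mm), scalp (60 mm), air outside.  The
white/gray interface can be corrugated
(`a·cos(fθ)·cos(fφ)·sinθ`, default amplitude 2 mm, angular frequency 8) to
emulate gyri and sulci: it modulates dipole orientations and produces fine
spatial structure in cortical maps that deeper surfaces smooth out.  The
corrugation is applied to the white/gray interface because that interface
defines the dipole orientations (the smoothed white-matter-indicator
gradient) and the fine cortical structure; its amplitude must stay below
the gray-ribbon thickness to preserve shell nesting.

Surface normals are estimated from a Gaussian-smoothed white-matter
indicator (default sigma 2 voxels); gray voxels with a vanishing gradient
fall back to the radial direction and are flagged.  Smoothing attenuates
corrugation harmonics, so estimated normals sit inside a cone of ~10°
around the exact surface normal at default settings rather than matching
it exactly.

Tissue conductivities come from the standard literature compilation
(resistivities in Ohm·cm with ±50% bounds, conductivities as reciprocals;
SI conversion ×100).  Two known inconsistencies in that compilation are
handled explicitly:

* **External air** is printed with conductivity 1e-6 S/cm but resistivity
  100,000 Ohm·cm (reciprocal 1e-5).  The solver treats external air as a
  perfect insulator regardless, so only the resistivity is kept; the
  printed figure is stored as metadata.
* **Dura and CSF in the replacement study.**  The compilation lists dura
  0.06 S/m and CSF 1.54 S/m.  An exact analytic computation on a 6-shell
  sphere (see below) shows that a complete 1 mm dura shell at 0.06 S/m
  *raises* scalp potentials relative to a CSF-filled one (ratio ≈ 0.87
  replaced/with-dura): its radial series resistance (1 mm / 0.06 S/m) is
  negligible next to the skull's (6 mm / 0.00625 S/m), so removing it only
  thickens the conductive shunt under the skull.  A 20–40% attenuation by
  the dura, with magnification near 1.66, arises only when the dura is
  strongly resistive — 0.001 S/m at 1 mm thickness — paired with CSF at
  0.06 S/m; under exactly that pair the analytic 6-shell model reproduces
  a magnification of 1.66.  The experiment defaults therefore use dura
  0.001 S/m (at 1 mm) and CSF 0.06 S/m as the study conductivities, while
  the conductivity table itself keeps the literature values.

Because the dura shell is one voxel thick, its conductivity is set by a
**sheet-resistance rule**: sigma_dura = voxel_size / R_sheet with
R_sheet = 1 mm / 0.001 S/m = 1.0 Ohm·m².  A 2 mm voxel dura then gets
0.002 S/m, preserving the radial barrier of the 1 mm physical layer, and
the simulated attenuation becomes resolution-independent (verified: the
analytic magnification for a 2 mm shell at 0.002 S/m matches the 1 mm
shell at 0.001 S/m to ~2%).

## Finite-volume solver

The grid is the native data structure, so the solver discretizes
`div(sigma grad phi)` with a cell-centered finite-volume scheme: the
conductance of the face between voxels i and j is the harmonic mean of
their conductivities times face area over center distance
(`g = 2·σi·σj/(σi+σj) · h`).  The harmonic mean composes resistances in
series, which is the correct limit across thin resistive layers such as
the dura; an arithmetic mean would overestimate coupling there.  Faces to
zero-conductivity (air) voxels carry no conductance.  The operator is
symmetric positive semidefinite with a constant null space; conjugate
gradients with Jacobi preconditioning and a mean-zero projection applied
every iteration solve it to a relative residual of 1e-8 (default), which
leaves the comparison statistics unchanged down to 1e-12.

Each dipole of moment p at center x with unit orientation u becomes a
balanced monopole pair: +I at x + h·u and −I at x − h·u, each deposited on
the eight surrounding voxel centers with trilinear weights.  With
separation d = 2h, I = |p|/d, and because trilinear interpolation
reproduces linear functions the discrete current distribution carries
exactly the first moment p for any orientation.  Injection weights landing
on non-conductive voxels are an error.

Discrete conservation holds by construction: the per-voxel divergence of
the face currents equals the injected current to solver tolerance, and the
symmetric operator gives exact reciprocity.

## Analytic oracle and solver accuracy

The independent reference is the classical separation-of-variables series
for a current dipole in N concentric shells: per Legendre degree n the
radial solution combines r^n and r^−(n+1), matched by continuity of
potential and radial current density at each interface, with zero radial
current at the outer surface.  The dipole may sit in any shell; the basis
is scaled per shell so the matching matrices stay well conditioned to
n ≈ 200.  The single-shell case agrees with the closed-form homogeneous
sphere potential to machine precision, and degenerate layering (all
conductivities equal) reduces to it exactly.

The validation phantom is a 4-shell sphere — brain 40 mm, CSF 46 mm, skull
54 mm, scalp 60 mm — with every shell at least two voxels thick at the
coarsest grid (a voxel scheme cannot represent sub-voxel shells, and the
validation targets solver accuracy, not geometry aliasing).  The single
skull layer stands for the hard+soft bone compartment, so it gets the
radial series-composite conductivity 8 mm/(6 mm/0.00625 + 2 mm/0.04)
≈ 0.0079 S/m.  With a tangential dipole at 0.7 of the brain radius the
finite-volume solution matches the series with RDM* ≈ 0.027 and
MAG ≈ 1.19 at 2 mm, improving to 0.020 and 1.13 at 1.5 mm (and ~1.09 at
1 mm).  The residual magnitude bias is a first-order staircase effect: the
voxelized spherical interface between the resistive skull and the
conductive scalp has ~1.5× the analytic contact area, which shortens the
effective resistive path and over-transmits by O(h).  It vanishes when no
conductive layer lies outside the skull and converges away under
refinement; shape agreement (RDM*) is an order of magnitude tighter.

## Experiments

* **Dura replacement.**  Both arms solved with the identical dipole field;
  scalp maps are restricted to the upper hemisphere ("above eye level";
  the cap plane defaults to the phantom center) and average-referenced
  over the retained points, in that order.  Reported: RDM*, MAG, K–S,
  distribution summaries, and the percent peak reduction at the test
  model's positive peak.
* **Trials.**  The comparison repeats with per-trial seeds
  (master seed + trial index, default 10 trials), reporting mean ± std of
  RDM* and MAG.
* **Surface cascade.**  Potentials on the cortex (gray|CSF), inner/outer
  dura, inner/outer skull and scalp surfaces, each independently
  average-referenced.  Surfaces are voxel sets of the named tissue with a
  6-connected neighbor of the partner tissue; 6-connectivity avoids
  double-counting corners.  Inner/outer pairs are compared on point sets
  matched by nearest angular position from the phantom center (the two
  surfaces have different voxel counts), with the outer surface as
  reference so MAG > 1 means larger potentials on the inner surface.
* **Skull sensitivity.**  The comparison repeats with the hard-skull
  conductivity scaled by {0.5, 1.0, 1.5}, same phantom and sources.

## The closed-shell cancellation artifact

A closed double layer of uniform moment density produces zero external
potential.  The whole-cortex source field on a shell phantom is exactly
that plus random fluctuations: the mean dipole magnitude contributes only
a discretization residual (staircase positions, estimated normals, voxel
areal density varying with corrugation slope), and the measurable scalp
map is the sum of that residual and the incoherent fluctuation field.
Decomposing the two parts shows the residual is comparable in norm to the
fluctuation part and has a model-dependent shape, so whole-cortex RDM*
between the dura and CSF-replaced arms (~0.6 at 2 mm) measures the
artifact, not the dura's transfer effect.  Real cortices are not closed
uniform shells — gyral geometry gives the ensemble map coherent structure
— so this artifact is specific to the synthetic phantom.  The per-source
transfer effect is artifact-free and is what the direction tests use: a
single representative cortical dipole through the full pipeline gives
MAG ≈ 1.68 with RDM* ≈ 0.08 at default conditions (1.47/1.81 at hard-skull
factors 0.5/1.5), in close agreement with the analytic 6-shell value.
Whole-cortex MAG still shows the attenuation direction (≈ 1.16) but with
the shape statistic dominated by the artifact; both are reported.

## Numerical details and degenerate inputs

* All internal computation is SI (S/m, A·m, V, m); the conductivity table
  is ingested in Ohm·cm / S/cm with explicit ×100 conversion; geometry is
  specified in mm.
* Voxel indexing is 0-based, axis order (x, y, z) as in the NIfTI affine;
  all mm coordinates are voxel centers.
* Zero dipole fields solve to identically zero potentials; surface
  comparisons of silent fields are skipped (RDM*/MAG undefined at zero
  norm, which is an error for direct metric calls).
* K–S ties are handled by evaluating both empirical CDFs at the pooled
  order statistics; for samples of ≤ 8 points the statistic equals an
  exhaustive sup-difference evaluation.
* Histograms use 50 equal-width bins over [min, max]; standard deviations
  of surface maps are population values (surfaces are enumerated, not
  sampled).
* Stochastic steps consume a single integer seed; per-trial seeds are
  seed + trial index.  Reports embed config, seeds and package version and
  regenerate bit-identically.

## Problem sizes

Default studies run on a 64³ grid at 2 mm (≈113k conductive unknowns,
≈11k cortical dipoles, one CG solve ≈ 1–3 s); the solver validation adds
an 86³ grid at 1.5 mm.  These sizes keep a full experiment battery —
comparison, 10 trials, cascade, sensitivity, validation — under a few
minutes on one core while leaving every layer at least one voxel thick.

## Known limitations

* Concentric shells cannot reproduce subject-specific magnitudes: printed
  values such as per-surface standard deviations in microvolts depend on
  real cortical geometry and are treated as orderings/directions here.
* The whole-cortex ensemble comparison carries the closed-shell
  cancellation artifact described above.
* No anisotropic conductivity (skull, white matter), no partial-volume
  labels, no adaptive refinement, no eccentric or ellipsoidal analytic
  shells.
* The one-voxel dura under-resolves the layer's internal potential
  profile even though its barrier (sheet resistance) is preserved.
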