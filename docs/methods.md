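# Methods

## Constitutive model

The bead hydrogel is modelled as a homogeneous, isotropic, compressible
Neo-Hookean solid with strain-energy density

    W(F) = μ/2 (I₁ − 3) − μ ln J + λ/2 (ln J)²,

which linearizes exactly to isotropic elasticity with Young's modulus E
and Poisson ratio ν (μ = E/(2(1+ν)), λ = Eν/((1+ν)(1−2ν))).  Defaults
are the measured bead values E = 1.8 kPa, ν = 0.443, giving a bulk
modulus κ = E/(3(1−2ν)) ≈ 5.26 kPa.  Other compressible Neo-Hookean
variants (e.g. the C10/D1 form used by commercial codes) coincide at
small strain but differ at large strain; all validation here uses the
same energy for the forward and inverse runs, so the conclusions about
the *method* do not depend on this choice.  Polyacrylamide is close to
Neo-Hookean up to roughly 10–15% strain; beyond that a dedicated
nonlinear law would be needed.

Two closed forms back the solver tests: for a uniform dilatation
F = J^{1/3} I the Cauchy stress is isotropic with
s(J) = (μ(J^{2/3} − 1) + λ ln J)/J, and the volume ratio under a
homogeneous surface pressure p solves s(J) + p = 0 (found by bracketed
bisection; the tensile branch uses the first, stable root and errors out
beyond the maximum sustainable traction).

## Finite elements

* **Elements.** 10-node quadratic tetrahedra (displacement-based),
  total-Lagrangian formulation.  At ν = 0.443 quadratic displacement
  elements are sufficient against volumetric locking; 4-node linear
  tetrahedra are supported for cheap experiments.
* **Curved boundaries.**  When a mesh is promoted to quadratic, boundary
  midside nodes are projected onto the bounding surface (the sphere, or
  the extracted isosurface), giving isoparametric curved boundary
  elements.  This matters for the inverse method: radial distance
  vectors are computed per boundary node, and chord-midpoint midsides
  would bias them by O(edge²/R).
* **Quadrature.**  Assembly uses a degree-4 11-point tetrahedron rule
  and a degree-4 6-point triangle rule for surface loads.  With degree-4
  integration the discrete divergence identity holds exactly on curved
  quadratic elements, so a uniform dilatation is the *exact* discrete
  solution of the homogeneous-pressure problem — the round trip then
  agrees at numerical precision rather than at a few-percent
  discretization error (which is what a degree-2 rule yields).  Stress
  recovery uses the positive-weight degree-2 4-point rule so every
  integration point carries a positive volume share in the
  volume-weighted means.
* **Loads.**  Surface pressures are follower loads: they act along the
  current surface normal on the current area, with the exact
  (nonsymmetric) load stiffness in the Newton tangent.  Tangential shear
  tractions are dead loads integrated over the reference area — the
  scenario definitions state only magnitudes and pole-to-pole
  orientation, and the mean-pressure conclusions are insensitive to the
  follower/dead distinction at these load levels.  Load fields are
  sampled at the face quadrature points (not per-face constants), which
  avoids aliasing of rapidly varying pressures on coarse meshes.
* **Newton.**  Full consistent tangent, relative force-residual
  tolerance 1e-8, default 5 proportional load steps with automatic
  halving on divergence or element inversion, plus an absolute stopping
  floor when the Newton increment falls below 1e-13 of the mesh size
  (relevant for zero-load states).  Sparse LU (`spsolve`) handles the
  nonsymmetric systems; at the production mesh (~1000 quadratic tets,
  ~16k unknowns) one solve takes seconds to tens of seconds.
* **Rigid-body modes.**  Pure-traction problems (all forward scenarios)
  are regularized by six Lagrange-multiplier constraints on the
  volume-weighted net translation and linearized rotation.  The
  multiplier forces are part of the equilibrium residual; they balance
  the small quadrature imbalance of nearly self-equilibrated loads.  The
  solution is reported in that gauge (translations are pinned at the
  weighted centroid), which is immaterial for stresses.
* **Units.**  Geometry in µm, moduli and stresses in Pa; the pair is
  consistent (forces come out in pN), so no internal rescaling is
  needed.

## Inverse reconstruction

The reference center defaults to the volume centroid of the deformed
mesh — unique and equivariant under rigid motions; the reference
diameter defaults to the production mean (17.0 µm), both overridable.
The radial construction requires the deformed surface to be star-shaped
about the center; this is checked (every outward boundary-face normal
must face away from the center) and violations raise an error rather
than silently producing a multivalued map.  The preprocessing and main
solves use the same material; the vectors are applied as one
proportional Dirichlet program with automatic substepping.

The radial-displacement assumption is the method's essential
approximation.  Loads producing radial surface displacements
(homogeneous pressure) are recovered at numerical precision; tangential
load components are invisible to the surface-shape observation, so local
surface-pressure and shear maps degrade while the volumetric mean
pressure — whose small-strain value depends only on t·x over the surface
and is therefore blind to tangential tractions on a sphere — remains
accurate.  The validation suite quantifies exactly this: mean pressure
within a fraction of a percent for all four scenarios, principal
directions within a fraction of a degree, local map discrepancies of
order 100 Pa for the shear scenario.

`approx_mean_pressure` (−κ·ΔV/V) is a deliberately crude small-strain
estimate: at 5% volume change it differs from the FE volumetric mean by
~7%, and the divergence grows with strain because the volume average of
the nonlinear local pressure is not the constitutive law evaluated at
the bead-scale volume change.

## Synthetic imaging

`render_bead_stack` emulates a confocal observation of a fluorescent
bead: each z-section is the exact planar cross-section polygon of the
surface, rasterized with subvoxel area-fraction (partial-volume)
intensities, then blurred with an isotropic Gaussian (default σ =
0.2 µm) and corrupted with additive Gaussian noise (default 5% of the
foreground intensity, clipped at zero).  Default spacings are 0.1 µm
in-plane and 1 µm between sections.  The model does **not** emulate an
anisotropic/defocused PSF, photon (Poisson) noise, bleaching, background
structures, refractive-index aberrations, or registration drift —
passing tests demonstrate the pipeline's correctness and its robustness
to plain intensity noise, not segmentation performance on difficult
in-vivo data.

Segmentation is Otsu's threshold on the full-stack histogram (scale
invariant and parameter free), per-slice hole filling, and largest
connected component.  Volumes are voxel counts × spacing_xy² ×
spacing_z; the equivalent diameter inverts the sphere volume.

Surface extraction box-filters the binary mask to an isotropic grid
(default spacing = the z-spacing) so in-plane detail becomes
partial-volume values, runs marching cubes at the 0.5 level, applies
Taubin smoothing, and rescales uniformly about the centroid to restore
the pre-smoothing enclosed volume (the volume is the physically decisive
quantity; Taubin alone shrinks coarse meshes by several percent).  The
render → segment → mesh round trip reproduces sphere and ellipsoid
volumes within ~2%.

Tetrahedralization is a Delaunay triangulation of the surface vertices
plus a jittered interior lattice (spacing from `max_tet_volume`),
keeping tetrahedra whose centroids lie inside the surface.  Surface
vertices are preserved exactly.  This is robust for the convex-to-mildly
non-convex, star-shaped shapes of deformed beads; deep concavities would
be bridged and are outside the method's domain anyway.

## Virtual experiments

The four validation scenarios on the standard bead: homogeneous pressure
(1000 Pa); pressure varying sinusoidally with the equatorial angle φ
between 600 and 1000 Pa with wavelength π/4 (sin with zero phase — only
the range and wavelength are constrained); a quadratic pole-to-equator
profile (1000 Pa equator, 600 Pa poles, z axis); and homogeneous 800 Pa
plus 120 Pa tangential shear, north→south (z poles) on the x > 0
hemisphere and east→west (x poles) on x < 0 — the hemisphere split and
pole conventions are a documented choice, and the summary-level
conclusions do not depend on them.  `run_validation` compares the
reconstruction against the forward truth on the matched deformed mesh,
isolating method error from imaging error; the image round trip is
exercised separately at looser tolerance.

Principal-direction comparisons handle degeneracy explicitly: when
reference eigenvalues cluster within 5% of the spectral scale (e.g. the
transverse pair of an axisymmetric state, or the nearly hydrostatic mean
of the 8-period sinusoid), angles are measured between each reference
eigenvector and the *subspace* of the matching cluster, since individual
eigenvectors of repeated eigenvalues are arbitrary.

The uncertainty analysis forward-solves once at the nominal bead, then
reconstructs the fixed observed shape with diameter and Young's modulus
drawn from normal distributions truncated at ±3 SD and at zero
(defaults: 17.0 ± 0.5 µm, 1.8 ± 0.7 kPa), reporting the spread of the
recovered mean pressure.  For a fixed shape and reference the stress is
exactly proportional to E, so the E-only relative spread of the pressure
equals that of E — the oracle the tests assert.  The exact sampling
protocol behind the published "up to 30%" spread figure is not
reproducible from the text and is not targeted.

## Problem sizes

Production runs and the acceptance script use an icosphere refinement-2
surface (320 faces) with a matched interior lattice, ~1000 quadratic
tetrahedra and ~16k displacement unknowns; most tests use refinement 1
(~140 tets), where all reported tolerances already hold.  Mean recovered
pressure changes by far less than 1% between the two resolutions.

## Known limitations

* Surface shear and strongly non-radial boundary displacements are not
  recoverable from shape alone; local stress maps under such loads are
  qualitative.
* Non-star-shaped deformed beads are rejected, not approximated.
* The voxel-counting volume and marching-cubes surface carry a ~1–2%
  bias at the production anisotropic spacings; this propagates to the
  reconstructed pressure roughly through κ·ΔV/V.
* Dynamics, viscoelasticity, poroelasticity and contact are out of
  scope; time series are reconstructed frame by frame, independently.
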