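# compax

Cell-scale stress sensing from deformed elastic hydrogel beads.

Soft polyacrylamide microbeads with cell-like stiffness (Young's modulus
≈ 1.8 kPa, Poisson ratio 0.443, diameter 17.0 ± 0.5 µm) can be implanted
into living tissue as probes: the surrounding cells deform them, and
because the beads are *compressible*, their shape change encodes both
anisotropic and isotropic (pressure) components of the local tissue
stress — something incompressible oil-droplet sensors cannot measure.
This package reconstructs the full Cauchy stress state σ inside such a
bead from nothing but its observed deformed 3-D shape, for
mechanobiologists analysing confocal z-stacks of embedded beads and for
method developers who want a verifiable, end-to-end synthetic test bed.

## Method

The bead is a compressible Neo-Hookean solid with strain energy

    W(F) = μ/2 (I₁ − 3) − μ ln J + λ/2 (ln J)²,

where F is the deformation gradient, J = det F, I₁ = tr(FᵀF), and
(μ, λ) are the Lamé constants of (E, ν).  The stress-free reference
configuration is assumed to be a sphere of the known production mean
diameter.  The inverse reconstruction proceeds in three steps:

1. **Mesh the deformed bead** — segment the confocal stack (Otsu
   threshold, per-slice hole filling, largest component), extract the
   isosurface, tetrahedralize (10-node quadratic tetrahedra).
2. **Build the reference mesh** — compute radial distance vectors from
   each deformed-surface node onto the reference sphere and apply them
   as Dirichlet data in a preprocessing finite-element solve; the
   displaced mesh becomes the assumed stress-free configuration.
3. **Main solve** — apply the *inverse* radial vectors as surface
   displacements to the reference mesh; the resulting Cauchy stress
   field is the estimate of the in-vivo stress state.

Reported summaries follow the bead-sensor conventions: pressure
σ_Pres = −tr(σ)/3 (positive = compression), the volume-weighted mean
tensor σ^Ø = Σᵢ σᵢ vᵢ / Σᵢ vᵢ over integration points, its principal
values σ₁^Ø ≥ σ₂^Ø ≥ σ₃^Ø and directions, and the small-strain estimate
σ_Pres^Ø ≈ −κ (V_c − V_r)/V_r with bulk modulus κ = E/(3(1−2ν)).

The geometrically nonlinear solver (follower pressure loads, full
Newton with consistent tangents, Lagrange-multiplier removal of
rigid-body modes for pure-traction problems) is implemented here on
numpy/scipy; see `docs/methods.md` for the numerical choices.

## Worked example

Validate the method on virtual experiments: a forward simulation deforms
the standard bead under a known load, then the reconstruction sees only
the deformed shape:

```sh
$ compax validate homogeneous pressure_shear --refinement 1
homogeneous: mean pressure 1000.0 Pa (reference 1000.0), rel diff +5.80e-15 -> PASS
pressure_shear: mean pressure 796.4 Pa (reference 791.3), rel diff +6.37e-03 -> PASS
```

Under a homogeneous 1000 Pa surface pressure the displacements are
exactly radial, so the reconstruction recovers the reference stress at
numerical precision (relative difference ~1e-15).  Adding 120 Pa of
tangential shear on the two hemispheres violates the radial-displacement
assumption: local surface-pressure maps now differ between truth and
reconstruction, but the volumetric mean pressure (796 vs 791 Pa, both
near the 800 Pa applied pressure component) is still recovered — the
quantity the sensor is designed to report.

Converting a measured bulk modulus to a Young's modulus:

```sh
$ compax material --kappa 6200 --nu 0.443
{
  "E_from_kappa_Pa": 2120.3999999999996
}
```

i.e. κ = 6.2 kPa with ν = 0.443 corresponds to E ≈ 2.1 kPa.

The same interfaces are available as a library
(`compax.run_compax`, `compax.run_validation`,
`compax.render_bead_stack`, ...), and `compax run stack.tif` drives the
full stack-to-stress pipeline, writing VTU stress fields, JSON
summaries, and normal-stress-profile CSV time series.

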