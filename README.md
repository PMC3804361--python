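# fealign

Nonrigid registration of closed surfaces via **feature images**, with a
discontinuous Galerkin (DG) finite element discretization, a linearized
volume-preservation term, and an optional **statistical deformation model**
prior.

Instead of matching surfaces point-to-point, `fealign` turns each surface
into a small set of images defined on a regular grid around it — a bounded
signed distance image and a curvature image — and looks for a smooth
deformation field `u` of the embedding space that makes the feature images
of the reference match those of the target:

```
J[u] =  D[u]                       image distance (sum over feature channels)
      + (mu/2)  ∫ |∇u|²            gradient smoothness
      + (nu/2)  ∫ (div u)²         linearized volume preservation
      + gamma · P[u]               statistical deformation prior (optional)
```

The field `u` lives in a vector-valued DG finite element space on a
quadtree/octree mesh that is adaptively refined near the reference surface,
and the functional is minimized by a semi-implicit discrete gradient flow
with energy backtracking, embedded in a coarse-to-fine multiresolution loop.

Why this combination is useful:

- **Feature images** sidestep correspondence: any closed surface
  representation that can be rasterized participates, and additional feature
  channels (curvature, application-specific maps) slot into the same
  functional with their own weights and robust estimators.
- **Volume preservation** expresses the prior knowledge that soft tissue is
  nearly incompressible without constraining the optimization.
- **The statistical prior** — a functional principal component analysis
  (FPCA) of training deformation fields — pulls the solution toward the
  subspace of *plausible* deformations. Its flagship use is restoring
  missing anatomy: registering an intact template to a damaged target with
  the prior active reconstructs the missing part (see example 4 below).

## Worked example

Registering a circle onto an ellipse with three mesh levels
(`examples/02_register_circle_to_ellipse.py`):

```python
import fealign as fa

reference = fa.make_shape(fa.ShapeSpec(family="circle", radius=0.25,
                                       resolution=512))
target = fa.make_shape(fa.ShapeSpec(family="ellipse", radii=(0.3, 0.22),
                                    resolution=512))

config = fa.RegistrationConfig(alpha=1.0, beta=0.05, mu=0.01, bound=0.1,
                               base_level=3, levels=3, tau=0.25,
                               steps_per_level=80, energy_tol=1e-9)
result = fa.register(reference, target, grid_shape=129, config=config)
```

Output of the example script:

```
level  elements   dofs  steps  final energy
    0        64    512     80  2.1631e-04
    1       244   1952     80  2.7793e-04
    2       628   5024     12  2.8006e-04

warped surface -> target distance: mean 3.25e-03, max 7.38e-03
finest mesh width h = 0.0312
sup |u| = 0.0487
```

The warped reference lands within a tenth of the finest mesh width of the
target surface. (Energies at different levels are not directly comparable —
refinement changes both the operator and the quadrature.)

The other examples, each a short narrative script with printed output:

- `examples/01_feature_images.py` — builds the bounded signed distance and
  curvature images of a star contour and verifies `|∇I| ≈ 1` in the band and
  `ΔI ≈ 1/r` on a circle:

  ```
  surface: 512 vertices, closed=True
  signed distance range: [-0.2268, +0.4443]
  bounded at b=0.1:      [-0.2268, +0.1000]
  |grad I| in the band:  0.9993 (should be ~1)
  curvature near circle: 3.332 (analytic 1/r = 3.333)
  ```

- `examples/03_volume_preservation.py` — registers a growing circle
  (a forced dilation) with and without the divergence penalty:

  ```
   nu   band |div u|_L2   distance term
    0           0.0552      1.6755e-02
    2           0.0366      2.6843e-02
  ```

  The penalty trades a slightly worse image match for a markedly less
  compressive field near the surface.

- `examples/04_prior_restoration.py` — the restoration experiment. A
  five-spiked star is registered to a damaged copy with one spike removed.
  An FPCA model is built from registrations of the intact star to ten
  smoothly warped variants; sweeping the prior weight `gamma`:

  ```
  model: 9 modes, variances [1.19e-05 1.09e-05 4.28e-06 2.33e-06 1.42e-06
                             5.08e-07 1.23e-07 6.61e-08 2.83e-08]

  gamma   tip displacement / spike length
      0   0.875
      1   0.138
     10   0.025
    100   0.023
  ```

  Without the prior the registration collapses 87% of the spike into the
  damaged target; with it the spike stays within a few percent of its
  original position while the rest of the star still matches.

## Command line

The `fealign` CLI wraps the library for file-based pipelines:

```bash
fealign synth --family star --out star.csv                # synthetic surface
fealign features --surface star.csv --bound 0.1 \
    --out-distance dist.nrrd --out-curvature curv.nrrd     # feature images
fealign register --reference ref.csv --target tgt.csv \
    --grid-shape 129 --levels 3 --out field.h5 \
    --out-surface warped.csv --report report.yaml          # registration
fealign warp-surface --surface ref.csv --field field.h5 --out warped.csv
fealign build-model --out model.h5 field1.h5 field2.h5 ...  # FPCA prior
```

Surfaces are read/written as CSV polylines or legacy VTK polydata; images as
MetaImage/NRRD (anything SimpleITK handles); deformation fields and models
as HDF5; configs and reports as YAML. `fealign COMMAND --help` lists all
options.

## Repository layout

```
src/fealign/
  images.py     grids, raster/analytic images, signed distance, curvature,
                bounding, robust weights, feature channels
  mesh.py       quadtree/octree tessellation with 2:1 balance
  basis.py      tensor-product Legendre DG basis, fields, prolongation
  ldg.py        interior-penalty (LDG-type) assembly of the elliptic operator
  energy.py     registration functional: values, gradients, bilinear forms
  prior.py      functional PCA deformation model: build/save/load, prior terms
  solver.py     semi-implicit gradient flow, backtracking, multiresolution
  synthetic.py  parametric shapes, warps, training populations, damage models
  io.py, cli.py file formats and the `fealign` command
examples/       narrative scripts (outputs quoted above)
tests/          pytest suite; tests/test_acceptance.py holds the headline checks
scripts/        acceptance.py
docs/methods.md mathematical and numerical details
```
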