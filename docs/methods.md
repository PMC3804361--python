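# Methods

This note records the mathematics implemented in `fealign` and the concrete
numerical choices made, module by module. Throughout, `d ∈ {2, 3}` is the
space dimension, `Ω = [0, 1]^d` the computational domain, and surfaces are
closed polylines (2D) or triangle meshes (3D) pre-aligned inside `Ω`.

## Feature images (`images.py`)

A surface `Γ` is represented by images on a regular grid over `Ω`:

- **Signed distance** `I(x) = ±dist(x, Γ)`, negative inside. Sign is
  decided by winding/parity of the closed surface; open surfaces raise
  `OrientationUndefinedError`. The distance is computed exactly per
  segment/triangle (no fast-marching approximation), which is affordable at
  the grid sizes used and gives a clean oracle for testing.
- **Bounding**: `I_b = min(I, b)` clips the *positive* tail only. Far-away
  structure then cannot dominate the matching term, while the interior —
  which carries the shape — is untouched. Bounding is idempotent.
- **Curvature image** `H = ΔI`, the grid Laplacian of the *unbounded*
  distance image, masked to the band `|I| < b − 2h` so neither the bounding
  kink nor the skeleton contaminates it. On the zero level set of a signed
  distance function, `ΔI` equals the sum of principal curvatures: `1/r` for
  a circle, `2/r` for a sphere — i.e. `(d−1)/r`.

A **feature channel** packs, for one feature (distance or curvature), the
fixed reference image `X₀`, the moving target image `X₁`, the precomputed
central-difference gradient images of `X₁`, a weight, and a robust-estimator
spec. The matching term is

```
D[u] = Σ_channels (w/2) ∫_Ω  (X₁(x + u(x)) − X₀(x))² / Q(x, u)  dx
```

with robust weight `Q ≡ 1` (`none`), `Q = C² + resid²` (`geman_mcclure`),
or `Q = |∇X₁(x+u)|² + resid²` (`demons`). In the demons case, points where
both the gradient and the residual vanish (flat far field) would give 0/0;
the implementation sets `Q = ∞` there, i.e. those points contribute nothing.

Images are sampled with multilinear interpolation, clamped at the domain
boundary. `AnalyticImage` provides closed-form channels (exact values *and*
exact gradients) so that derivative checks can isolate the variational
calculus from interpolation error: the gap between the precomputed
central-difference grid gradient and the exact derivative of the
multilinear interpolant is an O(h) sawtooth (measured 3·10⁻⁴–6·10⁻⁴ on the
grids used) that no finite-difference step size removes.

## Tessellation and DG basis (`mesh.py`, `basis.py`)

The deformation field lives on a quadtree (2D) / octree (3D) mesh over `Ω`
with enforced **2:1 balance** (neighbors differ by at most one refinement
level, so every face has at most two half-face neighbors). Cells are
axis-aligned squares/cubes; refinement near the surface uses the criterion
`|I₀| < Θ` with the schedule `Θ = 2h` per level.

On each cell the basis is the tensor product of shifted Legendre
polynomials of degree ≤ q per coordinate (`Q_q`), scaled to be orthonormal
in `L²` of the reference cell. Consequences used throughout:

- the mass matrix is **exactly diagonal**, `M = diag(|T|)` per mode;
- `L²` projection, prolongation to a refined mesh, and the FPCA inner
  product are all cheap and exact.

Vector fields store one coefficient block per component. Prolongation to a
nested refinement is exact (`L²` projection restricted to nested cells is
interpolation).

## Elliptic operator (`ldg.py`)

The regularizer

```
R[u] = (mu/2) ∫ |∇u|² + (nu/2) ∫ (div u)²
```

is discretized in **primal interior-penalty form equivalent to the
central-flux LDG method**: broken volume terms, symmetric consistency terms
with central averages on interior faces, and the penalty

```
η/h_F · ∫_F [u]·[v],      η = 4 q² (mu + nu)
```

with `h_F` the face width (half-faces at hanging nodes get their own
width). The assembled operator `L` is symmetric and positive semidefinite
(kernel = rigid constants when unpinned), and positive definite with
Dirichlet penalization on the domain boundary. The Poisson problem
converges at O(h²) for `q = 1` (measured `L²`-error ratio 3.94 per
refinement).

## Registration functional and derivatives (`energy.py`)

`total_energy` evaluates `J[u] = D[u] + R[u] + γ P[u]` by the per-cell
tensor Gauss quadrature of the DG basis. `distance_gradient` returns the
exact discrete gradient of `D` (chain rule through `X₁(x + u)` with the
channel's gradient images; robust weights are frozen per step, i.e. treated
as the lagged coefficient of a fixed-point iteration). The regularizer's
gradient is `L u` with the assembled bilinear form. All three derivative
blocks are validated against central finite differences of the energy.

## Statistical deformation model (`prior.py`)

Given training fields `u₁ … u_n` on one basis, functional PCA is computed
through the reduced `n × n` Gram eigenproblem of the `M^{1/2}`-weighted,
centered data matrix: eigenvectors `r_i` give `L²`-orthonormal modes
`ρ_i = M^{−1/2} r_i` and variances `σ_i²` (shrunk toward zero modes by the
`shrinkage` floor `σ²`). The prior is

```
P[u] = (1/2) [ Σ_i β_i²/σ_i²  +  ‖u − ū − Σ_i β_i ρ_i‖²_{L²} / σ² ],
β_i = ⟨u − ū, ρ_i⟩_{L²}
```

— Mahalanobis distance inside the model span plus an isotropic penalty on
the orthogonal remainder. `prior_operator` applies the corresponding
linear map matrix-free (rank-`n` update of a scaled mass matrix), so it
can sit inside the implicit solve. Models serialize to HDF5 with a basis
fingerprint; loading onto a different tessellation is rejected.

## Solver (`solver.py`)

One step of the semi-implicit discrete gradient flow solves

```
(M + τ L + τ A_P) u^{n+1} = M u^n − τ g_D(u^n) + τ A_P ū
```

with BiCGStab (`A_P` the prior operator, absent when `γ = 0`). The
explicit part is the nonlinear image term; the stiff elliptic and prior
parts are implicit, so `τ` is not tied to a CFL limit. Default
`τ = 0.1 h`. After each step the energy is evaluated; if it increased, the
step is redone with `τ/2` (backtracking) and a stagnation flag stops the
level when `τ` underflows or the decrease falls below `energy_tol`.

Multiresolution: start on a uniform mesh of `2^base_level` cells per axis,
run the flow, refine cells near the reference surface (`|I₀| < Θ`,
schedule `Θ = 2h` per level), prolong `u` by `L²` projection, repeat.
Energies are only comparable *within* a level — refinement changes both
the operator and the quadrature, so small jumps (~10⁻⁶) at level
transitions are expected and not treated as descent failures.

`register` wraps the loop: builds feature channels from two surfaces
(after checking the surfaces keep a margin from the domain boundary),
runs the levels, and returns the field, the warped reference surface, and
a per-level report.

## Synthetic data (`synthetic.py`)

Parametric shape families (circle, ellipse, radial-bump star and hand in
2D; UV-sphere and radial-bump blob in 3D), smooth invertible warps
(translation, dilation, Gaussian bumps with `sup|∇u| < 0.5` enforced by
amplitude caps), damage models (`remove_spike` for the restoration
experiment), and training populations. Star/hand bumps are Gaussian in
angle, hence not compactly supported — "unchanged away from the damage"
holds only beyond ~6 angular widths. `make_training_population(...,
exact=True)` whitens the coefficient draws so the *sample* covariance
equals the planted diagonal exactly; with plain iid draws the sampling
error of the covariance (≈ `1/√n`) would dominate any test of the FPCA
machinery, which is itself exact to round-off.

## I/O and CLI (`io.py`, `cli.py`)

Surfaces: CSV polylines and legacy VTK polydata. Images: anything
SimpleITK writes (MetaImage, NRRD, …), with grid geometry in the image
metadata. Fields and models: HDF5 (basis fingerprint included).
Configs/reports: YAML with unknown-key rejection. The `fealign` CLI
exposes `synth`, `features`, `register`, `warp-surface`, `build-model`.
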