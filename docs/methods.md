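# Methods

## Model

The data are triplets `(g_i, M_i, z_i)`: a binary label, a closed
two-dimensional surface embedded in R³ with vertices corresponded across
subjects, and a scalar vertex map on that surface.  The package assumes

- every `M_i` is topologically a sphere and is given as a triangle mesh
  with the *same* vertex count and correspondence as the template;
- maps are square-integrable; the classes differ in their mean map and/or
  mean geometry; within-class variation is smooth.

Each subject is linearized as `(v_i, x_i)`: a velocity field in a Gaussian
RKHS whose flow carries the template onto the subject, and the subject map
pulled back to the template.  The linear discriminant direction
`(β^G, β^F)` is the minimizer of the penalized least-squares criterion

    Σᵢ (yᵢ − ⟨vᵢ−v̄, β^G⟩ − ⟨xᵢ−x̄, β^F⟩)² + λ₁‖β^G‖²_V + λ₂ J(β^F),

with auxiliary responses `y_i ∈ {−n/n₁, +n/n₂}` and
`J(β) = ‖Δ_M β‖² + ε‖β‖²`.  This targets the population discriminant
direction `β₀ = L_C⁻¹(μ₂−μ₁)` without ever forming a covariance operator;
the estimator is consistent when `β₀` is smooth (a Sobolev-type condition),
which the synthetic generator enforces by construction (below).

Note the objective carries no `1/n` factor: the discretized system is
solved exactly as written above, so penalty values differ by a factor `n`
from the per-observation convention.  Reported λ values always refer to
the unnormalized convention.

## Representation

- **Alignment.**  Generalized Procrustes analysis removes translation,
  rotation (proper rotations only — reflections are never introduced) and
  scale; every aligned shape has centroid zero and unit centroid size, and
  the template is the iterated vertex-wise mean (convergence at relative
  change < 1e-8 of the mean Procrustes distance).
- **Deformation operator.**  `φ_v` is the explicit Euler flow of a
  *stationary* velocity field over unit time with a configurable number of
  sub-steps (default 8; one step reduces to `p ↦ p + v(p)`).  This is a
  deliberate, documented simplification relative to time-varying
  diffeomorphic flows: for the smooth, small-amplitude fields this package
  targets it preserves the two properties the model actually uses —
  invertible reconstruction and topology preservation — and every
  deformation reports a flipped-face fraction as a diffeomorphism
  diagnostic (0 expected; the simulator treats any flip as an error).
- **Kernel.**  `K(p,q) = exp(−|p−q|²/σ²)·I₃` with σ defaulting to 0.2 ×
  the template bounding-box diagonal.  The theory only requires a smooth
  RKHS; the Gaussian is the conventional concrete choice and σ is exposed
  everywhere.
- **Control points.**  Velocity fields are expanded over a farthest-point
  subsample of template vertices, `m = min(s, 512)`, bounding the kernel
  algebra while covering the surface.
- **Velocity estimation.**  For one flow step the regularized
  vertex-matching problem has the closed ridge form
  `(K_vcᵀK_vc + γK_cc)α = K_vcᵀ(Q − Ξ)` (equal to `(K+γI)α = Q−Ξ` when the
  control points are the vertices).  For several steps a damped
  Gauss–Newton iteration on the flow endpoint starts from the one-step
  solution; the Jacobian drops the deformation-gradient chain term and a
  backtracking line search guarantees a monotone objective.  Default
  matching ridge γ = 1e-8 (near-interpolation; raise it for noisy or
  partially corresponded data).
- **Pullback.**  Under exact vertex correspondence `x_i = z_i ∘ φ_{v_i}`
  is an index map — values are copied, never interpolated.
- **Mean field.**  With a shared kernel and control set, the mean velocity
  field is the field with the mean coefficients (these coincide with the
  L²-mean of the fields).

## Discretization and numerics

- **Elements.**  Linear (P1) elements on the triangle mesh.  All element
  integrals are exact for affine basis functions: mass block
  `(A/12)[[2,1,1],[1,2,1],[1,1,2]]`, stiffness `S_ij = e_i·e_j/(4A)` with
  opposite-edge vectors (the cotangent form).  No quadrature error enters
  the operators.
- **Degenerate triangles** (area ≤ 1e-12 × bbox-diagonal²) are a hard
  error naming the face: silently skipping them would corrupt the penalty.
  Orientation and closedness are checked, never repaired.
- **Mass lumping.**  The penalty uses `D = S M̃⁻¹ S + εM` with `M̃` the
  row-sum (lumped) diagonal of `M`, keeping `D` sparse; the consistent
  `M⁻¹` is never formed.
- **Augmented system.**  The penalized normal equations are solved as one
  sparse least-squares problem with rows `[Σ, XM]`, `[0, √λ₂ M̃^{-1/2}S]`,
  `[0, √(λ₂ε) R_M]`, `[√λ₁ L_Σ, 0]` where `R_MᵀR_M = M` (sparse LDLᵀ via
  an unpivoted symmetric SuperLU factorization, verified to 1e-12, dense
  Cholesky fallback) and `L_ΣᵀL_Σ = Σ + jitter·I` with
  `jitter = 1e-10·tr(Σ)/n` (any factor yields the identical quadratic
  form; the jitter keeps the factor defined when Σ is numerically
  rank-deficient).  LSQR solves the stacked system with
  `atol = btol = 1e-10` by default and never forms `AᵀA`; hitting the
  iteration cap emits a warning with the achieved tolerance and returns
  the iterate.
- **Gram quadrature.**  `Σ_ij` approximates the double kernel integral by
  evaluation at the control points with unit weights; the arbitrary
  overall scale is absorbed into λ₁ by the selection grid.
- **Eigenpairs.**  `Sφ = θMφ` by shift-invert Lanczos with shift −1e-8
  (robust around the zero mode of a closed mesh) and a *fixed* start
  vector: degenerate eigenspaces (the sphere's multiplets) otherwise get a
  random internal basis, which would silently break simulation
  reproducibility.
- **ε default** 1e-3 (pure shrinkage floor of `J`).  ε = 0 is allowed; the
  shrinkage block is then omitted and the penalty null space is the
  constants.
- **Thresholds.**  `c_th` maximizes Youden's J over midpoints of
  consecutive distinct scores (ties → smallest threshold; perfectly
  separated scores → gap midpoint); a fixed-specificity rule is available.
  Pipelines re-pick the threshold on validation scores.
- **Model selection** maximizes validation AUC over a (λ₁, λ₂) grid, ties
  broken toward the larger penalties (smoother estimates); the full audit
  table is always returned.

## The quadratic extension

`FunctionalQDA` fits one penalized direction per class (targets +1 / −1 on
*uncentered* maps, same sparse machinery, per-class `1/n_c` scaling),
projects every map to `u = (⟨x,β₁⟩, ⟨x,β₂⟩)`, and classifies with a
two-class Gaussian quadratic rule in that plane (class-wise means, 2×2
covariances with a 1e-12 relative jitter, priors from training
frequencies).  The Gaussian rule is this package's concrete choice for the
project-then-assign step: standard, deterministic, and reducing to a
linear rule when the projected covariances coincide.

## Synthetic data

The generator emulates exactly the structure the model assumes, on a unit
icosphere template:

- **Geometry**: `v_i = ±(a/2)·mean field + b·subject field`, smooth random
  kernel expansions normalized to unit RMS vertex displacement; subject
  meshes are the 8-step flows.  Any flipped face is an error (amplitudes
  must stay in the diffeomorphic regime).  Defaults a = 0.1, b = 0.03 (10%
  and 3% of the unit sphere radius — visible but far from folding).
- **Maps**: Karhunen–Loève noise over the first k = 40 Laplace–Beltrami
  eigenfunctions (constant mode excluded) with spectrum `θ_j = amp²·j^−2`
  (amp = 0.5 mm) around a 2.5 mm baseline — mimicking smooth, geometry
  -aware thickness variability.
- **Truth-first contrast.**  The generating discriminant direction is the
  smooth polar bump (width 0.7 rad) projected onto the noise modes and
  normalized; the class mean difference is the within-class covariance
  applied to that direction, scaled to L²-norm `map_delta` (default
  1.0 mm ⇒ peak contrast ≈ 0.5 mm, per-vertex effect size ≈ 4 — a clear
  neurodegeneration-like effect).  Constructing the scenario this way
  makes the population discriminant direction exactly the smooth bump, so
  the smoothness condition of the consistency theory holds by design;
  deriving the truth from a raw bump mean-difference instead would make
  `β₀` spectrally rough and cap recovery regardless of n.  The exact
  `β₀` (between-class rank-one term included, via Sherman–Morrison) and
  the exact out-of-sample risk of any estimate are available in closed
  form from the ground-truth record.
- **Unequal-covariance regime**: per-class decay exponents and amplitudes.
  The comparison scenario pairs a mean difference (δ = 0.5) with strongly
  different spectra (decay 1.3/amp 0.5 vs decay 3.0/amp 1.0): with exactly
  equal class means the class-wise least-squares directions collapse onto
  the constant mode and *neither* model can discriminate, so a pure
  -covariance scenario would be degenerate rather than hard.
- **Seeding**: one scenario seed feeds spawned, counter-based streams for
  geometry and maps; identical scenario + seed is bit-for-bit
  reproducible.

What the generator does **not** emulate: FreeSurfer segmentation
artifacts, misregistration (correspondence is exact by construction), real
cortical folding, heavy-tailed or spatially non-stationary noise.  Green
tests therefore certify the estimator under its own assumptions, not
robustness to real preprocessing error.

## Replication experiment sizes

The experiments in `fosda.experiments` (used by the test suite and
`scripts/acceptance.py`) run at desk scale, chosen so the full suite
completes in minutes on one CPU: solver-versus-oracle on 20 random
instances (s = 162, n = 40); direction recovery at s = 642, n = 200, 10
replicates, λ₂ selected by validation mean squared error of the auxiliary
-response prediction; risk decay over n ∈ {50, 100, 200, 400} at s = 162
with λ₂ tuned per (replicate, n) by exact risk — the empirical analogue of
the rate-optimal penalty sequence; null calibration over 50 replicates;
linear/quadratic comparison over 11 replicates; end-to-end pipeline runs
at s = 162 with 30 subjects per class.

## Limitations

- Correspondence is assumed given; no registration is performed.
- The stationary-velocity Euler flow is not a formal diffeomorphism
  guarantee; the flipped-face diagnostic is the operational check.
- The Gram quadrature at control points is a coarse approximation of the
  double kernel integral; only relative geometry between subjects enters
  the classifier, and the scale ambiguity is absorbed by λ₁ selection.
- FQDA covers the map component only, and its projected-plane rule is a
  documented substitution for an unavailable reference criterion.
- λ selection by validation AUC alone can prefer less interpretable
  directions; the audit table is returned so users can trade accuracy
  against smoothness explicitly.
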