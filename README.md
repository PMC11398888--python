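# fosda — discriminant analysis of functions on surfaces

`fosda` classifies subjects from *functions on surfaces* (FoSs): pairs
`(M_i, z_i)` of a closed two-dimensional surface embedded in R³ and a scalar
map on it, with vertices corresponded across subjects.  The motivating
setting is surface-based neuroimaging — subject-specific cortical surfaces
carrying cortical-thickness maps, with a binary diagnosis to predict — but
nothing in the package is specific to brains: any corresponded
surface-plus-map data (cardiac, musculoskeletal, synthetic) fits.

The difficulty is that the surfaces themselves are random: each subject
lives on its own nonlinear domain, so the predictors are not elements of a
common linear space.  `fosda` handles this in two stages.

**1. Linear representation.**  Every subject is rewritten as a pair of
objects in *linear* function spaces,

    (M_i, z_i)  ≈  (φ_{v_i}(M),  x_i ∘ φ_{v_i}⁻¹),

where `M` is a common template surface, `v_i : R³ → R³` is a smooth velocity
field in an RKHS `V(R³)` (Gaussian kernel) whose flow `φ_{v_i}` deforms the
template onto the subject's surface, and `x_i = z_i ∘ φ_{v_i}` is the map
pulled back to the template.  The representation is invertible, so anything
estimated in `(v, x)`-space can be mapped back to actual surfaces.

**2. Penalized discriminant regression.**  Coding the two classes as
auxiliary responses `y_i ∈ {−n/n₁, +n/n₂}` turns the discriminant problem
into least-squares regression.  The bivariate discriminant direction
`(β^G, β^F)` minimizes

    Σᵢ (yᵢ − ⟨vᵢ, β^G⟩ − ⟨xᵢ, β^F⟩_{L²(M)})²  +  λ₁‖β^G‖²_V  +  λ₂ J(β^F),

with `J(β) = ‖Δ_M β‖²_{L²(M)} + ε‖β‖²_{L²(M)}` a Laplace–Beltrami roughness
penalty that is aware of the geometry of the template.  No covariance
operator is ever formed: a representer expansion for `β^G` (Gram matrix Σ of
the velocity fields) and a linear finite-element discretization for `β^F`
(sparse mass `M`, stiffness `S`, lumped-mass penalty `D = S M̃⁻¹S + εM`)
reduce the problem to one sparse augmented least-squares system solved by
LSQR.  A quadratic extension (`FunctionalQDA`) fits one penalized direction
per class and classifies in the projected plane, for the case of unequal
class covariances.

New subjects are scored by `⟨v*−v̄, β̂^G⟩ + ⟨x*−x̄, β̂^F⟩ > c_th`; sweeping
`(c₁ β̂^G, c₂ β̂^F)` and mapping back through the flow produces discriminant
*trajectories* of surfaces — interpretable morphs from "typical class 1"
to "typical class 2".

## Worked example

Simulate a corresponded two-class dataset on an icosphere template (162
vertices, 40 subjects per class, a smooth thickness contrast plus smooth
geometric variation), fit the discriminant model, and score held-out
subjects:

```python
import numpy as np
from fosda import (SimulationScenario, simulate_dataset, FoSDesign,
                   FunctionalLDA, auc, stratified_split)

data = simulate_dataset(SimulationScenario(level=2, n_per_class=40, seed=7))
design = FoSDesign.from_representations(data.representations)
split = stratified_split(data.labels, (0.6, 0.0, 0.4), seed=7)
train, test = split == 0, split == 2

model = FunctionalLDA(operators=data.operators, lambda1=1.0, lambda2=1e-3)
model.fit(design.subset(np.nonzero(train)[0]), data.labels[train])

scores = model.decision_function(design.subset(np.nonzero(test)[0]))
print(f"test AUC:        {auc(scores, data.labels[test]):.3f}")
print(f"threshold c_th:  {model.threshold_:.3f}")
beta_f = model.discriminant_map()
truth = data.ground_truth.discriminant
M = data.operators.mass
cos = (beta_f.values @ (M @ truth)) / np.sqrt(
    (beta_f.values @ (M @ beta_f.values)) * (truth @ (M @ truth)))
print(f"cosine(beta_F, truth): {cos:.3f}")
```

Output:

```
test AUC:        1.000
threshold c_th:  -0.053
cosine(beta_F, truth): 0.696
```

The scenario's class contrast is strong, so held-out classification is
essentially perfect; the estimated thickness direction `β̂^F` already points
at the generating direction (cosine 0.70 from 48 training subjects at a
fixed λ₂ — with n = 200 and a tuned penalty the median cosine rises above
0.95, see below).  `model.discriminant_map()` / `model.discriminant_velocity()`
return `β̂^F` and `β̂^G` for inspection or for trajectory rendering via
`fosda.trajectory`.

The same workflow is available from the shell on datasets of OFF/PLY meshes
plus vertex-map tables:

```sh
fosda simulate --scenario scenario.yaml --out data/
fosda run --config config.yaml --out results/     # align → represent → fit → evaluate
fosda trajectory --model results/model.npz --template results/template.ply --out traj/
```

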