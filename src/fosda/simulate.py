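"""Synthetic functions-on-surfaces with known ground truth.

The generator emulates the statistical structure the discriminant model
assumes: subjects are smooth deformations of a spherical template carrying
scalar maps whose class-conditional means differ by a smooth bump and whose
fluctuations follow a Karhunen–Loève expansion in the Laplace–Beltrami
eigenbasis of the template (so the noise covariance is smooth and
geometry-aware).  Because both the mean contrast and the noise spectrum are
known in closed form, the induced population discriminant direction and the
exact out-of-sample risk of any estimate are available for testing.

Every random draw flows from a single scenario seed through spawned
`numpy` seed sequences, so sub-generators are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import trimesh

from .fem import FEMOperators, assemble_penalty, lb_eigenpairs
from .mesh import TriangleMesh, VertexFunction
from .representation import (FoS, KernelSpec, LinearRepresentation,
                             VelocityField, default_kernel, deform_mesh,
                             farthest_point_sample)

__all__ = [
    "SimulationScenario",
    "MapGroundTruth",
    "SimulatedDataset",
    "make_template",
    "simulate_maps",
    "simulate_geometries",
    "simulate_dataset",
]


def make_template(level: int) -> TriangleMesh:
    """Unit icosphere by repeated 1-to-4 subdivision of the icosahedron.

    Vertex counts by level: 12, 42, 162, 642, 2562, ...
    """
    if level < 0:
        raise ValueError("subdivision level must be >= 0")
    ico = trimesh.creation.icosphere(subdivisions=level, radius=1.0)
    verts = np.asarray(ico.vertices)
    verts = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    return TriangleMesh(vertices=verts, faces=np.asarray(ico.faces))


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one synthetic study.

    Defaults describe a desk-scale cortical-thickness-like study: a level-2
    icosphere template (162 vertices), 50 subjects per class, a 2.5 mm
    baseline map with a 0.5 mm class contrast concentrated in a smooth
    polar bump, Karhunen–Loève noise over 40 Laplace–Beltrami modes with
    quadratic spectral decay, and mild smooth geometric variation.
    """

    level: int = 2
    n_per_class: int = 50
    # map component
    map_baseline: float = 2.5          # mm, shared mean level
    map_delta: float = 1.0             # mm, L2(M) norm of the mean difference
    bump_center: tuple = (0.0, 0.0, 1.0)
    bump_width: float = 0.7            # radians on the unit sphere
    noise_modes: int = 40              # KL modes (constant mode excluded)
    decay: float = 2.0                 # spectral decay exponent, > 1
    decay_class2: float = 2.0          # used when covariance_regime="unequal"
    noise_amplitude: float = 0.5       # mm, overall KL noise scale
    noise_amplitude_class2: float | None = None
    covariance_regime: str = "equal"   # "equal" | "unequal"
    # geometric component
    geom_amplitude: float = 0.1        # class-mean displacement scale (mm)
    geom_noise: float = 0.03           # per-subject smooth field scale (mm)
    n_control: int = 512               # kernel control points (capped at s)
    kernel_sigma: float | None = None  # default: 0.2 * bbox diagonal
    flow_steps: int = 8
    epsilon: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decay <= 1 or self.decay_class2 <= 1:
            raise ValueError("decay exponents must be > 1 (square-summable "
                             "spectrum)")
        if self.covariance_regime not in ("equal", "unequal"):
            raise ValueError("covariance_regime must be 'equal' or 'unequal'")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")


@dataclass(frozen=True)
class MapGroundTruth:
    """Generating quantities of the map component.

    ``contrast`` is the class mean difference (mu2 - mu1) as vertex values;
    ``discriminant`` is the exact population discriminant direction (None in
    the unequal-covariance regime, where a single linear direction is not
    the right target); ``eigenvalues`` / ``eigenvectors`` span the noise
    model, and ``spectrum`` holds the per-mode noise variances of class 1.

    The scenario is constructed "truth first": the discriminant direction
    is the smooth bump itself and the mean difference is the covariance
    operator applied to it, so the smoothness assumption under which the
    penalized estimator is consistent holds by design.
    """

    contrast: np.ndarray
    contrast_coeffs: np.ndarray
    discriminant: np.ndarray | None
    discriminant_coeffs: np.ndarray | None
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    spectrum: np.ndarray


@dataclass(frozen=True)
class SimulatedDataset:
    labels: np.ndarray
    subjects: tuple[FoS, ...]
    representations: tuple[LinearRepresentation, ...]
    ground_truth: MapGroundTruth
    template: TriangleMesh
    operators: FEMOperators
    kernel: KernelSpec


def _bump_values(mesh: TriangleMesh, center: np.ndarray,
                 width: float) -> np.ndarray:
    """Gaussian bump in angular distance from a point on the unit sphere."""
    c = np.asarray(center, float)
    c = c / np.linalg.norm(c)
    v = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    ang = np.arccos(np.clip(v @ c, -1.0, 1.0))
    return np.exp(-0.5 * (ang / width) ** 2)


def _mode_spectrum(scenario: SimulationScenario, k: int,
                   decay: float, amplitude: float) -> np.ndarray:
    # mode j (1-based over the full eigenbasis) carries variance
    # amplitude^2 * j^-decay; the constant mode j=1 is excluded.
    j = np.arange(2, k + 1, dtype=float)
    return amplitude ** 2 * j ** (-decay)


def simulate_maps(ops: FEMOperators, scenario: SimulationScenario,
                  labels: np.ndarray, rng: np.random.Generator,
                  ) -> tuple[list[VertexFunction], MapGroundTruth]:
    """Class-structured maps  x_i = mu_{g_i} + KL noise  on the template.

    The generating discriminant direction is the spatial bump projected
    onto the simulated KL modes and normalized to unit L2(M) norm; the
    class mean difference is the within-class covariance applied to that
    direction, scaled so its L2(M) norm equals ``map_delta``.  With this
    construction the population discriminant direction (inverse covariance
    of the mean difference, between-class term included) is exactly
    proportional to the smooth bump, so the estimator's target is smooth
    by design.
    """
    s = ops.n_vertices
    k = scenario.noise_modes
    if not 1 < k < s:
        raise ValueError(f"noise_modes must satisfy 1 < k < {s}")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    vals, vecs = lb_eigenpairs(ops, k)
    phis = vecs[:, 1:]                       # drop the constant mode

    bump = _bump_values(ops.mesh, np.asarray(scenario.bump_center),
                        scenario.bump_width)
    b_coef = phis.T @ (ops.mass @ bump)      # eigen-coordinates of the bump
    norm = np.sqrt(np.sum(b_coef ** 2))
    if norm == 0:
        raise ValueError("bump has no component in the simulated modes")
    b_coef = b_coef / norm                   # unit-norm smooth direction

    theta1 = _mode_spectrum(scenario, k, scenario.decay,
                            scenario.noise_amplitude)
    if scenario.covariance_regime == "unequal":
        amp2 = (scenario.noise_amplitude_class2
                if scenario.noise_amplitude_class2 is not None
                else scenario.noise_amplitude)
        theta2 = _mode_spectrum(scenario, k, scenario.decay_class2, amp2)
    else:
        theta2 = theta1

    # mean difference = C_w applied to the bump direction, norm map_delta
    # (noiseless degenerate case: fall back to the raw bump direction)
    cb = theta1 * b_coef
    cb_norm = np.sqrt(np.sum(cb ** 2))
    if cb_norm == 0:
        cb, cb_norm = b_coef, 1.0
    d_coef = (scenario.map_delta * cb / cb_norm if scenario.map_delta != 0
              else np.zeros_like(cb))
    contrast = phis @ d_coef

    if scenario.covariance_regime == "equal":
        pi1 = float(np.mean(labels == classes[0]))
        pi2 = 1.0 - pi1
        # beta0 = (C_w + pi1 pi2 d d')^{-1} d  via Sherman-Morrison
        with np.errstate(divide="ignore"):
            w = np.where(theta1 > 0, d_coef / theta1, 0.0)
        shrink = 1.0 + pi1 * pi2 * float(d_coef @ w)
        beta_coef = w / shrink
        discriminant = phis @ beta_coef
    else:
        beta_coef = None
        discriminant = None

    maps = []
    for g in labels:
        is_first = g == classes[0]
        theta = theta1 if is_first else theta2
        mean = scenario.map_baseline + (-0.5 if is_first else 0.5) * contrast
        zeta = rng.standard_normal(k - 1)
        maps.append(VertexFunction(
            values=mean + phis @ (np.sqrt(theta) * zeta), mesh=ops.mesh))

    gt = MapGroundTruth(contrast=contrast, contrast_coeffs=d_coef,
                        discriminant=discriminant,
                        discriminant_coeffs=beta_coef,
                        eigenvalues=vals, eigenvectors=vecs,
                        spectrum=theta1)
    return maps, gt


def _unit_smooth_field(template: TriangleMesh, control: np.ndarray,
                       kernel: KernelSpec,
                       rng: np.random.Generator) -> VelocityField:
    """Random kernel expansion scaled to unit RMS vertex displacement."""
    coeffs = rng.standard_normal(control.shape)
    v = VelocityField(control_points=control, coefficients=coeffs,
                      kernel=kernel)
    disp = v(template.vertices)
    rms = np.sqrt(np.mean(np.sum(disp ** 2, axis=1)))
    if rms == 0:
        raise ValueError("degenerate random field")
    return (1.0 / rms) * v


def simulate_geometries(template: TriangleMesh, kernel: KernelSpec,
                        scenario: SimulationScenario, labels: np.ndarray,
                        rng: np.random.Generator,
                        ) -> tuple[list[VelocityField], list[TriangleMesh]]:
    """Subject meshes as flows of class-structured smooth velocity fields.

    v_i = +-(geom_amplitude / 2) * class-mean field + geom_noise * subject
    field, all expanded over a shared farthest-point control set.  Errors
    out if any deformation flips a face (amplitudes too large).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    m = min(scenario.n_control, template.n_vertices)
    idx = farthest_point_sample(template.vertices, m, seed=0)
    control = template.vertices[idx]

    mean_field = _unit_smooth_field(template, control, kernel, rng)
    velocities: list[VelocityField] = []
    meshes: list[TriangleMesh] = []
    for g in labels:
        sign = -0.5 if g == classes[0] else 0.5
        v = sign * scenario.geom_amplitude * mean_field
        if scenario.geom_noise > 0:
            v = v + scenario.geom_noise * _unit_smooth_field(
                template, control, kernel, rng)
        res = deform_mesh(template, v, steps=scenario.flow_steps)
        if res.flipped_fraction > 0:
            raise ValueError("deformation flipped faces; reduce "
                             "geom_amplitude / geom_noise")
        velocities.append(v)
        meshes.append(res.mesh)
    return velocities, meshes


def simulate_dataset(scenario: SimulationScenario) -> SimulatedDataset:
    """Full labeled dataset: subjects, exact representations, ground truth.

    Both the raw functions-on-surfaces and their exact linear
    representations are returned, so representation-estimation error can be
    isolated from discriminant-fitting error in experiments.
    """
    if scenario.n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    template = make_template(scenario.level)
    ops = assemble_penalty(template, epsilon=scenario.epsilon)
    kernel = (KernelSpec(scenario.kernel_sigma) if scenario.kernel_sigma
              else default_kernel(template))
    labels = np.repeat([1, 2], scenario.n_per_class)

    ss = np.random.SeedSequence(scenario.seed)
    geom_seed, map_seed = ss.spawn(2)
    vel, meshes = simulate_geometries(template, kernel, scenario, labels,
                                      np.random.default_rng(geom_seed))
    maps, gt = simulate_maps(ops, scenario, labels,
                             np.random.default_rng(map_seed))

    subjects = tuple(
        FoS(geometry=mesh,
            map=VertexFunction(values=fn.values.copy(), mesh=mesh))
        for mesh, fn in zip(meshes, maps))
    reps = tuple(LinearRepresentation(velocity=v, normalized_map=fn)
                 for v, fn in zip(vel, maps))
    return SimulatedDataset(labels=labels, subjects=subjects,
                            representations=reps, ground_truth=gt,
                            template=template, operators=ops, kernel=kernel)
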