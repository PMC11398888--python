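"""Dataset manifests, splits, model archives and the end-to-end pipeline.

A run goes: load (or simulate) corresponded surfaces + vertex maps + labels
-> Generalized Procrustes alignment -> velocity-field estimation against
the template -> pullback of the maps -> stratified train/validation/test
split -> lambda-grid fit with validation AUC selection -> threshold choice
on validation -> test evaluation -> artifacts (model archive, report,
optional discriminant-trajectory meshes).

Every artifact carries the hash of the effective configuration (defaults
materialized), and all randomness flows from the single configured seed, so
reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .discriminant import (FoSDesign, FunctionalLDA, auc, choose_threshold,
                           select_lambdas)
from .fem import FEMOperators, assemble_penalty
from .mesh import (TriangleMesh, VertexFunction, read_mesh,
                   read_vertex_function, write_mesh, write_vertex_function)
from .representation import (FoS, KernelSpec, LinearRepresentation,
                             VelocityField, default_kernel, estimate_velocity,
                             farthest_point_sample, gpa_align, pullback_map,
                             trajectory)
from .simulate import SimulationScenario, simulate_dataset

__all__ = [
    "DatasetManifest",
    "stratified_split",
    "split_dataset",
    "run_pipeline",
    "save_model",
    "load_model",
    "DEFAULT_CONFIG",
]


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetManifest:
    """Paths and labels of a dataset on disk, with optional split column."""

    template: str
    subjects: pd.DataFrame  # columns: mesh, map, label, [split]

    REQUIRED = ("mesh", "map", "label")

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        subjects = pd.DataFrame(raw["subjects"])
        for col in cls.REQUIRED:
            if col not in subjects.columns:
                raise ValueError(f"manifest missing per-subject field {col!r}")
        base = path.parent
        for col in ("mesh", "map"):
            subjects[col] = [str((base / p)) if not Path(p).is_absolute()
                             else p for p in subjects[col]]
        template = raw["template"]
        if not Path(template).is_absolute():
            template = str(base / template)
        missing = [p for p in ([template] + list(subjects["mesh"])
                               + list(subjects["map"]))
                   if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"manifest paths do not exist: "
                                    f"{missing[:3]} ...")
        return cls(template=template, subjects=subjects)

    def save(self, path: str | Path) -> None:
        payload = {"template": self.template,
                   "subjects": self.subjects.to_dict(orient="records")}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def stratified_split(labels: np.ndarray, fractions: tuple[float, ...],
                     seed: int) -> np.ndarray:
    """Stratified-by-class random split assignment.

    Returns an integer array (0 = train, 1 = validation, 2 = test, ...).
    Within each class the split sizes equal the rounded targets up to the
    +-1 forced by largest-remainder rounding.
    """
    fractions = np.asarray(fractions, float)
    if abs(fractions.sum() - 1.0) > 1e-9 or np.any(fractions < 0):
        raise ValueError("split fractions must be non-negative and sum to 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        rng.shuffle(idx)
        raw = fractions * len(idx)
        counts = np.floor(raw).astype(int)
        rem = len(idx) - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:rem]] += 1
        bounds = np.cumsum(counts)
        parts = np.split(idx, bounds[:-1])
        for k, part in enumerate(parts):
            assignment[part] = k
    return assignment


def split_dataset(manifest: DatasetManifest,
                  fractions: tuple[float, float, float] = (0.5, 0.2, 0.3),
                  seed: int = 0) -> DatasetManifest:
    """Attach a stratified train/validation/test split to a manifest."""
    labels = manifest.subjects["label"].to_numpy()
    assignment = stratified_split(labels, fractions, seed)
    names = np.array(["train", "validation", "test"])
    subjects = manifest.subjects.copy()
    subjects["split"] = names[assignment]
    return DatasetManifest(template=manifest.template, subjects=subjects)


# ---------------------------------------------------------------------------
# Model archive
# ---------------------------------------------------------------------------

def save_model(model: FunctionalLDA, path: str | Path,
               config_hash: str = "") -> None:
    """Serialize a fitted model (coefficients, means, tuning, threshold)."""
    payload = {
        "coef_map": model.coef_map_,
        "map_mean": model.map_mean_,
        "threshold": np.array(model.threshold_),
        "classes": model.classes_,
        "lambda1": np.array(model.lambda1),
        "lambda2": np.array(model.lambda2),
        "epsilon": np.array(model.operators.epsilon),
        "config_hash": np.array(config_hash),
    }
    if model.coef_geometry_ is not None:
        payload.update({
            "coef_geometry": model.coef_geometry_,
            "velocity_mean_coeffs": model.velocity_mean_.coefficients,
            "control_points": model.velocity_mean_.control_points,
            "kernel_sigma": np.array(model.velocity_mean_.kernel.sigma),
            "train_evals": model._train_evals_,
            "quad_weights": model._quad_weights_,
        })
    np.savez_compressed(str(path), **payload)


def load_model(path: str | Path, operators: FEMOperators) -> FunctionalLDA:
    with np.load(str(path), allow_pickle=False) as data:
        model = FunctionalLDA(operators=operators,
                              lambda1=float(data["lambda1"]),
                              lambda2=float(data["lambda2"]))
        model.coef_map_ = data["coef_map"]
        model.map_mean_ = data["map_mean"]
        model.threshold_ = float(data["threshold"])
        model.classes_ = data["classes"]
        if "coef_geometry" in data:
            kernel = KernelSpec(sigma=float(data["kernel_sigma"]))
            model.coef_geometry_ = data["coef_geometry"]
            model.velocity_mean_ = VelocityField(
                control_points=data["control_points"],
                coefficients=data["velocity_mean_coeffs"], kernel=kernel)
            model._quad_points_ = data["control_points"]
            model._quad_weights_ = data["quad_weights"]
            model._train_evals_ = data["train_evals"]
            from .discriminant import _weighted_kernel
            model._wkw_ = _weighted_kernel(kernel, model._quad_points_,
                                           model._quad_weights_)
        else:
            model.coef_geometry_ = None
            model.velocity_mean_ = None
    return model


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "representation": {
        "steps": 1,          # flow steps for velocity estimation/transport
        "gamma": 1e-8,       # matching ridge; near-interpolation by default
        "n_control": 512,
        "kernel_scale": 0.2,  # sigma as a fraction of the bbox diagonal
    },
    "fit": {
        "epsilon": 1e-3,
        "lambda1_grid": [1e-2, 1.0, 1e2],
        "lambda2_grid": [1e-4, 1e-2, 1.0],
        "solver_tol": 1e-10,
    },
    "split": {"fractions": [0.5, 0.2, 0.3]},
    "threshold": "youden",
    "trajectory": None,      # e.g. {"c1": [-1, 0, 1], "c2": [-1, 0, 1]}
}


def _merge(defaults: dict, override: dict) -> dict:
    out = {}
    for key, val in defaults.items():
        if key in override and isinstance(val, dict) \
                and isinstance(override[key], dict):
            out[key] = _merge(val, override[key])
        elif key in override:
            out[key] = override[key]
        else:
            out[key] = val
    for key, val in override.items():
        if key not in out:
            out[key] = val
    return out


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _load_inputs(config: dict):
    """Subjects (FoS), labels, from a scenario block or a manifest."""
    if "scenario" in config and config["scenario"]:
        scenario = SimulationScenario(**config["scenario"])
        data = simulate_dataset(scenario)
        return list(data.subjects), np.asarray(data.labels)
    if "data" in config and config["data"]:
        manifest = DatasetManifest.load(config["data"]["manifest"])
        subjects = []
        for _, row in manifest.subjects.iterrows():
            mesh = read_mesh(row["mesh"])
            fn = read_vertex_function(row["map"], mesh)
            subjects.append(FoS(geometry=mesh, map=fn))
        return subjects, manifest.subjects["label"].to_numpy()
    raise ValueError("config must provide either a 'scenario' or a 'data' "
                     "block")


def run_pipeline(config: dict, output_dir: str | Path | None = None) -> dict:
    """Execute the full align / represent / fit / evaluate pipeline.

    Returns the report dictionary; if ``output_dir`` is given, writes the
    effective config, the report, the model archive and any requested
    trajectory meshes there.
    """
    config = _merge(DEFAULT_CONFIG, config or {})
    chash = _config_hash(config)
    seed = int(config["seed"])

    subjects, labels = _load_inputs(config)
    n = len(subjects)
    if n != len(labels):
        raise ValueError("labels and subjects disagree on n")

    # 1. alignment
    meshes = [s.geometry for s in subjects]
    aligned, template = gpa_align(meshes)
    ops = assemble_penalty(template, epsilon=float(config["fit"]["epsilon"]))

    # 2. representation
    rep_cfg = config["representation"]
    kernel = default_kernel(template, scale=float(rep_cfg["kernel_scale"]))
    m = min(int(rep_cfg["n_control"]), template.n_vertices)
    control = template.vertices[farthest_point_sample(template.vertices, m,
                                                      seed=seed)]
    steps = int(rep_cfg["steps"])
    reps = []
    for i, (subject, mesh_i) in enumerate(zip(subjects, aligned)):
        try:
            v = estimate_velocity(template, mesh_i, kernel, control,
                                  gamma=float(rep_cfg["gamma"]), steps=steps)
            x = pullback_map(FoS(geometry=mesh_i, map=subject.map), template)
        except Exception as err:
            raise RuntimeError(f"representation failed for subject {i}: "
                               f"{err}") from err
        reps.append(LinearRepresentation(velocity=v, normalized_map=x))
    design = FoSDesign.from_representations(reps)

    # 3. split
    assignment = stratified_split(labels, tuple(config["split"]["fractions"]),
                                  seed)
    tr, va, te = (np.nonzero(assignment == k)[0] for k in range(3))

    # 4. model selection on the lambda grid
    grid = [(l1, l2) for l1 in config["fit"]["lambda1_grid"]
            for l2 in config["fit"]["lambda2_grid"]]
    best, table = select_lambdas(
        (design.subset(tr), labels[tr]), (design.subset(va), labels[va]),
        grid, ops, solver_tol=float(config["fit"]["solver_tol"]))

    # 5. threshold on validation, evaluation on test
    val_scores = best.decision_function(design.subset(va))
    crit = config["threshold"]
    if isinstance(crit, list):
        crit = tuple(crit)
    best.set_threshold(val_scores, labels[va], crit)
    test_scores = best.decision_function(design.subset(te))
    test_labels = labels[te]
    pos = test_labels == best.classes_[1]
    sensitivity = float((test_scores[pos] > best.threshold_).mean())
    specificity = float((test_scores[~pos] <= best.threshold_).mean())
    report = {
        "config_hash": chash,
        "seed": seed,
        "n_subjects": int(n),
        "n_vertices": int(template.n_vertices),
        "n_control_points": int(m),
        "split_sizes": {"train": int(len(tr)), "validation": int(len(va)),
                        "test": int(len(te))},
        "selected": {"lambda1": float(best.lambda1),
                     "lambda2": float(best.lambda2)},
        "threshold": float(best.threshold_),
        "validation_auc_table": table.to_dict(orient="records"),
        "test_auc": float(auc(test_scores, test_labels)),
        "test_sensitivity": sensitivity,
        "test_specificity": specificity,
    }

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config, fh, sort_keys=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        save_model(best, out / "model.npz", config_hash=chash)
        write_mesh(template, out / "template.ply")
        traj_cfg = config.get("trajectory")
        if traj_cfg:
            betaG = best.discriminant_velocity()
            betaF = best.discriminant_map()
            vmean = best.velocity_mean_
            if betaG is None or vmean is None:
                raise ValueError("trajectories need a geometric component")
            for c1 in traj_cfg["c1"]:
                for c2 in traj_cfg["c2"]:
                    fos = trajectory(template, vmean, betaG, betaF,
                                     float(c1), float(c2), steps=max(steps, 4))
                    tag = f"c1_{c1}_c2_{c2}".replace(".", "p")
                    write_mesh(fos.geometry, out / f"trajectory_{tag}.ply")
                    write_vertex_function(fos.map,
                                          out / f"trajectory_{tag}_map.tsv")
    return report
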