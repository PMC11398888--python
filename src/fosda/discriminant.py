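"""Penalized functional linear discriminant analysis (FLDA).

The two-class discriminant problem is recast as least-squares regression of
auxiliary responses y_i in {-n/n1, +n/n2} on the bivariate functional
predictors (v_i, x_i): velocity fields encoding subject geometry and
normalized maps on the template.  The discriminant direction (betaG, betaF)
minimizes

    || y - Sigma cG - X M cF ||^2 + lambda1 cG' Sigma cG + lambda2 cF' D cF

where Sigma is the RKHS Gram matrix of the velocity fields (the representer
basis for betaG), X holds the map coefficients, M the FE mass matrix and D
the Laplace–Beltrami roughness penalty.  The problem is solved as a sparse
augmented least-squares system by LSQR, never forming the normal matrix.

The estimator surface follows scikit-learn conventions: ``FunctionalLDA``
has ``fit`` / ``decision_function`` / ``predict`` and trailing-underscore
fitted attributes, and composes with sklearn model selection on top of the
:class:`FoSDesign` predictor container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score

from .fem import FEMOperators, sparse_cholesky
from .mesh import VertexFunction
from .representation import (KernelSpec, LinearRepresentation, VelocityField,
                             gaussian_kernel)

__all__ = [
    "AuxiliaryResponses",
    "GramMatrix",
    "FitConfig",
    "FoSDesign",
    "FunctionalLDA",
    "auxiliary_responses",
    "gram_matrix",
    "build_augmented_system",
    "solve_augmented",
    "fit_flda",
    "choose_threshold",
    "auc",
    "select_lambdas",
]


# ---------------------------------------------------------------------------
# Auxiliary responses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AuxiliaryResponses:
    """Regression targets y_i in {-n/n1, +n/n2} encoding the two classes."""

    y: np.ndarray
    n1: int
    n2: int

    @property
    def n(self) -> int:
        return self.n1 + self.n2


def auxiliary_responses(labels: np.ndarray) -> AuxiliaryResponses:
    """Encode binary labels as zero-mean regression targets.

    The first class in sorted label order is coded -n/n1, the second +n/n2,
    so that the responses sum to zero and the least-squares fit against them
    targets the discriminant direction.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    n = len(labels)
    n1 = int(np.sum(labels == classes[0]))
    n2 = n - n1
    y = np.where(labels == classes[0], -n / n1, n / n2).astype(float)
    return AuxiliaryResponses(y=y, n1=n1, n2=n2)


# ---------------------------------------------------------------------------
# Gram matrix of velocity fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GramMatrix:
    """Quadrature approximation of Sigma_ij = <v_i, L_K v_j>."""

    sigma: np.ndarray
    quadrature: str = "control-point evaluations, uniform unit weights"


def _weighted_kernel(kernel: KernelSpec, quad_points: np.ndarray,
                     quad_weights: np.ndarray) -> np.ndarray:
    K = gaussian_kernel(kernel, quad_points, quad_points)
    return quad_weights[:, None] * K * quad_weights[None, :]


def gram_matrix(velocities: Sequence[VelocityField], kernel: KernelSpec,
                quad_points: np.ndarray,
                quad_weights: np.ndarray) -> GramMatrix:
    """Pairwise kernel-weighted inner products of velocity fields.

    Approximates the double integral  Sigma_ij = int int v_i(p)' K(p, q)
    v_j(q) dp dq  by the double quadrature sum over ``quad_points`` with the
    given positive weights.
    """
    quad_points = np.atleast_2d(np.asarray(quad_points, float))
    quad_weights = np.asarray(quad_weights, float).ravel()
    if np.any(quad_weights <= 0):
        raise ValueError("quadrature weights must be positive")
    for v in velocities:
        if v.kernel != kernel:
            raise ValueError("velocity field kernel mismatch")
    evals = np.stack([v(quad_points) for v in velocities])  # (n, m, 3)
    WKW = _weighted_kernel(kernel, quad_points, quad_weights)
    sigma = np.einsum("iad,ab,jbd->ij", evals, WKW, evals, optimize=True)
    return GramMatrix(sigma=0.5 * (sigma + sigma.T))


# ---------------------------------------------------------------------------
# Fit configuration and predictor container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitConfig:
    """Tuning and solver parameters for the augmented least-squares fit."""

    lambda1: float = 1.0
    lambda2: float = 1.0
    epsilon: float = 0.0
    solver_tol: float = 1e-10
    max_iter: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lambda1 > 0 and self.lambda2 > 0):
            raise ValueError("lambda1 and lambda2 must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


@dataclass(frozen=True)
class FoSDesign:
    """Predictors for n subjects: velocity fields plus map coefficients.

    ``maps`` is the (n, s) matrix of vertex values of the normalized maps;
    ``velocities`` may be None for maps-only (univariate) modelling.
    """

    maps: np.ndarray
    velocities: tuple[VelocityField, ...] | None = None

    def __post_init__(self) -> None:
        maps = np.atleast_2d(np.asarray(self.maps, float))
        object.__setattr__(self, "maps", maps)
        if self.velocities is not None:
            vel = tuple(self.velocities)
            if len(vel) != len(maps):
                raise ValueError("velocities and maps disagree on n")
            object.__setattr__(self, "velocities", vel)

    def __len__(self) -> int:
        return len(self.maps)

    def subset(self, idx: np.ndarray) -> "FoSDesign":
        vel = None if self.velocities is None else tuple(
            self.velocities[i] for i in idx)
        return FoSDesign(maps=self.maps[idx], velocities=vel)

    @classmethod
    def from_representations(cls, reps: Sequence[LinearRepresentation]
                             ) -> "FoSDesign":
        maps = np.stack([r.normalized_map.values for r in reps])
        return cls(maps=maps, velocities=tuple(r.velocity for r in reps))


# ---------------------------------------------------------------------------
# Augmented sparse system
# ---------------------------------------------------------------------------

def build_augmented_system(sigma: GramMatrix | None, X: np.ndarray,
                           ops: FEMOperators, config: FitConfig,
                           y: AuxiliaryResponses | np.ndarray,
                           ) -> tuple[sp.csr_matrix, np.ndarray]:
    """Assemble the augmented least-squares form of the penalized problem.

    With n subjects and s vertices the matrix stacks, top to bottom:

        [ Sigma                 X M                    ]   (n rows, data fit)
        [ 0                     sqrt(l2) Mlump^-1/2 S  ]   (s rows, roughness)
        [ 0                     sqrt(l2 eps) R_M       ]   (s rows, shrinkage)
        [ sqrt(l1) L_Sigma      0                      ]   (n rows, RKHS norm)

    with R_M' R_M = M and L_Sigma' L_Sigma = Sigma, so that the normal
    equations reproduce the penalized stationarity conditions exactly.  The
    shrinkage block is omitted when epsilon = 0 (n + s + n rows instead of
    n + 2s + n); when ``sigma`` is None the Sigma blocks and the geometric
    coefficients are dropped entirely (maps-only model).  The right-hand
    side is (y, 0).
    """
    yvec = y.y if isinstance(y, AuxiliaryResponses) else np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, s = X.shape
    if s != ops.n_vertices:
        raise ValueError("map coefficient count does not match the mesh")
    if len(yvec) != n:
        raise ValueError("responses and design disagree on n")

    XM = sp.csr_matrix(X @ ops.mass)
    sl2 = np.sqrt(config.lambda2)
    rough = sl2 * sp.diags(1.0 / np.sqrt(ops.lumped_mass)) @ ops.stiffness

    right_blocks = [XM, rough]
    if config.epsilon > 0:
        RM = sparse_cholesky(ops.mass)
        right_blocks.append(sl2 * np.sqrt(config.epsilon) * RM)

    if sigma is None:
        A = sp.vstack([b.tocsr() for b in right_blocks], format="csr")
        rhs = np.concatenate([yvec, np.zeros(A.shape[0] - n)])
        return A, rhs

    S = sigma.sigma
    if S.shape != (n, n):
        raise ValueError("Gram matrix does not match the design size")
    trace = float(np.trace(S))
    if trace > 0:
        jitter = 1e-10 * trace / n
        L = np.linalg.cholesky(S + jitter * np.eye(n)).T  # L'L = Sigma
    else:
        L = np.zeros((n, n))
    sl1 = np.sqrt(config.lambda1)
    blocks = [[sp.csr_matrix(S), XM]]
    blocks += [[None, b] for b in right_blocks[1:]]
    blocks += [[sp.csr_matrix(sl1 * L), None]]
    A = sp.bmat(blocks, format="csr")
    rhs = np.concatenate([yvec, np.zeros(A.shape[0] - n)])
    return A, rhs


def solve_augmented(A: sp.spmatrix, rhs: np.ndarray,
                    config: FitConfig) -> np.ndarray:
    """LSQR solution of the augmented system; never forms A'A densely."""
    iter_lim = config.max_iter or max(10 * A.shape[1], 2000)
    sol = spla.lsqr(A, rhs, atol=config.solver_tol, btol=config.solver_tol,
                    iter_lim=iter_lim)
    coeffs, istop, itn = sol[0], sol[1], sol[2]
    if istop == 7:
        warnings.warn(f"LSQR hit the iteration cap ({itn}); achieved "
                      f"residual-gradient tolerance {sol[7]:.2e}",
                      RuntimeWarning, stacklevel=2)
    return coeffs


# ---------------------------------------------------------------------------
# Threshold / AUC / model selection helpers
# ---------------------------------------------------------------------------

def choose_threshold(scores: np.ndarray, labels: np.ndarray,
                     criterion: str | tuple = "youden") -> float:
    """Score cut-off for the rule  score > c_th  -> second class.

    ``criterion`` is "youden" (maximize sensitivity + specificity - 1) or
    ("fixed_specificity", q) for the smallest threshold with specificity at
    least q.  Candidate thresholds are midpoints between consecutive
    distinct scores; ties are broken toward the smallest threshold.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("need exactly 2 classes")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        raise ValueError("no discriminating threshold: all scores equal")
    cands = 0.5 * (uniq[:-1] + uniq[1:])
    pos = labels == classes[1]
    sens = np.array([(scores[pos] > c).mean() for c in cands])
    spec = np.array([(scores[~pos] <= c).mean() for c in cands])
    if criterion == "youden":
        J = sens + spec - 1.0
        return float(cands[np.argmax(J)])  # argmax takes the first (smallest)
    if isinstance(criterion, tuple) and criterion[0] == "fixed_specificity":
        q = float(criterion[1])
        ok = np.nonzero(spec >= q)[0]
        if ok.size == 0:
            raise ValueError(f"no threshold achieves specificity >= {q}")
        return float(cands[ok[0]])
    raise ValueError(f"unknown criterion {criterion!r}")


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann–Whitney) AUC with ties counted one half."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("need exactly 2 classes")
    return float(roc_auc_score(labels == classes[1], np.asarray(scores, float)))


# ---------------------------------------------------------------------------
# The estimator
# ---------------------------------------------------------------------------

class FunctionalLDA(BaseEstimator, ClassifierMixin):
    """Penalized functional linear discriminant classifier.

    Parameters
    ----------
    operators : FEMOperators
        Assembled FE structure of the template mesh (carries epsilon).
    lambda1 : float
        Penalty weight on the RKHS norm of the geometric direction betaG.
    lambda2 : float
        Penalty weight on the roughness J(betaF) of the map direction.
    solver_tol, max_iter :
        LSQR stopping parameters.
    threshold_criterion :
        Passed to :func:`choose_threshold` when fitting sets the score
        cut-off from the training scores (a pipeline will typically reset
        it from validation data via :meth:`set_threshold`).

    Attributes
    ----------
    coef_map_ : (s,) array
        FE coefficients of the map discriminant direction betaF.
    coef_geometry_ : (n,) array or None
        Representer coefficients of the geometric direction betaG.
    map_mean_ : (s,) array
        Training mean of the normalized maps (x bar).
    velocity_mean_ : VelocityField or None
        Training mean velocity field (v bar, mean of coefficients).
    threshold_ : float
        Score cut-off; predict assigns the second class when score > c_th.
    """

    def __init__(self, operators: FEMOperators | None = None,
                 lambda1: float = 1.0, lambda2: float = 1.0,
                 solver_tol: float = 1e-10, max_iter: int | None = None,
                 threshold_criterion: str | tuple = "youden"):
        self.operators = operators
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.solver_tol = solver_tol
        self.max_iter = max_iter
        self.threshold_criterion = threshold_criterion

    # -- internal ----------------------------------------------------------
    def _config(self) -> FitConfig:
        return FitConfig(lambda1=self.lambda1, lambda2=self.lambda2,
                         epsilon=self.operators.epsilon,
                         solver_tol=self.solver_tol, max_iter=self.max_iter)

    def _as_design(self, X) -> FoSDesign:
        if isinstance(X, FoSDesign):
            return X
        if (isinstance(X, Sequence) and len(X)
                and isinstance(X[0], LinearRepresentation)):
            return FoSDesign.from_representations(X)
        return FoSDesign(maps=np.asarray(X, float))

    def _centered_evals(self, velocities: Sequence[VelocityField]
                        ) -> np.ndarray:
        """Evaluate centered fields at the quadrature (= control) points."""
        out = np.stack([(v + (-1.0) * self.velocity_mean_)(self._quad_points_)
                        for v in velocities])
        return out

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y) -> "FunctionalLDA":
        if self.operators is None:
            raise ValueError("operators must be provided before fitting")
        design = self._as_design(X)
        labels = np.asarray(y)
        if len(labels) != len(design):
            raise ValueError("X and y disagree on n")
        resp = auxiliary_responses(labels)
        self.classes_ = np.unique(labels)
        ops = self.operators

        maps = design.maps
        if maps.shape[1] != ops.n_vertices:
            raise ValueError("maps do not live on the operators' mesh")
        self.map_mean_ = maps.mean(axis=0)
        Xc = maps - self.map_mean_

        sigma = None
        if design.velocities is not None:
            vel = design.velocities
            kernel = vel[0].kernel
            cps = vel[0].control_points
            mean_coef = np.mean([v.coefficients for v in vel], axis=0)
            self.velocity_mean_ = VelocityField(control_points=cps,
                                                coefficients=mean_coef,
                                                kernel=kernel)
            self._quad_points_ = cps
            self._quad_weights_ = np.ones(len(cps))
            self._train_evals_ = self._centered_evals(vel)
            WKW = _weighted_kernel(kernel, cps, self._quad_weights_)
            self._wkw_ = WKW
            smat = np.einsum("iad,ab,jbd->ij", self._train_evals_, WKW,
                             self._train_evals_, optimize=True)
            sigma = GramMatrix(sigma=0.5 * (smat + smat.T))
            self.gram_ = sigma
        else:
            self.velocity_mean_ = None
            self.gram_ = None

        geom_scale = 0.0 if sigma is None else float(np.abs(sigma.sigma).max())
        if float(np.abs(Xc).max()) == 0.0 and geom_scale == 0.0:
            raise ValueError("degenerate training data: all predictors "
                             "identical")

        config = self._config()
        A, rhs = build_augmented_system(sigma, Xc, ops, config, resp)
        coeffs = solve_augmented(A, rhs, config)
        n = len(design)
        if sigma is None:
            self.coef_geometry_ = None
            self.coef_map_ = coeffs
        else:
            self.coef_geometry_ = coeffs[:n]
            self.coef_map_ = coeffs[n:]

        self.train_scores_ = self.decision_function(design)
        try:
            self.threshold_ = choose_threshold(self.train_scores_, labels,
                                               self.threshold_criterion)
        except ValueError:
            self.threshold_ = 0.0
        return self

    def decision_function(self, X) -> np.ndarray:
        design = self._as_design(X)
        maps = design.maps
        if maps.shape[1] != self.operators.n_vertices:
            raise ValueError("maps do not live on the operators' mesh")
        scores = (maps - self.map_mean_) @ (self.operators.mass
                                            @ self.coef_map_)
        if self.coef_geometry_ is not None:
            if design.velocities is None:
                raise ValueError("model was fit with velocities; the design "
                                 "must supply them")
            evals = self._centered_evals(design.velocities)
            rows = np.einsum("iad,ab,jbd->ij", evals, self._wkw_,
                             self._train_evals_, optimize=True)
            scores = scores + rows @ self.coef_geometry_
        return scores

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[(scores > self.threshold_).astype(int)]

    def set_threshold(self, scores: np.ndarray, labels: np.ndarray,
                      criterion: str | tuple | None = None) -> float:
        """Re-pick the cut-off from held-out scores (e.g. a validation set)."""
        crit = criterion or self.threshold_criterion
        self.threshold_ = choose_threshold(scores, labels, crit)
        return self.threshold_

    def discriminant_map(self) -> VertexFunction:
        """betaF as a vertex function on the template mesh."""
        return VertexFunction(values=self.coef_map_.copy(),
                              mesh=self.operators.mesh)

    def discriminant_velocity(self) -> VelocityField | None:
        """betaG collapsed onto the shared control-point basis.

        With all training fields sharing control points and a Gaussian
        kernel, the representer expansion  sum_i cG_i int K(p,.) v_i(p) dp
        evaluated by the same control-point quadrature is itself a kernel
        expansion with coefficients  sum_i cG_i w_a v_i(p_a).
        """
        if self.coef_geometry_ is None:
            return None
        coeffs = np.einsum("i,iad,a->ad", self.coef_geometry_,
                           self._train_evals_, self._quad_weights_)
        return VelocityField(control_points=self._quad_points_,
                             coefficients=coeffs,
                             kernel=self.velocity_mean_.kernel)


def fit_flda(design, labels, operators: FEMOperators,
             config: FitConfig | None = None) -> FunctionalLDA:
    """Functional interface over :class:`FunctionalLDA`."""
    config = config or FitConfig()
    est = FunctionalLDA(operators=operators, lambda1=config.lambda1,
                        lambda2=config.lambda2, solver_tol=config.solver_tol,
                        max_iter=config.max_iter)
    return est.fit(design, labels)


def select_lambdas(train: tuple, validation: tuple,
                   grid: Sequence[tuple[float, float]],
                   operators: FEMOperators,
                   solver_tol: float = 1e-10,
                   ) -> tuple[FunctionalLDA, pd.DataFrame]:
    """Grid search (lambda1, lambda2) maximizing validation AUC.

    Ties are broken toward the larger penalties (smoother estimates).
    Returns the refitted best estimator and the full audit table.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty lambda grid")
    Xtr, ytr = train
    Xva, yva = validation
    rows = []
    for lam1, lam2 in grid:
        est = FunctionalLDA(operators=operators, lambda1=lam1, lambda2=lam2,
                            solver_tol=solver_tol)
        est.fit(Xtr, ytr)
        val_auc = auc(est.decision_function(Xva), yva)
        rows.append({"lambda1": lam1, "lambda2": lam2, "val_auc": val_auc})
    table = pd.DataFrame(rows)
    best_auc = table["val_auc"].max()
    top = table[table["val_auc"] == best_auc]
    top = top.sort_values(["lambda1", "lambda2"]).iloc[-1]
    best = FunctionalLDA(operators=operators, lambda1=float(top["lambda1"]),
                         lambda2=float(top["lambda2"]),
                         solver_tol=solver_tol).fit(Xtr, ytr)
    return best, table
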