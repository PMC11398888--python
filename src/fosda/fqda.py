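"""Approximate functional quadratic discriminant analysis (FQDA).

When the two classes are believed to have different covariance structures,
a single discriminant direction is insufficient.  FQDA fits one penalized
direction per class,

    beta1 = argmin (1/n1) sum_{g_i=1} (1 - <x_i, beta1>)^2 + lambda1 J(beta1)
    beta2 = argmin (1/n2) sum_{g_i=2} (1 + <x_i, beta2>)^2 + lambda2 J(beta2),

projects every map onto the plane u = (<x, beta1>, <x, beta2>), and
classifies in that plane with a two-class Gaussian quadratic rule
(class-wise means and 2x2 covariances, priors from training frequencies).
The Gaussian rule on the projections is this package's concrete choice for
the "project, then assign" step; it is standard, testable, and reduces to a
linear rule when the projected covariances coincide.

Maps are used uncentered: the class-specific targets +-1 make the fitted
directions track the class mean structure, and the projected covariances
carry the second-order differences.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin

from .discriminant import FitConfig, solve_augmented
from .fem import FEMOperators, sparse_cholesky

__all__ = ["FunctionalQDA", "fit_fqda", "classify_fqda"]


def _single_class_system(Xc: np.ndarray, ops: FEMOperators, lam: float,
                         target: float, config: FitConfig):
    """Augmented system for one class-specific penalized direction.

    Minimizes (1/n_c) || target*1 - Xc M c ||^2 + lam c' D c, stacked as
    [Xc M / sqrt(n_c); sqrt(lam) Mlump^-1/2 S; sqrt(lam eps) R_M].
    """
    n_c = len(Xc)
    XM = sp.csr_matrix(Xc @ ops.mass) / np.sqrt(n_c)
    sl = np.sqrt(lam)
    blocks = [XM, sl * sp.diags(1.0 / np.sqrt(ops.lumped_mass)) @ ops.stiffness]
    if ops.epsilon > 0:
        blocks.append(sl * np.sqrt(ops.epsilon) * sparse_cholesky(ops.mass))
    A = sp.vstack([sp.csr_matrix(b) for b in blocks], format="csr")
    rhs = np.concatenate([np.full(n_c, target) / np.sqrt(n_c),
                          np.zeros(A.shape[0] - n_c)])
    return A, rhs


class FunctionalQDA(BaseEstimator, ClassifierMixin):
    """Two-direction penalized quadratic discriminant classifier.

    Parameters
    ----------
    operators : FEMOperators
        FE structure of the template (mass, stiffness, penalty, epsilon).
    lambda1, lambda2 : float
        Roughness penalties for the class-1 and class-2 directions.

    Attributes
    ----------
    coef_class1_, coef_class2_ : (s,) arrays
        FE coefficients of beta1 and beta2.
    means_ : (2, 2) array; covariances_ : (2, 2, 2); priors_ : (2,)
        Gaussian parameters of the projected-plane classifier.
    """

    def __init__(self, operators: FEMOperators | None = None,
                 lambda1: float = 1.0, lambda2: float = 1.0,
                 solver_tol: float = 1e-10, max_iter: int | None = None):
        self.operators = operators
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.solver_tol = solver_tol
        self.max_iter = max_iter

    def fit(self, X, y) -> "FunctionalQDA":
        maps = np.atleast_2d(np.asarray(X, float))
        labels = np.asarray(y)
        classes = np.unique(labels)
        if len(classes) != 2:
            raise ValueError("need exactly 2 classes")
        ops = self.operators
        config = FitConfig(lambda1=self.lambda1, lambda2=self.lambda2,
                           epsilon=ops.epsilon, solver_tol=self.solver_tol,
                           max_iter=self.max_iter)
        self.classes_ = classes
        X1 = maps[labels == classes[0]]
        X2 = maps[labels == classes[1]]
        if len(X1) == 0 or len(X2) == 0:
            raise ValueError("empty class")
        A1, r1 = _single_class_system(X1, ops, self.lambda1, +1.0, config)
        A2, r2 = _single_class_system(X2, ops, self.lambda2, -1.0, config)
        self.coef_class1_ = solve_augmented(A1, r1, config)
        self.coef_class2_ = solve_augmented(A2, r2, config)

        U = self._project(maps)
        self.means_ = np.stack([U[labels == c].mean(axis=0) for c in classes])
        covs = []
        for c in classes:
            Uc = U[labels == c]
            cov = np.cov(Uc, rowvar=False)
            # jitter keeps the 2x2 covariance invertible in degenerate runs
            cov = cov + 1e-12 * max(np.trace(cov), 1.0) * np.eye(2)
            covs.append(cov)
        self.covariances_ = np.stack(covs)
        self.priors_ = np.array([len(X1), len(X2)]) / len(maps)
        return self

    def _project(self, maps: np.ndarray) -> np.ndarray:
        M = self.operators.mass
        u1 = maps @ (M @ self.coef_class1_)
        u2 = maps @ (M @ self.coef_class2_)
        return np.column_stack([u1, u2])

    def _log_discriminants(self, U: np.ndarray) -> np.ndarray:
        out = np.empty((len(U), 2))
        for k in range(2):
            cov = self.covariances_[k]
            diff = U - self.means_[k]
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                raise ValueError("projected covariance is not positive "
                                 "definite")
            maha = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
            out[:, k] = -0.5 * logdet - 0.5 * maha + np.log(self.priors_[k])
        return out

    def decision_function(self, X) -> np.ndarray:
        """Gaussian log-discriminant difference (class 2 minus class 1)."""
        U = self._project(np.atleast_2d(np.asarray(X, float)))
        if not np.all(np.isfinite(U)):
            raise ValueError("non-finite projection")
        d = self._log_discriminants(U)
        return d[:, 1] - d[:, 0]

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.decision_function(X) > 0).astype(int)]

    def project(self, X) -> np.ndarray:
        """2-D projections u = (<x, beta1>, <x, beta2>)."""
        return self._project(np.atleast_2d(np.asarray(X, float)))


def fit_fqda(maps: np.ndarray, labels: np.ndarray, operators: FEMOperators,
             lambda1: float = 1.0, lambda2: float = 1.0) -> FunctionalQDA:
    """Functional interface over :class:`FunctionalQDA`."""
    return FunctionalQDA(operators=operators, lambda1=lambda1,
                         lambda2=lambda2).fit(maps, labels)


def classify_fqda(model: FunctionalQDA, values: np.ndarray):
    """Classify one vertex map; returns (label, 2-D projection)."""
    values = np.asarray(values, float).reshape(1, -1)
    label = model.predict(values)[0]
    return label, model.project(values)[0]
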