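"""Linear finite elements on triangle meshes.

Discretizes the L2(M) inner product (mass matrix), the Dirichlet energy of
the surface gradient (stiffness matrix), and the Laplace–Beltrami roughness
penalty

    J(beta) = ||Delta_M beta||^2_{L2(M)} + eps * ||beta||^2_{L2(M)}

as the sparse quadratic form  c^T (S Mlump^{-1} S + eps M) c  in the vertex
coefficients c of a piecewise-linear field.  The dense inverse mass matrix
is replaced by the inverse of the lumped (row-sum diagonal) mass so that the
penalty stays sparse.

All integrals of products of affine basis functions are evaluated in closed
form (they are exact for linear elements): per triangle of area A the mass
block is (A/12) * [[2,1,1],[1,2,1],[1,1,2]] and the stiffness block is the
classical cotangent form  S_ij = e_i . e_j / (4A)  with e_i the edge vector
opposite vertex i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import TriangleMesh, VertexFunction

__all__ = [
    "FEMOperators",
    "assemble_mass",
    "assemble_stiffness",
    "lump_mass",
    "assemble_penalty",
    "lb_eigenpairs",
    "inner_product_l2",
    "sparse_cholesky",
]

_MASS_BLOCK = (np.ones((3, 3)) + np.eye(3)) / 12.0


@dataclass(frozen=True)
class FEMOperators:
    """Assembled sparse operators for one mesh.

    Attributes
    ----------
    mass : (s, s) sparse, SPD
        (M)_jj' = integral over the mesh of psi_j psi_j' (units: area).
    stiffness : (s, s) sparse, PSD with zero row sums
        (S)_jj' = integral of grad psi_j . grad psi_j' (dimensionless).
    lumped_mass : (s,) positive array
        Row sums of the mass matrix (diagonal lumped mass).
    penalty : (s, s) sparse, PSD
        S diag(lumped)^-1 S + epsilon * M; discretizes J.
    epsilon : float
        Shrinkage weight in J.
    """

    mesh: TriangleMesh
    mass: sp.csr_matrix
    stiffness: sp.csr_matrix
    lumped_mass: np.ndarray
    penalty: sp.csr_matrix
    epsilon: float

    @property
    def n_vertices(self) -> int:
        return self.mesh.n_vertices


def _face_geometry(mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-face areas and opposite-edge vectors; errors on degenerate faces."""
    mesh.validate()
    p = mesh.vertices[mesh.faces]  # (t, 3, 3)
    # e[k] is the edge opposite local vertex k, consistently oriented
    edges = np.stack([p[:, 2] - p[:, 1],
                      p[:, 0] - p[:, 2],
                      p[:, 1] - p[:, 0]], axis=1)  # (t, 3, 3)
    areas = 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
                                 axis=1)
    return areas, edges


def _accumulate(mesh: TriangleMesh, blocks: np.ndarray) -> sp.csr_matrix:
    """Scatter (t, 3, 3) per-element blocks into a sparse s x s matrix."""
    f = mesh.faces
    rows = np.repeat(f, 3, axis=1).ravel()            # i index
    cols = np.tile(f, (1, 3)).ravel()                 # j index
    mat = sp.coo_matrix((blocks.ravel(), (rows, cols)),
                        shape=(mesh.n_vertices, mesh.n_vertices))
    return mat.tocsr()


def assemble_mass(mesh: TriangleMesh) -> sp.csr_matrix:
    """Sparse FE mass matrix, exact for affine basis functions."""
    areas, _ = _face_geometry(mesh)
    blocks = areas[:, None, None] * _MASS_BLOCK[None]
    return _accumulate(mesh, blocks)


def assemble_stiffness(mesh: TriangleMesh) -> sp.csr_matrix:
    """Sparse surface stiffness (cotangent) matrix; rows sum to zero."""
    areas, edges = _face_geometry(mesh)
    # grad psi_i . grad psi_j integrated over the triangle = e_i.e_j / (4A)
    blocks = np.einsum("tik,tjk->tij", edges, edges) / (4.0 * areas)[:, None, None]
    return _accumulate(mesh, blocks)


def lump_mass(mass: sp.spmatrix) -> np.ndarray:
    """Diagonal lumped mass: row sums of the consistent mass matrix."""
    lumped = np.asarray(mass.sum(axis=1)).ravel()
    if np.any(lumped <= 0):
        j = int(np.argmin(lumped))
        raise ValueError(f"non-positive lumped mass at vertex {j} (broken mesh)")
    return lumped


def assemble_penalty(mesh: TriangleMesh, epsilon: float = 0.0) -> FEMOperators:
    """Assemble mass, stiffness, lumped mass and the roughness penalty."""
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    mass = assemble_mass(mesh)
    stiffness = assemble_stiffness(mesh)
    lumped = lump_mass(mass)
    inv_lump = sp.diags(1.0 / lumped)
    penalty = (stiffness @ inv_lump @ stiffness + epsilon * mass).tocsr()
    return FEMOperators(mesh=mesh, mass=mass, stiffness=stiffness,
                        lumped_mass=lumped, penalty=penalty,
                        epsilon=float(epsilon))


def lb_eigenpairs(ops: FEMOperators, k: int) -> tuple[np.ndarray, np.ndarray]:
    """First ``k`` Laplace–Beltrami eigenpairs  S phi = theta M phi.

    Solved by shift-invert (shift just below zero) so the null eigenvalue of
    a closed connected mesh is resolved robustly.  Eigenvalues are returned
    ascending; eigenvectors are columns, M-orthonormal.
    """
    s = ops.n_vertices
    if not 0 < k < s:
        raise ValueError(f"k must satisfy 0 < k < {s}, got {k}")
    # deterministic start vector: repeated calls must return the same basis
    # within degenerate eigenspaces
    v0 = np.random.default_rng(0).standard_normal(s)
    vals, vecs = spla.eigsh(ops.stiffness.tocsc(), k=k, M=ops.mass.tocsc(),
                            sigma=-1e-8, which="LM", v0=v0)
    order = np.argsort(vals)
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    return vals, vecs


def inner_product_l2(ops: FEMOperators, f: VertexFunction | np.ndarray,
                     g: VertexFunction | np.ndarray) -> float:
    """L2(M) inner product  f^T M g  of two piecewise-linear fields."""
    fv = f.values if isinstance(f, VertexFunction) else np.asarray(f, float)
    gv = g.values if isinstance(g, VertexFunction) else np.asarray(g, float)
    if fv.shape != (ops.n_vertices,) or gv.shape != (ops.n_vertices,):
        raise ValueError("vertex-function length does not match the mesh")
    return float(fv @ (ops.mass @ gv))


def sparse_cholesky(mat: sp.spmatrix) -> sp.csr_matrix:
    """Upper factor R with R^T R = mat for a sparse SPD matrix.

    Uses an LDL^T factorization through SuperLU with natural ordering (no
    pivoting is needed for the well-conditioned FE mass matrix); falls back
    to a dense Cholesky if the unpivoted factorization is inaccurate.
    """
    mat = sp.csc_matrix(mat)
    n = mat.shape[0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lu = spla.splu(mat, permc_spec="NATURAL", diag_pivot_thresh=0.0,
                           options={"SymmetricMode": True})
        if (lu.perm_r == np.arange(n)).all() and (lu.perm_c == np.arange(n)).all():
            d = lu.U.diagonal()
            if np.all(d > 0):
                R = (lu.L @ sp.diags(np.sqrt(d))).T.tocsr()
                resid = abs(R.T @ R - mat).max()
                if resid <= 1e-10 * max(1.0, abs(mat).max()):
                    return R
    except RuntimeError:
        pass
    dense = np.linalg.cholesky(mat.toarray())  # lower L, L L^T = mat
    return sp.csr_matrix(dense.T)
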