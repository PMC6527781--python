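"""Exact small-scale GLS and mixed-model-equation solvers.

These certify the AGLS approximation on instances small enough to invert
V = sigma_a2 * Z A Z' + sigma_e2 * I directly.  The GLS route

    b_hat = (X' V^-1 X)^- X' V^-1 y

and the Henderson mixed-model-equation route (joint BLUE/BLUP solve, with
b_hat also reproducible as (X'X)^- X'(y - Z a_hat)) are algebraically
identical; the pair gives a dual-route oracle for the per-SNP cell-means
contrasts that AGLS approximates with 2*PTA in place of the BLUP a_hat.

This is a test instrument: n is capped (default 2,000) and everything is
dense.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_N_CAP = 2000
RANK_TOL = 1e-10


@dataclass
class ExactModel:
    y: np.ndarray          # (n,)
    X: np.ndarray          # (n, p) fixed-effect design (cell means)
    Z: np.ndarray          # (n, q) incidence of random polygenic effects
    A: np.ndarray          # (q, q) relationship matrix, invertible
    sigma_a2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, float))
        self.Z = np.atleast_2d(np.asarray(self.Z, float))
        self.A = np.atleast_2d(np.asarray(self.A, float))
        n = self.y.size
        if n > DEFAULT_N_CAP:
            raise ValueError(f"oracle capped at n <= {DEFAULT_N_CAP}")
        if self.X.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("design row counts must match y")
        if self.sigma_e2 <= 0:
            raise ValueError("sigma_e2 must be positive")

    @property
    def V(self) -> np.ndarray:
        n = self.y.size
        return (
            self.sigma_a2 * self.Z @ self.A @ self.Z.T
            + self.sigma_e2 * np.eye(n)
        )


def ginv(M: np.ndarray, tol: float = RANK_TOL) -> np.ndarray:
    """Moore-Penrose inverse of a symmetric matrix via eigen-decomposition."""
    M = np.asarray(M, float)
    w, U = np.linalg.eigh((M + M.T) / 2.0)
    cut = tol * max(abs(w).max(), 1e-300)
    inv_w = np.where(np.abs(w) > cut, 1.0 / np.where(w == 0, 1.0, w), 0.0)
    return (U * inv_w) @ U.T


def gls_blue(model: ExactModel) -> np.ndarray:
    """BLUE of the fixed effects via the explicit V inverse."""
    V = model.V
    try:
        Vi = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        raise ValueError("singular V") from None
    XtVi = model.X.T @ Vi
    return ginv(XtVi @ model.X) @ (XtVi @ model.y)


def mme_blue(model: ExactModel) -> tuple[np.ndarray, np.ndarray]:
    """Solve Henderson's mixed-model equations; returns (BLUE b_hat, BLUP a_hat).

    In the sigma_a2 -> 0 limit a_hat = 0 and b_hat is ordinary least squares.
    """
    X, Z, y = model.X, model.Z, model.y
    if model.sigma_a2 == 0.0:
        b = ginv(X.T @ X) @ (X.T @ y)
        return b, np.zeros(Z.shape[1])
    try:
        Ai = np.linalg.inv(model.A)
    except np.linalg.LinAlgError:
        raise ValueError("singular A") from None
    lam = model.sigma_e2 / model.sigma_a2
    p, q = X.shape[1], Z.shape[1]
    C = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * Ai]])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = ginv(C) @ rhs
    return sol[:p], sol[p:]


def mme_blue_reconstructed(model: ExactModel) -> np.ndarray:
    """b_hat recomputed as (X'X)^- X'(y - Z a_hat) from the MME BLUP."""
    _, a_hat = mme_blue(model)
    X = model.X
    return ginv(X.T @ X) @ (X.T @ (model.y - model.Z @ a_hat))


def exact_contrast_t(model: ExactModel, contrast: np.ndarray) -> float:
    """GLS t-statistic |c' b_hat| / sqrt(c' (X'V^-1 X)^- c) for one contrast."""
    c = np.asarray(contrast, float).ravel()
    V = model.V
    Vi = np.linalg.inv(V)
    XtViX = model.X.T @ Vi @ model.X
    Cov = ginv(XtViX)
    # estimability: c must lie in the row space of X'V^-1X
    proj = XtViX @ Cov @ c
    if not np.allclose(proj, c, atol=1e-8 * max(1.0, np.abs(c).max())):
        raise ValueError("contrast not estimable")
    b = Cov @ (model.X.T @ Vi @ model.y)
    var = float(c @ Cov @ c)
    if var <= 0:
        raise ValueError("non-positive contrast variance")
    return abs(float(c @ b)) / np.sqrt(var)
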