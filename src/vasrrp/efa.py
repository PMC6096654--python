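"""Exploratory analysis by principal components with oblique rotation.

Principal-component extraction works directly on a correlation matrix and
therefore tolerates singular input -- the property that makes it the one
factoring method applicable to ipsative (ranking) data, whose covariance
matrix has rows summing to zero.  Components are obliquely rotated with
promax (varimax followed by a least-squares fit to the powered target,
power 4), yielding a pattern matrix and a component correlation matrix in
the convention of the classic statistical packages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EFAFit",
    "extract_components",
    "varimax",
    "promax",
    "rotate_oblique",
    "structure_table",
    "align_columns",
]


@dataclass
class EFAFit:
    """Principal-component solution for one correlation matrix."""

    loadings: np.ndarray            # p x k, unrotated
    eigenvalues: np.ndarray         # all p, nonincreasing
    pve: float                      # percent variance explained by the k kept
    pattern: np.ndarray | None = None
    component_corr: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


def extract_components(corr: np.ndarray, k: int) -> EFAFit:
    """Top-k principal components of a correlation matrix.

    Loadings are eigenvectors scaled by the square root of their
    eigenvalues; each column is reflected so its largest-magnitude entry is
    positive.  PVE = 100 * (sum of the k largest eigenvalues) / p.
    """
    C = np.asarray(corr, float)
    p = C.shape[0]
    if k > p:
        raise ValueError("cannot extract more components than variables")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w = w[order]
    V = V[:, order]
    top = np.clip(w[:k], 0.0, None)
    loadings = V[:, :k] * np.sqrt(top)
    for j in range(k):
        if loadings[np.abs(loadings[:, j]).argmax(), j] < 0:
            loadings[:, j] *= -1.0
    pve = 100.0 * top.sum() / p
    return EFAFit(loadings=loadings, eigenvalues=w, pve=float(pve))


def varimax(
    loadings: np.ndarray,
    normalize: bool = True,
    tol: float = 1e-5,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation (with Kaiser row normalization).

    Returns the rotated loadings and the rotation matrix T such that
    ``rotated = loadings @ T`` (after undoing the row normalization).
    """
    A = np.asarray(loadings, float).copy()
    p, k = A.shape
    if k < 2:
        return A, np.eye(k)
    h = np.sqrt((A**2).sum(axis=1))
    if normalize:
        A = A / h[:, None]
    T = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        L = A @ T
        B = A.T @ (L**3 - L @ np.diag((L**2).sum(axis=0)) / p)
        U, s, Vt = np.linalg.svd(B)
        T = U @ Vt
        d_new = s.sum()
        if d_new < d * (1.0 + tol):
            break
        d = d_new
    L = A @ T
    if normalize:
        L = L * h[:, None]
    return L, T


def promax(
    loadings: np.ndarray, power: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Oblique promax rotation.

    Varimax-rotates the loadings, builds the element-wise powered target
    ``|x|^(power-1) * x``, and fits the varimax solution to it by least
    squares, normalizing so the implied component correlation matrix has a
    unit diagonal.  Returns (pattern matrix, component correlation matrix).
    """
    X, _ = varimax(loadings)
    if X.shape[1] < 2:
        return X, np.eye(X.shape[1])
    Q = X * np.abs(X) ** (power - 1)
    U, *_ = np.linalg.lstsq(X, Q, rcond=None)
    if np.linalg.matrix_rank(U) < U.shape[1]:
        raise ValueError("degenerate loading matrix: rotation target is rank-deficient")
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U @ np.diag(np.sqrt(d))
    pattern = X @ U
    component_corr = np.linalg.inv(U.T @ U)
    return pattern, component_corr


def rotate_oblique(fit: EFAFit, power: int = 4) -> EFAFit:
    """Attach the promax pattern and component correlations to a solution."""
    if fit.k < 2:
        raise ValueError("oblique rotation needs at least two components")
    pattern, phi = promax(fit.loadings, power=power)
    return EFAFit(
        loadings=fit.loadings,
        eigenvalues=fit.eigenvalues,
        pve=fit.pve,
        pattern=pattern,
        component_corr=phi,
    )


def align_columns(
    pattern: np.ndarray, item_to_latent: np.ndarray
) -> np.ndarray:
    """Assign each component to the generating latent whose items load on
    it most strongly (greedy maximum mean |loading| congruence).  Returns
    ``assignment[latent] = component column``."""
    P = np.asarray(pattern, float)
    k = P.shape[1]
    congr = np.zeros((k, k))
    for l in range(k):
        congr[l] = np.abs(P[item_to_latent == l]).mean(axis=0)
    assignment = np.full(k, -1)
    work = congr.copy()
    for _ in range(k):
        l, c = np.unravel_index(np.argmax(work), work.shape)
        assignment[l] = c
        work[l, :] = -np.inf
        work[:, c] = -np.inf
    return assignment


def structure_table(
    pattern: np.ndarray,
    threshold: float = 0.3,
    item_labels=None,
) -> pd.DataFrame:
    """Structure table with small loadings blanked.

    Entries with |loading| <= threshold become NaN (printed blank); the
    returned frame carries per-item counts of surviving loadings in a
    ``n_loadings`` column -- 0 flags a non-loading item, >= 2 a
    complex-structure item.
    """
    P = np.asarray(pattern, float)
    masked = np.where(np.abs(P) > threshold, P, np.nan)
    cols = [f"component_{j + 1}" for j in range(P.shape[1])]
    df = pd.DataFrame(masked, columns=cols, index=item_labels)
    df["n_loadings"] = (~np.isnan(masked)).sum(axis=1)
    return df
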