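"""Constraint-form L1 solvers.

Both stages of factorize-recover use the *budget* form of the LASSO,

    min ||y - A u||_2^2   subject to   ||u||_1 <= t,

which is solved here with FISTA where the proximal step is Euclidean
projection onto the L1 ball of radius t.  The budget form is used directly
(rather than sweeping the penalty path) because the hyperparameters of the
method are L1 budgets, not penalty weights.

All solvers accept multiple right-hand sides at once: the constraint applies
to each column independently, while the gradient work is shared.
"""
from __future__ import annotations

import numpy as np


def project_l1_ball(V: np.ndarray, radius: float) -> np.ndarray:
    """Project each column of V onto the L1 ball of the given radius.

    Duchi et al.'s sort-based algorithm, vectorized over columns.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    V = np.atleast_2d(V)
    A = np.abs(V)
    norms = A.sum(axis=0)
    inside = norms <= radius
    if inside.all():
        return V.copy()
    out = V.copy()
    cols = np.where(~inside)[0]
    Asub = np.sort(A[:, cols], axis=0)[::-1]  # descending per column
    css = np.cumsum(Asub, axis=0)
    k = np.arange(1, Asub.shape[0] + 1)[:, None]
    cond = Asub - (css - radius) / k > 0
    rho = cond.shape[0] - 1 - np.argmax(cond[::-1], axis=0)  # last True index
    theta = (css[rho, np.arange(len(cols))] - radius) / (rho + 1)
    out[:, cols] = np.sign(V[:, cols]) * np.maximum(A[:, cols] - theta, 0.0)
    return out


def _power_lipschitz(G: np.ndarray, n_iter: int = 100, seed: int = 0) -> float:
    """Largest eigenvalue of the PSD matrix G by power iteration."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(G.shape[0])
    v /= np.linalg.norm(v)
    lam = 1.0
    for _ in range(n_iter):
        w = G @ v
        nw = np.linalg.norm(w)
        if nw == 0:
            return 1.0
        lam, v = nw, w / nw
    return float(lam)


def constrained_lasso_gram(
    G: np.ndarray,
    b: np.ndarray,
    radius: float,
    *,
    max_iter: int = 2000,
    tol: float = 1e-8,
    lipschitz: float | None = None,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Solve min ||y - A u||^2 s.t. ||u||_1 <= radius, per column, in Gram form.

    Parameters
    ----------
    G : A.T @ A, (d, d)
    b : A.T @ Y, (d, k) — one column per right-hand side
    radius : L1 budget per column
    lipschitz : precomputed largest eigenvalue of G (recomputed if None)

    Returns U of shape (d, k).  Convergence is measured by the largest
    coordinate move between FISTA iterates.
    """
    b = np.atleast_2d(b.astype(float, copy=False))
    if b.ndim == 1:
        b = b[:, None]
    d, k = b.shape
    L = _power_lipschitz(G) if lipschitz is None else lipschitz
    L = max(L, 1e-12)
    if radius == 0:
        return np.zeros((d, k))
    U = np.zeros((d, k)) if init is None else project_l1_ball(init.copy(), radius)
    Z = U.copy()
    t = 1.0
    for _ in range(max_iter):
        grad = G @ Z - b
        U_next = project_l1_ball(Z - grad / L, radius)
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        Z = U_next + ((t - 1.0) / t_next) * (U_next - U)
        delta = np.max(np.abs(U_next - U)) if U.size else 0.0
        U, t = U_next, t_next
        if delta < tol:
            break
    return U


def constrained_lasso(
    A: np.ndarray,
    Y: np.ndarray,
    radius: float,
    *,
    max_iter: int = 2000,
    tol: float = 1e-8,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Budget-form LASSO min ||Y[:, j] - A u_j||^2 s.t. ||u_j||_1 <= radius."""
    A = np.asarray(A, dtype=float)
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    G = A.T @ A
    b = A.T @ Y
    U = constrained_lasso_gram(
        G, b, radius, max_iter=max_iter, tol=tol, lipschitz=_power_lipschitz(G), init=init
    )
    return U[:, 0] if squeeze else U


def elastic_net_prox(
    A: np.ndarray,
    y: np.ndarray,
    l1: float,
    l2: float,
    *,
    max_iter: int = 5000,
    tol: float = 1e-10,
) -> np.ndarray:
    """Penalty-form elastic net by FISTA with soft-thresholding.

    Solves min_b 0.5 ||y - A b||^2 + l1 ||b||_1 + (l2 / 2) ||b||^2.
    Used as an independent oracle for the sklearn-backed baseline.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    G = A.T @ A
    c = A.T @ y
    L = _power_lipschitz(G) + l2
    b = np.zeros(A.shape[1])
    z = b.copy()
    t = 1.0
    for _ in range(max_iter):
        grad = G @ z - c + l2 * z
        w = z - grad / L
        b_next = np.sign(w) * np.maximum(np.abs(w) - l1 / L, 0.0)
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        z = b_next + ((t - 1.0) / t_next) * (b_next - b)
        delta = np.max(np.abs(b_next - b))
        b, t = b_next, t_next
        if delta < tol:
            break
    return b
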