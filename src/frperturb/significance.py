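"""Permutation significance for effect estimates.

Row permutations of the design matrix X leave the expression factorization
untouched (the factorize step never sees X), so each permutation replicate
only re-runs the recover step against the fixed factorization and recomposes
a null effect matrix.  Row-permuting X also leaves X^T X unchanged, so the
Gram matrix and its Lipschitz constant are computed once for all replicates.

Two-tailed p-values use the add-one estimator p = (1 + #{|null| >= |b|}) /
(K + 1).  Entries whose estimate beats every one of the K permutations are
refined by fitting an Azzalini skew-t distribution to their empirical null
and recomputing the two-tailed p from the fitted tails.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, stats
from statsmodels.stats.multitest import multipletests

from .containers import Factorization
from .estimator import compose_effects, recover
from .solvers import _power_lipschitz

DF_BOUNDS = (2.1, 100.0)


@dataclass
class NullEnsemble:
    """K permutation replicates of the effect matrix (K x P x G, float32)."""

    null_B: np.ndarray
    n_permutations: int
    seed: int


def permutation_null(
    factorization: Factorization,
    X_prime: np.ndarray,
    n_permutations: int = 500,
    seed: int = 0,
    lambda2: float = 10.0,
    correction_factors: np.ndarray | None = None,
) -> NullEnsemble:
    """Recover + compose on row-permuted X', K times.

    The (data-derived) LOESS correction factors, when given, are applied to
    every null slice so nulls and estimates live on the same scale.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    X_prime = np.asarray(X_prime, dtype=float)
    U_tilde, W = factorization.U_tilde, factorization.W
    n = X_prime.shape[0]
    gram = X_prime.T @ X_prime
    lip = _power_lipschitz(gram)
    rng = np.random.default_rng(seed)
    out = np.empty((n_permutations, X_prime.shape[1], W.shape[1]), dtype=np.float32)
    for k in range(n_permutations):
        perm = rng.permutation(n)
        xty = X_prime[perm].T @ U_tilde
        U_k = recover(U_tilde, X_prime, lambda2, gram=gram, xty=xty, lipschitz=lip)
        B_k = compose_effects(U_k, W)
        if correction_factors is not None:
            B_k = B_k * correction_factors[None, :]
        out[k] = B_k
    return NullEnsemble(out, n_permutations, seed)


def empirical_pvalues(
    B_hat: np.ndarray, ensemble: NullEnsemble
) -> tuple[np.ndarray, np.ndarray]:
    """Add-one two-tailed permutation p-values.

    Returns (p, flagged) where flagged marks entries with a raw exceedance
    count of zero (candidates for tail refinement).
    """
    K = ensemble.n_permutations
    absB = np.abs(B_hat).astype(np.float32)
    count = np.zeros(B_hat.shape, dtype=np.int64)
    for start in range(0, K, 50):  # chunked to bound peak memory
        block = ensemble.null_B[start : start + 50]
        count += (np.abs(block) >= absB[None, :, :]).sum(axis=0)
    p = (1.0 + count) / (K + 1.0)
    return p, count == 0


def _skewt_neg_loglik(theta: np.ndarray, x: np.ndarray) -> float:
    xi, log_omega, alpha, s = theta
    omega = np.exp(log_omega)
    lo, hi = DF_BOUNDS
    nu = lo + (hi - lo) / (1.0 + np.exp(-s))
    z = (x - xi) / omega
    w = alpha * z * np.sqrt((nu + 1.0) / (nu + z * z))
    ll = (
        np.log(2.0)
        - log_omega
        + stats.t.logpdf(z, nu)
        + stats.t.logcdf(w, nu + 1.0)
    )
    val = -np.sum(ll)
    return val if np.isfinite(val) else 1e12


def fit_skew_t(x: np.ndarray, max_iter: int = 300) -> dict:
    """Numerical MLE of the Azzalini skew-t (location, scale, skew, df).

    Moment-based initialization; df constrained to [2.1, 100] through a
    logistic reparameterization.  Raises on optimizer failure.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 50:
        raise ValueError("need at least 50 null draws for a skew-t fit")
    m, s = float(np.mean(x)), float(np.std(x))
    if s <= 0:
        raise ValueError("degenerate null (zero spread)")
    skew = float(stats.skew(x))
    init = np.array([m, np.log(s), np.clip(3.0 * skew, -5.0, 5.0), 0.0])
    res = optimize.minimize(
        _skewt_neg_loglik,
        init,
        args=(x,),
        method="Nelder-Mead",
        options={"maxiter": max_iter, "xatol": 1e-4, "fatol": 1e-4},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError("skew-t likelihood did not evaluate")
    xi, log_omega, alpha, sraw = res.x
    lo, hi = DF_BOUNDS
    return {
        "xi": float(xi),
        "omega": float(np.exp(log_omega)),
        "alpha": float(alpha),
        "df": float(lo + (hi - lo) / (1.0 + np.exp(-sraw))),
    }


def skew_t_pdf(x, params: dict):
    z = (np.asarray(x, dtype=float) - params["xi"]) / params["omega"]
    nu, alpha = params["df"], params["alpha"]
    w = alpha * z * np.sqrt((nu + 1.0) / (nu + z * z))
    return 2.0 / params["omega"] * stats.t.pdf(z, nu) * stats.t.cdf(w, nu + 1.0)


def skew_t_two_tailed_p(value: float, params: dict) -> float:
    """P(|T| >= |value|) under the fitted skew-t, by tail integration."""
    v = abs(float(value))
    upper, _ = integrate.quad(lambda x: skew_t_pdf(x, params), v, np.inf, limit=200)
    lower, _ = integrate.quad(lambda x: skew_t_pdf(x, params), -np.inf, -v, limit=200)
    return float(np.clip(upper + lower, 0.0, 1.0))


def skew_t_refine(
    B_hat: np.ndarray,
    ensemble: NullEnsemble,
    p: np.ndarray,
    flagged: np.ndarray,
) -> np.ndarray:
    """Replace flagged entries' p-values with skew-t tail p-values.

    Entries whose fit fails keep the add-one permutation p with a warning.
    """
    refined = p.copy()
    idx = np.argwhere(flagged)
    failures = 0
    for i, j in idx:
        draws = ensemble.null_B[:, i, j].astype(float)
        try:
            params = fit_skew_t(draws)
            refined[i, j] = max(skew_t_two_tailed_p(B_hat[i, j], params), 1e-300)
        except (ValueError, RuntimeError):
            failures += 1
    if failures:
        warnings.warn(f"skew-t refinement failed for {failures} entries; kept add-one p")
    return refined


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values over the flattened matrix."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    flat = p.ravel()
    _, q, *_ = multipletests(flat, method="fdr_bh")
    return q.reshape(p.shape)


def attach_significance(
    estimator,
    n_permutations: int = 500,
    seed: int = 0,
    refine: bool = True,
    store_ensemble: bool = True,
):
    """Compute p and q values for a fitted FRPerturb estimator in place."""
    ensemble = permutation_null(
        estimator.factorization_,
        estimator.X_prime_,
        n_permutations=n_permutations,
        seed=seed,
        lambda2=estimator.lambda2,
        correction_factors=estimator.correction_factors_,
    )
    p, flagged = empirical_pvalues(estimator.effects_, ensemble)
    if n_permutations < 50:
        refine = False  # too few draws for a stable tail fit
    if refine and flagged.any():
        p = skew_t_refine(estimator.effects_, ensemble, p, flagged)
    estimator.p_values_ = p
    estimator.q_values_ = bh_fdr(p)
    estimator.null_ensemble_ = ensemble if store_ensemble else None
    return estimator


def significant_perturbations_for_program(
    estimator, program_gene_idx: np.ndarray, q_threshold: float = 0.05
) -> np.ndarray:
    """Perturbation columns with a significant mean effect on a gene program.

    The program-level statistic per perturbation is the mean B_hat over the
    program's genes; its null comes from the same means of the stored
    permutation ensemble, followed by BH across perturbations.
    """
    if getattr(estimator, "null_ensemble_", None) is None:
        raise ValueError("estimator has no stored permutation ensemble")
    idx = np.asarray(program_gene_idx)
    stat = estimator.effects_[:, idx].mean(axis=1)
    null = estimator.null_ensemble_.null_B[:, :, idx].mean(axis=2)
    K = null.shape[0]
    count = (np.abs(null) >= np.abs(stat)[None, :]).sum(axis=0)
    p = (1.0 + count) / (K + 1.0)
    _, q, *_ = multipletests(p, method="fdr_bh")
    return np.where(q < q_threshold)[0]
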