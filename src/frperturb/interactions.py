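"""Second-order (epistatic) effect estimation.

Two complementary routes:

* pairwise — expand the design with products of indicator columns
  (perturbation pairs supported by at least ``min_cells`` droplets), subtract
  the first-order fit, and run factorize-recover on the residual Y'' = Y' - XB
  against the pair design X2.
* module-level — contrast mean standardized program expression between cells
  carrying zero, one, or two guides from a co-functional module: with set
  means mu0, mu1, mu11 (and mu12 across two modules), the first-order effect
  is beta1 = mu1 - mu0, the intra-module interaction beta11 = mu11 - 2*beta1
  - mu0, and the inter-module interaction beta12 = mu12 - beta1 - beta2 -
  mu0.  Significance by permuting set labels; standard errors by
  bootstrapping within sets.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .containers import DesignMatrix, EffectResult
from .estimator import (
    compose_effects,
    factorize,
    loess_bias_correction,
    normalize_design,
    recover,
)
from .preprocess import regress_out_covariates
from .solvers import _power_lipschitz, constrained_lasso_gram

MIN_CELLS_DEFAULT = 5


def count_candidate_pairs(n_perturbations: int) -> int:
    """Number of unordered perturbation pairs before support filtering."""
    return comb(n_perturbations, 2)


@dataclass
class PairDesign:
    X2: np.ndarray  # droplets x Q binary pair indicators
    pair_ids: list[tuple[str, str]]
    min_cells: int
    n_candidate_pairs: int


def expand_pairwise(design: DesignMatrix, min_cells: int = MIN_CELLS_DEFAULT) -> PairDesign:
    """Indicator columns for perturbation pairs co-occurring in >= min_cells.

    Supported pairs are found from the co-occurrence matrix X^T X so the full
    candidate set (P choose 2) is never materialized.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    Xt = design.targeting_block()
    P = Xt.shape[1]
    co = Xt.T @ Xt
    ii, jj = np.where(np.triu(co, k=1) >= min_cells)
    X2 = Xt[:, ii] * Xt[:, jj]
    pair_ids = [
        (design.perturbation_ids[i], design.perturbation_ids[j])
        for i, j in zip(ii, jj)
    ]
    return PairDesign(X2, pair_ids, min_cells, count_candidate_pairs(P))


def _sparse_code(Y: np.ndarray, W: np.ndarray, lambda1: float) -> np.ndarray:
    """Code rows of Y against a fixed dictionary W under the L1 budget."""
    G = W @ W.T
    return constrained_lasso_gram(
        G, W @ Y.T, lambda1, lipschitz=_power_lipschitz(G), max_iter=500, tol=1e-9
    ).T


def fit_second_order(
    Y: np.ndarray,
    design: DesignMatrix,
    first_order: EffectResult,
    pair_design: PairDesign,
    rank: int = 10,
    lambda1: float = 0.1,
    lambda2: float = 10.0,
    mode: str = "guide_pooled",
    control_level: np.ndarray | None = None,
    n_permutations: int = 0,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> EffectResult:
    """Estimate pairwise interaction effects B2 on the residual Y'' = Y' - XB.

    Significance (when ``n_permutations`` > 0) jointly permutes the rows of X
    and X2 and re-estimates the first-order effects inside every permutation,
    so the uncertainty of B propagates into the null of B2.  Within each
    permutation the expression dictionaries are held fixed and only the
    coding and recover steps are re-run.
    """
    from .significance import bh_fdr

    if pair_design.X2.shape[1] == 0:
        empty = np.zeros((0, Y.shape[1]))
        return EffectResult(empty, [], gene_ids or [], mode=mode)
    Xp = normalize_design(design.X, mode)
    B1 = first_order.B_hat
    Y2 = Y - Xp @ B1
    fac2 = factorize(Y2, rank=rank, lambda1=lambda1, seed=seed)
    U2 = recover(fac2.U_tilde, pair_design.X2, lambda2)
    B2 = compose_effects(U2, fac2.W)
    factors2 = None
    if control_level is not None:
        B2, factors2 = loess_bias_correction(B2, control_level)
    p = q = None
    if n_permutations > 0:
        fac1 = factorize(Y, rank=rank, lambda1=lambda1, seed=seed)
        gram1 = Xp.T @ Xp
        lip1 = _power_lipschitz(gram1)
        gram2 = pair_design.X2.T @ pair_design.X2
        lip2 = _power_lipschitz(gram2)
        rng = np.random.default_rng(seed)
        count = np.zeros(B2.shape, dtype=np.int64)
        absB2 = np.abs(B2)
        for _ in range(n_permutations):
            perm = rng.permutation(Y.shape[0])
            xty1 = Xp[perm].T @ fac1.U_tilde
            U1k = recover(fac1.U_tilde, Xp, lambda2, gram=gram1, xty=xty1, lipschitz=lip1)
            B1k = compose_effects(U1k, fac1.W)
            Y2k = Y - Xp[perm] @ B1k
            Ut2k = _sparse_code(Y2k, fac2.W, lambda1)
            xty2 = pair_design.X2[perm].T @ Ut2k
            U2k = recover(
                Ut2k, pair_design.X2, lambda2, gram=gram2, xty=xty2, lipschitz=lip2
            )
            B2k = compose_effects(U2k, fac2.W)
            if factors2 is not None:
                B2k = B2k * factors2[None, :]
            count += np.abs(B2k) >= absB2
        p = (1.0 + count) / (n_permutations + 1.0)
        q = bh_fdr(p)
    genes = gene_ids or [f"gene{i}" for i in range(Y.shape[1])]
    return EffectResult(
        B_hat=B2,
        perturbation_ids=[f"{a}:{b}" for a, b in pair_design.pair_ids],
        gene_ids=list(genes),
        U=U2,
        p_values=p,
        q_values=q,
        mode=mode,
        hyperparams={"rank": rank, "lambda1": lambda1, "lambda2": lambda2},
        correction_applied=factors2 is not None,
    )


# ---------------------------------------------------------------- modules


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene-set file: name <tab> description <tab> genes..."""
    modules: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                modules[parts[0]] = [g for g in parts[2:] if g]
    return modules


def make_modules(
    ids: list[str], n_modules: int, module_size: int, seed: int = 0
) -> dict[str, list[str]]:
    """Disjoint synthetic co-functional modules drawn from an id universe."""
    if n_modules * module_size > len(ids):
        raise ValueError("not enough ids for disjoint modules")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ids), size=n_modules * module_size, replace=False)
    return {
        f"module{m:02d}": [ids[i] for i in chosen[m * module_size : (m + 1) * module_size]]
        for m in range(n_modules)
    }


def module_pairs(modules: dict[str, list[str]]) -> list[tuple[str, str]]:
    """All unordered pairs of module names (inter-module candidates)."""
    return list(combinations(sorted(modules), 2))


@dataclass
class ModuleSets:
    control: np.ndarray
    first_order: np.ndarray
    second_order: np.ndarray
    first_order_2: np.ndarray | None = None  # second module (inter only)


def _present_genes(design: DesignMatrix) -> list[set[int]]:
    Xt = design.targeting_block()
    return [set(np.where(row == 1)[0]) for row in Xt]


def module_sets(
    design: DesignMatrix,
    module_genes: list[str],
    significant_perturbations: set[str] | list[str],
    module_genes_2: list[str] | None = None,
) -> ModuleSets:
    """Partition cells into control / first-order / second-order sets.

    Control guides are non-targeting or safe-targeting guides and guides for
    genes without significant effects on the program (and outside the
    module).  Cells fitting no definition are excluded.  With
    ``module_genes_2`` the second-order set holds cells with at least one
    guide from each module (inter-module contrast) and ``first_order_2`` the
    cells with guides from the second module only.
    """
    col = {g: i for i, g in enumerate(design.perturbation_ids)}
    m1 = {col[g] for g in module_genes if g in col}
    m2 = {col[g] for g in (module_genes_2 or []) if g in col}
    sig = {col[g] for g in significant_perturbations if g in col}
    ctrl_genes = set(range(design.n_perturbations)) - sig - m1 - m2

    control, first1, first2, second = [], [], [], []
    for i, present in enumerate(_present_genes(design)):
        rest_ok = (present - m1 - m2) <= ctrl_genes
        if not rest_ok:
            continue
        n1, n2 = len(present & m1), len(present & m2)
        if module_genes_2 is None:
            if n1 == 0:
                control.append(i)
            elif n1 == 1:
                first1.append(i)
            elif n1 == 2:
                second.append(i)
        else:
            if n1 == 0 and n2 == 0:
                control.append(i)
            elif n1 == 1 and n2 == 0:
                first1.append(i)
            elif n1 == 0 and n2 == 1:
                first2.append(i)
            elif n1 >= 1 and n2 >= 1:
                second.append(i)
    return ModuleSets(
        control=np.array(control, dtype=int),
        first_order=np.array(first1, dtype=int),
        second_order=np.array(second, dtype=int),
        first_order_2=np.array(first2, dtype=int) if module_genes_2 is not None else None,
    )


def standardize_expression(
    values: np.ndarray, covariates=None
) -> np.ndarray:
    """Residualize on covariates, then z-score each gene (mean 0, var 1)."""
    Y = np.asarray(values, dtype=float)
    if covariates is not None:
        Y = regress_out_covariates(Y, covariates)
    sd = Y.std(axis=0)
    sd[sd == 0] = 1.0
    return (Y - Y.mean(axis=0)) / sd


@dataclass
class ModuleInteraction:
    kind: str  # "intra" or "inter"
    mu0: float
    mu1: float
    mu_int: float  # mu11 (intra) or mu12 (inter)
    beta1: float
    beta_int: float
    se: float
    p: float
    n_cells: dict[str, int]
    mu2: float | None = None
    beta2: float | None = None


def _interaction_stat(scores: np.ndarray, groups: list[np.ndarray], kind: str):
    mus = [scores[g].mean() for g in groups]
    if kind == "intra":
        mu0, mu1, mu11 = mus
        beta1 = mu1 - mu0
        return mus, beta1, None, mu11 - 2.0 * beta1 - mu0
    mu0, mu1, mu2, mu12 = mus
    beta1, beta2 = mu1 - mu0, mu2 - mu0
    return mus, beta1, beta2, mu12 - beta1 - beta2 - mu0


def module_interaction(
    Y_standardized: np.ndarray,
    program_gene_idx: np.ndarray,
    sets: ModuleSets,
    kind: str = "intra",
    n_permutations: int = 10000,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> ModuleInteraction:
    """Estimate the module-level interaction effect on a gene program.

    The per-cell program score is the mean standardized expression of the
    program's genes.  P-value: two-tailed add-one permutation of set labels;
    SE: bootstrap resampling within each set.
    """
    if kind not in ("intra", "inter"):
        raise ValueError("kind must be 'intra' or 'inter'")
    idx = np.asarray(program_gene_idx, dtype=int)
    if idx.size == 0:
        raise ValueError("empty program gene set")
    scores = Y_standardized[:, idx].mean(axis=1)
    groups = [sets.control, sets.first_order]
    if kind == "inter":
        if sets.first_order_2 is None:
            raise ValueError("inter-module contrast needs first_order_2")
        groups.append(sets.first_order_2)
    groups.append(sets.second_order)
    if any(len(g) == 0 for g in groups):
        raise ValueError("every cell set must be non-empty")

    mus, beta1, beta2, beta_int = _interaction_stat(scores, groups, kind)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum(sizes)[:-1]

    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        pg = np.split(perm, bounds)
        _, _, _, b = _interaction_stat(scores, pg, kind)
        if abs(b) >= abs(beta_int):
            exceed += 1
    p = (1.0 + exceed) / (n_permutations + 1.0)

    boots = np.empty(n_bootstrap)
    for b_i in range(n_bootstrap):
        bg = [g[rng.integers(0, len(g), size=len(g))] for g in groups]
        _, _, _, boots[b_i] = _interaction_stat(scores, bg, kind)
    se = float(boots.std(ddof=1))

    names = (
        ["control", "first_order", "second_order"]
        if kind == "intra"
        else ["control", "first_order", "first_order_2", "second_order"]
    )
    return ModuleInteraction(
        kind=kind,
        mu0=float(mus[0]),
        mu1=float(mus[1]),
        mu2=float(mus[2]) if kind == "inter" else None,
        mu_int=float(mus[-1]),
        beta1=float(beta1),
        beta2=float(beta2) if beta2 is not None else None,
        beta_int=float(beta_int),
        se=se,
        p=float(p),
        n_cells=dict(zip(names, sizes)),
    )
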