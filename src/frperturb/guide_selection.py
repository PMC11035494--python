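"""Choosing the guide subset that replicates best across sample splits.

sgRNAs vary in knockout efficiency; dead guides dilute the collapsed
gene-level indicator.  For each perturbed gene, every non-empty subset of its
designed guides (15 subsets for four guides) is scored by refitting the
estimator on two random halves of the cells — with only the focal gene's
design column rebuilt from the subset — and computing the squared Pearson
correlation (R^2) between the two half-estimates of that gene's effect row,
restricted to effects significant (FDR q below a threshold, default 0.2) in
either half.  The subset with the highest R^2 wins; ties break toward larger
subsets, then lexicographically.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .estimator import (
    compose_effects,
    factorize,
    loess_bias_correction,
    normalize_design,
    recover,
)
from .io import build_design
from .significance import bh_fdr
from .solvers import _power_lipschitz


@dataclass
class GuideSelection:
    gene: str
    chosen_guides: tuple[str, ...]
    best_r2: float
    n_entries_compared: int
    table: pd.DataFrame  # one row per candidate subset


def _recover_and_test(fac, X_prime, lambda2, control_level, n_permutations, seed):
    """Recover + compose + bias-correct + permutation q-values for one design."""
    gram = X_prime.T @ X_prime
    lip = _power_lipschitz(gram)
    U = recover(fac.U_tilde, X_prime, lambda2, gram=gram, lipschitz=lip)
    B = compose_effects(U, fac.W)
    factors = None
    if control_level is not None:
        B, factors = loess_bias_correction(B, control_level)
    rng = np.random.default_rng(seed)
    count = np.zeros(B.shape, dtype=np.int64)
    absB = np.abs(B)
    for _ in range(n_permutations):
        perm = rng.permutation(X_prime.shape[0])
        xty = X_prime[perm].T @ fac.U_tilde
        Bk = compose_effects(
            recover(fac.U_tilde, X_prime, lambda2, gram=gram, xty=xty, lipschitz=lip),
            fac.W,
        )
        if factors is not None:
            Bk = Bk * factors[None, :]
        count += np.abs(Bk) >= absB
    p = (1.0 + count) / (n_permutations + 1.0)
    return B, bh_fdr(p)


def select_guide_subset(
    Y: np.ndarray,
    assignments: pd.DataFrame,
    guide_map: pd.DataFrame,
    gene: str,
    mode: str = "cell_pooled",
    q_threshold: float = 0.2,
    split_seed: int = 0,
    rank: int = 10,
    lambda1: float = 0.1,
    lambda2: float = 10.0,
    n_permutations: int = 200,
    control_level: np.ndarray | None = None,
    exact_refit: bool = False,
) -> GuideSelection:
    """Pick the subset of a gene's guides with the most replicable effects.

    Y must be the centered expression matrix aligned with
    ``build_design(assignments, guide_map)`` row order.  By default one
    factorization per half is shared across all candidate subsets (the
    factorize step never sees the design); ``exact_refit=True`` refactorizes
    per subset, which is equivalent here because the two coincide — the flag
    exists to make the approximation explicit and testable.
    """
    guides = sorted(
        guide_map.loc[
            (guide_map["guide_class"] == "targeting")
            & (guide_map["target_gene"] == gene),
            "guide_id",
        ]
    )
    if not 1 <= len(guides) <= 4:
        raise ValueError(f"gene {gene} has {len(guides)} guides; expected 1-4")
    base = build_design(assignments, guide_map)
    if Y.shape[0] != len(base.droplet_ids):
        raise ValueError("Y rows must align with the design built from assignments")
    gene_col = base.perturbation_ids.index(gene)

    rng = np.random.default_rng(split_seed)
    order = rng.permutation(Y.shape[0])
    halves = (np.sort(order[: len(order) // 2]), np.sort(order[len(order) // 2 :]))

    facs = [
        factorize(Y[h], rank=rank, lambda1=lambda1, seed=split_seed) for h in halves
    ]

    subsets = [
        tuple(c) for size in range(1, len(guides) + 1) for c in combinations(guides, size)
    ]
    records = []
    for subset in subsets:
        design = build_design(
            assignments,
            guide_map,
            active_guide_subsets={gene: set(subset)},
            droplet_ids=base.droplet_ids,
        )
        Xp = normalize_design(design.X, mode)
        rows_ab = []
        for h_idx, h in enumerate(halves):
            fac = (
                factorize(Y[h], rank=rank, lambda1=lambda1, seed=split_seed)
                if exact_refit
                else facs[h_idx]
            )
            B, qmat = _recover_and_test(
                fac, Xp[h], lambda2, control_level, n_permutations, split_seed + h_idx
            )
            rows_ab.append((B[gene_col], qmat[gene_col]))
        (b_a, q_a), (b_b, q_b) = rows_ab
        keep = (q_a < q_threshold) | (q_b < q_threshold)
        if keep.sum() >= 2 and np.std(b_a[keep]) > 0 and np.std(b_b[keep]) > 0:
            r2 = float(np.corrcoef(b_a[keep], b_b[keep])[0, 1] ** 2)
        else:
            r2 = np.nan
        records.append(
            {
                "subset": ",".join(subset),
                "size": len(subset),
                "r2": r2,
                "n_entries": int(keep.sum()),
            }
        )
    table = pd.DataFrame(records)
    valid = table.dropna(subset=["r2"])
    if valid.empty:
        warnings.warn(
            f"no effects passed q < {q_threshold} for any subset of {gene}; "
            "keeping all guides"
        )
        return GuideSelection(gene, tuple(guides), float("nan"), 0, table)
    best = valid.sort_values(
        ["r2", "size", "subset"], ascending=[False, False, True], kind="mergesort"
    ).iloc[0]
    return GuideSelection(
        gene=gene,
        chosen_guides=tuple(best["subset"].split(",")),
        best_r2=float(best["r2"]),
        n_entries_compared=int(best["n_entries"]),
        table=table,
    )
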