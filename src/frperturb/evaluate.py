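"""Baseline estimator and comparison metrics.

The elastic-net baseline regresses each gene column of Y' on the design with
the penalty-form objective  0.5 ||y - X b||^2 + l1 ||b||_1 + (l2/2) ||b||^2
(the convention of the earliest Perturb-seq analyses), with a pooled
permutation null for significance.  Metrics: sign concordance, Pearson
correlation of the top significant effects, precision-recall against a truth
set, and a seeded downsampling harness.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import ElasticNet

from .containers import DesignMatrix, EffectResult
from .estimator import FRPerturb, normalize_design
from .significance import bh_fdr


class ElasticNetEffects(BaseEstimator):
    """Per-gene elastic-net effect estimation (baseline).

    Parameters l1 and l2 are the weights of the L1 and (halved) squared-L2
    penalties in the objective above; defaults 0.00025 / 0.00025.  p-values
    come from ``n_null_perms`` row permutations of X pooled across all
    entries (default 10).
    """

    def __init__(
        self,
        l1: float = 0.00025,
        l2: float = 0.00025,
        mode: str = "cell_pooled",
        n_null_perms: int = 10,
        random_state: int = 0,
    ):
        self.l1 = l1
        self.l2 = l2
        self.mode = mode
        self.n_null_perms = n_null_perms
        self.random_state = random_state

    def _solve(self, Xp: np.ndarray, Y: np.ndarray) -> np.ndarray:
        n = Xp.shape[0]
        alpha = (self.l1 + self.l2) / n
        l1_ratio = self.l1 / (self.l1 + self.l2)
        model = ElasticNet(
            alpha=alpha, l1_ratio=l1_ratio, fit_intercept=False, max_iter=50000
        )
        model.fit(Xp, Y)
        coef = model.coef_
        return coef.T if coef.ndim == 2 else coef[:, None]

    def fit(self, X, Y):
        design = X if isinstance(X, DesignMatrix) else None
        Xmat = X.X if design is not None else np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        Xp = normalize_design(Xmat, self.mode)
        self.effects_ = self._solve(Xp, Y)
        rng = np.random.default_rng(self.random_state)
        if self.n_null_perms > 0:
            pool = []
            for _ in range(self.n_null_perms):
                perm = rng.permutation(Xp.shape[0])
                pool.append(np.abs(self._solve(Xp[perm], Y)).ravel())
            pooled = np.sort(np.concatenate(pool))
            m = pooled.size
            # p = (1 + #{|null| >= |b|}) / (m + 1), via searchsorted on |null|
            ge = m - np.searchsorted(pooled, np.abs(self.effects_).ravel(), side="left")
            self.p_values_ = ((1.0 + ge) / (m + 1.0)).reshape(self.effects_.shape)
            self.q_values_ = bh_fdr(self.p_values_)
        else:
            self.p_values_ = self.q_values_ = None
        self.column_ids_ = design.column_ids if design is not None else [
            f"col{i}" for i in range(Xmat.shape[1])
        ]
        return self

    def result(self, gene_ids: list[str] | None = None) -> EffectResult:
        genes = (
            list(gene_ids)
            if gene_ids is not None
            else [f"gene{i}" for i in range(self.effects_.shape[1])]
        )
        return EffectResult(
            B_hat=self.effects_,
            perturbation_ids=self.column_ids_,
            gene_ids=genes,
            p_values=self.p_values_,
            q_values=self.q_values_,
            mode=self.mode,
            hyperparams={"l1": self.l1, "l2": self.l2},
        )


def elastic_net_fit(
    Y: np.ndarray, X, l1: float = 0.00025, l2: float = 0.00025,
    mode: str = "cell_pooled", n_null_perms: int = 10, seed: int = 0,
) -> EffectResult:
    """Thin functional wrapper over :class:`ElasticNetEffects`."""
    est = ElasticNetEffects(l1=l1, l2=l2, mode=mode, n_null_perms=n_null_perms,
                            random_state=seed)
    est.fit(X, Y)
    return est.result()


def sign_concordance(B_a: np.ndarray, B_b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Fraction of entries with matching sign; zero entries are excluded."""
    a, b = np.asarray(B_a, dtype=float), np.asarray(B_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    keep = (a != 0) & (b != 0)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    if not keep.any():
        return float("nan")
    return float((np.sign(a[keep]) == np.sign(b[keep])).mean())


def _top_k_order(result: EffectResult, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the k most significant entries: by p, ties by |effect| desc,
    then row-major index (deterministic)."""
    flat_b = result.B_hat.ravel()
    if result.p_values is not None:
        keys = np.lexsort((np.arange(flat_b.size), -np.abs(flat_b),
                           result.p_values.ravel()))
    else:
        keys = np.lexsort((np.arange(flat_b.size), -np.abs(flat_b)))
    top = keys[:k]
    return np.unravel_index(top, result.B_hat.shape)


def top_effect_correlation(result_a: EffectResult, result_b: EffectResult, k: int) -> float:
    """Pearson r between the two results over a's k most significant entries."""
    if result_a.B_hat.shape != result_b.B_hat.shape:
        raise ValueError("results must share shape (same perturbations x genes)")
    rows, cols = _top_k_order(result_a, k)
    va, vb = result_a.B_hat[rows, cols], result_b.B_hat[rows, cols]
    if np.std(va) == 0 or np.std(vb) == 0:
        return float("nan")
    return float(np.corrcoef(va, vb)[0, 1])


def precision_recall(
    p_values: np.ndarray, truth_significant: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """PR curve sweeping the p-value threshold; AUPRC by trapezoid over recall.

    ``truth_significant`` is a boolean matrix/array of the same size marking
    true effects.
    """
    from sklearn.metrics import precision_recall_curve

    p = np.asarray(p_values, dtype=float).ravel()
    truth = np.asarray(truth_significant, dtype=bool).ravel()
    if truth.size != p.size:
        raise ValueError("p-values and truth sizes differ")
    if not truth.any():
        raise ValueError("truth set is empty")
    precision, recall, _ = precision_recall_curve(truth, -p)
    # recall is decreasing along the returned arrays; integrate over recall
    auprc = float(-np.trapezoid(precision, recall))
    return precision, recall, auprc


def downsample_harness(
    Y: np.ndarray,
    design: DesignMatrix,
    fractions: list[float],
    seeds: list[int],
    mode: str = "guide_pooled",
    control_level: np.ndarray | None = None,
    axis: str = "droplets",
    n_channels: int = 20,
    top_k: int = 500,
    estimator_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Seeded subsample-refit-evaluate loop against a held-out split.

    Droplets are split 50/50 per seed; the reference fit uses the full
    held-out half, the evaluated fit a subsampled training half (by droplets
    or by whole channels — contiguous droplet blocks).  Emits a tidy table of
    sign concordance and top-k Pearson r per (seed, fraction).
    """
    if axis not in ("droplets", "cells", "channels"):
        raise ValueError("axis must be droplets, cells or channels")
    kwargs = dict(estimator_kwargs or {})
    kwargs.setdefault("mode", mode)
    rows = []
    n = Y.shape[0]
    for seed in seeds:
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        train, held = np.sort(order[: n // 2]), np.sort(order[n // 2 :])
        ref = FRPerturb(random_state=seed, **kwargs).fit(
            design.X[held], Y[held], control_level=control_level
        )
        ref_res = ref.result()
        for frac in fractions:
            if not 0 < frac <= 1:
                raise ValueError("fractions must be in (0, 1]")
            if axis == "channels":
                blocks = np.array_split(train, n_channels)
                take = max(1, int(round(frac * n_channels)))
                picked = rng.choice(n_channels, size=take, replace=False)
                sub = np.sort(np.concatenate([blocks[i] for i in picked]))
            else:
                take = max(1, int(round(frac * len(train))))
                sub = np.sort(rng.choice(train, size=take, replace=False))
            est = FRPerturb(random_state=seed, **kwargs).fit(
                design.X[sub], Y[sub], control_level=control_level
            )
            res = est.result()
            k = min(top_k, res.B_hat.size)
            rows.append(
                {
                    "seed": seed,
                    "fraction": frac,
                    "n_droplets": len(sub),
                    "sign_concordance": sign_concordance(res.B_hat, ref_res.B_hat),
                    "top_k_pearson_r": top_effect_correlation(res, ref_res, k),
                }
            )
    return pd.DataFrame(rows)
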