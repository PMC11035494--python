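"""Expression normalization, control centering and covariate residualization.

The estimator consumes Y' whose rows are log(TP10K + 1) expression minus the
mean control profile log(c), with technical covariates regressed out.  The
control profile is computed over droplets whose only called guides are
non-targeting ("control cells").
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, DesignMatrix

DEFAULT_SCALE_FACTOR = 1e4
DEFAULT_PSEUDOCOUNT = 1.0
CELL_CYCLE_SEED = 12345


@dataclass
class NormalizedMatrix:
    values: np.ndarray  # droplets x genes, log(TP10K + 1)
    droplet_ids: list[str]
    gene_ids: list[str]
    scale_factor: float = DEFAULT_SCALE_FACTOR
    pseudocount: float = DEFAULT_PSEUDOCOUNT


@dataclass
class ControlProfile:
    log_c: np.ndarray  # per-gene mean log(TP10K + 1) in control droplets
    level: np.ndarray  # per-gene ln(mean TP10K) in control droplets (floored)
    n_control: int


def log_tp10k(
    cm: CountMatrix,
    scale_factor: float = DEFAULT_SCALE_FACTOR,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> NormalizedMatrix:
    """Depth-normalize to TP10K and log-transform: ln(count/total*1e4 + 1)."""
    totals = cm.counts.sum(axis=1).astype(float)
    keep = totals > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-total droplets")
    counts = cm.counts[keep].astype(float)
    totals = totals[keep]
    values = np.log(counts / totals[:, None] * scale_factor + pseudocount)
    ids = [d for d, k in zip(cm.droplet_ids, keep) if k]
    return NormalizedMatrix(values, ids, list(cm.gene_ids), scale_factor, pseudocount)


def control_profile(
    norm: NormalizedMatrix,
    design: DesignMatrix,
    level_floor: float = 0.01,
) -> ControlProfile:
    """Mean log(TP10K+1) profile over non-targeting-only droplets.

    Also records each gene's control expression level ln(mean TP10K + floor),
    the x-axis of the LOESS magnitude-bias correction; the small floor keeps
    unexpressed genes finite.
    """
    row_of = {d: i for i, d in enumerate(norm.droplet_ids)}
    mask = design.control_mask()
    ctrl_rows = [row_of[d] for d, m in zip(design.droplet_ids, mask) if m and d in row_of]
    if not ctrl_rows:
        raise ValueError("no non-targeting-only control droplets available")
    sub = norm.values[ctrl_rows]
    log_c = sub.mean(axis=0)
    mean_tp10k = (np.exp(sub) - norm.pseudocount).clip(min=0).mean(axis=0)
    level = np.log(mean_tp10k + level_floor)
    return ControlProfile(log_c=log_c, level=level, n_control=len(ctrl_rows))


def center_on_controls(norm: NormalizedMatrix, profile: ControlProfile) -> np.ndarray:
    """Rows of Y' = log(y_i) - log(c)."""
    return norm.values - profile.log_c


def regress_out_covariates(Y: np.ndarray, covariates: pd.DataFrame | np.ndarray) -> np.ndarray:
    """OLS-residualize every gene column on mean-centered covariates.

    An intercept column is appended internally, so per-gene means survive only
    through the intercept (residual columns are mean zero).  Collinear
    covariates are handled by the minimum-norm least-squares solution.
    """
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if np.isnan(C).any():
        raise ValueError("covariates contain missing values")
    C = C - C.mean(axis=0)
    n = C.shape[0]
    if n != Y.shape[0]:
        raise ValueError("covariate rows != expression rows")
    design = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("covariate matrix is rank-deficient; using minimum-norm fit")
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    return Y - design @ coef


def cell_cycle_score(
    norm: NormalizedMatrix,
    signature_genes: list[str],
    seed: int = CELL_CYCLE_SEED,
    n_background: int | None = None,
) -> np.ndarray:
    """Signature-minus-background module score per droplet.

    Mean normalized expression of the signature genes minus the mean of a
    size-matched random background gene set (seeded, drawn from non-signature
    genes).  A transparent stand-in for binned cell-cycle scoring: it only
    needs to capture the cell-cycle axis as a covariate.
    """
    gene_idx = {g: i for i, g in enumerate(norm.gene_ids)}
    sig = [gene_idx[g] for g in signature_genes if g in gene_idx]
    if not sig:
        raise ValueError("signature genes do not intersect the matrix genes")
    pool = np.setdiff1d(np.arange(len(norm.gene_ids)), sig)
    size = len(sig) if n_background is None else n_background
    rng = np.random.default_rng(seed)
    if len(pool) == 0:
        bg_mean = np.zeros(norm.values.shape[0])
    else:
        bg = rng.choice(pool, size=min(size, len(pool)), replace=False)
        bg_mean = norm.values[:, bg].mean(axis=1)
    return norm.values[:, sig].mean(axis=1) - bg_mean


def build_covariates(
    cm: CountMatrix,
    norm: NormalizedMatrix,
    s_genes: list[str] | None = None,
    g2m_genes: list[str] | None = None,
    guides_per_droplet: np.ndarray | None = None,
    mito_prefix: str = "MT-",
    seed: int = CELL_CYCLE_SEED,
) -> pd.DataFrame:
    """Standard per-droplet technical covariates, mean-centered.

    total UMI count, mitochondrial fraction, optional S / G2M cell-cycle
    scores and optional guides-per-droplet.
    """
    row_of = {d: i for i, d in enumerate(cm.droplet_ids)}
    rows = [row_of[d] for d in norm.droplet_ids]
    counts = cm.counts[rows]
    totals = counts.sum(axis=1).astype(float)
    mito_cols = [i for i, g in enumerate(cm.gene_ids) if g.startswith(mito_prefix)]
    mito = counts[:, mito_cols].sum(axis=1) / totals if mito_cols else np.zeros(len(rows))
    cov = pd.DataFrame(
        {"total_umi": totals, "mito_fraction": mito}, index=norm.droplet_ids
    )
    if s_genes:
        cov["s_score"] = cell_cycle_score(norm, s_genes, seed=seed)
    if g2m_genes:
        cov["g2m_score"] = cell_cycle_score(norm, g2m_genes, seed=seed + 1)
    if guides_per_droplet is not None:
        cov["guides_per_cell"] = np.asarray(guides_per_droplet, dtype=float)
    cov = cov.loc[:, cov.std(axis=0) > 0]  # constant columns carry no signal
    return cov - cov.mean(axis=0)


def prepare_expression(
    cm: CountMatrix,
    design: DesignMatrix,
    covariates: pd.DataFrame | np.ndarray | None = None,
    scale_factor: float = DEFAULT_SCALE_FACTOR,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[np.ndarray, ControlProfile, NormalizedMatrix]:
    """Full preprocessing: normalize, center on controls, residualize.

    Returns (Y_centered aligned to the design's droplet order, control
    profile, normalized matrix).  Droplets present in the design but missing
    from the counts are an error.
    """
    norm = log_tp10k(cm, scale_factor, pseudocount)
    profile = control_profile(norm, design)
    row_of = {d: i for i, d in enumerate(norm.droplet_ids)}
    missing = [d for d in design.droplet_ids if d not in row_of]
    if missing:
        raise ValueError(f"design droplets missing from counts: {missing[:5]}")
    order = [row_of[d] for d in design.droplet_ids]
    Y = center_on_controls(norm, profile)[order]
    if covariates is not None:
        Y = regress_out_covariates(Y, covariates)
    return Y, profile, norm
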