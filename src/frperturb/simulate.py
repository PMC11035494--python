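"""Synthetic compressed Perturb-seq screens.

Emulates the structure of a pooled CRISPR screen with droplet overloading
(cell-pooling: several single-guide cells per droplet) or high-MOI
transduction (guide-pooling: several guides per cell), on top of a
negative-binomial control-cell model with lognormal gene means.  Ground-truth
effects are sparse and low-rank: B = U W with at most ``max_cofunctional``
non-zero perturbations per latent column — the structure whose recovery from
composite samples takes O((q + r) log n) samples.

Every output is reproducible bit-exactly from (configuration, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import CountMatrix, DesignMatrix, SimTruth
from .io import build_design, call_guides

P_CONTROL_DEFAULT = 0.10  # probability a guide slot carries a control guide


@dataclass
class ControlCellModel:
    """Negative-binomial control expression model.

    Gene means are lognormal on the TP10K scale (defaults: ln-mean -2,
    ln-sd 1.5); per-cell library sizes are lognormal; counts are
    gamma-Poisson with a common dispersion (var = mu + dispersion * mu^2).
    """

    gene_means_tp10k: np.ndarray
    dispersion: float = 0.3
    library_median: float = 5000.0
    library_sigma: float = 0.3
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.gene_means_tp10k = np.asarray(self.gene_means_tp10k, dtype=float)
        if not self.gene_ids:
            self.gene_ids = [f"gene{i:05d}" for i in range(len(self.gene_means_tp10k))]


def make_control_model(
    n_genes: int,
    seed: int = 0,
    ln_mean: float = -2.0,
    ln_sd: float = 1.5,
    dispersion: float = 0.3,
    library_median: float = 5000.0,
    library_sigma: float = 0.3,
) -> ControlCellModel:
    rng = np.random.default_rng(seed)
    means = np.exp(rng.normal(ln_mean, ln_sd, size=n_genes))
    return ControlCellModel(means, dispersion, library_median, library_sigma)


def _sample_counts(
    model: ControlCellModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n control cells of NB counts (float array, integer-valued)."""
    g = len(model.gene_means_tp10k)
    if n == 0:
        return np.zeros((0, g))
    libs = model.library_median * np.exp(
        rng.normal(0.0, model.library_sigma, size=n) - model.library_sigma**2 / 2
    )
    p = model.gene_means_tp10k / model.gene_means_tp10k.sum()
    mu = libs[:, None] * p[None, :]
    if model.dispersion > 0:
        shape = 1.0 / model.dispersion
        lam = rng.gamma(shape, mu * model.dispersion)
    else:
        lam = mu
    return rng.poisson(lam).astype(float)


def sample_control_cells(model: ControlCellModel, n: int, seed: int = 0) -> CountMatrix:
    """Draw n unperturbed cells from the control model."""
    rng = np.random.default_rng(seed)
    counts = _sample_counts(model, n, rng).astype(np.int64)
    ids = [f"CTRL{i:06d}" for i in range(n)]
    return CountMatrix(counts, ids, list(model.gene_ids))


def make_truth(
    n_perturbations: int = 100,
    n_genes: int = 2000,
    rank: int = 10,
    max_cofunctional: int = 10,
    effect_scale: float = 0.5,
    seed: int = 0,
    guides_per_target: int = 4,
    n_non_targeting: int = 20,
    n_safe_targeting: int = 20,
    guide_efficiency: float = 1.0,
) -> SimTruth:
    """Sparse low-rank ground-truth log fold changes plus a guide library.

    U_true (P x r) has at most ``max_cofunctional`` non-zero entries per
    column; W_true (r x G) is dense with unit-RMS rows.  Non-zero entries of
    B_true = U_true @ W_true are rescaled to RMS ``effect_scale``.
    """
    rng = np.random.default_rng(seed)
    P, G, r, q = n_perturbations, n_genes, rank, max_cofunctional
    U = np.zeros((P, r))
    for col in range(r):
        if q > 0:
            rows = rng.choice(P, size=min(q, P), replace=False)
            U[rows, col] = rng.standard_normal(len(rows))
    W = rng.standard_normal((r, G))
    W /= np.sqrt((W**2).mean(axis=1))[:, None]
    B = U @ W
    nz = B != 0
    if nz.any():
        rms = np.sqrt((B[nz] ** 2).mean())
        scale = effect_scale / rms
        U *= scale
        B *= scale

    pert_ids = [f"PGENE{i:04d}" for i in range(P)]
    rows = [
        (f"{g}_g{k + 1}", g, "targeting")
        for g in pert_ids
        for k in range(guides_per_target)
    ]
    rows += [(f"NT_{i:03d}", "", "non_targeting") for i in range(n_non_targeting)]
    rows += [(f"SAFE_{i:03d}", "", "safe_targeting") for i in range(n_safe_targeting)]
    gmap = pd.DataFrame(rows, columns=["guide_id", "target_gene", "guide_class"])
    eff = {gid: guide_efficiency for gid in gmap["guide_id"]}
    gene_ids = [f"gene{i:05d}" for i in range(G)]
    return SimTruth(
        B_true=B,
        perturbation_ids=pert_ids,
        gene_ids=gene_ids,
        rank=r,
        max_cofunctional=q,
        U_true=U,
        W_true=W,
        guide_map=gmap,
        guide_efficiency=eff,
        seed=seed,
    )


def inject_interactions(
    truth: SimTruth,
    pair_list: list[tuple[str, str]],
    interaction_effects: np.ndarray,
) -> SimTruth:
    """Return a copy of the truth with second-order effects on listed pairs.

    ``interaction_effects`` is len(pair_list) x G (log fold changes applied
    multiplicatively, on top of the first-order product, when both members of
    a pair are present in a cell).
    """
    eff = np.atleast_2d(np.asarray(interaction_effects, dtype=float))
    if eff.shape != (len(pair_list), len(truth.gene_ids)):
        raise ValueError("interaction_effects must be n_pairs x n_genes")
    known = set(truth.perturbation_ids)
    for a, b in pair_list:
        if a not in known or b not in known:
            raise KeyError(f"unknown perturbation in pair ({a}, {b})")
    return replace(truth, pair_ids=list(pair_list), pair_effects=eff)


@dataclass
class SimulatedScreen:
    """A simulated screen: counts + guide tables + design + ground truth."""

    counts: CountMatrix
    guide_umis: pd.DataFrame
    guide_map: pd.DataFrame
    design: DesignMatrix
    truth: SimTruth
    composition: list[list[str]]  # called guides per retained droplet/cell


def _stochastic_round(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Expectation-preserving rounding to integers."""
    lo = np.floor(x)
    return (lo + (rng.random(x.shape) < (x - lo))).astype(np.int64)


def _targeting_guides(truth: SimTruth) -> dict[str, list[str]]:
    gm = truth.guide_map
    t = gm[gm["guide_class"] == "targeting"]
    return {g: grp["guide_id"].tolist() for g, grp in t.groupby("target_gene")}


def _control_pool(truth: SimTruth) -> list[str]:
    gm = truth.guide_map
    return gm.loc[gm["guide_class"] != "targeting", "guide_id"].tolist()


def _guide_umi_table(
    composition: list[list[str]], droplet_ids: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    for did, guides in zip(droplet_ids, composition):
        for gid in sorted(set(guides)):
            rows.append((did, gid, 5 + int(rng.poisson(15))))
    return pd.DataFrame(rows, columns=["droplet_id", "guide_id", "umi_count"])


def _assemble(
    counts: np.ndarray,
    composition: list[list[str]],
    truth: SimTruth,
    rng: np.random.Generator,
    prefix: str,
) -> SimulatedScreen:
    ids = [f"{prefix}{i:06d}" for i in range(counts.shape[0])]
    cm = CountMatrix(counts, ids, list(truth.gene_ids))
    umis = _guide_umi_table(composition, ids, rng)
    design = build_design(call_guides(umis), truth.guide_map, droplet_ids=ids)
    return SimulatedScreen(cm, umis, truth.guide_map, design, truth, composition)


def _draw_cell_guides(
    truth: SimTruth,
    m: int,
    p_control: float,
    rng: np.random.Generator,
    guides_of: dict[str, list[str]],
    controls: list[str],
) -> tuple[list[str], list[int]]:
    """Guide content of one cell.

    With probability ``p_control`` the cell is a control cell (one control
    guide, no expression change); otherwise it carries guides for m distinct
    perturbations.  Returns (guide ids, effective perturbation indices) — a
    perturbation is effective only if its guide passes the efficiency draw.
    """
    if rng.random() < p_control:
        return [controls[rng.integers(len(controls))]], []
    P = len(truth.perturbation_ids)
    perts = rng.choice(P, size=min(m, P), replace=False)
    guides, effective = [], []
    for j in perts:
        gene = truth.perturbation_ids[j]
        gid = guides_of[gene][rng.integers(len(guides_of[gene]))]
        guides.append(gid)
        eff = 1.0 if truth.guide_efficiency is None else truth.guide_efficiency[gid]
        if rng.random() < eff:
            effective.append(int(j))
    return guides, effective


def simulate_cell_pooled(
    truth: SimTruth,
    model: ControlCellModel,
    n_droplets: int,
    m_cells: int,
    p_control: float = P_CONTROL_DEFAULT,
    seed: int = 0,
) -> SimulatedScreen:
    """Droplet-overloaded screen: m single-guide cells averaged per droplet.

    Each member cell carries one guide (control with probability
    ``p_control``); its counts are a control draw scaled by exp(beta) of its
    perturbation.  Droplet counts are the arithmetic mean of the m member
    cells, stochastically rounded.
    """
    if m_cells < 1:
        raise ValueError("m_cells must be >= 1")
    if len(model.gene_means_tp10k) != len(truth.gene_ids):
        raise ValueError("model and truth gene dimensions differ")
    rng = np.random.default_rng(seed)
    guides_of = _targeting_guides(truth)
    controls = _control_pool(truth)
    n_cells = n_droplets * m_cells
    base = _sample_counts(model, n_cells, rng)
    factors = np.ones_like(base)
    composition: list[list[str]] = [[] for _ in range(n_droplets)]
    for c in range(n_cells):
        guides, effective = _draw_cell_guides(
            truth, 1, p_control, rng, guides_of, controls
        )
        composition[c // m_cells] += guides
        for j in effective:
            factors[c] *= np.exp(truth.B_true[j])
    scaled = base * factors
    droplet = scaled.reshape(n_droplets, m_cells, -1).mean(axis=1)
    counts = _stochastic_round(droplet, rng)
    return _assemble(counts, composition, truth, rng, "DROP")


def simulate_guide_pooled(
    truth: SimTruth,
    model: ControlCellModel,
    n_cells: int,
    m_guides: int,
    p_control: float = P_CONTROL_DEFAULT,
    seed: int = 0,
) -> SimulatedScreen:
    """High-MOI screen: each cell carries m guides, effects multiply.

    Counts of a control draw are scaled by the elementwise product of
    exp(beta) over the cell's effective perturbations (plus any injected
    pairwise interaction factors), then stochastically rounded.
    """
    if m_guides < 1:
        raise ValueError("m_guides must be >= 1")
    if len(model.gene_means_tp10k) != len(truth.gene_ids):
        raise ValueError("model and truth gene dimensions differ")
    rng = np.random.default_rng(seed)
    guides_of = _targeting_guides(truth)
    controls = _control_pool(truth)
    base = _sample_counts(model, n_cells, rng)
    factors = np.ones_like(base)
    pair_idx = {
        frozenset((a, b)): k for k, (a, b) in enumerate(truth.pair_ids or [])
    }
    name_of = truth.perturbation_ids
    composition: list[list[str]] = []
    for c in range(n_cells):
        guides, effective = _draw_cell_guides(
            truth, m_guides, p_control, rng, guides_of, controls
        )
        composition.append(guides)
        lfc = truth.B_true[effective].sum(axis=0) if effective else 0.0
        if pair_idx and len(effective) >= 2:
            for a in range(len(effective)):
                for b in range(a + 1, len(effective)):
                    key = frozenset((name_of[effective[a]], name_of[effective[b]]))
                    k = pair_idx.get(key)
                    if k is not None:
                        lfc = lfc + truth.pair_effects[k]
        factors[c] = np.exp(lfc)
    counts = _stochastic_round(base * factors, rng)
    return _assemble(counts, composition, truth, rng, "CELL")


def arithmetic_vs_geometric(
    cell_counts: np.ndarray, m_cells: int
) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic and geometric droplet pooling of consecutive m-cell groups.

    The geometric mean is taken on counts + 1 (then shifted back) so zeros do
    not annihilate it.  Returns two (n_droplets x genes) arrays.
    """
    n = (cell_counts.shape[0] // m_cells) * m_cells
    grouped = cell_counts[:n].reshape(-1, m_cells, cell_counts.shape[1])
    arith = grouped.mean(axis=1)
    geom = np.exp(np.log(grouped + 1.0).mean(axis=1)) - 1.0
    return arith, geom
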