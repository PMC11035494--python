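"""Core in-memory containers shared across the package.

All containers are plain dataclasses over numpy arrays / pandas objects.
Droplets (or cells — a droplet holds one cell in a conventional screen) are
always rows; genes are always columns.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GUIDE_CLASSES = ("targeting", "non_targeting", "safe_targeting")
#: names of the two control indicator columns appended to every design matrix
CONTROL_COLUMNS = ("non_targeting", "safe_targeting")


@dataclass
class CountMatrix:
    """Raw UMI counts, droplets x genes."""

    counts: np.ndarray
    droplet_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.droplet_ids = list(self.droplet_ids)
        self.gene_ids = list(self.gene_ids)
        n, g = self.counts.shape
        if n != len(self.droplet_ids) or g != len(self.gene_ids):
            raise ValueError(
                f"count matrix is {n}x{g} but {len(self.droplet_ids)} droplet "
                f"ids / {len(self.gene_ids)} gene ids were given"
            )
        if len(set(self.droplet_ids)) != n:
            raise ValueError("droplet ids are not unique")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene ids are not unique")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)):
                raise ValueError("non-integer counts")
            self.counts = self.counts.astype(np.int64)

    @property
    def n_droplets(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class DesignMatrix:
    """Binary droplets x (P + 2) perturbation indicators.

    The last two columns flag the presence of a non-targeting and a
    safe-targeting control guide respectively.  ``guides_per_droplet`` (g_i)
    counts *called guides*, the proxy for the number of cells in a droplet
    under cell-pooling.
    """

    X: np.ndarray
    perturbation_ids: list[str]
    droplet_ids: list[str]
    guides_per_droplet: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.guides_per_droplet = np.asarray(self.guides_per_droplet)
        n, p2 = self.X.shape
        if p2 != len(self.perturbation_ids) + len(CONTROL_COLUMNS):
            raise ValueError("design width != P + 2")
        if n != len(self.droplet_ids) or n != len(self.guides_per_droplet):
            raise ValueError("row labels / g_i length mismatch")
        if not np.isin(self.X, (0.0, 1.0)).all():
            raise ValueError("design entries must be 0/1")
        if np.any(self.guides_per_droplet < 1):
            raise ValueError("droplets with zero called guides must be excluded")

    @property
    def column_ids(self) -> list[str]:
        return list(self.perturbation_ids) + list(CONTROL_COLUMNS)

    @property
    def n_perturbations(self) -> int:
        return len(self.perturbation_ids)

    def targeting_block(self) -> np.ndarray:
        return self.X[:, : self.n_perturbations]

    def control_mask(self) -> np.ndarray:
        """Droplets containing only non-targeting guides (baseline cells)."""
        nt = self.X[:, self.n_perturbations] == 1
        other = self.X[:, : self.n_perturbations].sum(axis=1) + self.X[:, -1]
        return nt & (other == 0)


@dataclass
class Factorization:
    """Sparse factorization Y' ~ U_tilde @ W (droplets x R times R x genes)."""

    U_tilde: np.ndarray
    W: np.ndarray
    rank: int
    lambda1: float
    objective: float
    converged: bool
    seed: int | None = None

    @property
    def reconstruction(self) -> np.ndarray:
        return self.U_tilde @ self.W


@dataclass
class EffectResult:
    """Perturbation-by-gene log fold change estimates with significance."""

    B_hat: np.ndarray
    perturbation_ids: list[str]
    gene_ids: list[str]
    U: np.ndarray | None = None
    p_values: np.ndarray | None = None
    q_values: np.ndarray | None = None
    mode: str = "cell_pooled"
    hyperparams: dict = field(default_factory=dict)
    correction_applied: bool = False

    def to_long(self) -> pd.DataFrame:
        """Long-format (perturbation, gene, lfc, p, q) table."""
        p_idx, g_idx = np.meshgrid(
            np.arange(len(self.perturbation_ids)),
            np.arange(len(self.gene_ids)),
            indexing="ij",
        )
        out = pd.DataFrame(
            {
                "perturbation": np.asarray(self.perturbation_ids)[p_idx.ravel()],
                "gene": np.asarray(self.gene_ids)[g_idx.ravel()],
                "lfc": self.B_hat.ravel(),
            }
        )
        if self.p_values is not None:
            out["p"] = self.p_values.ravel()
        if self.q_values is not None:
            out["q"] = self.q_values.ravel()
        return out


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator for recovery testing."""

    B_true: np.ndarray  # P x G log fold changes
    perturbation_ids: list[str]
    gene_ids: list[str]
    rank: int
    max_cofunctional: int  # q: max non-zeros per latent column
    U_true: np.ndarray | None = None
    W_true: np.ndarray | None = None
    guide_map: pd.DataFrame | None = None
    guide_efficiency: dict[str, float] | None = None
    pair_ids: list[tuple[str, str]] = field(default_factory=list)
    pair_effects: np.ndarray | None = None  # len(pair_ids) x G interaction lfc
    seed: int | None = None
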