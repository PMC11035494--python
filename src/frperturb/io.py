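"""Reading the CellRanger-style trio, guide calling and design construction.

On disk the count matrix follows the CellRanger convention: a MatrixMarket
coordinate file of genes x droplets, with ``features.tsv`` and
``barcodes.tsv`` label files (one entry per line).  In memory everything is
droplets x genes.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CONTROL_COLUMNS, GUIDE_CLASSES, CountMatrix, DesignMatrix

#: a guide is called present in a droplet at this many supporting UMIs
DEFAULT_MIN_UMI = 5


class FormatError(ValueError):
    """Malformed on-disk input."""


def _read_lines(path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts(matrix_path, barcodes_path, features_path) -> CountMatrix:
    """Load an MTX + barcodes + features trio into a droplets x genes matrix.

    The on-disk matrix is genes x droplets (CellRanger); it is transposed on
    load.  Label files must match the header dimensions exactly.
    """
    try:
        mat = scipy.io.mmread(matrix_path)
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"cannot parse MatrixMarket file: {exc}") from exc
    mat = scipy.sparse.coo_matrix(mat)
    barcodes = _read_lines(barcodes_path)
    features = _read_lines(features_path)
    n_genes, n_droplets = mat.shape
    if len(features) != n_genes:
        raise FormatError(
            f"features file has {len(features)} entries, header says {n_genes} genes"
        )
    if len(barcodes) != n_droplets:
        raise FormatError(
            f"barcodes file has {len(barcodes)} entries, header says {n_droplets} droplets"
        )
    dense = np.asarray(mat.todense())
    if np.any(dense < 0):
        raise FormatError("negative count entries")
    if not np.issubdtype(dense.dtype, np.integer) and np.any(dense != np.round(dense)):
        raise FormatError("non-integer count entries")
    return CountMatrix(dense.T.astype(np.int64), droplet_ids=barcodes, gene_ids=features)


def write_counts(cm: CountMatrix, matrix_path, barcodes_path, features_path) -> None:
    """Write a CountMatrix back to the on-disk trio (genes x droplets MTX)."""
    sp = scipy.sparse.coo_matrix(cm.counts.T)
    scipy.io.mmwrite(str(matrix_path), sp, field="integer")
    # mmwrite appends .mtx only when the suffix is missing; normalise
    written = Path(str(matrix_path))
    if not written.exists() and written.with_suffix(written.suffix + ".mtx").exists():
        written.with_suffix(written.suffix + ".mtx").rename(written)
    Path(barcodes_path).write_text("".join(b + "\n" for b in cm.droplet_ids))
    Path(features_path).write_text("".join(g + "\n" for g in cm.gene_ids))


def read_guide_umis(path) -> pd.DataFrame:
    """Guide UMI table: droplet_id, guide_id, umi_count (TSV with header)."""
    df = pd.read_csv(path, sep="\t", dtype={"droplet_id": str, "guide_id": str})
    missing = {"droplet_id", "guide_id", "umi_count"} - set(df.columns)
    if missing:
        raise FormatError(f"guide UMI table missing columns: {sorted(missing)}")
    return df


def read_guide_map(path) -> pd.DataFrame:
    """Guide map: guide_id, target_gene, guide_class (TSV with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"guide_id", "target_gene", "guide_class"} - set(df.columns)
    if missing:
        raise FormatError(f"guide map missing columns: {sorted(missing)}")
    bad = set(df["guide_class"]) - set(GUIDE_CLASSES)
    if bad:
        raise FormatError(f"unknown guide classes: {sorted(bad)}")
    return df


def call_guides(guide_umis: pd.DataFrame, min_umi: int = DEFAULT_MIN_UMI) -> pd.DataFrame:
    """Call guides present in droplets: keep pairs with umi_count >= min_umi."""
    if (guide_umis["umi_count"] < 0).any():
        raise FormatError("negative UMI counts in guide table")
    dups = guide_umis.duplicated(["droplet_id", "guide_id"])
    if dups.any():
        raise FormatError("duplicate (droplet, guide) pairs in guide table")
    called = guide_umis.loc[guide_umis["umi_count"] >= min_umi].reset_index(drop=True)
    return called


def build_design(
    assignments: pd.DataFrame,
    guide_map: pd.DataFrame,
    active_guide_subsets: dict[str, set[str]] | None = None,
    droplet_ids: list[str] | None = None,
) -> DesignMatrix:
    """Collapse called guides to a binary droplets x (P + 2) design matrix.

    x_ij = 1 iff droplet i carries at least one *active* guide targeting gene
    j; the two trailing columns indicate non-targeting and safe-targeting
    control guides.  g_i counts all called guides in the droplet (including
    guides made inactive for their gene by ``active_guide_subsets``, which
    only restricts which guides assert the gene's indicator).  Droplets with
    zero called guides are excluded.

    Parameters
    ----------
    active_guide_subsets : optional mapping gene -> set of guide ids that
        count toward that gene's indicator (see guide selection).
    droplet_ids : optional explicit row universe/order (droplets without
        called guides are still dropped).
    """
    gm = guide_map.set_index("guide_id")
    unknown = set(assignments["guide_id"]) - set(gm.index)
    if unknown:
        raise KeyError(f"guides not in guide map: {sorted(unknown)[:5]}")

    targeting = gm[gm["guide_class"] == "targeting"]
    perturbation_ids = sorted(targeting["target_gene"].unique())
    col_of = {g: i for i, g in enumerate(perturbation_ids)}
    P = len(perturbation_ids)

    df = assignments.copy()
    df["guide_class"] = gm.loc[df["guide_id"], "guide_class"].to_numpy()
    df["target_gene"] = gm.loc[df["guide_id"], "target_gene"].to_numpy()

    observed = df["droplet_id"].unique().tolist()
    if droplet_ids is None:
        rows = observed
    else:
        keep = set(observed)
        rows = [d for d in droplet_ids if d in keep]
    row_of = {d: i for i, d in enumerate(rows)}

    X = np.zeros((len(rows), P + len(CONTROL_COLUMNS)))
    g_i = np.zeros(len(rows), dtype=int)
    nt_col, safe_col = P, P + 1
    for droplet, guide, gclass, target in zip(
        df["droplet_id"], df["guide_id"], df["guide_class"], df["target_gene"]
    ):
        i = row_of[droplet]
        g_i[i] += 1
        if gclass == "non_targeting":
            X[i, nt_col] = 1
        elif gclass == "safe_targeting":
            X[i, safe_col] = 1
        else:
            if active_guide_subsets is not None and target in active_guide_subsets:
                if guide not in active_guide_subsets[target]:
                    continue
            X[i, col_of[target]] = 1

    return DesignMatrix(X, perturbation_ids, rows, g_i)


def make_guide_library(
    n_genes: int = 598,
    guides_per_gene: int = 4,
    n_non_targeting: int = 500,
    n_safe_targeting: int = 500,
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Build a guide-library design table (guide_id, target_gene, guide_class).

    Defaults mirror a genome-scale immune-gene KO library: 4 sgRNAs per
    perturbed gene plus non-targeting and safe-targeting control pools.
    """
    if gene_ids is None:
        gene_ids = [f"GENE{i:04d}" for i in range(n_genes)]
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    rows = [
        (f"{g}_g{k + 1}", g, "targeting")
        for g in gene_ids
        for k in range(guides_per_gene)
    ]
    rows += [(f"NT_{i:04d}", "", "non_targeting") for i in range(n_non_targeting)]
    rows += [(f"SAFE_{i:04d}", "", "safe_targeting") for i in range(n_safe_targeting)]
    return pd.DataFrame(rows, columns=["guide_id", "target_gene", "guide_class"])
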