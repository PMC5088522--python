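"""Multi-tissue FPKM expression matrices: loading, expression calls, clustering.

The in-memory container pairs a genes x samples FPKM table with a sample
design (sample -> tissue, replicate).  Downstream rules follow the standard
bulk RNA-Seq conventions: a gene is *expressed* in a tissue when at least one
replicate reaches the FPKM threshold (default 1), analysis happens on
log2(FPKM + 1), and samples are compared with the rank-based
1 - Spearman-correlation distance followed by agglomerative clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import rankdata

__all__ = [
    "ExpressionMatrix",
    "ExpressionCalls",
    "Dendrogram",
    "log_transform",
    "detect_expressed",
    "filter_expressed_genes",
    "sample_distance",
    "cluster_samples",
    "tissue_means",
]

DESIGN_COLUMNS = ("sample_id", "tissue", "replicate")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus the sample design.

    ``values``: DataFrame indexed by gene id, one column per sample id.
    ``design``: DataFrame with columns sample_id, tissue, replicate.
    ``log_scale``: True once values are log2(FPKM + 1); several operations
    (expression calls, log transform) insist on the FPKM scale and raise on
    misuse.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        if v.columns.duplicated().any():
            raise ValueError("duplicate sample ids in expression matrix")
        arr = v.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if not self.log_scale and (arr < 0).any():
            raise ValueError("FPKM values must be non-negative")
        missing = set(DESIGN_COLUMNS) - set(self.design.columns)
        if missing:
            raise ValueError(f"design table lacks columns: {sorted(missing)}")
        if set(v.columns) != set(self.design["sample_id"]):
            raise ValueError("design sample_ids do not match matrix columns")
        # keep design in matrix column order
        self.design = (
            self.design.set_index("sample_id").loc[list(v.columns)].reset_index()
        )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tissues(self) -> list[str]:
        return list(pd.unique(self.design["tissue"]))

    def samples_of_tissue(self, tissue: str) -> list[str]:
        return list(self.design.loc[self.design["tissue"] == tissue, "sample_id"])

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes]
        return ExpressionMatrix(self.values.loc[genes], self.design.copy(), self.log_scale)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        design = self.design[self.design["sample_id"].isin(samples)].copy()
        return ExpressionMatrix(self.values[samples], design, self.log_scale)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def read(cls, matrix_path: str | Path, design_path: str | Path,
             log_scale: bool = False) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t", dtype={"sample_id": str, "tissue": str})
        return cls(values, design, log_scale)

    def write(self, matrix_path: str | Path, design_path: str | Path | None = None) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(matrix_path, sep="\t")
        if design_path is not None:
            self.design.to_csv(design_path, sep="\t", index=False)


@dataclass
class ExpressionCalls:
    """Per-gene expression calls at a fixed FPKM threshold."""

    table: pd.DataFrame  # columns: tissues_expressed_in, expressed_in_all_samples, expressed_in_all_tissues
    threshold: float
    n_tissues: int

    def expressed_in_all_samples(self) -> set[str]:
        return set(self.table.index[self.table["expressed_in_all_samples"]])

    def expressed_in_all_tissues(self) -> set[str]:
        return set(self.table.index[self.table["expressed_in_all_tissues"]])

    def write(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Return the matrix on the log2(FPKM + 1) scale."""
    if matrix.log_scale:
        raise ValueError("matrix is already log-transformed")
    return ExpressionMatrix(
        np.log2(matrix.values + 1.0), matrix.design.copy(), log_scale=True
    )


def detect_expressed(matrix: ExpressionMatrix, threshold: float = 1.0) -> ExpressionCalls:
    """Call expression per gene: a tissue counts when >=1 replicate reaches
    ``threshold`` FPKM ("equal or higher"); ubiquity flags additionally track
    all-sample and all-tissue expression.
    """
    if matrix.log_scale:
        raise ValueError("detect_expressed requires the FPKM scale, got a log matrix")
    arr = matrix.values.to_numpy()
    hit = arr >= threshold
    tissues = matrix.tissues
    cols = {t: [matrix.sample_ids.index(s) for s in matrix.samples_of_tissue(t)] for t in tissues}
    per_tissue = np.column_stack([hit[:, idx].any(axis=1) for t, idx in cols.items()])
    table = pd.DataFrame(
        {
            "tissues_expressed_in": per_tissue.sum(axis=1),
            "expressed_in_all_samples": hit.all(axis=1),
            "expressed_in_all_tissues": per_tissue.all(axis=1),
        },
        index=matrix.values.index,
    )
    return ExpressionCalls(table, threshold=threshold, n_tissues=len(tissues))


def filter_expressed_genes(
    matrix: ExpressionMatrix, threshold: float = 1.0, rule: str = "any_tissue"
) -> ExpressionMatrix:
    """Drop genes without relevant signal, judged on per-tissue replicate means.

    rule="any_tissue" (default) keeps a gene when its replicate-mean FPKM
    reaches ``threshold`` in at least one tissue; rule="all_tissues" requires
    it in every tissue (which retains only ubiquitous genes).
    """
    if matrix.log_scale:
        raise ValueError("filter on the FPKM scale before log transforming")
    means = tissue_means(matrix).values.to_numpy()
    if rule == "any_tissue":
        keep = (means >= threshold).any(axis=1)
    elif rule == "all_tissues":
        keep = (means >= threshold).all(axis=1)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return ExpressionMatrix(matrix.values.loc[keep], matrix.design.copy(), matrix.log_scale)


def _rank_rows(arr: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(rankdata, 1, arr)  # average ranks for ties


def sample_distance(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Pairwise 1 - Spearman-correlation distance between samples.

    Zero-variance samples have undefined rank correlation; they are reported
    with a warning and placed at the maximum distance (2) from everything.
    """
    arr = matrix.values.to_numpy(dtype=float).T  # samples x genes
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    ranks = _rank_rows(arr)
    sd = ranks.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        bad = [s for s, d in zip(matrix.sample_ids, degenerate) if d]
        warnings.warn(f"zero-variance samples set to maximum distance: {bad}")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks)
    dist = 1.0 - corr
    dist[np.isnan(dist)] = 2.0
    dist[degenerate, :] = 2.0
    dist[:, degenerate] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    return pd.DataFrame(dist, index=matrix.sample_ids, columns=matrix.sample_ids)


@dataclass
class Dendrogram:
    """Agglomerative clustering result: a scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray
    labels: list[str]
    method: str

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        import skbio

        tree = skbio.TreeNode.from_linkage_matrix(self.linkage, self.labels)
        return str(tree).strip()

    def first_merge(self) -> tuple[set[str], float]:
        """Leaf labels joined by the lowest merge, with its height."""
        i, j, h = self.linkage[0, 0], self.linkage[0, 1], self.linkage[0, 2]
        return {self.labels[int(i)], self.labels[int(j)]}, float(h)

    def cut(self, n_clusters: int) -> dict[str, int]:
        flat = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))


def cluster_samples(distances: pd.DataFrame, method: str = "complete") -> Dendrogram:
    """Hierarchical clustering of a symmetric distance matrix (hclust-style)."""
    arr = distances.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    condensed = arr[np.triu_indices_from(arr, k=1)]
    Z = hierarchy.linkage(condensed, method=method)
    return Dendrogram(Z, list(distances.index), method)


def tissue_means(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse replicates: one column per tissue, the arithmetic mean of its
    replicates on the current scale."""
    cols = {t: matrix.samples_of_tissue(t) for t in matrix.tissues}
    data = {t: matrix.values[s].mean(axis=1) for t, s in cols.items()}
    values = pd.DataFrame(data, index=matrix.values.index)
    design = pd.DataFrame(
        {"sample_id": list(cols), "tissue": list(cols), "replicate": 1}
    )
    return ExpressionMatrix(values, design, matrix.log_scale)
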