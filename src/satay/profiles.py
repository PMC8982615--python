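"""Variable-gene selection, library clustering, and co-essentiality profiles.

Genes that are required under the same set of conditions tend to work in
the same pathway or complex.  The profile of a gene is the vector of its
normalized transposon counts across libraries; Pearson correlation of
profiles over the most variable genes, hierarchically clustered, exposes
such co-essential modules.  Libraries themselves are Ward-clustered on
the same normalized counts (replicate-like libraries cluster as nearest
neighbors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from skbio.tree import TreeNode

from .fitness import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class VariableGeneSet:
    """Top-k genes by standard deviation of normalized counts across
    libraries, ordered by descending StdDev (ties broken by gene id)."""

    gene_ids: list[str]
    stddevs: pd.Series
    k: int


@dataclass
class Dendrogram:
    """A hierarchical merge tree over items (libraries or genes)."""

    linkage_matrix: np.ndarray
    items: list[str]
    method: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.items[i] for i in leaves_list(self.linkage_matrix)]

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.items)
        return str(tree).strip()


@dataclass
class GeneCorrelationMatrix:
    """Symmetric gene x gene Pearson correlation matrix of insertion
    profiles across libraries.  Zero-variance genes carry NaN rows."""

    r: pd.DataFrame
    n_libraries: int

    @property
    def gene_ids(self) -> list[str]:
        return list(self.r.index)


def select_variable_genes(norm: NormalizedMatrix, k: int) -> VariableGeneSet:
    """Rank genes by sample StdDev (n-1) of normalized counts across
    libraries and return the top k (deterministic: ties break by gene id)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if norm.values.shape[1] < 2:
        raise ValueError("variable-gene selection needs >= 2 libraries")
    sd = norm.values.std(axis=1, ddof=1)
    order = sorted(sd.index, key=lambda g: (-sd[g], g))
    if k > len(order):
        logger.warning("k=%d exceeds gene count %d; returning all genes", k, len(order))
        k_eff = len(order)
    else:
        k_eff = k
    chosen = order[:k_eff]
    return VariableGeneSet(gene_ids=chosen, stddevs=sd[chosen], k=k)


def cluster_libraries(norm: NormalizedMatrix, method: str = "ward",
                      log_transform: bool = False) -> Dendrogram:
    """Agglomerative clustering of libraries (items) on their per-gene
    normalized counts (features), Ward criterion on Euclidean distances.
    ``log_transform`` applies log2(x + 1) variance stabilization first
    (default off: raw normalized counts are clustered)."""
    X = norm.values.T.to_numpy(dtype=float)
    if log_transform:
        X = np.log2(X + 1.0)
    if X.shape[0] < 2:
        raise ValueError("library clustering needs >= 2 libraries")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in normalized matrix")
    Z = linkage(X, method=method)
    return Dendrogram(linkage_matrix=Z, items=norm.library_ids, method=method)


def gene_correlation(norm: NormalizedMatrix,
                     gene_subset: VariableGeneSet | list[str]) -> GeneCorrelationMatrix:
    """Pairwise Pearson correlation of gene profiles across libraries.

    Genes with zero variance across libraries get NaN correlations (they
    are excluded from clustering, with a warning).
    """
    genes = gene_subset.gene_ids if isinstance(gene_subset, VariableGeneSet) else list(gene_subset)
    missing = set(genes) - set(norm.values.index)
    if missing:
        raise ValueError(f"genes absent from matrix: {sorted(missing)[:5]}")
    n_lib = norm.values.shape[1]
    if n_lib < 3:
        raise ValueError("gene correlation needs >= 3 libraries")
    X = norm.values.loc[genes].to_numpy(dtype=float)
    centered = X - X.mean(axis=1, keepdims=True)
    ss = np.sqrt((centered**2).sum(axis=1))
    zero_var = ss == 0
    if zero_var.any():
        logger.warning("%d zero-variance genes have undefined correlations",
                       int(zero_var.sum()))
    ss_safe = np.where(zero_var, np.nan, ss)
    r = (centered @ centered.T) / np.outer(ss_safe, ss_safe)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, np.where(zero_var, np.nan, 1.0))
    return GeneCorrelationMatrix(r=pd.DataFrame(r, index=genes, columns=genes),
                                 n_libraries=n_lib)


def cluster_correlation(corr: GeneCorrelationMatrix,
                        method: str = "ward") -> tuple[Dendrogram, pd.DataFrame]:
    """Hierarchically cluster genes on distance 1 - r (Ward) and return the
    dendrogram plus the correlation matrix reordered for clusterogram
    display.  Genes with undefined correlations are excluded (logged)."""
    r = corr.r
    defined = r.index[np.isfinite(np.diag(r.to_numpy()))]
    dropped = len(r) - len(defined)
    if dropped:
        logger.warning("excluding %d genes with undefined correlations from clustering",
                       dropped)
    r = r.loc[defined, defined]
    if len(r) < 2:
        raise ValueError("need >= 2 genes with defined correlations to cluster")
    d = 1.0 - r.to_numpy()
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method=method)
    dend = Dendrogram(linkage_matrix=Z, items=list(r.index), method=method)
    order = dend.leaf_order
    return dend, r.loc[order, order]
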