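"""Subpopulation discovery: PCA gene selection, SNN clustering, markers.

Tumor subpopulations are found by (1) selecting the most informative
genes as the top loadings of the first principal components of the
z-scored matrix, (2) building a shared-nearest-neighbor (SNN) graph —
k-nearest neighbors in PC space with edges reweighted by the Jaccard
overlap of the endpoints' neighbor sets — and (3) maximizing modularity
on that graph. Cluster markers come from a two-part one-vs-rest test
combining a detection-proportion z-test with a rank-sum test on
expressed values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from snrs.matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class Embedding:
    """Cell coordinates in PC space, with variance explained per PC."""

    coords: pd.DataFrame  # cells x components
    variance_ratio: np.ndarray

    @property
    def cells(self) -> pd.Index:
        return self.coords.index


def pca_select_genes(
    z: ExpressionMatrix,
    n_pcs: int = 5,
    top_loadings: int = 20,
) -> tuple[list[str], Embedding]:
    """Select the union of top-loading genes from the first PCs.

    PCA is computed on the gene-standardized matrix (cells as samples);
    from each of the first ``n_pcs`` components the ``top_loadings``
    genes by absolute loading are taken and the union returned (in the
    matrix's gene order), together with the cell embedding and variance
    explained.
    """
    z.require_state("zscore")
    X = z.values.values.T  # cells x genes
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("constant matrix has no principal components")
    n_pcs_eff = min(n_pcs, min(X.shape) - 1)
    if n_pcs_eff < n_pcs:
        logger.warning("pca_select_genes: only %d non-degenerate PCs available", n_pcs_eff)
    pca = PCA(n_components=n_pcs_eff, svd_solver="full", random_state=0)
    coords = pca.fit_transform(X)
    selected: set[str] = set()
    genes = z.values.index.to_numpy()
    for comp in pca.components_:
        top = np.argsort(-np.abs(comp), kind="stable")[:top_loadings]
        selected.update(genes[top])
    ordered = [g for g in genes if g in selected]
    embedding = Embedding(
        coords=pd.DataFrame(
            coords, index=z.values.columns, columns=[f"PC{i + 1}" for i in range(n_pcs_eff)]
        ),
        variance_ratio=pca.explained_variance_ratio_,
    )
    return ordered, embedding


@dataclass
class SNNGraph:
    """Weighted SNN graph over cells (Jaccard overlap of k-NN sets)."""

    cells: pd.Index
    edges: np.ndarray  # (n_edges, 2) int indices, i < j
    weights: np.ndarray
    k: int

    def to_igraph(self) -> ig.Graph:
        g = ig.Graph(n=len(self.cells), edges=[tuple(e) for e in self.edges])
        g.es["weight"] = list(self.weights)
        return g


def build_snn_graph(X: np.ndarray, cells: pd.Index, k: int = 20) -> SNNGraph:
    """k-NN graph (Euclidean) reweighted by Jaccard neighbor-set overlap.

    Neighbor sets include the cell itself; an edge is kept between every
    pair that appears in each other's candidate k-NN lists, weighted by
    |N(i) ∩ N(j)| / |N(i) ∪ N(j)|, and zero-weight edges are pruned.
    """
    n = len(cells)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    _, idx = nn.kneighbors(X)
    neighbor_sets = [set(row) for row in idx]
    pairs = set()
    for i in range(n):
        for j in idx[i]:
            if i != j:
                pairs.add((min(i, int(j)), max(i, int(j))))
    edges, weights = [], []
    for i, j in sorted(pairs):
        inter = len(neighbor_sets[i] & neighbor_sets[j])
        union = len(neighbor_sets[i] | neighbor_sets[j])
        w = inter / union
        if w > 0:
            edges.append((i, j))
            weights.append(w)
    return SNNGraph(
        cells=cells, edges=np.array(edges, dtype=int), weights=np.array(weights), k=k
    )


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels and the modularity of the partition."""

    labels: pd.Series  # cell -> cluster id (0-based, size-ordered)
    modularity: float

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def snn_cluster(
    data: Embedding | pd.DataFrame,
    k: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
) -> ClusterAssignment:
    """Cluster cells by modularity maximization on the SNN graph.

    ``data`` is an :class:`Embedding` or a cells x features frame.
    Partitioning uses seeded Leiden-style local moving on the weighted
    graph (equivalent to modularity at resolution 1); cluster ids are
    relabeled 0..K-1 in decreasing size order for determinism.
    """
    if isinstance(data, Embedding):
        frame = data.coords
    else:
        frame = data
    X = np.asarray(frame.values, dtype=float)
    graph = build_snn_graph(X, frame.index, k=k)
    g = graph.to_igraph()
    partition = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    membership = np.array(partition.membership)
    # relabel by decreasing cluster size, ties by original id
    order = pd.Series(membership).value_counts().sort_values(ascending=False).index
    remap = {old: new for new, old in enumerate(order)}
    labels = pd.Series([remap[c] for c in membership], index=frame.index, name="cluster")
    modularity = g.modularity(membership, weights="weight")
    logger.info("snn_cluster: %d clusters, modularity %.3f", labels.nunique(), modularity)
    return ClusterAssignment(labels=labels, modularity=modularity)


def _two_proportion_z(k1, n1, k2, n2) -> np.ndarray:
    """Vectorized two-sided two-proportion z-test p-values."""
    k1, k2 = np.asarray(k1, float), np.asarray(k2, float)
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, (p1 - p2) / se, 0.0)
    return 2 * stats.norm.sf(np.abs(z))


def find_markers(
    m: ExpressionMatrix,
    clusters: ClusterAssignment,
    min_lfc: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest two-part marker test per cluster.

    For each gene and cluster: a two-proportion z-test on the detection
    rate (fraction of cells with expression > 0) and a Wilcoxon
    rank-sum test on the expressed values, combined by Fisher's method;
    Benjamini-Hochberg adjustment across genes within each cluster.
    A marker satisfies FDR < ``alpha`` and |log2 fold change| >=
    ``min_lfc``, with fold change on mean expression + pseudocount 1.
    Clusters with fewer than 3 cells are skipped with a warning.
    """
    labels = clusters.labels.reindex(m.values.columns)
    if labels.isna().any():
        raise ValueError("cluster assignment does not cover all cells in the matrix")
    cluster_ids = sorted(labels.unique())
    if len(cluster_ids) < 2:
        raise ValueError("marker detection requires at least 2 clusters")
    values = m.values.values
    results = []
    for cid in cluster_ids:
        in_mask = (labels == cid).values
        n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
        if n_in < 3:
            logger.warning("find_markers: cluster %s has < 3 cells, skipped", cid)
            continue
        x_in, x_out = values[:, in_mask], values[:, ~in_mask]
        det_in, det_out = (x_in > 0).sum(axis=1), (x_out > 0).sum(axis=1)
        p_det = _two_proportion_z(det_in, n_in, det_out, n_out)

        p_rank = np.ones(values.shape[0])
        for gi in range(values.shape[0]):
            a = x_in[gi][x_in[gi] > 0]
            b = x_out[gi][x_out[gi] > 0]
            if len(a) >= 2 and len(b) >= 2:
                p_rank[gi] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue

        chi = -2 * (np.log(np.clip(p_det, 1e-300, 1)) + np.log(np.clip(p_rank, 1e-300, 1)))
        p_comb = stats.chi2.sf(chi, df=4)
        fdr = multipletests(p_comb, method="fdr_bh")[1]
        lfc = np.log2((x_in.mean(axis=1) + 1) / (x_out.mean(axis=1) + 1))
        results.append(
            pd.DataFrame(
                {
                    "gene": m.values.index,
                    "cluster": cid,
                    "log2_fc": lfc,
                    "p_detection": p_det,
                    "p_ranksum": p_rank,
                    "statistic": chi,
                    "p": p_comb,
                    "fdr": fdr,
                    "marker": (fdr < alpha) & (np.abs(lfc) >= min_lfc),
                }
            )
        )
    return pd.concat(results, ignore_index=True)
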