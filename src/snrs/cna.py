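"""Copy-number inference from single-nucleus expression profiles.

Large chromosomal gains and losses shift the expression of every gene
they span; averaging relative expression over runs of genomically
adjacent genes suppresses gene-level noise so that segment-level dosage
shows through. The procedure:

1. scale each cell's total (log-scale) expression to a common value
   (100,000) so cells are comparable;
2. order genes genomically and drop weakly expressed genes
   (mean < 0.15 after scaling);
3. subtract the per-gene mean of a diploid baseline population and clip
   relative values to [-3, +3] to tame expression outliers;
4. take a 50-gene moving average within each chromosome, then center
   each cell's profile at zero;
5. hierarchically cluster all cells (Ward linkage, Euclidean distance)
   together with the baseline, cut into two groups, and label the group
   holding the majority of baseline cells diploid, the other aneuploid.

Tumor purity of a selected cell set is the percentage called aneuploid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from snrs.errors import EmptyInputError, TieError
from snrs.matrix import ExpressionMatrix, GeneAnnotation, chromosome_sort_key

logger = logging.getLogger(__name__)


def scale_cells(m: ExpressionMatrix, total: float = 100_000.0) -> ExpressionMatrix:
    """Scale every cell's total expression to ``total``.

    Applied to the log2(x+1) matrix so that per-cell sums are directly
    comparable before baseline subtraction. All-zero cells cannot be
    scaled and are left untouched (logged).
    """
    m.require_state("log2p1")
    sums = m.values.sum(axis=0)
    zero = sums == 0
    if zero.any():
        logger.warning("scale_cells: %d all-zero cells left unscaled", int(zero.sum()))
    factors = pd.Series(np.where(zero, 1.0, total / sums.replace(0, np.nan)), index=m.cells)
    return m.evolve(m.values.mul(factors.fillna(1.0), axis=1), "cell_scaled", "scale_cells")


def order_filter_genes(
    m: ExpressionMatrix,
    annotation: GeneAnnotation,
    min_mean: float = 0.15,
) -> tuple[ExpressionMatrix, GeneAnnotation]:
    """Sort genes genomically and drop unannotated or weakly expressed ones.

    Genes absent from the annotation are dropped (logged); remaining
    genes are sorted by (chromosome, start); genes whose mean expression
    across all cells is below ``min_mean`` are removed (a gene at
    exactly ``min_mean`` is kept).
    """
    m.require_state("cell_scaled", "log2p1")
    annotated = [g for g in m.genes if g in annotation]
    n_drop = len(m.genes) - len(annotated)
    if n_drop:
        logger.info("order_filter_genes: dropped %d unannotated genes", n_drop)
    sub_ann = annotation.table.loc[annotated]
    order = (
        sub_ann.assign(_ck=sub_ann["chromosome"].map(chromosome_sort_key))
        .sort_values(["_ck", "chromosome", "start", "gene"], kind="mergesort")["gene"]
        .tolist()
    )
    values = m.values.loc[order]
    keep = values.mean(axis=1) >= min_mean
    values = values.loc[keep]
    if values.shape[0] == 0:
        raise EmptyInputError("no genes survive annotation + mean-expression filtering")
    kept_ann = GeneAnnotation(
        annotation.table.loc[values.index, ["chromosome", "start", "end", "gene"]].reset_index(
            drop=True
        )
    )
    out = m.evolve(values, m.state, "order_filter_genes")
    return out, kept_ann


@dataclass
class RelativeExpressionMatrix:
    """Baseline-normalized, clipped expression in genomic gene order."""

    values: pd.DataFrame  # genes x cells
    annotation: GeneAnnotation
    clip: float = 3.0

    @property
    def cells(self) -> pd.Index:
        return self.values.columns


def relative_to_baseline(
    m: ExpressionMatrix,
    annotation: GeneAnnotation,
    baseline_cells,
    clip: float = 3.0,
) -> RelativeExpressionMatrix:
    """Subtract the baseline population's per-gene mean; clip to ±clip.

    The baseline cells define copy-number-neutral expression; they must
    be present in the matrix and have passed through the same scaling.
    """
    baseline_cells = list(baseline_cells)
    if not baseline_cells:
        raise EmptyInputError("baseline cell set is empty")
    missing = [c for c in baseline_cells if c not in m.values.columns]
    if missing:
        raise KeyError(f"baseline cells missing from matrix: {missing[:5]}")
    baseline_mean = m.values[baseline_cells].mean(axis=1)
    rel = m.values.sub(baseline_mean, axis=0).clip(lower=-clip, upper=clip)
    return RelativeExpressionMatrix(rel, annotation, clip=clip)


@dataclass
class CNAProfileMatrix:
    """Smoothed, per-cell-centered log2 copy-number ratios.

    ``windows`` maps each profile row to its chromosome and the gene
    span it averages (first/last gene id and per-chromosome indices).
    """

    values: pd.DataFrame  # windows x cells
    windows: pd.DataFrame  # window_id, chromosome, start_index, end_index, start_gene, end_gene

    @property
    def cells(self) -> pd.Index:
        return self.values.columns


def moving_average(r: RelativeExpressionMatrix, window: int = 50) -> CNAProfileMatrix:
    """Sliding mean over runs of adjacent genes, then per-cell centering.

    Within each chromosome, every run of ``window`` consecutive genes
    (stride 1) contributes one profile row; windows never cross
    chromosome boundaries, and a chromosome with fewer genes than the
    window contributes its single whole-chromosome mean. Each cell's
    profile is then centered by subtracting its own mean.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    ann = r.annotation.table
    chroms = ann["chromosome"].values
    rows = []
    meta = []
    values = r.values.values
    gene_ids = r.values.index.to_numpy()
    # annotation rows are aligned with matrix rows by construction
    start = 0
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        block = values[idx]
        n = len(idx)
        w = min(window, n)
        # cumulative-sum sliding means: one row per full window
        cs = np.vstack([np.zeros((1, block.shape[1])), np.cumsum(block, axis=0)])
        means = (cs[w:] - cs[:-w]) / w
        for j in range(means.shape[0]):
            meta.append(
                (
                    f"{chrom}:{j}",
                    chrom,
                    j,
                    j + w,
                    gene_ids[idx[j]],
                    gene_ids[idx[j + w - 1]],
                )
            )
        rows.append(means)
        start += n
    profile = np.vstack(rows)
    windows = pd.DataFrame(
        meta,
        columns=["window_id", "chromosome", "start_index", "end_index", "start_gene", "end_gene"],
    )
    df = pd.DataFrame(profile, index=windows["window_id"].values, columns=r.values.columns)
    centered = df.sub(df.mean(axis=0), axis=1)
    return CNAProfileMatrix(centered, windows)


@dataclass
class PloidyCall:
    """Per-cell diploid/aneuploid labels from profile clustering."""

    labels: pd.Series  # cell -> "diploid" | "aneuploid"
    clusters: pd.Series  # cell -> cluster id (1 or 2)
    linkage_method: str = "ward"
    distance_metric: str = "euclidean"

    def aneuploid_cells(self) -> list:
        return self.labels.index[self.labels == "aneuploid"].tolist()

    def diploid_cells(self) -> list:
        return self.labels.index[self.labels == "diploid"].tolist()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.labels.index, "ploidy": self.labels.values,
                             "cluster": self.clusters.values})


def call_ploidy(p: CNAProfileMatrix, baseline_cells, refine: bool = True) -> PloidyCall:
    """Separate diploid from aneuploid cells by hierarchical clustering.

    All cells (sample + baseline) are clustered on their smoothed
    profiles with Ward linkage on Euclidean distances; the dendrogram is
    cut into two groups and the group containing the majority of
    baseline cells is labeled diploid. If no structure exists (all
    profiles identical) every cell is labeled diploid. An exact 50/50
    baseline split cannot be resolved and raises :class:`TieError`.

    With ``refine`` (the default) the two groups are polished by
    reassigning each cell to the nearer group mean profile until
    convergence. The dendrogram cut fixes the two groups; the
    refinement corrects cells stranded in the wrong branch by greedy
    merge order, which otherwise contaminates the diploid group with
    borderline aneuploid profiles.
    """
    baseline_cells = [c for c in baseline_cells]
    if not baseline_cells:
        raise EmptyInputError("baseline cell set is empty")
    missing = [c for c in baseline_cells if c not in p.values.columns]
    if missing:
        raise KeyError(f"baseline cells missing from profiles: {missing[:5]}")
    X = p.values.values.T  # cells as observations
    cells = p.values.columns
    if np.allclose(X, X[0], atol=1e-12):
        labels = pd.Series("diploid", index=cells)
        return PloidyCall(labels=labels, clusters=pd.Series(1, index=cells))
    Z = linkage(X, method="ward", metric="euclidean")
    clusters = pd.Series(fcluster(Z, t=2, criterion="maxclust"), index=cells)
    if clusters.nunique() == 1:
        labels = pd.Series("diploid", index=cells)
        return PloidyCall(labels=labels, clusters=clusters)
    if refine:
        lab = clusters.values.copy()
        for _ in range(100):
            m1 = X[lab == 1].mean(axis=0)
            m2 = X[lab == 2].mean(axis=0)
            d1 = np.linalg.norm(X - m1, axis=1)
            d2 = np.linalg.norm(X - m2, axis=1)
            new = np.where(d1 <= d2, 1, 2)
            if len(np.unique(new)) < 2:  # refusal to empty a group
                break
            if (new == lab).all():
                break
            lab = new
        clusters = pd.Series(lab, index=cells)
    counts = clusters.loc[baseline_cells].value_counts()
    top = counts.index[0]
    if len(counts) == 2 and counts.iloc[0] == counts.iloc[1]:
        raise TieError(
            "baseline cells split evenly between the two clusters; "
            "supply a larger or cleaner diploid baseline"
        )
    labels = clusters.map(lambda c: "diploid" if c == top else "aneuploid")
    sizes = clusters.value_counts()
    if (sizes == 0).any():
        raise RuntimeError("dendrogram cut produced an empty group")
    logger.info(
        "call_ploidy: %d diploid, %d aneuploid",
        int((labels == "diploid").sum()),
        int((labels == "aneuploid").sum()),
    )
    return PloidyCall(labels=labels, clusters=clusters)


def purity(call: PloidyCall, sample_cells) -> float:
    """Percent of the given cells called aneuploid (tumor purity)."""
    sample_cells = list(sample_cells)
    if not sample_cells:
        raise EmptyInputError("sample cell set is empty")
    missing = [c for c in sample_cells if c not in call.labels.index]
    if missing:
        raise KeyError(f"sample cells without a ploidy call: {missing[:5]}")
    aneu = (call.labels.loc[sample_cells] == "aneuploid").sum()
    return 100.0 * aneu / len(sample_cells)


def run_cna_pipeline(
    m: ExpressionMatrix,
    annotation: GeneAnnotation,
    baseline_cells,
    window: int = 50,
    clip: float = 3.0,
    min_mean: float = 0.15,
    scale_total: float = 100_000.0,
) -> tuple[CNAProfileMatrix, PloidyCall]:
    """Scale → order/filter → baseline-normalize → smooth → call ploidy."""
    scaled = scale_cells(m, total=scale_total)
    ordered, kept_ann = order_filter_genes(scaled, annotation, min_mean=min_mean)
    rel = relative_to_baseline(ordered, kept_ann, baseline_cells, clip=clip)
    profile = moving_average(rel, window=window)
    call = call_ploidy(profile, baseline_cells)
    return profile, call
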