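"""Normalization and quality-control filtering of expression matrices.

Gene filtering keeps a gene only when it reaches a minimum count in a
minimum number of cells (defaults 10 and 30); cell filtering keeps
wells with enough detected genes and molecules. Both are idempotent and
order-independent. Transforms track the matrix normalization state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from snrs.errors import StateError
from snrs.matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class FilterThresholds:
    """Cell- and gene-level QC thresholds.

    The gene rule removes genes unless they reach ``gene_min_count`` in
    at least ``gene_min_cells`` cells. Cell defaults sit well below
    typical per-nucleus yields (thousands of genes detected) and are
    meant to drop empty or failed wells, not to be tight.
    """

    min_genes_per_cell: int = 500
    min_umis_per_cell: int = 1000
    gene_min_count: int = 10
    gene_min_cells: int = 30

    def __post_init__(self) -> None:
        for name in (
            "min_genes_per_cell",
            "min_umis_per_cell",
            "gene_min_count",
            "gene_min_cells",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) transform of a counts or TPM matrix."""
    m.require_state("counts", "tpm")
    return m.evolve(np.log2(m.values + 1.0), "log2p1", "log_transform")


def filter_genes(m: ExpressionMatrix, t: FilterThresholds | None = None) -> ExpressionMatrix:
    """Keep genes with count >= gene_min_count in >= gene_min_cells cells."""
    m.require_state("counts")
    t = t or FilterThresholds()
    if m.values.size == 0:
        logger.warning("filter_genes: empty matrix")
        return m.evolve(m.values.copy(), m.state, "filter_genes")
    n_cells_with = (m.values >= t.gene_min_count).sum(axis=1)
    keep = n_cells_with >= t.gene_min_cells
    logger.info("filter_genes: kept %d / %d genes", int(keep.sum()), len(keep))
    return m.evolve(m.values.loc[keep], m.state, "filter_genes")


def filter_cells(metrics: pd.DataFrame, t: FilterThresholds | None = None) -> list:
    """Return the wells passing the per-cell QC thresholds.

    ``metrics`` is the per-well table from ``compute_metrics`` (or any
    frame with ``genes_detected`` and ``distinct_umis`` columns).
    """
    t = t or FilterThresholds()
    keep = (metrics["genes_detected"] >= t.min_genes_per_cell) & (
        metrics["distinct_umis"] >= t.min_umis_per_cell
    )
    return metrics.index[keep].tolist()


def metrics_from_counts(m: ExpressionMatrix) -> pd.DataFrame:
    """Derive per-cell metrics directly from a counts matrix.

    Used when the pipeline starts from a matrix rather than reads; the
    molecule total stands in for distinct UMIs.
    """
    m.require_state("counts")
    return pd.DataFrame(
        {
            "total_reads": m.values.sum(axis=0).astype(int),
            "assigned_reads": m.values.sum(axis=0).astype(int),
            "distinct_umis": m.values.sum(axis=0).astype(int),
            "genes_detected": (m.values > 0).sum(axis=0).astype(int),
        },
        index=m.cells,
    )


def zscore(m: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each gene to mean 0, SD 1 (population SD, /n).

    Genes with zero variance carry no contrast and are dropped with a
    warning.
    """
    m.require_state("log2p1")
    mu = m.values.mean(axis=1)
    sd = m.values.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        logger.warning("zscore: dropping %d constant genes", int(constant.sum()))
    values = m.values.loc[~constant]
    z = values.sub(mu[~constant], axis=0).div(sd[~constant], axis=0)
    return m.evolve(z, "zscore", "zscore")


def tpm_from_counts(m: ExpressionMatrix, gene_lengths: pd.Series) -> ExpressionMatrix:
    """Convert counts to transcripts-per-million given gene lengths (bp).

    Provided as a convenience; quantifier-produced TPM can be supplied
    directly instead.
    """
    m.require_state("counts")
    lengths = gene_lengths.reindex(m.genes)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:5]
        raise ValueError(f"genes without length: {missing}")
    rate = m.values.div(lengths / 1_000.0, axis=0)
    tpm = rate.div(rate.sum(axis=0), axis=1) * 1e6
    return m.evolve(tpm.fillna(0.0), "tpm", "tpm_from_counts")


def invert_log_transform(m: ExpressionMatrix) -> pd.DataFrame:
    """Inverse of :func:`log_transform` (for round-trip checks)."""
    if m.state != "log2p1":
        raise StateError("inverse requires a log2p1 matrix")
    return 2.0**m.values - 1.0
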