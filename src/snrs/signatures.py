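"""Gene-set scoring, cell-cycle phase assignment, centroid subtyping.

A gene-set score is the per-cell mean log2(TPM+1) expression over the
set's genes present in the matrix. Cell-cycle phases are called by
hierarchically clustering cells on centered G1/S/G2/M scores and
labeling each cluster by its dominant (positive) mean score; clusters
with no positive program are left unassigned (G0-like). Subtype calls
are nearest-centroid with a rank-correlation confidence: cells whose
best Spearman correlation to any centroid falls below the threshold
(default 0.7) are set to "undefined".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import rankdata

from snrs.errors import EmptyInputError
from snrs.matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

PHASE_COLUMNS = ("G1", "S", "G2", "M")
UNASSIGNED = "G0/unassigned"


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name, description, members (tab-separated)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, _desc, *members = fields
        members = [g for g in members if g]
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        sets[name] = list(dict.fromkeys(members))
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    lines = [f"{name}\t{description}\t" + "\t".join(genes) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def score_gene_set(m: ExpressionMatrix, genes, name: str = "set") -> pd.Series:
    """Mean expression of the set's genes per cell.

    Genes absent from the matrix are dropped with a warning; an entirely
    absent set is an error naming the set.
    """
    m.require_state("log2p1")
    genes = list(dict.fromkeys(genes))
    present = [g for g in genes if g in m.values.index]
    if not present:
        raise EmptyInputError(f"no genes of set {name!r} present in the matrix")
    if len(present) < len(genes):
        logger.warning(
            "score_gene_set(%s): %d of %d genes absent", name, len(genes) - len(present), len(genes)
        )
    return m.values.loc[present].mean(axis=0).rename(name)


def score_phases(m: ExpressionMatrix, phase_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Score the four cell-cycle programs; returns a cell x phase table."""
    missing = [p for p in PHASE_COLUMNS if p not in phase_sets]
    if missing:
        raise ValueError(f"phase sets missing: {missing}")
    return pd.DataFrame({p: score_gene_set(m, phase_sets[p], name=p) for p in PHASE_COLUMNS})


def assign_phases(scores: pd.DataFrame, n_clusters: int = 5) -> pd.DataFrame:
    """Assign a cell-cycle phase per cell from its four phase scores.

    Scores are centered per phase (column mean over cells subtracted),
    cells are Ward/Euclidean clustered into ``n_clusters`` groups, and
    each group takes the phase with the largest positive mean centered
    score; groups with no positive program are ``G0/unassigned``
    (nuclei with an absence of cycling scores).
    """
    missing = [p for p in PHASE_COLUMNS if p not in scores.columns]
    if missing:
        raise ValueError(f"score table missing phase columns: {missing}")
    if len(scores) < n_clusters:
        raise ValueError(f"{len(scores)} cells < {n_clusters} requested clusters")
    centered = scores[list(PHASE_COLUMNS)] - scores[list(PHASE_COLUMNS)].mean(axis=0)
    X = centered.values
    if np.allclose(X, X[0], atol=1e-12):
        clusters = pd.Series(1, index=scores.index)
    else:
        Z = linkage(X, method="ward", metric="euclidean")
        clusters = pd.Series(fcluster(Z, t=n_clusters, criterion="maxclust"), index=scores.index)
    out = scores.copy()
    out["cluster"] = clusters
    phase = pd.Series(UNASSIGNED, index=scores.index, dtype=object)
    for cid, members in clusters.groupby(clusters).groups.items():
        mean_scores = centered.loc[members].mean(axis=0)
        if (mean_scores > 0).any():
            phase.loc[members] = mean_scores.idxmax()
    out["phase"] = phase
    return out


@dataclass
class SubtypeCall:
    """Nearest-centroid subtype calls with per-cell confidence."""

    table: pd.DataFrame  # cell_id index; best_subtype, confidence, label
    threshold: float

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]


def _spearman_matrix(cells: pd.DataFrame, centroids: pd.DataFrame) -> np.ndarray:
    """Spearman correlation of every cell (column) with every centroid."""
    rc = np.apply_along_axis(rankdata, 0, cells.values)
    rk = np.apply_along_axis(rankdata, 0, centroids.values)

    def _standardize(a: np.ndarray) -> np.ndarray:
        z = a - a.mean(axis=0)
        sd = z.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sd > 0, z / sd, np.nan)

    zc, zk = _standardize(rc), _standardize(rk)
    return (zc.T @ zk) / cells.shape[0]


def classify_centroid(
    m: ExpressionMatrix,
    centroids: pd.DataFrame,
    threshold: float = 0.7,
) -> SubtypeCall:
    """Classify cells against subtype centroids by rank correlation.

    ``centroids`` is a gene x subtype table. Confidence is the Spearman
    correlation between the cell's expression and each centroid over the
    shared genes; the best subtype is the argmax (ties broken by subtype
    name order) and cells whose best confidence is below ``threshold``
    are labeled ``undefined``. Rank correlation makes labels invariant
    to any strictly monotone transform of the cell's expression.
    """
    if centroids.shape[1] < 2:
        raise ValueError("need at least 2 subtype centroids")
    shared = [g for g in m.values.index if g in centroids.index]
    if not shared:
        raise EmptyInputError("no genes shared between matrix and centroids")
    if len(shared) < 10:
        logger.warning("classify_centroid: only %d shared genes", len(shared))
    centroids = centroids.loc[shared, sorted(centroids.columns)]
    cells = m.values.loc[shared]
    corr = _spearman_matrix(cells, centroids)

    subtype_names = np.array(centroids.columns)
    best_idx = np.nanargmax(np.where(np.isnan(corr), -np.inf, corr), axis=1)
    confidence = corr[np.arange(len(best_idx)), best_idx]
    best = subtype_names[best_idx]
    undefined = np.isnan(confidence) | (confidence < threshold)
    labels = np.where(undefined, "undefined", best)
    table = pd.DataFrame(
        {"best_subtype": best, "confidence": confidence, "label": labels},
        index=cells.columns,
    ).rename_axis("cell_id")
    return SubtypeCall(table=table, threshold=threshold)


def exclude_er_positive(
    m: ExpressionMatrix, marker_gene: str, cutoff: float = 1.0
) -> ExpressionMatrix:
    """Optional pre-filter removing cells expressing an ER marker gene.

    Intended for TNBC subtyping, where hormone-receptor-positive cells
    are excluded first; the marker gene (e.g. ESR1) is caller-supplied.
    """
    if marker_gene not in m.values.index:
        raise KeyError(f"marker gene {marker_gene!r} not in matrix")
    keep = m.values.loc[marker_gene] < cutoff
    return m.evolve(m.values.loc[:, keep], m.state, f"exclude_er_positive({marker_gene})")
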