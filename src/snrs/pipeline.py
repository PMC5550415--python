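"""End-to-end orchestration: scenarios, stage running, run manifest.

A single run executes simulate → (demux → count, when the scenario is
read-level) → qc → cna → cycle → classify → cluster → markers, writing
every stage output as delimited text plus a JSON manifest recording the
config snapshot, seeds, file digests, timings and tallies. Stages can
be resumed from prior outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from snrs import __version__
from snrs.cna import run_cna_pipeline, purity
from snrs.demux import compute_metrics, count_umis, demultiplex, read_gene_table
from snrs.errors import ConfigError
from snrs.matrix import ExpressionMatrix
from snrs.qc import FilterThresholds, filter_cells, filter_genes, log_transform, metrics_from_counts, zscore
from snrs.signatures import (
    assign_phases,
    classify_centroid,
    score_phases,
    write_gmt,
)
from snrs.simulate import (
    GroundTruth,
    PlantedSegment,
    SimulationConfig,
    simulate_dispense,
    simulate_expression,
    simulate_reads,
    write_whitelist,
)
from snrs.subpop import find_markers, pca_select_genes, snn_cluster

logger = logging.getLogger(__name__)


def tnbc_default_config(seed: int = 0) -> SimulationConfig:
    """The default triple-negative tumor scenario.

    Emulates the study composition: 380 normal baseline nuclei plus 502
    selected tumor-sample nuclei — 5 diploid stromal cells and 497
    aneuploid tumor cells split over three subpopulations at the
    reported 52.2/29.1/18.8% proportions (259/145/93). Arm-level
    copy-number events at |log2 ratio| = 0.5 are planted on the
    chromosomes reported for the tumor (1q and 19q gains; 1p, 3, 4,
    11p, 12q, 17p and 22 losses), each subpopulation carries ten
    4-fold marker genes, and cell-cycle phases are drawn so that
    18.75% of cells are in G2 or M.
    """
    genes_per_chrom = 150
    half = genes_per_chrom // 2
    layout = tuple((f"chr{i}", genes_per_chrom) for i in range(1, 23))
    subs = ("A", "B", "C")
    segments = (
        PlantedSegment("chr1", 0, half, -0.5, subs),  # 1p loss
        PlantedSegment("chr1", half, genes_per_chrom, +0.5, subs),  # 1q gain
        PlantedSegment("chr3", 0, genes_per_chrom, -0.5, subs),
        PlantedSegment("chr4", 0, genes_per_chrom, -0.5, subs),
        PlantedSegment("chr11", 0, half, -0.5, subs),  # 11p loss
        PlantedSegment("chr12", half, genes_per_chrom, -0.5, subs),  # 12q loss
        PlantedSegment("chr17", 0, half, -0.5, subs),  # 17p loss
        PlantedSegment("chr19", half, genes_per_chrom, +0.5, subs),  # 19q gain
        PlantedSegment("chr22", 0, genes_per_chrom, -0.5, subs),
    )
    # marker blocks on chr5 (no planted segments there)
    markers = {
        "A": tuple(f"chr5_g{i:04d}" for i in range(0, 10)),
        "B": tuple(f"chr5_g{i:04d}" for i in range(10, 20)),
        "C": tuple(f"chr5_g{i:04d}" for i in range(20, 30)),
    }
    return SimulationConfig(
        chromosome_layout=layout,
        n_normal_cells=380,
        stromal_count=5,
        tumor_composition=(
            ("A", 259, markers["A"]),
            ("B", 145, markers["B"]),
            ("C", 93, markers["C"]),
        ),
        cna_segments=segments,
        seed=seed,
    )


def mini_config(seed: int = 0) -> SimulationConfig:
    """A small read-level scenario exercising demux and UMI counting."""
    layout = (("chr1", 60), ("chr2", 60))
    return SimulationConfig(
        n_wells=200,
        chromosome_layout=layout,
        n_normal_cells=30,
        stromal_count=2,
        tumor_composition=(("A", 20, tuple(f"chr2_g{i:04d}" for i in range(5))),),
        cna_segments=(PlantedSegment("chr1", 0, 60, 0.5, ("A",)),),
        genes_per_phase_set=5,
        duplication_rate=0.2,
        seed=seed,
    )


SCENARIOS = {"tnbc-default": tnbc_default_config, "mini": mini_config}

#: Scenarios whose cells are too shallow for the default QC thresholds.
_SCENARIO_QC = {
    "mini": FilterThresholds(
        min_genes_per_cell=5, min_umis_per_cell=10, gene_min_count=1, gene_min_cells=3
    )
}

#: Scenarios small enough to simulate reads for.
_READ_LEVEL = {"mini"}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Accumulates per-stage records for a pipeline run."""

    def __init__(self, config: dict, seed: int):
        self.data = {
            "version": __version__,
            "seed": seed,
            "config": config,
            "stages": {},
        }

    def record(self, stage: str, elapsed: float, outputs: list[Path], **tallies) -> None:
        self.data["stages"][stage] = {
            "elapsed_s": round(elapsed, 3),
            "outputs": {p.name: _sha256(p) for p in outputs},
            **tallies,
        }

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.data, indent=2, default=str) + "\n")


def build_centroids_from_truth(
    logm: ExpressionMatrix, truth: GroundTruth, extra_top_variable: int = 100
) -> pd.DataFrame:
    """Reference centroids from planted subpopulation mean profiles.

    Synthetic stand-in for a user-supplied centroid table (real analyses
    load published subtype centroids instead): the mean log expression
    per subpopulation over the planted marker genes plus the most
    variable genes.
    """
    subs = sorted(set(truth.cells["subpopulation"]) - {"normal", "stromal"})
    marker_genes = truth.genes.loc[truth.genes["marker_of"] != "", "gene"].tolist()
    variances = logm.values.var(axis=1).sort_values(ascending=False)
    top = variances.index[:extra_top_variable].tolist()
    genes = [g for g in logm.values.index if g in set(marker_genes) | set(top)]
    cols = {}
    for sub in subs:
        members = truth.cells.loc[truth.cells["subpopulation"] == sub, "cell_id"]
        cols[sub] = logm.values.loc[genes, members].mean(axis=1)
    return pd.DataFrame(cols)


def run_pipeline(
    scenario: str = "tnbc-default",
    out_dir: str | Path = "snrs_run",
    seed: int = 0,
    resume: bool = False,
    qc_thresholds: FilterThresholds | None = None,
    window: int = 50,
    n_pcs: int = 5,
    top_loadings: int = 20,
    k: int = 20,
    resolution: float = 1.0,
    min_lfc: float = 1.0,
    alpha: float = 0.05,
) -> RunManifest:
    """Run every stage on a named synthetic scenario; write all outputs."""
    if scenario not in SCENARIOS:
        raise ConfigError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = SCENARIOS[scenario](seed=seed)
    qc_t = qc_thresholds or _SCENARIO_QC.get(scenario, FilterThresholds())
    manifest = RunManifest({"scenario": scenario, **dataclasses.asdict(config)}, seed)

    # -- simulate ----------------------------------------------------------
    t0 = time.perf_counter()
    wells = simulate_dispense(config)
    expr, truth = simulate_expression(config)
    counts_path = out / "counts.tsv"
    if not (resume and counts_path.exists()):
        wells.to_csv(out / "wells.csv", index=False)
        expr.to_tsv(counts_path)
        truth.write(out)
        truth.annotation().to_bed(out / "genes.bed")
        write_whitelist(config, out / "whitelist.txt")
        write_gmt(truth.cycle_sets(), out / "cycle_sets.gmt")
    manifest.record(
        "simulate",
        time.perf_counter() - t0,
        [counts_path, out / "wells.csv", out / "truth_cells.csv", out / "genes.bed"],
        n_cells=int(expr.shape[1]),
        n_genes=int(expr.shape[0]),
        single_occupancy_wells=int(wells["selected"].sum()),
    )

    # -- demux + count (read-level scenarios only) -------------------------
    if scenario in _READ_LEVEL:
        t0 = time.perf_counter()
        reads = simulate_reads(truth, expr, config, out)
        demux = demultiplex(
            reads.r1_path,
            reads.r2_path,
            whitelist=truth.cells["barcode"].tolist(),
            barcode_length=config.barcode_length,
            umi_length=config.umi_length,
        )
        gene_tbl = read_gene_table(reads.read_gene_path)
        barcode_to_cell = dict(zip(truth.cells["barcode"], truth.cells["cell_id"]))
        counts = count_umis(
            demux, gene_tbl, genes=list(expr.genes), wells=truth.cells["barcode"].tolist()
        )
        metrics = compute_metrics(demux, counts, gene_tbl)
        metrics.to_csv(out / "metrics.csv")
        # continue downstream from the demultiplexed counts, by cell id
        expr = ExpressionMatrix(
            counts.values.rename(columns=barcode_to_cell).astype(float),
            state="counts",
            history=["demux_count"],
        )
        manifest.record(
            "demux_count",
            time.perf_counter() - t0,
            [out / "metrics.csv"],
            **demux.tallies,
            n_molecules=reads.n_molecules,
        )
    else:
        metrics = metrics_from_counts(expr)
        metrics.index = expr.cells
        metrics.to_csv(out / "metrics.csv")

    # -- qc ----------------------------------------------------------------
    t0 = time.perf_counter()
    filtered = filter_genes(expr, qc_t)
    kept_cells = filter_cells(metrics.set_axis(expr.cells, axis=0), qc_t)
    filtered = filtered.evolve(filtered.values[kept_cells], filtered.state, "filter_cells")
    filtered.to_tsv(out / "qc_counts.tsv")
    logm = log_transform(filtered)
    manifest.record(
        "qc",
        time.perf_counter() - t0,
        [out / "qc_counts.tsv"],
        genes_kept=int(filtered.shape[0]),
        cells_kept=len(kept_cells),
    )

    # -- cna ---------------------------------------------------------------
    t0 = time.perf_counter()
    annotation = truth.annotation()
    logm_all = log_transform(expr)  # CNA runs on all cells, unfiltered genes
    baseline = truth.baseline_cells()
    profile, ploidy = run_cna_pipeline(logm_all, annotation, baseline, window=window)
    profile.values.to_csv(out / "cna_profiles.tsv", sep="\t", index_label="window")
    ploidy.to_frame().to_csv(out / "ploidy.csv", index=False)
    sample = truth.sample_cells()
    sample_purity = purity(ploidy, sample)
    manifest.record(
        "cna",
        time.perf_counter() - t0,
        [out / "cna_profiles.tsv", out / "ploidy.csv"],
        purity_percent=round(sample_purity, 2),
        diploid_in_sample=int((ploidy.labels.loc[sample] == "diploid").sum()),
    )

    # -- cycle -------------------------------------------------------------
    # phase programs are scored on the full gene universe (cell-filtered
    # only): the QC gene filter keeps high-count genes and would thin the
    # cycle sets themselves
    t0 = time.perf_counter()
    logm_kept = logm_all.evolve(logm_all.values[kept_cells], "log2p1", "filter_cells")
    scores = score_phases(logm_kept, truth.cycle_sets())
    phases = assign_phases(scores)
    phases.to_csv(out / "phases.csv", index_label="cell_id")
    manifest.record("cycle", time.perf_counter() - t0, [out / "phases.csv"])

    # -- classify ----------------------------------------------------------
    t0 = time.perf_counter()
    centroids = build_centroids_from_truth(logm, truth)
    if centroids.shape[1] >= 2:
        centroids.to_csv(out / "centroids.tsv", sep="\t", index_label="gene")
        calls = classify_centroid(logm, centroids)
        calls.table.to_csv(out / "subtypes.csv")
        manifest.record("classify", time.perf_counter() - t0, [out / "subtypes.csv"])
    else:
        logger.warning("fewer than 2 subpopulations; classify stage skipped")

    # -- cluster + markers (aneuploid cells only) --------------------------
    t0 = time.perf_counter()
    aneuploid = [c for c in logm.cells if ploidy.labels.get(c) == "aneuploid"]
    if len(aneuploid) > k:
        sub = logm.evolve(logm.values[aneuploid], logm.state, "subset_aneuploid")
        z = zscore(sub)
        genes_sel, embedding = pca_select_genes(z, n_pcs=n_pcs, top_loadings=top_loadings)
        zsel = z.evolve(z.values.loc[genes_sel], "zscore", "select_genes")
        assignment = snn_cluster(zsel.values.T, k=k, resolution=resolution, seed=seed)
        assignment.labels.to_csv(out / "clusters.csv", index_label="cell_id")
        counts_sub = filtered.evolve(
            filtered.values.loc[:, [c for c in filtered.cells if c in set(aneuploid)]],
            "counts",
            "subset_aneuploid",
        )
        markers = find_markers(counts_sub, assignment, min_lfc=min_lfc, alpha=alpha)
        markers.to_csv(out / "markers.csv", index=False)
        manifest.record(
            "cluster_markers",
            time.perf_counter() - t0,
            [out / "clusters.csv", out / "markers.csv"],
            n_clusters=int(assignment.labels.nunique()),
            modularity=round(assignment.modularity, 4),
            n_markers=int(markers["marker"].sum()),
        )
    else:
        logger.warning("too few aneuploid cells for clustering; stage skipped")

    manifest.write(out / "manifest.json")
    return manifest


def load_yaml_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}
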