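"""Demultiplexing of barcoded reads, UMI deduplication, per-well metrics.

Read 1 carries the cell identity: the first 11 nt are the well barcode
and the next 10 nt the UMI, both parsed positionally. Assignment is by
exact whitelist match by default; an optional 1-mismatch correction can
rescue barcodes with a unique Hamming-1 neighbor on the whitelist
(ambiguous corrections are rejected). UMI collapse is by exact sequence
identity: the count of a gene in a well is the number of distinct UMIs
observed among that gene's reads in that well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from snrs.matrix import CountMatrix
from snrs.simulate import _open_maybe_gz

logger = logging.getLogger(__name__)

_ALPHABET = "ACGT"


def read_whitelist(path) -> list[str]:
    """Load a one-barcode-per-line whitelist, validating length/uniqueness."""
    barcodes = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    lengths = {len(b) for b in barcodes}
    if len(lengths) > 1:
        raise ValueError(f"whitelist barcodes have mixed lengths: {sorted(lengths)}")
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in whitelist")
    return barcodes


@dataclass
class DemuxResult:
    """Per-read well assignments plus conservation tallies.

    ``assignments`` has one row per assigned read: read_id, barcode, umi.
    total == assigned + unassigned + rejected always holds.
    """

    assignments: pd.DataFrame
    total: int
    assigned: int
    unassigned: int
    rejected: int
    tallies: dict = field(default_factory=dict)


def _hamming1_neighbors(barcode: str):
    for i, b in enumerate(barcode):
        for alt in _ALPHABET:
            if alt != b:
                yield barcode[:i] + alt + barcode[i + 1 :]


def demultiplex(
    fastq_r1,
    fastq_r2=None,
    whitelist: list[str] | None = None,
    barcode_length: int = 11,
    umi_length: int = 10,
    correct_one_mismatch: bool = False,
) -> DemuxResult:
    """Assign reads to wells by well barcode; parse UMIs.

    Reads shorter than barcode+UMI and reads whose UMI contains ``N``
    are rejected (undefined molecule identity). Reads whose barcode is
    not on the whitelist go to the unassigned pool; with
    ``correct_one_mismatch`` a barcode with exactly one Hamming-1
    whitelist neighbor is rescued, while ambiguous ones stay unassigned.
    Read 2 is accepted for interface symmetry but carries no identity.
    """
    if whitelist is None:
        raise ValueError("a barcode whitelist is required")
    wl = set(whitelist)
    min_len = barcode_length + umi_length

    rows = []
    total = unassigned = rejected = 0
    with _open_maybe_gz(fastq_r1, "rt") as handle:
        for title, seq, _qual in FastqGeneralIterator(handle):
            total += 1
            if len(seq) < min_len:
                rejected += 1
                continue
            barcode = seq[:barcode_length]
            umi = seq[barcode_length:min_len]
            if "N" in umi:
                rejected += 1
                continue
            if barcode not in wl:
                if correct_one_mismatch:
                    hits = [n for n in _hamming1_neighbors(barcode) if n in wl]
                    if len(hits) == 1:
                        barcode = hits[0]
                    else:
                        unassigned += 1
                        continue
                else:
                    unassigned += 1
                    continue
            rows.append((title.split()[0], barcode, umi))

    assignments = pd.DataFrame(rows, columns=["read_id", "barcode", "umi"])
    assigned = len(assignments)
    logger.info(
        "demultiplex: %d total, %d assigned, %d unassigned, %d rejected",
        total, assigned, unassigned, rejected,
    )
    return DemuxResult(
        assignments=assignments,
        total=total,
        assigned=assigned,
        unassigned=unassigned,
        rejected=rejected,
        tallies={
            "total": total,
            "assigned": assigned,
            "unassigned": unassigned,
            "rejected": rejected,
        },
    )


def read_gene_table(path) -> pd.DataFrame:
    """Load the read-to-gene sidecar table (read_id, gene)."""
    return pd.read_csv(path, sep="\t", dtype=str)


def count_umis(
    assignments: pd.DataFrame | DemuxResult,
    gene_table: pd.DataFrame,
    genes: list[str] | None = None,
    wells: list[str] | None = None,
) -> CountMatrix:
    """Count distinct UMIs per (gene, well), dropping duplicated UMIs.

    count(g, w) is the number of distinct UMI sequences among the reads
    of gene g assigned to well w. Assigned reads without a gene label
    are excluded (and logged). Pass ``genes``/``wells`` to fix the output
    shape; otherwise observed ids define it.
    """
    if isinstance(assignments, DemuxResult):
        assignments = assignments.assignments
    merged = assignments.merge(gene_table, on="read_id", how="left")
    unlabeled = int(merged["gene"].isna().sum())
    if unlabeled:
        logger.info("count_umis: %d assigned reads without a gene label excluded", unlabeled)
        merged = merged.dropna(subset=["gene"])

    if len(merged):
        grouped = merged.groupby(["gene", "barcode"], sort=True)["umi"].nunique()
        mat = grouped.unstack(fill_value=0)
    else:
        mat = pd.DataFrame(dtype=int)
    if genes is not None:
        mat = mat.reindex(index=pd.Index(genes), fill_value=0)
    if wells is not None:
        mat = mat.reindex(columns=pd.Index(wells), fill_value=0)
    return CountMatrix(mat.fillna(0).astype(int))


def compute_metrics(
    assignments: pd.DataFrame | DemuxResult,
    counts: CountMatrix,
    gene_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-well sequencing metrics: reads, distinct UMIs, genes detected.

    ``total_reads`` counts every read assigned to the well;
    ``assigned_reads`` those that also carry a gene label (all of them
    when no gene table is given); ``distinct_umis`` the distinct UMI
    sequences in the well; ``genes_detected`` genes with count > 0.
    """
    if isinstance(assignments, DemuxResult):
        assignments = assignments.assignments
    wells = counts.wells
    per_well_reads = assignments.groupby("barcode").size().reindex(wells, fill_value=0)
    if gene_table is not None:
        labeled = assignments.merge(gene_table, on="read_id", how="left").dropna(subset=["gene"])
    else:
        labeled = assignments
    per_well_assigned = labeled.groupby("barcode").size().reindex(wells, fill_value=0)
    per_well_umis = (
        assignments.groupby("barcode")["umi"].nunique().reindex(wells, fill_value=0)
    )
    genes_detected = (counts.values > 0).sum(axis=0)
    return pd.DataFrame(
        {
            "total_reads": per_well_reads.astype(int),
            "assigned_reads": per_well_assigned.astype(int),
            "distinct_umis": per_well_umis.astype(int),
            "genes_detected": genes_detected.astype(int),
        },
        index=wells,
    ).rename_axis("barcode")
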