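"""Synthetic data generation for the nanogrid single-nucleus pipeline.

Emulates the physical and molecular layers of a nanowell single-nucleus
RNA-seq experiment so every downstream stage can be tested against
planted ground truth:

* Poisson dispensing of nuclei into a 5184-well grid at ~1 nucleus per
  50 nL dispense, with single-occupancy wells flagged as selected.
* Barcoded reads: an 11 nt well barcode plus 10 nt UMI on read 1, a
  placeholder cDNA read 2, and a sidecar read-to-gene table standing in
  for alignment (out of scope here).
* Expression: negative-binomial counts with logistic dropout at low
  expression (the zero-inflation seen in real single-nucleus data),
  planted chromosome-arm copy-number segments in aneuploid cells,
  marker-gene up-shifts per tumor subpopulation, and multiplicative
  cell-cycle phase programs.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from snrs.errors import ConfigError, GenerationError
from snrs.matrix import ExpressionMatrix, GeneAnnotation

_BASES = np.array(list("ACGT"))

PHASES = ("G1", "S", "G2", "M")

#: Default phase proportions; G2 + M together are 18.75% of cells.
DEFAULT_PHASE_PROPORTIONS = {"G1": 0.5625, "S": 0.25, "G2": 0.125, "M": 0.0625}


@dataclass
class PlantedSegment:
    """A planted copy-number event spanning a run of adjacent genes.

    ``start`` and ``end`` are gene indices within the chromosome,
    0-based half-open. ``log2_ratio`` is the planted copy-number shift
    (e.g. +0.5 for a single-copy-like gain); expression means of genes
    inside the segment are multiplied by ``2**log2_ratio`` in affected
    cells.
    """

    chromosome: str
    start: int
    end: int
    log2_ratio: float
    subpopulations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 0:
            raise ConfigError(
                f"segment on {self.chromosome}: need 0 <= start <= end, "
                f"got [{self.start}, {self.end})"
            )
        if not math.isfinite(self.log2_ratio):
            raise ConfigError("segment log2_ratio must be finite")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment.

    Defaults mirror the study conditions: a 5184-well grid loaded at
    one nucleus per dispense on average, 11 nt well barcodes, 10 nt
    UMIs, and a 380-nucleus normal baseline population.
    """

    n_wells: int = 5184
    mean_occupancy: float = 1.0
    chromosome_layout: tuple[tuple[str, int], ...] = (("chr1", 100), ("chr2", 100))
    n_normal_cells: int = 380
    stromal_count: int = 0
    #: (subpopulation id, cell count, marker gene ids)
    tumor_composition: tuple[tuple[str, int, tuple[str, ...]], ...] = ()
    cna_segments: tuple[PlantedSegment, ...] = ()
    nb_mean: float = 2.0
    nb_dispersion: float = 2.0  # NB size parameter: var = mu + mu^2 / size
    nb_mean_log_sd: float = 1.0  # lognormal spread of per-gene baseline means
    dropout_midpoint: float | None = 0.0  # log2-mean at 50% dropout; None disables
    dropout_slope: float = 1.0
    marker_effect: float = 4.0  # fold up-shift of a subpopulation's markers
    phase_effect: float = 2.0  # fold up-shift of a phase's gene set
    phase_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_PROPORTIONS)
    )
    genes_per_phase_set: int = 20
    umi_length: int = 10
    barcode_length: int = 11
    duplication_rate: float = 0.0
    read2_length: int = 50
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return sum(n for _, n in self.chromosome_layout)

    @property
    def n_cells(self) -> int:
        return (
            self.n_normal_cells
            + self.stromal_count
            + sum(n for _, n, _ in self.tumor_composition)
        )

    def validate(self) -> None:
        if self.n_wells < 1:
            raise ConfigError("n_wells must be >= 1")
        if self.mean_occupancy < 0:
            raise ConfigError("mean_occupancy (lambda) must be >= 0")
        if not (0 <= self.duplication_rate < 1):
            raise ConfigError("duplication_rate must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.nb_mean <= 0:
            raise ConfigError("nb_mean must be > 0")
        for name in ("n_normal_cells", "stromal_count", "umi_length", "barcode_length"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for _, n, _ in self.tumor_composition:
            if n < 0:
                raise ConfigError("tumor subpopulation counts must be >= 0")
        chrom_sizes = dict(self.chromosome_layout)
        if len(chrom_sizes) != len(self.chromosome_layout):
            raise ConfigError("duplicate chromosome in layout")
        for seg in self.cna_segments:
            if seg.chromosome not in chrom_sizes:
                raise ConfigError(f"segment chromosome {seg.chromosome!r} not in layout")
            if seg.end > chrom_sizes[seg.chromosome]:
                raise ConfigError(
                    f"segment [{seg.start}, {seg.end}) exceeds {seg.chromosome} "
                    f"size {chrom_sizes[seg.chromosome]}"
                )
        total = sum(self.phase_proportions.get(p, 0.0) for p in PHASES)
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ConfigError("phase proportions must sum to 1")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class GroundTruth:
    """Planted per-cell and per-gene labels from the simulator.

    cells: cell_id, barcode, sample (normal|tumor), ploidy
    (diploid|aneuploid), subpopulation, phase.
    genes: gene, chromosome, start, end, marker_of, cycle_set.
    """

    cells: pd.DataFrame
    genes: pd.DataFrame
    segments: tuple[PlantedSegment, ...] = ()

    def annotation(self) -> GeneAnnotation:
        return GeneAnnotation(
            self.genes[["chromosome", "start", "end", "gene"]].reset_index(drop=True)
        )

    def cycle_sets(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for phase in PHASES:
            members = self.genes.loc[self.genes["cycle_set"] == phase, "gene"]
            if len(members):
                out[phase] = members.tolist()
        return out

    def baseline_cells(self) -> list[str]:
        return self.cells.loc[self.cells["sample"] == "normal", "cell_id"].tolist()

    def sample_cells(self) -> list[str]:
        return self.cells.loc[self.cells["sample"] == "tumor", "cell_id"].tolist()

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        self.cells.to_csv(out / "truth_cells.csv", index=False)
        self.genes.to_csv(out / "truth_genes.csv", index=False)


def random_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """Draw *n* distinct random DNA sequences of the given length."""
    if n > 4**length:
        raise GenerationError(f"cannot draw {n} distinct {length}-mers")
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        batch = _BASES[rng.integers(0, 4, size=(n - len(out) + 16, length))]
        for row in batch:
            bc = "".join(row)
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
                if len(out) == n:
                    break
    return out


def simulate_dispense(config: SimulationConfig) -> pd.DataFrame:
    """Simulate Poisson dispensing of nuclei into the nanogrid.

    Each well's occupancy is i.i.d. Poisson(lambda); wells with exactly
    one nucleus are flagged ``selected``, mirroring the imaging step
    that excludes doublets and empty wells.

    Returns a per-well table: well_id, barcode, occupancy, selected.
    """
    config.validate()
    rng = config.rng(stream=1)
    occupancy = rng.poisson(config.mean_occupancy, size=config.n_wells)
    barcodes = random_barcodes(config.n_wells, config.barcode_length, config.rng(stream=2))
    return pd.DataFrame(
        {
            "well_id": np.arange(config.n_wells),
            "barcode": barcodes,
            "occupancy": occupancy,
            "selected": occupancy == 1,
        }
    )


def _build_genes(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for chrom, n in config.chromosome_layout:
        for i in range(n):
            rows.append((f"{chrom}_g{i:04d}", chrom, i * 10_000, i * 10_000 + 1_000))
    genes = pd.DataFrame(rows, columns=["gene", "chromosome", "start", "end"])
    genes["marker_of"] = ""
    genes["cycle_set"] = ""

    # Marker genes named in tumor_composition
    for sub, _, markers in config.tumor_composition:
        for g in markers:
            if g not in set(genes["gene"]):
                raise ConfigError(f"marker gene {g!r} not in chromosome layout")
            genes.loc[genes["gene"] == g, "marker_of"] = sub

    # Cycle sets: disjoint blocks of unassigned genes, spread over the genome
    free = genes.index[(genes["marker_of"] == "") & (genes["cycle_set"] == "")]
    need = config.genes_per_phase_set * len(PHASES)
    if need > 0 and len(free) >= need:
        picked = rng.choice(free, size=need, replace=False)
        for k, phase in enumerate(PHASES):
            block = picked[k * config.genes_per_phase_set : (k + 1) * config.genes_per_phase_set]
            genes.loc[block, "cycle_set"] = phase
    return genes


def _build_cells(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows: list[tuple[str, str, str, str]] = []
    for i in range(config.n_normal_cells):
        rows.append((f"normal_{i:04d}", "normal", "diploid", "normal"))
    for i in range(config.stromal_count):
        rows.append((f"stromal_{i:04d}", "tumor", "diploid", "stromal"))
    for sub, n, _ in config.tumor_composition:
        for i in range(n):
            rows.append((f"{sub}_{i:04d}", "tumor", "aneuploid", sub))
    cells = pd.DataFrame(rows, columns=["cell_id", "sample", "ploidy", "subpopulation"])

    props = np.array([config.phase_proportions.get(p, 0.0) for p in PHASES])
    phases = rng.choice(np.array(PHASES), size=len(cells), p=props / props.sum())
    cells["phase"] = phases

    if len(cells) > config.n_wells:
        raise ConfigError(f"{len(cells)} cells exceed {config.n_wells} wells")
    whitelist = random_barcodes(config.n_wells, config.barcode_length, config.rng(stream=2))
    slots = rng.choice(config.n_wells, size=len(cells), replace=False)
    cells["barcode"] = [whitelist[s] for s in slots]
    return cells


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a counts matrix with planted structure, plus ground truth.

    Per-gene baseline means are lognormal around ``nb_mean``. For each
    cell the mean is modulated multiplicatively by planted copy-number
    segments (``2**log2_ratio``), subpopulation marker effects, and the
    cell's cycle-phase program; counts are drawn negative-binomial and
    then zeroed by logistic dropout in log2 mean expression.
    """
    config.validate()
    rng = config.rng(stream=3)
    genes = _build_genes(config, rng)
    cells = _build_cells(config, rng)

    n_g, n_c = len(genes), len(cells)
    base = rng.lognormal(mean=math.log(config.nb_mean), sigma=config.nb_mean_log_sd, size=n_g)
    mu = np.tile(base[:, None], (1, n_c))

    # Planted copy-number segments: aneuploid subpopulations only
    gene_pos_in_chrom = genes.groupby("chromosome").cumcount().values
    for seg in config.cna_segments:
        in_seg = (
            (genes["chromosome"].values == seg.chromosome)
            & (gene_pos_in_chrom >= seg.start)
            & (gene_pos_in_chrom < seg.end)
        )
        if seg.subpopulations:
            affected = cells["subpopulation"].isin(seg.subpopulations).values
        else:
            affected = (cells["ploidy"] == "aneuploid").values
        affected = affected & (cells["ploidy"] == "aneuploid").values
        mu[np.ix_(in_seg, affected)] *= 2.0**seg.log2_ratio

    # Subpopulation marker effects
    for sub, _, markers in config.tumor_composition:
        if not markers:
            continue
        g_mask = genes["gene"].isin(markers).values
        c_mask = (cells["subpopulation"] == sub).values
        mu[np.ix_(g_mask, c_mask)] *= config.marker_effect

    # Cell-cycle phase programs
    for phase in PHASES:
        g_mask = (genes["cycle_set"] == phase).values
        c_mask = (cells["phase"] == phase).values
        if g_mask.any() and c_mask.any():
            mu[np.ix_(g_mask, c_mask)] *= config.phase_effect

    size = config.nb_dispersion
    counts = rng.negative_binomial(size, size / (size + mu)).astype(np.int64)

    if config.dropout_midpoint is not None:
        with np.errstate(divide="ignore"):
            logmu = np.log2(mu)
        p_drop = 1.0 / (1.0 + np.exp(config.dropout_slope * (logmu - config.dropout_midpoint)))
        counts[rng.random(size=mu.shape) < p_drop] = 0

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes["gene"].values, columns=cells["cell_id"].values),
        state="counts",
        history=["simulate_expression"],
    )
    truth = GroundTruth(cells=cells, genes=genes, segments=tuple(config.cna_segments))
    return matrix, truth


def dropout_probability(mean: np.ndarray, midpoint: float, slope: float) -> np.ndarray:
    """Logistic dropout probability as a function of log2 mean expression."""
    return 1.0 / (1.0 + np.exp(slope * (np.log2(mean) - midpoint)))


def _open_maybe_gz(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class ReadSimResult:
    """Paths and tallies from a read simulation run."""

    r1_path: Path
    r2_path: Path
    read_gene_path: Path
    n_molecules: int
    n_reads: int


def simulate_reads(
    truth: GroundTruth,
    expr: ExpressionMatrix,
    config: SimulationConfig,
    out_dir,
) -> ReadSimResult:
    """Emit paired FASTQ plus a read-to-gene sidecar table.

    Read 1 carries the 11 nt well barcode, the 10 nt UMI and a poly-T
    tail; read 2 is a fixed-length random sequence (gene identity
    travels in the sidecar table, standing in for alignment). One read
    is emitted per molecule, with extra duplicate reads injected so that
    the expected duplicate fraction equals ``duplication_rate``.
    """
    expr.require_state("counts")
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = config.rng(stream=4)

    barcodes = truth.cells.set_index("cell_id")["barcode"]
    if barcodes.duplicated().any():
        raise GenerationError("barcode collision among simulated cells")
    missing = [c for c in expr.cells if c not in barcodes.index]
    if missing:
        raise GenerationError(f"cells without a barcode: {missing[:5]}")

    r1_path = out / "reads_R1.fastq"
    r2_path = out / "reads_R2.fastq"
    table_path = out / "read_gene.tsv"
    tail = "T" * 9  # oligo-dT remnant after barcode+UMI
    n_molecules = 0
    n_reads = 0

    with (
        _open_maybe_gz(r1_path, "wt") as r1,
        _open_maybe_gz(r2_path, "wt") as r2,
        open(table_path, "w") as tbl,
    ):
        tbl.write("read_id\tgene\n")
        counts = expr.values
        for cell in counts.columns:
            bc = barcodes[cell]
            col = counts[cell]
            col = col[col > 0]
            if not len(col):
                continue
            total = int(col.sum())
            umis = random_barcodes(total, config.umi_length, rng)
            # molecules: (gene, umi) pairs; UMIs distinct within the cell
            molecules: list[tuple[str, str]] = []
            k = 0
            for gene, c in col.items():
                for _ in range(int(c)):
                    molecules.append((gene, umis[k]))
                    k += 1
            n_molecules += len(molecules)
            dup = config.duplication_rate
            n_extra = int(round(dup / (1.0 - dup) * len(molecules)))
            extra_idx = (
                rng.integers(0, len(molecules), size=n_extra) if n_extra else np.array([], int)
            )
            emitted = molecules + [molecules[i] for i in extra_idx]
            for gene, umi in emitted:
                rid = f"read_{n_reads:08d}"
                seq1 = bc + umi + tail
                seq2 = "".join(_BASES[rng.integers(0, 4, size=config.read2_length)])
                r1.write(f"@{rid}\n{seq1}\n+\n{'I' * len(seq1)}\n")
                r2.write(f"@{rid}\n{seq2}\n+\n{'I' * len(seq2)}\n")
                tbl.write(f"{rid}\t{gene}\n")
                n_reads += 1

    return ReadSimResult(r1_path, r2_path, table_path, n_molecules, n_reads)


def write_whitelist(config: SimulationConfig, path) -> list[str]:
    """Write the well-barcode whitelist (one barcode per line) and return it.

    The chip's barcodes are preprinted and known; the same seeded draw
    used to assign cell barcodes regenerates the identical whitelist.
    """
    barcodes = random_barcodes(config.n_wells, config.barcode_length, config.rng(stream=2))
    Path(path).write_text("\n".join(barcodes) + "\n")
    return barcodes
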