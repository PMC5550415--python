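"""Core in-memory containers: expression matrices, counts, gene annotation.

Matrices are gene x cell pandas DataFrames. An :class:`ExpressionMatrix`
carries an explicit normalization-state tag so that each transform can
check its precondition (e.g. log transform refuses already-logged input)
and the provenance of a matrix is always recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from snrs.errors import StateError

#: Recognized normalization states, in the order the pipeline produces them.
STATES = ("counts", "tpm", "log2p1", "cell_scaled", "zscore")


@dataclass
class ExpressionMatrix:
    """A gene x cell expression matrix with a named normalization state.

    Parameters
    ----------
    values
        DataFrame with gene ids as the index and cell ids as columns.
    state
        One of ``counts``, ``tpm``, ``log2p1``, ``cell_scaled``, ``zscore``.
    history
        Transform names applied so far, oldest first.
    """

    values: pd.DataFrame
    state: str = "counts"
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise StateError(f"unknown normalization state {self.state!r}")
        if self.state in ("counts", "tpm") and (self.values.values < 0).any():
            raise ValueError(f"negative values in a {self.state} matrix")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cells(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def require_state(self, *states: str) -> None:
        if self.state not in states:
            raise StateError(
                f"operation requires state in {states}, matrix is {self.state!r} "
                f"(history: {self.history or 'none'})"
            )

    def evolve(self, values: pd.DataFrame, state: str, step: str) -> "ExpressionMatrix":
        """Return a new matrix with *step* appended to the history."""
        return ExpressionMatrix(values, state=state, history=[*self.history, step])

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path, state: str = "counts") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, state=state)


@dataclass
class CountMatrix:
    """Deduplicated UMI (or read) counts per gene per well."""

    values: pd.DataFrame  # genes x wells, nonnegative integers

    def __post_init__(self) -> None:
        v = self.values.values
        if (v < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def wells(self) -> pd.Index:
        return self.values.columns

    def as_expression(self) -> ExpressionMatrix:
        return ExpressionMatrix(self.values.astype(float), state="counts")


class GeneAnnotation:
    """Per-gene genomic coordinates used to order genes for smoothing.

    Coordinates are 0-based half-open internally; pass ``one_based=True``
    when loading tables that use 1-based inclusive starts.
    """

    COLUMNS = ("chromosome", "start", "end", "gene")

    def __init__(self, table: pd.DataFrame, one_based: bool = False):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        table = table.loc[:, list(self.COLUMNS)].copy()
        if one_based:
            table["start"] = table["start"] - 1
        if table["gene"].duplicated().any():
            dups = table.loc[table["gene"].duplicated(), "gene"].tolist()[:5]
            raise ValueError(f"duplicate gene ids in annotation: {dups}")
        if (table["start"] < 0).any() or (table["start"] >= table["end"]).any():
            raise ValueError("annotation requires 0 <= start < end")
        self.table = table.set_index("gene", drop=False)
        self.table.index.name = None

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, gene: str) -> bool:
        return gene in self.table.index

    def genomic_order(self) -> pd.Index:
        """Gene ids sorted by (chromosome, start) with natural chromosome order."""
        key = self.table["chromosome"].map(chromosome_sort_key)
        order = self.table.assign(_ck=key).sort_values(
            ["_ck", "chromosome", "start", "gene"], kind="mergesort"
        )
        return pd.Index(order["gene"])

    @classmethod
    def from_bed(cls, path, one_based: bool = False) -> "GeneAnnotation":
        """Load a BED-like TSV: chrom, start, end, gene id (no header)."""
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chromosome", "start", "end", "gene"],
            comment="#",
        )
        return cls(df, one_based=one_based)

    def to_bed(self, path) -> None:
        self.table[["chromosome", "start", "end", "gene"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def chromosome_sort_key(chrom: str) -> tuple[int, float | str]:
    """Natural chromosome ordering: 1..22, X, Y, MT, then others lexically."""
    name = str(chrom)
    if name.lower().startswith("chr"):
        name = name[3:]
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if name.isdigit():
        return (0, int(name))
    if name.upper() in special:
        return (0, special[name.upper()])
    return (1, name)


def write_mtx(counts: CountMatrix, prefix: str) -> None:
    """Write a CountMatrix as MatrixMarket plus gene/barcode index files."""
    from scipy import io as spio
    from scipy import sparse

    spio.mmwrite(f"{prefix}.mtx", sparse.csr_matrix(counts.values.values))
    pd.Series(counts.genes).to_csv(f"{prefix}.genes.txt", index=False, header=False)
    pd.Series(counts.wells).to_csv(f"{prefix}.barcodes.txt", index=False, header=False)


def read_mtx(prefix: str) -> CountMatrix:
    from scipy import io as spio

    m = spio.mmread(f"{prefix}.mtx").toarray()
    genes = pd.read_csv(f"{prefix}.genes.txt", header=None)[0]
    wells = pd.read_csv(f"{prefix}.barcodes.txt", header=None)[0]
    return CountMatrix(pd.DataFrame(np.asarray(m), index=genes, columns=wells))
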