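"""FPKM quantification on union-exon gene lengths, and expression bounds
for genes overlapped by an opposite-strand gene in non-strand-specific data.

FPKM here is reads × 1e9 / (gene length in nt × library size in reads),
with gene length the union-exon length from :mod:`hetflag.annotation_io`.

For an antisense gene pair in unstranded libraries, reads falling in the
shared exonic region cannot be assigned to a strand.  The target gene's
expression is therefore reported as an interval: the *underestimated*
FPKM uses only reads in the target-exclusive exonic region, the
*overestimated* FPKM additionally includes all ambiguous-region reads.
Both bounds divide by the full target union length, so "under" is a true
lower bound under the fixed gene model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import GeneModel, GenomicInterval
from .errors import HetflagError, MissingGeneError


@dataclass(frozen=True)
class CountTable:
    """Per-cell read counts plus the cell's library size (total mapped reads)."""

    cell_id: str
    counts: Mapping[str, int]
    library_size: int

    def __post_init__(self):
        if self.library_size <= 0:
            raise HetflagError(f"{self.cell_id}: library_size must be positive")
        for gid, c in self.counts.items():
            if c < 0:
                raise HetflagError(f"{self.cell_id}: negative count for {gid}")
            if c > self.library_size:
                raise HetflagError(
                    f"{self.cell_id}: count for {gid} exceeds library size"
                )


@dataclass
class ExpressionMatrix:
    """Genes × cells FPKM matrix with unique, ordered identifiers."""

    genes: list[str]
    cells: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise HetflagError("matrix shape inconsistent with gene/cell ids")
        if len(set(self.genes)) != len(self.genes):
            raise HetflagError("gene ids not unique")
        if len(set(self.cells)) != len(self.cells):
            raise HetflagError("cell ids not unique")
        if self.values.size and (np.isnan(self.values).any() or (self.values < 0).any()):
            raise HetflagError("matrix contains negative or NaN entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(df)


def fpkm(count: float, length: int, library_size: int) -> float:
    """reads × 1e9 / (length_nt × library_size)."""
    if length <= 0:
        raise HetflagError(f"gene length must be positive, got {length}")
    if library_size <= 0:
        raise HetflagError(f"library size must be positive, got {library_size}")
    if count < 0:
        raise HetflagError(f"count must be non-negative, got {count}")
    return count * 1e9 / (length * library_size)


def fpkm_matrix(counts_by_cell: Sequence[CountTable],
                lengths: Mapping[str, int]) -> ExpressionMatrix:
    """Vectorised FPKM over a set of per-cell count tables.

    The gene set is the union of genes over all cells; a gene absent from
    ``lengths`` is an error, never a silent zero.  A gene absent from one
    cell's table gets count 0 in that cell.
    """
    genes = sorted({g for ct in counts_by_cell for g in ct.counts})
    missing = [g for g in genes if g not in lengths]
    if missing:
        raise MissingGeneError(missing)
    cells = [ct.cell_id for ct in counts_by_cell]
    if len(set(cells)) != len(cells):
        raise HetflagError("duplicate cell ids in count tables")
    length_arr = np.array([lengths[g] for g in genes], dtype=float)
    if (length_arr <= 0).any():
        raise HetflagError("all gene lengths must be positive")
    vals = np.zeros((len(genes), len(cells)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for j, ct in enumerate(counts_by_cell):
        col = np.zeros(len(genes))
        for g, c in ct.counts.items():
            col[gene_pos[g]] = c
        vals[:, j] = col * 1e9 / (length_arr * ct.library_size)
    return ExpressionMatrix(genes, cells, vals)


@dataclass(frozen=True)
class AmbiguityPartition:
    """Target union exons split into antisense-exclusive vs shared regions."""

    exclusive_region: tuple[GenomicInterval, ...]
    ambiguous_region: tuple[GenomicInterval, ...]
    count_exclusive: int
    count_ambiguous: int

    @property
    def exclusive_nt(self) -> int:
        return sum(e.length for e in self.exclusive_region)

    @property
    def ambiguous_nt(self) -> int:
        return sum(e.length for e in self.ambiguous_region)


def exon_partition(target: GeneModel, antisense: GeneModel) -> tuple[
        tuple[GenomicInterval, ...], tuple[GenomicInterval, ...]]:
    """Split the target's union exons by exonic intersection with the
    opposite-strand gene. Returns (exclusive, ambiguous) interval tuples."""
    if target.chrom != antisense.chrom:
        raise HetflagError("target and antisense genes must share a chromosome")
    if target.strand == antisense.strand:
        raise HetflagError(
            "ambiguity bounds apply to opposite-strand gene pairs only"
        )
    anti = [(e.start, e.end) for e in antisense.union_exons]
    exclusive, ambiguous = [], []
    for e in target.union_exons:
        cursor = e.start
        for a0, a1 in anti:
            lo, hi = max(cursor, a0), min(e.end, a1)
            if lo < hi:
                if cursor < lo:
                    exclusive.append(GenomicInterval(e.chrom, cursor, lo, e.strand))
                ambiguous.append(GenomicInterval(e.chrom, lo, hi, e.strand))
                cursor = hi
        if cursor < e.end:
            exclusive.append(GenomicInterval(e.chrom, cursor, e.end, e.strand))
    return tuple(exclusive), tuple(ambiguous)


def ambiguity_bounds(target: GeneModel, antisense: GeneModel,
                     partition_counts: tuple[int, int],
                     library_size: int) -> tuple[float, float]:
    """Under/over-estimated FPKM for ``target`` given reads already assigned
    to its exclusive and ambiguous exonic regions."""
    count_exclusive, count_ambiguous = partition_counts
    if count_exclusive < 0 or count_ambiguous < 0:
        raise HetflagError("partition counts must be non-negative")
    exon_partition(target, antisense)  # validates pair geometry
    under = fpkm(count_exclusive, target.union_length, library_size)
    over = fpkm(count_exclusive + count_ambiguous, target.union_length, library_size)
    return under, over


def partition_to_bed(partition: AmbiguityPartition, path: str | Path,
                     name_prefix: str = "region") -> None:
    """Export the partition geometry as BED (0-based half-open) for external
    read counting."""
    with Path(path).open("w") as fh:
        for label, region in (("exclusive", partition.exclusive_region),
                              ("ambiguous", partition.ambiguous_region)):
            for i, iv in enumerate(region):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                         f"{name_prefix}_{label}_{i}\t0\t{iv.strand}\n")


def read_counts_tsv(path: str | Path, library_sizes: Mapping[str, int]) -> list[CountTable]:
    """Counts TSV (gene_id column + one integer column per cell) →
    :class:`CountTable` per cell, with caller-supplied library sizes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    tables = []
    for cell in df.columns:
        if cell not in library_sizes:
            raise HetflagError(f"no library size for cell {cell!r}")
        tables.append(CountTable(cell, df[cell].astype(int).to_dict(),
                                 int(library_sizes[cell])))
    return tables
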