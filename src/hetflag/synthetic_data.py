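"""Synthetic single-cell expression data with planted ground truth.

The generator emulates the data regime the analysis is built for: a
genes × cells FPKM matrix with a dropout-style excess of exact zeros, in
which each gene is expressed (above 3 FPKM) in a planted number of cells
N drawn from one of two populations — a high-heterogeneity class
(expressed in few cells) and a low-heterogeneity class (expressed in most
cells) — with biotype-specific class probabilities.  Positive cells
receive magnitudes from a truncated log-normal, keeping each gene's
maximum inside either the moderate (3–30 FPKM) analysis window or, for a
configurable fraction of genes, the high-expression (>30 FPKM) stratum
used only by the CV comparison.

Defaults mirror the regime the pipeline targets: 96 cells, 2000 genes per
biotype, planted high-heterogeneity probabilities 0.74 for lncRNAs and
0.35 for mRNAs, and well-separated N-class distributions (see
docs/methods.md for the rationale behind each default).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import GeneModel, GenomicInterval, TranscriptModel
from .errors import ConfigError
from .quantification import CountTable, ExpressionMatrix


@dataclass(frozen=True)
class SimulationSpec:
    """Generator parameters; all N-scale parameters are in cells.

    ``frac_high_expr`` genes are planted in the >30 FPKM stratum with
    their own biotype-shifted N distributions (abundant genes drop out
    less); the rest are moderate-window genes whose N comes from the
    high/low-heterogeneity class mixture.
    """

    n_cells: int = 96
    n_lnc: int = 2000
    n_mrna: int = 2000
    p_high_lnc: float = 0.74
    p_high_mrna: float = 0.35
    n_high_mean: float = 6.0
    n_high_sd: float = 3.0
    n_low_mean: float = 55.0
    n_low_sd: float = 12.0
    frac_high_expr: float = 0.0
    n_highexpr_lnc_mean: float = 35.0
    n_highexpr_lnc_sd: float = 8.0
    n_highexpr_mrna_mean: float = 75.0
    n_highexpr_mrna_sd: float = 10.0
    mag_meanlog: float = 2.25   # ln FPKM location of positive-cell magnitudes
    mag_sdlog: float = 0.8
    mag_low: float = 3.2        # positive cells stay strictly above threshold
    mag_high: float = 29.5      # moderate-stratum maxima stay inside (3, 30]
    mag_top: float = 300.0      # ceiling for the high-expression stratum
    background_noise: bool = False  # uniform(0, 3) instead of exact zeros
    n_distribution: str = "normal"  # or "negbin" (skewed robustness mode)
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_high_lnc, self.p_high_mrna, self.frac_high_expr):
            if not 0 <= p <= 1:
                raise ConfigError("probabilities must lie in [0, 1]")
        if self.n_cells < 2:
            raise ConfigError("need at least 2 cells")
        if not self.n_high_mean < self.n_low_mean:
            raise ConfigError("high-heterogeneity class mean must be the smaller")
        if self.n_distribution not in ("normal", "negbin"):
            raise ConfigError("n_distribution must be 'normal' or 'negbin'")
        if not 0 < self.mag_low < self.mag_high:
            raise ConfigError("require 0 < mag_low < mag_high")
        # refuse class distributions that would clamp most draws
        for mean, sd in ((self.n_high_mean, self.n_high_sd),
                         (self.n_low_mean, self.n_low_sd)):
            inside = (stats.norm.cdf(self.n_cells + 0.5, mean, sd)
                      - stats.norm.cdf(0.5, mean, sd))
            if inside < 0.5:
                raise ConfigError(
                    f"N class Normal({mean}, {sd}) lies outside [1, {self.n_cells}] "
                    "in more than half of draws"
                )


def _draw_n(rng: np.random.Generator, mean: float, sd: float, size: int,
            n_cells: int, mode: str) -> np.ndarray:
    if mode == "negbin" and sd ** 2 > mean:
        r = mean ** 2 / (sd ** 2 - mean)
        p = r / (r + mean)
        draws = rng.negative_binomial(r, p, size=size).astype(float)
    else:
        draws = rng.normal(mean, sd, size=size)
    return np.clip(np.rint(draws), 1, n_cells).astype(int)


def _truncated_lognormal(rng: np.random.Generator, size: int, meanlog: float,
                         sdlog: float, lo: float, hi: float) -> np.ndarray:
    a = (np.log(lo) - meanlog) / sdlog
    b = (np.log(hi) - meanlog) / sdlog
    z = stats.truncnorm.rvs(a, b, loc=meanlog, scale=sdlog, size=size,
                            random_state=rng)
    return np.exp(z)


def simulate_matrix(spec: SimulationSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate an FPKM matrix plus its truth table.

    The truth table has one row per gene: gene_id, biotype
    (noncoding/coding), stratum (moderate/high), het_class (high/low for
    moderate genes, 'na' for high-stratum genes), true_n, and the
    comma-joined ids of the positive cells.  Deterministic for a fixed
    spec (the seed is part of the spec).
    """
    rng = np.random.default_rng(spec.seed)
    cells = [f"cell_{i:03d}" for i in range(spec.n_cells)]
    gene_ids, biotypes = [], []
    for i in range(spec.n_lnc):
        gene_ids.append(f"lnc_{i:05d}")
        biotypes.append("noncoding")
    for i in range(spec.n_mrna):
        gene_ids.append(f"mrna_{i:05d}")
        biotypes.append("coding")
    n_genes = len(gene_ids)

    values = np.zeros((n_genes, spec.n_cells))
    if spec.background_noise:
        values = rng.uniform(0.0, 3.0, size=values.shape)
    truth_rows = []
    for i, (gid, bt) in enumerate(zip(gene_ids, biotypes)):
        high_expr = rng.random() < spec.frac_high_expr
        if high_expr:
            stratum, het_class = "high", "na"
            if bt == "noncoding":
                n = _draw_n(rng, spec.n_highexpr_lnc_mean, spec.n_highexpr_lnc_sd,
                            1, spec.n_cells, spec.n_distribution)[0]
            else:
                n = _draw_n(rng, spec.n_highexpr_mrna_mean, spec.n_highexpr_mrna_sd,
                            1, spec.n_cells, spec.n_distribution)[0]
        else:
            stratum = "moderate"
            p_high = spec.p_high_lnc if bt == "noncoding" else spec.p_high_mrna
            het_class = "high" if rng.random() < p_high else "low"
            mean, sd = ((spec.n_high_mean, spec.n_high_sd)
                        if het_class == "high" else (spec.n_low_mean, spec.n_low_sd))
            n = _draw_n(rng, mean, sd, 1, spec.n_cells, spec.n_distribution)[0]
        pos = rng.choice(spec.n_cells, size=n, replace=False)
        if stratum == "moderate":
            mags = _truncated_lognormal(rng, n, spec.mag_meanlog, spec.mag_sdlog,
                                        spec.mag_low, spec.mag_high)
        else:
            mags = _truncated_lognormal(rng, n, spec.mag_meanlog, spec.mag_sdlog,
                                        spec.mag_low, spec.mag_top)
            # one designated cell guarantees the >30 FPKM stratum membership
            mags[0] = _truncated_lognormal(rng, 1, spec.mag_meanlog, spec.mag_sdlog,
                                           30.000001, spec.mag_top)[0]
        values[i, pos] = mags
        truth_rows.append({
            "gene_id": gid, "biotype": bt, "stratum": stratum,
            "het_class": het_class, "true_n": int(n),
            "positive_cells": ",".join(cells[j] for j in sorted(pos)),
        })
    matrix = ExpressionMatrix(gene_ids, cells, values)
    return matrix, pd.DataFrame(truth_rows)


def biotype_map(truth: pd.DataFrame) -> dict[str, str]:
    """gene_id → coding/noncoding mapping from a truth table."""
    return dict(zip(truth["gene_id"], truth["biotype"]))


def true_posterior_high(spec: SimulationSpec, n_values) -> np.ndarray:
    """Posterior of the high-heterogeneity class under the *generating*
    mixture (pooled class priors over both biotypes), for moderate genes.

    This is the planted-truth reference used to score flag fidelity.
    """
    n_mod = spec.n_lnc + spec.n_mrna
    w_high = (spec.n_lnc * spec.p_high_lnc + spec.n_mrna * spec.p_high_mrna) / n_mod
    x = np.asarray(n_values, dtype=float)
    num = w_high * stats.norm.pdf(x, spec.n_high_mean, spec.n_high_sd)
    den = num + (1 - w_high) * stats.norm.pdf(x, spec.n_low_mean, spec.n_low_sd)
    return num / den


def simulate_counts(targets: ExpressionMatrix, lengths: Mapping[str, int],
                    library_size: int) -> list[CountTable]:
    """Invert the FPKM formula: integer counts whose FPKM round-trips to the
    target matrix within the rounding bound 1e9/(2·length·library_size)."""
    tables = []
    length_arr = np.array([lengths[g] for g in targets.genes], dtype=float)
    for j, cell in enumerate(targets.cells):
        counts = np.rint(
            targets.values[:, j] * length_arr * library_size / 1e9
        ).astype(int)
        tables.append(CountTable(cell, dict(zip(targets.genes, counts)),
                                 library_size))
    return tables


# ---------------------------------------------------------------------------
# annotation / sequence fixtures


def random_gene_models(rng: np.random.Generator, n_genes: int = 50,
                       chrom: str = "chrS") -> list[GeneModel]:
    """Random non-pathological gene models with a mix of NM_/NR_/lincRNA
    transcripts, for exercising the annotation module."""
    genes = []
    cursor = 1000
    for i in range(n_genes):
        kind = rng.choice(["NM_", "NR_", "XM_", "XR_", "linc", "other"])
        strand = "+" if rng.random() < 0.5 else "-"
        n_tx = int(rng.integers(1, 4))
        transcripts = []
        gene_start = cursor
        for t in range(n_tx):
            n_ex = int(rng.integers(1, 5))
            exons, pos = [], gene_start + int(rng.integers(0, 200))
            for _ in range(n_ex):
                length = int(rng.integers(50, 400))
                exons.append(GenomicInterval(chrom, pos, pos + length, strand))
                pos += length + int(rng.integers(30, 500))
            if kind == "linc":
                tid, src = f"LINC{i:04d}.{t}", "lincRNA"
            elif kind == "other":
                tid, src = f"TX{i:05d}.{t}", None
            else:
                tid, src = f"{kind}{100000 + i * 10 + t}", None
            transcripts.append(TranscriptModel(tid, tuple(exons), source_class=src))
        genes.append(GeneModel(f"gene_{i:04d}", f"GENE{i:04d}", tuple(transcripts)))
        cursor = max(e.end for t in transcripts for e in t.exons) + int(
            rng.integers(500, 3000))
    return genes


def write_fixture_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Serialize gene models to GTF (1-based inclusive, quoted attributes)."""
    with Path(path).open("w") as fh:
        for g in genes:
            for t in g.transcripts:
                for e in t.exons:
                    attrs = (f'gene_id "{g.gene_id}"; transcript_id '
                             f'"{t.transcript_id}"; gene_name "{g.gene_name}";')
                    if t.source_class:
                        attrs += f' gene_type "{t.source_class}";'
                    fh.write(f"{e.chrom}\thetflag\texon\t{e.start + 1}\t{e.end}\t"
                             f".\t{e.strand}\t.\t{attrs}\n")


def random_antisense_pair(rng: np.random.Generator,
                          chrom: str = "chrS") -> tuple[GeneModel, GeneModel]:
    """A random opposite-strand gene pair with possibly overlapping exons,
    for the under/over bounds property."""

    def _exons(start: int, strand: str) -> tuple[GenomicInterval, ...]:
        exons, pos = [], start
        for _ in range(int(rng.integers(1, 5))):
            length = int(rng.integers(100, 2000))
            exons.append(GenomicInterval(chrom, pos, pos + length, strand))
            pos += length + int(rng.integers(0, 1500)) + 1
        return tuple(exons)

    t_start = int(rng.integers(0, 5000))
    a_start = int(rng.integers(0, 8000))
    target = GeneModel("target", "TARGET", (
        TranscriptModel("NR_900001", _exons(t_start, "+")),))
    anti = GeneModel("anti", "ANTI", (
        TranscriptModel("NM_900002", _exons(a_start, "-")),))
    return target, anti


def random_sequence(rng: np.random.Generator, length: int,
                    composition: Mapping[str, float] | None = None) -> str:
    probs = ([composition.get(b, 0.0) for b in "ACGT"] if composition
             else [0.25] * 4)
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=np.array(probs)))


def write_fixture_fasta(records: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
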