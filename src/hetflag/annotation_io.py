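"""Gene annotation: GTF reading, union-exon gene models and biotype rules.

The biotype vocabulary follows RefSeq accession prefixes: ``NM_``/``XM_``
(mRNA, curated / predicted) and ``NP_``/``XP_`` (peptide) mark a gene as
protein-coding; ``NR_``/``XR_`` (ncRNA) or a ``lincRNA`` source label mark
it as non-coding.  A non-coding gene whose exons overlap, on the same
strand, the exons of a coding gene is reclassified coding: such geometry
permits transcriptional read-through from the lncRNA promoter into the
coding gene, and the conservative choice is to keep the lncRNA set clean.
Genes with neither kind of evidence are ``excluded`` from both sets.

Gene length throughout the package is the *union-exon* length: the number
of bases covered by at least one exon of at least one isoform, each base
counted once.  Internally all intervals are 0-based half-open; GTF's
1-based inclusive coordinates are converted exactly once, in
:func:`parse_gtf`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .errors import GtfParseError, HetflagError

logger = logging.getLogger(__name__)

CODING_PREFIXES = ("NM_", "XM_", "NP_", "XP_")
NONCODING_PREFIXES = ("NR_", "XR_")
LINCRNA_LABEL = "lincRNA"

_ATTR_QUOTED = re.compile(r'\s*(\w+)\s+"([^"]*)"\s*')
_ATTR_EQUALS = re.compile(r"\s*(\w+)\s*=\s*\"?([^\";]*?)\"?\s*$")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not self.start < self.end:
            raise HetflagError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise HetflagError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """One isoform: an ordered, non-overlapping exon chain on one strand."""

    transcript_id: str
    exons: tuple[GenomicInterval, ...]
    source_class: str | None = None

    def __post_init__(self):
        if not self.exons:
            raise HetflagError(f"transcript {self.transcript_id} has no exons")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise HetflagError(
                f"transcript {self.transcript_id} mixes chromosomes/strands"
            )
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise HetflagError(
                    f"transcript {self.transcript_id} has overlapping exons"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    def accession_prefix(self) -> str | None:
        m = re.match(r"^([A-Z]{2}_)", self.transcript_id)
        return m.group(1) if m else None


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> tuple[GenomicInterval, ...]:
    """Merge overlapping/adjacent same-chromosome intervals into a disjoint,
    sorted set. All intervals must share one chromosome and strand."""
    ivs = sorted(intervals, key=lambda e: (e.start, e.end))
    if not ivs:
        return ()
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.chrom != last.chrom or iv.strand != last.strand:
            raise HetflagError("cannot merge intervals across chromosomes/strands")
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return tuple(merged)


@dataclass(frozen=True)
class GeneModel:
    """A gene: its isoforms plus the derived union-exon set and length."""

    gene_id: str
    gene_name: str
    transcripts: tuple[TranscriptModel, ...]
    union_exons: tuple[GenomicInterval, ...] = field(init=False)
    union_length: int = field(init=False)

    def __post_init__(self):
        if not self.transcripts:
            raise HetflagError(f"gene {self.gene_id} has no transcripts")
        union = merge_intervals(e for t in self.transcripts for e in t.exons)
        object.__setattr__(self, "union_exons", union)
        object.__setattr__(self, "union_length", sum(e.length for e in union))

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand


@dataclass(frozen=True)
class Biotype:
    """Coding/noncoding/excluded label plus a human-readable audit trail."""

    value: str
    reason: str

    def __post_init__(self):
        if self.value not in ("coding", "noncoding", "excluded"):
            raise HetflagError(f"unknown biotype {self.value!r}")
        if not self.reason:
            raise HetflagError("biotype reason must be non-empty")


def union_exon_length(gene: GeneModel) -> int:
    """Total bases covered by at least one exon of any isoform."""
    return gene.union_length


def _parse_attributes(attr_field: str, lineno: int) -> dict[str, str]:
    # Accepts both `key "value";` (GTF) and `key=value` dialects.
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        m = _ATTR_QUOTED.fullmatch(chunk) or _ATTR_EQUALS.fullmatch(chunk)
        if m:
            attrs.setdefault(m.group(1), m.group(2))
    if not attrs:
        raise GtfParseError(f"line {lineno}: unparsable attribute field")
    return attrs


def parse_gtf(path: str | Path) -> list[GeneModel]:
    """Read a GTF file into :class:`GeneModel` objects.

    Only ``exon`` features contribute; coordinates are converted from GTF's
    1-based inclusive to the internal 0-based half-open convention here and
    nowhere else.  Malformed lines raise :class:`GtfParseError` naming the
    line number; exact duplicate exon records are dropped with a warning.
    """
    path = Path(path)
    # gene_id -> transcript_id -> list of exon intervals
    genes: dict[str, dict[str, list[GenomicInterval]]] = {}
    gene_names: dict[str, str] = {}
    sources: dict[str, str | None] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, source, feature, start_s, end_s, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise GtfParseError(f"line {lineno}: end < start")
            if strand not in ("+", "-"):
                raise GtfParseError(f"line {lineno}: unknown strand {strand!r}")
            attrs = _parse_attributes(attr, lineno)
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise GtfParseError(
                    f"line {lineno}: exon lacks gene_id/transcript_id attributes"
                )
            gid, tid = attrs["gene_id"], attrs["transcript_id"]
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            exon_list = genes.setdefault(gid, {}).setdefault(tid, [])
            if iv in exon_list:
                logger.warning(
                    "%s line %d: duplicate exon %s:%d-%d for %s dropped",
                    path.name, lineno, chrom, start1, end1, tid,
                )
                continue
            exon_list.append(iv)
            gene_names.setdefault(gid, attrs.get("gene_name", gid))
            src = attrs.get("gene_type") or attrs.get("transcript_type") or source
            sources.setdefault(tid, src)
    models = []
    for gid, txs in genes.items():
        transcripts = tuple(
            TranscriptModel(tid, tuple(exons), source_class=sources.get(tid))
            for tid, exons in txs.items()
        )
        models.append(GeneModel(gid, gene_names[gid], transcripts))
    return models


class OverlapIndex:
    """Per (chromosome, strand) interval trees over exons of coding genes."""

    def __init__(self, genes: Sequence[GeneModel], biotype_evidence: Mapping[str, str]):
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for g in genes:
            if biotype_evidence.get(g.gene_id) != "coding":
                continue
            tree = self._trees.setdefault((g.chrom, g.strand), IntervalTree())
            for e in g.union_exons:
                tree.addi(e.start, e.end, g.gene_id)

    def overlapping_coding_genes(self, gene: GeneModel) -> list[str]:
        tree = self._trees.get((gene.chrom, gene.strand))
        if tree is None:
            return []
        hits = {
            iv.data
            for e in gene.union_exons
            for iv in tree.overlap(e.start, e.end)
            if iv.data != gene.gene_id
        }
        return sorted(hits)


def _evidence(gene: GeneModel) -> tuple[bool, bool]:
    coding = any(t.accession_prefix() in CODING_PREFIXES for t in gene.transcripts)
    noncoding = any(
        t.accession_prefix() in NONCODING_PREFIXES or t.source_class == LINCRNA_LABEL
        for t in gene.transcripts
    )
    return coding, noncoding


def classify_biotype(gene: GeneModel, all_genes: Sequence[GeneModel],
                     index: OverlapIndex | None = None) -> Biotype:
    """Label one gene coding/noncoding/excluded.

    ``index`` may be precomputed with :func:`build_overlap_index` when
    classifying many genes against the same annotation.
    """
    if index is None:
        index = build_overlap_index(all_genes)
    coding, noncoding = _evidence(gene)
    if coding and noncoding:
        return Biotype("coding", "mixed evidence: carries both coding and "
                                 "noncoding transcripts; resolved to coding")
    if coding:
        return Biotype("coding", "RefSeq coding accession prefix")
    if noncoding:
        partners = index.overlapping_coding_genes(gene)
        if partners:
            return Biotype(
                "coding",
                "possible read-through: same-strand exonic overlap with "
                f"coding gene(s) {', '.join(partners)}",
            )
        return Biotype("noncoding", "RefSeq noncoding prefix or lincRNA label")
    return Biotype("excluded", "no recognized coding or noncoding evidence")


def build_overlap_index(all_genes: Sequence[GeneModel]) -> OverlapIndex:
    evidence = {}
    for g in all_genes:
        c, n = _evidence(g)
        evidence[g.gene_id] = "coding" if c else ("noncoding" if n else "none")
    return OverlapIndex(all_genes, evidence)


def classify_all(genes: Sequence[GeneModel]) -> dict[str, Biotype]:
    """Biotype for every gene, sharing one overlap index."""
    index = build_overlap_index(genes)
    return {g.gene_id: classify_biotype(g, genes, index=index) for g in genes}


def filter_min_length(genes: Iterable[GeneModel], min_len: int = 200) -> list[GeneModel]:
    """Keep genes whose union-exon length is strictly greater than ``min_len``."""
    return [g for g in genes if g.union_length > min_len]


def write_gene_table(genes: Sequence[GeneModel], biotypes: Mapping[str, Biotype],
                     path: str | Path) -> None:
    """TSV export: one row per gene with union length and biotype audit."""
    with Path(path).open("w") as fh:
        fh.write("gene_id\tgene_name\tchrom\tstrand\tunion_length\tbiotype\tbiotype_reason\n")
        for g in genes:
            b = biotypes[g.gene_id]
            fh.write(
                f"{g.gene_id}\t{g.gene_name}\t{g.chrom}\t{g.strand}\t"
                f"{g.union_length}\t{b.value}\t{b.reason}\n"
            )
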