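"""Genome and annotation summary statistics plus windowed GC tracks."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import ChromosomeSeq, GeneRecord
from .ploidy import per_kb_density


@dataclass
class GenomeSummary:
    """Headline assembly and annotation metrics for one strain."""

    genome_size: int
    gc_percent: float
    n_chroms: int
    longest_chrom: int
    shortest_chrom: int
    gene_count: int
    gene_density: float  # genes per kb
    percent_genes_with_introns: float
    mean_introns_per_gene: float
    mean_exon_size: float
    mean_intron_size: float | None  # None when the annotation has no introns

    def to_series(self) -> pd.Series:
        d = self.__dict__.copy()
        if d["mean_intron_size"] is None:
            d["mean_intron_size"] = ""
        return pd.Series(d)


def gene_density(gene_count: int, genome_bp: int) -> float:
    """Genes per kilobase of assembly."""
    return per_kb_density(gene_count, genome_bp)


def summarize_genome(
    chroms: Sequence[ChromosomeSeq], genes: Sequence[GeneRecord]
) -> GenomeSummary:
    """Aggregate assembly metrics and exon/intron structure.

    Introns are the gaps between consecutive exons of a gene; means are
    arithmetic over the whole exon / intron / gene populations. GC% is
    computed over non-N bases. Rounding is left to report time.
    """
    if not chroms:
        raise ValidationError("summarize_genome: no chromosomes")
    known = {c.chrom_id for c in chroms}
    lengths = [c.length for c in chroms]
    gc = at = 0
    for c in chroms:
        gc += c.sequence.count("G") + c.sequence.count("C")
        at += c.sequence.count("A") + c.sequence.count("T")
    genome_size = sum(lengths)

    exon_sizes: list[int] = []
    intron_sizes: list[int] = []
    n_with_introns = 0
    for g in genes:
        if g.chrom_id not in known:
            raise ValidationError(
                f"gene {g.gene_id!r} is on unknown chromosome {g.chrom_id!r}"
            )
        exon_sizes.extend(e - s + 1 for s, e in g.exons)
        introns = g.introns
        intron_sizes.extend(e - s + 1 for s, e in introns)
        if introns:
            n_with_introns += 1

    n_genes = len(genes)
    return GenomeSummary(
        genome_size=genome_size,
        gc_percent=100.0 * gc / (gc + at) if gc + at else 0.0,
        n_chroms=len(chroms),
        longest_chrom=max(lengths),
        shortest_chrom=min(lengths),
        gene_count=n_genes,
        gene_density=gene_density(n_genes, genome_size),
        percent_genes_with_introns=100.0 * n_with_introns / n_genes if n_genes else 0.0,
        mean_introns_per_gene=len(intron_sizes) / n_genes if n_genes else 0.0,
        mean_exon_size=float(np.mean(exon_sizes)) if exon_sizes else 0.0,
        mean_intron_size=float(np.mean(intron_sizes)) if intron_sizes else None,
    )


def gc_track(
    chrom: ChromosomeSeq, window: int = 10_000, step: int = 5_000
) -> pd.DataFrame:
    """Sliding-window GC/AT percentages over non-N bases.

    Columns: chrom, start, end (1-based closed), gc_percent, at_percent,
    n_fraction. A chromosome shorter than the window yields one whole-
    chromosome window. All-N windows report NaN percentages.
    """
    seq = np.frombuffer(chrom.sequence.encode(), dtype="S1")
    is_gc = np.isin(seq, [b"G", b"C"]).astype(np.int64)
    is_n = (seq == b"N").astype(np.int64)
    cgc = np.concatenate([[0], np.cumsum(is_gc)])
    cn = np.concatenate([[0], np.cumsum(is_n)])
    L = len(seq)
    starts = [0] if L <= window else list(range(0, L - window + 1, step))
    rows = []
    for s in starts:
        e = min(s + window, L)
        n_n = cn[e] - cn[s]
        denom = (e - s) - n_n
        gc = 100.0 * (cgc[e] - cgc[s]) / denom if denom else np.nan
        rows.append(
            {
                "chrom": chrom.chrom_id,
                "start": s + 1,
                "end": e,
                "gc_percent": gc,
                "at_percent": 100.0 - gc if denom else np.nan,
                "n_fraction": n_n / (e - s),
            }
        )
    return pd.DataFrame(rows)
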