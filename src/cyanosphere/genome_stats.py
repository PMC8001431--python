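"""Genome property summaries for curated MAGs.

Given annotation counts (genome size, coding and G+C base pairs, gene-class
counts), compute the percent-of-total columns of a standard genome report
and the gene density in base pairs per gene.  Percent cells round half-up to
two decimals against the stated denominator (genome size for bp rows, total
genes for gene rows); density rounds half-up to the nearest integer.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

#: rows whose percent denominator is genome_size_bp (the rest use total_genes)
BP_FIELDS = ("coding_bp", "gc_bp")

GENE_FIELDS = (
    "protein_coding_genes",
    "rna_genes",
    "pseudo_genes",
    "genes_with_function",
    "genes_with_cogs",
    "genes_with_pfam",
    "genes_with_signal_peptides",
    "genes_with_tm_helices",
    "crispr_repeats",
)


@dataclass
class GenomeAnnotationCounts:
    genome_size_bp: int
    coding_bp: int
    gc_bp: int
    contig_count: int
    total_genes: int
    protein_coding_genes: int
    rna_genes: int
    pseudo_genes: int
    genes_with_function: int
    genes_with_cogs: int
    genes_with_pfam: int
    genes_with_signal_peptides: int
    genes_with_tm_helices: int
    crispr_repeats: int

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")
        if self.coding_bp > self.genome_size_bp or self.gc_bp > self.genome_size_bp:
            raise ValueError("coding_bp/gc_bp cannot exceed genome_size_bp")
        for f in GENE_FIELDS:
            if getattr(self, f) > self.total_genes:
                raise ValueError(f"{f} cannot exceed total_genes")


@dataclass
class GenomeStatsReport:
    counts: GenomeAnnotationCounts
    percents: dict  # field name -> percent of its denominator, 2 decimals
    gene_density_bp_per_gene: int


def _pct(x: int, denom: int) -> float:
    return float((Decimal(x) * 100 / Decimal(denom)).quantize(Decimal("0.01"), ROUND_HALF_UP))


def summarize_genome(counts: GenomeAnnotationCounts) -> GenomeStatsReport:
    """Percent-of-total for every count plus bp-per-gene density."""
    if counts.total_genes <= 0 or counts.genome_size_bp <= 0:
        raise ValueError("total_genes and genome_size_bp must be positive")
    percents = {"genome_size_bp": 100.0, "total_genes": 100.0}
    for name in BP_FIELDS:
        percents[name] = _pct(getattr(counts, name), counts.genome_size_bp)
    for name in GENE_FIELDS:
        percents[name] = _pct(getattr(counts, name), counts.total_genes)
    density = int(
        (Decimal(counts.genome_size_bp) / Decimal(counts.total_genes)).quantize(
            Decimal("1"), ROUND_HALF_UP
        )
    )
    return GenomeStatsReport(counts=counts, percents=percents,
                             gene_density_bp_per_gene=density)


def read_counts_table(path) -> dict:
    """Read a tidy annotation-counts TSV (one row per genome, one column per
    :class:`GenomeAnnotationCounts` field plus ``genome``); thousands
    separators are accepted."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = {}
    for _, row in df.iterrows():
        kwargs = {
            f.name: int(str(row[f.name]).replace(",", ""))
            for f in fields(GenomeAnnotationCounts)
        }
        out[row["genome"]] = GenomeAnnotationCounts(**kwargs)
    return out


def report_frame(reports: dict) -> pd.DataFrame:
    """Flatten {genome -> GenomeStatsReport} into a value/percent table."""
    rows = []
    for genome, rep in reports.items():
        for f in fields(GenomeAnnotationCounts):
            rows.append(
                {
                    "genome": genome,
                    "attribute": f.name,
                    "value": getattr(rep.counts, f.name),
                    "pct_of_total": rep.percents.get(f.name),
                }
            )
        rows.append(
            {
                "genome": genome,
                "attribute": "gene_density_bp_per_gene",
                "value": rep.gene_density_bp_per_gene,
                "pct_of_total": None,
            }
        )
    return pd.DataFrame(rows)
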