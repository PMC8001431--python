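"""Bundled example tables: the published summary statistics of the three
cyanobacterial MAG study datasets, re-typed as TSV.

``load_mag_annotation_counts`` gives the annotation counts of the three
curated cyanobacterial MAGs (genome size, coding/GC base pairs, gene-class
counts).  ``load_community_bins`` gives the 36 community bins (completeness
>= 80%, coverage > 25-fold) with their quality, size, coverage and final
classification.  Both are inputs for worked examples and regression checks;
no sequence data is bundled.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .formats_io import BinRecord
from .genome_stats import GenomeAnnotationCounts


def _data(name: str):
    return files("cyanosphere") / "data" / name


def load_mag_annotation_counts() -> dict:
    """Annotation counts per curated cyanobacterial MAG (genome name -> counts)."""
    with (_data("mag_annotation_counts.tsv")).open("r") as fh:  # type: ignore[union-attr]
        df = pd.read_csv(fh, sep="\t", dtype=str)
    out = {}
    for _, row in df.iterrows():
        kwargs = {k: int(str(row[k]).replace(",", "")) for k in df.columns if k != "genome"}
        out[row["genome"]] = GenomeAnnotationCounts(**kwargs)
    return out


def load_community_bins(as_records: bool = True):
    """The 36 high-completeness, high-coverage community bins.

    Returns a DataFrame, or with ``as_records=True`` a list of
    :class:`BinRecord` plus the raw frame: ``(records, frame)``.
    """
    with (_data("community_bins.tsv")).open("r") as fh:  # type: ignore[union-attr]
        df = pd.read_csv(fh, sep="\t")
    if not as_records:
        return df
    records = [
        BinRecord(
            bin_id=row["bin_id"],
            completeness=float(row["completeness"]),
            contamination=float(row["contamination"]),
            coverage=float(row["coverage"]),
            size_bp=int(row["size_bp"]),
            n_contigs=int(row["contigs"]),
        )
        for _, row in df.iterrows()
    ]
    return records, df
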