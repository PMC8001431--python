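"""Readers and writers for the external tables the pipeline touches.

Supported formats: FASTA contig sets, BLAST tabular output in the fixed
dialect ``-outfmt "6 std stitle"`` (12 standard columns plus the subject
title), GFF3 or 5-column TSV feature tables, and TSV bin / quality /
coverage tables.  Parsing is strict: other BLAST dialects are rejected
rather than guessed, and inconsistent bin tables raise instead of being
silently merged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

log = logging.getLogger("cyanosphere")


class FormatError(ValueError):
    """Malformed or unsupported input file."""


class ConsistencyError(ValueError):
    """Input tables contradict each other (duplicate keys, double binning)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

FEATURE_TYPES = ("rRNA_16S", "rRNA_23S", "rRNA_5S", "tRNA", "other")


@dataclass
class Contig:
    """One assembled contig; sequence is optional (length/GC may be given)."""

    id: str
    length: int
    sequence: str | None = None
    gc_count: int = 0

    def __post_init__(self):
        if self.sequence is not None:
            if self.length and self.length != len(self.sequence):
                raise ValueError(f"{self.id}: length {self.length} != sequence length {len(self.sequence)}")
            self.length = len(self.sequence)
            if not self.gc_count:
                s = self.sequence.upper()
                self.gc_count = s.count("G") + s.count("C")
        if self.length < 0 or self.gc_count > self.length:
            raise ValueError(f"{self.id}: invalid length/gc_count")


@dataclass
class BlastHit:
    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    evalue: float
    bitscore: float
    stitle: str = ""

    def __post_init__(self):
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of [0,100]: {self.pct_identity}")
        if self.evalue < 0:
            raise ValueError(f"negative e-value: {self.evalue}")


@dataclass
class BinRecord:
    """A named set of contigs with quality, coverage and size metadata.

    Missing quality or coverage values are explicit ``None`` (never zero) so
    downstream filters can tell "fails threshold" from "unknown".
    """

    bin_id: str
    contig_ids: set = field(default_factory=set)
    completeness: float | None = None
    contamination: float | None = None
    coverage: float | None = None
    size_bp: int | None = None
    marker_lineage: str | None = None
    n_contigs: int | None = None  # from summary tables when contig ids unknown


@dataclass
class FeatureRecord:
    contig_id: str
    feature_type: str  # one of FEATURE_TYPES
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "+"

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise FormatError(f"{self.contig_id}: bad coordinates {self.start}..{self.end}")
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_contigs(path) -> list[Contig]:
    """Read a FASTA contig set; ids must be unique."""
    contigs, seen = [], set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ConsistencyError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        contigs.append(Contig(id=rec.id, length=len(rec.seq), sequence=str(rec.seq).upper()))
    return contigs


def write_contigs(contigs, path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            if c.sequence is None:
                raise ValueError(f"{c.id}: cannot write contig without sequence")
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), 80):
                fh.write(c.sequence[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt "6 std stitle")
# ---------------------------------------------------------------------------

def read_blast_table(path, expect_stitle: bool = True) -> list[BlastHit]:
    """Parse BLAST ``-outfmt "6 std stitle"`` output.

    The 12 standard columns are qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore; anything from column 13 onward
    is re-joined (titles may themselves contain tabs) into ``stitle``.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"{path}:{lineno}: expected >=12 tab-separated columns, got {len(cols)}")
            if expect_stitle and len(cols) < 13:
                raise FormatError(f"{path}:{lineno}: stitle column missing (only 12 columns)")
            try:
                hit = BlastHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    pct_identity=float(cols[2]),
                    aln_length=int(cols[3]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                    stitle="\t".join(cols[12:]) if len(cols) > 12 else "",
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_blast_table(hits, path) -> None:
    """Write hits back out in the same fixed dialect (round-trip partner)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        str(h.aln_length),
                        "0", "0", "1", str(h.aln_length), "1", str(h.aln_length),
                        f"{h.evalue:.2e}",
                        f"{h.bitscore:.1f}",
                        h.stitle,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# bin / quality / coverage tables
# ---------------------------------------------------------------------------

def _read_tsv(path, expected_cols):
    df = pd.read_csv(path, sep="\t", dtype=str)
    lower = {c.lower(): c for c in df.columns}
    missing = [c for c in expected_cols if c not in lower]
    if missing:
        # fall back to positional columns for headerless-style tables
        df = pd.read_csv(path, sep="\t", dtype=str, header=None)
        if df.shape[1] < len(expected_cols):
            raise FormatError(f"{path}: need columns {expected_cols}, found {list(lower)}")
        df.columns = list(expected_cols) + [f"extra{i}" for i in range(df.shape[1] - len(expected_cols))]
        # the sniffed first row may have been a header
        if str(df.iloc[0, 0]).lower() in (expected_cols[0], expected_cols[0].lower()):
            df = df.iloc[1:].reset_index(drop=True)
        return df
    return df.rename(columns={lower[c]: c for c in expected_cols})


def _num(value, kind=float):
    """Parse a number, accepting thousands separators; blank -> None."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip().replace(",", "")
    if not s or s.lower() in ("na", "nan", "none", "x", "-"):
        return None
    return kind(float(s)) if kind is int else kind(s)


def read_bin_tables(assignments, quality, coverage) -> list[BinRecord]:
    """Join per-contig bin assignments with CheckM-style quality and coverage.

    Every bin named in *assignments* yields one :class:`BinRecord`; bins
    missing from the quality or coverage table get ``None`` metrics and a
    logged warning.  A contig assigned to two bins or duplicate bin rows in
    the quality/coverage tables raise :class:`ConsistencyError`.
    """
    asg = _read_tsv(assignments, ("contig_id", "bin_id"))
    dup = asg["contig_id"][asg["contig_id"].duplicated()]
    if not dup.empty:
        raise ConsistencyError(f"{assignments}: contig(s) assigned to two bins: {sorted(set(dup))[:5]}")

    qual = _read_tsv(quality, ("bin_id", "completeness", "contamination"))
    if qual["bin_id"].duplicated().any():
        raise ConsistencyError(f"{quality}: duplicate bin_id rows")
    cov = _read_tsv(coverage, ("bin_id", "coverage"))
    if cov["bin_id"].duplicated().any():
        raise ConsistencyError(f"{coverage}: duplicate bin_id rows")

    qual_by_bin = qual.set_index("bin_id")
    cov_by_bin = cov.set_index("bin_id")
    bins = []
    for bin_id, group in asg.groupby("bin_id", sort=True):
        rec = BinRecord(bin_id=str(bin_id), contig_ids=set(group["contig_id"]))
        if bin_id in qual_by_bin.index:
            row = qual_by_bin.loc[bin_id]
            rec.completeness = _num(row["completeness"])
            rec.contamination = _num(row["contamination"])
            if "marker_lineage" in qual.columns:
                rec.marker_lineage = row.get("marker_lineage")
        else:
            log.warning("bin %s missing from quality table %s", bin_id, quality)
        if bin_id in cov_by_bin.index:
            rec.coverage = _num(cov_by_bin.loc[bin_id, "coverage"])
        else:
            log.warning("bin %s missing from coverage table %s", bin_id, coverage)
        bins.append(rec)
    return bins


def read_bin_summary(path) -> list[BinRecord]:
    """Read a flat per-bin summary table (bin_id, completeness, contamination,
    contigs, size_bp, coverage, ...), the layout of published binning-result
    tables.  Thousands separators in sizes are accepted."""
    df = _read_tsv(path, ("bin_id", "completeness", "contamination"))
    if df["bin_id"].duplicated().any():
        raise ConsistencyError(f"{path}: duplicate bin_id rows")
    cols = {c.lower(): c for c in df.columns}
    out = []
    for _, row in df.iterrows():
        rec = BinRecord(
            bin_id=str(row["bin_id"]),
            completeness=_num(row["completeness"]),
            contamination=_num(row["contamination"]),
        )
        if "coverage" in cols:
            rec.coverage = _num(row[cols["coverage"]])
        if "size_bp" in cols:
            rec.size_bp = _num(row[cols["size_bp"]], int)
        if "contigs" in cols:
            rec.n_contigs = _num(row[cols["contigs"]], int)
        if "marker_lineage" in cols:
            rec.marker_lineage = row[cols["marker_lineage"]]
        out.append(rec)
    return out


def attach_contig_sizes(bins, contigs) -> None:
    """Fill BinRecord.size_bp from member contig lengths (in place).

    Contigs named in a bin but absent from *contigs* leave size_bp ``None``
    (flagged unknown) with a warning.
    """
    by_id = {c.id: c for c in contigs}
    for rec in bins:
        missing = [cid for cid in rec.contig_ids if cid not in by_id]
        if missing:
            log.warning("bin %s: %d contig(s) missing from FASTA; size unknown", rec.bin_id, len(missing))
            rec.size_bp = None
        else:
            rec.size_bp = sum(by_id[cid].length for cid in rec.contig_ids)


# ---------------------------------------------------------------------------
# feature tables (GFF3 or TSV)
# ---------------------------------------------------------------------------

#: normalised product/type strings -> internal feature type
FEATURE_SYNONYMS = {
    "16s ribosomal rna": "rRNA_16S",
    "16s rrna": "rRNA_16S",
    "rrna_16s": "rRNA_16S",
    "ssu rrna": "rRNA_16S",
    "23s ribosomal rna": "rRNA_23S",
    "23s rrna": "rRNA_23S",
    "rrna_23s": "rRNA_23S",
    "lsu rrna": "rRNA_23S",
    "5s ribosomal rna": "rRNA_5S",
    "5s rrna": "rRNA_5S",
    "rrna_5s": "rRNA_5S",
    "trna": "tRNA",
}


def _map_feature_type(*texts, synonyms=None) -> str:
    table = FEATURE_SYNONYMS if synonyms is None else synonyms
    for text in texts:
        if not text:
            continue
        key = str(text).strip().lower()
        if key in table:
            return table[key]
        if key.startswith("trna"):
            return "tRNA"
    return "other"


def read_features(path, synonyms=None) -> list[FeatureRecord]:
    """Read rRNA/tRNA feature locations from GFF3 or a 5-column TSV.

    TSV columns: contig_id, feature_type, start, end, strand.  Coordinates
    are 1-based inclusive in both formats.  Unknown types map to "other".
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return []
    is_gff = path.suffix.lower() in (".gff", ".gff3") or text.lstrip().startswith("##gff")
    records = []
    if is_gff:
        from gffutils.feature import feature_from_line

        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            feat = feature_from_line(line)
            product = (feat.attributes.get("product") or [None])[0]
            ftype = _map_feature_type(product, feat.featuretype, synonyms=synonyms)
            records.append(
                FeatureRecord(
                    contig_id=feat.seqid,
                    feature_type=ftype,
                    start=int(feat.start),
                    end=int(feat.end),
                    strand=feat.strand if feat.strand in "+-" else "+",
                )
            )
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if lineno == 1 and cols[0].lower() == "contig_id":
                continue
            if len(cols) < 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            records.append(
                FeatureRecord(
                    contig_id=cols[0],
                    feature_type=_map_feature_type(cols[1], synonyms=synonyms),
                    start=int(cols[2]),
                    end=int(cols[3]),
                    strand=cols[4] if cols[4] in "+-" else "+",
                )
            )
    return records


# ---------------------------------------------------------------------------
# report writer
# ---------------------------------------------------------------------------

def write_report(records, path, percent_cols=()) -> None:
    """Write a homogeneous record list (dicts, dataclasses or a DataFrame)
    as a UTF-8 TSV with a header row; percent columns render two decimals."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = []
        for rec in records:
            if hasattr(rec, "__dataclass_fields__"):
                rows.append({k: getattr(rec, k) for k in rec.__dataclass_fields__})
            else:
                rows.append(dict(rec))
        keys = list(rows[0]) if rows else []
        if any(list(r) != keys for r in rows):
            raise ValueError("records are not homogeneous")
        df = pd.DataFrame(rows, columns=keys)
    for col in percent_cols:
        if col in df.columns:
            df[col] = df[col].map(lambda v: "" if v is None or pd.isna(v) else f"{float(v):.2f}")
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
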