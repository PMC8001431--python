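"""Community composition of a cyanobacterial culture's microbiome.

Bins passing a completeness/coverage filter are assigned to lineage
categories (Cyanobacteria, Alpha- and Betaproteobacteria, Bacteroidetes,
Actinobacteria, other) and summarised under three abundance views: share of
bins, share of attributed DNA (genome size x coverage, with an extra
below-completeness category), and share of genome coverage.  Coverage acts
as a genome-equivalent proxy, so the phototroph:heterotroph ratio is the
summed heterotroph coverage over the host's coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .formats_io import BinRecord
from .lexicon import Lexicon, default_lexicon
from .markers import TaxonCall

log = logging.getLogger("cyanosphere")

CATEGORIES = (
    "Cyanobacteria",
    "Alphaproteobacteria",
    "Betaproteobacteria",
    "Bacteroidetes",
    "Actinobacteria",
    "other",
)

#: display palette; below_completeness is the light-gray DNA-view category
PALETTE = {
    "Cyanobacteria": "#4daf4a",
    "Alphaproteobacteria": "#377eb8",
    "Betaproteobacteria": "#984ea3",
    "Bacteroidetes": "#ff7f00",
    "Actinobacteria": "#e41a1c",
    "other": "#555555",
    "below_completeness": "#bbbbbb",
}


@dataclass
class CommunityProfile:
    host_bin_id: str
    bin_count_share: dict = field(default_factory=dict)  # category -> %
    dna_share: dict = field(default_factory=dict)  # incl. below_completeness
    coverage_share: dict = field(default_factory=dict)
    ratio_n: float | None = None  # phototroph:heterotroph = 1:N
    n_passing: int = 0
    n_below: int = 0

    @property
    def ratio(self) -> str:
        return "undefined" if self.ratio_n is None else f"1:{self.ratio_n:.1f}"


def filter_bins(bins, completeness_min: float = 80.0, coverage_min: float = 25.0):
    """Split bins into (passing, below-threshold).

    Passing means completeness at or above ``completeness_min`` AND coverage
    strictly above ``coverage_min``.  Unknown (null) metrics send a bin to
    the below-threshold set with a warning.
    """
    passing, below = [], []
    for rec in bins:
        if rec.completeness is None or rec.coverage is None:
            log.warning("bin %s has unknown completeness/coverage; treated as below threshold",
                        rec.bin_id)
            below.append(rec)
        elif rec.completeness >= completeness_min and rec.coverage > coverage_min:
            passing.append(rec)
        else:
            below.append(rec)
    return passing, below


def categorize(bin_record: BinRecord, call: TaxonCall | None,
               lineage_map: dict | None = None, lexicon: Lexicon | None = None,
               host_bin_id: str | None = None) -> str:
    """Map a bin to its lineage category via its taxon call.

    An explicit ``lineage_map`` (name -> category, case-insensitive) wins;
    otherwise the lexicon resolves the call's name to a class/phylum
    category.  The host bin is always Cyanobacteria; unclassified or unknown
    names go to "other" with a log entry.
    """
    if host_bin_id is not None and bin_record.bin_id == host_bin_id:
        return "Cyanobacteria"
    if call is None or call.rank is None or not call.name or call.name == "unclassified":
        return "other"
    if lineage_map:
        lowered = {k.lower(): v for k, v in lineage_map.items()}
        hit = lowered.get(call.name.lower())
        if hit:
            return hit
    lexicon = lexicon or default_lexicon()
    category = lexicon.category_of(call.name)
    if category == "other":
        log.info("bin %s: name %r not in lineage map; categorised as other",
                 bin_record.bin_id, call.name)
    return category


def abundance_views(passing_with_categories, below_bins, host_bin_id: str) -> CommunityProfile:
    """Compute the three abundance views and the phototroph:heterotroph ratio.

    ``passing_with_categories`` is a list of ``(BinRecord, category)``.  Bin
    and coverage shares are over passing bins only; the DNA view (size_bp x
    coverage) additionally carries a below_completeness slice for the
    below-threshold bins.  The ratio N in "1:N" is total passing heterotroph
    coverage over host coverage, one decimal.
    """
    passing = list(passing_with_categories)
    if not any(rec.bin_id == host_bin_id for rec, _ in passing):
        raise ValueError(f"host bin {host_bin_id!r} not among passing bins")

    profile = CommunityProfile(host_bin_id=host_bin_id,
                               n_passing=len(passing), n_below=len(below_bins))

    n = len(passing)
    for cat in CATEGORIES:
        profile.bin_count_share[cat] = 100.0 * sum(1 for _, c in passing if c == cat) / n

    def dna(rec):
        if rec.size_bp is None or rec.coverage is None:
            return 0.0
        return rec.size_bp * rec.coverage

    dna_total = sum(dna(rec) for rec, _ in passing) + sum(dna(rec) for rec in below_bins)
    if dna_total > 0:
        for cat in CATEGORIES:
            profile.dna_share[cat] = 100.0 * sum(dna(r) for r, c in passing if c == cat) / dna_total
        profile.dna_share["below_completeness"] = (
            100.0 * sum(dna(r) for r in below_bins) / dna_total
        )

    cov_total = sum(rec.coverage or 0.0 for rec, _ in passing)
    host_cov = next(rec.coverage for rec, _ in passing if rec.bin_id == host_bin_id)
    if cov_total > 0:
        for cat in CATEGORIES:
            profile.coverage_share[cat] = (
                100.0 * sum((r.coverage or 0.0) for r, c in passing if c == cat) / cov_total
            )
    if host_cov:
        profile.ratio_n = round((cov_total - host_cov) / host_cov, 1)
    return profile


def wordcloud_export(passing_with_calls, host_bin_id: str | None = None,
                     lexicon: Lexicon | None = None) -> pd.DataFrame:
    """Weight table for a word-cloud rendering: one row per passing bin with
    (display_name, weight = coverage, color = category hex).  Unclassified
    bins display their bin id in dark gray."""
    rows = []
    for rec, call in passing_with_calls:
        category = categorize(rec, call, lexicon=lexicon, host_bin_id=host_bin_id)
        named = call is not None and call.rank is not None and call.name != "unclassified"
        rows.append(
            {
                "display_name": call.name if named else rec.bin_id,
                "weight": rec.coverage,
                "color": PALETTE[category],
                "category": category,
            }
        )
    return pd.DataFrame(rows, columns=["display_name", "weight", "color", "category"])
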