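"""Multi-binner concordance analysis for a target organism's contigs.

Contigs from the compared bins are labelled by nucleotide BLAST evidence as
belonging to the target organism ("target", e.g. cyanobacterial), to some
other organism ("other"), or as having no passing hit ("no_hit").  The
binners' contig sets are then partitioned into Venn regions and each
binner's recovery of the authentic target contigs is reported.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .textmine import tokenize_title

LABELS = ("target", "other", "no_hit")


@dataclass(frozen=True)
class ContigLabel:
    contig_id: str
    label: str  # target | other | no_hit


@dataclass
class VennPartition:
    """Disjoint regions of up to three binner contig sets.

    ``regions`` maps a frozenset of binner names (the binners containing the
    region) to the region's contig-id set; ``label_counts`` holds per-region
    counts split by contig label.
    """

    binners: tuple
    regions: dict = field(default_factory=dict)
    label_counts: dict = field(default_factory=dict)


def label_contigs(hits, target_name_set, identity_min: float = 90.0,
                  evalue_max: float = 1e-10) -> list[ContigLabel]:
    """Label each query contig by its passing BLAST hits.

    A hit passes with identity strictly above ``identity_min`` and e-value
    strictly below ``evalue_max``.  A contig is "target" when any passing
    hit's title contains a token from ``target_name_set`` (case-insensitive),
    "other" when it has passing hits but none match, "no_hit" otherwise.
    """
    targets = {t.lower() for t in target_name_set}
    status: dict[str, str] = {}
    for hit in hits:
        qid = hit.query_id
        status.setdefault(qid, "no_hit")
        if not (hit.pct_identity > identity_min and hit.evalue < evalue_max):
            continue
        tokens = {t.lower() for t in tokenize_title(hit.stitle, stopwords=frozenset())}
        if tokens & targets:
            status[qid] = "target"
        elif status[qid] != "target":
            status[qid] = "other"
    return [ContigLabel(cid, lab) for cid, lab in status.items()]


def venn_partition(bin_sets: dict, labels=None) -> VennPartition:
    """Partition 2 or 3 binner contig sets into standard Venn regions."""
    binners = tuple(bin_sets)
    if not 2 <= len(binners) <= 3:
        raise ValueError(f"venn_partition supports 2 or 3 binners, got {len(binners)}; "
                         "report pairwise comparisons instead")
    label_by_contig = {l.contig_id: l.label for l in (labels or [])}
    universe = set().union(*bin_sets.values())
    part = VennPartition(binners=binners)
    for k in range(len(binners), 0, -1):
        for combo in combinations(binners, k):
            part.regions[frozenset(combo)] = set()
    for contig in universe:
        members = frozenset(b for b in binners if contig in bin_sets[b])
        part.regions[members].add(contig)
    for region, contigs in part.regions.items():
        part.label_counts[region] = Counter(
            label_by_contig.get(c, "no_hit") for c in contigs
        )
    return part


def recovery_stats(bin_sets: dict, labels) -> pd.DataFrame:
    """Per-binner recovery and precision of target-labelled contigs.

    The reference set is the union over binners of target-labelled contigs;
    recovery is each binner's share of it (percent, two decimals), precision
    the target fraction within the binner's own set.  An empty reference set
    yields null recovery.
    """
    target_ids = {l.contig_id for l in labels if l.label == "target"}
    union = set().union(*bin_sets.values())
    reference = target_ids & union
    rows = []
    for binner, contigs in bin_sets.items():
        in_ref = len(contigs & reference)
        rows.append(
            {
                "binner": binner,
                "recovery_pct": round(100.0 * in_ref / len(reference), 2) if reference else None,
                "precision_pct": round(100.0 * len(contigs & target_ids) / len(contigs), 2)
                if contigs
                else None,
                "n_target_recovered": in_ref,
                "n_in_bin": len(contigs),
                "n_reference": len(reference),
            }
        )
    return pd.DataFrame(rows)
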