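"""Marker-based taxonomy: 16S novelty calling, RpoB species rule, chimera
screening, evidence integration across channels, and MAG quality tiering.

16S rRNA best-hit identities are compared against a ladder of rank
thresholds (Yarza et al. 2014 style: a sequence whose identity to its
closest relative falls strictly below the genus threshold of 94.5% likely
represents a new genus, below the family threshold of 86.5% a new family,
and so on).  RpoB amino-acid identity of at least 96% to a reference places
a bin in the same species.  The integrator combines CheckM marker lineages,
16S novelty, RpoB and text-mining calls into one conservative taxon call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .lexicon import RANKS, RANK_DEPTH, Lexicon, default_lexicon


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class TaxonCall:
    """A taxonomic assignment for a bin.

    ``rank`` is ``None`` only for unclassified text-mining results; every
    integrated call carries a rank.
    """

    bin_id: str
    rank: str | None
    name: str
    evidence: set = field(default_factory=set)
    identity: float | None = None
    dominance: float | None = None
    ambiguous: bool = False
    conflict: bool = False
    note: str = ""

    def __post_init__(self):
        if self.rank is not None and self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")


@dataclass
class NoveltyCall:
    sequence_id: str
    best_hit_name: str
    best_identity: float
    proposed_level: str  # "none" or the rank at which the sequence is new


@dataclass
class RpoBCall:
    best_hit_name: str
    identity: float
    rank: str | None  # species / genus / family, None when under-sampled
    name: str
    undersampled: bool = False


@dataclass
class ChimeraVerdict:
    verdict: str  # consistent | possible chimera | untested
    name_5prime: str | None = None
    name_3prime: str | None = None


@dataclass
class QualityTier:
    tier: str  # high-quality draft | medium | low
    completeness_ok: bool
    contamination_ok: bool
    rrna_ok: bool
    trna_ok: bool


class ThresholdLadder:
    """Ordered rank -> minimum-identity thresholds for 16S novelty calling.

    The genus (94.5) and family (86.5) values are the published 16S cutoffs
    used directly here; species (98.7), order (82.0), class (78.5) and
    phylum (75.0) are the remaining Yarza et al. (2014) ladder entries,
    included as configurable defaults.
    """

    DEFAULTS = {
        "species": 98.7,
        "genus": 94.5,
        "family": 86.5,
        "order": 82.0,
        "class": 78.5,
        "phylum": 75.0,
    }

    def __init__(self, thresholds: dict | None = None):
        self.thresholds = dict(thresholds) if thresholds is not None else dict(self.DEFAULTS)
        ordered = [r for r in RANKS if r in self.thresholds]
        values = [self.thresholds[r] for r in ordered]  # broad -> narrow
        if any(not 0 <= v <= 100 for v in values):
            raise ValueError("thresholds must be in [0,100]")
        if any(a >= b for a, b in zip(values, values[1:])):
            raise ValueError("thresholds must strictly increase with narrower rank")
        #: narrowest rank first (species ... phylum)
        self.ranks_narrow_to_broad = list(reversed(ordered))


DEFAULT_LADDER = ThresholdLadder()


# ---------------------------------------------------------------------------
# 16S novelty and chimera screen
# ---------------------------------------------------------------------------

def call_16s_novelty(best_identity: float, ladder: ThresholdLadder | None = None,
                     sequence_id: str = "", best_hit_name: str = "") -> NoveltyCall:
    """Propose the rank at which a 16S sequence represents a new taxon.

    Thresholds are minimum identities for membership: identity strictly
    below a rank's threshold means novelty at that rank; the broadest rank
    whose threshold is still exceeded wins (89.53% -> new genus, 82.02% ->
    new family).  Identity at or above every threshold -> "none".
    """
    if not 0 <= best_identity <= 100:
        raise ValueError(f"identity out of range: {best_identity}")
    ladder = ladder or DEFAULT_LADDER
    proposed = "none"
    for rank in ladder.ranks_narrow_to_broad:
        if best_identity < ladder.thresholds[rank]:
            proposed = rank
        else:
            break
    return NoveltyCall(sequence_id, best_hit_name, best_identity, proposed)


def bisect_chimera_check(best_hit_5prime, best_hit_3prime, rank: str = "genus",
                         lexicon: Lexicon | None = None) -> ChimeraVerdict:
    """Compare the best hits of the 5' and 3' halves of a 16S sequence.

    Consistent halves (same genus, or same name at the configured rank via
    the lexicon) argue against a chimeric assembly.  A missing half yields
    "untested".
    """
    if not best_hit_5prime or not best_hit_3prime:
        return ChimeraVerdict("untested", best_hit_5prime or None, best_hit_3prime or None)

    def name_at_rank(name: str) -> str:
        if lexicon is not None:
            entry = lexicon.lookup(name)
            if entry is not None and entry.ancestor(rank):
                return entry.ancestor(rank).lower()
        return name.split()[0].rstrip(".,;").lower()

    same = name_at_rank(best_hit_5prime) == name_at_rank(best_hit_3prime)
    return ChimeraVerdict("consistent" if same else "possible chimera",
                          best_hit_5prime, best_hit_3prime)


# ---------------------------------------------------------------------------
# RpoB rule
# ---------------------------------------------------------------------------

def call_rpob(best_identity: float, best_hit_name: str, species_threshold: float = 96.0,
              genus_min: float = 90.0, undersampled_floor: float = 85.0,
              lexicon: Lexicon | None = None) -> RpoBCall:
    """Classify from an RpoB amino-acid best-hit identity.

    At least ``species_threshold`` (inclusive) -> same species as the best
    hit; the 90–96 band -> genus level (an artifact convention, surfaced in
    the parameters — no published genus cutoff exists); the 85–90 band ->
    family level via the lexicon; below ``undersampled_floor`` the lineage is
    flagged as non- or under-sampled and no rank is assigned.
    """
    genus = best_hit_name.split()[0].rstrip(".,;") if best_hit_name else ""
    if best_identity >= species_threshold:
        return RpoBCall(best_hit_name, best_identity, "species", best_hit_name)
    if best_identity >= genus_min:
        return RpoBCall(best_hit_name, best_identity, "genus", genus)
    if best_identity >= undersampled_floor:
        lexicon = lexicon or default_lexicon()
        entry = lexicon.lookup(genus)
        family = entry.ancestor("family") if entry else None
        return RpoBCall(best_hit_name, best_identity, "family", family or genus)
    return RpoBCall(best_hit_name, best_identity, None, best_hit_name, undersampled=True)


# ---------------------------------------------------------------------------
# evidence integration
# ---------------------------------------------------------------------------

_CHECKM_PREFIXES = {"k": "kingdom", "p": "phylum", "c": "class", "o": "order",
                    "f": "family", "g": "genus", "s": "species"}


def parse_checkm_lineage(lineage: str | None, lexicon: Lexicon | None = None):
    """Turn a CheckM marker-lineage string ('k__Bacteria', 'o__Rhizobiales'
    or a plain name) into (rank, name); unknown/'root' -> kingdom Bacteria."""
    if not lineage or lineage.strip().lower() in ("root", "bacteria"):
        return "kingdom", "Bacteria"
    lineage = lineage.strip().split("(")[0].strip()
    if "__" in lineage:
        prefix, name = lineage.split("__", 1)
        rank = _CHECKM_PREFIXES.get(prefix.strip().lower())
        if rank:
            return rank, name.strip()
    lexicon = lexicon or default_lexicon()
    entry = lexicon.lookup(lineage)
    if entry is not None:
        return entry.rank, entry.name
    return "kingdom", "Bacteria"


def _lift(name: str, from_rank: str, to_rank: str, lexicon: Lexicon) -> str | None:
    """Name of *name*'s ancestor at ``to_rank`` (via lexicon), else None."""
    if from_rank == to_rank:
        return name
    entry = lexicon.lookup(name)
    if entry is not None:
        return entry.ancestor(to_rank)
    return None


def integrate_calls(bin_id: str, checkm_lineage: str | None = None,
                    novelty: NoveltyCall | None = None, rpob: RpoBCall | None = None,
                    textmine: TaxonCall | None = None,
                    lexicon: Lexicon | None = None) -> TaxonCall:
    """Combine evidence channels into one taxon call for a bin.

    The deepest rank supported by at least one channel and contradicted by
    none wins.  A 16S novelty proposal caps the assignable rank one level
    above the novel rank (a new genus can at most be placed in a family).
    Conflicting names at the winning rank fall back to the deepest rank at
    which the channels' lineages agree, with the conflict flagged.  With no
    evidence at all, the call is kingdom-level "Bacteria" with an empty
    evidence set.
    """
    lexicon = lexicon or default_lexicon()
    proposals = []  # (channel, rank, name)
    if checkm_lineage:
        rank, name = parse_checkm_lineage(checkm_lineage, lexicon)
        proposals.append(("checkm", rank, name))
    if rpob is not None and rpob.rank is not None:
        proposals.append(("rpoB", rpob.rank, rpob.name))
    if textmine is not None and textmine.rank is not None and not textmine.ambiguous:
        proposals.append(("textmine", textmine.rank, textmine.name))

    ranked = [(ch, r, n) for ch, r, n in proposals if r is not None and n]
    if not ranked:
        flagged = bool(novelty is not None or (textmine is not None))
        return TaxonCall(bin_id=bin_id, rank="kingdom", name="Bacteria",
                         evidence=set(), note="no evidence" if not flagged else "no rankable evidence")

    cap_depth = RANK_DEPTH["species"]
    if novelty is not None and novelty.proposed_level != "none":
        cap_depth = max(RANK_DEPTH[novelty.proposed_level] - 1, RANK_DEPTH["kingdom"])

    # lift proposals deeper than the cap to the cap rank where possible
    capped = []
    cap_rank = RANKS[cap_depth]
    for ch, rank, name in ranked:
        if RANK_DEPTH[rank] > cap_depth:
            lifted = _lift(name, rank, cap_rank, lexicon)
            capped.append((ch, cap_rank, lifted) if lifted else (ch, cap_rank, name))
        else:
            capped.append((ch, rank, name))

    winning_depth = max(RANK_DEPTH[r] for _, r, _ in capped)
    winning_rank = RANKS[winning_depth]
    at_rank = {}
    for ch, rank, name in capped:
        lifted = _lift(name, rank, winning_rank, lexicon) if RANK_DEPTH[rank] < winning_depth else None
        if rank == winning_rank:
            at_rank[ch] = name
        elif lifted:
            at_rank[ch] = lifted

    extra_evidence = {"16S"} if novelty is not None else set()
    names = {n.lower(): n for n in at_rank.values()}
    if len(names) == 1:
        name = next(iter(names.values()))
        evidence = {ch for ch, _, _ in capped} | extra_evidence
        identity = rpob.identity if rpob is not None and "rpoB" in at_rank else None
        if winning_rank == "species" and not (rpob is not None and rpob.rank == "species"):
            # species calls need the protein-marker rule behind them
            winning_rank, name = "genus", name.split()[0]
        return TaxonCall(bin_id=bin_id, rank=winning_rank, name=name,
                         evidence=evidence, identity=identity)

    # conflict at the winning rank: climb to the deepest agreed rank
    conflict_note = "conflict: " + " vs ".join(sorted(at_rank[ch] for ch in sorted(at_rank)))
    for depth in range(winning_depth - 1, -1, -1):
        rank = RANKS[depth]
        lifted = {}
        for ch, r, n in capped:
            up = _lift(n, r, rank, lexicon)
            if up:
                lifted[ch] = up
        distinct = {n.lower(): n for n in lifted.values()}
        if lifted and len(distinct) == 1:
            return TaxonCall(bin_id=bin_id, rank=rank, name=next(iter(distinct.values())),
                             evidence={ch for ch, _, _ in capped} | extra_evidence,
                             conflict=True, note=conflict_note)
    return TaxonCall(bin_id=bin_id, rank="kingdom", name="Bacteria",
                     evidence={ch for ch, _, _ in capped} | extra_evidence,
                     conflict=True, note=conflict_note)


def flag_eukaryote(best_hit_name: str, lexicon: Lexicon | None = None) -> bool:
    """True when a marker best-hit name resolves to a eukaryote.

    Such sequences are reported separately and never integrated into a
    bacterial bin's taxon call.
    """
    lexicon = lexicon or default_lexicon()
    return lexicon.is_eukaryote(best_hit_name)


# ---------------------------------------------------------------------------
# MAG quality tiering
# ---------------------------------------------------------------------------

def mag_quality_tier(completeness: float, contamination: float, rrna_present,
                     trna_count: int, trna_min: int = 18,
                     require_trna: bool = True) -> QualityTier:
    """MIMAG-style quality tier with per-criterion booleans.

    High-quality draft: completeness > 90, contamination < 5, all of the
    16S/23S/5S rRNA genes present and (configurably) >= 18 tRNAs.  Medium:
    completeness >= 50 and contamination < 10.  Otherwise low.
    """
    rrna = set(rrna_present)
    completeness_ok = completeness > 90
    contamination_ok = contamination < 5
    rrna_ok = {"16S", "23S", "5S"} <= rrna
    trna_ok = trna_count >= trna_min
    criteria = [completeness_ok, contamination_ok, rrna_ok] + ([trna_ok] if require_trna else [])
    if all(criteria):
        tier = "high-quality draft"
    elif completeness >= 50 and contamination < 10:
        tier = "medium"
    else:
        tier = "low"
    return QualityTier(tier, completeness_ok, contamination_ok, rrna_ok, trna_ok)
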