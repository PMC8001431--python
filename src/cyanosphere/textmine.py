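"""BLASTN-dependent text-mining taxonomy for metagenomic bins.

For every contig the subject titles of its best nucleotide-database hits
(e-value strictly below a cutoff, identity strictly above a cutoff, at most
``top_hits`` titles) are tokenised, uninformative words ("complete",
"genome", "DNA", "sequence", "sp.", "strain", "assembly") are dropped, and
the most common words per bin are counted.  The leading word that matches a
known taxon name yields the bin's text-mining taxon call.

An exact-substring adapter screen guards the classifier against residual
library adapters in assembled sequences — untrimmed adapters otherwise make
vector/artifact titles dominate the word counts (the "carp artifact").
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from Bio.Seq import reverse_complement

from .formats_io import BlastHit, BinRecord
from .lexicon import Lexicon, default_lexicon
from .markers import TaxonCall

log = logging.getLogger("cyanosphere")

#: Illumina library primer/adapter sequences screened out before text mining
DEFAULT_ADAPTERS = (
    "AATGATACGGCGACCACCGAGATCT",
    "GTATGCCGTCTTCTGC",
    "AAGAGCGTCGTGTAGGGAAAGA",
    "GATCGGAAGAGCACACGTCTGAACTCCAGTCAC",
)

DEFAULT_STOPWORDS = frozenset({"complete", "genome", "DNA", "sequence", "sp.", "strain", "assembly"})


@dataclass
class TextMineConfig:
    evalue_max: float = 1e-10
    identity_min: float = 90.0
    top_hits: int = 20
    top_words: int = 20
    stopwords: frozenset = DEFAULT_STOPWORDS
    adapters: tuple = DEFAULT_ADAPTERS

    def __post_init__(self):
        if self.top_hits < 1 or self.top_words < 1:
            raise ValueError("top_hits and top_words must be >= 1")
        if not 0 <= self.identity_min <= 100:
            raise ValueError("identity_min must be in [0,100]")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")


@dataclass
class WordProfile:
    bin_id: str
    ranked_words: list  # [(word, count)], counts non-increasing
    n_contigs_with_hits: int
    n_contigs_total: int


@dataclass
class AdapterFlag:
    contig_id: str
    adapter_index: int  # 1-based position in the adapter list
    position: int  # 1-based match start on the contig
    orientation: str  # "forward" | "reverse_complement"


# ---------------------------------------------------------------------------
# adapter screen
# ---------------------------------------------------------------------------

def screen_adapters(contigs, adapters=DEFAULT_ADAPTERS) -> list[AdapterFlag]:
    """Flag contigs carrying any adapter as an exact substring, on either
    strand.  Contigs without sequence are skipped with a warning."""
    flags = []
    for contig in contigs:
        if contig.sequence is None:
            log.warning("contig %s has no sequence; adapter screen skipped", contig.id)
            continue
        seq = contig.sequence.upper()
        for idx, adapter in enumerate(adapters, start=1):
            for query, orient in ((adapter.upper(), "forward"),
                                  (reverse_complement(adapter.upper()), "reverse_complement")):
                pos = seq.find(query)
                if pos >= 0:
                    flags.append(AdapterFlag(contig.id, idx, pos + 1, orient))
    return flags


# ---------------------------------------------------------------------------
# hit filtering
# ---------------------------------------------------------------------------

def filter_hits(hits, cfg: TextMineConfig | None = None):
    """Per query: keep hits with e-value strictly below ``evalue_max`` AND
    identity strictly above ``identity_min``, then truncate to the
    ``top_hits`` best by ascending e-value (ties: descending bitscore, then
    input order).

    Returns ``(kept, no_hit)``: a dict query -> surviving hits, and the list
    of queries that had hits in the input but none surviving.
    """
    cfg = cfg or TextMineConfig()
    by_query: dict[str, list] = defaultdict(list)
    order: dict[str, int] = {}
    for i, hit in enumerate(hits):
        order.setdefault(hit.query_id, len(order))
        by_query[hit.query_id].append((i, hit))

    kept: dict[str, list] = {}
    no_hit: list[str] = []
    for query in sorted(by_query, key=order.get):
        passing = [
            (i, h)
            for i, h in by_query[query]
            if h.evalue < cfg.evalue_max and h.pct_identity > cfg.identity_min
        ]
        passing.sort(key=lambda ih: (ih[1].evalue, -ih[1].bitscore, ih[0]))
        if passing:
            kept[query] = [h for _, h in passing[: cfg.top_hits]]
        else:
            no_hit.append(query)
    return kept, no_hit


# ---------------------------------------------------------------------------
# tokenizer
# ---------------------------------------------------------------------------

_STRIP_CHARS = ",;:()[]{}<>'\"`!?*/\\|="
_NUMERIC_RE = re.compile(r"[\d.,–-]+$")


def _stop_set(stopwords) -> frozenset:
    out = set()
    for w in stopwords:
        out.add(w.lower())
        out.add(w.lower().rstrip("."))
    return frozenset(out)


def tokenize_title(stitle: str, stopwords=DEFAULT_STOPWORDS) -> list[str]:
    """Split a subject title into informative tokens.

    Tokens are whitespace-separated; leading/trailing punctuation is stripped
    (internal hyphens and dots are kept, so "sp." still matches its
    stopword); stopwords are dropped case-insensitively, as are tokens
    shorter than two characters, pure punctuation and pure numbers.
    """
    stops = _stop_set(stopwords)
    tokens = []
    for raw in stitle.split():
        token = raw.strip(_STRIP_CHARS)
        if len(token) < 2:
            continue
        if _NUMERIC_RE.fullmatch(token):
            continue
        low = token.lower()
        if low in stops or low.rstrip(".") in stops:
            continue
        tokens.append(token)
    return tokens


# ---------------------------------------------------------------------------
# per-bin profiling
# ---------------------------------------------------------------------------

def profile_bin(bin_record: BinRecord, kept_hits, cfg: TextMineConfig | None = None) -> WordProfile:
    """Count title words over all kept hits of the bin's member contigs.

    Each title contributes each of its tokens once per occurrence; the
    ``top_words`` most common words are reported, ties broken alphabetically.
    """
    cfg = cfg or TextMineConfig()
    if not bin_record.contig_ids:
        raise ValueError(f"bin {bin_record.bin_id} has no contigs")
    counts: Counter = Counter()
    n_with_hits = 0
    for contig_id in sorted(bin_record.contig_ids):
        contig_hits = kept_hits.get(contig_id, [])
        if contig_hits:
            n_with_hits += 1
        for hit in contig_hits:
            counts.update(tokenize_title(hit.stitle, cfg.stopwords))
    ranked = sorted(counts.items(), key=lambda wc: (-wc[1], wc[0]))[: cfg.top_words]
    return WordProfile(
        bin_id=bin_record.bin_id,
        ranked_words=ranked,
        n_contigs_with_hits=n_with_hits,
        n_contigs_total=len(bin_record.contig_ids),
    )


def infer_dominant_taxon(profile: WordProfile, lexicon: Lexicon | None = None) -> TaxonCall:
    """Turn a word profile into a taxon call.

    The highest-ranked word matching a known genus gives a genus-level call;
    if only broader-rank names match, the call is made at that rank; with no
    match at all the call is "unclassified" (rank ``None``) carrying the raw
    profile.  A tie in counts between two distinct genera flags the call as
    ambiguous.  The dominance score is the leading matching word's count over
    the total counts of the reported words.
    """
    lexicon = lexicon or default_lexicon()
    total = sum(c for _, c in profile.ranked_words)
    matches = []  # (word, count, entry)
    for word, count in profile.ranked_words:
        entry = lexicon.lookup(word)
        if entry is not None:
            matches.append((word, count, entry))

    genus_matches = [(w, c, e) for w, c, e in matches if e.rank == "genus"]
    if genus_matches:
        word, count, entry = genus_matches[0]
        tied = sorted({e.name for w, c, e in genus_matches if c == count and e.name != entry.name})
        return TaxonCall(
            bin_id=profile.bin_id,
            rank="genus",
            name=entry.name,
            evidence={"textmine"},
            dominance=(count / total) if total else None,
            ambiguous=bool(tied),
            note=("tied with " + ", ".join(tied)) if tied else "",
        )
    if matches:
        word, count, entry = matches[0]
        return TaxonCall(
            bin_id=profile.bin_id,
            rank=entry.rank,
            name=entry.name,
            evidence={"textmine"},
            dominance=(count / total) if total else None,
        )
    return TaxonCall(
        bin_id=profile.bin_id,
        rank=None,
        name="unclassified",
        evidence={"textmine"},
        note="; ".join(f"{w}:{c}" for w, c in profile.ranked_words),
    )


def classify_bins(bins, hits, cfg: TextMineConfig | None = None, lexicon: Lexicon | None = None):
    """Convenience pipeline: filter hits once, then profile and call each bin.

    Returns ``(profiles, calls)`` keyed by bin id.
    """
    cfg = cfg or TextMineConfig()
    kept, _ = filter_hits(hits, cfg)
    profiles, calls = {}, {}
    for rec in bins:
        profile = profile_bin(rec, kept, cfg)
        profiles[rec.bin_id] = profile
        calls[rec.bin_id] = infer_dominant_taxon(profile, lexicon)
    return profiles, calls
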