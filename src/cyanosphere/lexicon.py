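"""Built-in taxon-name lexicon.

A small reference taxonomy (~60 names spanning cyanobacteria and the
heterotroph lineages typically found in their cultures) so that taxonomic
name lookup, lineage-aware call integration and lineage categorisation work
out of the box, without an NCBI taxonomy dump.  Users can extend or replace
it with their own :class:`Lexicon`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: rank name -> depth (kingdom shallowest)
RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}


@dataclass(frozen=True)
class TaxonEntry:
    """One named taxon with its rank and ancestor names per rank."""

    name: str
    rank: str
    lineage: dict = field(default_factory=dict)  # rank -> ancestor name (incl. self)

    def ancestor(self, rank: str) -> str | None:
        return self.lineage.get(rank)


# genus, family, order, class, phylum  (kingdom Bacteria unless noted)
_BACTERIA = [
    # Cyanobacteria
    ("Stigonema", "Stigonemataceae", "Nostocales", "Cyanophyceae", "Cyanobacteria"),
    ("Nostoc", "Nostocaceae", "Nostocales", "Cyanophyceae", "Cyanobacteria"),
    ("Anabaena", "Nostocaceae", "Nostocales", "Cyanophyceae", "Cyanobacteria"),
    ("Chlorogloea", "Entophysalidaceae", "Chroococcales", "Cyanophyceae", "Cyanobacteria"),
    ("Gomphosphaeria", "Gomphosphaeriaceae", "Chroococcales", "Cyanophyceae", "Cyanobacteria"),
    ("Microcystis", "Microcystaceae", "Chroococcales", "Cyanophyceae", "Cyanobacteria"),
    ("Synechocystis", "Merismopediaceae", "Chroococcales", "Cyanophyceae", "Cyanobacteria"),
    ("Synechococcus", "Synechococcaceae", "Synechococcales", "Cyanophyceae", "Cyanobacteria"),
    # Alphaproteobacteria
    ("Devosia", "Hyphomicrobiaceae", "Rhizobiales", "Alphaproteobacteria", "Proteobacteria"),
    ("Bosea", "Boseaceae", "Rhizobiales", "Alphaproteobacteria", "Proteobacteria"),
    ("Bradyrhizobium", "Bradyrhizobiaceae", "Rhizobiales", "Alphaproteobacteria", "Proteobacteria"),
    ("Rhizobium", "Rhizobiaceae", "Rhizobiales", "Alphaproteobacteria", "Proteobacteria"),
    ("Mesorhizobium", "Phyllobacteriaceae", "Rhizobiales", "Alphaproteobacteria", "Proteobacteria"),
    ("Sphingomonas", "Sphingomonadaceae", "Sphingomonadales", "Alphaproteobacteria", "Proteobacteria"),
    ("Sphingopyxis", "Sphingomonadaceae", "Sphingomonadales", "Alphaproteobacteria", "Proteobacteria"),
    ("Novosphingobium", "Sphingomonadaceae", "Sphingomonadales", "Alphaproteobacteria", "Proteobacteria"),
    ("Brevundimonas", "Caulobacteraceae", "Caulobacterales", "Alphaproteobacteria", "Proteobacteria"),
    ("Caulobacter", "Caulobacteraceae", "Caulobacterales", "Alphaproteobacteria", "Proteobacteria"),
    ("Hyphomonas", "Hyphomonadaceae", "Caulobacterales", "Alphaproteobacteria", "Proteobacteria"),
    ("Azospirillum", "Azospirillaceae", "Rhodospirillales", "Alphaproteobacteria", "Proteobacteria"),
    ("Ruegeria", "Rhodobacteraceae", "Rhodobacterales", "Alphaproteobacteria", "Proteobacteria"),
    # Betaproteobacteria
    ("Hydrogenophaga", "Comamonadaceae", "Burkholderiales", "Betaproteobacteria", "Proteobacteria"),
    ("Variovorax", "Comamonadaceae", "Burkholderiales", "Betaproteobacteria", "Proteobacteria"),
    ("Acidovorax", "Comamonadaceae", "Burkholderiales", "Betaproteobacteria", "Proteobacteria"),
    ("Burkholderia", "Burkholderiaceae", "Burkholderiales", "Betaproteobacteria", "Proteobacteria"),
    ("Cupriavidus", "Burkholderiaceae", "Burkholderiales", "Betaproteobacteria", "Proteobacteria"),
    ("Ralstonia", "Burkholderiaceae", "Burkholderiales", "Betaproteobacteria", "Proteobacteria"),
    # Gammaproteobacteria
    ("Escherichia", "Enterobacteriaceae", "Enterobacterales", "Gammaproteobacteria", "Proteobacteria"),
    ("Pseudomonas", "Pseudomonadaceae", "Pseudomonadales", "Gammaproteobacteria", "Proteobacteria"),
    # Bacteroidetes
    ("Spirosoma", "Cytophagaceae", "Cytophagales", "Cytophagia", "Bacteroidetes"),
    ("Adhaeribacter", "Hymenobacteraceae", "Cytophagales", "Cytophagia", "Bacteroidetes"),
    ("Hymenobacter", "Hymenobacteraceae", "Cytophagales", "Cytophagia", "Bacteroidetes"),
    ("Chitinophaga", "Chitinophagaceae", "Chitinophagales", "Chitinophagia", "Bacteroidetes"),
    ("Sediminibacterium", "Chitinophagaceae", "Chitinophagales", "Chitinophagia", "Bacteroidetes"),
    ("Flavobacterium", "Flavobacteriaceae", "Flavobacteriales", "Flavobacteriia", "Bacteroidetes"),
    ("Pedobacter", "Sphingobacteriaceae", "Sphingobacteriales", "Sphingobacteriia", "Bacteroidetes"),
    ("Mucilaginibacter", "Sphingobacteriaceae", "Sphingobacteriales", "Sphingobacteriia", "Bacteroidetes"),
    # Actinobacteria
    ("Mycobacterium", "Mycobacteriaceae", "Corynebacteriales", "Actinomycetia", "Actinobacteria"),
    ("Pseudonocardia", "Pseudonocardiaceae", "Pseudonocardiales", "Actinomycetia", "Actinobacteria"),
    ("Streptomyces", "Streptomycetaceae", "Streptomycetales", "Actinomycetia", "Actinobacteria"),
    ("Microbacterium", "Microbacteriaceae", "Micrococcales", "Actinomycetia", "Actinobacteria"),
    ("Nocardioides", "Nocardioidaceae", "Propionibacteriales", "Actinomycetia", "Actinobacteria"),
    # Chloroflexi
    ("Dehalogenimonas", "Dehalococcoidaceae", "Dehalococcoidales", "Dehalococcoidia", "Chloroflexi"),
    ("Dehalococcoides", "Dehalococcoidaceae", "Dehalococcoidales", "Dehalococcoidia", "Chloroflexi"),
    # Planctomycetes / Verrucomicrobia / Acidobacteria
    ("Planctomyces", "Planctomycetaceae", "Planctomycetales", "Planctomycetia", "Planctomycetes"),
    ("Gemmata", "Gemmataceae", "Planctomycetales", "Planctomycetia", "Planctomycetes"),
    ("Verrucomicrobium", "Verrucomicrobiaceae", "Verrucomicrobiales", "Verrucomicrobiae", "Verrucomicrobia"),
    ("Luteitalea", "Vicinamibacteraceae", "Vicinamibacterales", "Vicinamibacteria", "Acidobacteria"),
]

# eukaryotic contaminants seen in cyanobacterial cultures (fungi, amoebae)
_EUKARYOTES = [
    ("Basidiobolus", "Basidiobolaceae", "Basidiobolales", "Basidiobolomycetes", "Zoopagomycota"),
    ("Acanthamoeba", "Acanthamoebidae", "Centramoebida", "Discosea", "Amoebozoa"),
    ("Mycamoeba", "Dermamoebidae", "Dermamoebida", "Discosea", "Amoebozoa"),
    ("Platyamoeba", "Vannellidae", "Vannellida", "Discosea", "Amoebozoa"),
    ("Naegleria", "Vahlkampfiidae", "Schizopyrenida", "Heterolobosea", "Percolozoa"),
    ("Fumarolamoeba", "Vahlkampfiidae", "Schizopyrenida", "Heterolobosea", "Percolozoa"),
]

#: phylum- or class-level names -> community-composition category
CATEGORY_BY_NAME = {
    "cyanobacteria": "Cyanobacteria",
    "alphaproteobacteria": "Alphaproteobacteria",
    "betaproteobacteria": "Betaproteobacteria",
    "bacteroidetes": "Bacteroidetes",
    "actinobacteria": "Actinobacteria",
}


class Lexicon:
    """Case-insensitive name -> :class:`TaxonEntry` lookup with lineages."""

    def __init__(self, rows=None, kingdom="Bacteria", extra_kingdoms=()):
        self._entries: dict[str, TaxonEntry] = {}
        for kdm, table in [(kingdom, rows if rows is not None else _BACTERIA)] + list(extra_kingdoms):
            for genus, family, order, class_, phylum in table:
                lineage = {
                    "kingdom": kdm,
                    "phylum": phylum,
                    "class": class_,
                    "order": order,
                    "family": family,
                    "genus": genus,
                }
                self._add(genus, "genus", lineage)
                for rank in ("family", "order", "class", "phylum", "kingdom"):
                    sub = {r: n for r, n in lineage.items() if RANK_DEPTH[r] <= RANK_DEPTH[rank]}
                    self._add(lineage[rank], rank, sub)

    def _add(self, name: str, rank: str, lineage: dict) -> None:
        key = name.lower()
        if key not in self._entries:
            self._entries[key] = TaxonEntry(name=name, rank=rank, lineage=dict(lineage))

    def lookup(self, name: str) -> TaxonEntry | None:
        """Resolve a name; binomials fall back to their genus."""
        if not name:
            return None
        key = name.strip().lower()
        hit = self._entries.get(key)
        if hit is not None:
            return hit
        # "Spirosoma linguale DSM 74" -> try the leading token as a genus
        head = key.split()[0].rstrip(".,;")
        return self._entries.get(head)

    def is_eukaryote(self, name: str) -> bool:
        entry = self.lookup(name)
        return entry is not None and entry.ancestor("kingdom") == "Eukaryota"

    def category_of(self, name: str) -> str:
        """Map a taxon name to its composition category ('other' if unknown)."""
        entry = self.lookup(name)
        candidates = [name.lower()]
        if entry is not None:
            for rank in ("class", "phylum"):
                anc = entry.ancestor(rank)
                if anc:
                    candidates.append(anc.lower())
        for cand in candidates:
            if cand in CATEGORY_BY_NAME:
                return CATEGORY_BY_NAME[cand]
        return "other"

    def genera(self) -> list[str]:
        return [e.name for e in self._entries.values() if e.rank == "genus"]

    def __contains__(self, name: str) -> bool:
        return self.lookup(name) is not None

    def __len__(self) -> int:
        return len(self._entries)


def default_lexicon() -> Lexicon:
    """The built-in lexicon: bacteria plus known eukaryotic contaminants."""
    return Lexicon(_BACTERIA, kingdom="Bacteria", extra_kingdoms=[("Eukaryota", _EUKARYOTES)])
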