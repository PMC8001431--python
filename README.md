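# cyanosphere

Post-binning analysis of metagenomes from **non-axenic cyanobacterial
cultures**: text-mining taxonomy from BLAST subject titles, 16S-rRNA/RpoB
marker classification with novelty calling, multi-binner concordance,
scripted (replayable) MAG curation, genome report statistics, community
composition — and a fully seeded synthetic-community generator that provides
ground truth for every stage.

## The scientific problem

Many cyanobacteria cannot be grown axenically: decades-old culture-collection
strains carry a stable entourage of heterotrophic bacteria (the
"cyanosphere"). Shotgun-sequencing such a culture yields a low-complexity
metagenome — one dominant phototroph plus tens of heterotroph genomes — from
which a curated, near-complete cyanobacterial MAG
(metagenome-assembled genome) and a census of the accompanying community can
both be extracted. The analysis steps after assembly and binning are simple
but full of conventions that matter:

- **Text-mining taxonomy.** Each contig is searched against a nucleotide
  database (`blastn -outfmt "6 std stitle"`). Hits with e-value < 1e-10 and
  identity > 90% (both strict) are kept, at most 20 per contig; the words of
  the surviving subject titles are counted per bin (boilerplate such as
  "complete", "genome", "sp.", "strain" is stopworded) and the
  highest-ranking word that is a known taxon name classifies the bin. An
  adapter screen guards against a nasty artifact: a library adapter inside a
  contig can make the title profile converge on whatever organism's deposited
  genome also retained that adapter.
- **Marker classification.** 16S-rRNA best-hit identity is held against a
  ladder of rank thresholds (species 98.7, genus 94.5, family 86.5, order
  82.0, class 78.5, phylum 75.0); identity below a threshold proposes a novel
  taxon at that rank, and the broadest undershot rank wins. RpoB amino-acid
  identity ≥ 96% (inclusive) supports a species-level link; below 85% the
  lineage is flagged as under-sampled in the database.
- **Curation.** "Manual" bin fixes — removing foreign rRNA/tRNA contigs,
  rescuing authentic ones from other bins, merging split bins — are expressed
  as a declarative edit script that is validated, logged and exactly
  replayable. Removed contigs return to the unbinned pool; contigs are never
  created or destroyed.
- **Composition.** Bins with completeness ≥ 80% and coverage > 25-fold enter
  the community census; abundance is reported as share of bins, share of
  attributed DNA (size × coverage) and share of coverage, and coverage acts
  as genome-equivalent proxy for the phototroph:heterotroph ratio (1:N).

## Worked example

Simulate a 5-genome community (host + 4 heterotrophs), then classify the
best binner's bins by title text-mining:

```python
from cyanosphere import SimulationConfig, simulate_all, classify_bins, BinRecord

sim = simulate_all(SimulationConfig(seed=7, n_heterotrophs=4))
truth = {g.genome_id: g.taxon for g in sim.truth.genomes}
bins = [BinRecord(bin_id=g, contig_ids=c) for g, c in sim.binner_sets["maxbin"].items()]
profiles, calls = classify_bins(bins, sim.blast_hits)
for gid in sorted(calls):
    c = calls[gid]
    print(f"{gid:5} {truth[gid]:15} {c.rank}:{c.name:15} {c.dominance:.2f}")
```

```text
G00   Stigonema       genus:Stigonema       0.21
G01   Bradyrhizobium  genus:Bradyrhizobium  0.21
G02   Acidovorax      genus:Acidovorax      0.20
G03   Pseudomonas     genus:Pseudomonas     0.21
G04   Mesorhizobium   genus:Mesorhizobium   0.21
```

Marker calls follow the documented threshold conventions exactly:

```python
from cyanosphere import call_16s_novelty, call_rpob

for ident in (99.2, 93.8, 89.53, 82.02):
    print(f"16S identity {ident:6.2f} -> novel {call_16s_novelty(ident).proposed_level}")
for ident in (100.0, 96.0, 92.5, 75.22):
    c = call_rpob(ident, "Hydrogenophaga flava")
    label = "under-sampled lineage" if c.undersampled else f"{c.rank}: {c.name}"
    print(f"RpoB identity {ident:6.2f} -> {label}")
```

```text
16S identity  99.20 -> novel none
16S identity  93.80 -> novel genus
16S identity  89.53 -> novel genus
16S identity  82.02 -> novel family
RpoB identity 100.00 -> species: Hydrogenophaga flava
RpoB identity  96.00 -> species: Hydrogenophaga flava
RpoB identity  92.50 -> genus: Hydrogenophaga
RpoB identity  75.22 -> under-sampled lineage
```

And a genome report from the bundled annotation counts:

```python
from cyanosphere import load_mag_annotation_counts, summarize_genome

counts = load_mag_annotation_counts()["Stigonema_ocellatum"]
rep = summarize_genome(counts)
print("genome size (bp):", f"{counts.genome_size_bp:,}")
print("coding density  :", rep.percents["coding_bp"], "%")
print("G+C content     :", rep.percents["gc_bp"], "%")
print("gene density    :", rep.gene_density_bp_per_gene, "bp per gene")
```

```text
genome size (bp): 10,354,468
coding density  : 77.1 %
G+C content     : 43.8 %
gene density    : 1173 bp per gene
```

A `cyp` console script mirrors the library: `cyp simulate`,
`cyp screen-adapters`, `cyp textmine`, `cyp classify`, `cyp compare-binners`,
`cyp curate`, `cyp compose`, `cyp genome-stats`. Try
`cyp --help` or e.g. `cyp simulate --seed 7 --n-heterotrophs 4 --out sim/`.

## Numerical conventions

- Published-report percentages round **half-up** to two decimals (Python's
  `decimal` module), not banker's rounding; gene density rounds half-up to
  the nearest integer.
- Text-mining and contig-labelling thresholds are strict (`<` 1e-10, `>` 90),
  while the 16S ladder and the RpoB 96% species rule treat the threshold
  identity itself as membership (inclusive).
- All simulation randomness flows from one integer seed through
  `numpy.random.SeedSequence`; derived child seeds stay below 2³¹.

See `docs/methods.md` for the full methods note.
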