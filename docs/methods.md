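# Methods

This note records the model behind each analysis stage, the conventions it
follows, and the design of the synthetic-community generator used to test
everything end to end.

## 1. Input formats (`formats_io`)

- **Contigs**: FASTA via Biopython; duplicate ids are a hard error. A
  `Contig` may carry length/GC without sequence (summary-only workflows).
- **BLAST tables**: tabular `-outfmt "6 std stitle"` — twelve standard
  columns plus the subject title. Columns 13+ are re-joined with tabs so
  titles containing tabs survive; malformed rows fail with the 1-based line
  number. `expect_stitle=True` (default) rejects 12-column tables because
  every downstream text-mining step needs titles.
- **Bin tables**: separate assignment (contig → bin), quality
  (completeness/contamination) and coverage tables are joined loss-free; a
  contig in two bins or duplicate quality rows are consistency errors.
  Missing metrics stay `None` — never silently zero, because zero
  completeness is a meaningful value to the downstream filter.
- **Features**: GFF3 (parsed with gffutils) or a 5-column TSV; product
  strings are normalised to `rRNA_16S` / `rRNA_23S` / `rRNA_5S` / `tRNA` /
  `other`. Coordinates are 1-based inclusive and `start ≤ end` is enforced.

## 2. Text-mining taxonomy (`textmine`)

Per contig, hits with **e-value strictly < 1e-10 and identity strictly
> 90%** are kept, sorted by (e-value ascending, bitscore descending, input
order) and truncated to the **top 20**. Titles are tokenised by whitespace;
punctuation is stripped from token ends but internal dots and hyphens are
kept (`NIES-843`, `sp.`); pure numerics and one-character tokens are
dropped; the stopword set is {complete, genome, DNA, sequence, sp., strain,
assembly}, matched with and without a trailing dot. Per bin, tokens are
counted over all kept hits of member contigs and the **top 20 words** are
ranked (ties alphabetical). The best-ranked word matching a known genus
gives a genus call; failing that, a broader-rank name (family/order/…) gives
a call at that rank; otherwise the bin is unclassified. A count tie between
two genera marks the call ambiguous. The dominance score is the top taxon
word's share of the summed top-word counts.

The **adapter screen** searches contigs for four Illumina library adapters
(exact substring, both strands). Adapter-bearing contigs can make a bin's
title profile converge on an unrelated organism whose deposited assembly
retained the same adapter, so flagged contigs should be excluded from
text-mining evidence.

## 3. Marker taxonomy (`markers`)

- **16S novelty ladder**: thresholds are minimum identities for membership
  at a rank — species 98.7, genus 94.5, family 86.5, order 82.0, class 78.5,
  phylum 75.0. Identity **strictly below** a threshold proposes a novel
  taxon; scanning narrow → broad, the broadest undershot rank wins (e.g.
  89.53 → novel genus, 82.02 → novel family); the threshold value itself is
  membership, not novelty.
- **Bisect chimera check**: the two halves of a 16S gene are classified
  independently; disagreement at the compared rank flags a possible chimera.
- **RpoB**: amino-acid identity ≥ 96 (inclusive) supports species, 90–96
  genus, 85–90 family; < 85 flags an under-sampled lineage and yields no
  rank.
- **Evidence integration**: marker-lineage (CheckM-style `k__;p__;…`
  strings), RpoB and non-ambiguous text-mining calls are combined; the
  deepest proposed rank wins; a 16S novelty call caps the integrated rank
  one level above the novel rank (a novel genus cannot carry a genus name);
  name conflicts climb to the deepest rank on which the proposals agree via
  the bundled lineage lexicon and set a conflict flag; no evidence at all
  returns kingdom Bacteria.
- **Quality tiers**: high-quality draft requires completeness > 90%,
  contamination < 5%, all three rRNAs and ≥ 18 tRNAs (configurable); medium
  is completeness ≥ 50% and contamination < 10%.

## 4. Binner concordance (`concordance`)

Contigs are labelled `target` / `other` / `no_hit` from their passing BLAST
hits (same strict thresholds; a title token must equal a target name —
substring matches do not count). Two or three binner contig sets are
partitioned into disjoint Venn regions (> 3 binners is rejected; use
pairwise comparisons). Recovery is each binner's share of the union of
target-labelled contigs; precision is the target fraction inside the
binner's own set.

## 5. Curation (`curation`)

Curation is a declarative, ordered edit script over three actions:
`remove_contig` (to the unbinned pool), `add_contig` (from a named source
bin or the pool) and `merge_bin`. Removing a non-member, adding a duplicate
or merging overlapping bins are hard errors. Every edit is logged with
before/after cardinalities, so a curated MAG is exactly replayable from the
original binning; conservation of contigs is an invariant.
`suggest_rrna_edits` proposes (never applies) removals for member
rRNA/tRNA contigs whose per-contig best-hit genus conflicts with the bin's
call and additions for matching marker contigs found elsewhere.
`assembly_stats` reports size, contig count, GC (one decimal) and N50.

## 6. Composition (`composition`)

Bins pass the census filter with **completeness ≥ 80% (inclusive) and
coverage > 25-fold (strict)**; unknown metrics fail the filter with a
warning. Passing bins are mapped to six categories (Cyanobacteria, Alpha-,
Betaproteobacteria, Bacteroidetes, Actinobacteria, other) via an explicit
lineage map or the bundled lexicon; the host bin is always Cyanobacteria.
Three abundance views: share of bins, share of attributed DNA
(size × coverage, plus a `below_completeness` slice for filtered-out bins),
and share of coverage. Coverage is the genome-equivalent proxy:
the phototroph:heterotroph ratio is `1:N` with
N = (total passing coverage − host coverage) / host coverage, one decimal.
A fixed palette keys the categories for word-cloud/plot export.

## 7. Genome statistics (`genome_stats`)

Percent-of-total columns use genome size as denominator for base-pair rows
and total genes for gene rows, rounded **half-up** to two decimals with the
`decimal` module (floating-point `round` uses banker's rounding and
reproduces the published-style cells only most of the time). Gene density is
genome size / total genes, half-up to an integer. Counts are validated
(non-negative, gene classes ≤ total genes, coding/GC bp ≤ genome size).

## 8. Synthetic communities (`simulate`)

Everything is a pure function of `(config, seed)`; `simulate_all` derives
three child seeds (< 2³¹) from one `SeedSequence`. Default condition: one
host genome (2 Mb, 44% GC) holding **15%** of total coverage — exact in the
ground truth, with 3% multiplicative lognormal measurement noise on the
emitted coverage table — plus **20 heterotrophs** (150–400 kb, lognormal
coverage, median ≈ 90-fold) drawn from the lexicon's non-cyanobacterial
genera. Genomes are cut into contigs (lognormal lengths, mean 2.5 kb, min
500 bp) that sum exactly to the genome size; sequences are i.i.d.
nucleotides at the genome's GC (no k-mer structure — nothing downstream of
binning uses composition); adapters are planted at rate 0.02.

- **Binners**: three error profiles — recall/contamination 0.99/0.02,
  0.75/0.05, 0.55/0.05 — one bin per genome; contamination is drawn from the
  still-unassigned contigs of other genomes.
- **BLAST**: 5–20 hits per contig; identity uniform in (90, 100], e-value
  10^U(−180, −11); 20% of titles name a random other genus (off-target
  noise); 5% of contigs receive only sub-threshold hits (exercising the
  no-hit path).
- **Markers**: each heterotroph is planted a novelty level
  (none 0.65 / genus 0.30 / family 0.05); its 16S identity is sampled
  strictly inside the corresponding ladder band, so the planted level is
  exactly recoverable; RpoB identities are planted to match.

Realism and limits: the generator reproduces the *decision structure* of the
analysis (thresholds, ties, noise, sub-threshold contigs), not sequence
evolution; binning errors are independent per contig, whereas real binners
fail systematically on shared k-mer/coverage profiles; coverage is uniform
along each genome. These parameters are the study conditions for the
property suite and are deliberately not tuned against the tests.

## 9. Limitations

- The lexicon is a small curated name table (~50 genera with lineages),
  sufficient for the bundled data and simulations — not a taxonomy service.
- The text-mining classifier inherits database composition bias: whatever
  organism dominates the reference titles dominates the profile.
- No assembly, read simulation or alignment is performed; the package starts
  at contigs + BLAST tables and ends at curated bins and community summaries.
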