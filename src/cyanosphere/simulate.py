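"""Seeded synthetic low-complexity communities with full ground truth.

Emulates the data a non-axenic cyanobacterial culture yields after assembly
and binning: one dominant phototroph ("host") genome plus a configurable
number of heterotroph genomes with lognormal coverage; contigs with
per-genome GC and optional adapter contamination; per-binner contig
assignments with controlled recall and contamination; BLAST hit tables whose
subject titles embed the true taxon names plus off-target noise; and marker
(16S/RpoB) best-hit identity tables drawn from planted novelty levels.

Everything is a pure function of (config, seed), so every pipeline stage is
testable end to end without external data.  Sequences are i.i.d. nucleotides
at the genome's GC content — no stage downstream of binning uses
compositional signatures, so k-mer structure is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .formats_io import BlastHit, BinRecord, Contig, write_blast_table, write_contigs
from .lexicon import Lexicon, default_lexicon
from .markers import ThresholdLadder, DEFAULT_LADDER

_EPITHETS = ("aquatica", "limnetica", "palustris", "borealis", "sylvestris",
             "riparia", "lacustris", "fontis")
_COLLECTIONS = ("DSM", "PCC", "SAG", "NIES", "ATCC")

#: planted 16S novelty levels and their default probabilities
NOVELTY_LEVELS = ("none", "genus", "family")


@dataclass
class SimulationConfig:
    """Study-like community conditions.

    Defaults mirror a deeply sequenced non-axenic culture: 20 heterotrophs
    around one host holding 15% of the coverage (within the observed 11–31%
    host range), lognormal heterotroph coverage, three binner error profiles
    spanning the observed ~0.99 / >=0.71 / 0.47–0.69 recall bands, and 20%
    off-target title noise in the simulated BLAST output.
    """

    seed: int = 42
    n_heterotrophs: int = 20
    host_taxon: str = "Stigonema"
    host_coverage_share: float = 0.15
    host_genome_bp: int = 2_000_000
    het_genome_bp: tuple = (150_000, 400_000)
    coverage_lognormal_mu: float = 4.5  # median ~90-fold
    coverage_lognormal_sigma: float = 0.5
    coverage_noise_sd: float = 0.03  # multiplicative lognormal measurement noise
    contig_length_mean: int = 2500
    contig_length_sigma: float = 0.4
    contig_length_min: int = 500
    binner_profiles: dict = field(
        default_factory=lambda: {
            "maxbin": (0.99, 0.02),
            "concoct": (0.75, 0.05),
            "metabat": (0.55, 0.05),
        }
    )
    blast_noise: float = 0.2
    subthreshold_fraction: float = 0.05
    max_hits_per_contig: int = 20
    adapter_rate: float = 0.02
    novelty_probs: dict = field(
        default_factory=lambda: {"none": 0.65, "genus": 0.30, "family": 0.05}
    )
    with_sequences: bool = True

    def __post_init__(self):
        if self.n_heterotrophs < 1:
            raise ValueError("need at least one heterotroph genome")
        if not 0 < self.host_coverage_share < 1:
            raise ValueError("host_coverage_share must be in (0,1)")
        for name, value in (("blast_noise", self.blast_noise),
                            ("subthreshold_fraction", self.subthreshold_fraction),
                            ("adapter_rate", self.adapter_rate)):
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        for recall, cont in self.binner_profiles.values():
            if not (0 <= recall <= 1 and 0 <= cont <= 1):
                raise ValueError("binner recall/contamination rates must be in [0,1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")


@dataclass
class GenomeTruth:
    genome_id: str
    taxon: str  # genus
    genome_size_bp: int
    gc_fraction: float
    coverage: float  # true coverage
    is_host: bool
    novelty_level: str = "none"  # planted 16S novelty
    rpob_identity: float = 100.0
    rpob_ref: str = ""


@dataclass
class CommunityTruth:
    genomes: list
    contig_map: dict = field(default_factory=dict)  # contig_id -> genome_id

    @property
    def host(self) -> GenomeTruth:
        return next(g for g in self.genomes if g.is_host)

    def contigs_of(self, genome_id: str) -> set:
        return {c for c, g in self.contig_map.items() if g == genome_id}


@dataclass
class SimulationResult:
    config: SimulationConfig
    truth: CommunityTruth
    contigs: list
    coverage: pd.DataFrame  # genome_id, coverage (with measurement noise)
    binner_sets: dict = field(default_factory=dict)  # binner -> genome_id -> contig set
    unbinned: dict = field(default_factory=dict)  # binner -> contig set
    blast_hits: list = field(default_factory=list)
    markers: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# community + contigs
# ---------------------------------------------------------------------------

def _random_sequence(rng, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2])
    return "".join(rng.choice(np.array(list("ATGC")), size=length, p=p))


def simulate_community(cfg: SimulationConfig, lexicon: Lexicon | None = None,
                       adapters=None):
    """Draw the community ground truth, its contigs and the coverage table.

    Returns ``(truth, contigs, coverage_df)``.  The host's realised coverage
    share equals the requested share exactly in truth; the emitted coverage
    table adds multiplicative measurement noise (coverage estimates from
    read mapping are never exact).
    """
    rng = np.random.default_rng(cfg.seed)
    lexicon = lexicon or default_lexicon()

    pool = sorted(
        g for g in lexicon.genera()
        if lexicon.category_of(g) != "Cyanobacteria" and not lexicon.is_eukaryote(g)
    )
    order = rng.permutation(len(pool))
    het_taxa = [pool[order[i % len(pool)]] for i in range(cfg.n_heterotrophs)]

    levels = list(cfg.novelty_probs)
    probs = np.array([cfg.novelty_probs[l] for l in levels], dtype=float)
    probs = probs / probs.sum()

    genomes = [
        GenomeTruth(
            genome_id="G00",
            taxon=cfg.host_taxon,
            genome_size_bp=cfg.host_genome_bp,
            gc_fraction=0.44,
            coverage=0.0,  # set after heterotroph draws
            is_host=True,
            novelty_level="none",
            rpob_identity=float(rng.uniform(97, 100)),
        )
    ]
    het_cov = rng.lognormal(cfg.coverage_lognormal_mu, cfg.coverage_lognormal_sigma,
                            cfg.n_heterotrophs)
    for i, taxon in enumerate(het_taxa, start=1):
        level = levels[rng.choice(len(levels), p=probs)]
        if level == "none":
            rpob = float(rng.uniform(96, 100))
        elif level == "genus":
            rpob = float(rng.uniform(90, 96))
        else:
            rpob = float(rng.uniform(75, 85))
        genomes.append(
            GenomeTruth(
                genome_id=f"G{i:02d}",
                taxon=taxon,
                genome_size_bp=int(rng.integers(*cfg.het_genome_bp)),
                gc_fraction=float(rng.uniform(0.35, 0.65)),
                coverage=float(het_cov[i - 1]),
                is_host=False,
                novelty_level=level,
                rpob_identity=rpob,
            )
        )
    share = cfg.host_coverage_share
    genomes[0].coverage = share / (1 - share) * float(het_cov.sum())

    truth = CommunityTruth(genomes=genomes)
    contigs = []
    adapters = adapters if adapters is not None else _default_adapters()
    for genome in genomes:
        remaining, idx = genome.genome_size_bp, 0
        while remaining > 0:
            length = int(rng.lognormal(np.log(cfg.contig_length_mean), cfg.contig_length_sigma))
            length = max(cfg.contig_length_min, min(length, remaining))
            if remaining - length < cfg.contig_length_min:
                length = remaining
            cid = f"{genome.genome_id}_c{idx:04d}"
            seq = None
            if cfg.with_sequences:
                seq = _random_sequence(rng, length, genome.gc_fraction)
                if adapters and rng.random() < cfg.adapter_rate:
                    adapter = adapters[rng.integers(len(adapters))]
                    pos = int(rng.integers(0, max(1, length - len(adapter))))
                    seq = seq[:pos] + adapter + seq[pos + len(adapter):]
            contigs.append(Contig(id=cid, length=length, sequence=seq,
                                  gc_count=0 if seq else int(round(length * genome.gc_fraction))))
            truth.contig_map[cid] = genome.genome_id
            remaining -= length
            idx += 1

    noise = rng.lognormal(0.0, cfg.coverage_noise_sd, len(genomes)) if cfg.coverage_noise_sd else np.ones(len(genomes))
    coverage = pd.DataFrame(
        {
            "genome_id": [g.genome_id for g in genomes],
            "taxon": [g.taxon for g in genomes],
            "coverage": [g.coverage * n for g, n in zip(genomes, noise)],
        }
    )
    return truth, contigs, coverage


def _default_adapters():
    from .textmine import DEFAULT_ADAPTERS

    return DEFAULT_ADAPTERS


# ---------------------------------------------------------------------------
# binner emulation
# ---------------------------------------------------------------------------

def simulate_binners(truth: CommunityTruth, profiles: dict, seed: int):
    """Assign contigs to per-binner bins with stated recall and contamination.

    Each genome becomes one bin per binner; a genome contig enters its bin
    with probability *recall*; contaminating contigs (drawn from the still
    unassigned contigs of other genomes) are injected at the stated rate.
    Returns ``(binner_sets, unbinned)``: binner -> genome_id -> contig set,
    and binner -> leftover contig set.
    """
    rng = np.random.default_rng(seed)
    by_genome = {g.genome_id: sorted(truth.contigs_of(g.genome_id)) for g in truth.genomes}
    binner_sets, unbinned = {}, {}
    for binner, (recall, cont_rate) in profiles.items():
        assigned = {}
        taken = set()
        for gid, contigs in by_genome.items():
            keep = [c for c in contigs if rng.random() < recall] if recall < 1 else list(contigs)
            assigned[gid] = set(keep)
            taken |= assigned[gid]
        free = sorted(set(truth.contig_map) - taken)
        for gid in by_genome:
            if not cont_rate or not free:
                continue
            candidates = [c for c in free if truth.contig_map[c] != gid]
            k = min(rng.binomial(len(assigned[gid]), cont_rate), len(candidates))
            if k:
                picked = rng.choice(len(candidates), size=k, replace=False)
                for j in picked:
                    assigned[gid].add(candidates[j])
                free = [c for c in free if c not in assigned[gid]]
        binner_sets[binner] = assigned
        unbinned[binner] = set(truth.contig_map) - set().union(*assigned.values())
    return binner_sets, unbinned


# ---------------------------------------------------------------------------
# BLAST emulation
# ---------------------------------------------------------------------------

def _title(rng, genus: str) -> str:
    code = f"{_COLLECTIONS[rng.integers(len(_COLLECTIONS))]} {rng.integers(100, 99999)}"
    template = rng.integers(4)
    epithet = _EPITHETS[rng.integers(len(_EPITHETS))]
    if template == 0:
        return f"{genus} {epithet} strain {code}, complete genome"
    if template == 1:
        return f"{genus} sp. {code} chromosome 1, complete sequence"
    if template == 2:
        return f"{genus} {epithet} {code} genomic scaffold, whole genome shotgun sequence"
    return f"{genus} sp. {code} plasmid DNA, complete sequence"


def simulate_blast(truth: CommunityTruth, lexicon: Lexicon | None = None,
                   noise: float = 0.2, subthreshold_fraction: float = 0.05,
                   max_hits: int = 20, seed: int = 0) -> list[BlastHit]:
    """Emit per-contig nucleotide-database hits with titles naming taxa.

    On-target hits carry the contig's true genus, identity in (90, 100] and
    e-value below 1e-10; a *noise* fraction of titles name a random other
    taxon instead; a *subthreshold_fraction* of contigs receive only hits
    that fail the identity/e-value thresholds (exercising "no hit").
    """
    rng = np.random.default_rng(seed)
    lexicon = lexicon or default_lexicon()
    genera = sorted(set(lexicon.genera()))
    taxon_of = {g.genome_id: g.taxon for g in truth.genomes}

    hits = []
    for contig_id in sorted(truth.contig_map):
        true_genus = taxon_of[truth.contig_map[contig_id]]
        if rng.random() < subthreshold_fraction:
            for j in range(3):
                hits.append(BlastHit(
                    query_id=contig_id,
                    subject_id=f"subthr{j}",
                    pct_identity=float(rng.uniform(60, 89)),
                    aln_length=int(rng.integers(100, 400)),
                    evalue=float(10 ** rng.uniform(-9, -2)),
                    bitscore=float(rng.uniform(40, 90)),
                    stitle=_title(rng, genera[rng.integers(len(genera))]),
                ))
            continue
        n_hits = int(rng.integers(5, max_hits + 1))
        for j in range(n_hits):
            if rng.random() < noise:
                genus = genera[rng.integers(len(genera))]
            else:
                genus = true_genus
            aln = int(rng.integers(300, 5000))
            hits.append(BlastHit(
                query_id=contig_id,
                subject_id=f"acc{rng.integers(10**6, 10**7)}",
                pct_identity=float(rng.uniform(90.01, 100.0)),
                aln_length=aln,
                evalue=float(10 ** rng.uniform(-180, -11)),
                bitscore=float(2 * aln),
                stitle=_title(rng, genus),
            ))
    return hits


# ---------------------------------------------------------------------------
# marker emulation
# ---------------------------------------------------------------------------

def simulate_markers(truth: CommunityTruth, ladder: ThresholdLadder | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Marker best-hit identity table from planted novelty levels.

    The 16S identity is sampled strictly inside the band the planted level
    implies on the threshold ladder (novel genus -> [family, genus)
    thresholds, etc.; "none" -> at or above the narrowest threshold), so
    novelty calls are exactly recoverable.  RpoB identities are emitted as
    planted.
    """
    rng = np.random.default_rng(seed)
    ladder = ladder or DEFAULT_LADDER
    ranks = ladder.ranks_narrow_to_broad  # narrow -> broad
    rows = []
    for g in truth.genomes:
        level = g.novelty_level
        if level == "none":
            low, high = ladder.thresholds[ranks[0]], 100.0
        else:
            i = ranks.index(level)
            high = ladder.thresholds[level]
            low = ladder.thresholds[ranks[i + 1]] if i + 1 < len(ranks) else high - 5
        identity = float(rng.uniform(low, high - 0.01)) if high - 0.01 > low else low
        rows.append({"sequence_id": g.genome_id, "marker": "16S",
                     "best_hit_name": f"{g.taxon} sp.", "identity": identity})
        rows.append({"sequence_id": g.genome_id, "marker": "rpoB",
                     "best_hit_name": f"{g.taxon} {_EPITHETS[rng.integers(len(_EPITHETS))]}",
                     "identity": g.rpob_identity})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration and output
# ---------------------------------------------------------------------------

def simulate_all(cfg: SimulationConfig, lexicon: Lexicon | None = None) -> SimulationResult:
    """Run every generator with child seeds derived from ``cfg.seed``."""
    lexicon = lexicon or default_lexicon()
    ss = np.random.SeedSequence(cfg.seed)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    truth, contigs, coverage = simulate_community(cfg, lexicon=lexicon)
    binner_sets, unbinned = simulate_binners(truth, cfg.binner_profiles, seed=child[0])
    hits = simulate_blast(truth, lexicon=lexicon, noise=cfg.blast_noise,
                          subthreshold_fraction=cfg.subthreshold_fraction,
                          max_hits=cfg.max_hits_per_contig, seed=child[1])
    markers = simulate_markers(truth, seed=child[2])
    return SimulationResult(config=cfg, truth=truth, contigs=contigs, coverage=coverage,
                            binner_sets=binner_sets, unbinned=unbinned,
                            blast_hits=hits, markers=markers)


def truth_bins(result: SimulationResult, completeness_range=(90.0, 100.0),
               contamination_range=(0.0, 3.0), seed: int | None = None) -> list[BinRecord]:
    """BinRecords for the truth partition (one bin per genome) with plausible
    quality metrics — the input shape the composition stage consumes."""
    rng = np.random.default_rng(result.config.seed if seed is None else seed)
    cov = dict(zip(result.coverage["genome_id"], result.coverage["coverage"]))
    bins = []
    for g in result.truth.genomes:
        bins.append(BinRecord(
            bin_id=g.genome_id,
            contig_ids=result.truth.contigs_of(g.genome_id),
            completeness=float(rng.uniform(*completeness_range)),
            contamination=float(rng.uniform(*contamination_range)),
            coverage=float(cov[g.genome_id]),
            size_bp=g.genome_size_bp,
        ))
    return bins


def write_simulation(result: SimulationResult, outdir) -> None:
    """Write contigs.fasta, coverage.tsv, truth.tsv, markers.tsv, blast.tsv
    and one assignments_<binner>.tsv per binner into *outdir*."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if result.config.with_sequences:
        write_contigs(result.contigs, out / "contigs.fasta")
    result.coverage.to_csv(out / "coverage.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "genome_id": g.genome_id,
                "taxon": g.taxon,
                "genome_size_bp": g.genome_size_bp,
                "gc_fraction": round(g.gc_fraction, 4),
                "coverage": g.coverage,
                "is_host": g.is_host,
                "novelty_level": g.novelty_level,
                "rpob_identity": round(g.rpob_identity, 2),
            }
            for g in result.truth.genomes
        ]
    ).to_csv(out / "truth.tsv", sep="\t", index=False)
    result.markers.to_csv(out / "markers.tsv", sep="\t", index=False)
    write_blast_table(result.blast_hits, out / "blast.tsv")
    for binner, bins in result.binner_sets.items():
        rows = [
            {"contig_id": cid, "bin_id": gid}
            for gid, contigs in sorted(bins.items())
            for cid in sorted(contigs)
        ]
        pd.DataFrame(rows).to_csv(out / f"assignments_{binner}.tsv", sep="\t", index=False)
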