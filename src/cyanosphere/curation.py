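"""Scripted, provenance-logged curation of metagenomic bins.

"Manual" curation is expressed as a declarative edit script (remove a
contig, add a contig from another bin or the unbinned pool, merge two bins)
that is applied in order and logged, so a curated MAG is exactly replayable
from the original binning.  Removed contigs return to the unbinned pool —
conservation of contigs is an invariant, nothing vanishes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import pandas as pd

from .formats_io import BinRecord, Contig

ACTIONS = ("remove_contig", "add_contig", "merge_bin")
REASONS = ("wrong_rRNA", "wrong_tRNA", "authentic_rRNA", "textmine_rescue",
           "plasmid_bin_merge", "other")


class CurationError(ValueError):
    """An edit references a non-member contig or would duplicate membership."""


@dataclass(frozen=True)
class CurationEdit:
    action: str  # remove_contig | add_contig | merge_bin
    target_bin: str
    contig_id: str | None = None
    source_bin: str | None = None  # add_contig origin, or the bin merged in
    reason: str = "other"
    note: str = ""

    def __post_init__(self):
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if self.reason not in REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")


@dataclass
class LogEntry:
    index: int
    edit: CurationEdit
    before_count: int
    after_count: int


@dataclass
class CurationLog:
    entries: list = field(default_factory=list)

    @property
    def edits(self):
        return [e.edit for e in self.entries]


def apply_curation(bins, edits, unbinned=None):
    """Apply an ordered edit script to bins.

    Returns ``(curated_bins, unbinned_pool, log)``.  Removing a non-member
    contig or adding one that is already a member raises
    :class:`CurationError` (hard errors prevent silent drift).  ``merge_bin``
    unions the source bin into the target and drops the source.
    """
    state = {b.bin_id: set(b.contig_ids) for b in bins}
    meta = {b.bin_id: b for b in bins}
    pool = set(unbinned or ())
    log = CurationLog()

    for i, edit in enumerate(edits):
        if edit.target_bin not in state:
            raise CurationError(f"edit {i}: unknown target bin {edit.target_bin!r}")
        target = state[edit.target_bin]
        before = len(target)

        if edit.action == "remove_contig":
            if edit.contig_id not in target:
                raise CurationError(
                    f"edit {i}: contig {edit.contig_id!r} not a member of {edit.target_bin!r}"
                )
            target.discard(edit.contig_id)
            pool.add(edit.contig_id)

        elif edit.action == "add_contig":
            if edit.contig_id in target:
                raise CurationError(
                    f"edit {i}: contig {edit.contig_id!r} already in {edit.target_bin!r}"
                )
            if edit.source_bin:
                if edit.source_bin not in state:
                    raise CurationError(f"edit {i}: unknown source bin {edit.source_bin!r}")
                if edit.contig_id not in state[edit.source_bin]:
                    raise CurationError(
                        f"edit {i}: contig {edit.contig_id!r} not in source {edit.source_bin!r}"
                    )
                state[edit.source_bin].discard(edit.contig_id)
            else:
                if edit.contig_id not in pool:
                    raise CurationError(
                        f"edit {i}: contig {edit.contig_id!r} not in the unbinned pool"
                    )
                pool.discard(edit.contig_id)
            target.add(edit.contig_id)

        elif edit.action == "merge_bin":
            if not edit.source_bin or edit.source_bin not in state:
                raise CurationError(f"edit {i}: unknown source bin {edit.source_bin!r}")
            overlap = target & state[edit.source_bin]
            if overlap:
                raise CurationError(f"edit {i}: merge would duplicate contigs {sorted(overlap)[:3]}")
            target |= state.pop(edit.source_bin)
            src_meta = meta.pop(edit.source_bin)
            tgt_meta = meta[edit.target_bin]
            if tgt_meta.size_bp is not None and src_meta.size_bp is not None:
                tgt_meta.size_bp += src_meta.size_bp

        log.entries.append(LogEntry(i, edit, before, len(target)))

    curated = []
    for bin_id, contigs in state.items():
        rec = copy.copy(meta[bin_id])
        rec.contig_ids = contigs
        rec.n_contigs = len(contigs)
        curated.append(rec)
    return curated, pool, log


def replay(bins, log: CurationLog, unbinned=None):
    """Re-apply a curation log to the original bins (determinism check)."""
    return apply_curation(bins, log.edits, unbinned=unbinned)


# ---------------------------------------------------------------------------
# edit proposals from misplaced marker features
# ---------------------------------------------------------------------------

def suggest_rrna_edits(bin_record: BinRecord, features, contig_calls: dict,
                       bin_call_name: str, all_bins=None, unbinned=None) -> list[CurationEdit]:
    """Propose rRNA/tRNA curation edits for one bin.  Proposals only —
    nothing is applied.

    Removal is proposed for marker-bearing member contigs whose per-contig
    taxon call (genus-level best-hit name) conflicts with the bin's call;
    addition is proposed for marker-bearing contigs elsewhere (other bins or
    the unbinned pool) whose call matches the bin's call.
    """
    def genus(name):
        return name.split()[0].rstrip(".,;").lower() if name else None

    bin_genus = genus(bin_call_name)
    marker_contigs = {f.contig_id: f.feature_type for f in features
                      if f.feature_type != "other"}
    reason_by_type = {"tRNA": "wrong_tRNA"}
    proposals = []
    for contig_id in sorted(bin_record.contig_ids):
        ftype = marker_contigs.get(contig_id)
        if ftype is None:
            continue
        call = contig_calls.get(contig_id)
        if call and bin_genus and genus(call) != bin_genus:
            proposals.append(CurationEdit(
                action="remove_contig", target_bin=bin_record.bin_id, contig_id=contig_id,
                reason=reason_by_type.get(ftype, "wrong_rRNA"),
                note=f"{ftype} best hit {call}",
            ))
    home = {}
    for other in all_bins or []:
        if other.bin_id == bin_record.bin_id:
            continue
        for cid in other.contig_ids:
            home[cid] = other.bin_id
    for cid in unbinned or ():
        home[cid] = None
    for contig_id, source in sorted(home.items()):
        ftype = marker_contigs.get(contig_id)
        if ftype is None or ftype == "tRNA":
            continue
        call = contig_calls.get(contig_id)
        if call and bin_genus and genus(call) == bin_genus:
            proposals.append(CurationEdit(
                action="add_contig", target_bin=bin_record.bin_id, contig_id=contig_id,
                source_bin=source, reason="authentic_rRNA",
                note=f"{ftype} best hit {call}",
            ))
    return proposals


# ---------------------------------------------------------------------------
# assembly statistics
# ---------------------------------------------------------------------------

@dataclass
class AssemblyStats:
    size_bp: int
    n_contigs: int
    gc_percent: float  # one decimal
    n50: int


def assembly_stats(contigs) -> AssemblyStats:
    """Size, contig count, GC percent (one decimal) and N50 of a contig set."""
    contigs = list(contigs)
    if not contigs:
        raise ValueError("empty bin: no contigs to summarise")
    total = sum(c.length for c in contigs)
    gc = sum(c.gc_count for c in contigs)
    lengths = sorted((c.length for c in contigs), reverse=True)
    half, cum, n50 = total / 2, 0, lengths[0]
    for length in lengths:
        cum += length
        if cum >= half:
            n50 = length
            break
    return AssemblyStats(
        size_bp=total,
        n_contigs=len(contigs),
        gc_percent=round(100.0 * gc / total, 1),
        n50=n50,
    )


# ---------------------------------------------------------------------------
# edit-script I/O
# ---------------------------------------------------------------------------

def read_edit_script(path) -> list[CurationEdit]:
    """Read a TSV edit script: action, target_bin, contig_id, source_bin,
    reason, note (header required; empty cells -> None)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    edits = []
    for _, row in df.iterrows():
        edits.append(CurationEdit(
            action=row["action"],
            target_bin=row["target_bin"],
            contig_id=row.get("contig_id") or None,
            source_bin=row.get("source_bin") or None,
            reason=row.get("reason") or "other",
            note=row.get("note", ""),
        ))
    return edits


def write_edit_script(edits, path) -> None:
    pd.DataFrame(
        [
            {
                "action": e.action,
                "target_bin": e.target_bin,
                "contig_id": e.contig_id or "",
                "source_bin": e.source_bin or "",
                "reason": e.reason,
                "note": e.note,
            }
            for e in edits
        ]
    ).to_csv(path, sep="\t", index=False)
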