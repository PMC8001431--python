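import numpy as np
import pytest

from cyanosphere import (
    AssemblyStats,
    BinRecord,
    Contig,
    CurationEdit,
    CurationError,
    FeatureRecord,
    apply_curation,
    assembly_stats,
    read_edit_script,
    replay,
    suggest_rrna_edits,
    write_edit_script,
)


def _bin(bin_id, n, prefix=None, size_bp=None):
    prefix = prefix or bin_id
    return BinRecord(bin_id=bin_id, contig_ids={f"{prefix}_{i}" for i in range(n)},
                     size_bp=size_bp)


class TestStudyReplays:
    """The three published curation outcomes, replayed as edit scripts."""

    def test_eight_removals_one_rescue_516_to_509(self):
        # the deeply fragmented host: 8 foreign rRNA/tRNA contigs out,
        # one authentic 16S/23S contig rescued from another bin
        host = _bin("host", 516)
        donor = _bin("bin40", 30)
        edits = [CurationEdit("remove_contig", "host", contig_id=f"host_{i}",
                              reason="wrong_rRNA") for i in range(8)]
        edits.append(CurationEdit("add_contig", "host", contig_id="bin40_0",
                                  source_bin="bin40", reason="authentic_rRNA"))
        curated, pool, log = apply_curation([host, donor], edits)
        by_id = {b.bin_id: b for b in curated}
        assert len(by_id["host"].contig_ids) == 509
        assert len(by_id["bin40"].contig_ids) == 29
        assert len(pool) == 8  # removals return to the unbinned pool

    def test_merge_then_trim_229_to_228(self):
        # host split over two bins (chromosome + satellite): merge to 229
        # contigs, drop 2 foreign marker contigs, rescue 1 from another bin
        part1, part2 = _bin("bin01", 150), _bin("bin02", 79)
        donor = _bin("bin34", 12)
        edits = [
            CurationEdit("merge_bin", "bin01", source_bin="bin02",
                         reason="plasmid_bin_merge"),
            CurationEdit("remove_contig", "bin01", contig_id="bin01_0", reason="wrong_rRNA"),
            CurationEdit("remove_contig", "bin01", contig_id="bin02_0", reason="wrong_tRNA"),
            CurationEdit("add_contig", "bin01", contig_id="bin34_3",
                         source_bin="bin34", reason="authentic_rRNA"),
        ]
        curated, pool, log = apply_curation([part1, part2, donor], edits)
        by_id = {b.bin_id: b for b in curated}
        assert "bin02" not in by_id  # merged away
        assert log.entries[0].after_count == 229
        assert len(by_id["bin01"].contig_ids) == 228

    def test_one_removal_two_rescues_748_to_749(self):
        host = _bin("host", 748)
        donor = _bin("bin20", 40)
        edits = [
            CurationEdit("remove_contig", "host", contig_id="host_7", reason="wrong_rRNA"),
            CurationEdit("add_contig", "host", contig_id="bin20_1",
                         source_bin="bin20", reason="authentic_rRNA"),
            CurationEdit("add_contig", "host", contig_id="bin20_2",
                         source_bin="bin20", reason="authentic_rRNA"),
        ]
        curated, _, _ = apply_curation([host, donor], edits)
        by_id = {b.bin_id: b for b in curated}
        assert len(by_id["host"].contig_ids) == 749


class TestEditSemantics:
    def test_removing_non_member_is_hard_error(self):
        with pytest.raises(CurationError, match="not a member"):
            apply_curation([_bin("b1", 3)],
                           [CurationEdit("remove_contig", "b1", contig_id="ghost")])

    def test_adding_existing_member_is_hard_error(self):
        with pytest.raises(CurationError, match="already in"):
            apply_curation([_bin("b1", 3)],
                           [CurationEdit("add_contig", "b1", contig_id="b1_0")])

    def test_add_from_pool_requires_pool_membership(self):
        with pytest.raises(CurationError, match="unbinned pool"):
            apply_curation([_bin("b1", 3)],
                           [CurationEdit("add_contig", "b1", contig_id="free1")],
                           unbinned=set())
        curated, pool, _ = apply_curation(
            [_bin("b1", 3)],
            [CurationEdit("add_contig", "b1", contig_id="free1")],
            unbinned={"free1"})
        assert "free1" in curated[0].contig_ids and pool == set()

    def test_merge_overlap_rejected(self):
        a = BinRecord(bin_id="a", contig_ids={"c1", "c2"})
        b = BinRecord(bin_id="b", contig_ids={"c2", "c3"})
        with pytest.raises(CurationError, match="duplicate"):
            apply_curation([a, b], [CurationEdit("merge_bin", "a", source_bin="b")])

    def test_merge_sums_sizes(self):
        a = _bin("a", 2, size_bp=1000)
        b = _bin("b", 2, size_bp=500)
        curated, _, _ = apply_curation([a, b], [CurationEdit("merge_bin", "a", source_bin="b")])
        assert curated[0].size_bp == 1500

    def test_unknown_action_or_reason_rejected(self):
        with pytest.raises(ValueError):
            CurationEdit("explode_bin", "b1")
        with pytest.raises(ValueError):
            CurationEdit("remove_contig", "b1", contig_id="c", reason="felt_like_it")

    def test_contig_conservation_under_random_scripts(self):
        rng = np.random.default_rng(11)
        bins = [_bin(f"b{i}", 20) for i in range(4)]
        all_ids = {c for b in bins for c in b.contig_ids}
        state = {b.bin_id: set(b.contig_ids) for b in bins}
        pool0 = {"p1", "p2"}
        edits = []
        pool_now = set(pool0)
        for _ in range(50):
            target = f"b{rng.integers(4)}"
            members = sorted(state[target])
            if rng.random() < 0.5 and members:
                cid = members[rng.integers(len(members))]
                edits.append(CurationEdit("remove_contig", target, contig_id=cid))
                state[target].discard(cid)
                pool_now.add(cid)
            elif pool_now:
                cid = sorted(pool_now)[rng.integers(len(pool_now))]
                edits.append(CurationEdit("add_contig", target, contig_id=cid))
                state[target].add(cid)
                pool_now.discard(cid)
        curated, pool, _ = apply_curation(bins, edits, unbinned=pool0)
        final = {c for b in curated for c in b.contig_ids} | pool
        assert final == all_ids | pool0  # nothing created or destroyed

    def test_inputs_not_mutated_and_replay_deterministic(self):
        host = _bin("host", 10)
        before = set(host.contig_ids)
        edits = [CurationEdit("remove_contig", "host", contig_id="host_0")]
        curated1, pool1, log = apply_curation([host], edits)
        assert host.contig_ids == before  # originals untouched
        curated2, pool2, _ = replay([host], log)
        assert {b.bin_id: b.contig_ids for b in curated1} == \
               {b.bin_id: b.contig_ids for b in curated2}
        assert pool1 == pool2

    def test_edit_script_roundtrip(self, tmp_path):
        edits = [
            CurationEdit("remove_contig", "host", contig_id="c1", reason="wrong_rRNA",
                         note="23S best hit elsewhere"),
            CurationEdit("add_contig", "host", contig_id="c9", source_bin="bin40",
                         reason="authentic_rRNA"),
            CurationEdit("merge_bin", "host", source_bin="bin02", reason="plasmid_bin_merge"),
        ]
        p = tmp_path / "edits.tsv"
        write_edit_script(edits, p)
        assert read_edit_script(p) == edits


class TestSuggestions:
    def test_foreign_rrna_proposed_for_removal_matching_proposed_for_addition(self):
        host = BinRecord(bin_id="host", contig_ids={"h1", "h2"})
        other = BinRecord(bin_id="bin40", contig_ids={"o1"})
        features = [
            FeatureRecord(contig_id="h2", feature_type="rRNA_16S", start=1, end=1500, strand="+"),
            FeatureRecord(contig_id="o1", feature_type="rRNA_23S", start=1, end=2900, strand="+"),
        ]
        calls = {"h2": "Devosia riboflavina", "o1": "Stigonema ocellatum"}
        proposals = suggest_rrna_edits(host, features, calls, "Stigonema ocellatum",
                                       all_bins=[host, other])
        actions = {(p.action, p.contig_id) for p in proposals}
        assert ("remove_contig", "h2") in actions
        assert ("add_contig", "o1") in actions
        add = next(p for p in proposals if p.action == "add_contig")
        assert add.source_bin == "bin40"

    def test_matching_member_rrna_kept(self):
        host = BinRecord(bin_id="host", contig_ids={"h1"})
        features = [FeatureRecord(contig_id="h1", feature_type="rRNA_16S",
                                  start=1, end=1500, strand="+")]
        proposals = suggest_rrna_edits(host, features, {"h1": "Stigonema sp."},
                                       "Stigonema ocellatum")
        assert proposals == []


class TestAssemblyStats:
    def test_n50_textbook_example(self):
        contigs = [Contig(id=f"c{i}", length=l, gc_count=0)
                   for i, l in enumerate([1, 2, 3, 4, 10])]
        assert assembly_stats(contigs).n50 == 10

    def test_size_gc_and_counts(self):
        contigs = [Contig(id="c1", length=100, sequence="GC" * 50),
                   Contig(id="c2", length=100, sequence="AT" * 50)]
        stats = assembly_stats(contigs)
        assert stats == AssemblyStats(size_bp=200, n_contigs=2, gc_percent=50.0, n50=100)

    def test_empty_bin_raises(self):
        with pytest.raises(ValueError):
            assembly_stats([])
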