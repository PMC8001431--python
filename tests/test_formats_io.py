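import pandas as pd
import pytest

from cyanosphere import formats_io as fio


def _blast_line(query="q1", ident=99.1, evalue=1e-50, bitscore=500.0,
                stitle="Some organism, complete genome"):
    cols = [query, "subj", f"{ident}", "1000", "0", "0", "1", "1000", "1", "1000",
            f"{evalue}", f"{bitscore}", stitle]
    return "\t".join(cols)


class TestBlastTable:
    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("")
        assert fio.read_blast_table(p) == []

    def test_identities_parsed_in_row_order(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(_blast_line(ident=99.1) + "\n" + _blast_line(ident=85.0) + "\n")
        hits = fio.read_blast_table(p)
        assert [h.pct_identity for h in hits] == [99.1, 85.0]

    def test_title_with_commas_preserved_verbatim(self, tmp_path):
        title = "Microcystis aeruginosa NIES-843 DNA, complete genome"
        p = tmp_path / "hits.tsv"
        p.write_text(_blast_line(stitle=title) + "\n")
        hits = fio.read_blast_table(p)
        assert hits[0].stitle == title
        # round-trip through the writer
        out = tmp_path / "rt.tsv"
        fio.write_blast_table(hits, out)
        assert fio.read_blast_table(out)[0].stitle == title

    def test_missing_stitle_rejected_when_expected(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("\t".join(_blast_line().split("\t")[:12]) + "\n")
        with pytest.raises(fio.FormatError, match="stitle"):
            fio.read_blast_table(p, expect_stitle=True)
        assert fio.read_blast_table(p, expect_stitle=False)[0].stitle == ""

    def test_malformed_row_names_line_number(self, tmp_path):
        p = tmp_path / "hits.tsv"
        bad = _blast_line().split("\t")
        bad[2] = "not-a-number"
        p.write_text(_blast_line() + "\n" + "\t".join(bad) + "\n")
        with pytest.raises(fio.FormatError, match=":2"):
            fio.read_blast_table(p)

    def test_one_hit_per_nonempty_line(self, tmp_path):
        p = tmp_path / "hits.tsv"
        lines = [_blast_line(query=f"q{i}") for i in range(7)]
        p.write_text("\n".join(lines) + "\n\n")
        assert len(fio.read_blast_table(p)) == 7


class TestBinTables:
    def _write(self, tmp_path, assignments, quality, coverage):
        a, q, c = tmp_path / "a.tsv", tmp_path / "q.tsv", tmp_path / "c.tsv"
        a.write_text("contig_id\tbin_id\n" + "".join(f"{c_}\t{b}\n" for c_, b in assignments))
        q.write_text("bin_id\tcompleteness\tcontamination\n" +
                     "".join(f"{b}\t{x}\t{y}\n" for b, x, y in quality))
        c.write_text("bin_id\tcoverage\n" + "".join(f"{b}\t{v}\n" for b, v in coverage))
        return a, q, c

    def test_simple_join(self, tmp_path):
        a, q, c = self._write(tmp_path,
                              [("c1", "b1"), ("c2", "b1"), ("c3", "b1")],
                              [("b1", 99.0, 1.0)], [("b1", 50.0)])
        (rec,) = fio.read_bin_tables(a, q, c)
        assert rec.contig_ids == {"c1", "c2", "c3"}
        assert (rec.completeness, rec.contamination, rec.coverage) == (99.0, 1.0, 50.0)

    def test_contig_in_two_bins_rejected(self, tmp_path):
        a, q, c = self._write(tmp_path, [("c1", "b1"), ("c1", "b2")],
                              [("b1", 99, 1)], [("b1", 50)])
        with pytest.raises(fio.ConsistencyError):
            fio.read_bin_tables(a, q, c)

    def test_duplicate_quality_rows_rejected(self, tmp_path):
        a, q, c = self._write(tmp_path, [("c1", "b1")],
                              [("b1", 99, 1), ("b1", 98, 2)], [("b1", 50)])
        with pytest.raises(fio.ConsistencyError):
            fio.read_bin_tables(a, q, c)

    def test_missing_metrics_are_none_not_zero(self, tmp_path):
        a, q, c = self._write(tmp_path, [("c1", "b1"), ("c2", "b2")],
                              [("b1", 99, 1)], [("b1", 50)])
        recs = {r.bin_id: r for r in fio.read_bin_tables(a, q, c)}
        assert recs["b2"].completeness is None
        assert recs["b2"].coverage is None

    def test_published_style_summary_roundtrip(self, tmp_path):
        """A re-typed five-bin summary parses with thousands separators."""
        rows = [
            ("bin03", "97.82", "0.11", "746", "5,354,489", "85.91"),
            ("bin04", "100.00", "5.55", "277", "4,200,065", "58.22"),
            ("bin05", "94.48", "4.22", "247", "2,796,749", "49.08"),
            ("bin06", "99.53", "1.40", "378", "4,670,292", "34.15"),
            ("bin07", "98.54", "2.51", "174", "3,619,276", "29.06"),
        ]
        p = tmp_path / "bins.tsv"
        p.write_text("bin_id\tcompleteness\tcontamination\tcontigs\tsize_bp\tcoverage\n" +
                     "".join("\t".join(r) + "\n" for r in rows))
        recs = {r.bin_id: r for r in fio.read_bin_summary(p)}
        assert len(recs) == 5
        assert recs["bin03"].coverage == 85.91
        assert recs["bin03"].size_bp == 5354489

    def test_size_unknown_when_contig_absent_from_fasta(self, tmp_path):
        a, q, c = self._write(tmp_path, [("c1", "b1"), ("ghost", "b1")],
                              [("b1", 99, 1)], [("b1", 50)])
        (rec,) = fio.read_bin_tables(a, q, c)
        fio.attach_contig_sizes([rec], [fio.Contig(id="c1", length=100, sequence="A" * 100)])
        assert rec.size_bp is None

    def test_join_is_loss_free(self, tmp_path):
        assignments = [(f"c{i}", f"b{i % 3}") for i in range(30)]
        a, q, c = self._write(tmp_path, assignments,
                              [(f"b{i}", 90, 1) for i in range(3)],
                              [(f"b{i}", 10) for i in range(3)])
        recs = fio.read_bin_tables(a, q, c)
        seen = [cid for r in recs for cid in r.contig_ids]
        assert sorted(seen) == sorted(cid for cid, _ in assignments)


class TestFeatures:
    def test_gff3_product_synonym_mapping(self, tmp_path):
        p = tmp_path / "f.gff3"
        p.write_text(
            "##gff-version 3\n"
            'ctg1\tprodigal\trRNA\t10\t1500\t.\t+\t.\tID=r1;product=16S ribosomal RNA\n'
        )
        (rec,) = fio.read_features(p)
        assert rec.feature_type == "rRNA_16S"
        assert (rec.start, rec.end, rec.strand) == (10, 1500, "+")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("")
        assert fio.read_features(p) == []

    def test_mixed_tsv_types(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text(
            "contig_id\tfeature_type\tstart\tend\tstrand\n"
            "c1\t16S rRNA\t1\t1500\t+\n"
            "c2\t23S ribosomal RNA\t5\t2900\t-\n"
            "c3\ttRNA-Ala\t1\t76\t+\n"
            "c4\thypothetical protein\t1\t300\t+\n"
        )
        recs = fio.read_features(p)
        assert [r.feature_type for r in recs] == ["rRNA_16S", "rRNA_23S", "tRNA", "other"]

    def test_reversed_coordinates_rejected(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("c1\t16S rRNA\t100\t10\t+\n")
        with pytest.raises(fio.FormatError):
            fio.read_features(p)


class TestWriteReport:
    def test_percent_rendering_two_decimals(self, tmp_path):
        out = tmp_path / "r.tsv"
        fio.write_report([{"name": "coding", "pct": 0.770999 * 100}], out, percent_cols=("pct",))
        lines = out.read_text().splitlines()
        assert lines[1].split("\t")[1] == "77.10"

    def test_single_row_has_header_plus_row(self, tmp_path):
        out = tmp_path / "r.tsv"
        fio.write_report([{"a": 1, "b": 2}], out)
        assert len(out.read_text().splitlines()) == 2

    def test_empty_frame_is_header_only(self, tmp_path):
        out = tmp_path / "r.tsv"
        fio.write_report(pd.DataFrame(columns=["a", "b"]), out)
        assert out.read_text().splitlines() == ["a\tb"]

    def test_roundtrip_to_rendered_precision(self, tmp_path):
        out = tmp_path / "r.tsv"
        rows = [{"bin": "b1", "share": 33.333333}, {"bin": "b2", "share": 66.666667}]
        fio.write_report(rows, out, percent_cols=("share",))
        back = pd.read_csv(out, sep="\t")
        assert list(back["share"]) == [33.33, 66.67]
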