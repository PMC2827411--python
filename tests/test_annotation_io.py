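"""annotation_io: genePred/PSL parsing, identity filtering, integration."""

import io

import pytest

from remapkit.annotation_io import (
    AnnotationParseError,
    DEFAULT_NEAR_BEST_WINDOW,
    SourceDB,
    TranscriptAlignment,
    TranscriptCollection,
    filter_transcript_alignments,
    integrate_collections,
    parse_genepred,
    parse_psl,
    parse_xref,
    write_genepred,
)
from remapkit.synthetic_fixtures import SimConfig, simulate_annotation

from conftest import make_transcript


class TestGenePred:
    def test_single_exon_line_maps_directly(self):
        coll = parse_genepred(io.StringIO("t1\tchr1\t+\t100\t200\t100\t200\t1\t100,\t200,\n"))
        (rec,) = coll.records
        assert rec.exons == ((100, 200),)
        assert (rec.cds_start, rec.cds_end) == (100, 200)
        assert rec.is_coding

    @pytest.mark.parametrize(
        "line,match",
        [
            ("t1\tchr1\t+\t100\t200\t100\t200\t2\t100,150,180,\t140,200,\n", "exonCount"),
            ("t1\tchr1\t+\t100\tabc\t100\t200\t1\t100,\t200,\n", "coordinate"),
            ("t1\tchr1\t+\t200\t100\t100\t100\t1\t200,\t100,\n", ""),
            ("t1\tchr1\t+\t100\t200\t100\t200\t1\t100,\n", "fields"),
        ],
    )
    def test_malformed_lines_name_the_line(self, line, match):
        with pytest.raises(AnnotationParseError, match="line 1"):
            parse_genepred(io.StringIO(line))

    def test_duplicate_transcript_id_rejected(self):
        text = (
            "t1\tchr1\t+\t100\t200\t100\t200\t1\t100,\t200,\n"
            "t1\tchr1\t+\t300\t400\t300\t400\t1\t300,\t400,\n"
        )
        with pytest.raises(AnnotationParseError, match="duplicate"):
            parse_genepred(io.StringIO(text))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_identity(self, seed):
        """Write-then-parse reproduces every record of a simulated collection."""
        ann = simulate_annotation(SimConfig(seed=seed))
        buf = io.StringIO()
        write_genepred(ann.collection, buf, header="round trip")
        buf.seek(0)
        reread = parse_genepred(buf)
        assert len(reread) == len(ann.collection)
        for rec in ann.collection:
            got = reread.get(rec.transcript_id)
            assert (got.chrom, got.strand, got.exons) == (rec.chrom, rec.strand, rec.exons)
            assert (got.cds_start, got.cds_end) == (rec.cds_start, rec.cds_end)


PSL_ROW = (
    "960\t40\t0\t0\t0\t0\t1\t500\t+\tq1\t1000\t0\t1000\tchr1\t50000\t2000\t3500\t"
    "2\t400,600,\t0,400,\t2000,2900,\n"
)


class TestPSL:
    def test_identity_is_match_ratio(self):
        (aln,) = parse_psl(io.StringIO(PSL_ROW))
        assert aln.base_identity == pytest.approx(0.96)
        assert aln.chrom == "chr1"
        assert aln.blocks == ((2000, 2400), (2900, 3500))

    def test_empty_stream_gives_empty_list(self):
        assert parse_psl(io.StringIO("")) == []

    def test_header_prefixed_equals_headerless(self):
        header = (
            "psLayout version 3\n\n"
            "match\tmis- \trep. \tN's\tQ gap\tQ gap\tT gap\tT gap\tstrand\tQ\n"
            "     \tmatch\tmatch\t   \tcount\tbases\tcount\tbases\t      \tname\n"
            "---------------------------------------------------------------\n"
        )
        assert parse_psl(io.StringIO(header + PSL_ROW)) == parse_psl(io.StringIO(PSL_ROW))

    def test_wrong_column_count_rejected(self):
        with pytest.raises(AnnotationParseError, match="21"):
            parse_psl(io.StringIO("960\t40\t0\n"))


def _aln(tid, identity, source=SourceDB.REFSEQ, start=1000):
    return TranscriptAlignment(
        transcript_id=tid, source_db=source, chrom="chr1", strand="+",
        tx_start=start, tx_end=start + 100, blocks=((start, start + 100),),
        base_identity=identity,
    )


class TestAlignmentFilter:
    def test_min_identity_boundary(self):
        """The 96% identity cut keeps 0.960 and drops 0.959."""
        coll = filter_transcript_alignments([_aln("a", 0.959), _aln("b", 0.960)])
        assert [r.transcript_id for r in coll] == ["b"]

    def test_refseq_near_best_window(self):
        """RefSeq placements within 0.1% of the best survive; worse ones drop."""
        both = filter_transcript_alignments([_aln("t", 0.990), _aln("t", 0.9895, start=5000)])
        assert len(both) == 2
        only_best = filter_transcript_alignments([_aln("t", 0.990), _aln("t", 0.988, start=5000)])
        assert len(only_best) == 1
        assert only_best.records[0].tx_start == 1000

    def test_genbank_window_is_wider(self):
        assert DEFAULT_NEAR_BEST_WINDOW[SourceDB.GENBANK] == pytest.approx(0.005)
        kept = filter_transcript_alignments(
            [_aln("t", 0.99, SourceDB.GENBANK), _aln("t", 0.986, SourceDB.GENBANK, start=5000)]
        )
        assert len(kept) == 2

    def test_single_placement_kept_unchanged(self):
        coll = filter_transcript_alignments([_aln("t", 0.97)])
        (rec,) = coll.records
        assert rec.transcript_id == "t"
        assert rec.exons == ((1000, 1100),)

    def test_monotone_in_min_identity(self):
        """Raising min_identity never adds records; the filter is idempotent."""
        alns = [_aln(f"t{i}", 0.9 + 0.01 * i, start=1000 * i + 100) for i in range(10)]
        previous = None
        for cut in (0.90, 0.94, 0.96, 0.99):
            ids = {r.transcript_id for r in filter_transcript_alignments(alns, min_identity=cut)}
            if previous is not None:
                assert ids <= previous
            previous = ids

    def test_cds_attached_when_supplied(self):
        coll = filter_transcript_alignments([_aln("t", 0.99)], cds={"t": (1010, 1090)})
        assert (coll.records[0].cds_start, coll.records[0].cds_end) == (1010, 1090)
        nocds = filter_transcript_alignments([_aln("t", 0.99)])
        assert not nocds.records[0].is_coding


class TestIntegrate:
    def _coll(self, n, prefix, source, name):
        recs = [
            make_transcript(f"{prefix}{i}", [(i * 1000, i * 1000 + 100)], source=source)
            for i in range(n)
        ]
        return TranscriptCollection(tuple(recs), name=name)

    def test_disjoint_union(self):
        colls = [
            self._coll(2, "a", SourceDB.GENBANK, "genbank"),
            self._coll(3, "b", SourceDB.REFSEQ, "refseq"),
            self._coll(4, "c", SourceDB.ENSEMBL, "ensembl"),
        ]
        merged = integrate_collections(colls)
        assert len(merged) == 9
        assert max(len(c) for c in colls) <= len(merged) <= sum(len(c) for c in colls)

    def test_collision_retains_both_under_prefixes(self):
        a = self._coll(1, "x", SourceDB.GENBANK, "genbank")
        b = self._coll(1, "x", SourceDB.REFSEQ, "refseq")
        merged = integrate_collections([a, b])
        ids = sorted(r.transcript_id for r in merged)
        assert ids == ["genbank:x0", "refseq:x0"]

    def test_empty_input(self):
        assert len(integrate_collections([])) == 0


def test_parse_xref_rejects_conflicting_mapping():
    good = parse_xref(io.StringIO("t1\tgA\nt2\tgA\nt3\tgB\n"))
    assert good == {"t1": "gA", "t2": "gA", "t3": "gB"}
    with pytest.raises(AnnotationParseError):
        parse_xref(io.StringIO("t1\tgA\nt1\tgB\n"))
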