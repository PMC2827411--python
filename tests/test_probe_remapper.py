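"""probe_remapper: matching, rescue, classification, grouping, comparison."""

import io
import random

import pytest

from remapkit.annotation_io import TranscriptCollection
from remapkit.gene_definition import LinkageMethod, cluster_transcripts
from remapkit.probe_remapper import (
    ACCOUNTING_LABELS,
    MatchType,
    ProbeClass,
    ProbeRecord,
    Sense,
    assign_signature,
    classify_and_group,
    compare_remappings,
    good_probe_percentage,
    match_probes,
    read_probeset_definitions,
    rescue_junction_probes,
    reverse_complement,
    summarize_category_counts,
    write_probeset_files,
)

from conftest import make_transcript, run_remap


def _genome(seed=0, n=2000):
    rng = random.Random(seed)
    return {"chr1": "".join(rng.choice("ACGT") for _ in range(n))}


class TestMatchProbes:
    def test_forward_hit(self):
        g = _genome()
        probe = ProbeRecord("p", g["chr1"][100:125])
        (hit,) = match_probes([probe], g)
        assert (hit.chrom, hit.strand, hit.start, hit.end) == ("chr1", "+", 100, 125)
        assert hit.match_type is MatchType.GENOMIC

    def test_reverse_complement_hit_on_minus_strand(self):
        g = _genome()
        probe = ProbeRecord("p", reverse_complement(g["chr1"][200:225]))
        (hit,) = match_probes([probe], g)
        assert (hit.strand, hit.start) == ("-", 200)

    def test_probe_planted_at_two_loci_gets_two_hits(self):
        g = _genome()
        seq = list(g["chr1"])
        seq[500:525] = seq[100:125]
        g = {"chr1": "".join(seq)}
        hits = match_probes([ProbeRecord("p", g["chr1"][100:125])], g)
        assert sorted(h.start for h in hits) == [100, 500]

    def test_non_acgt_probe_skipped_with_warning(self, caplog):
        g = _genome()
        with caplog.at_level("WARNING"):
            hits = match_probes([ProbeRecord("p", "N" * 25)], g)
        assert hits == []
        assert "non-ACGT" in caplog.text


class TestJunctionRescue:
    def _world(self, strand="+"):
        g = _genome(3, 3000)
        t = make_transcript("t1", [(100, 300), (500, 800)], strand=strand)
        return g, TranscriptCollection((t,))

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_junction_probe_rescued_with_no_genomic_hit(self, strand):
        g, coll = self._world(strand)
        # transcript-sense sequence across the junction: 13 + 12 bases
        chunk = g["chr1"][287:300] + g["chr1"][500:512]
        probe_seq = reverse_complement(chunk) if strand == "-" else chunk
        probe = ProbeRecord("jp", probe_seq)
        assert match_probes([probe], g) == []
        (hit,) = rescue_junction_probes([probe], coll, g)
        assert hit.match_type is MatchType.SPLICED
        assert hit.transcripts == ("t1",)
        assert hit.strand == strand  # sense match
        assert hit.start == 287  # leftmost genomic base covered

    def test_probe_matching_two_transcripts_signature_is_both(self):
        g = _genome(3, 3000)
        t1 = make_transcript("t1", [(100, 300), (500, 800)])
        t2 = make_transcript("t2", [(50, 300), (500, 700)])  # same junction
        coll = TranscriptCollection((t1, t2))
        probe = ProbeRecord("jp", g["chr1"][287:300] + g["chr1"][500:512])
        hits = rescue_junction_probes([probe], coll, g)
        assert {h.transcripts[0] for h in hits} == {"t1", "t2"}

    def test_transcript_on_absent_chromosome_skipped(self, caplog):
        g, _ = self._world()
        coll = TranscriptCollection(
            (make_transcript("ghost", [(0, 100)], chrom="chrMissing"),)
        )
        with caplog.at_level("WARNING"):
            hits = rescue_junction_probes([ProbeRecord("p", "A" * 25)], coll, g)
        assert hits == []
        assert "absent chromosome" in caplog.text


class TestAssignSignature:
    def _setup(self):
        t1 = make_transcript("t1", [(100, 300), (500, 800)])
        t2 = make_transcript("t2", [(100, 300), (500, 700)])
        t3 = make_transcript("t3", [(100, 300)])
        coll = TranscriptCollection((t1, t2, t3))
        genes = cluster_transcripts(coll, LinkageMethod.EXLINK)
        return coll, genes

    def _hit(self, start, strand="+"):
        from remapkit.probe_remapper import ProbeGenomeHit

        return ProbeGenomeHit("p", "chr1", strand, start, start + 25, MatchType.GENOMIC)

    def test_constitutive_exon_signature_is_all_transcripts(self):
        coll, genes = self._setup()
        a = assign_signature(self._hit(150), genes, coll)
        assert a.signature == frozenset({"t1", "t2", "t3"})
        assert a.sense is Sense.SENSE
        assert len(a.gene_ids) == 1

    def test_isoform_specific_exon(self):
        coll, genes = self._setup()
        a = assign_signature(self._hit(710), genes, coll)  # only t1's exon reaches 800
        assert a.signature == frozenset({"t1"})

    def test_exon_edge_straddler_has_no_signature(self):
        coll, genes = self._setup()
        assert assign_signature(self._hit(290), genes, coll) is None  # 13 exonic bases

    def test_antisense_hit(self):
        coll, genes = self._setup()
        a = assign_signature(self._hit(150, strand="-"), genes, coll)
        assert a.sense is Sense.ANTISENSE


class TestClassifyAndGroup:
    def test_truth_vector_reproduced(self, sim_world, sim_remapping):
        _, probes, truth = sim_world
        got = {c: 0 for c in ProbeClass}
        for c in sim_remapping.probe_class.values():
            got[c] += 1
        assert got == {c: truth.category_counts().get(c, 0) for c in ProbeClass}
        assert sim_remapping.accounting.total == len(probes)
        assert len(sim_remapping.probe_sets) == truth.probe_set_count

    def test_min_probes_one_disables_the_size_filter(self, sim_world):
        annotation, probes, _ = sim_world
        res = run_remap(annotation, probes, min_probes=1)
        assert res.accounting.counts[ProbeClass.UNDERPOPULATED_SET] == 0

    def test_min_probes_sweep_is_monotone_in_good(self, sim_world):
        annotation, probes, _ = sim_world
        goods = [
            run_remap(annotation, probes, min_probes=k).accounting.counts[ProbeClass.GOOD]
            for k in (1, 2, 3, 4, 5)
        ]
        assert goods == sorted(goods, reverse=True)

    def test_no_probe_in_two_sets(self, sim_remapping):
        seen = set()
        for ps in sim_remapping.probe_sets:
            assert not (ps.probe_ids & seen)
            seen |= ps.probe_ids

    def test_antisense_set_flagged_rc_and_good(self, sim_remapping):
        rc_sets = [ps for ps in sim_remapping.probe_sets if ps.sense is Sense.ANTISENSE]
        assert rc_sets
        assert all(ps.probe_set_id.endswith("_RC") for ps in rc_sets)

    def test_drop_antisense_filters_rc_sets(self, sim_world):
        annotation, probes, truth = sim_world
        from remapkit.gene_definition import cluster_transcripts
        from remapkit.probe_remapper import match_probes, rescue_junction_probes

        genes = cluster_transcripts(annotation.collection, LinkageMethod.EXLINK)
        hits = match_probes(probes, annotation.genome)
        matched = {h.probe_id for h in hits}
        hits += rescue_junction_probes(
            [p for p in probes if p.probe_id not in matched],
            annotation.collection, annotation.genome,
        )
        res = classify_and_group(probes, hits, genes, annotation.collection,
                                 drop_antisense=True)
        assert all(ps.sense is Sense.SENSE for ps in res.probe_sets)
        assert res.accounting.total == len(probes)

    def test_enlarging_collection_never_adds_unannotated_probes(self, sim_world):
        """Dropping transcripts (a database view) can only move probes toward
        INTRONIC/INTERGENIC, never away from them."""
        annotation, probes, _ = sim_world
        full = run_remap(annotation, probes)
        n_full = (
            full.accounting.counts[ProbeClass.INTRONIC]
            + full.accounting.counts[ProbeClass.INTERGENIC]
        )
        for view in annotation.views.values():
            sub_ids = {r.transcript_id for r in view}
            kept = TranscriptCollection(
                tuple(r for r in annotation.collection if r.transcript_id in sub_ids),
                name=view.name,
            )
            genes = cluster_transcripts(kept, LinkageMethod.EXLINK)
            from remapkit.probe_remapper import match_probes, rescue_junction_probes

            hits = match_probes(probes, annotation.genome)
            matched = {h.probe_id for h in hits}
            hits += rescue_junction_probes(
                [p for p in probes if p.probe_id not in matched], kept, annotation.genome
            )
            res = classify_and_group(probes, hits, genes, kept)
            n_view = (
                res.accounting.counts[ProbeClass.INTRONIC]
                + res.accounting.counts[ProbeClass.INTERGENIC]
            )
            assert n_view >= n_full


class TestAccounting:
    def test_percentage_to_three_decimals(self):
        assert good_probe_percentage(117782, 249752) == 47.160
        assert good_probe_percentage(0, 0) == 0.0

    def test_summary_requires_good_entry(self):
        with pytest.raises(KeyError):
            summarize_category_counts({"a": 1}, good_label="Good probes")

    def test_row_labels_match_published_wording(self, sim_remapping):
        labels = [r[0] for r in sim_remapping.accounting.rows()]
        assert labels[:7] == [
            "Probes with multiple alignments to the genome",
            "Probes with no alignment to the genome",
            "Probes matching multiple genes",
            "Probes matching intergenic region",
            "Probes matching intron region",
            "< 3 probes per probe set",
            "Good probes",
        ]
        assert labels[7:] == ["Percentage of good probes", "Probe sets"]
        assert set(ACCOUNTING_LABELS) == set(ProbeClass)


class TestCompare:
    def test_identical_results_all_same(self, sim_remapping):
        table = compare_remappings(sim_remapping, sim_remapping)
        assert table.diff == table.unique_a == table.unique_b == 0
        assert table.same == len({ps.gene_id for ps in sim_remapping.probe_sets})

    def test_split_probe_set_counts_diff(self, sim_remapping):
        import copy
        from remapkit.probe_remapper import ProbeSetDefinition

        other = copy.deepcopy(sim_remapping)
        big = max(other.probe_sets, key=lambda ps: len(ps.probe_ids))
        ids = sorted(big.probe_ids)
        half = len(ids) // 2
        other.probe_sets.remove(big)
        for i, chunk in enumerate((ids[:half], ids[half:])):
            other.probe_sets.append(
                ProbeSetDefinition(
                    probe_set_id=f"{big.probe_set_id}.{i}",
                    gene_id=big.gene_id,
                    signature=big.signature,
                    sense=big.sense,
                    probe_ids=frozenset(chunk),
                )
            )
        table = compare_remappings(sim_remapping, other)
        assert table.diff == 1
        assert table.same == len({ps.gene_id for ps in sim_remapping.probe_sets}) - 1

    def test_gene_present_only_in_a_is_unique(self, sim_remapping):
        import copy

        other = copy.deepcopy(sim_remapping)
        victim = other.probe_sets[0].gene_id
        dropped = [ps for ps in other.probe_sets if ps.gene_id == victim]
        for ps in dropped:
            other.probe_sets.remove(ps)
            for pid in ps.probe_ids:
                other.probe_class[pid] = ProbeClass.UNDERPOPULATED_SET
        table = compare_remappings(sim_remapping, other)
        assert table.unique_a == 1

    def test_different_probe_universe_rejected(self, sim_remapping):
        import copy

        other = copy.deepcopy(sim_remapping)
        other.probe_class["stranger"] = ProbeClass.NO_GENOME
        with pytest.raises(ValueError, match="universe"):
            compare_remappings(sim_remapping, other)


class TestFiles:
    def test_definition_rows_and_round_trip(self, sim_remapping):
        d, a, n = io.StringIO(), io.StringIO(), io.StringIO()
        write_probeset_files(sim_remapping, d, a, n, header="test run")
        n_rows = sum(
            1 for line in d.getvalue().splitlines()
            if line and not line.startswith(("#", "probe_set_id"))
        )
        assert n_rows == sum(len(ps.probe_ids) for ps in sim_remapping.probe_sets)
        d.seek(0)
        reread = read_probeset_definitions(d)
        assert sorted(reread, key=lambda p: p.probe_set_id) == sorted(
            sim_remapping.probe_sets, key=lambda p: p.probe_set_id
        )

    def test_output_is_deterministic_across_input_orderings(self, sim_world):
        annotation, probes, _ = sim_world
        shuffled = list(probes)
        random.Random(5).shuffle(shuffled)
        out = []
        for plist in (list(probes), shuffled):
            res = run_remap(annotation, plist)
            d, a, n = io.StringIO(), io.StringIO(), io.StringIO()
            write_probeset_files(res, d, a, n)
            out.append((d.getvalue(), a.getvalue(), n.getvalue()))
        assert out[0] == out[1]
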