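"""Gene-model parsing, intron derivation and the two selection filters."""
import numpy as np
import pytest

from chromprofiler.annotation import (
    GenomeAnnotation,
    GtfParseError,
    derive_introns,
    read_gtf,
    select_exon_transcripts,
    select_metagene_genes,
    write_gtf,
)
from chromprofiler.intervals import GenomicInterval
from chromprofiler.synth import SyntheticGenomeSpec, generate_annotation

from conftest import (
    brute_force_isolated,
    brute_force_nonoverlapping,
    make_gene,
    make_transcript,
)


class TestGtfIO:
    def test_coordinate_convention(self, tmp_path):
        """GTF 1-based closed [101, 200] becomes internal 0-based [100, 200)."""
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\t'
            'gene_id "g1"; transcript_id "t1"; gene_biotype "protein_coding";\n'
        )
        ann = read_gtf(gtf)
        (gene,) = ann.genes
        exon = gene.transcripts[0].exons[0]
        assert (exon.start, exon.end) == (100, 200)

    def test_empty_file_gives_empty_annotation(self, tmp_path):
        gtf = tmp_path / "empty.gtf"
        gtf.write_text("")
        ann = read_gtf(gtf)
        assert len(ann) == 0

    def test_malformed_line_names_line_number(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text("# header\nchr1\tonly\tthree\n")
        with pytest.raises(GtfParseError, match="line 2"):
            read_gtf(gtf)

    def test_exon_without_transcript_id_errors(self, tmp_path):
        gtf = tmp_path / "orphan.gtf"
        gtf.write_text('chr1\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "g1";\n')
        with pytest.raises(GtfParseError, match="transcript_id"):
            read_gtf(gtf)

    def test_synthetic_gtf_matches_generator_truth(self, tmp_path, synth_ann):
        """Round trip: generator -> GTF -> read_gtf preserves gene count and
        per-gene exon counts recorded in the ground truth."""
        ann, truth = synth_ann
        path = tmp_path / "synth.gtf"
        write_gtf(ann, path)
        ann2 = read_gtf(path, chrom_sizes=ann.chrom_sizes)
        assert len(ann2) == len(truth["genes"])
        for g in ann2.genes:
            t = truth["genes"][g.id]
            longest = max(g.transcripts, key=lambda x: x.span.length)
            assert len(longest.exons) == t["n_exons"]
            assert (g.span.start, g.span.end) == (t["start"], t["end"])
            assert g.strand == t["strand"]
            assert g.biotype == t["biotype"]

    def test_round_trip_preserves_intervals_and_attrs(self, tmp_path, synth_ann):
        ann, _ = synth_ann
        p1, p2 = tmp_path / "one.gtf", tmp_path / "two.gtf"
        write_gtf(ann, p1)
        ann2 = read_gtf(p1, chrom_sizes=ann.chrom_sizes)
        write_gtf(ann2, p2)
        assert p1.read_text() == p2.read_text()

    def test_utr_features_attach_to_transcripts(self, tmp_path):
        lines = [
            'chr1\ts\texon\t1\t300\t.\t+\t.\tgene_id "g"; transcript_id "t"; gene_biotype "protein_coding";',
            'chr1\ts\tfive_prime_utr\t1\t50\t.\t+\t.\tgene_id "g"; transcript_id "t";',
            'chr1\ts\tthree_prime_utr\t251\t300\t.\t+\t.\tgene_id "g"; transcript_id "t";',
        ]
        ann = read_gtf_from_text(tmp_path, "\n".join(lines) + "\n")
        t = ann.genes[0].transcripts[0]
        assert [(u.start, u.end) for u in t.utr5] == [(0, 50)]
        assert [(u.start, u.end) for u in t.utr3] == [(250, 300)]


def read_gtf_from_text(tmp_path, text):
    p = tmp_path / "inline.gtf"
    p.write_text(text)
    return read_gtf(p)


class TestIntrons:
    @pytest.mark.parametrize(
        "exons,expected",
        [
            ([(100, 200), (300, 400)], [(200, 300)]),
            ([(0, 600)], []),
            ([(0, 10), (10, 20)], []),  # abutting exons: no zero-length intron
            ([(0, 10), (20, 30), (50, 80)], [(10, 20), (30, 50)]),
        ],
    )
    def test_intron_derivation(self, exons, expected):
        t = make_transcript("t", "g", "chr1", "+", exons)
        assert [(i.start, i.end) for i in derive_introns(t)] == expected

    def test_exons_and_introns_tile_span(self, synth_ann):
        """Sum of exon and intron lengths equals the transcript span length,
        with no overlap, for every synthetic transcript."""
        ann, _ = synth_ann
        for t in ann.transcripts:
            introns = derive_introns(t)
            pieces = sorted(
                [(e.start, e.end) for e in t.exons]
                + [(i.start, i.end) for i in introns]
            )
            total = sum(e - s for s, e in pieces)
            assert total == t.span.length
            for (s1, e1), (s2, e2) in zip(pieces, pieces[1:]):
                assert e1 == s2  # contiguous, no gap, no overlap


class TestMetageneSelection:
    def _two_gene_ann(self, gap):
        g1 = make_gene("A", "chr1", 10000, 11000)
        g2 = make_gene("B", "chr1", 11000 + gap, 12000 + gap)
        return GenomeAnnotation({"chr1": 100000}, [g1, g2])

    def test_distant_genes_both_selected(self):
        ann = self._two_gene_ann(gap=10000)
        assert [g.id for g in select_metagene_genes(ann)] == ["A", "B"]

    def test_close_genes_neither_selected(self):
        ann = self._two_gene_ann(gap=1000)
        assert select_metagene_genes(ann) == []

    def test_length_boundary_599_excluded_600_included(self):
        for length, expected in [(599, []), (600, ["S"])]:
            g = make_gene("S", "chr1", 50000, 50000 + length)
            ann = GenomeAnnotation({"chr1": 100000}, [g])
            assert [x.id for x in select_metagene_genes(ann)] == expected

    def test_nonprotein_neighbors_still_exclude(self):
        """A lncRNA within the window disqualifies a coding gene even though
        lncRNAs themselves are never selected."""
        coding = make_gene("C", "chr1", 10000, 11000)
        lnc = make_gene("L", "chr1", 12000, 12500, biotype="lncRNA")
        ann = GenomeAnnotation({"chr1": 100000}, [coding, lnc])
        assert select_metagene_genes(ann) == []

    def test_matches_brute_force_on_synthetic(self, synth_ann):
        ann, truth = synth_ann
        got = sorted(g.id for g in select_metagene_genes(ann))
        oracle = brute_force_isolated(ann.genes, ann.chrom_sizes)
        assert got == oracle == truth["metagene_gene_ids"]

    def test_order_independent(self, synth_ann):
        ann, _ = synth_ann
        shuffled = list(ann.genes)
        np.random.default_rng(0).shuffle(shuffled)
        ann2 = GenomeAnnotation(ann.chrom_sizes, shuffled)
        assert [g.id for g in select_metagene_genes(ann)] == [
            g.id for g in select_metagene_genes(ann2)
        ]


class TestExonTranscriptSelection:
    def test_longest_transcript_chosen(self):
        t_short = make_transcript("t.short", "G", "chr1", "+", [(0, 2000), (4000, 5000)])
        t_long = make_transcript("t.long", "G", "chr1", "+", [(0, 2000), (7000, 8000)])
        g = make_gene("G", "chr1", 0, 8000, transcripts=[t_short, t_long])
        ann = GenomeAnnotation({"chr1": 100000}, [g])
        assert [t.id for t in select_exon_transcripts(ann)] == ["t.long"]

    def test_tie_breaks_to_smallest_id(self):
        t_b = make_transcript("t.b", "G", "chr1", "+", [(0, 5000)])
        t_a = make_transcript("t.a", "G", "chr1", "+", [(0, 5000)])
        g = make_gene("G", "chr1", 0, 5000, transcripts=[t_b, t_a])
        ann = GenomeAnnotation({"chr1": 100000}, [g])
        assert [t.id for t in select_exon_transcripts(ann)] == ["t.a"]

    def test_one_bp_overlap_removes_both(self):
        t1 = make_transcript("t1", "G1", "chr1", "+", [(0, 1001)])
        t2 = make_transcript("t2", "G2", "chr1", "-", [(1000, 2000)])
        g1 = make_gene("G1", "chr1", 0, 1001, transcripts=[t1])
        g2 = make_gene("G2", "chr1", 1000, 2000, strand="-", transcripts=[t2])
        ann = GenomeAnnotation({"chr1": 100000}, [g1, g2])
        assert select_exon_transcripts(ann) == []

    def test_abutting_transcripts_both_kept(self):
        t1 = make_transcript("t1", "G1", "chr1", "+", [(0, 1000)])
        t2 = make_transcript("t2", "G2", "chr1", "-", [(1000, 2000)])
        g1 = make_gene("G1", "chr1", 0, 1000, transcripts=[t1])
        g2 = make_gene("G2", "chr1", 1000, 2000, strand="-", transcripts=[t2])
        ann = GenomeAnnotation({"chr1": 100000}, [g1, g2])
        assert [t.id for t in select_exon_transcripts(ann)] == ["t1", "t2"]

    def test_chain_overlap_all_removed(self):
        """A long transcript spanning two short ones removes all three."""
        ts = [
            make_transcript("w", "GW", "chr1", "+", [(0, 10000)]),
            make_transcript("x", "GX", "chr1", "-", [(2000, 3000)]),
            make_transcript("y", "GY", "chr1", "+", [(5000, 6000)]),
        ]
        genes = [
            make_gene("GW", "chr1", 0, 10000, transcripts=[ts[0]]),
            make_gene("GX", "chr1", 2000, 3000, strand="-", transcripts=[ts[1]]),
            make_gene("GY", "chr1", 5000, 6000, transcripts=[ts[2]]),
        ]
        ann = GenomeAnnotation({"chr1": 100000}, genes)
        assert select_exon_transcripts(ann) == []

    @pytest.mark.parametrize("seed", [0, 7, 42])
    def test_output_has_no_pairwise_overlaps(self, seed):
        """Property: the selected set never contains an overlapping pair, and
        agrees with the all-pairs brute-force oracle on candidate longest
        transcripts."""
        ann, _ = generate_annotation(SyntheticGenomeSpec(n_genes=40, seed=seed))
        selected = select_exon_transcripts(ann)
        for i, a in enumerate(selected):
            for b in selected[i + 1:]:
                assert not (a.chrom == b.chrom and a.span.start < b.span.end
                            and b.span.start < a.span.end)
        candidates = [
            max(g.transcripts, key=lambda t: (t.span.length, t.id))
            for g in ann.genes if g.biotype == "protein_coding" and g.transcripts
        ]
        assert sorted(t.id for t in selected) == brute_force_nonoverlapping(candidates)

    def test_pyranges_cross_check(self, tmp_path, synth_ann):
        """Independent oracle: pyranges' GTF reader sees the same exon
        intervals as our parser on a generator-written file."""
        pr = pytest.importorskip("pyranges")
        ann, _ = synth_ann
        path = tmp_path / "x.gtf"
        write_gtf(ann, path)
        df = pr.read_gtf(str(path), as_df=True)
        exons = df[df.Feature == "exon"]
        ours = sorted(
            (t.chrom, e.start, e.end, t.id)
            for t in ann.transcripts for e in t.exons
        )
        theirs = sorted(
            zip(exons.Chromosome.astype(str), exons.Start.astype(int),
                exons.End.astype(int), exons.transcript_id)
        )
        assert ours == theirs
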