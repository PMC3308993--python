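import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plastidcomp.genome_model import (
    AnnotatedGenome,
    GeneFeature,
    GenomeModelError,
    Interval,
    interval_from_genbank,
    interval_to_genbank,
    normalize_gene_name,
    read_genbank,
    read_gff_fasta,
    reverse_complement,
    write_genbank,
    write_gff_fasta,
)
from plastidcomp.synthetic_data import simulate_genome


class TestInterval:
    def test_basic_length(self):
        assert Interval(0, 300).length() == 300

    def test_wrapping_length_is_modular(self):
        assert Interval(90, 10, wraps=True).length(100) == 20

    def test_full_circle_wrap(self):
        assert Interval(5, 5, wraps=True).length(100) == 100

    @pytest.mark.parametrize("start,end", [(5, 5), (10, 5), (-1, 3)])
    def test_invalid_intervals_rejected(self, start, end):
        with pytest.raises(GenomeModelError):
            Interval(start, end)

    def test_wrapping_needs_genome_length(self):
        with pytest.raises(GenomeModelError):
            Interval(90, 10, wraps=True).length()

    def test_genbank_coordinate_round_trip(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            s = int(rng.integers(1, 10_000))
            e = int(rng.integers(s, 10_001))
            iv = interval_from_genbank(s, e)
            assert iv.length() == e - s + 1
            assert interval_to_genbank(iv) == (s, e)

    def test_unwrap_pieces(self):
        assert Interval(90, 10, wraps=True).unwrap(100) == [(90, 100), (0, 10)]
        assert Interval(3, 9).unwrap(100) == [(3, 9)]


class TestGeneFeature:
    def test_exon_plus_intron_equals_span(self):
        f = GeneFeature("g", "g", "CDS", "+",
                        [Interval(0, 900), Interval(2380, 2780)])
        assert f.exon_bases() == 1300
        assert f.intron_bases() == 2780 - 1300
        assert f.span().length() == f.exon_bases() + f.intron_bases()

    def test_bad_type_rejected(self):
        with pytest.raises(GenomeModelError):
            GeneFeature("g", "g", "misc", "+", [Interval(0, 10)])

    def test_feature_outside_sequence_is_hard_error(self):
        f = GeneFeature("far", "far", "CDS", "+", [Interval(50, 120)])
        with pytest.raises(GenomeModelError, match="far"):
            AnnotatedGenome(id="x", sequence="A" * 100, features=[f])

    def test_empty_sequence_is_hard_error(self):
        with pytest.raises(GenomeModelError):
            AnnotatedGenome(id="x", sequence="")


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expect",
        [("ACGT", "ACGT"), ("AAAC", "GTTT"), ("N", "N"), ("", "")],
    )
    def test_examples(self, seq, expect):
        assert reverse_complement(seq) == expect

    @given(st.text(alphabet="ACGTN", max_size=200))
    def test_involution(self, s):
        assert reverse_complement(reverse_complement(s)) == s

    def test_non_iupac_rejected(self):
        with pytest.raises(GenomeModelError):
            reverse_complement("ACXGT")


class TestNormalizeGeneName:
    @pytest.mark.parametrize(
        "raw,expect",
        [
            ("PsbA", "psbA"),
            ("psbA", "psbA"),
            ("RbcL", "rbcL"),
            ("ycf13", "mat1"),
            ("rpl3", "ycf65"),
            ("ycf65", "ycf65"),
            ("tRNA-Ala", "trnA"),
            ("trnA-UGC", "trnA-UGC"),
            ("trna-ala (ugc)", "trnA-UGC"),
            ("16S ribosomal RNA", "rrn16"),
            ("orf248", "orf248"),
        ],
    )
    def test_examples(self, raw, expect):
        assert normalize_gene_name(raw) == expect

    def test_orf_flagged_non_conserved(self):
        from plastidcomp.genome_model import is_conserved_name

        assert not is_conserved_name(normalize_gene_name("orf248"))
        assert is_conserved_name(normalize_gene_name("ycf65"))

    @given(
        st.sampled_from(
            ["PsbA", "tRNA-Ala", "trnM-CAU", "ycf13", "ORF123", "atpF",
             "rpoC1", "Rrn16", "rpl3", "random-label", "psaJ"]
        )
    )
    def test_idempotent(self, raw):
        once = normalize_gene_name(raw)
        assert normalize_gene_name(once) == once

    def test_user_synonyms_extend_builtin(self):
        assert normalize_gene_name("foo1", {"foo1": "bar1"}) == "bar1"
        assert normalize_gene_name("ycf13", {"foo1": "bar1"}) == "mat1"


class TestGenBankIO:
    def test_circular_topology_and_length(self, tmp_path):
        g = AnnotatedGenome(id="big", sequence="ACGT" * 16905 + "AC",
                            topology="circular")
        assert len(g) == 67622
        path = tmp_path / "big.gb"
        write_genbank(g, path)
        back = read_genbank(path)
        assert back.topology == "circular"
        assert len(back) == 67622

    def test_zero_features(self, tmp_path):
        g = AnnotatedGenome(id="empty", sequence="ACGT" * 100)
        write_genbank(g, tmp_path / "e.gb")
        assert read_genbank(tmp_path / "e.gb").features == []

    def test_spliced_cds_exon_intron_bases(self, tmp_path):
        # join of 900 + 400 exon bases spanning 2780 -> intron 1480
        seq = "ACGT" * 800
        f = GeneFeature("psaA", "psaA", "CDS", "+",
                        [Interval(10, 910), Interval(2390, 2790)])
        g = AnnotatedGenome(id="spliced", sequence=seq, features=[f])
        write_genbank(g, tmp_path / "s.gb")
        back = read_genbank(tmp_path / "s.gb")
        (feat,) = back.features
        assert feat.exon_bases() == 1300
        assert feat.intron_bases() == 1480

    def test_round_trip_simulator_genome(self, tmp_path, default_sim):
        genome, _ = default_sim
        write_genbank(genome, tmp_path / "sim.gb")
        back = read_genbank(tmp_path / "sim.gb")
        assert back.sequence == genome.sequence
        assert len(back.features) == len(genome.features)
        for a, b in zip(
            sorted(genome.features, key=lambda f: (f.start, f.name)),
            sorted(back.features, key=lambda f: (f.start, f.name)),
        ):
            assert (a.name, a.ftype, a.strand) == (b.name, b.ftype, b.strand)
            assert a.segments == b.segments

    def test_missing_sequence_is_hard_error(self, tmp_path):
        p = tmp_path / "noseq.gb"
        p.write_text(
            "LOCUS       x 0 bp DNA circular UNK 01-JAN-2000\n"
            "DEFINITION  x.\nFEATURES             Location/Qualifiers\n//\n"
        )
        with pytest.raises((GenomeModelError, ValueError)):
            read_genbank(p)


class TestGffIO:
    def test_coordinate_convention(self, tmp_path):
        (tmp_path / "g.fasta").write_text(">chr1\n" + "ACGT" * 100 + "\n")
        (tmp_path / "g.gff3").write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tCDS\t1\t300\t.\t+\t.\tID=c1;Name=psbA\n"
        )
        g = read_gff_fasta(tmp_path / "g.gff3", tmp_path / "g.fasta")
        assert g.features[0].segments == [Interval(0, 300)]

    def test_negative_strand_transcription_order(self, tmp_path):
        (tmp_path / "g.fasta").write_text(">chr1\n" + "ACGT" * 100 + "\n")
        (tmp_path / "g.gff3").write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tCDS\t11\t100\t.\t-\t.\tID=c1;Name=rpoB\n"
            "chr1\tsrc\tCDS\t151\t300\t.\t-\t.\tID=c1;Name=rpoB\n"
        )
        (feat,) = read_gff_fasta(tmp_path / "g.gff3", tmp_path / "g.fasta").features
        assert feat.strand == "-"
        # transcription order: downstream (higher-coordinate) segment first
        assert feat.segments == [Interval(150, 300), Interval(10, 100)]

    def test_id_mismatch_is_hard_error(self, tmp_path):
        (tmp_path / "g.fasta").write_text(">chr1\nACGTACGT\n")
        (tmp_path / "g.gff3").write_text(
            "chrX\tsrc\tCDS\t1\t6\t.\t+\t.\tID=c1\n"
        )
        with pytest.raises(GenomeModelError):
            read_gff_fasta(tmp_path / "g.gff3", tmp_path / "g.fasta")

    def test_unknown_types_ignored(self, tmp_path, caplog):
        (tmp_path / "g.fasta").write_text(">chr1\n" + "ACGT" * 10 + "\n")
        (tmp_path / "g.gff3").write_text(
            "chr1\tsrc\trepeat_region\t1\t6\t.\t+\t.\tID=r1\n"
            "chr1\tsrc\tCDS\t7\t36\t.\t+\t.\tID=c1;Name=psbB\n"
        )
        g = read_gff_fasta(tmp_path / "g.gff3", tmp_path / "g.fasta")
        assert [f.name for f in g.features] == ["psbB"]

    def test_round_trip_identity(self, tmp_path, default_sim):
        genome, _ = default_sim
        write_gff_fasta(genome, tmp_path / "sim.gff3", tmp_path / "sim.fasta")
        back = read_gff_fasta(tmp_path / "sim.gff3", tmp_path / "sim.fasta")
        assert back.sequence == genome.sequence
        got = {(f.name, f.ftype, f.strand, tuple(f.segments))
               for f in back.features}
        want = {(f.name, f.ftype, f.strand, tuple(f.segments))
                for f in genome.features}
        assert got == want

    def test_wrapping_feature_round_trip(self, tmp_path):
        f = GeneFeature("psbA", "psbA", "CDS", "+",
                        [Interval(380, 20, wraps=True)])
        g = AnnotatedGenome(id="w", sequence="ACGT" * 100, features=[f])
        write_gff_fasta(g, tmp_path / "w.gff3", tmp_path / "w.fasta")
        back = read_gff_fasta(tmp_path / "w.gff3", tmp_path / "w.fasta")
        assert back.features[0].segments == [Interval(380, 20, wraps=True)]
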