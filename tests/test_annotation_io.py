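import io

import pytest

from mitoarch.annotation_io import (GeneFeature, MitogenomeRecord,
                                    read_gene_table, read_genbank,
                                    write_gene_table)
from mitoarch.errors import (LengthError, ParseError, UnsupportedFeatureError,
                             ValidationError)

from conftest import make_genbank


class TestReadGeneTable:
    def test_reference_fixture_counts(self, ref_record):
        by_class = {}
        for f in ref_record.features:
            by_class[f.gene_class] = by_class.get(f.gene_class, 0) + 1
        assert by_class == {"PCG": 13, "tRNA": 22, "rRNA": 2,
                            "control_region": 1}
        assert len(ref_record.features) == 38
        assert max(f.end for f in ref_record.features) == 17164
        cr = ref_record.feature("CR")
        assert (cr.start, cr.end, cr.size) == (15408, 17164, 1757)
        assert cr.strand is None

    def test_size_derived_when_column_absent(self):
        tsv = "gene\tstrand\tstart\tend\natp8\t+\t7753\t7956\n"
        rec = read_gene_table(io.StringIO(tsv))
        assert rec.feature("atp8").size == 204

    def test_size_contradiction_lists_rows(self):
        tsv = ("gene\tstrand\tstart\tend\tsize\n"
               "atp8\t+\t7753\t7956\t204\n"
               "atp6\t+\t7914\t8594\t999\n")
        with pytest.raises(ValidationError, match="atp6"):
            read_gene_table(io.StringIO(tsv))

    def test_empty_table_is_error(self):
        with pytest.raises(ValidationError):
            read_gene_table(io.StringIO("gene\tstrand\tstart\tend\n"))
        with pytest.raises(ValidationError):
            read_gene_table(io.StringIO(""))

    def test_fasta_attached_and_length_checked(self, tmp_path):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">g\n" + "ACGT" * 3 + "\n")
        tsv = "gene\tstrand\tstart\tend\nnad1\t+\t1\t9\n"
        rec = read_gene_table(io.StringIO(tsv), fasta=fasta)
        assert rec.sequence == "ACGT" * 3
        tsv_long = "gene\tstrand\tstart\tend\nnad1\t+\t1\t99\n"
        with pytest.raises(LengthError):
            read_gene_table(io.StringIO(tsv_long), fasta=fasta)


class TestWriteGeneTable:
    def test_single_feature_one_row(self):
        rec = MitogenomeRecord(features=[GeneFeature(
            "nad1", "PCG", "+", 1, 9, start_codon="ATG", stop_codon="TAA")])
        lines = write_gene_table(rec).strip().split("\n")
        assert len(lines) == 2  # header + 1 row

    def test_reference_fixture_38_rows(self, ref_record):
        lines = write_gene_table(ref_record).strip().split("\n")
        assert len(lines) == 39

    def test_roundtrip_identity(self, ref_record):
        text = write_gene_table(ref_record)
        back = read_gene_table(io.StringIO(text))
        assert back.features == ref_record.features

    def test_unsorted_input_sorted_on_output(self):
        f1 = GeneFeature("trnF", "tRNA", "+", 100, 165, anticodon="GAA")
        f2 = GeneFeature("trnV", "tRNA", "+", 1, 67, anticodon="TAC")
        rec = MitogenomeRecord(features=[f1, f2])
        lines = write_gene_table(rec).strip().split("\n")
        # sort oracle: rows appear in ascending start order
        assert [ln.split("\t")[0] for ln in lines[1:]] == ["trnV", "trnF"]

    def test_incomplete_stop_token_preserved(self, ref_record):
        text = write_gene_table(ref_record)
        back = read_gene_table(io.StringIO(text))
        assert back.feature("nad4").stop_codon == "T(AA)"
        assert back.feature("nad4").has_incomplete_stop
        assert not back.feature("nad1").has_incomplete_stop


class TestReadGenbank:
    def test_minimal_single_cds(self, tmp_path):
        path = make_genbank(tmp_path / "mini.gb", 30,
                            "     CDS             1..9\n"
                            "                     /gene=\"nad1\"")
        rec = read_genbank(path)
        assert len(rec.features) == 1
        feat = rec.features[0]
        assert feat.gene_class == "PCG"
        assert feat.size == 9
        assert feat.strand == "+"
        assert rec.sequence == rec.sequence.upper()

    def test_complement_trna_strand_and_coords(self, tmp_path):
        path = make_genbank(tmp_path / "trnq.gb", 3900,
                            "     tRNA            complement(3754..3824)\n"
                            "                     /gene=\"trnQ\"")
        rec = read_genbank(path)
        feat = rec.feature("trnQ")
        assert (feat.strand, feat.start, feat.end) == ("-", 3754, 3824)
        assert feat.gene_class == "tRNA"

    def test_dloop_maps_to_cr(self, tmp_path):
        path = make_genbank(tmp_path / "cr.gb", 60,
                            "     D-loop          31..60")
        rec = read_genbank(path)
        feat = rec.features[0]
        assert feat.gene_class == "control_region"
        assert feat.name == "CR"
        assert feat.strand is None

    def test_origin_spanning_feature_rejected(self, tmp_path):
        path = make_genbank(tmp_path / "wrap.gb", 60,
                            "     CDS             join(55..60,1..6)\n"
                            "                     /gene=\"nad1\"")
        with pytest.raises(UnsupportedFeatureError):
            read_genbank(path)

    def test_malformed_file_raises_parse_error(self, tmp_path):
        bad = tmp_path / "bad.gb"
        bad.write_text("FEATURES nothing sensible\n")
        with pytest.raises(ParseError):
            read_genbank(bad)

    def test_genbank_roundtrips_through_gene_table(self, tmp_path):
        path = make_genbank(tmp_path / "mini.gb", 30,
                            "     CDS             1..9\n"
                            "                     /gene=\"nad1\"")
        rec = read_genbank(path)
        back = read_gene_table(io.StringIO(write_gene_table(rec)))
        assert back.features == rec.features


class TestInvariants:
    def test_feature_size_invariant(self, ref_record):
        for f in ref_record.features:
            assert f.size == f.end - f.start + 1

    def test_pcg_iff_start_codon(self, ref_record):
        for f in ref_record.features:
            assert (f.gene_class == "PCG") == (f.start_codon is not None)

    def test_anticodon_iff_trna(self, ref_record):
        for f in ref_record.features:
            assert (f.anticodon is not None) == (f.gene_class == "tRNA")

    def test_bad_coordinates_rejected(self):
        with pytest.raises(ValidationError):
            GeneFeature("x", "PCG", "+", 10, 5, start_codon="ATG").validate()
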