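"""Feature-table / GenBank / FASTA round trips and coordinate conventions."""

from __future__ import annotations

import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from mitocomp.annotation_io import (
    extract_region,
    read_fasta,
    read_feature_table,
    read_genbank,
    revcomp,
    write_fasta,
    write_feature_table,
)
from mitocomp.model import GeneFeature, MitoAnnotation


class TestReadFeatureTable:
    def test_published_row_values(self, table4):
        cox1 = table4.feature("cox1")
        assert (cox1.start, cox1.end, cox1.strand) == (1506, 3041, "J")
        assert cox1.start_codon == "CGA" and cox1.stop_codon == "TAA"
        assert cox1.gclass == "PCG"

    def test_full_table_shape(self, table4):
        assert table4.genome_length == 15721
        assert len(table4.features) == 38
        assert table4.control_region.name == "AT_rich"
        assert (table4.control_region.start, table4.control_region.end) == (15316, 15721)
        assert len(table4.pcgs) == 13

    def test_thousands_separators_and_unicode_minus(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "Gene name\tStart\tStop\tStrand\tLength\tAnticodon\tStart codon\t"
            "End codon\tIntergenic nucleotides\n"
            "cox1\t1,506\t3,041\tJ\t1,536\t/\tCGA\tTAA\t−5\n"
        )
        ann = read_feature_table(p)
        assert ann.feature("cox1").length == 1536

    def test_minimal_single_feature(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "Gene name\tStart\tStop\tStrand\tLength\tAnticodon\tStart codon\tEnd codon\n"
            "g\t1\t1\tJ\t\t/\t/\t/\n"
        )
        ann = read_feature_table(p)
        assert ann.feature("g").length == 1
        assert ann.genome_length >= 1

    @pytest.mark.parametrize(
        "row, match",
        [
            ("trnM\t1\t68\tJ\t68\tCAT\t/\t/\n" "trnM\t70\t90\tJ\t21\tCAT\t/\t/", "duplicate"),
            ("trnM\tx\t68\tJ\t68\tCAT\t/\t/", "row 2"),
            ("trnM\t1\t68\tZ\t68\tCAT\t/\t/", "strand"),
        ],
    )
    def test_rejects_bad_rows(self, tmp_path, row, match):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "Gene name\tStart\tStop\tStrand\tLength\tAnticodon\tStart codon\tEnd codon\n"
            + row + "\n"
        )
        with pytest.raises(ValueError, match=match):
            read_feature_table(p)

    def test_printed_length_retained_not_applied(self, table4):
        # the nad4 row prints 1,338 but the coordinates give 1,339
        assert table4.printed_lengths["nad4"] == 1338
        assert table4.feature("nad4").length == 1339


class TestRoundTrip:
    def test_table_round_trip_is_identity(self, table4, tmp_path):
        out = tmp_path / "rt.tsv"
        write_feature_table(table4, out)
        back = read_feature_table(out)
        for a, b in zip(table4.features, back.features):
            assert (a.name, a.start, a.end, a.strand, a.gclass) == (
                b.name, b.start, b.end, b.strand, b.gclass
            )
            assert (a.anticodon, a.start_codon, a.stop_codon) == (
                b.anticodon, b.start_codon, b.stop_codon
            )

    def test_write_without_sequence(self, table4, tmp_path):
        out = tmp_path / "noseq.tsv"
        write_feature_table(table4, out)
        assert out.exists() and out.read_text().startswith("Gene name\t")

    def test_synthetic_round_trip(self, synthetic_ann, tmp_path):
        out = tmp_path / "syn.tsv"
        write_feature_table(synthetic_ann, out)
        back = read_feature_table(out)
        assert [f.name for f in back.features] == [f.name for f in synthetic_ann.features]
        assert back.genome_length == synthetic_ann.genome_length

    def test_fasta_round_trip_70_col(self, synthetic_ann, tmp_path):
        out = tmp_path / "g.fasta"
        write_fasta(synthetic_ann.sequence, out)
        lines = out.read_text().splitlines()
        assert max(len(line) for line in lines[1:]) == 70
        assert read_fasta(out) == synthetic_ann.sequence


class TestExtractRegion:
    def _mini(self, strand):
        feat = GeneFeature("AT_rich", 2, 3, strand if strand in "JN" else "J", "control")
        return MitoAnnotation(genome_length=4, features=[feat], sequence="ACGT"), feat

    def test_j_strand_slice(self):
        ann, feat = self._mini("J")
        assert extract_region(ann, feat) == "CG"

    def test_n_strand_reverse_complement(self):
        ann, feat = self._mini("N")
        assert extract_region(ann, feat) == "CG"  # palindromic
        feat2 = GeneFeature("x", 1, 2, "N", "control")
        assert extract_region(ann, feat2) == "GT"  # AC -> revcomp GT

    def test_length_identity(self, synthetic_ann):
        for feat in synthetic_ann.features:
            assert len(extract_region(synthetic_ann, feat)) == feat.length

    def test_nad4_coding_sense_starts_with_planned_start(self, synthetic_ann):
        nad4 = synthetic_ann.feature("nad4")
        assert nad4.strand == "N"
        assert extract_region(synthetic_ann, nad4).startswith(nad4.start_codon)

    def test_requires_sequence(self, table4):
        with pytest.raises(ValueError, match="no sequence"):
            extract_region(table4, table4.feature("cox1"))


class TestReadGenBank:
    @pytest.fixture()
    def genbank_file(self, synthetic_ann, tmp_path):
        """A GenBank rendering of the synthetic genome, with messy names."""
        raw_names = {
            "cox1": ("CDS", "COI"), "cox2": ("CDS", "COII"), "cox3": ("CDS", "COIII"),
            "cob": ("CDS", "CYTB"), "nad4l": ("CDS", "ND4L"),
        }
        feats = []
        for f in synthetic_ann.features:
            if f.gclass == "control":
                continue  # left unannotated: the reader must infer it
            ftype = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}[f.gclass]
            _, label = raw_names.get(f.name, (ftype, f.name))
            quals = {"gene": [label]}
            if f.gclass == "tRNA":
                aa3 = {
                    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe",
                    "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "L": "Leu",
                    "M": "Met", "N": "Asn", "P": "Pro", "Q": "Gln", "R": "Arg",
                    "S": "Ser", "T": "Thr", "V": "Val", "W": "Trp", "Y": "Tyr",
                }
                aa = aa3[f.name[3]]
                quals = {
                    "product": [f"tRNA-{aa}"],
                    "anticodon": [f"(pos:1..3,aa:{aa},seq:{f.anticodon.lower()})"],
                }
            feats.append(
                SeqFeature(
                    FeatureLocation(f.start - 1, f.end, strand=-1 if f.strand == "N" else 1),
                    type=ftype,
                    qualifiers=quals,
                )
            )
        record = SeqRecord(
            Seq(synthetic_ann.sequence), id="SYN0001", name="SYN0001",
            description="synthetic mitogenome", features=feats,
            annotations={"molecule_type": "DNA", "topology": "circular"},
        )
        path = tmp_path / "syn.gb"
        with open(path, "w") as fh:
            seqio_write([record], fh, "genbank")
        return path

    def test_names_strands_coordinates(self, genbank_file, synthetic_ann):
        ann = read_genbank(genbank_file)
        for f in synthetic_ann.features:
            if f.gclass == "control":
                continue
            got = ann.feature(f.name)
            assert (got.start, got.end, got.strand) == (f.start, f.end, f.strand)

    def test_serine_leucine_disambiguation(self, genbank_file):
        ann = read_genbank(genbank_file)
        assert ann.feature("trnS1").anticodon == "GCT"
        assert ann.feature("trnS2").anticodon == "TGA"
        assert ann.feature("trnL1").anticodon == "TAG"

    def test_control_gap_inferred(self, genbank_file, synthetic_ann):
        ann = read_genbank(genbank_file)
        ctrl = ann.control_region
        assert ctrl is not None
        ref = synthetic_ann.control_region
        assert (ctrl.start, ctrl.end) == (ref.start, ref.end)


def test_revcomp_involution():
    s = "ACGTTGCAN"
    assert revcomp(revcomp(s)) == s
    assert revcomp("AC") == "GT"
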