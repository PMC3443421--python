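"""Annotation loading, coordinate conventions and substring indexing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirquant.reference import (
    GenomicInterval,
    MatureMiRNA,
    SubstringIndex,
    load_exclusion_db,
    load_mirna_annotation,
    parse_location,
    write_mirna_annotation,
)

# frozen by hand before implementation: complement-and-reverse of the 22-mer
TOY_PLUS = "ACGTACGTTAGCCGATTACGGT"
TOY_RC = "ACCGTAATCGGCTAACGTACGT"


class TestGenomicInterval:
    def test_printed_coordinates_are_one_based_inclusive(self):
        iv = parse_location("chr9:21512157-21512177")
        assert (iv.chrom, iv.start, iv.end) == ("chr9", 21512156, 21512177)
        assert len(iv) == 21
        assert iv.as_printed() == "chr9:21512157-21512177"

    def test_rejects_empty_interval_and_bad_strand(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 30, strand="*")

    def test_rejects_malformed_location(self):
        with pytest.raises(ValueError, match="malformed"):
            parse_location("chr9_21512157_21512177")


def _write_bed(path, rows):
    path.write_text(
        "".join(f"{c}\t{s}\t{e}\t{n}\t0\t{st}\n" for c, s, e, n, st in rows)
    )


class TestAnnotationLoading:
    def test_same_name_merges_to_multi_locus_entry(self, tmp_path):
        """Two annotation lines with one name become one 2-locus miRNA."""
        bed = tmp_path / "ann.bed"
        _write_bed(
            bed,
            [
                ("chr7", 100, 122, "mir-x", "+"),
                ("chr1", 900, 922, "mir-x", "+"),
                ("chr2", 50, 72, "mir-y", "+"),
            ],
        )
        fa = tmp_path / "mature.fa"
        fa.write_text(f">mir-x\n{TOY_PLUS}\n>mir-y\n{'ACGT' * 5 + 'AC'}\n")
        mirnas = load_mirna_annotation(bed, mature_fasta=fa)
        assert set(mirnas) == {"mir-x", "mir-y"}
        assert mirnas["mir-x"].n_loci == 2
        assert mirnas["mir-y"].n_loci == 1

    def test_genome_extraction_plus_and_minus_strand(self, tmp_path):
        genome = tmp_path / "genome.fa"
        pad = "G" * 10
        genome.write_text(f">chrT\n{pad}{TOY_PLUS}{pad}\n")
        bed = tmp_path / "ann.bed"
        _write_bed(bed, [("chrT", 10, 32, "plus-mir", "+"), ("chrT", 10, 32, "minus-mir", "-")])
        mirnas = load_mirna_annotation(bed, genome_fasta=genome)
        assert mirnas["plus-mir"].mature_seq == TOY_PLUS
        assert mirnas["minus-mir"].mature_seq == TOY_RC

    def test_mature_fasta_wins_over_genome(self, tmp_path):
        genome = tmp_path / "genome.fa"
        genome.write_text(f">chrT\n{'G' * 10}{TOY_PLUS}{'G' * 10}\n")
        fa = tmp_path / "mature.fa"
        override = "TTTTACGTACGTACGTACGTTT"
        fa.write_text(f">mir-z\n{override}\n")
        bed = tmp_path / "ann.bed"
        _write_bed(bed, [("chrT", 10, 32, "mir-z", "+")])
        mirnas = load_mirna_annotation(bed, mature_fasta=fa, genome_fasta=genome)
        assert mirnas["mir-z"].mature_seq == override

    def test_missing_sequence_is_hard_error_naming_mirna(self, tmp_path):
        bed = tmp_path / "ann.bed"
        _write_bed(bed, [("chrT", 10, 32, "mir-gone", "+")])
        fa = tmp_path / "mature.fa"
        fa.write_text(">other\nACGTACGTACGTACGTAC\n")
        with pytest.raises(ValueError, match="mir-gone"):
            load_mirna_annotation(bed, mature_fasta=fa)

    def test_malformed_bed_reports_line_number(self, tmp_path):
        bed = tmp_path / "ann.bed"
        bed.write_text("chr1\t10\t32\tmir-a\t0\t+\nchr1\tnope\n")
        with pytest.raises(ValueError, match="line 2"):
            load_mirna_annotation(bed, mature_fasta=None, genome_fasta=None)

    def test_gff3_name_attribute_and_coordinates(self, tmp_path):
        gff = tmp_path / "ann.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chrT\tsrc\tmiRNA\t11\t32\t.\t+\t.\tID=m1;Name=mir-g\n"
        )
        fa = tmp_path / "mature.fa"
        fa.write_text(f">mir-g\n{TOY_PLUS}\n")
        mirnas = load_mirna_annotation(gff, mature_fasta=fa)
        iv = mirnas["mir-g"].loci[0]
        assert (iv.start, iv.end) == (10, 32)

    def test_round_trip_and_line_order_invariance(self, tmp_path, toy_mirnas):
        bed, fa = tmp_path / "out.bed", tmp_path / "out.fa"
        write_mirna_annotation(toy_mirnas, bed, fa)
        reloaded = load_mirna_annotation(bed, mature_fasta=fa)
        assert reloaded == toy_mirnas
        # shuffle annotation lines: the merged bundle must not change
        lines = bed.read_text().strip().splitlines()
        shuffled = tmp_path / "shuf.bed"
        shuffled.write_text("\n".join(lines[::-1]) + "\n")
        assert load_mirna_annotation(shuffled, mature_fasta=fa) == toy_mirnas


class TestMatureMiRNA:
    def test_u_to_t_normalization(self):
        m = MatureMiRNA("m", "ACGUACGUUAGCCGAUUACGGU", [GenomicInterval("c", 0, 22)])
        assert m.mature_seq == TOY_PLUS

    def test_span_must_be_consistent_with_mature_length(self):
        with pytest.raises(ValueError, match="inconsistent"):
            MatureMiRNA("m", TOY_PLUS, [GenomicInterval("c", 0, 28)])


class TestSubstringIndex:
    def test_trivial_containment(self, toy_exons):
        idx = SubstringIndex()
        for name, seq in toy_exons.items():
            idx.add(name, seq)
        exon = toy_exons["exon_1"]
        assert idx.contains_substring(exon[40:62])
        assert not idx.contains_substring("ACGT" * 6)  # periodic, absent

    def test_matches_brute_force_on_random_queries(self):
        """Indexed lookup equals the naive scan on 1,000 exons x 200 queries."""
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        seqs = {f"s{i}": "".join(rng.choice(bases, 50)) for i in range(1000)}
        idx = SubstringIndex()
        for n, s in seqs.items():
            idx.add(n, s)
        for _ in range(100):
            q = "".join(rng.choice(bases, int(rng.integers(8, 31))))
            assert idx.find(q) == {n for n, s in seqs.items() if q in s}
        # planted queries guaranteed to hit
        for _ in range(100):
            name = f"s{int(rng.integers(1000))}"
            s = seqs[name]
            a = int(rng.integers(0, 30))
            q = s[a : a + int(rng.integers(10, 21))]
            assert idx.find(q) == {n for n, s2 in seqs.items() if q in s2}

    @settings(deadline=None, max_examples=50)
    @given(
        seqs=st.lists(st.text(alphabet="ACGT", min_size=5, max_size=40), max_size=8),
        query=st.text(alphabet="ACGT", min_size=1, max_size=30),
    )
    def test_index_oracle_equivalence_property(self, seqs, query):
        idx = SubstringIndex(k=6)
        named = {f"q{i}": s for i, s in enumerate(seqs)}
        for n, s in named.items():
            idx.add(n, s)
        assert idx.find(query) == {n for n, s in named.items() if query in s}

    def test_empty_exclusion_db_warns(self, tmp_path):
        fa = tmp_path / "empty.fa"
        fa.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            idx = load_exclusion_db(fa)
        assert not idx.contains_substring("ACGTACGTACGTACGT")

    def test_mature_seq_retrievable_from_its_index(self, toy_bundle):
        for m in toy_bundle.mirnas.values():
            assert m.name in toy_bundle.mature_index.find(m.mature_seq)
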