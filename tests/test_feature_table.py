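"""Feature-table parsing and circular-genome accounting."""

import pytest

from mitochar import feature_table as ft

MINI_TSV = """\
Gene	Class	From	To	Strand	StartCodon	StopCodon
geneA	protein_coding	1	9	H	ATG	TAA
trn1	tRNA	10	15	L
"""


def make_table(rows, genome_length=None):
    feats = [
        ft.GeneFeature(name, ft.FeatureClass(cls), start, end, strand)
        for name, cls, start, end, strand in rows
    ]
    t = ft.MitoFeatureTable(feats)
    t.genome_length = genome_length or (ft.infer_genome_length(t) if feats else None)
    return t


class TestParsing:
    def test_canonical_table_parses(self, canonical_table):
        assert len(canonical_table) == 38
        nd5 = canonical_table.get("ND5")
        assert (nd5.start, nd5.end, nd5.strand) == (11959, 13797, "H")
        assert canonical_table.genome_length == 16500

    def test_empty_input_gives_empty_table(self):
        t = ft.parse_feature_table("# nothing here\n")
        assert len(t) == 0 and t.genome_length is None

    @pytest.mark.parametrize(
        "row, message",
        [
            ("geneX\tprotein_coding\tabc\t10\tH", "non-integer"),
            ("geneX\tprotein_coding\t1\t10\tQ", "strand"),
            ("geneX\tnot_a_class\t1\t10\tH", "class"),
        ],
    )
    def test_malformed_rows_rejected_naming_the_row(self, row, message):
        text = "Gene\tClass\tFrom\tTo\tStrand\n" + row + "\n"
        with pytest.raises(ft.FeatureTableError, match=message):
            ft.parse_feature_table(text)

    def test_duplicate_names_rejected(self):
        text = MINI_TSV + "geneA\ttRNA\t20\t25\tH\n"
        with pytest.raises(ft.FeatureTableError, match="duplicate"):
            ft.parse_feature_table(text)

    def test_round_trip_is_byte_identical(self, canonical_table):
        once = ft.write_feature_table(canonical_table)
        assert ft.write_feature_table(ft.parse_feature_table(once)) == once


class TestLengths:
    @pytest.mark.parametrize(
        "start, end, glen, expected",
        [
            (11959, 13797, 16500, 1839),  # ND5
            (15675, 16500, 16500, 826),  # control region
            (1, 68, 16500, 68),  # tRNA-Phe
        ],
    )
    def test_linear_lengths(self, start, end, glen, expected):
        f = ft.GeneFeature("x", ft.FeatureClass.tRNA, start, end, "H")
        assert ft.feature_length(f, glen) == expected

    def test_wrapping_feature_length(self):
        f = ft.GeneFeature("x", ft.FeatureClass.tRNA, 16400, 100, "H", wraps=True)
        assert ft.feature_length(f, 16500) == 201

    def test_out_of_range_coordinates_raise(self):
        f = ft.GeneFeature("x", ft.FeatureClass.tRNA, 100, 200, "H")
        with pytest.raises(ft.FeatureTableError, match="exceed"):
            ft.feature_length(f, 150)

    def test_wrap_without_flag_rejected(self):
        with pytest.raises(ft.FeatureTableError, match="wrap"):
            ft.GeneFeature("x", ft.FeatureClass.tRNA, 100, 50, "H")


class TestGenomeLength:
    def test_canonical(self, canonical_table):
        assert ft.infer_genome_length(canonical_table) == 16500

    def test_small_cases(self):
        assert ft.infer_genome_length(make_table([("a", "tRNA", 1, 68, "H")])) == 68
        two = make_table([("a", "tRNA", 1, 10, "H"), ("b", "tRNA", 5, 7, "H")])
        assert ft.infer_genome_length(two) == 10

    def test_empty_table_raises(self):
        with pytest.raises(ft.FeatureTableError):
            ft.infer_genome_length(ft.MitoFeatureTable([]))


class TestGapsAndSpacers:
    def test_known_gaps(self, canonical_table):
        gaps = {
            (r.upstream_name, r.downstream_name): r.signed_gap
            for r in ft.intergenic_gaps(canonical_table)
        }
        assert gaps[("ATP8", "ATP6")] == -10
        assert gaps[("tRNA-Asn", "tRNA-Cys")] == 37  # the O_L gap
        assert gaps[("COII", "tRNA-Lys")] == 0  # abutting

    def test_adjacency_identity(self, canonical_table):
        # signed_gap + len(up) + len(down) == inclusive span start(up)..end(down)
        feats = canonical_table.sorted_by_start()
        glen = canonical_table.genome_length
        for up, down, rec in zip(
            feats, feats[1:], ft.intergenic_gaps(canonical_table, circular=False)
        ):
            span = down.end - up.start + 1
            assert rec.signed_gap + ft.feature_length(up, glen) + ft.feature_length(
                down, glen
            ) == span

    def test_circular_closure(self, canonical_table):
        # lengths plus all signed gaps (overlaps negative, wrap gap included)
        # tile the circle exactly
        glen = canonical_table.genome_length
        total_len = sum(
            ft.feature_length(f, glen) for f in canonical_table.features
        )
        total_gap = sum(r.signed_gap for r in ft.intergenic_gaps(canonical_table))
        assert total_len + total_gap == glen

    def test_published_spacer_census(self, canonical_table):
        assert ft.spacer_summary(canonical_table) == (36, 11)

    def test_no_positive_gaps(self):
        t = make_table(
            [("a", "tRNA", 1, 10, "H"), ("b", "tRNA", 11, 20, "H")], genome_length=20
        )
        assert ft.spacer_summary(t, exclude=()) == (0, 0)

    def test_sign_filtering(self):
        t = make_table(
            [
                ("a", "tRNA", 1, 10, "H"),
                ("b", "tRNA", 13, 20, "H"),  # +2
                ("c", "tRNA", 16, 30, "H"),  # -5
                ("d", "tRNA", 34, 40, "H"),  # +3
            ],
            genome_length=40,
        )
        assert ft.spacer_summary(t, exclude=()) == (5, 2)


class TestCensus:
    def test_trna_strands(self, canonical_table):
        census = ft.strand_census(canonical_table)
        assert census[(ft.FeatureClass.tRNA, "L")] == 8
        assert census[(ft.FeatureClass.tRNA, "H")] == 14

    def test_nd6_is_the_only_l_strand_protein(self, canonical_table):
        census = ft.strand_census(canonical_table)
        assert census[(ft.FeatureClass.protein_coding, "L")] == 1
        assert canonical_table.get("ND6").strand == "L"

    def test_empty_table_gives_empty_census(self):
        assert ft.strand_census(ft.MitoFeatureTable([])) == {}

    def test_trna_size_range(self, canonical_table):
        assert ft.trna_size_range(canonical_table) == (66, 74)

    def test_trna_size_range_small(self):
        single = make_table([("t", "tRNA", 1, 70, "H")])
        assert ft.trna_size_range(single) == (70, 70)
        two = make_table([("t", "tRNA", 1, 66, "H"), ("u", "tRNA", 70, 143, "H")])
        assert ft.trna_size_range(two) == (66, 74)

    def test_no_trnas_raise(self):
        t = make_table([("g", "protein_coding", 1, 9, "H")])
        with pytest.raises(ft.FeatureTableError):
            ft.trna_size_range(t)


class TestValidator:
    def test_canonical_table_is_clean(self, canonical_table):
        assert ft.validate_table(canonical_table) == []

    def test_declared_text_sizes_reported_but_not_fatal(self, canonical_table):
        # published text quotes 947/1684 bp; coordinates give 949/1702 and win
        warnings = ft.validate_table(
            canonical_table, declared_sizes={"12S_rRNA": 947, "16S_rRNA": 1684}
        )
        assert any("12S_rRNA" in w and "949" in w for w in warnings)
        assert any("16S_rRNA" in w and "1702" in w for w in warnings)

    def test_inconsistent_stop_flagged(self):
        f = ft.GeneFeature(
            "g", ft.FeatureClass.protein_coding, 1, 10, "H", "ATG", "TAA"
        )
        t = ft.MitoFeatureTable([f])
        t.genome_length = 10
        warnings = ft.validate_table(t, expect_standard_complement=False)
        assert any("inconsistent" in w for w in warnings)


GENBANK_MINI = """\
LOCUS       TESTMITO                 100 bp    DNA     circular VRT 01-JAN-2015
DEFINITION  synthetic test record.
ACCESSION   TESTMITO
FEATURES             Location/Qualifiers
     tRNA            1..30
                     /gene="tRNA-Phe"
     CDS             31..60
                     /gene="ND1"
     rRNA            complement(61..90)
                     /gene="12S"
     D-loop          91..100
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
       61 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
//
"""


def test_genbank_reader(tmp_path):
    path = tmp_path / "mini.gb"
    path.write_text(GENBANK_MINI)
    table = ft.load_genbank(path)
    assert [f.name for f in table.features] == ["tRNA-Phe", "ND1", "12S", "D-loop"]
    nd1 = table.get("ND1")
    assert (nd1.start, nd1.end, nd1.feature_class) == (
        31,
        60,
        ft.FeatureClass.protein_coding,
    )
    assert table.get("12S").strand == "L"
    assert table.genome_length == 100


def test_fasta_reader(tmp_path):
    path = tmp_path / "g.fasta"
    path.write_text(">g\nacgt\nACGT\n")
    assert ft.read_genome_fasta(path) == "ACGTACGT"
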