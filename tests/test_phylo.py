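"""Supermatrix construction, saturation, distances, NJ and bootstrap."""

import numpy as np
import pytest

from mitochar import phylo as ph
from mitochar.synthetic_data import SimSpec, simulate_alignment
from _oracles import jc69_closed_form


def aln(gene, kind, rows):
    return ph.GeneAlignment(gene, kind, rows)


class TestStrip:
    def test_nd6_removed(self):
        genes = [aln(f"g{i}", "protein_coding", {"A": "ATGTAA"}) for i in range(12)]
        genes.append(aln("ND6", "protein_coding", {"A": "ATGTAA"}))
        out = ph.strip_stops_and_nd6(genes)
        assert len(out) == 12 and all(g.gene != "ND6" for g in out)

    @pytest.mark.parametrize(
        "row, expected_len",
        [("ATGAAATAA", 6), ("ATGAAATA", 6), ("ATGAAAT", 6)],
    )
    def test_terminal_stop_trimmed_by_length_class(self, row, expected_len):
        (out,) = ph.strip_stops_and_nd6([aln("g", "protein_coding", {"A": row})])
        assert out.length == expected_len

    def test_rrna_unchanged(self):
        (out,) = ph.strip_stops_and_nd6([aln("12S", "rRNA", {"A": "ACGTA"})])
        assert out.length == 5

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ph.PhyloError, match="ragged"):
            aln("g", "protein_coding", {"A": "ACGTAA", "B": "ACG"})


class TestSupermatrix:
    def test_small_example(self):
        genes = [
            aln("g", "protein_coding", {"A": "ATGGCA", "B": "ATGGCC"}),
            aln("12S", "rRNA", {"A": "ACGT", "B": "ACGA"}),
        ]
        pa = ph.build_supermatrix(genes)
        assert pa.partition_sizes() == {"codon1": 2, "codon2": 2, "rRNA": 4}
        assert pa.total_columns == 8
        assert pa.matrix["A"] == "ATGC" + "ACGT"  # codon3 columns dropped

    def test_column_extraction_matches_stride_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            n_codons = int(rng.integers(2, 40))
            row = "".join(rng.choice(list("ACGT"), size=3 * n_codons))
            pa = ph.build_supermatrix([aln("g", "protein_coding", {"A": row})])
            expected = "".join(row[i] for i in range(len(row)) if i % 3 != 2)
            assert pa.matrix["A"] == expected
            # exact 2/3 arithmetic for every input
            assert pa.partition_sizes()["codon1"] == n_codons
            assert pa.partition_sizes()["codon2"] == n_codons

    def test_missing_taxon_is_named(self):
        genes = [
            aln("g1", "protein_coding", {"A": "ATG", "B": "ATG"}),
            aln("g2", "protein_coding", {"A": "ATG"}),
        ]
        with pytest.raises(ph.PhyloError, match="B"):
            ph.build_supermatrix(genes)

    def test_partition_map_is_raxml_style(self):
        genes = [
            aln("g", "protein_coding", {"A": "ATGGCA"}),
            aln("12S", "rRNA", {"A": "ACGT"}),
        ]
        text = ph.write_partition_map(ph.build_supermatrix(genes))
        assert "DNA, codon1 = 1,3" in text
        assert "DNA, rRNA = 5-8" in text


class TestSaturation:
    def test_identical_sequences(self):
        rep = ph.saturation_stats({"A": "ACGT" * 25, "B": "ACGT" * 25})
        (pair,) = rep.pairs
        assert (pair.p_distance, pair.s_proportion, pair.v_proportion) == (0, 0, 0)

    def test_single_transition(self):
        a = "A" + "C" * 99
        b = "G" + "C" * 99
        rep = ph.saturation_stats({"A": a, "B": b})
        (pair,) = rep.pairs
        assert pair.p_distance == pytest.approx(0.01)
        assert pair.s_proportion == pytest.approx(0.01)
        assert pair.v_proportion == 0.0

    def test_p_equals_s_plus_v(self):
        rng = np.random.default_rng(3)
        rows = {
            t: "".join(rng.choice(list("ACGT-"), size=300)) for t in "ABCDE"
        }
        rep = ph.saturation_stats(rows)
        for pair in rep.pairs:
            assert pair.p_distance == pytest.approx(
                pair.s_proportion + pair.v_proportion
            )
            assert 0 <= pair.p_distance <= 1

    @pytest.mark.parametrize("mean_distance, expect_saturated", [(2.0, True), (0.1, False)])
    def test_simulated_divergence_flags(self, mean_distance, expect_saturated):
        # 10-taxon stars whose tip depths spread around mean_distance / 2, so
        # pairwise divergences average mean_distance; 20 JC replicates each
        depths = np.linspace(0.2 * mean_distance / 2, 1.8 * mean_distance / 2, 10)
        tree = "(" + ",".join(f"T{i}:{d:.4f}" for i, d in enumerate(depths)) + ");"
        for seed in range(20):
            spec = SimSpec(tree=tree, genes=[("g", "rRNA", 2000)], model="JC69", seed=seed)
            (g,), _ = simulate_alignment(spec)
            assert ph.saturation_stats(g.sequences).saturated is expect_saturated, seed

    def test_all_gap_pair_skipped(self):
        rep = ph.saturation_stats({"A": "----", "B": "ACGT", "C": "ACGA"})
        assert ("A", "B") in rep.skipped_pairs


class TestDistances:
    def test_identical_rows_zero_for_every_model(self):
        rows = {"A": "ACGT" * 10, "B": "ACGT" * 10}
        for model in ("p", "jc69", "k80"):
            dm = ph.pairwise_distance(rows, model)
            assert dm.values[0, 1] == 0.0

    def test_jc69_matches_independent_closed_form(self):
        # exactly 748 differing sites out of 10,000
        a = "A" * 10000
        b = "G" * 748 + "A" * 9252
        dm = ph.pairwise_distance({"A": a, "B": b}, "jc69")
        assert dm.values[0, 1] == pytest.approx(jc69_closed_form(0.0748), abs=1e-3)

    def test_k80_reduces_to_jc69_when_ts_is_half_tv(self):
        # 2 transitions (A->G) and 4 transversions (A->C) in 600 sites
        a = "A" * 600
        b = "G" * 2 + "C" * 4 + "A" * 594
        jc = ph.pairwise_distance({"A": a, "B": b}, "jc69").values[0, 1]
        k80 = ph.pairwise_distance({"A": a, "B": b}, "k80").values[0, 1]
        assert k80 == pytest.approx(jc, abs=1e-9)

    def test_saturated_pair_flagged_infinite(self):
        a = "A" * 100
        b = "G" * 80 + "C" * 20  # p = 1.0
        dm = ph.pairwise_distance({"A": a, "B": b}, "jc69")
        assert np.isinf(dm.values[0, 1]) and dm.infinite_pairs == [("A", "B")]

    def test_monotone_in_observed_divergence(self):
        base = "A" * 1000
        prev = {"p": -1.0, "jc69": -1.0}
        for k in (10, 50, 100, 200, 400):
            other = "G" * k + "A" * (1000 - k)
            for model in ("p", "jc69"):
                d = ph.pairwise_distance({"A": base, "B": other}, model).values[0, 1]
                assert d > prev[model]
                prev[model] = d


class TestNJ:
    def additive_matrix(self):
        # distances induced by the tree ((A:1,B:2):1,(C:3,D:1))
        d = np.array(
            [
                [0, 3, 5, 3],
                [3, 0, 6, 4],
                [5, 6, 0, 4],
                [3, 4, 4, 0],
            ],
            dtype=float,
        )
        return ph.DistanceMatrix(["A", "B", "C", "D"], d)

    def test_three_taxa_unique_topology(self):
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        tree = ph.nj_tree(ph.DistanceMatrix(["A", "B", "C"], d))
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == {"A", "B", "C"}

    def test_additive_matrix_recovered_exactly(self):
        tree = ph.nj_tree(self.additive_matrix())
        assert ph.has_split(tree, ["A", "B"])
        assert ph.has_split(tree, ["C", "D"])
        # branch lengths: leaf edges carry the generating values
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 1.0})
        # and the patristic distances reproduce the input matrix
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        dm = self.additive_matrix()
        for i, a in enumerate(dm.taxa):
            for j, b in enumerate(dm.taxa):
                if i < j:
                    assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(
                        dm.values[i, j]
                    )

    def test_taxon_order_permutation_invariant(self):
        dm = self.additive_matrix()
        perm = [2, 0, 3, 1]
        shuffled = ph.DistanceMatrix(
            [dm.taxa[i] for i in perm], dm.values[np.ix_(perm, perm)]
        )
        t2 = ph.nj_tree(shuffled)
        assert ph.has_split(t2, ["A", "B"]) and ph.has_split(t2, ["C", "D"])

    def test_too_few_taxa_rejected(self):
        d = np.array([[0, 1], [1, 0]], dtype=float)
        with pytest.raises(ph.PhyloError):
            ph.nj_tree(ph.DistanceMatrix(["A", "B"], d))


@pytest.fixture(scope="module")
def small_pa():
    spec = SimSpec(
        tree="((A:0.05,B:0.05):0.05,(C:0.05,D:0.05):0.05,E:0.1);",
        genes=[("g1", "protein_coding", 300), ("r1", "rRNA", 200)],
        seed=17,
    )
    genes, _ = simulate_alignment(spec)
    return ph.build_supermatrix(ph.strip_stops_and_nd6(genes))


class TestBootstrap:
    def test_same_seed_is_bitwise_reproducible(self, small_pa):
        t1 = ph.bootstrap_consensus(small_pa, 30, seed=5)
        t2 = ph.bootstrap_consensus(small_pa, 30, seed=5)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_supports_are_percentages(self, small_pa):
        tree = ph.bootstrap_consensus(small_pa, 30, seed=5)
        supports = [
            node.support
            for node in tree.preorder_internal_node_iter()
            if getattr(node, "support", None) is not None
        ]
        assert supports and all(0.0 <= s <= 100.0 for s in supports)

    def test_consensus_splits_are_compatible(self, small_pa):
        # a majority-rule consensus is a tree, so its splits must nest
        tree = ph.bootstrap_consensus(small_pa, 30, seed=5)
        leaf_sets = [
            frozenset(l.taxon.label for l in node.leaf_iter())
            for node in tree.preorder_internal_node_iter()
        ]
        for a in leaf_sets:
            for b in leaf_sets:
                assert a <= b or b <= a or not (a & b)

    def test_zero_replicates_rejected(self, small_pa):
        with pytest.raises(ph.PhyloError):
            ph.bootstrap_consensus(small_pa, 0, seed=1)


def test_alignment_io_round_trip(tmp_path):
    rows = {"taxon_one": "ATGAAATAA", "taxon_two": "ATGCCCTAA"}
    fasta = tmp_path / "g.fasta"
    fasta.write_text("".join(f">{t}\n{s}\n" for t, s in rows.items()))
    g = ph.read_alignment(fasta, "g", "protein_coding")
    assert g.sequences == rows
    phylip = tmp_path / "g.phy"
    phylip.write_text(
        "2 9\ntaxon_one  ATGAAATAA\ntaxon_two  ATGCCCTAA\n"
    )
    g2 = ph.read_alignment(phylip, "g", "protein_coding", fmt="phylip")
    assert g2.sequences == rows
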