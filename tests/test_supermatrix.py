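"""Gene-alignment ingestion, concatenation, coverage, taxon pruning, screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phylodissect.supermatrix import (
    AlignmentFormatError,
    CladeConstraintSet,
    GeneAlignment,
    GeneAlignmentSet,
    concatenate,
    coverage_table,
    load_gene_alignments,
    screen_gene,
    subset_taxa,
)
from phylodissect.simulate import simulate_alignment
from phylodissect.treeops import PhyloTree
from phylodissect import build_model


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


class TestLoadGeneAlignments:
    def test_identity_ingestion(self, tmp_path):
        for i in (1, 2):
            write_fasta(
                tmp_path / f"gene{i}.fasta",
                [("t1", "ARNDCQEGHI"), ("t2", "arndcqeghi"),
                 ("t3", "AAAAAAAAAA"), ("t4", "RN-DCQXGHI")],
            )
        genes = load_gene_alignments(
            [tmp_path / "gene1.fasta", tmp_path / "gene2.fasta"]
        )
        assert len(genes) == 2
        assert [g.length for g in genes] == [10, 10]
        assert genes["gene1"].rows[1] == "ARNDCQEGHI"  # lowercase normalized

    def test_ragged_alignment_names_file_and_row(self, tmp_path):
        write_fasta(tmp_path / "bad.fasta", [("t1", "ARNDCQEGHI"), ("t2", "ARNDCQEGH")])
        with pytest.raises(AlignmentFormatError, match="bad.fasta"):
            load_gene_alignments([tmp_path / "bad.fasta"])

    def test_empty_file_rejected(self, tmp_path):
        (tmp_path / "empty.fasta").write_text("")
        with pytest.raises(AlignmentFormatError, match="empty"):
            load_gene_alignments([tmp_path / "empty.fasta"])

    def test_duplicate_taxon_rejected(self, tmp_path):
        write_fasta(tmp_path / "dup.fasta", [("t1", "ARND"), ("t1", "ARNE")])
        with pytest.raises(AlignmentFormatError, match="duplicate"):
            load_gene_alignments([tmp_path / "dup.fasta"])

    def test_invalid_characters_rejected(self):
        with pytest.raises(AlignmentFormatError, match="invalid"):
            GeneAlignment("g", ["t1"], ["AR8D"])


class TestConcatenate:
    @pytest.fixture()
    def two_genes(self):
        g1 = GeneAlignment("g1", ["t1", "t2", "t3", "t4"],
                           ["ARN", "RND", "NDC", "DCQ"])
        g2 = GeneAlignment("g2", ["t1", "t2", "t3", "t4"],
                           ["CQEGH", "QEGHI", "EGHIL", "GHILK"])
        return GeneAlignmentSet([g1, g2])

    def test_lengths_add_and_partitions_tile(self, two_genes):
        sm = concatenate(two_genes)
        assert sm.length == 8
        assert sm.partitions == [("g1", 1, 3), ("g2", 4, 8)]

    def test_padding_and_coverage(self):
        g1 = GeneAlignment("g1", ["t1", "t2", "t3", "t4"],
                           ["ARN", "RND", "NDC", "DCQ"])
        g2 = GeneAlignment("g2", ["t2", "t3", "t4"],
                           ["CQEGH", "QEGHI", "EGHIL"])
        sm = concatenate(GeneAlignmentSet([g1, g2]))
        row_t1 = sm.rows[sm.taxa.index("t1")]
        assert row_t1 == "ARN" + "-" * 5
        assert sm.coverage()["t1"] == pytest.approx(100 * 3 / 8)

    def test_round_trip_recovers_each_gene(self):
        g1 = GeneAlignment("g1", ["t1", "t2", "t3", "t4"],
                           ["ARN", "RND", "NDC", "DCQ"])
        g2 = GeneAlignment("g2", ["t2", "t3", "t4"],
                           ["CQEGH", "QEGHI", "EGHIL"])
        sm = concatenate(GeneAlignmentSet([g1, g2]))
        for original in (g1, g2):
            extracted = sm.extract_gene(original.name)
            assert extracted.taxa == original.taxa
            assert extracted.rows == original.rows

    def test_supplied_universe_and_unknown_taxon(self, two_genes):
        sm = concatenate(two_genes, taxon_universe=["t1", "t2", "t3", "t4", "t5"])
        assert "t5" in sm.taxa
        assert sm.coverage()["t5"] == 0.0
        with pytest.raises(AlignmentFormatError, match="t4"):
            concatenate(two_genes, taxon_universe=["t1", "t2", "t3"])

    def test_empty_gene_set_rejected(self):
        with pytest.raises(AlignmentFormatError):
            GeneAlignmentSet([])

    def test_coverage_invariant_to_gene_order(self):
        g1 = GeneAlignment("g1", ["t1", "t2", "t3", "t4"], ["AR", "RN", "ND", "DC"])
        g2 = GeneAlignment("g2", ["t2", "t3", "t4"], ["CQE", "QEG", "EGH"])
        c12 = concatenate(GeneAlignmentSet([g1, g2])).coverage()
        c21 = concatenate(GeneAlignmentSet([g2, g1])).coverage()
        assert c12.sort_index().equals(c21.sort_index())

    @given(
        lengths=st.lists(st.integers(min_value=1, max_value=9), min_size=1, max_size=6)
    )
    @settings(max_examples=25, deadline=None)
    def test_partitions_always_tile(self, lengths):
        genes = GeneAlignmentSet(
            [
                GeneAlignment(f"g{i}", ["t1", "t2", "t3", "t4"], ["A" * n] * 4)
                for i, n in enumerate(lengths)
            ]
        )
        sm = concatenate(genes)
        assert sm.length == sum(lengths)
        pos = 1
        for _, start, end in sm.partitions:
            assert start == pos
            pos = end + 1
        assert pos == sm.length + 1


class TestCoverageTable:
    def test_flags_and_percentages(self):
        g1 = GeneAlignment("g1", ["t1", "t2", "t3", "t4"], ["AR", "RN", "ND", "DC"])
        g2 = GeneAlignment("g2", ["t2", "t3", "t4"], ["CQ", "QE", "EG"])
        table = coverage_table(concatenate(GeneAlignmentSet([g1, g2])))
        assert table.loc["t1", "coverage_pct"] == pytest.approx(50.0)
        assert bool(table.loc["t1", "g1"]) and not bool(table.loc["t1", "g2"])
        # identical rows -> identical coverage
        assert table.loc["t2", "coverage_pct"] == table.loc["t3", "coverage_pct"]

    def test_full_row_is_100(self):
        g = GeneAlignment("g", ["t1", "t2", "t3", "t4"], ["ARND"] * 4)
        assert concatenate(GeneAlignmentSet([g])).coverage()["t1"] == 100.0


class TestSubsetTaxa:
    @pytest.fixture()
    def sm(self):
        g1 = GeneAlignment("g1", ["t1", "t2", "t3", "t4", "t5", "t6"],
                           ["ARN", "RND", "NDC", "DCQ", "CQE", "QEG"])
        return concatenate(GeneAlignmentSet([g1]))

    def test_empty_removal_is_identity(self, sm):
        out = subset_taxa(sm, [])
        assert out.taxa == sm.taxa
        assert out.rows == sm.rows
        assert out.partitions == sm.partitions

    def test_removal_keeps_columns(self, sm):
        out = subset_taxa(sm, ["t5", "t6"])
        assert out.taxa == ["t1", "t2", "t3", "t4"]
        assert out.length == sm.length  # constant columns retained

    def test_unknown_and_too_few_rejected(self, sm):
        with pytest.raises(AlignmentFormatError, match="tX"):
            subset_taxa(sm, ["tX"])
        with pytest.raises(AlignmentFormatError, match="at least 4"):
            subset_taxa(sm, ["t1", "t2", "t3"])

    def test_commutes_with_concatenate(self):
        g1 = GeneAlignment("g1", ["t1", "t2", "t3", "t4", "t5"],
                           ["ARN", "RND", "NDC", "DCQ", "CQE"])
        g2 = GeneAlignment("g2", ["t1", "t2", "t4", "t5"],
                           ["CQEG", "QEGH", "EGHI", "GHIL"])
        remove = ["t3"]
        a = subset_taxa(concatenate(GeneAlignmentSet([g1, g2])), remove)
        pruned = GeneAlignmentSet(
            [g.restrict([t for t in g.taxa if t not in remove]) for g in (g1, g2)]
        )
        b = concatenate(pruned, taxon_universe=a.taxa)
        assert a.taxa == b.taxa
        assert a.rows == b.rows


class TestOutputs:
    def test_partition_file_format(self, tmp_path):
        g1 = GeneAlignment("geneA", ["t1", "t2", "t3", "t4"], ["ARN"] * 4)
        g2 = GeneAlignment("geneB", ["t1", "t2", "t3", "t4"], ["CQEGH"] * 4)
        sm = concatenate(GeneAlignmentSet([g1, g2]))
        out = tmp_path / "parts.txt"
        sm.write_partition_file(out)
        assert out.read_text() == "LG, geneA = 1-3\nLG, geneB = 4-8\n"

    def test_fasta_phylip_round_trip(self, tmp_path):
        g = GeneAlignment("g", ["t1", "t2", "t3", "t4"], ["ARND"] * 4)
        sm = concatenate(GeneAlignmentSet([g]))
        sm.write_fasta(tmp_path / "sm.fasta")
        back = load_gene_alignments([tmp_path / "sm.fasta"])
        assert back["sm"].rows == sm.rows
        sm.write_phylip(tmp_path / "sm.phy")
        header = (tmp_path / "sm.phy").read_text().splitlines()[0]
        assert header == "4 4"


class TestScreening:
    def test_clean_gene_kept(self):
        # gene simulated on a tree where both constraint clades are monophyletic
        tree = PhyloTree.from_newick(
            "((A1:0.2,A2:0.2):0.3,(B1:0.2,B2:0.2):0.3,(C1:0.2,C2:0.2):0.1);"
        )
        model = build_model("LG", k=4, alpha=1.0)
        aln, _ = simulate_alignment(tree, model, 1500, seed=3)
        constraints = CladeConstraintSet(
            clades={"cladeA": {"A1", "A2"}, "cladeB": {"B1", "B2"}}, tau=0.95
        )
        report = screen_gene(aln, constraints, n_bootstrap=30, seed=1)
        assert report.verdict == "keep"
        assert report.conflicts == []

    def test_violating_gene_excluded(self):
        # strong signal placing A1 inside the B clade violates cladeA
        tree = PhyloTree.from_newick(
            "((A2:0.2,C1:0.2):0.3,((A1:0.2,B1:0.2):0.4,B2:0.2):0.3,C2:0.2);"
        )
        model = build_model("LG", k=4, alpha=1.0)
        aln, _ = simulate_alignment(tree, model, 10000, seed=5)
        constraints = CladeConstraintSet(
            clades={"cladeA": {"A1", "A2"}, "cladeB": {"B1", "B2"}}, tau=0.95
        )
        report = screen_gene(aln, constraints, n_bootstrap=30, seed=1)
        assert report.verdict == "exclude"
        assert any(c["support"] >= 0.95 for c in report.conflicts)

    def test_unscreenable_gene_skipped_not_crashed(self):
        aln = GeneAlignment("g", ["A1", "A2", "Z1", "Z2"], ["ARND"] * 4)
        constraints = CladeConstraintSet(clades={"cladeA": {"A1", "A2", "A3"}})
        report = screen_gene(aln, constraints)
        assert report.verdict == "unscreenable"

    def test_constraint_validation(self):
        with pytest.raises(ValueError):
            CladeConstraintSet(clades={"x": {"a"}})
        with pytest.raises(ValueError):
            CladeConstraintSet(clades={"x": {"a", "b"}}, tau=1.5)
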