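"""Tree and table ingestion: indexing, validation, round trips."""

import io

import numpy as np
import pytest

import coevonet as cn
from coevonet.errors import FormatError, ValidationError
from coevonet.phylo import EdgeList
from coevonet.simulate import random_tree


class TestReadNewick:
    def test_balanced_quartet_counts(self, tree4):
        assert tree4.n_leaves == 4
        assert tree4.n_branches == 6
        assert tree4.leaf_names == ("A", "B", "C", "D")

    def test_polytomy_resolved_with_zero_length_branches(self):
        t = cn.read_newick("((A:1,B:1,C:1):1,D:1);")
        assert t.n_leaves == 4
        assert t.n_branches == 6
        assert np.count_nonzero(t.branch_lengths == 0.0) == 1
        assert set(t.leaf_names) == {"A", "B", "C", "D"}

    def test_trifurcating_root_rooted_on_first_child_edge(self):
        t = cn.read_newick("(A:1,B:1,C:2);")
        assert t.n_leaves == 3
        assert t.n_branches == 4
        # first root child is the original first child
        first = t.children[0][0]
        assert t.leaf_labels[first] == "A"

    @pytest.mark.parametrize("n", [10, 50, 282])
    def test_branch_count_is_2n_minus_2(self, n):
        t = random_tree(n, np.random.default_rng(n), mean_length=0.2)
        assert t.n_leaves == n
        assert t.n_branches == 2 * n - 2

    def test_parse_error_reports_position(self):
        with pytest.raises(FormatError):
            cn.read_newick("((A:1,B:1:1,(C:1,D:1):1);")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            cn.read_newick("((A:1,A:1):1,(C:1,D:1):1);")

    def test_missing_branch_length_rejected(self):
        with pytest.raises(FormatError):
            cn.read_newick("((A:1,B):1,(C:1,D:1):1);")

    def test_all_zero_lengths_rejected(self):
        with pytest.raises(ValidationError):
            cn.read_newick("((A:0,B:0):0,(C:0,D:0):0);")

    def test_fewer_than_three_leaves_rejected(self):
        with pytest.raises((FormatError, ValidationError)):
            cn.read_newick("(A:1,B:1);")


class TestBranchIndexing:
    def test_preorder_indexing_is_contiguous(self, tree6):
        idx = [tree6.branch_index(v) for v in range(1, tree6.n_nodes)]
        assert idx == list(range(tree6.n_branches))

    def test_root_has_no_branch(self, tree4):
        with pytest.raises(ValueError):
            tree4.branch_index(0)

    @pytest.mark.parametrize("seed", range(5))
    def test_roundtrip_preserves_everything(self, seed):
        t = random_tree(12, np.random.default_rng(seed))
        t2 = cn.read_newick(t.to_newick())
        assert t2.to_newick() == t.to_newick()
        assert t2.leaf_names == t.leaf_names
        assert np.allclose(t2.branch_lengths, t.branch_lengths, atol=1e-12)
        assert list(t2.parent) == list(t.parent)


class TestPhyleticPattern:
    def _tsv(self, tree, rows, genes=None):
        genes = genes or [f"g{i}" for i in range(len(rows))]
        lines = ["gene\t" + "\t".join(tree.leaf_names)]
        for g, r in zip(genes, rows):
            lines.append(g + "\t" + "\t".join(str(x) for x in r))
        return io.StringIO("\n".join(lines))

    def test_all_ones_flagged_constant(self, tree4):
        p = cn.read_phyletic_pattern(self._tsv(tree4, [[1, 1, 1, 1]] * 2), tree4)
        assert p.n_genes == 2
        assert p.constant_mask.all()
        assert not p.all_absent_mask.any()

    def test_non_binary_cell_is_format_error(self, tree4):
        with pytest.raises(FormatError, match="non-binary"):
            cn.read_phyletic_pattern(self._tsv(tree4, [[0, 1, 2, 1]]), tree4)

    def test_genome_mismatch_lists_difference(self, tree4):
        buf = io.StringIO("gene\tA\tB\tC\tX\ng0\t0\t1\t0\t1\n")
        with pytest.raises(ValidationError) as err:
            cn.read_phyletic_pattern(buf, tree4)
        assert "D" in str(err.value) and "X" in str(err.value)

    def test_columns_reordered_to_tree(self, tree4):
        buf = io.StringIO("gene\tD\tC\tB\tA\ng0\t1\t0\t0\t1\n")
        p = cn.read_phyletic_pattern(buf, tree4)
        assert p.genome_ids == list(tree4.leaf_names)
        assert p.matrix.tolist() == [[1, 0, 0, 1]]

    def test_write_read_roundtrip(self, tree8, tmp_path, model_k1):
        sim = cn.simulate_genes(tree8, model_k1, 10, np.random.default_rng(1))
        p = cn.PhyleticPattern(
            gene_ids=[f"g{i}" for i in range(10)],
            genome_ids=list(tree8.leaf_names),
            matrix=sim.leaf_states,
        )
        path = tmp_path / "pat.tsv"
        cn.write_phyletic_pattern(p, path)
        p2 = cn.read_phyletic_pattern(path, tree8)
        assert p2.gene_ids == p.gene_ids
        assert (p2.matrix == p.matrix).all()


class TestEdgeList:
    def test_unordered_deduplication(self):
        e = EdgeList.from_pairs([("b", "a"), ("a", "b")])
        assert len(e) == 1
        assert list(e) == [("a", "b")]

    def test_score_threshold_is_inclusive(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("a\tb\t650\na\tc\t700\nb\tc\t701\n")
        e = cn.read_edge_list(path, score_threshold=700)
        assert len(e) == 2
        assert ("a", "b") not in e

    def test_empty_file(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("")
        assert len(cn.read_edge_list(path)) == 0

    def test_self_loops_dropped_not_fatal(self, tmp_path, caplog):
        path = tmp_path / "e.tsv"
        path.write_text("a\ta\na\tb\n")
        e = cn.read_edge_list(path)
        assert len(e) == 1

    def test_restrict_to_universe(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("a\tb\nb\tz\n")
        e = cn.read_edge_list(path, universe=["a", "b", "c"])
        assert list(e) == [("a", "b")]

    def test_roundtrip_with_scores(self, tmp_path):
        e = EdgeList.from_pairs([("x", "y"), ("y", "z")], scores={("x", "y"): 800.0, ("y", "z"): 900.0})
        path = tmp_path / "e.tsv"
        cn.write_edge_list(e, path)
        e2 = cn.read_edge_list(path, score_threshold=0)
        assert e2.edges == e.edges


def test_read_annotation(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text("g1\tflagellum\ng2\tsecretion\n")
    ann = cn.read_annotation(path)
    assert ann == {"g1": "flagellum", "g2": "secretion"}
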