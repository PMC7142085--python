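"""Alignment entropy and evolutionary-trace ranking."""

import numpy as np
import pytest

from glycolocale.conservation import (
    GAP_AS_SYMBOL,
    SKIP_GAPPED_ROWS,
    OrthologAlignment,
    column_entropy,
    et_rank,
    link_alignment,
    read_msa,
    region_mean_entropy,
)
from glycolocale.io_annotation import GlycoproteinRecord


def _aln(*rows, reference="t0"):
    return OrthologAlignment(
        rows=tuple((f"t{i}", seq) for i, seq in enumerate(rows)),
        reference_taxon=reference,
    )


class TestReadMsa:
    def test_ref_map_skips_gaps(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">human\nA-C\n>mouse\nAAC\n")
        aln = read_msa(p, "human")
        assert aln.ref_map.tolist() == [0, 2]
        assert aln.reference_sequence == "AC"

    def test_ragged_rows_error(self):
        with pytest.raises(ValueError, match="ragged"):
            _aln("AAC", "AC")

    def test_missing_reference_error(self):
        with pytest.raises(ValueError, match="reference"):
            _aln("AAC", "AAC", reference="human")

    def test_link_alignment_mismatch(self):
        aln = _aln("A-C", "AAC")
        rec = GlycoproteinRecord("p", "AAC")
        with pytest.raises(ValueError, match="does not match"):
            link_alignment(aln, rec)


class TestColumnEntropy:
    def test_invariant_column_zero(self):
        aln = _aln("A", "A", "A", "A")
        assert column_entropy(aln, 0) == 0.0

    def test_uniform_four_symbols(self):
        aln = _aln("A", "C", "D", "E")
        assert column_entropy(aln, 0) == pytest.approx(2.0)

    def test_gap_as_symbol(self):
        aln = _aln("A", "A", "-", "C")
        expected = -(0.5 * np.log2(0.5) + 2 * 0.25 * np.log2(0.25))
        assert column_entropy(aln, 0) == pytest.approx(expected)  # 1.5 bits

    def test_skip_gapped_rows(self):
        aln = _aln("A", "A", "-", "C")
        p = np.array([2 / 3, 1 / 3])
        assert column_entropy(aln, 0, SKIP_GAPPED_ROWS) == pytest.approx(
            float(-(p * np.log2(p)).sum())
        )

    def test_all_gap_column_na_under_skip(self):
        aln = _aln("-", "-")
        assert np.isnan(column_entropy(aln, 0, SKIP_GAPPED_ROWS))

    def test_entropy_bounds(self, rng):
        symbols = np.array(list("ACDEFG-"))
        for _ in range(30):
            rows = ["".join(rng.choice(symbols, size=8)) for _ in range(5)]
            aln = _aln(*rows)
            for c in range(8):
                h = column_entropy(aln, c, GAP_AS_SYMBOL)
                assert 0.0 <= h <= np.log2(21)

    def test_substitution_never_decreases_entropy(self, rng):
        """Replacing one residue of an invariant-ish column with a new symbol
        cannot lower the entropy."""
        for _ in range(30):
            n = int(rng.integers(3, 8))
            col = ["A"] * n
            h0 = column_entropy(_aln(*col), 0)
            col[int(rng.integers(n))] = "C"
            h1 = column_entropy(_aln(*col), 0)
            assert h1 >= h0


class TestRegionMeanEntropy:
    def test_identical_orthologs_zero(self):
        aln = _aln("ACDEF", "ACDEF", "ACDEF")
        assert region_mean_entropy(aln, [0, 2, 4]) == 0.0

    def test_single_position_equals_column(self):
        aln = _aln("AC", "AA")
        assert region_mean_entropy(aln, [1]) == column_entropy(aln, 1)

    def test_empty_region_error(self):
        with pytest.raises(ValueError):
            region_mean_entropy(_aln("AC", "AA"), [])

    def test_positions_map_through_gapped_reference(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">human\nA--C\n>mouse\nAGGC\n>rat\nAGGA\n")
        aln = read_msa(p, "human")
        # reference position 1 is column 3: symbols C, C, A
        pr = np.array([2 / 3, 1 / 3])
        assert region_mean_entropy(aln, [1]) == pytest.approx(
            float(-(pr * np.log2(pr)).sum())
        )


QUARTET = "((A:1,B:1):1,(C:1,D:1):1);"


def _quartet_aln(colA, colB, colC, colD):
    return OrthologAlignment(
        rows=(("A", colA), ("B", colB), ("C", colC), ("D", colD)),
        reference_taxon="A",
    )


class TestEtRank:
    def test_invariant_column_rank_one(self):
        aln = _quartet_aln("L", "L", "L", "L")
        assert et_rank(aln, QUARTET).column_ranks.tolist() == [1]

    def test_unique_per_leaf_rank_n(self):
        aln = _quartet_aln("L", "V", "I", "F")
        assert et_rank(aln, QUARTET).column_ranks.tolist() == [4]

    def test_clade_invariant_rank_two(self):
        aln = _quartet_aln("L", "L", "V", "V")
        assert et_rank(aln, QUARTET).column_ranks.tolist() == [2]

    def test_leaf_mismatch_error(self):
        aln = _quartet_aln("L", "L", "V", "V")
        with pytest.raises(ValueError, match="leaves"):
            et_rank(aln, "((A:1,B:1):1,(C:1,E:1):1);")

    def test_row_order_permutation_invariance(self, rng):
        cols = ["LLVV", "LVLV", "AAAA", "LVIF"]
        rows = [("A", "LLAL"), ("B", "LVAV"), ("C", "VLAI"), ("D", "VVAF")]
        base = et_rank(
            OrthologAlignment(rows=tuple(rows), reference_taxon="A"), QUARTET
        ).column_ranks
        for _ in range(5):
            perm = rng.permutation(4)
            shuffled = OrthologAlignment(
                rows=tuple(rows[i] for i in perm), reference_taxon="A"
            )
            assert (et_rank(shuffled, QUARTET).column_ranks == base).all()

    def test_matches_bruteforce_on_random_trees(self, rng):
        """Trace ranks equal an independent first-unopened-ancestor oracle on
        random 6-leaf trees and alignments."""
        import dendropy

        for trial in range(15):
            newick, parents, root = _random_tree(rng, n_leaves=6)
            n_cols = 12
            leaves = [f"L{i}" for i in range(6)]
            rows = tuple(
                (leaf, "".join(rng.choice(list("LV-A"), size=n_cols)))
                for leaf in leaves
            )
            aln = OrthologAlignment(rows=rows, reference_taxon="L0")
            got = et_rank(aln, newick).column_ranks
            want = _oracle_ranks(newick, aln)
            assert got.tolist() == want, (trial, newick)


def _random_tree(rng, n_leaves):
    """Random binary rooted tree by sequential joining; returns newick."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        la, lb = rng.uniform(0.1, 2.0), rng.uniform(0.1, 2.0)
        nodes.append(f"({a}:{la:.3f},{b}:{lb:.3f})")
    return nodes[0] + ";", None, None


def _oracle_ranks(newick, aln):
    """Independent rank oracle: group of a leaf at level k = its first
    unopened ancestor on the root path; checks invariance level by level."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    root = tree.seed_node
    dist = {}
    order = {}
    internals = []
    for idx, node in enumerate(tree.preorder_node_iter()):
        order[id(node)] = idx
        dist[id(node)] = (
            0.0
            if node is root
            else dist[id(node.parent_node)] + (node.edge.length or 1.0)
        )
        if not node.is_leaf():
            internals.append(node)
    internals.sort(key=lambda nd: (dist[id(nd)], order[id(nd)]))
    seq = dict(aln.rows)
    leaves = list(tree.leaf_node_iter())
    ranks = []
    for col in range(aln.width):
        rank = None
        for k in range(1, len(internals) + 2):
            opened = {id(nd) for nd in internals[: k - 1]}
            groups = {}
            for leaf in leaves:
                path = [leaf]
                while path[-1] is not root:
                    path.append(path[-1].parent_node)
                anchor = next(nd for nd in reversed(path) if id(nd) not in opened)
                groups.setdefault(id(anchor), []).append(leaf.taxon.label)
            if all(
                len({seq[t][col] for t in members}) == 1
                for members in groups.values()
            ):
                rank = k
                break
        ranks.append(rank if rank is not None else len(leaves))
    return ranks
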