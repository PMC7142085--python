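"""Conservation of glycosite neighborhoods: column entropy and trace ranks.

Works on per-protein ortholog multiple alignments with a designated human
reference row.  Region positions (neighborhoods, 11-mer controls) are defined
on the ungapped reference and mapped to alignment columns through
``ref_map``.  Two conservation measures:

* per-column Shannon entropy in bits, with the gap either a 21st symbol
  (default) or gapped rows skipped;
* the classic integer evolutionary trace: internal tree nodes sorted by
  distance from the root define partition levels 1..L; the rank of a column
  is the smallest level at which every leaf group is invariant for that
  column (1 = invariant overall, #leaves = never group-invariant before the
  all-singleton partition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from Bio import AlignIO

from .io_annotation import GlycoproteinRecord

log = logging.getLogger(__name__)

GAP = "-"
GAP_AS_SYMBOL = "gap_as_symbol"
SKIP_GAPPED_ROWS = "skip_gapped_rows"


@dataclass(frozen=True)
class OrthologAlignment:
    """Ortholog MSA with a designated reference (human) row."""

    rows: tuple[tuple[str, str], ...]  # (taxon_id, aligned sequence)
    reference_taxon: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        widths = {len(seq) for _, seq in self.rows}
        if len(widths) != 1:
            raise ValueError("ragged alignment: rows of unequal length")
        if self.reference_taxon not in dict(self.rows):
            raise ValueError(f"reference taxon {self.reference_taxon!r} missing")

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def taxa(self) -> list[str]:
        return [t for t, _ in self.rows]

    @property
    def reference_sequence(self) -> str:
        """Ungapped reference row."""
        return dict(self.rows)[self.reference_taxon].replace(GAP, "")

    @property
    def ref_map(self) -> np.ndarray:
        """Strictly increasing map: ungapped reference position -> column."""
        aligned = dict(self.rows)[self.reference_taxon]
        return np.flatnonzero(np.frombuffer(aligned.encode(), dtype="S1") != GAP.encode())

    def matrix(self) -> np.ndarray:
        """(n_rows, width) byte matrix of the alignment."""
        return np.array(
            [np.frombuffer(seq.encode(), dtype="S1") for _, seq in self.rows]
        )


def read_msa(path: str | Path, reference_taxon: str) -> OrthologAlignment:
    """Read an aligned FASTA into an :class:`OrthologAlignment`."""
    aln = AlignIO.read(str(path), "fasta")
    rows = tuple((rec.id, str(rec.seq).upper()) for rec in aln)
    return OrthologAlignment(rows=rows, reference_taxon=reference_taxon)


def link_alignment(
    alignment: OrthologAlignment, record: GlycoproteinRecord
) -> None:
    """Validate that the reference row matches the record it annotates."""
    if alignment.reference_sequence != record.sequence:
        raise ValueError(
            f"{record.protein_id}: ungapped reference row does not match the "
            "record sequence"
        )


def column_entropy(
    alignment: OrthologAlignment, column: int, gap_policy: str = GAP_AS_SYMBOL
) -> float:
    """Shannon entropy (bits) of one alignment column.

    ``gap_as_symbol`` treats '-' as a 21st symbol; ``skip_gapped_rows``
    discards gapped rows first (NaN for an all-gap column).
    """
    if not 0 <= column < alignment.width:
        raise IndexError(f"column {column} out of range")
    symbols = [seq[column] for _, seq in alignment.rows]
    if gap_policy == SKIP_GAPPED_ROWS:
        symbols = [s for s in symbols if s != GAP]
        if not symbols:
            return float("nan")
    elif gap_policy != GAP_AS_SYMBOL:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    _, counts = np.unique(symbols, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def column_entropies(
    alignment: OrthologAlignment, gap_policy: str = GAP_AS_SYMBOL
) -> np.ndarray:
    """Entropy of every column (vectorized convenience)."""
    return np.array(
        [column_entropy(alignment, c, gap_policy) for c in range(alignment.width)]
    )


def region_mean_entropy(
    alignment: OrthologAlignment,
    reference_positions,
    gap_policy: str = GAP_AS_SYMBOL,
) -> float:
    """Mean column entropy over reference positions, NA-aware."""
    positions = np.asarray(reference_positions, dtype=int)
    if positions.size == 0:
        raise ValueError("empty reference position set")
    cols = alignment.ref_map[positions]
    values = np.array([column_entropy(alignment, int(c), gap_policy) for c in cols])
    values = values[~np.isnan(values)]
    return float(values.mean()) if values.size else float("nan")


# ---------------------------------------------------------------------------
# evolutionary trace
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ETRankResult:
    """Integer trace rank per alignment column, mapped to reference positions."""

    column_ranks: np.ndarray  # per alignment column
    position_ranks: np.ndarray  # per ungapped reference position
    n_leaves: int

    def region_mean_rank(self, reference_positions) -> float:
        positions = np.asarray(reference_positions, dtype=int)
        if positions.size == 0:
            return float("nan")
        return float(self.position_ranks[positions].mean())


def _load_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    tree = str(tree)
    if "(" in tree:
        return dendropy.Tree.get(data=tree, schema="newick")
    return dendropy.Tree.get(path=tree, schema="newick")


def _partition_levels(tree: dendropy.Tree) -> list[list[list[str]]]:
    """Leaf partitions for levels 1..L, L = #internal nodes + 1.

    Internal nodes are sorted by distance from the root (missing edge lengths
    count 1); ties break by preorder traversal order.  Level k "opens" the
    first k-1 internal nodes; groups are the maximal unopened subtrees.
    """
    root = tree.seed_node
    dist: dict[int, float] = {id(root): 0.0}
    order: dict[int, int] = {}
    internals = []
    for idx, node in enumerate(tree.preorder_node_iter()):
        order[id(node)] = idx
        if node is not root:
            edge = node.edge.length if node.edge.length is not None else 1.0
            dist[id(node)] = dist[id(node.parent_node)] + edge
        if not node.is_leaf():
            internals.append(node)
    internals.sort(key=lambda nd: (dist[id(nd)], order[id(nd)]))

    def leaf_labels(node) -> list[str]:
        return [lf.taxon.label for lf in node.leaf_iter()]

    levels = []
    for k in range(1, len(internals) + 2):
        opened = {id(nd) for nd in internals[: k - 1]}
        groups: list[list[str]] = []

        def visit(node) -> None:
            if node.is_leaf() or id(node) not in opened:
                groups.append(leaf_labels(node))
            else:
                for child in node.child_nodes():
                    visit(child)

        visit(root)
        levels.append(groups)
    return levels


def et_rank(alignment: OrthologAlignment, tree) -> ETRankResult:
    """Classic integer evolutionary trace rank of every column.

    ``tree`` may be a dendropy Tree, a newick string, or a path to one; its
    leaf set must equal the alignment's taxa.  An unrooted tree is
    midpoint-rooted with a warning.  Gaps count as a distinct symbol.
    """
    t = _load_tree(tree)
    if not t.is_rooted and len(t.seed_node.child_nodes()) > 2:
        log.warning("unrooted tree: midpoint-rooting for trace ranking")
        t.reroot_at_midpoint(update_bipartitions=False)
    leaves = {lf.taxon.label for lf in t.leaf_node_iter()}
    if leaves != set(alignment.taxa):
        raise ValueError(
            f"tree leaves {sorted(leaves)} do not match alignment taxa "
            f"{sorted(alignment.taxa)}"
        )

    mat = alignment.matrix()
    row_index = {taxon: i for i, taxon in enumerate(alignment.taxa)}
    n_cols = alignment.width
    ranks = np.zeros(n_cols, dtype=int)
    unresolved = np.ones(n_cols, dtype=bool)
    for k, groups in enumerate(_partition_levels(t), start=1):
        ok = np.ones(n_cols, dtype=bool)
        for group in groups:
            rows = [row_index[taxon] for taxon in group]
            sub = mat[rows]
            ok &= (sub == sub[0]).all(axis=0)
        newly = unresolved & ok
        ranks[newly] = k
        unresolved &= ~newly
        if not unresolved.any():
            break
    # the final (all-singleton, for binary trees) level resolves everything;
    # any residual column (multifurcating trees) gets rank = #leaves
    ranks[unresolved] = len(leaves)
    position_ranks = ranks[alignment.ref_map]
    return ETRankResult(
        column_ranks=ranks, position_ranks=position_ranks, n_leaves=len(leaves)
    )


def compare_region_ranks(
    per_protein_means: dict[str, dict[str, float]],
) -> "pd.DataFrame":
    """Cross-protein paired Wilcoxon between per-region mean trace ranks.

    ``per_protein_means`` maps protein_id -> {region_name: mean rank (NaN ok)}.
    Returns one row per region pair with the paired test summary.
    """
    import pandas as pd

    from .regions import wilcoxon_signed_rank

    regions = sorted({r for means in per_protein_means.values() for r in means})
    rows = []
    for i, ra in enumerate(regions):
        for rb in regions[i + 1 :]:
            pairs = [
                (means.get(ra, float("nan")), means.get(rb, float("nan")))
                for means in per_protein_means.values()
            ]
            res = wilcoxon_signed_rank(pairs)
            va = np.array([p[0] for p in pairs])
            vb = np.array([p[1] for p in pairs])
            rows.append(
                {
                    "region_a": ra,
                    "region_b": rb,
                    "mean_a": float(np.nanmean(va)) if np.any(~np.isnan(va)) else float("nan"),
                    "mean_b": float(np.nanmean(vb)) if np.any(~np.isnan(vb)) else float("nan"),
                    "n_effective": res.n_effective,
                    "W": res.statistic,
                    "p": res.p_two_sided,
                    "method": res.method,
                }
            )
    return pd.DataFrame(rows)
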