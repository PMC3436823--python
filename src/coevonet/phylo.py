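"""Trees, phyletic matrices, edge lists and annotation tables.

The central container is :class:`Phylogeny`, a rooted bifurcating tree with a
deterministic branch indexing.  Every downstream quantity that is laid out
"per branch" (expected gain/loss events, simulated event counts) uses this
indexing, so it is fixed once at ingestion time: nodes are numbered in
preorder from the root, children visited in Newick file order, and the branch
leading into non-root node ``i`` has branch index ``i - 1``.  A tree with
``n`` leaves therefore has ``2n - 2`` branches indexed ``0 .. 2n - 3``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger("coevonet")

__all__ = [
    "Phylogeny",
    "PhyleticPattern",
    "EdgeList",
    "read_newick",
    "read_phyletic_pattern",
    "write_phyletic_pattern",
    "read_edge_list",
    "write_edge_list",
    "read_annotation",
]


class _Node:
    """Mutable helper used only while ingesting a parsed Newick tree."""

    __slots__ = ("label", "length", "children")

    def __init__(self, label=None, length=None, children=None):
        self.label = label
        self.length = length
        self.children = children if children is not None else []


@dataclass(frozen=True)
class Phylogeny:
    """Rooted bifurcating tree in flat-array form.

    Attributes
    ----------
    parent : ndarray of int
        ``parent[i]`` is the parent node id of node ``i``; ``-1`` for the root
        (node 0).  Node ids are preorder ranks.
    children : tuple of tuple of int
        Children of each node in Newick file order; empty for leaves.
    lengths : ndarray of float
        ``lengths[i]`` is the length of the branch *into* node ``i``
        (substitutions/site); entry 0 (root) is 0 and unused.
    leaf_labels : tuple of str or None
        ``leaf_labels[i]`` is the taxon label for leaf ``i``, ``None`` for
        internal nodes.
    """

    parent: np.ndarray
    children: tuple
    lengths: np.ndarray
    leaf_labels: tuple

    # -- derived structure -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def leaves(self) -> tuple:
        return tuple(i for i in range(self.n_nodes) if not self.children[i])

    @property
    def leaf_names(self) -> tuple:
        """Leaf labels in preorder (Newick file order)."""
        return tuple(self.leaf_labels[i] for i in self.leaves)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    def branch_index(self, node: int) -> int:
        """Index of the branch leading into ``node`` (root has no branch)."""
        if node <= 0:
            raise ValueError("the root has no incoming branch")
        return node - 1

    @property
    def branch_lengths(self) -> np.ndarray:
        """Branch lengths ordered by branch index (length ``2n - 2``)."""
        return self.lengths[1:]

    def postorder(self) -> list:
        """Node ids, children before parents."""
        order, stack = [], [0]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    def preorder(self) -> list:
        return list(range(self.n_nodes))

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        def render(v: int) -> str:
            if not self.children[v]:
                body = self.leaf_labels[v]
            else:
                body = "(" + ",".join(render(c) for c in self.children[v]) + ")"
            if v == 0:
                return body
            return f"{body}:{float(self.lengths[v])!r}"

        return render(0) + ";"

    def _validate(self) -> None:
        names = [lab for lab in self.leaf_labels if lab is not None]
        if len(names) < 3:
            raise ValidationError(f"need at least 3 leaves, found {len(names)}")
        if len(set(names)) != len(names):
            dupes = sorted({x for x in names if names.count(x) > 1})
            raise ValidationError(f"duplicate leaf labels: {dupes}")
        if any(not lab for lab in names):
            raise ValidationError("empty leaf label")
        for v in range(self.n_nodes):
            nc = len(self.children[v])
            if nc not in (0, 2):
                raise ValidationError(f"node {v} has {nc} children after resolution")
        if np.any(self.lengths[1:] < 0):
            raise ValidationError("negative branch length")
        if not np.any(self.lengths[1:] > 0):
            raise ValidationError("all branch lengths are zero")
        if self.n_branches != 2 * self.n_leaves - 2:
            raise ValidationError("branch count does not equal 2n - 2")


def _from_dendropy(node: "dendropy.Node") -> _Node:
    out = _Node()
    if node.is_leaf():
        out.label = node.taxon.label if node.taxon is not None else None
    out.length = node.edge.length
    out.children = [_from_dendropy(c) for c in node.child_nodes()]
    return out


def _resolve_polytomies(node: _Node, is_root: bool) -> None:
    """Force a bifurcating topology, inserting zero-length branches.

    A multifurcating root (the usual unrooted-Newick trifurcation) is rooted
    on its first child edge: the first child is kept, the remaining children
    are pushed under a new zero-length node.  Internal polytomies are resolved
    left-branching.  Zero-length branches receive zero expected events under
    the gain/loss model, so inference is unaffected by the arbitrary choice.
    """
    for c in node.children:
        _resolve_polytomies(c, False)
    while len(node.children) > 2:
        if is_root:
            rest = _Node(length=0.0, children=node.children[1:])
            node.children = [node.children[0], rest]
        else:
            left = _Node(length=0.0, children=node.children[:2])
            node.children = [left] + node.children[2:]


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a validated :class:`Phylogeny`.

    Polytomies are resolved into bifurcations with zero-length branches.
    Branch lengths are required on every non-root edge; internal node labels
    and support values are ignored.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        if "Duplicate taxon labels" in str(exc):
            raise ValidationError(f"duplicate leaf labels: {exc}") from exc
        raise FormatError(f"Newick parse failure: {exc}") from exc
    if dtree.seed_node is None or not dtree.seed_node.child_nodes():
        raise FormatError("Newick parse failure: empty tree")

    root = _from_dendropy(dtree.seed_node)
    _resolve_polytomies(root, True)

    parent, children, lengths, labels = [], [], [], []

    def number(node: _Node, par: int) -> None:
        vid = len(parent)
        parent.append(par)
        children.append(None)
        labels.append(node.label)
        if par == -1:
            lengths.append(0.0)
        else:
            if node.length is None:
                raise FormatError("missing branch length on a non-root edge")
            lengths.append(float(node.length))
        kid_ids = []
        for c in node.children:
            kid_ids.append(len(parent))
            number(c, vid)
        children[vid] = tuple(kid_ids)

    number(root, -1)
    tree = Phylogeny(
        parent=np.asarray(parent, dtype=np.int64),
        children=tuple(children),
        lengths=np.asarray(lengths, dtype=float),
        leaf_labels=tuple(labels),
    )
    tree._validate()
    return tree


# ---------------------------------------------------------------------------
# Phyletic pattern
# ---------------------------------------------------------------------------


@dataclass
class PhyleticPattern:
    """0/1 presence/absence matrix, genes x genomes.

    ``genome_ids`` always matches the tree's preorder leaf order after
    ingestion through :func:`read_phyletic_pattern`.  Genes present in zero
    or in all genomes are retained but flagged constant: their event vectors
    carry (next to) no signal and they cannot produce finite correlations.
    """

    gene_ids: list
    genome_ids: list
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.gene_ids), len(self.genome_ids)):
            raise ValidationError("matrix shape does not match id lists")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if not np.isin(self.matrix, (0, 1)).all():
            raise FormatError("matrix entries must be 0 or 1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def constant_mask(self) -> np.ndarray:
        """True for genes present in all genomes or in none."""
        s = self.matrix.sum(axis=1)
        return (s == 0) | (s == self.matrix.shape[1])

    @property
    def all_absent_mask(self) -> np.ndarray:
        return self.matrix.sum(axis=1) == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.gene_ids, columns=self.genome_ids)


def read_phyletic_pattern(path, tree: Phylogeny) -> PhyleticPattern:
    """Read a tab-separated presence/absence table and align it to ``tree``.

    The header row holds genome ids and the first column gene ids.  Every cell
    must be literally ``0`` or ``1`` — no imputation.  Columns are reordered
    to the tree's leaf order.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    genomes = [str(c) for c in df.columns]
    leaf_set = set(tree.leaf_names)
    if set(genomes) != leaf_set:
        missing = sorted(leaf_set - set(genomes))
        extra = sorted(set(genomes) - leaf_set)
        raise ValidationError(
            f"genome set does not match tree leaves; missing from table: {missing}; "
            f"not in tree: {extra}"
        )
    values = df.to_numpy()
    bad = ~np.isin(values, ("0", "1"))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"non-binary cell {values[r, c]!r} at gene {df.index[r]!r}, "
            f"genome {df.columns[c]!r}"
        )
    df = df[list(tree.leaf_names)]
    pattern = PhyleticPattern(
        gene_ids=[str(g) for g in df.index],
        genome_ids=list(tree.leaf_names),
        matrix=df.to_numpy(dtype=np.int8),
    )
    n_const = int(pattern.constant_mask.sum())
    if n_const:
        logger.info("%d constant gene(s) flagged (absent or present everywhere)", n_const)
    return pattern


def write_phyletic_pattern(pattern: PhyleticPattern, path) -> None:
    pattern.to_frame().to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Edge lists and annotations
# ---------------------------------------------------------------------------


@dataclass
class EdgeList:
    """Undirected simple graph as canonical (sorted) gene-id pairs."""

    edges: set = field(default_factory=set)
    scores: dict = field(default_factory=dict)

    @staticmethod
    def canonical(a: str, b: str) -> tuple:
        return (a, b) if a <= b else (b, a)

    @classmethod
    def from_pairs(cls, pairs: Iterable, scores: Mapping | None = None) -> "EdgeList":
        out = cls()
        for a, b in pairs:
            if a == b:
                continue
            out.edges.add(cls.canonical(a, b))
        if scores:
            out.scores = {cls.canonical(a, b): s for (a, b), s in scores.items()}
        return out

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair) -> bool:
        return self.canonical(*pair) in self.edges

    def __iter__(self):
        return iter(sorted(self.edges))

    def restrict(self, universe: Iterable) -> "EdgeList":
        uni = set(universe)
        kept = {e for e in self.edges if e[0] in uni and e[1] in uni}
        return EdgeList(edges=kept, scores={e: s for e, s in self.scores.items() if e in kept})

    def node_set(self) -> set:
        return {g for e in self.edges for g in e}


def read_edge_list(path, universe: Iterable | None = None, score_threshold: float = 700.0) -> EdgeList:
    """Read a headerless two/three-column TSV of gene pairs.

    A third numeric column is treated as an edge score and filtered at
    ``score_threshold`` (kept if score >= threshold; the conventional
    high-confidence cut is 700 on STRING-style scores).  Self-loop rows are
    dropped with a warning.  If ``universe`` is given, edges are restricted
    to it.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return EdgeList()
    if df.shape[1] < 2:
        raise FormatError("edge list needs at least two columns")
    out = EdgeList()
    has_score = df.shape[1] >= 3
    for row in df.itertuples(index=False):
        a, b = str(row[0]), str(row[1])
        if a == b:
            logger.warning("dropping self-loop edge (%s, %s)", a, b)
            continue
        if has_score:
            try:
                score = float(row[2])
            except ValueError as exc:
                raise FormatError(f"non-numeric score {row[2]!r}") from exc
            if score_threshold is not None and score < score_threshold:
                continue
            out.scores[EdgeList.canonical(a, b)] = score
        out.edges.add(EdgeList.canonical(a, b))
    if universe is not None:
        out = out.restrict(universe)
    return out


def write_edge_list(edges: EdgeList, path) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            if (a, b) in edges.scores:
                fh.write(f"{a}\t{b}\t{edges.scores[(a, b)]}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def read_annotation(path) -> dict:
    """Read a two-column TSV mapping gene id -> functional category."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError("annotation table needs two columns")
    out = {}
    for row in df.itertuples(index=False):
        gene, cat = str(row[0]), str(row[1])
        if gene in out and out[gene] != cat:
            raise ValidationError(f"conflicting annotations for gene {gene!r}")
        out[gene] = cat
    return out
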