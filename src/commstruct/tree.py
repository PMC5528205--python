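"""Rooted phylogenies: newick I/O, patristic distances, trait covariance, BLADJ ages.

The tree is the substrate of every phylogenetic statistic in the package:
mean nearest taxon distance (MNTD) averages patristic distances, Blomberg's K
uses the phylogenetic variance-covariance matrix C, and BLADJ-style age
smoothing turns a topology with a handful of dated nodes into a time tree.

Trees are held as :class:`PhyloTree`, a thin validated wrapper around a
:mod:`dendropy` tree.  All trees are treated as rooted at the newick root.
Branch lengths are in time units; node ages are "time before present" with
tips at 0 by default.  A missing branch length is recorded as absent, never
silently treated as 0 or 1 -- statistics that need lengths refuse such trees.
"""

from __future__ import annotations

import io
from collections import deque
from typing import Dict, Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np


class NewickParseError(ValueError):
    """Malformed newick input."""


class TreeError(ValueError):
    """Structurally invalid tree or invalid tree operation."""


class LabeledMatrix:
    """A square matrix over an ordered set of taxon labels.

    Used for both patristic distance matrices and phylogenetic covariance
    matrices.  Supports label-based lookup and restriction to a label subset.
    """

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(labels), len(labels)):
            raise ValueError("matrix shape does not match label count")
        self.labels = list(labels)
        self.values = values
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def indices(self, labels: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._index[l] for l in labels], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown taxon {exc.args[0]!r}") from None

    def submatrix(self, labels: Sequence[str]) -> "LabeledMatrix":
        idx = self.indices(labels)
        return LabeledMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __len__(self) -> int:
        return len(self.labels)


class PhyloTree:
    """A rooted phylogeny with optional branch lengths and node ages."""

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return parse_newick(fh.read())

    def clone(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def _validate(self) -> None:
        seen = set()
        for leaf in self._tree.leaf_node_iter():
            label = _tip_label(leaf)
            if not label:
                raise TreeError("tip with empty label")
            if label in seen:
                raise TreeError(f"duplicate tip label {label!r}")
            seen.add(label)
        if not seen:
            raise TreeError("tree has no tips")

    # -- basic accessors --------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list:
        return [_tip_label(l) for l in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def has_all_branch_lengths(self) -> bool:
        return not self._missing_length_edges()

    def _missing_length_edges(self) -> list:
        missing = []
        root = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                missing.append(_node_name(node))
        return missing

    def _require_lengths(self) -> None:
        missing = self._missing_length_edges()
        if missing:
            raise TreeError(
                "branch length absent on edge(s) above: " + ", ".join(missing)
            )
        for node in self._tree.preorder_node_iter():
            if node is not self._tree.seed_node and node.edge.length < 0:
                raise TreeError(f"negative branch length above {_node_name(node)}")

    def depth(self) -> float:
        """Maximum root-to-tip path length."""
        self._require_lengths()
        return max(self._node_depths().values())

    def _node_depths(self) -> Dict[dendropy.Node, float]:
        depths: Dict[dendropy.Node, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + node.edge.length
        return depths

    # -- matrices ---------------------------------------------------------

    def patristic_matrix(self, taxa: Optional[Sequence[str]] = None) -> LabeledMatrix:
        return patristic_matrix(self, taxa)

    def vcv_matrix(self) -> LabeledMatrix:
        return vcv_matrix(self)

    def newick(self) -> str:
        return write_newick(self)


def _tip_label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label is not None:
        return node.taxon.label
    return node.label or ""


def _node_name(node: dendropy.Node) -> str:
    label = _tip_label(node)
    if label:
        return label
    tips = [_tip_label(l) for l in node.leaf_iter()]
    return "mrca(" + ",".join(sorted(tips)[:3]) + (",..." if len(tips) > 3 else "") + ")"


# -- newick I/O -----------------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse a single newick tree.

    The dialect is plain newick: branch lengths and internal labels optional,
    no comments or NHX annotations (these are rejected so no metadata can be
    dropped silently).  Missing branch lengths stay absent.
    """
    if text is None or not text.strip():
        raise NewickParseError("empty newick input")
    if "[" in text or "]" in text:
        pos = text.find("[") if "[" in text else text.find("]")
        raise NewickParseError(
            f"newick comments/NHX are not supported (bracket at position {pos})"
        )
    _check_balance(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickParseError(f"newick parse error: {exc}") from exc
    return PhyloTree(dtree)


def _check_balance(text: str) -> None:
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(f"unbalanced ')' at position {pos}")
    if depth != 0:
        raise NewickParseError(
            f"unbalanced parentheses: {depth} '(' left open at end of input"
        )


def write_newick(tree: PhyloTree) -> str:
    """Serialize to newick; round-trip stable for topology, labels, lengths."""
    out = tree.dendropy_tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".17g",
    ).strip()
    return out


# -- patristic and covariance matrices ------------------------------------


def _tip_arrays(tree: PhyloTree):
    """Tip labels, per-tip depth, and per-node tip index lists (postorder)."""
    labels = tree.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    depths = tree._node_depths()
    tip_depth = np.zeros(len(labels))
    below: Dict[dendropy.Node, np.ndarray] = {}
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            i = index[_tip_label(node)]
            tip_depth[i] = depths[node]
            below[node] = np.array([i], dtype=int)
        else:
            below[node] = np.concatenate([below[c] for c in node.child_nodes()])
    return labels, index, depths, tip_depth, below


def patristic_matrix(tree: PhyloTree, taxa: Optional[Sequence[str]] = None) -> LabeledMatrix:
    """Matrix of path-length (patristic) distances between tips.

    d(a, b) = depth(a) + depth(b) - 2 * depth(MRCA(a, b)); zero diagonal.
    """
    tree._require_lengths()
    labels, index, depths, tip_depth, below = _tip_arrays(tree)
    n = len(labels)
    D = np.zeros((n, n))
    for node in tree.dendropy_tree.postorder_internal_node_iter():
        dn = depths[node]
        kids = node.child_nodes()
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                ia, ib = below[kids[i]], below[kids[j]]
                d = tip_depth[ia][:, None] + tip_depth[ib][None, :] - 2.0 * dn
                D[np.ix_(ia, ib)] = d
                D[np.ix_(ib, ia)] = d.T
    full = LabeledMatrix(labels, D)
    if taxa is None:
        return full
    taxa = list(taxa)
    for t in taxa:
        if t not in full:
            raise KeyError(f"unknown taxon {t!r}")
    return full.submatrix(taxa)


def vcv_matrix(tree: PhyloTree) -> LabeledMatrix:
    """Phylogenetic covariance matrix C: C[i, j] = root-to-MRCA depth.

    C[i, i] is the root-to-tip depth; for an ultrametric tree the diagonal is
    constant.  C is symmetric positive semi-definite by construction (it is a
    Gram matrix of shared-path lengths).
    """
    tree._require_lengths()
    labels, index, depths, tip_depth, below = _tip_arrays(tree)
    n = len(labels)
    C = np.zeros((n, n))
    for node in tree.dendropy_tree.postorder_internal_node_iter():
        dn = depths[node]
        kids = node.child_nodes()
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                ia, ib = below[kids[i]], below[kids[j]]
                C[np.ix_(ia, ib)] = dn
                C[np.ix_(ib, ia)] = dn
    C[np.diag_indices(n)] = tip_depth
    return LabeledMatrix(labels, C)


# -- pruning --------------------------------------------------------------


def prune_to_taxa(tree: PhyloTree, taxa: Iterable[str]) -> PhyloTree:
    """Induced subtree on ``taxa``; collapses degree-2 nodes, summing lengths.

    Patristic distances among the retained taxa are unchanged.
    """
    taxa = list(dict.fromkeys(taxa))
    if len(taxa) < 2:
        raise TreeError("prune_to_taxa requires at least 2 taxa")
    tips = set(tree.tip_labels)
    missing = [t for t in taxa if t not in tips]
    if missing:
        raise TreeError("taxa not in tree: " + ", ".join(missing))
    dtree = tree.dendropy_tree.clone(depth=1)
    dtree.retain_taxa_with_labels(taxa)
    dtree.suppress_unifurcations()
    # drop a dangling root edge left by pruning (does not affect tip-tip paths)
    dtree.seed_node.edge.length = None
    return PhyloTree(dtree)


# -- BLADJ-style age smoothing --------------------------------------------


def bladj_smooth(
    tree: PhyloTree,
    fixed_ages: Mapping[str, float],
    root_age: Optional[float] = None,
) -> PhyloTree:
    """Assign ages to undated nodes by even interpolation (BLADJ behaviour).

    Dated anchors are the root (``root_age`` or its entry in ``fixed_ages``),
    any node whose label appears in ``fixed_ages``, and the tips (age 0 unless
    fixed).  Working root-to-tip, each undated node receives an age evenly
    interpolated along the chain from its nearest dated ancestor to its
    nearest dated descendant (fewest intervening nodes; ties broken by
    traversal order).  Branch lengths are recomputed as
    ``age(parent) - age(child)``; ages of dated nodes are never changed.
    """
    fixed = dict(fixed_ages)
    out = tree.clone()
    dtree = out.dendropy_tree
    label_to_node: Dict[str, dendropy.Node] = {}
    for node in dtree.preorder_node_iter():
        label = _tip_label(node)
        if label:
            if label in label_to_node:
                raise TreeError(f"duplicate node label {label!r}")
            label_to_node[label] = node
    unknown = [l for l in fixed if l not in label_to_node]
    if unknown:
        raise TreeError(
            "fixed_ages reference unlabeled/unknown node(s): " + ", ".join(unknown)
        )

    age: Dict[dendropy.Node, float] = {}
    for label, a in fixed.items():
        if a < 0:
            raise TreeError(f"negative age for node {label!r}")
        age[label_to_node[label]] = float(a)
    for leaf in dtree.leaf_node_iter():
        age.setdefault(leaf, 0.0)
    root = dtree.seed_node
    if root not in age:
        if root_age is None:
            raise TreeError("root age must be fixed (root_age or fixed_ages)")
        age[root] = float(root_age)
    elif root_age is not None and age[root] != root_age:
        raise TreeError("root age given twice with different values")

    # anchor consistency: every dated ancestor at least as old as any dated
    # descendant
    for node, a in age.items():
        p = node.parent_node
        while p is not None:
            if p in age:
                if age[p] < a - 1e-12:
                    raise TreeError(
                        f"fixed age of {_node_name(p)} ({age[p]}) is younger than "
                        f"its descendant {_node_name(node)} ({a})"
                    )
                break
            p = p.parent_node

    for node in dtree.preorder_node_iter():
        if node in age:
            continue
        # nearest dated ancestor (root is dated, so this terminates)
        anc = node.parent_node
        up = 1
        while anc not in age:
            anc = anc.parent_node
            up += 1
        # nearest dated descendant by BFS (tips are dated)
        queue = deque([(node, 0)])
        desc, down = None, None
        while queue:
            cur, dist = queue.popleft()
            if cur in age:
                desc, down = cur, dist
                break
            for child in cur.child_nodes():
                queue.append((child, dist + 1))
        span = up + down
        a = age[anc] - (age[anc] - age[desc]) * (up / span)
        age[node] = a

    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        bl = age[node.parent_node] - age[node]
        if bl < -1e-9:
            raise TreeError(
                f"age interpolation produced a negative branch above "
                f"{_node_name(node)}; fixed ages are mutually inconsistent"
            )
        node.edge.length = max(bl, 0.0)
        node.age_before_present = age[node]
    root.age_before_present = age[root]
    return out
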