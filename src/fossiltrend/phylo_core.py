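"""Time-calibrated trees with extinct tips.

Trees are rooted, with branch lengths in millions of years (Myr). Every tip
carries an occurrence age ``t_i`` in Ma before present; the present (age 0)
is defined by the youngest tip unless an explicit root age is supplied.
Extinct (fossil) tips have ``t_i > 0``; an ultrametric tree has all tip ages
equal. The class exposes the temporal geometry every trait-model likelihood
needs: root-to-MRCA shared-path matrices, tip ages, and branch editing
(terminal truncation, tip grafting, pruning).
"""

from __future__ import annotations

import io
import warnings
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "NewickError",
    "TimeTree",
    "TreeSample",
    "read_newick",
    "read_tree_sample",
]

_AGE_TOL = 1e-9


class NewickError(ValueError):
    """Raised for malformed Newick input or missing branch lengths."""


class TimeTree:
    """A rooted time tree with branch lengths in Myr and tip ages in Ma.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted tree; every non-root edge must have a branch length >= 0.
    root_age : float, optional
        Age of the root in Ma before present. When omitted the youngest tip
        defines the present (age 0).
    """

    def __init__(self, tree: dendropy.Tree, root_age: float | None = None):
        self._tree = tree
        self._validate_lengths()
        self._depths = {}
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                self._depths[node] = 0.0
            else:
                self._depths[node] = self._depths[parent] + node.edge.length
        self._leaves = list(tree.leaf_node_iter())
        labels = [lf.taxon.label if lf.taxon is not None else None for lf in self._leaves]
        if any(lab is None for lab in labels):
            raise NewickError("every tip must be labelled")
        if len(set(labels)) != len(labels):
            raise NewickError("tip labels must be unique")
        self.tip_labels: list[str] = labels
        depths = np.array([self._depths[lf] for lf in self._leaves])
        if root_age is None:
            root_age = float(depths.max())
        self.root_age: float = float(root_age)
        ages = self.root_age - depths
        if ages.min() < -1e-6:
            raise ValueError(
                f"explicit root age {root_age} is younger than the deepest tip"
            )
        self._tip_ages = np.clip(ages, 0.0, None)
        zero_terminal = [
            lab
            for lab, lf in zip(labels, self._leaves)
            if lf.edge.length is not None and lf.edge.length <= _AGE_TOL
        ]
        if zero_terminal:
            warnings.warn(
                "zero-length terminal branch(es): " + ", ".join(sorted(zero_terminal)),
                stacklevel=2,
            )

    # ------------------------------------------------------------------ basics

    def _validate_lengths(self) -> None:
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                if node.edge.length is None:
                    node.edge.length = 0.0
                continue
            if node.edge.length is None:
                lab = node.taxon.label if node.taxon else "<internal>"
                raise NewickError(f"missing branch length on edge above {lab!r}")
            if node.edge.length < 0:
                lab = node.taxon.label if node.taxon else "<internal>"
                raise NewickError(f"negative branch length on edge above {lab!r}")

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def tip_ages(self) -> dict[str, float]:
        """Occurrence age (Ma before present) per tip label."""
        return dict(zip(self.tip_labels, self._tip_ages))

    def tip_age_array(self, order: Sequence[str] | None = None) -> np.ndarray:
        ages = self.tip_ages
        labels = self.tip_labels if order is None else list(order)
        return np.array([ages[lab] for lab in labels])

    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path lengths (Myr), in ``tip_labels`` order."""
        return self.root_age - self._tip_ages

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        return float(self._tip_ages.max() - self._tip_ages.min()) <= tol

    def copy(self) -> "TimeTree":
        return TimeTree(self._tree.clone(depth=1), root_age=self.root_age)

    # ------------------------------------------------------------- I/O

    @classmethod
    def from_newick(cls, source: str, root_age: float | None = None) -> "TimeTree":
        """Parse a Newick string (or the contents of a file-like path)."""
        try:
            tree = dendropy.Tree.get(
                data=source,
                schema="newick",
                suppress_internal_node_taxa=False,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error classes
            raise NewickError(f"malformed Newick: {exc}") from exc
        return cls(tree, root_age=root_age)

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".12g",
        )
        return s.strip() + "\n"

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick())

    # ------------------------------------------------- temporal geometry

    def shared_path_matrix(self) -> np.ndarray:
        """Root-to-MRCA path length (Myr) for every tip pair.

        Entry (i, j) is the path length from the root to the most recent
        common ancestor of tips i and j; the diagonal holds root-to-tip path
        lengths. Symmetric and positive semidefinite. Row/column order
        follows ``tip_labels``.
        """
        n = self.n_tips
        idx = {lf: i for i, lf in enumerate(self._leaves)}
        M = np.zeros((n, n))
        below: dict = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                i = idx[node]
                M[i, i] = self._depths[node]
                below[node] = [i]
            else:
                groups = [below.pop(ch) for ch in node.child_nodes()]
                d = self._depths[node]
                for a in range(len(groups)):
                    for b in range(a + 1, len(groups)):
                        for i in groups[a]:
                            for j in groups[b]:
                                M[i, j] = M[j, i] = d
                merged: list[int] = []
                for g in groups:
                    merged.extend(g)
                below[node] = merged
        return M

    def mrca_ages(self) -> np.ndarray:
        """Age (Ma) of the MRCA of each tip pair; diagonal = tip ages."""
        return self.root_age - self.shared_path_matrix()

    # ------------------------------------------------- branch editing

    def _leaf_by_label(self, label: str):
        for lf in self._leaves:
            if lf.taxon.label == label:
                return lf
        raise KeyError(f"unknown tip {label!r}")

    def truncate_terminal(self, tip: str, new_age: float) -> "TimeTree":
        """Shorten a terminal branch so the tip's occurrence age is ``new_age``.

        Used to impose a minimum (oldest-possible) age on a tip from a dated
        fossil occurrence of an extant species, creating a pseudo-fossil tip.
        The time frame (root age, all other branches) is unchanged.
        """
        current = self.tip_ages[tip]  # KeyError for unknown tips
        if new_age < current - _AGE_TOL:
            raise ValueError(
                f"new_age {new_age} would lengthen the branch (tip age {current}); "
                "truncation can only make a tip older"
            )
        new = self.copy()
        leaf = new._leaf_by_label(tip)
        parent_age = new.root_age - new._depths[leaf.parent_node]
        if new_age > parent_age + _AGE_TOL:
            raise ValueError(
                f"new_age {new_age} is older than the tip's parent node ({parent_age:g} Ma)"
            )
        leaf.edge.length = max(0.0, parent_age - new_age)
        return TimeTree(new._tree, root_age=self.root_age)

    def graft_tip(
        self,
        new_label: str,
        attach_edge: str,
        attach_age: float,
        tip_age: float,
    ) -> "TimeTree":
        """Insert a new tip on the edge above the node labelled ``attach_edge``.

        ``attach_age`` must lie strictly within the edge's age span and
        ``tip_age`` must be younger than ``attach_age``. All preexisting
        pairwise shared paths are unchanged.
        """
        if new_label in self.tip_labels:
            raise ValueError(f"tip label {new_label!r} already present")
        if tip_age >= attach_age:
            raise ValueError("tip_age must be younger than attach_age")
        new = self.copy()
        target = None
        for node in new._tree.preorder_node_iter():
            lab = node.taxon.label if node.taxon is not None else node.label
            if lab == attach_edge:
                target = node
                break
        if target is None or target.parent_node is None:
            raise KeyError(f"no non-root edge above a node labelled {attach_edge!r}")
        child_age = new.root_age - new._depths[target]
        parent_age = new.root_age - new._depths[target.parent_node]
        if not (child_age + _AGE_TOL < attach_age < parent_age - _AGE_TOL):
            raise ValueError(
                f"attach_age {attach_age} outside the span of edge "
                f"({child_age:g}, {parent_age:g}) Ma"
            )
        parent = target.parent_node
        upper = parent_age - attach_age
        lower = attach_age - child_age
        mid = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(mid)
        mid.edge.length = upper
        mid.add_child(target)
        target.edge.length = lower
        taxon = new._tree.taxon_namespace.new_taxon(label=new_label)
        tipnode = dendropy.Node(taxon=taxon)
        mid.add_child(tipnode)
        tipnode.edge.length = attach_age - tip_age
        return TimeTree(new._tree, root_age=self.root_age)

    def prune_tips(self, labels: Iterable[str]) -> "TimeTree":
        """Drop the given tips, suppressing unifurcations; ages of the
        remaining tips are preserved exactly."""
        drop = set(labels)
        unknown = drop - set(self.tip_labels)
        if unknown:
            raise KeyError(f"unknown tip(s): {sorted(unknown)}")
        keep = [lab for lab in self.tip_labels if lab not in drop]
        if not keep:
            raise ValueError("cannot prune every tip")
        old_ages = self.tip_ages
        new = self.copy()
        new._tree.retain_taxa_with_labels(keep)
        new._tree.suppress_unifurcations()
        # re-anchor: any retained tip must keep its age
        pruned = TimeTree(new._tree)
        ref = pruned.tip_labels[0]
        depth_ref = pruned.root_age - pruned.tip_ages[ref]
        new_root_age = old_ages[ref] + depth_ref
        stem = self.root_age - new_root_age
        if stem > 1e-12:
            # keep the original time frame: restore the collapsed root stem
            # so every retained pairwise shared path is preserved exactly
            seed = pruned._tree.seed_node
            seed.edge.length = stem  # any old root-edge length was not a path
            root = dendropy.Node()
            root.add_child(seed)
            pruned._tree.seed_node = root
        return TimeTree(pruned._tree, root_age=self.root_age)


class TreeSample:
    """An ordered collection of posterior tree draws sharing one tip set."""

    def __init__(self, trees: Sequence[TimeTree]):
        if not trees:
            raise ValueError("empty tree sample")
        ref = set(trees[0].tip_labels)
        for i, t in enumerate(trees):
            if set(t.tip_labels) != ref:
                raise ValueError(f"tree {i} has a different tip-label set")
        self.trees = list(trees)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i) -> TimeTree:
        return self.trees[i]

    @classmethod
    def from_newick(cls, source: str) -> "TreeSample":
        """Parse a multi-tree Newick string or one-tree-per-line text."""
        try:
            tl = dendropy.TreeList.get(
                data=source, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            raise NewickError(f"malformed Newick: {exc}") from exc
        return cls([TimeTree(t) for t in tl])

    def to_newick(self) -> str:
        return "".join(t.to_newick() for t in self.trees)


def read_newick(path_or_text: str, root_age: float | None = None) -> TimeTree:
    """Read a single time tree from a Newick file path or literal string."""
    text = path_or_text
    if "(" not in path_or_text:
        try:
            with open(path_or_text) as fh:
                text = fh.read()
        except OSError as exc:
            raise NewickError(
                f"not a Newick string and not a readable file: {path_or_text!r}"
            ) from exc
    return TimeTree.from_newick(text, root_age=root_age)


def read_tree_sample(path_or_text: str) -> TreeSample:
    text = path_or_text
    if "(" not in path_or_text:
        with open(path_or_text) as fh:
            text = fh.read()
    return TreeSample.from_newick(text)
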