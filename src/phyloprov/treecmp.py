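"""Tree rooting, annotation and pairwise divergence metrics.

Implements the three divergence measures used to compare trees built from
different supermatrix windows:

* Robinson–Foulds symmetric distance — the count of non-trivial
  bipartitions (splits) present in exactly one of the two trees.
* Branch-score distance — the Euclidean distance between branch-length
  vectors indexed by the union of bipartitions, with length 0 for a split
  absent from a tree.  Pendant (leaf) branches are included by default.
* Rate-standardized branch-score distance — the same after rescaling each
  tree so its total branch length (tree length) is 1, which removes
  uniform rate differences between trees and leaves only relative
  branch-length structure.

Bipartitions are extracted by the module's own traversal; the two edges
incident to the root of a rooted-binary Newick represent the same unrooted
branch and their lengths are pooled, so all metrics are invariant under
re-rooting.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass

import numpy as np
from Bio import Phylo

from .core import Project, Tree, UnknownIdError

__all__ = [
    "bipartitions",
    "tree_length",
    "rf_distance",
    "branch_score",
    "standardized_branch_score",
    "pairwise_matrix",
    "root_and_annotate",
    "DistanceMatrix",
    "LeafSetMismatchError",
]


class LeafSetMismatchError(ValueError):
    """Two trees under comparison do not share the same leaf-label set."""

    def __init__(self, only_first: set[str], only_second: set[str]):
        super().__init__(
            "leaf sets differ; only in first: "
            f"{sorted(only_first)}; only in second: {sorted(only_second)}"
        )
        self.only_first = only_first
        self.only_second = only_second


def _phylo(newick: str):
    return Phylo.read(_io.StringIO(newick), "newick")


def _newick_of(tree: Tree | str) -> str:
    return tree.newick if isinstance(tree, Tree) else tree


def tree_length(tree: Tree | str) -> float:
    """Sum of all branch lengths (absent lengths count as 0)."""
    total = 0.0
    for clade in _phylo(_newick_of(tree)).find_clades():
        if clade.branch_length is not None:
            total += clade.branch_length
    return total


def bipartitions(
    tree: Tree | str, *, require_lengths: bool = False
) -> tuple[frozenset[str], dict[frozenset[str], float]]:
    """Extract the bipartition → branch-length map of a tree.

    Each branch of the unrooted tree induces a split of the leaf set; the
    split is keyed canonically by the side not containing the
    lexicographically smallest leaf.  The two root-incident edges of a
    rooted-binary Newick describe the same unrooted branch, so their
    lengths are summed into one entry.  Returns ``(leaf_set, splits)``;
    trivial (pendant) splits are included with their lengths and filtered
    by callers that only need topology.
    """
    ptree = _phylo(_newick_of(tree))
    leaves = frozenset(term.name for term in ptree.get_terminals())
    if len(leaves) != ptree.count_terminals():
        raise ValueError("duplicate leaf labels in tree")
    ref = min(leaves)
    splits: dict[frozenset[str], float] = {}
    for clade in ptree.find_clades():
        if clade is ptree.root:
            continue
        side = frozenset(term.name for term in clade.get_terminals())
        if ref in side:
            side = leaves - side
        if not side or side == leaves:
            continue
        length = clade.branch_length
        if length is None:
            if require_lengths:
                raise ValueError(f"branch without length above leaves {sorted(side)[:3]}...")
            length = 0.0
        splits[side] = splits.get(side, 0.0) + length
    return leaves, splits


def _check_same_leaves(a: frozenset[str], b: frozenset[str]) -> None:
    if a != b:
        raise LeafSetMismatchError(a - b, b - a)


def _nontrivial(splits, leaves):
    return {s for s in splits if 1 < len(s) < len(leaves) - 1}


def rf_distance(t1: Tree | str, t2: Tree | str) -> int:
    """Robinson–Foulds symmetric distance between two trees.

    Counts the non-trivial bipartitions present in exactly one tree; 0 iff
    the unrooted topologies agree, at most ``2(n-3)`` for binary trees.
    """
    leaves1, s1 = bipartitions(t1)
    leaves2, s2 = bipartitions(t2)
    _check_same_leaves(leaves1, leaves2)
    return len(_nontrivial(s1, leaves1) ^ _nontrivial(s2, leaves2))


def branch_score(
    t1: Tree | str, t2: Tree | str, *, include_pendant: bool = True
) -> float:
    """Branch-score distance: sqrt of summed squared branch-length differences.

    The sum runs over the union of bipartitions of the two trees, with a
    branch length of 0 for a split absent from a tree.  ``include_pendant``
    keeps the terminal-branch terms (the cited metric includes them); set
    False to compare internal structure only.
    """
    leaves1, s1 = bipartitions(t1, require_lengths=True)
    leaves2, s2 = bipartitions(t2, require_lengths=True)
    _check_same_leaves(leaves1, leaves2)
    keys = set(s1) | set(s2)
    if not include_pendant:
        keys = _nontrivial(keys, leaves1)
    return math.sqrt(sum((s1.get(k, 0.0) - s2.get(k, 0.0)) ** 2 for k in keys))


def standardized_branch_score(
    t1: Tree | str, t2: Tree | str, *, include_pendant: bool = True
) -> float:
    """Branch-score distance after per-tree normalization by tree length.

    Every branch length is divided by its own tree's total length before
    the comparison, so two trees differing only by a uniform evolutionary
    rate scale are at distance 0.
    """
    leaves1, s1 = bipartitions(t1, require_lengths=True)
    leaves2, s2 = bipartitions(t2, require_lengths=True)
    _check_same_leaves(leaves1, leaves2)
    tl1 = sum(s1.values())
    tl2 = sum(s2.values())
    if tl1 <= 0 or tl2 <= 0:
        raise ValueError("standardization requires strictly positive tree length")
    keys = set(s1) | set(s2)
    if not include_pendant:
        keys = _nontrivial(keys, leaves1)
    return math.sqrt(
        sum((s1.get(k, 0.0) / tl1 - s2.get(k, 0.0) / tl2) ** 2 for k in keys)
    )


METRICS = {
    "rf": rf_distance,
    "branch_score": branch_score,
    "standardized_branch_score": standardized_branch_score,
}


@dataclass
class DistanceMatrix:
    """Symmetric matrix of a tree metric over an ordered tree list."""

    ids: list[str]
    values: np.ndarray
    metric: str

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    def plot_heatmap(self, path) -> None:
        """Render the matrix as a heatmap (white = identical, dark = divergent)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1 + 0.5 * len(self.ids),) * 2)
        im = ax.imshow(self.values, cmap="Blues")
        ax.set_xticks(range(len(self.ids)), self.ids, rotation=90)
        ax.set_yticks(range(len(self.ids)), self.ids)
        ax.set_title(self.metric)
        fig.colorbar(im, ax=ax)
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)


def pairwise_matrix(trees: list[Tree | str], metric: str, ids: list[str] | None = None) -> DistanceMatrix:
    """Full pairwise distance matrix over a list of trees with shared leaves."""
    if len(trees) < 2:
        raise ValueError("need at least two trees")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    fn = METRICS[metric]
    n = len(trees)
    if ids is None:
        ids = [
            t.object_id if isinstance(t, Tree) else f"tree_{i}"
            for i, t in enumerate(trees)
        ]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                values[i, j] = values[j, i] = fn(trees[i], trees[j])
            except (ValueError, LeafSetMismatchError) as exc:
                raise ValueError(f"pair ({ids[i]}, {ids[j]}): {exc}") from exc
    return DistanceMatrix(ids=ids, values=values, metric=metric)


def root_and_annotate(
    project: Project,
    tree: Tree,
    outgroup: dict | list[str],
    fields: list[str] = (),
) -> Tree:
    """Root a tree on a metadata-selected outgroup and annotate its leaves.

    ``outgroup`` is either an explicit list of leaf labels or a metadata
    predicate ``{field: value}`` evaluated against each leaf's underlying
    record (via ``leaf_map``).  The matched leaves must form one side of an
    existing bipartition (monophyletic in the unrooted tree), else an error
    names the conflict.  ``fields`` lists metadata keys to copy onto each
    leaf as annotations, later embedded in PhyloXML output.
    """
    ptree = _phylo(tree.newick)
    leaf_labels = [term.name for term in ptree.get_terminals()]

    def record_of(label: str):
        target = tree.leaf_map.get(label, label)
        if target in project.records:
            return project.records[target]
        for rec in project.records.values():
            if rec.otu == target:
                return rec
        return None

    if isinstance(outgroup, dict):
        og = []
        for label in leaf_labels:
            rec = record_of(label)
            if rec is None:
                continue
            if all(
                (rec.otu if k == "otu" else rec.metadata.get(k)) == v
                for k, v in outgroup.items()
            ):
                og.append(label)
    else:
        og = list(outgroup)
    if not og:
        raise ValueError("outgroup selector matched no leaves")
    missing = set(og) - set(leaf_labels)
    if missing:
        raise UnknownIdError(next(iter(missing)), leaf_labels)

    leaves, splits = bipartitions(tree.newick)
    og_set = frozenset(og)
    if len(og_set) > 1:
        comp = leaves - og_set
        if og_set not in splits and comp not in splits and len(comp) > 1:
            raise ValueError(
                f"outgroup is not monophyletic in the unrooted tree: {sorted(og_set)}"
            )

    ptree.root_with_outgroup(*og)
    buf = _io.StringIO()
    Phylo.write(ptree, buf, "newick")

    annotations: dict[str, dict] = {}
    for label in leaf_labels:
        rec = record_of(label)
        if rec is None:
            continue
        ann = {}
        for f in fields:
            ann[f] = rec.otu if f == "otu" else rec.metadata.get(f)
        annotations[label] = ann

    pid = project.next_process_id("root_and_annotate")
    rooted = Tree(
        object_id=f"{pid}_tree",
        newick=buf.getvalue().strip(),
        leaf_map=dict(tree.leaf_map),
        produced_by=pid,
        annotations=annotations,
        rooted=True,
    )
    project.trees[rooted.object_id] = rooted
    project.log(
        "root_and_annotate",
        {"outgroup": sorted(og), "fields": list(fields)},
        input_ids=[tree.object_id],
        output_ids=[rooted.object_id],
        process_id=pid,
    )
    return rooted
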