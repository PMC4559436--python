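"""Synthetic multilocus datasets and random trees for desk-scale runs.

The generator emulates the structure of a published-style phylogenomic
input — by default 465 pre-aligned loci across 26 taxa with full
occupancy — with a controllable per-locus diversity gradient.  Each
locus gets a target column entropy (bits); every column draws its
residues i.i.d. from a distribution with one dominant base whose weight
is solved so the distribution's Shannon entropy equals the target.
Sorting the loci by empirical median entropy therefore recovers the
prescribed gradient, which is what the sliding-window machinery is
tested against.

Sequences are generated gap-free and equal-length per locus (pre-aligned
input), so the native pass-through aligner registers them directly.  No
tree-based substitution model is used: the statistics path needs an
entropy gradient, not phylogenetic realism.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from .core import Locus, Project, SequenceRecord, Tree, create_project
from .stages import StageConf, align

__all__ = ["synth_dataset", "synth_trees", "dominant_weight_for_entropy"]

_BASES = np.array(list("ACGT"))


def dominant_weight_for_entropy(target_bits: float) -> float:
    """Weight of the dominant base giving a 4-state distribution the target entropy.

    The distribution is (p, q, q, q) with q = (1-p)/3; entropy decreases
    monotonically from 2 bits at p = 1/4 to 0 at p = 1, so the weight is
    unique.  Targets outside [0, 2] are infeasible for DNA.
    """
    if not 0 <= target_bits <= 2:
        raise ValueError(f"entropy target {target_bits} outside feasible [0, 2] bits for DNA")
    if target_bits >= 2:
        return 0.25
    if target_bits <= 0:
        return 1.0

    def h(p: float) -> float:
        q = (1 - p) / 3
        return -(p * math.log2(p) + 3 * q * math.log2(q)) - target_bits

    return brentq(h, 0.25 + 1e-12, 1 - 1e-12)


def synth_dataset(
    n_loci: int = 465,
    n_taxa: int = 26,
    locus_length: int = 500,
    entropy_targets: list[float] | None = None,
    occupancy: float = 1.0,
    seed: int = 0,
    title: str = "synthetic multilocus dataset",
) -> Project:
    """Generate a project with aligned synthetic loci along an entropy gradient.

    ``entropy_targets`` gives one target (bits) per locus in generation
    order; the default is a linear gradient from 1.9 down to 0.1, so
    generation order equals descending-entropy order.  ``occupancy`` is
    the probability that a given taxon has data for a given locus (1.0 =
    complete matrix; with partial occupancy every locus keeps at least
    one taxon).  Deterministic under the seed.
    """
    if n_loci < 1 or n_taxa < 1 or locus_length < 1:
        raise ValueError("n_loci, n_taxa and locus_length must be positive")
    if not 0 < occupancy <= 1:
        raise ValueError("occupancy must be in (0, 1]")
    if entropy_targets is None:
        entropy_targets = list(np.linspace(1.9, 0.1, n_loci))
    if len(entropy_targets) != n_loci:
        raise ValueError(f"need {n_loci} entropy targets, got {len(entropy_targets)}")

    rng = np.random.default_rng(seed)
    taxa = [f"Taxon_{i + 1:03d}" for i in range(n_taxa)]
    loci = [
        Locus(name=f"locus_{i:04d}", feature_type="CDS", char_type="dna")
        for i in range(n_loci)
    ]
    project = create_project(loci, title=title)

    for i, (locus, target) in enumerate(zip(loci, entropy_targets)):
        p = dominant_weight_for_entropy(target)
        weights = np.full((locus_length, 4), (1 - p) / 3)
        dominant = rng.integers(0, 4, size=locus_length)
        weights[np.arange(locus_length), dominant] = p
        # one multinomial draw per column per taxon
        cumulative = np.cumsum(weights, axis=1)
        u = rng.random((n_taxa, locus_length, 1))
        picks = np.clip((u > cumulative[None, :, :]).sum(axis=2), 0, 3)
        matrix = _BASES[picks]

        if occupancy < 1.0:
            present = rng.random(n_taxa) < occupancy
            if not present.any():
                present[rng.integers(0, n_taxa)] = True
        else:
            present = np.ones(n_taxa, dtype=bool)

        for t, taxon in enumerate(taxa):
            if not present[t]:
                continue
            serial = project.next_record_serial()
            project.add_record(
                SequenceRecord(
                    record_id=f"{locus.name}_{taxon}_f{serial}",
                    locus_name=locus.name,
                    otu=taxon,
                    sequence="".join(matrix[t]),
                    metadata={"organism": taxon, "entropy_target": f"{target:.6f}",
                              "generation_rank": str(i)},
                )
            )

    project.log(
        "synth_dataset",
        {"n_loci": n_loci, "n_taxa": n_taxa, "locus_length": locus_length,
         "occupancy": occupancy, "seed": seed},
    )
    align(project, StageConf(stage="align", method="native"))
    return project


# -- random trees -----------------------------------------------------------


class _Node:
    __slots__ = ("name", "children", "length")

    def __init__(self, name=None, children=None, length=0.1):
        self.name = name
        self.children = children or []
        self.length = length

    def copy(self) -> "_Node":
        return _Node(self.name, [c.copy() for c in self.children], self.length)

    def newick(self, top: bool = True) -> str:
        if not self.children:
            body = self.name
        else:
            body = "(" + ",".join(c.newick(top=False) for c in self.children) + ")"
        if top:
            return body + ";"
        return f"{body}:{self.length:.6f}"


def _random_tree(taxa: list[str], rng: np.random.Generator) -> _Node:
    nodes = [_Node(name=t, length=float(rng.exponential(0.1)) + 0.01) for t in taxa]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = _Node(
            children=[nodes[i], nodes[j]],
            length=float(rng.exponential(0.1)) + 0.01,
        )
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return _Node(children=nodes)


def _nni(root: _Node, rng: np.random.Generator) -> None:
    """One random nearest-neighbor interchange, in place."""
    parents: list[tuple[_Node, _Node]] = []

    def walk(node):
        for child in node.children:
            if child.children:
                parents.append((node, child))
            walk(child)

    walk(root)
    if not parents:
        return
    parent, child = parents[rng.integers(0, len(parents))]
    siblings = [c for c in parent.children if c is not child]
    if not siblings:
        return
    sibling = siblings[rng.integers(0, len(siblings))]
    grandchild = child.children[rng.integers(0, len(child.children))]
    parent.children[parent.children.index(sibling)] = grandchild
    child.children[child.children.index(grandchild)] = sibling


def synth_trees(
    n_taxa: int = 8,
    n_trees: int = 6,
    divergence: int = 0,
    seed: int = 0,
) -> list[Tree]:
    """Random binary trees on a shared leaf set.

    ``divergence`` is the number of random NNI rearrangements applied to
    the base topology for each subsequent tree: 0 yields identical
    copies; large values approach independent random topologies, letting
    the Robinson–Foulds distance reach its 2(n-3) ceiling.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(seed)
    taxa = [f"Taxon_{i + 1:03d}" for i in range(n_taxa)]
    base = _random_tree(taxa, rng)
    trees = []
    for k in range(n_trees):
        node = base.copy()
        if k > 0:
            for _ in range(divergence):
                _nni(node, rng)
        trees.append(
            Tree(
                object_id=f"synth_tree_{k}",
                newick=node.newick(),
                leaf_map={t: t for t in taxa},
                produced_by="synth_trees",
            )
        )
    return trees
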