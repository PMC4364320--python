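"""Distance-based phylogenetics: p-distances, neighbor-joining, clades.

The family's evolutionary structure is summarised with a classical
distance-based reconstruction: pairwise global alignments give p-distances
(proportion of differing sites among compared, non-gap columns - pairwise
deletion), and a neighbor-joining (NJ) tree is built from the distance
matrix.  NJ is exact on additive matrices: when the distances derive from
a tree, it returns that tree, topology and branch lengths both - which is
also how the implementation is tested.

Determinism: ties in the Q-criterion are broken on the lexicographically
smallest pair of subtree labels, and negative branch-length estimates are
clamped to zero with the deficit moved to the sibling branch.  Note that
p-distances need not satisfy the triangle inequality; NJ does not require
it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import make_aligner
from .errors import InputError, ValidationError


# --------------------------------------------------------------------------
# distance matrices


@dataclass
class DistanceMatrix:
    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match taxa")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("distance matrix has non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if np.any(self.values < -1e-12):
            raise ValidationError("distance matrix has negative entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)


def pdistance_matrix(
    sequences: dict[str, str], aligner=None
) -> DistanceMatrix:
    """p-distance matrix from pairwise global alignments.

    For each pair, gap columns are excluded (pairwise deletion) and the
    distance is mismatches / compared columns, in [0, 1].
    """
    taxa = tuple(sorted(sequences))
    if len(taxa) < 3:
        raise InputError("need at least 3 sequences for a distance matrix")
    if aligner is None:
        aligner = make_aligner()
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sequences[taxa[i]].upper(), sequences[taxa[j]].upper()
            if a == b:
                continue
            alignment = aligner.align(a, b)[0]
            compared = matches = 0
            for (a0, a1), (b0, b1) in zip(*alignment.aligned):
                compared += a1 - a0
                matches += sum(
                    x == y for x, y in zip(a[a0:a1], b[b0:b1])
                )
            if compared == 0:
                raise ValidationError(
                    f"no comparable columns between {taxa[i]} and {taxa[j]}"
                )
            d[i, j] = d[j, i] = (compared - matches) / compared
    return DistanceMatrix(taxa=taxa, values=d)


# --------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    name: str | None = None
    #: (child, branch length) pairs; empty for leaves.
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def _sort_key(self) -> str:
        return self.name if self.is_leaf else min(
            child._sort_key() for child, _ in self.children
        )

    def newick(self, decimals: int = 6) -> str:
        return self._newick(decimals) + ";"

    def _newick(self, decimals: int) -> str:
        if self.is_leaf:
            return self.name
        parts = [
            f"{child._newick(decimals)}:{length:.{decimals}f}"
            for child, length in sorted(
                self.children, key=lambda cl: cl[0]._sort_key()
            )
        ]
        return "(" + ",".join(parts) + ")"

    def total_length(self) -> float:
        return sum(
            length + child.total_length() for child, length in self.children
        )

    def bipartitions(self) -> set[frozenset]:
        """Leaf sets under every edge (trivial leaf edges included)."""
        out: set[frozenset] = set()

        def walk(node: TreeNode):
            for child, _ in node.children:
                out.add(frozenset(child.leaves()))
                walk(child)

        walk(self)
        return out

    def nontrivial_bipartitions(self) -> set[frozenset]:
        """Internal-edge splits, canonicalised to the smaller side."""
        leaves = frozenset(self.leaves())
        out = set()
        for side in self.bipartitions():
            if 1 < len(side) < len(leaves) - 1:
                other = leaves - side
                out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out


# --------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Classical neighbor-joining with deterministic tie-breaking.

    Pair selection minimises Q(i, j) = (n-2) d(i,j) - r_i - r_j; ties are
    broken on the lexicographically smallest (label_i, label_j) pair, where
    a subtree's label is its smallest leaf name.  Branch lengths follow the
    standard formulas; negative estimates are clamped to zero with the
    deficit moved to the sibling so the pair's summed length is preserved.
    On an additive matrix the generating tree is recovered exactly.
    """
    n = len(matrix.taxa)
    if n < 3:
        raise InputError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in matrix.taxa]
    labels: list[str] = list(matrix.taxa)
    d = matrix.values.astype(float).copy()
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for i, j in itertools.combinations(active, 2):
            q = (m - 2) * d[i, j] - r[i] - r[j]
            a, b = sorted((labels[i], labels[j]))
            key = (q, a, b)
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # replace i with the parent, drop j
        new_d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0]
        for k in active:
            if k in (i, j):
                continue
            new_d[u, k] = new_d[k, u] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = new_d
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = TreeNode(
        children=[
            (nodes[i], max(li, 0.0)),
            (nodes[j], max(lj, 0.0)),
            (nodes[k], max(lk, 0.0)),
        ]
    )
    return root


def check_monophyly(
    tree: TreeNode, label_map: dict[str, str]
) -> dict[str, bool]:
    """Whether each label's leaves form a clade of the unrooted tree.

    A label is monophyletic iff some edge bipartition separates exactly its
    leaves from the rest; singletons are trivially monophyletic.
    """
    leaves = tree.leaves()
    unlabeled = sorted(set(leaves) - set(label_map))
    if unlabeled:
        raise InputError(f"unlabeled leaf/leaves: {', '.join(unlabeled)}")
    all_leaves = frozenset(leaves)
    splits = tree.bipartitions()
    sides = splits | {all_leaves - s for s in splits}
    result = {}
    for label in sorted(set(label_map[l] for l in leaves)):
        group = frozenset(l for l in leaves if label_map[l] == label)
        result[label] = len(group) == 1 or group in sides
    return result
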