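"""Poisson-corrected amino-acid distances, neighbor joining and bootstrap.

The Poisson model corrects the observed proportion ``p`` of differing sites
for multiple substitutions: ``d = -ln(1 - p)`` substitutions per site, with
pairwise deletion of gapped columns.  Trees are built by classical
neighbor joining (exact on additive matrices) with deterministic
tie-breaking, and edge supports come from column-resampling bootstrap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

GAP_CHARS = {"-", ".", " "}


class UndefinedDistanceError(ValueError):
    """p >= 1: the Poisson correction is undefined."""


def poisson_distance(aligned_a: str, aligned_b: str) -> float:
    """Poisson-corrected distance between two aligned amino-acid strings.

    Columns where either sequence is gapped are removed (pairwise deletion).
    Raises ``ValueError`` when no comparable sites remain and
    :class:`UndefinedDistanceError` when all comparable sites differ.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    compared = diffs = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        compared += 1
        if x != y:
            diffs += 1
    if compared == 0:
        raise ValueError("no comparable (ungapped) sites")
    p = diffs / compared
    if p >= 1.0:
        raise UndefinedDistanceError("all comparable sites differ (p >= 1)")
    return -math.log(1.0 - p)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of Poisson distances (substitutions per site)."""

    ids: list[str]
    values: np.ndarray

    @classmethod
    def from_alignment(cls, alignment: dict[str, str]) -> "DistanceMatrix":
        ids = list(alignment)
        n = len(ids)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = poisson_distance(alignment[ids[i]], alignment[ids[j]])
        return cls(ids=ids, values=m)

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for name, row in zip(self.ids, self.values):
                fh.write(name[:10].ljust(12) + " ".join(f"{v:.6f}" for v in row) + "\n")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class TreeNode:
    """A node of an unrooted tree stored with an arbitrary internal root."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> set[str]:
        return {l.name for l in self.leaves()}

    def newick(self, with_support: bool = False) -> str:
        def fmt(node: TreeNode) -> str:
            if not node.children:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits in canonical form (the smaller side of each
        internal edge; ties by sorted names), so splits compare across trees
        regardless of where each tree is rooted."""
        all_leaves = self.leaf_names()
        out = set()

        def walk(node: TreeNode):
            for c in node.children:
                names = frozenset(c.leaf_names())
                if 1 < len(names) < len(all_leaves) - 1:
                    comp = frozenset(all_leaves - names)
                    out.add(min(names, comp, key=lambda s: (len(s), sorted(s))))
                walk(c)

        walk(self)
        return out

    def _internal_nodes(self):
        def walk(node):
            for c in node.children:
                if c.children:
                    yield c
                    yield from walk(c)

        yield from walk(self)


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix.

    Ties in the Q criterion are broken by taxon-id order, so the topology is
    deterministic.  Negative branch lengths are clamped to zero with a
    warning.  The returned tree is rooted arbitrarily at the final
    three-way junction (topologically unrooted).
    """
    n = len(matrix.ids)
    if n < 2:
        raise ValueError("need at least two taxa")
    if not np.all(np.isfinite(matrix.values)):
        raise ValueError("distance matrix contains undefined distances")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=name) for i, name in enumerate(matrix.ids)
    }
    D = {
        (i, j): float(matrix.values[i, j])
        for i in range(n)
        for j in range(n)
        if i != j
    }
    active = list(range(n))
    next_id = n
    clamped = False
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[(i, j)] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * D[(i, j)] - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        li = 0.5 * D[(i, j)] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[(i, j)] - li
        if li < 0 or lj < 0:
            clamped = True
        node = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        for k in active:
            if k in (i, j):
                continue
            D[(next_id, k)] = D[(k, next_id)] = 0.5 * (
                D[(i, k)] + D[(j, k)] - D[(i, j)]
            )
        nodes[next_id] = node
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    root = TreeNode()
    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (D[(i, j)] + D[(i, k)] - D[(j, k)])
        lj = 0.5 * (D[(i, j)] + D[(j, k)] - D[(i, k)])
        lk = 0.5 * (D[(i, k)] + D[(j, k)] - D[(i, j)])
        for idx, ln in zip((i, j, k), (li, lj, lk)):
            if ln < 0:
                clamped = True
            nodes[idx].length = max(ln, 0.0)
            root.children.append(nodes[idx])
    else:  # two remaining nodes
        i, j = active
        nodes[i].length = nodes[j].length = max(D[(i, j)], 0.0) / 2
        root.children = [nodes[i], nodes[j]]
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to zero")
    return root


def bootstrap_support(
    alignment: dict[str, str], n_reps: int = 500, seed: int = 0
) -> TreeNode:
    """NJ tree with bootstrap supports from column resampling.

    Supports are the percentage of replicate trees (columns resampled with
    replacement, distances and NJ recomputed) containing each bipartition of
    the tree built on the original alignment.
    """
    names = list(alignment)
    if len(names) < 3:
        raise ValueError("need at least three taxa for bootstrap supports")
    L = len(next(iter(alignment.values())))
    if any(len(s) != L for s in alignment.values()):
        raise ValueError("alignment rows must have equal length")
    arr = np.array([list(s) for s in alignment.values()])
    tree = nj_tree(DistanceMatrix.from_alignment(alignment))
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, L, L)
        rep = {name: "".join(arr[i, cols]) for i, name in enumerate(names)}
        try:
            rep_tree = nj_tree(DistanceMatrix.from_alignment(rep))
        except (ValueError, UndefinedDistanceError):
            continue
        rep_bps = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    all_leaves = tree.leaf_names()

    def annotate(node: TreeNode):
        for c in node.children:
            names_c = frozenset(c.leaf_names())
            if c.children and 1 < len(names_c) < len(all_leaves) - 1:
                comp = frozenset(all_leaves - names_c)
                key = min(names_c, comp, key=lambda s: (len(s), sorted(s)))
                c.support = 100.0 * counts.get(key, 0) / n_reps
            annotate(c)

    annotate(tree)
    return tree
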