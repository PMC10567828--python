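"""Identity distances and neighbour-joining trees for screened sequences.

Sequences are compared on their match-state alignment (equal-length
strings over A/C/G/T/-): the p-distance is the fraction of mismatching
columns among those where both sequences carry a residue.  Trees are
built by classical neighbour joining (Q-matrix agglomeration with
Studier-Keppler branch lengths), which is exact on additive matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import InvalidInputError, UndefinedPairError

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with taxon ids."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise InvalidInputError("matrix shape must match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise InvalidInputError("matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise InvalidInputError("diagonal must be zero")


@dataclass
class PhyloTree:
    """Unrooted tree as an undirected adjacency with branch lengths."""

    leaves: list[str]
    adjacency: dict = field(default_factory=dict)  # node -> {neighbour: length}
    newick: str = ""

    def path_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths along the unique a-b path."""
        if a == b:
            return 0.0
        stack = [(a, None, 0.0)]
        while stack:
            node, prev, dist = stack.pop()
            for nb, length in self.adjacency[node].items():
                if nb == prev:
                    continue
                if nb == b:
                    return dist + length
                stack.append((nb, node, dist + length))
        raise InvalidInputError(f"no path between {a!r} and {b!r}")


def pairwise_distances(aligned: Mapping[str, str]) -> DistanceMatrix:
    """p-distances between match-state-aligned sequences.

    Gap-gap and residue-gap columns are excluded; a pair with no
    comparable column raises :class:`UndefinedPairError`.
    """
    ids = list(aligned)
    if not ids:
        raise InvalidInputError("no sequences")
    width = len(aligned[ids[0]])
    for name in ids:
        if len(aligned[name]) != width:
            raise InvalidInputError(f"sequence {name!r} has mismatched length")
    mat = np.array([list(aligned[name].upper()) for name in ids])
    residue = mat != "-"
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = residue[i] & residue[j]
            comparable = int(both.sum())
            if comparable == 0:
                raise UndefinedPairError(
                    f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
                )
            mismatch = int((mat[i, both] != mat[j, both]).sum())
            d[i, j] = d[j, i] = mismatch / comparable
    return DistanceMatrix(ids=ids, d=d)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbour-joining tree from a distance matrix.

    Q-matrix pair selection with ties broken on the lexicographically
    smallest id pair; Studier-Keppler branch lengths with negatives
    clamped to zero (logged).  Exact on additive matrices.
    """
    n = len(dm.ids)
    if n < 3:
        raise InvalidInputError(f"neighbour joining needs >= 3 taxa, got {n}")
    labels = list(dm.ids)
    # sort keys for deterministic tie-breaks on internal nodes too
    dist = {a: {} for a in labels}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                dist[a][b] = float(dm.d[i, j])
    adjacency: dict[str, dict[str, float]] = {a: {} for a in labels}
    next_internal = 0

    def clamp(x: float, edge: str) -> float:
        if x < 0:
            logger.info("nj: clamping negative branch length %.4g on %s", x, edge)
            return 0.0
        return x

    active = list(labels)
    while len(active) > 2:
        r = len(active)
        rowsum = {a: sum(dist[a][b] for b in active if b != a) for a in active}
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                a, b = active[i], active[j]
                q = (r - 2) * dist[a][b] - rowsum[a] - rowsum[b]
                key = (q, *sorted((a, b)))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = dist[a][b]
        va = dab / 2.0 + (rowsum[a] - rowsum[b]) / (2.0 * (r - 2))
        vb = dab - va
        u = f"_nj{next_internal}"
        next_internal += 1
        adjacency[u] = {}
        adjacency[u][a] = adjacency.setdefault(a, {})[u] = clamp(va, f"{a}-{u}")
        adjacency[u][b] = adjacency.setdefault(b, {})[u] = clamp(vb, f"{b}-{u}")
        dist[u] = {}
        for c in active:
            if c in (a, b):
                continue
            duc = (dist[a][c] + dist[b][c] - dab) / 2.0
            dist[u][c] = dist[c][u] = duc
        active = [c for c in active if c not in (a, b)] + [u]
    a, b = active
    adjacency[a][b] = adjacency[b][a] = clamp(dist[a][b], f"{a}-{b}")

    tree = PhyloTree(leaves=list(dm.ids), adjacency=adjacency)
    tree.newick = _to_newick(tree)
    return tree


def _to_newick(tree: PhyloTree) -> str:
    """Serialise rooted at the last internal node (or first leaf)."""
    internals = [n for n in tree.adjacency if n.startswith("_nj")]
    root = internals[-1] if internals else tree.leaves[0]

    def render(node: str, prev: str | None) -> str:
        children = [nb for nb in tree.adjacency[node] if nb != prev]
        if not children:
            return node
        parts = [f"{render(nb, node)}:{tree.adjacency[node][nb]:.6g}" for nb in children]
        label = "" if node.startswith("_nj") else node
        return f"({','.join(parts)}){label}"

    return render(root, None) + ";"
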