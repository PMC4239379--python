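"""Distance-based phylogeny: neighbor joining, bootstrap, clade extraction.

Trees are unrooted and kept as an undirected adjacency map. Neighbor
joining follows the Saitou-Nei agglomeration with two determinism
guarantees: Q-matrix ties are broken by the smallest (row, column) index
pair, and negative branch-length estimates are clamped to zero (the
original value is logged). Bootstrap supports are bipartition frequencies
over column-resampled replicates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger("xylptools")

GAP_CHARS = frozenset("-.")

Alignment = Sequence[tuple[str, str]]


@dataclass(frozen=True)
class DistanceMatrix:
    """A symmetric pairwise distance matrix over named taxa."""

    ids: tuple[str, ...]
    values: np.ndarray
    model: str = "p-distance"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match taxon count")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.ids)


class PhyloTree:
    """An unrooted tree with branch lengths and optional bootstrap supports.

    ``adjacency`` maps each node to ``{neighbor: branch length}``. Leaves
    are taxon labels; internal nodes carry synthetic labels. ``supports``
    maps canonical bipartitions (see :meth:`bipartitions`) to fractions in
    [0, 1].
    """

    def __init__(self, adjacency: Mapping[str, Mapping[str, float]],
                 supports: Optional[dict[frozenset, float]] = None) -> None:
        self.adjacency = {u: dict(nbrs) for u, nbrs in adjacency.items()}
        self.supports = supports
        self._validate()

    def _validate(self) -> None:
        for u, nbrs in self.adjacency.items():
            for v, w in nbrs.items():
                if self.adjacency.get(v, {}).get(u) != w:
                    raise ValueError(f"asymmetric adjacency at edge {u}-{v}")
                if w < 0:
                    raise ValueError(f"negative branch length on edge {u}-{v}")
        # connected & acyclic
        nodes = list(self.adjacency)
        seen = {nodes[0]}
        stack = [(nodes[0], None)]
        edges = 0
        while stack:
            u, parent = stack.pop()
            for v in self.adjacency[u]:
                if v == parent:
                    continue
                edges += 1
                if v in seen:
                    raise ValueError("tree contains a cycle")
                seen.add(v)
                stack.append((v, u))
        if len(seen) != len(nodes):
            raise ValueError("tree is not connected")

    def leaves(self) -> list[str]:
        return sorted(u for u, nbrs in self.adjacency.items() if len(nbrs) == 1)

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for u, nbrs in self.adjacency.items():
            for v, w in nbrs.items():
                if u < v:
                    out.append((u, v, w))
        return sorted(out)

    def _side_leaves(self, u: str, v: str) -> frozenset:
        """Leaves on the v-side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        leaves = set()
        while stack:
            x = stack.pop()
            nbrs = [y for y in self.adjacency[x] if y not in seen]
            if len(self.adjacency[x]) == 1:
                leaves.add(x)
            for y in nbrs:
                seen.add(y)
                stack.append(y)
        return frozenset(leaves)

    def bipartitions(self) -> dict[frozenset, tuple[str, str]]:
        """Canonical internal-edge bipartitions.

        Each internal edge splits the leaf set in two; the canonical key is
        the side that does not contain the lexicographically smallest leaf.
        Only non-trivial bipartitions (both sides >= 2 leaves) are returned.
        """
        all_leaves = set(self.leaves())
        if not all_leaves:
            return {}
        anchor = min(all_leaves)
        out: dict[frozenset, tuple[str, str]] = {}
        for u, v, _w in self.edges():
            side = self._side_leaves(u, v)
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue
            key = side if anchor not in side else frozenset(all_leaves - side)
            out[key] = (u, v)
        return out

    def path_edges(self, a: str, b: str) -> list[frozenset]:
        """Edges on the unique path between two nodes."""
        parent: dict[str, Optional[str]] = {a: None}
        stack = [a]
        while stack:
            u = stack.pop()
            if u == b:
                break
            for v in self.adjacency[u]:
                if v not in parent:
                    parent[v] = u
                    stack.append(v)
        if b not in parent:
            raise KeyError(f"no path between {a!r} and {b!r}")
        edges = []
        node = b
        while parent[node] is not None:
            edges.append(frozenset({node, parent[node]}))
            node = parent[node]
        return edges

    def to_newick(self, include_supports: bool = True) -> str:
        """Serialize as Newick, writing supports as internal-node labels."""
        internals = [u for u, nbrs in self.adjacency.items() if len(nbrs) > 1]
        root = min(internals) if internals else min(self.adjacency)
        bips = self.bipartitions() if (self.supports and include_supports) else {}
        edge_support: dict[frozenset, float] = {}
        for key, (u, v) in bips.items():
            if key in (self.supports or {}):
                edge_support[frozenset({u, v})] = self.supports[key]

        def render(u: str, parent: Optional[str]) -> str:
            children = [v for v in self.adjacency[u] if v != parent]
            if not children:
                return u
            inner = ",".join(
                f"{render(v, u)}:{self.adjacency[u][v]:.6g}" for v in children
            )
            label = ""
            if parent is not None:
                sup = edge_support.get(frozenset({u, parent}))
                if sup is not None:
                    label = f"{sup:.6g}"
            return f"({inner}){label}"

        return render(root, None) + ";"


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def pairwise_distances(alignment: Alignment, model: str = "p-distance") -> DistanceMatrix:
    """Pairwise distances from an alignment with pairwise gap deletion.

    ``p-distance`` is mismatches over compared sites after dropping any
    position where either sequence has a gap; ``kimura-protein`` applies
    Kimura's correction d = -ln(1 - p - 0.2 p^2).
    """
    if model not in {"p-distance", "kimura-protein"}:
        raise ValueError(f"unknown distance model {model!r}")
    ids = tuple(name for name, _ in alignment)
    seqs = [seq for _, seq in alignment]
    if len(ids) < 3:
        raise ValueError("need at least 3 taxa")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("aligned sequences must all have the same length")
    arr = np.array([list(s) for s in seqs])
    is_gap = np.isin(arr, list(GAP_CHARS))
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = ~(is_gap[i] | is_gap[j])
            compared = int(usable.sum())
            if compared == 0:
                raise ValueError(
                    f"sequences {ids[i]!r} and {ids[j]!r} share no comparable sites"
                )
            mismatches = int((arr[i, usable] != arr[j, usable]).sum())
            p = mismatches / compared
            if model == "kimura-protein":
                arg = 1.0 - p - 0.2 * p * p
                if arg <= 0:
                    raise ValueError(
                        f"p-distance {p:.3f} between {ids[i]!r} and {ids[j]!r} "
                        "too large for the Kimura protein correction"
                    )
                p = -float(np.log(arg))
            d[i, j] = d[j, i] = p
    return DistanceMatrix(ids, d, model)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.info("clamping negative branch length %.6g to 0 (%s)", length, context)
        return 0.0
    return length


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining, deterministic for a given matrix."""
    m = len(dm)
    if m < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    labels = list(dm.ids)
    D = dm.values.copy()
    adjacency: dict[str, dict[str, float]] = {lab: {} for lab in labels}
    counter = 0

    def connect(u: str, v: str, w: float) -> None:
        adjacency.setdefault(u, {})[v] = w
        adjacency.setdefault(v, {})[u] = w

    while len(labels) > 3:
        k = len(labels)
        r = D.sum(axis=1)
        # Q[i, j] = (k - 2) d_ij - r_i - r_j ; pick min, ties by (i, j) order
        best = None
        best_q = np.inf
        for i in range(k):
            for j in range(i + 1, k):
                q = (k - 2) * D[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = D[i, j] - li
        new_label = f"_nj{counter}"
        counter += 1
        connect(labels[i], new_label, _clamp(li, f"{labels[i]} -> {new_label}"))
        connect(labels[j], new_label, _clamp(lj, f"{labels[j]} -> {new_label}"))
        rest = [x for x in range(k) if x not in (i, j)]
        new_row = np.array([0.5 * (D[i, x] + D[j, x] - D[i, j]) for x in rest])
        D = np.vstack([
            np.hstack([D[np.ix_(rest, rest)], new_row[:, None]]),
            np.hstack([new_row, [0.0]]),
        ])
        labels = [labels[x] for x in rest] + [new_label]

    # final three-way join around a central node (closed form)
    a, b, c = labels
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    center = f"_nj{counter}"
    connect(a, center, _clamp(la, f"{a} -> {center}"))
    connect(b, center, _clamp(lb, f"{b} -> {center}"))
    connect(c, center, _clamp(lc, f"{c} -> {center}"))
    return PhyloTree(adjacency)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_supports(alignment: Alignment, model: str = "p-distance",
                       replicates: int = 1000, seed: int = 0) -> PhyloTree:
    """Attach bootstrap supports to the NJ tree of the full alignment.

    Alignment columns are resampled with replacement; the support of each
    internal edge of the original tree is the fraction of replicate trees
    containing the same bipartition. With fewer than four taxa there are no
    internal edges and supports are empty.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tree = neighbor_joining(pairwise_distances(alignment, model))
    original = tree.bipartitions()
    if not original:
        tree.supports = {}
        return tree
    rng = np.random.default_rng(seed)
    length = len(alignment[0][1])
    names = [name for name, _ in alignment]
    seqs = np.array([list(seq) for _, seq in alignment])
    hits = {key: 0 for key in original}
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        resampled = ["".join(row) for row in seqs[:, cols]]
        rep_tree = neighbor_joining(
            pairwise_distances(list(zip(names, resampled)), model))
        rep_bips = rep_tree.bipartitions()
        for key in hits:
            if key in rep_bips:
                hits[key] += 1
    tree.supports = {key: count / replicates for key, count in hits.items()}
    return tree


# ---------------------------------------------------------------------------
# clades
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CladeAssignment:
    """Leaf-to-clade mapping induced by user-supplied anchor leaves."""

    assignments: Mapping[str, str]
    anchors: Mapping[str, str]  # clade label -> anchor leaf

    def members(self, clade: str) -> list[str]:
        return sorted(l for l, c in self.assignments.items() if c == clade)


def assign_clades(tree: PhyloTree, anchors: Mapping[str, str]) -> CladeAssignment:
    """Partition leaves into clades around anchor leaves.

    The separating edges are the edges on the paths between anchor pairs
    (the anchor Steiner tree). Each leaf joins the clade of the anchor whose
    path from the leaf crosses the fewest separating edges; a leaf tied
    between anchors is left unassigned.
    """
    leaves = set(tree.leaves())
    for clade, leaf in anchors.items():
        if leaf not in leaves:
            raise KeyError(f"anchor leaf {leaf!r} for clade {clade!r} not in tree")
    anchor_items = sorted(anchors.items())
    separating: set[frozenset] = set()
    for idx, (_, a) in enumerate(anchor_items):
        for _, b in anchor_items[idx + 1:]:
            separating.update(tree.path_edges(a, b))
    assignments: dict[str, str] = {}
    for leaf in leaves:
        best_clade = None
        best_count = None
        tied = False
        for clade, anchor in anchor_items:
            count = sum(1 for e in tree.path_edges(leaf, anchor) if e in separating)
            if best_count is None or count < best_count:
                best_clade, best_count, tied = clade, count, False
            elif count == best_count:
                tied = True
        assignments[leaf] = "unassigned" if tied else best_clade
    return CladeAssignment(assignments, dict(anchors))
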