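"""Independent oracles used by the test suite.

Everything here is deliberately naive (regular expressions, exhaustive
enumeration, brute-force least squares) and shares no code with the
implementations it checks.
"""
from __future__ import annotations

import itertools
import re
from collections import defaultdict

import numpy as np


# ---------------------------------------------------------------------------
# eight-cysteine motif via regular expression
# ---------------------------------------------------------------------------

def cys_pattern_regex(spec, allow_internal_cys: bool = False) -> re.Pattern:
    """Build a regex equivalent of a gap-constrained cysteine template."""
    unit = "." if allow_internal_cys else "[^C]"

    def gap(gap_set) -> str:
        alts = "|".join(f"{unit}{{{g}}}" for g in sorted(gap_set))
        return f"(?:{alts})"

    hyd = "".join(sorted(spec.hydrophobic_set))
    pattern = (
        "C" + gap(spec.gap_sets[0]) +
        "C" + gap(spec.gap_sets[1]) +
        "CC" + gap(spec.gap_sets[2]) +
        "C" + f"[{hyd}]" +
        "C" + gap(spec.gap_sets[3]) +
        "C" + gap(spec.gap_sets[4]) +
        "C"
    )
    return re.compile(pattern, re.DOTALL)


def regex_motif_start(sequence: str, spec, allow_internal_cys: bool = False):
    """1-based leftmost match start per the regex oracle, or None."""
    m = cys_pattern_regex(spec, allow_internal_cys).search(sequence)
    return m.start() + 1 if m else None


# ---------------------------------------------------------------------------
# PAST windows, exhaustively
# ---------------------------------------------------------------------------

def past_regions_bruteforce(sequence: str, window: int, threshold: float):
    """Enumerate every window; return (start, end, score) regions, 1-based."""
    n = len(sequence)
    w = min(window, n)
    covered = [False] * n
    for start in range(n - w + 1):
        chunk = sequence[start:start + w]
        frac = sum(c in "PAST" for c in chunk) / w
        if frac > threshold:
            for k in range(start, start + w):
                covered[k] = True
    regions = []
    i = 0
    while i < n:
        if covered[i]:
            j = i
            while j + 1 < n and covered[j + 1]:
                j += 1
            seg = sequence[i:j + 1]
            score = sum(c in "PAST" for c in seg) / len(seg)
            regions.append((i + 1, j + 1, score))
            i = j + 1
        else:
            i += 1
    return regions


# ---------------------------------------------------------------------------
# glycomodule scan, exhaustively
# ---------------------------------------------------------------------------

def glycomodules_bruteforce(sequence: str, dipeptides) -> list[tuple[int, str]]:
    """Leftmost non-overlapping dipeptide hits, 1-based."""
    hits = []
    i = 0
    while i < len(sequence) - 1:
        dp = sequence[i:i + 2]
        if dp in dipeptides:
            hits.append((i + 1, dp))
            i += 2
        else:
            i += 1
    return hits


# ---------------------------------------------------------------------------
# EST specificity, exhaustively
# ---------------------------------------------------------------------------

def est_specific_bruteforce(counts: dict[str, int]):
    """Return the specific tissue (count > half of total) or None."""
    total = sum(counts.values())
    for tissue, value in counts.items():
        if total > 0 and value > total / 2:
            return tissue
    return None


# ---------------------------------------------------------------------------
# tandem rule, exhaustively
# ---------------------------------------------------------------------------

def tandem_pairs_bruteforce(family, loci, max_intervening):
    """All tandem family pairs by re-deriving ranks from coordinates."""
    per_chrom = defaultdict(list)
    for g in loci:
        per_chrom[g.chromosome].append(g)
    order = {}
    for chrom, genes in per_chrom.items():
        for rank, g in enumerate(sorted(genes, key=lambda x: x.start)):
            order[g.gene_id] = (chrom, rank)
    pairs = set()
    for a, b in itertools.combinations(sorted(family), 2):
        ca, ra = order[a]
        cb, rb = order[b]
        if ca == cb and abs(ra - rb) - 1 <= max_intervening:
            pairs.add((a, b))
    return pairs


# ---------------------------------------------------------------------------
# tree enumeration and least-squares topology search
# ---------------------------------------------------------------------------

def enumerate_unrooted_topologies(taxa):
    """All unrooted binary topologies (edge sets) via leaf insertion."""
    taxa = list(taxa)
    trees = [({(t, "i0") for t in taxa[:3]}, 1)]
    for leaf in taxa[3:]:
        nxt = []
        for edges, ni in trees:
            for edge in sorted(edges):
                u, v = edge
                mid = f"i{ni}"
                ne = set(edges)
                ne.remove(edge)
                ne.update({(u, mid), (mid, v), (leaf, mid)})
                nxt.append((ne, ni + 1))
        trees = nxt
    return [t[0] for t in trees]


def _adjacency(edges):
    adj = defaultdict(set)
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def _path_edges(adj, a, b):
    parent = {a: None}
    stack = [a]
    while stack:
        x = stack.pop()
        for y in adj[x]:
            if y not in parent:
                parent[y] = x
                stack.append(y)
    path = []
    node = b
    while parent[node] is not None:
        path.append(frozenset({node, parent[node]}))
        node = parent[node]
    return path


def topology_bipartitions(edges, taxa):
    """Canonical non-trivial bipartitions of an edge-set topology."""
    adj = _adjacency(edges)
    taxa_set = set(taxa)
    anchor = min(taxa_set)
    bips = set()
    for u, v in edges:
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            x = stack.pop()
            if x in taxa_set:
                side.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 2 <= len(side) <= len(taxa_set) - 2:
            key = frozenset(side) if anchor not in side else frozenset(taxa_set - side)
            bips.add(key)
    return bips


def ls_residual(edges, taxa, D) -> float:
    """Ordinary-least-squares fit residual of distances to a topology."""
    adj = _adjacency(edges)
    edge_list = sorted(frozenset(e) for e in edges)
    index = {e: k for k, e in enumerate(edge_list)}
    rows, target = [], []
    for i, j in itertools.combinations(range(len(taxa)), 2):
        row = np.zeros(len(edge_list))
        for e in _path_edges(adj, taxa[i], taxa[j]):
            row[index[e]] = 1.0
        rows.append(row)
        target.append(D[i, j])
    A = np.asarray(rows)
    x, *_ = np.linalg.lstsq(A, np.asarray(target), rcond=None)
    resid = A @ x - np.asarray(target)
    return float(resid @ resid)


def best_ls_topology(taxa, D):
    """Bipartitions of the minimum-residual topology (exhaustive search)."""
    best, best_r = None, np.inf
    for edges in enumerate_unrooted_topologies(taxa):
        r = ls_residual(edges, taxa, D)
        if r < best_r - 1e-12:
            best_r, best = r, edges
    return topology_bipartitions(best, taxa)


def random_additive_tree(taxa, rng, noise_sd: float = 0.0):
    """A random topology with random branch lengths and its distance matrix."""
    topos = enumerate_unrooted_topologies(taxa)
    edges = topos[int(rng.integers(0, len(topos)))]
    lengths = {frozenset(e): float(rng.uniform(0.1, 1.0)) for e in edges}
    adj = _adjacency(edges)
    n = len(taxa)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        dist = sum(lengths[e] for e in _path_edges(adj, taxa[i], taxa[j]))
        D[i, j] = D[j, i] = dist
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, (n, n))
        D = np.abs(D + (noise + noise.T) / 2.0)
        np.fill_diagonal(D, 0.0)
    return topology_bipartitions(edges, taxa), D
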