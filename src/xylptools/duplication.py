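"""Tandem and segmental duplication calling for gene families.

Tandem duplicates are family genes on the same chromosome separated by no
more than a fixed number of intervening annotated genes (default 5,
boundary inclusive), counted over the whole annotation, not just family
members. Segmental duplicates are homolog pairs whose two genes fall on
the two regions of one duplicated chromosomal block, within a maximal
collinear-pair distance (default 500 kb).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from xylptools.io import FormatError, GeneLocus, rank_loci

DEFAULT_MAX_INTERVENING = 5
DEFAULT_MAX_PAIR_DISTANCE_KB = 500.0


@dataclass(frozen=True)
class HomologPair:
    """An unordered pair of family genes deemed homologous."""

    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self pair {self.gene_a!r}")
        if self.gene_b < self.gene_a:  # canonical order
            object.__setattr__(self, "gene_a", self.gene_b)
            object.__setattr__(self, "gene_b", self.gene_a)

    def __iter__(self):
        return iter((self.gene_a, self.gene_b))


@dataclass(frozen=True)
class DuplicationBlock:
    """A duplicated chromosomal block: two paired regions A and B."""

    block_id: str
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int

    def __post_init__(self) -> None:
        if self.start_a > self.end_a or self.start_b > self.end_b:
            raise FormatError(f"block {self.block_id!r} has malformed regions")
        if min(self.start_a, self.start_b) < 1:
            raise FormatError(f"block {self.block_id!r}: coordinates are 1-based")


@dataclass(frozen=True)
class DuplicationCall:
    """A tandem or segmental duplication verdict for a set of genes.

    Pair callers emit two-gene calls; a whole tandem array or a printed
    gene list may also be wrapped as a single multi-gene call.
    """

    genes: tuple[str, ...]
    kind: str  # tandem | segmental
    evidence: Mapping[str, object]

    def __post_init__(self) -> None:
        if self.kind not in {"tandem", "segmental"}:
            raise ValueError(f"unknown duplication kind {self.kind!r}")


@dataclass(frozen=True)
class DuplicationSummary:
    n_tandem_genes: int
    n_segmental_genes: int
    n_union: int
    pct_union: float


# ---------------------------------------------------------------------------
# tandem
# ---------------------------------------------------------------------------

def call_tandem(family_gene_ids: Iterable[str], all_loci: Sequence[GeneLocus],
                max_intervening: int = DEFAULT_MAX_INTERVENING) -> list[DuplicationCall]:
    """Call tandem duplications by the intervening-gene rule.

    For every pair of family genes on one chromosome, the number of
    intervening genes is |rank difference| - 1 over the full annotation; a
    pair is tandem iff that count is at most ``max_intervening`` (boundary
    inclusive). Strand is ignored: the rule is purely count-based.
    """
    if max_intervening < 0:
        raise ValueError("max_intervening must be >= 0")
    if any(g.rank < 0 for g in all_loci):
        all_loci = rank_loci(all_loci)
    by_id = {g.gene_id: g for g in all_loci}
    family = sorted(set(family_gene_ids))
    missing = [g for g in family if g not in by_id]
    if missing:
        raise KeyError(f"family genes missing from annotation: {', '.join(missing)}")
    calls: list[DuplicationCall] = []
    for i, ga in enumerate(family):
        for gb in family[i + 1:]:
            la, lb = by_id[ga], by_id[gb]
            if la.chromosome != lb.chromosome:
                continue
            intervening = abs(la.rank - lb.rank) - 1
            if intervening <= max_intervening:
                calls.append(DuplicationCall(
                    (ga, gb), "tandem",
                    {"chromosome": la.chromosome, "intervening": intervening},
                ))
    return calls


def tandem_arrays(calls: Iterable[DuplicationCall]) -> list[tuple[str, ...]]:
    """Chain tandem pair calls into arrays by transitive closure."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for call in calls:
        if call.kind != "tandem":
            continue
        a, b = call.genes
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, set[str]] = {}
    for gene in parent:
        groups.setdefault(find(gene), set()).add(gene)
    return sorted(tuple(sorted(members)) for members in groups.values())


# ---------------------------------------------------------------------------
# segmental
# ---------------------------------------------------------------------------

def _region_distance(midpoint: float, chrom: str, region_chrom: str,
                     start: int, end: int) -> float:
    """Distance in bp from a gene midpoint to a block region (0 if inside)."""
    if chrom != region_chrom:
        return float("inf")
    if start <= midpoint <= end:
        return 0.0
    return min(abs(midpoint - start), abs(midpoint - end))


def assign_segmental(family_loci: Sequence[GeneLocus],
                     pairs: Iterable[HomologPair | tuple[str, str]],
                     blocks: Sequence[DuplicationBlock],
                     max_pair_distance_kb: float = DEFAULT_MAX_PAIR_DISTANCE_KB,
                     anchors: Optional[Mapping[str, Sequence[tuple[int, int]]]] = None,
                     ) -> list[DuplicationCall]:
    """Assign homolog pairs to segmental duplication blocks.

    A pair is segmental iff one gene matches region A and the other region
    B of the same block within ``max_pair_distance_kb``. A gene matches a
    region when its midpoint lies on the region's chromosome at distance 0
    (inside the region) or within the distance cap of the nearest region
    boundary. When per-block collinear ``anchors`` are supplied (block id ->
    list of (coordinate on A, coordinate on B)), the distance to the nearest
    anchor coordinate is used instead of the boundary proxy.
    """
    if max_pair_distance_kb <= 0:
        raise ValueError("max_pair_distance_kb must be positive")
    cap_bp = max_pair_distance_kb * 1000.0
    by_id = {g.gene_id: g for g in family_loci}
    calls: list[DuplicationCall] = []
    for pair in pairs:
        pair = pair if isinstance(pair, HomologPair) else HomologPair(*pair)
        if pair.gene_a not in by_id or pair.gene_b not in by_id:
            missing = [g for g in pair if g not in by_id]
            raise KeyError(f"pair genes missing from family loci: {', '.join(missing)}")
        la, lb = by_id[pair.gene_a], by_id[pair.gene_b]
        best: Optional[tuple[float, DuplicationBlock, float, float]] = None
        for block in blocks:
            for first, second in ((la, lb), (lb, la)):
                da = _gene_to_side_distance(first, block, "a", anchors)
                db = _gene_to_side_distance(second, block, "b", anchors)
                if da <= cap_bp and db <= cap_bp:
                    worst = max(da, db)
                    if best is None or worst < best[0]:
                        best = (worst, block, da, db)
        if best is not None:
            _, block, da, db = best
            calls.append(DuplicationCall(
                tuple(pair), "segmental",
                {"block_id": block.block_id,
                 "distance_kb_a": da / 1000.0,
                 "distance_kb_b": db / 1000.0},
            ))
    return calls


def _gene_to_side_distance(locus: GeneLocus, block: DuplicationBlock, side: str,
                           anchors: Optional[Mapping[str, Sequence[tuple[int, int]]]],
                           ) -> float:
    chrom = block.chrom_a if side == "a" else block.chrom_b
    start = block.start_a if side == "a" else block.start_b
    end = block.end_a if side == "a" else block.end_b
    if anchors and block.block_id in anchors:
        if locus.chromosome != chrom:
            return float("inf")
        idx = 0 if side == "a" else 1
        return min(abs(locus.midpoint - pair[idx]) for pair in anchors[block.block_id])
    return _region_distance(locus.midpoint, locus.chromosome, chrom, start, end)


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def duplication_summary(calls: Iterable[DuplicationCall],
                        family_size: int) -> DuplicationSummary:
    """Count duplicated genes and their share of the family.

    The union counts genes appearing in any tandem or segmental call; the
    percentage of ``family_size`` is rounded to 2 decimals.
    """
    if family_size <= 0:
        raise ValueError("family_size must be positive")
    tandem_genes: set[str] = set()
    segmental_genes: set[str] = set()
    for call in calls:
        target = tandem_genes if call.kind == "tandem" else segmental_genes
        target.update(call.genes)
    union = tandem_genes | segmental_genes
    pct = round(100.0 * len(union) / family_size, 2)
    return DuplicationSummary(len(tandem_genes), len(segmental_genes),
                              len(union), pct)
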