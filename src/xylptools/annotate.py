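"""Structural annotation and classification of xylogen-like proteins.

A xylogen-like protein (XYLP) is a chimeric arabinogalactan protein: a
secreted backbone carrying one or more Pro/Ala/Ser/Thr (PAST)-rich regions
studded with arabinogalactan glycomodules, plus a non-specific lipid
transfer protein (nsLTP)-like domain whose eight cysteines follow the
C-X-C-X-CC-X-CXC-X-C-X-C template. This module implements the three
structural scans (PAST-rich regions, glycomodules, the gap-constrained
eight-cysteine motif) and the conjunctive classification rule.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from xylptools.io import AnnotationFlags, ProteinRecord

logger = logging.getLogger("xylptools")

PAST_RESIDUES = frozenset("PAST")

#: canonical arabinogalactan glycomodule dipeptides
DEFAULT_GLYCOMODULES = ("AP", "PA", "SP", "TP", "GP", "VP")

DEFAULT_WINDOW = 50
DEFAULT_THRESHOLD = 0.35

HYDROPHOBIC = frozenset("LIV")

CLADE_LABELS = ("A", "B", "C", "D")


@dataclass(frozen=True)
class SequenceRegion:
    """A 1-based inclusive residue interval with a kind and a score."""

    start: int
    end: int
    kind: str  # past_rich | nsltp_domain | signal_peptide | gpi_signal
    score: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad region coordinates {self.start}..{self.end}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"region score {self.score} outside [0, 1]")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CysPatternSpec:
    """A gap-constrained eight-cysteine motif template.

    The template is ``C g1 C g2 CC g3 C h C g4 C g5 C`` where each inter-
    cysteine gap ``gi`` must take a length from ``gap_sets[i]`` and ``h`` is
    the single hydrophobic residue between the fifth and sixth cysteine.
    """

    name: str
    gap_sets: tuple[frozenset[int], ...]
    hydrophobic_set: frozenset[str] = HYDROPHOBIC
    clade: Optional[str] = None  # set for clade-specific templates

    def __post_init__(self) -> None:
        if len(self.gap_sets) != 5:
            raise ValueError("a cysteine pattern needs exactly five gap sets")
        for gs in self.gap_sets:
            if not gs or any(g < 0 for g in gs):
                raise ValueError("gap sets must be non-empty with lengths >= 0")
        if not self.hydrophobic_set:
            raise ValueError("hydrophobic set must be non-empty")
        if self.clade is not None and self.clade not in CLADE_LABELS:
            raise ValueError(f"unknown clade label {self.clade!r}")


@dataclass(frozen=True)
class CysPatternMatch:
    """A located eight-cysteine motif match (all positions 1-based)."""

    spec_name: str
    cys_positions: tuple[int, ...]
    hydrophobic_residue: str
    gaps: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.cys_positions) != 8 or len(self.gaps) != 5:
            raise ValueError("a motif match has eight cysteines and five gaps")

    @property
    def start(self) -> int:
        return self.cys_positions[0]

    @property
    def end(self) -> int:
        return self.cys_positions[-1]


@dataclass(frozen=True)
class GlycomoduleHit:
    """One non-overlapping glycomodule dipeptide hit (1-based start)."""

    position: int
    dipeptide: str


@dataclass(frozen=True)
class XylpAnnotation:
    """Full structural annotation and classification verdict for one protein."""

    protein_id: str
    flags: AnnotationFlags
    past_regions: tuple[SequenceRegion, ...]
    glycomodules: tuple[GlycomoduleHit, ...]
    nsltp_match: Optional[CysPatternMatch]
    is_xylp: bool
    clade_hypothesis: str = "unassigned"


def clade_a_spec() -> CysPatternSpec:
    """Clade A spacing: C-X9/10-C-X16/17-CC-X12/14-C-[LVI]-C-X22/23/24-C-X7/8/9-C."""
    return CysPatternSpec(
        name="cladeA",
        gap_sets=(
            frozenset({9, 10}),
            frozenset({16, 17}),
            frozenset({12, 14}),
            frozenset({22, 23, 24}),
            frozenset({7, 8, 9}),
        ),
        hydrophobic_set=frozenset("LVI"),
        clade="A",
    )


def clade_c_spec() -> CysPatternSpec:
    """Clade C spacing: C-X9-C-X14-CC-X12-C-[LV]-C-X25/27-C-X9/10-C."""
    return CysPatternSpec(
        name="cladeC",
        gap_sets=(
            frozenset({9}),
            frozenset({14}),
            frozenset({12}),
            frozenset({25, 27}),
            frozenset({9, 10}),
        ),
        hydrophobic_set=frozenset("LV"),
        clade="C",
    )


def generic_spec(max_gap: int = 60) -> CysPatternSpec:
    """The unconstrained eight-cysteine template (gaps 1..max_gap)."""
    anygap = frozenset(range(1, max_gap + 1))
    return CysPatternSpec(
        name="generic",
        gap_sets=(anygap,) * 5,
        hydrophobic_set=HYDROPHOBIC,
        clade=None,
    )


def default_specs() -> list[CysPatternSpec]:
    """Default motif templates: clade-specific first, then the generic one."""
    return [clade_a_spec(), clade_c_spec(), generic_spec()]


def widen_gap_sets(spec: CysPatternSpec) -> CysPatternSpec:
    """Replace each gap set with the full integer range it spans.

    Reads a printed spacing like 12/14 as the range 12..14 instead of the
    two-element set; intended for sensitivity analysis.
    """
    widened = tuple(frozenset(range(min(gs), max(gs) + 1)) for gs in spec.gap_sets)
    return CysPatternSpec(spec.name + "_widened", widened, spec.hydrophobic_set, spec.clade)


# ---------------------------------------------------------------------------
# PAST-rich regions
# ---------------------------------------------------------------------------

def find_past_regions(record: ProteinRecord, window: int = DEFAULT_WINDOW,
                      threshold: float = DEFAULT_THRESHOLD) -> list[SequenceRegion]:
    """Locate maximal PAST-rich regions by a sliding-window scan.

    A window qualifies when its P/A/S/T fraction strictly exceeds
    ``threshold`` (default 0.35, i.e. the >35% rule); every residue covered
    by at least one qualifying window is PAST-covered, and maximal runs of
    covered residues become regions. Each region is scored by its own PAST
    fraction. Sequences shorter than the window are scanned with a single
    whole-sequence window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    seq = record.sequence
    n = len(seq)
    w = min(window, n)
    is_past = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_past = np.isin(is_past, np.frombuffer(b"PAST", dtype=np.uint8)).astype(np.int64)
    window_sums = np.convolve(is_past, np.ones(w, dtype=np.int64), mode="valid")
    qualifying = window_sums > threshold * w
    covered = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(qualifying):
        covered[i:i + w] = True
    regions: list[SequenceRegion] = []
    i = 0
    while i < n:
        if covered[i]:
            j = i
            while j + 1 < n and covered[j + 1]:
                j += 1
            score = float(is_past[i:j + 1].sum()) / (j - i + 1)
            regions.append(SequenceRegion(i + 1, j + 1, "past_rich", score))
            i = j + 1
        else:
            i += 1
    return regions


# ---------------------------------------------------------------------------
# glycomodules
# ---------------------------------------------------------------------------

def scan_glycomodules(record: ProteinRecord,
                      dipeptide_set: Sequence[str] = DEFAULT_GLYCOMODULES,
                      restrict_to_past: bool = True,
                      past_regions: Optional[Sequence[SequenceRegion]] = None,
                      window: int = DEFAULT_WINDOW,
                      threshold: float = DEFAULT_THRESHOLD) -> list[GlycomoduleHit]:
    """Scan for non-overlapping glycomodule dipeptides, left to right.

    When ``restrict_to_past`` is true (the default) a hit counts only if the
    whole dipeptide lies inside a PAST-rich region (computed with the given
    window/threshold unless ``past_regions`` is supplied). The leftmost
    eligible dipeptide always wins; an overlapping later start is skipped.
    """
    dipeptides = frozenset(dipeptide_set)
    if not dipeptides:
        raise ValueError("dipeptide set must be non-empty")
    if any(len(d) != 2 for d in dipeptides):
        raise ValueError("glycomodules are dipeptides")
    seq = record.sequence
    n = len(seq)
    if restrict_to_past:
        if past_regions is None:
            past_regions = find_past_regions(record, window, threshold)
        covered = np.zeros(n, dtype=bool)
        for region in past_regions:
            if region.kind == "past_rich":
                covered[region.start - 1:region.end] = True
    hits: list[GlycomoduleHit] = []
    i = 0
    while i < n - 1:
        dp = seq[i:i + 2]
        if dp in dipeptides and (not restrict_to_past or (covered[i] and covered[i + 1])):
            hits.append(GlycomoduleHit(i + 1, dp))
            i += 2
        else:
            i += 1
    return hits


# ---------------------------------------------------------------------------
# eight-cysteine motif
# ---------------------------------------------------------------------------

def match_cys_pattern(record: ProteinRecord, spec: CysPatternSpec,
                      allow_internal_cys: bool = False) -> Optional[CysPatternMatch]:
    """Find the leftmost placement of the eight-cysteine template.

    Gap segments must be cysteine-free unless ``allow_internal_cys`` is set,
    so that exactly eight cysteines form the motif. Candidate start
    positions are scanned left to right and gap lengths in ascending order,
    which makes the returned match deterministic.
    """
    seq = record.sequence
    n = len(seq)
    gap_lists = [sorted(gs) for gs in spec.gap_sets]

    def gap_clean(lo: int, hi: int) -> bool:
        # segment seq[lo:hi] (0-based, half-open) may not contain cysteine
        return allow_internal_cys or "C" not in seq[lo:hi]

    for p1 in range(n):
        if seq[p1] != "C":
            continue
        m = _extend_match(seq, n, p1, gap_lists, spec, gap_clean)
        if m is not None:
            return m
    return None


def _extend_match(seq: str, n: int, p1: int, gap_lists, spec: CysPatternSpec,
                  gap_clean) -> Optional[CysPatternMatch]:
    for g1 in gap_lists[0]:
        p2 = p1 + 1 + g1
        if p2 >= n or seq[p2] != "C" or not gap_clean(p1 + 1, p2):
            continue
        for g2 in gap_lists[1]:
            p3 = p2 + 1 + g2
            p4 = p3 + 1
            if p4 >= n or seq[p3] != "C" or seq[p4] != "C" or not gap_clean(p2 + 1, p3):
                continue
            for g3 in gap_lists[2]:
                p5 = p4 + 1 + g3
                p6 = p5 + 2
                if p6 >= n or seq[p5] != "C" or not gap_clean(p4 + 1, p5):
                    continue
                h = seq[p5 + 1]
                if h not in spec.hydrophobic_set or seq[p6] != "C":
                    continue
                for g4 in gap_lists[3]:
                    p7 = p6 + 1 + g4
                    if p7 >= n or seq[p7] != "C" or not gap_clean(p6 + 1, p7):
                        continue
                    for g5 in gap_lists[4]:
                        p8 = p7 + 1 + g5
                        if p8 >= n or seq[p8] != "C" or not gap_clean(p7 + 1, p8):
                            continue
                        positions = tuple(p + 1 for p in (p1, p2, p3, p4, p5, p6, p7, p8))
                        return CysPatternMatch(spec.name, positions, h,
                                               (g1, g2, g3, g4, g5))
    return None


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class MissingFlagsError(KeyError):
    """Raised when a protein has no annotation-flags row."""


def classify_xylp(record: ProteinRecord, flags: AnnotationFlags,
                  specs: Optional[Sequence[CysPatternSpec]] = None,
                  window: int = DEFAULT_WINDOW,
                  threshold: float = DEFAULT_THRESHOLD,
                  dipeptide_set: Sequence[str] = DEFAULT_GLYCOMODULES,
                  restrict_to_past: bool = True,
                  allow_internal_cys: bool = False) -> XylpAnnotation:
    """Annotate one protein and apply the XYLP classification rule.

    A protein is called a XYLP iff its signal-peptide flag is set, some
    motif template matches, and at least one glycomodule is found. The GPI
    flag is recorded but not required. The clade hypothesis is the clade of
    the first clade-specific template that matched (templates are tried in
    the order given; clade-specific templates should precede the generic
    one, as in :func:`default_specs`).
    """
    if specs is None:
        specs = default_specs()
    past = tuple(find_past_regions(record, window, threshold))
    glyco = tuple(scan_glycomodules(record, dipeptide_set, restrict_to_past,
                                    past_regions=past))
    nsltp: Optional[CysPatternMatch] = None
    clade = "unassigned"
    for spec in specs:
        m = match_cys_pattern(record, spec, allow_internal_cys)
        if m is not None:
            nsltp = m
            if spec.clade is not None:
                clade = spec.clade
            break
    is_xylp = bool(flags.has_signal_peptide and nsltp is not None and len(glyco) >= 1)
    return XylpAnnotation(record.id, flags, past, glyco, nsltp, is_xylp,
                          clade if nsltp is not None else "unassigned")


def annotate_family(records: Iterable[ProteinRecord],
                    flags: Mapping[str, AnnotationFlags],
                    specs: Optional[Sequence[CysPatternSpec]] = None,
                    **kwargs) -> list[XylpAnnotation]:
    """Classify a collection of proteins against a shared flag table."""
    out: list[XylpAnnotation] = []
    for rec in records:
        if rec.id not in flags:
            raise MissingFlagsError(f"no annotation flags for protein {rec.id!r}")
        out.append(classify_xylp(rec, flags[rec.id], specs, **kwargs))
    return out


def annotation_table(annotations: Sequence[XylpAnnotation]):
    """Summarize annotations as a tidy DataFrame (one row per protein)."""
    import pandas as pd

    rows = []
    for a in annotations:
        rows.append({
            "protein_id": a.protein_id,
            "is_xylp": a.is_xylp,
            "clade_hypothesis": a.clade_hypothesis,
            "signal_peptide": a.flags.has_signal_peptide,
            "gpi_anchor": a.flags.has_gpi_anchor,
            "n_past_regions": len(a.past_regions),
            "n_glycomodules": len(a.glycomodules),
            "motif_spec": a.nsltp_match.spec_name if a.nsltp_match else "",
            "motif_start": a.nsltp_match.start if a.nsltp_match else 0,
        })
    return pd.DataFrame(rows)
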