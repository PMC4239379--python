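"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emits the same file formats the pipeline consumes plus a
machine-readable truth table describing what was planted, so recovery can
be asserted without any external data. All generators are deterministic
under a fixed seed.

Sequence alphabets are chosen so the planted structure is unambiguous:
proline appears only inside planted PAST regions (every default
glycomodule dipeptide contains P, so no accidental glycomodules can occur
elsewhere) and cysteine appears only inside the planted eight-cysteine
motif (so the motif placement found by the scanner is the planted one).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from xylptools.annotate import CysPatternSpec, clade_a_spec, clade_c_spec
from xylptools.duplication import DuplicationBlock, HomologPair
from xylptools.io import (
    AnnotationFlags,
    ExpressionMatrix,
    GeneLocus,
    ProteinRecord,
    rank_loci,
    write_fasta,
    write_flags,
    write_gff3,
)

# alphabets (see module docstring): no P, no C outside planted elements
_SIGNAL_ALPHABET = "LVFIW"
_GAP_ALPHABET = "GEKNDQRH"
_TAIL_ALPHABET = "NQDEG"
_PAST_FILLER = "AST"

#: dipeptides used for planting; all-PAST letters so regions stay 100% PAST
_PLANT_DIPEPTIDES = ("AP", "SP", "TP")

DECOY_CLASSES = ("seven_cys", "wrong_gap", "no_glycomodules", "no_signal")


def _choice_str(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


# ---------------------------------------------------------------------------
# protein families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Parameters of a planted XYLP protein family.

    ``n_per_clade`` gives the number of true family members per clade
    template; ``decoys`` the number of decoys per violated-rule class. Each
    decoy violates exactly one conjunct of the classification rule, so
    classifier errors are attributable. ``signal_flag_noise`` is the
    probability of flipping the emitted signal-peptide flag (truth labels
    follow the emitted flag).
    """

    n_per_clade: Mapping[str, int] = field(
        default_factory=lambda: {"A": 10, "C": 10})
    decoys: Mapping[str, int] = field(
        default_factory=lambda: {c: 2 for c in DECOY_CLASSES})
    past_length_range: tuple[int, int] = (30, 60)
    glycomodule_range: tuple[int, int] = (2, 6)
    signal_flag_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_clade.values()):
            raise ValueError("clade counts must be >= 0")
        unknown = set(self.decoys) - set(DECOY_CLASSES)
        if unknown:
            raise ValueError(f"unknown decoy classes: {sorted(unknown)}")
        if not 0.0 <= self.signal_flag_noise <= 1.0:
            raise ValueError("signal_flag_noise must lie in [0, 1]")


@dataclass
class FamilyData:
    records: list[ProteinRecord]
    flags: dict[str, AnnotationFlags]
    truth: dict

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, directory / "family.fasta")
        write_flags(self.flags, directory / "flags.tsv")
        (directory / "truth.json").write_text(json.dumps(self.truth, indent=1))


_CLADE_SPECS = {"A": clade_a_spec, "C": clade_c_spec}


def _sample_motif(rng: np.random.Generator, spec: CysPatternSpec,
                  drop_last_cys: bool = False,
                  corrupt_first_gap: bool = False) -> str:
    """Draw one motif realization from a clade template's gap sets."""
    gaps = [int(rng.choice(sorted(gs))) for gs in spec.gap_sets]
    if corrupt_first_gap:
        gaps[0] = max(spec.gap_sets[0]) + 2  # outside every default gap set
    h = sorted(spec.hydrophobic_set)[int(rng.integers(0, len(spec.hydrophobic_set)))]
    parts = [
        "C", _choice_str(rng, _GAP_ALPHABET, gaps[0]),
        "C", _choice_str(rng, _GAP_ALPHABET, gaps[1]),
        "CC", _choice_str(rng, _GAP_ALPHABET, gaps[2]),
        "C", h,
        "C", _choice_str(rng, _GAP_ALPHABET, gaps[3]),
        "C", _choice_str(rng, _GAP_ALPHABET, gaps[4]),
        "C" if not drop_last_cys else _GAP_ALPHABET[0],
    ]
    return "".join(parts)


def _sample_past_region(rng: np.random.Generator, length_range: tuple[int, int],
                        n_glyco: int) -> tuple[str, int]:
    """A 100%-PAST segment carrying exactly ``n_glyco`` scanner hits."""
    lo, hi = length_range
    target_len = int(rng.integers(lo, hi + 1))
    pieces: list[str] = []
    used = 0
    for _ in range(n_glyco):
        filler = _choice_str(rng, _PAST_FILLER, int(rng.integers(1, 4)))
        # never end filler with a letter that extends a dipeptide leftwards:
        # with dipeptides {AP, SP, TP} any filler from {A, S, T} followed by
        # the dipeptide start is safe because no dipeptide starts with P
        dp = _PLANT_DIPEPTIDES[int(rng.integers(0, len(_PLANT_DIPEPTIDES)))]
        pieces.append(filler + dp)
        used += len(filler) + 2
    pad = max(target_len - used, 1)
    pieces.append("T" * pad)
    region = "".join(pieces)
    return region, n_glyco


def generate_family(spec: SyntheticFamilySpec) -> FamilyData:
    """Generate a planted protein family with flags and truth labels.

    Each true member is signal stub + leading PAST region with glycomodules
    + clade motif + (optionally) trailing PAST region + C-terminal stub.
    Decoys violate exactly one rule: ``seven_cys`` (last motif cysteine
    removed), ``wrong_gap`` (first inter-cysteine gap outside the clade's
    set), ``no_glycomodules`` (PAST region without proline), ``no_signal``
    (signal-peptide flag false). Truth labels hold for classification
    against the clade-specific templates (clade A + clade C).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    flags: dict[str, AnnotationFlags] = {}
    truth: dict[str, dict] = {}

    def build(name: str, clade: str, decoy: Optional[str]) -> None:
        pattern = _CLADE_SPECS[clade]()
        signal = "M" + _choice_str(rng, _SIGNAL_ALPHABET, 19)
        n_glyco = int(rng.integers(spec.glycomodule_range[0],
                                   spec.glycomodule_range[1] + 1))
        if decoy == "no_glycomodules":
            # proline-free PAST region: no default glycomodule can occur
            past, n_glyco = _choice_str(rng, _PAST_FILLER,
                                        spec.past_length_range[0]), 0
        else:
            past, n_glyco = _sample_past_region(rng, spec.past_length_range, n_glyco)
        motif = _sample_motif(
            rng, pattern,
            drop_last_cys=(decoy == "seven_cys"),
            corrupt_first_gap=(decoy == "wrong_gap"),
        )
        trailing = ""
        extra_glyco = 0
        if decoy is None and rng.random() < 0.5:
            extra = int(rng.integers(1, 4))
            trailing, extra_glyco = _sample_past_region(
                rng, spec.past_length_range, extra)
        tail = _choice_str(rng, _TAIL_ALPHABET, 10)
        seq = signal + past + motif + trailing + tail
        signal_flag = decoy != "no_signal"
        if spec.signal_flag_noise > 0 and rng.random() < spec.signal_flag_noise:
            signal_flag = not signal_flag
        gpi_flag = bool(rng.random() < 0.9)
        motif_ok = decoy not in {"seven_cys", "wrong_gap"}
        n_total_glyco = n_glyco + extra_glyco
        is_xylp = signal_flag and motif_ok and n_total_glyco >= 1
        records.append(ProteinRecord(name, seq))
        flags[name] = AnnotationFlags(name, signal_flag, gpi_flag, ())
        truth[name] = {
            "is_xylp": bool(is_xylp),
            "clade": clade if motif_ok else None,
            "decoy_class": decoy,
            "n_glycomodules": int(n_total_glyco),
            "past_core": [len(signal) + 1, len(signal) + len(past)],
            "motif_start": len(signal) + len(past) + 1,
        }

    clades = sorted(spec.n_per_clade)
    for clade in clades:
        for i in range(spec.n_per_clade[clade]):
            build(f"XYLP{clade}{i + 1:03d}", clade, None)
    for decoy in DECOY_CLASSES:
        count = spec.decoys.get(decoy, 0)
        for i in range(count):
            clade = clades[i % len(clades)] if clades else "A"
            build(f"DECOY_{decoy}_{i + 1:02d}", clade, decoy)
    return FamilyData(records, flags, truth)


# ---------------------------------------------------------------------------
# genome layouts
# ---------------------------------------------------------------------------

@dataclass
class GenomeLayout:
    loci: list[GeneLocus]
    family_ids: list[str]
    pairs: list[HomologPair]
    blocks: list[DuplicationBlock]
    truth: dict

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_gff3(self.loci, directory / "genome.gff3")
        with open(directory / "pairs.tsv", "w") as fh:
            fh.write("gene_a\tgene_b\n")
            for p in self.pairs:
                fh.write(f"{p.gene_a}\t{p.gene_b}\n")
        with open(directory / "blocks.tsv", "w") as fh:
            fh.write("block_id\tchrom_a\tstart_a\tend_a\tchrom_b\tstart_b\tend_b\n")
            for b in self.blocks:
                fh.write(f"{b.block_id}\t{b.chrom_a}\t{b.start_a}\t{b.end_a}\t"
                         f"{b.chrom_b}\t{b.start_b}\t{b.end_b}\n")
        (directory / "truth.json").write_text(json.dumps(self.truth, indent=1))


def generate_genome_layout(
    tandem_arrays: Sequence[Sequence[int]] = ((2,), (0, 5), (6,)),
    segmental_pairs: Sequence[tuple[float, float]] = ((0.0, 0.0), (0.0, 600.0)),
    n_background: int = 80,
    max_intervening: int = 5,
    max_pair_distance_kb: float = 500.0,
    seed: int = 0,
) -> GenomeLayout:
    """Plant tandem arrays and segmental block pairs in a gene annotation.

    ``tandem_arrays`` lists, per array, the intervening-gene counts between
    consecutive family members (so ``(0, 5)`` is a three-gene array whose
    neighbours are adjacent and five-genes-apart). All arrays share one
    chromosome, separated by enough background genes that cross-array pairs
    are never tandem. ``segmental_pairs`` lists per planted homolog pair
    the distance (kb) of each gene from its block region; 0 places the gene
    inside the region. Truth labels apply the boundary-inclusive
    ``max_intervening`` and ``max_pair_distance_kb`` rules to the planted
    values.
    """
    rng = np.random.default_rng(seed)
    loci: list[GeneLocus] = []
    family_ids: list[str] = []
    truth: dict = {"tandem_pairs": {}, "tandem_arrays": [],
                   "segmental_pairs": {}, "max_intervening": max_intervening,
                   "max_pair_distance_kb": max_pair_distance_kb}

    # --- tandem chromosome: an ordered roster of gene names
    spacer = max_intervening + 10
    roster: list[str] = []
    bg_counter = 0

    def background(n: int) -> None:
        nonlocal bg_counter
        for _ in range(n):
            bg_counter += 1
            roster.append(f"BG{bg_counter:04d}")

    background(3)
    array_members: list[list[str]] = []
    for a_idx, intervening_counts in enumerate(tandem_arrays):
        members = [f"TD{a_idx + 1}_1"]
        roster.append(members[0])
        for m_idx, count in enumerate(intervening_counts):
            if count < 0:
                raise ValueError("intervening counts must be >= 0")
            background(count)
            name = f"TD{a_idx + 1}_{m_idx + 2}"
            members.append(name)
            roster.append(name)
        array_members.append(members)
        family_ids.extend(members)
        background(spacer)
    background(max(n_background - bg_counter, 0))

    # planted pair labels from cumulative intervening counts
    for members, counts in zip(array_members, tandem_arrays):
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                between = sum(counts[i:j]) + (j - i - 1)
                key = f"{members[i]}|{members[j]}"
                truth["tandem_pairs"][key] = {
                    "intervening": between,
                    "expected_tandem": between <= max_intervening,
                }
        expected_array = _expected_array(members, counts, max_intervening)
        if expected_array:
            truth["tandem_arrays"].append(expected_array)

    pos = 1
    for name in roster:
        length = int(rng.integers(1000, 3000))
        gap = int(rng.integers(2000, 8000))
        strand = "+" if rng.random() < 0.5 else "-"
        loci.append(GeneLocus(name, "chr01", pos, pos + length, strand))
        pos += length + gap

    # --- segmental chromosomes: one block per planted pair
    pairs: list[HomologPair] = []
    blocks: list[DuplicationBlock] = []
    region_width = 300_000
    for p_idx, (offset_a_kb, offset_b_kb) in enumerate(segmental_pairs):
        block_id = f"BLK{p_idx + 1}"
        chrom_a, chrom_b = f"chrS{p_idx + 1}a", f"chrS{p_idx + 1}b"
        start_a, start_b = 1_000_000, 2_000_000
        blocks.append(DuplicationBlock(block_id,
                                       chrom_a, start_a, start_a + region_width,
                                       chrom_b, start_b, start_b + region_width))
        ga, gb = f"SG{p_idx + 1}a", f"SG{p_idx + 1}b"
        for name, chrom, start, offset_kb in (
                (ga, chrom_a, start_a, offset_a_kb),
                (gb, chrom_b, start_b, offset_b_kb)):
            if offset_kb == 0:
                mid = start + region_width // 2
            else:
                mid = start + region_width + int(offset_kb * 1000)
            loci.append(GeneLocus(name, chrom, mid - 500, mid + 500, "+"))
        pairs.append(HomologPair(ga, gb))
        family_ids.extend([ga, gb])
        expected = offset_a_kb <= max_pair_distance_kb and offset_b_kb <= max_pair_distance_kb
        truth["segmental_pairs"][f"{ga}|{gb}"] = {
            "offset_a_kb": offset_a_kb,
            "offset_b_kb": offset_b_kb,
            "expected_segmental": bool(expected),
        }

    return GenomeLayout(rank_loci(loci), sorted(set(family_ids)), pairs, blocks, truth)


def _expected_array(members: Sequence[str], counts: Sequence[int],
                    max_intervening: int) -> list[str]:
    """Transitive closure of consecutive tandem links within one array."""
    linked: list[set[str]] = []
    current = {members[0]}
    for member, count in zip(members[1:], counts):
        if count <= max_intervening:
            current.add(member)
        else:
            if len(current) > 1:
                linked.append(current)
            current = {member}
    if len(current) > 1:
        linked.append(current)
    return sorted(set().union(*linked)) if linked else []


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

DEFAULT_TISSUES = ("stem", "root", "leaf", "SAM", "panicle")
DEFAULT_MPSS_LIBRARIES = ("NYR", "NRA", "NST", "NYL", "NME", "NPO", "NOS", "NIP", "NCA")
DEFAULT_MICROARRAY_SAMPLES = ("YR", "ML", "YL", "SAM", "P1", "P2", "P3", "P4",
                              "P5", "P6", "S1", "S2", "S3", "S4", "S5")
DEFAULT_STRESS_CONDITIONS = ("drought", "salt", "cold")
_MPSS_MEDIANS = {"low": 10.0, "moderate": 150.0, "strong": 2000.0}


@dataclass
class ExpressionData:
    est: ExpressionMatrix
    mpss: ExpressionMatrix
    microarray: ExpressionMatrix
    stress_control: ExpressionMatrix
    stress_treated: ExpressionMatrix
    truth: dict

    def write(self, directory: str | Path) -> None:
        from xylptools.io import write_expression_table

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_expression_table(self.est, directory / "est_counts.tsv")
        write_expression_table(self.mpss, directory / "mpss_tpm.tsv")
        write_expression_table(self.microarray, directory / "microarray_signal.tsv")
        write_expression_table(self.stress_control, directory / "stress_control.tsv")
        write_expression_table(self.stress_treated, directory / "stress_treated.tsv")
        (directory / "truth.json").write_text(json.dumps(self.truth, indent=1))


def _truncated_lognormal(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with z-scores truncated to ±2.5."""
    z = np.clip(rng.standard_normal(size), -2.5, 2.5)
    return np.exp(sigma * z)


def generate_expression(
    n_genes: int = 20,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    n_specific: int = 4,
    mpss_class_cycle: Sequence[str] = ("strong", "moderate", "low"),
    stress_folds: Sequence[tuple[int, str, float]] = (
        (0, "drought", 2.5),
        (1, "drought", 0.4), (1, "salt", 0.4),
        (2, "drought", 0.4), (2, "salt", 0.4),
        (3, "drought", 0.4), (3, "salt", 0.4),
    ),
    noise_sd: float = 0.1,
    seed: int = 0,
) -> ExpressionData:
    """Generate EST, MPSS, microarray and stress tables with planted truth.

    EST counts are multinomial with planted majority tissues (specific
    genes put 65-85% of their counts in one tissue; non-specific genes are
    capped at half). MPSS tpm values are log-normal around the planted
    class median with truncated noise, so the planted class always
    survives. Stress tables carry planted true fold changes; ``noise_sd``
    is the standard deviation of the log measurement error of the fold
    (applied to the treated matrix; the control is the clean baseline).
    """
    if n_specific > n_genes:
        raise ValueError("n_specific cannot exceed n_genes")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:03d}" for i in range(n_genes)]
    tissues = list(tissues)
    truth: dict = {"specific": {}, "mpss_class": {}, "true_folds": {},
                   "noise_sd": noise_sd}

    # --- EST counts
    est = np.zeros((n_genes, len(tissues)), dtype=int)
    for g in range(n_genes):
        total = int(rng.integers(20, 60))
        if g < n_specific:
            tissue_idx = g % len(tissues)
            share = rng.uniform(0.65, 0.85)
            major = max(int(np.ceil(share * total)), total // 2 + 1)
            rest = rng.multinomial(total - major,
                                   np.ones(len(tissues) - 1) / (len(tissues) - 1))
            row = np.insert(rest, tissue_idx, major)
            truth["specific"][genes[g]] = tissues[tissue_idx]
        else:
            row = rng.multinomial(total, np.ones(len(tissues)) / len(tissues))
            # cap the maximum at half the total so the gene stays non-specific
            while row.max() > total / 2:
                row[row.argmax()] -= 1
                row[row.argmin()] += 1
            truth["specific"][genes[g]] = None
        est[g] = row

    # --- MPSS tpm
    mpss = np.zeros((n_genes, len(DEFAULT_MPSS_LIBRARIES)))
    for g in range(n_genes):
        cls = mpss_class_cycle[g % len(mpss_class_cycle)]
        median = _MPSS_MEDIANS[cls]
        mpss[g] = median * _truncated_lognormal(rng, 0.2, len(DEFAULT_MPSS_LIBRARIES))
        truth["mpss_class"][genes[g]] = cls

    # --- microarray signals
    base = rng.uniform(100.0, 3000.0, size=n_genes)
    signal = base[:, None] * _truncated_lognormal(
        rng, 0.3, (n_genes, len(DEFAULT_MICROARRAY_SAMPLES)))

    # --- stress fold changes
    conditions = list(DEFAULT_STRESS_CONDITIONS)
    control = rng.uniform(200.0, 1000.0, size=(n_genes, len(conditions)))
    folds = np.ones((n_genes, len(conditions)))
    for gene_idx, condition, fold in stress_folds:
        if fold <= 0:
            raise ValueError("true folds must be positive")
        folds[gene_idx, conditions.index(condition)] = fold
        truth["true_folds"].setdefault(genes[gene_idx], {})[condition] = fold
    noise = (np.exp(noise_sd * rng.standard_normal(control.shape))
             if noise_sd > 0 else 1.0)
    treated = control * folds * noise

    return ExpressionData(
        est=ExpressionMatrix(pd.DataFrame(est, index=genes, columns=tissues), "count"),
        mpss=ExpressionMatrix(pd.DataFrame(mpss, index=genes,
                                           columns=list(DEFAULT_MPSS_LIBRARIES)), "tpm"),
        microarray=ExpressionMatrix(pd.DataFrame(signal, index=genes,
                                                 columns=list(DEFAULT_MICROARRAY_SAMPLES)),
                                    "signal"),
        stress_control=ExpressionMatrix(pd.DataFrame(control, index=genes,
                                                     columns=conditions), "signal"),
        stress_treated=ExpressionMatrix(pd.DataFrame(treated, index=genes,
                                                     columns=conditions), "signal"),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

@dataclass
class QpcrData:
    """Simulated qPCR Ct table: standards at 1/3/9/27 plus unknown samples."""

    table: pd.DataFrame  # columns: gene, sample, quantity, replicate, ct
    truth: dict

    def standard_cts(self, gene: str) -> dict[float, list[float]]:
        rows = self.table[(self.table.gene == gene) & self.table.quantity.notna()]
        out: dict[float, list[float]] = {}
        for _, row in rows.iterrows():
            out.setdefault(float(row.quantity), []).append(float(row.ct))
        return out

    def sample_ct(self, gene: str, sample: str) -> float:
        rows = self.table[(self.table.gene == gene) & (self.table["sample"] == sample)]
        if rows.empty:
            raise KeyError(f"no Ct rows for gene {gene!r}, sample {sample!r}")
        return float(rows.ct.mean())

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(directory / "qpcr_ct.csv", index=False)
        (directory / "truth.json").write_text(json.dumps(self.truth, indent=1))


def generate_qpcr(
    efficiencies: Mapping[str, float],
    sample_quantities: Optional[Mapping[str, Mapping[str, float]]] = None,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    dilutions: Sequence[float] = (1.0, 3.0, 9.0, 27.0),
    replicates: int = 3,
) -> QpcrData:
    """Simulate Ct values from known efficiencies and template quantities.

    For each gene the standard series covers ``dilutions`` in
    ``replicates`` wells; Ct = intercept + slope * log10(quantity) +
    Gaussian noise, with slope = -1/log10(1 + efficiency). Unknown samples
    come from ``sample_quantities`` (gene -> sample -> true quantity).
    """
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    for gene, eff in efficiencies.items():
        if not 0.5 < eff <= 1.1:
            raise ValueError(f"efficiency for {gene!r} must lie in (0.5, 1.1]")
    sample_quantities = sample_quantities or {}
    rng = np.random.default_rng(seed)
    rows = []
    truth: dict = {"efficiency": dict(efficiencies), "intercept": {},
                   "slope": {}, "quantities": {}}
    for gene in sorted(efficiencies):
        eff = efficiencies[gene]
        slope = -1.0 / np.log10(1.0 + eff)
        intercept = float(rng.uniform(22.0, 28.0))
        truth["slope"][gene] = float(slope)
        truth["intercept"][gene] = intercept
        for q in dilutions:
            if q <= 0:
                raise ValueError("dilution quantities must be positive")
            for rep in range(replicates):
                noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rows.append({"gene": gene, "sample": f"std_{q:g}", "quantity": q,
                             "replicate": rep + 1,
                             "ct": intercept + slope * np.log10(q) + noise})
        for sample, q in sorted(sample_quantities.get(gene, {}).items()):
            if q <= 0:
                raise ValueError("sample quantities must be positive")
            truth["quantities"].setdefault(gene, {})[sample] = q
            for rep in range(replicates):
                noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rows.append({"gene": gene, "sample": sample, "quantity": np.nan,
                             "replicate": rep + 1,
                             "ct": intercept + slope * np.log10(q) + noise})
    return QpcrData(pd.DataFrame(rows), truth)
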