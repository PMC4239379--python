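"""Readers, writers and shared domain types for the XYLP pipeline.

All genomic and residue coordinates are 1-based inclusive throughout the
package (the convention of GFF3 and of the family table); any half-open
arithmetic is confined to private helpers.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("xylptools")

#: the 20 standard amino acids plus X (unknown residue)
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY") | {"X"}

EXPRESSION_UNITS = ("tpm", "signal", "count", "ct")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a unique identifier.

    The sequence is stored uppercased and must consist of the 20 standard
    one-letter amino-acid codes plus ``X``.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid protein id: {self.id!r}")
        seq = self.sequence.upper()
        if not seq:
            raise FormatError(f"empty sequence for record {self.id!r}")
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise FormatError(
                f"record {self.id!r} contains non-amino-acid characters: "
                f"{''.join(sorted(bad))}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotationFlags:
    """Externally predicted per-protein annotation flags.

    Signal-peptide and GPI-anchor predictions are consumed as input (they
    come from dedicated predictors), never computed here.
    """

    protein_id: str
    has_signal_peptide: bool
    has_gpi_anchor: bool
    n_glycosylation_sites: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if any(p < 1 for p in self.n_glycosylation_sites):
            raise FormatError(
                f"flags for {self.protein_id!r}: N-glycosylation positions "
                "must be 1-based and positive"
            )


@dataclass(frozen=True)
class GeneLocus:
    """A gene's genomic coordinates plus its ordinal rank on its chromosome."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "?"
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise FormatError(f"gene {self.gene_id!r}: coordinates are 1-based")
        if self.strand not in {"+", "-", "?"}:
            raise FormatError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class ExpressionMatrix:
    """A rectangular gene-by-sample expression table with a units tag.

    ``units`` is one of ``tpm`` (MPSS tag abundance), ``signal`` (microarray
    intensity), ``count`` (EST counts) or ``ct`` (qPCR threshold cycles).
    Negative values are rejected for all units except ``ct``.
    """

    data: pd.DataFrame
    units: str

    def __post_init__(self) -> None:
        if self.units not in EXPRESSION_UNITS:
            raise FormatError(f"unknown expression units {self.units!r}")
        if self.data.empty:
            raise FormatError("empty expression table")
        if self.data.isna().any().any():
            raise FormatError("expression table contains missing cells")
        if self.units != "ct" and (self.data.to_numpy() < 0).any():
            raise FormatError(f"negative values not allowed for units {self.units!r}")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise FormatError("duplicate gene or sample labels in expression table")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class Table1Row:
    """One gene of the packaged family table."""

    gene: str
    clade: str
    rgap_locus: str
    rapdb_locus: str
    location: str
    chromosome: str
    size_aa: int
    signal: bool
    gpi: bool
    fl_cdna: bool
    est: bool
    microarray: bool
    mpss: bool


@dataclass(frozen=True)
class Table1Fixture:
    """The packaged 21-gene rice XYLP family table.

    Flags are stored as printed in the source table (check mark = present,
    dash = absent). The chromosome is parsed out of the location string; the
    location string itself is kept verbatim.
    """

    rows: tuple[Table1Row, ...]

    def __post_init__(self) -> None:
        if len(self.rows) != 21:
            raise FormatError(f"family table must have 21 rows, got {len(self.rows)}")

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, gene: str) -> Table1Row:
        for r in self.rows:
            if r.gene == gene:
                return r
        raise KeyError(gene)

    def chromosome_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.rows:
            counts[r.chromosome] = counts.get(r.chromosome, 0) + 1
        return counts

    def expression_evidence_counts(self) -> dict[str, int]:
        """Marginal counts of transcript evidence across the family.

        Returns the number of genes with full-length cDNA or EST support,
        with both, and with EST support only.
        """
        fl_or_est = sum(1 for r in self.rows if r.fl_cdna or r.est)
        fl_and_est = sum(1 for r in self.rows if r.fl_cdna and r.est)
        est_only = sum(1 for r in self.rows if r.est and not r.fl_cdna)
        return {
            "fl_or_est": fl_or_est,
            "fl_and_est": fl_and_est,
            "est_only": est_only,
        }


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file, preserving order.

    Raises :class:`FormatError` on an empty file, duplicate identifiers or
    non-amino-acid characters (other than X), naming the offending record.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, str(rec.seq)))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as single-line-sequence FASTA (lossless round trip)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_alignment(path: str | Path) -> list[tuple[str, str]]:
    """Read a precomputed multiple sequence alignment.

    Accepts aligned FASTA or Clustal format (auto-detected); returns
    ``(id, aligned sequence)`` pairs in file order. Gap characters ``-`` and
    ``.`` are preserved.
    """
    from Bio import AlignIO

    path = Path(path)
    with open(path) as fh:
        head = fh.read(7)
    fmt = "clustal" if head.upper().startswith("CLUSTAL") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    pairs = [(rec.id, str(rec.seq).upper()) for rec in aln]
    ids = [p[0] for p in pairs]
    if len(set(ids)) != len(ids):
        raise FormatError(f"duplicate ids in alignment {path}")
    return pairs


def write_alignment(pairs: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in pairs:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff3(path: str | Path, feature_types: frozenset[str] = frozenset({"gene"})) -> list[GeneLocus]:
    """Read gene features from a GFF3 file into ranked loci.

    Ranks are assigned per chromosome by ascending start coordinate
    (0 = first gene). Coordinates stay 1-based inclusive as in GFF3.
    """
    raw: list[GeneLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in feature_types:
                continue
            attributes = _parse_gff3_attributes(attrs)
            if "ID" not in attributes:
                raise FormatError(f"{path}:{lineno}: gene feature without ID attribute")
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if s > e:
                raise FormatError(
                    f"{path}:{lineno}: start {s} > end {e} for {attributes['ID']!r}"
                )
            raw.append(GeneLocus(attributes["ID"], chrom,
                                 s, e, strand if strand in "+-" else "?"))
    if not raw:
        raise FormatError(f"no gene features found in {path}")
    return rank_loci(raw)


def rank_loci(loci: Iterable[GeneLocus]) -> list[GeneLocus]:
    """Assign per-chromosome ranks by ascending start; returns sorted loci."""
    ordered = sorted(loci, key=lambda g: (g.chromosome, g.start, g.end, g.gene_id))
    out: list[GeneLocus] = []
    current_chrom: str | None = None
    rank = 0
    for g in ordered:
        if g.chromosome != current_chrom:
            current_chrom = g.chromosome
            rank = 0
        out.append(GeneLocus(g.gene_id, g.chromosome, g.start, g.end, g.strand, rank))
        rank += 1
    return out


def write_gff3(loci: Iterable[GeneLocus], path: str | Path, source: str = "xylptools") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in loci:
            fh.write(
                f"{g.chromosome}\t{source}\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand if g.strand in '+-' else '.'}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# TSV/CSV tables
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_expression_table(path: str | Path, units: str,
                          allow_missing: bool = False) -> ExpressionMatrix:
    """Read a gene-by-sample expression table (genes in the first column).

    Missing cells are rejected by default; with ``allow_missing`` they are
    imputed as zero (count/tpm/signal) before validation.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"unreadable expression table {path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"empty expression table {path}")
    if df.isna().any().any():
        if not allow_missing or units == "ct":
            raise FormatError(f"missing cells in expression table {path}")
        df = df.fillna(0.0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric values in expression table {path}") from exc
    return ExpressionMatrix(df, units)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    matrix.data.to_csv(path, sep=sep)


def read_flags(path: str | Path) -> dict[str, AnnotationFlags]:
    """Read a per-protein annotation flag table (TSV/CSV).

    Expected columns: protein_id, has_signal_peptide, has_gpi_anchor,
    n_glycosylation_sites (comma-separated 1-based positions, may be empty).
    """
    df = _read_table(path)
    required = {"protein_id", "has_signal_peptide", "has_gpi_anchor"}
    if not required.issubset(df.columns):
        raise FormatError(f"flag table {path} missing columns {required - set(df.columns)}")
    out: dict[str, AnnotationFlags] = {}
    for _, row in df.iterrows():
        pid = row["protein_id"]
        if pid in out:
            raise FormatError(f"duplicate flags row for protein {pid!r}")
        sites_text = str(row.get("n_glycosylation_sites", "") or "")
        sites = tuple(int(t) for t in sites_text.split(",") if t.strip())
        out[pid] = AnnotationFlags(
            pid,
            _parse_bool(row["has_signal_peptide"]),
            _parse_bool(row["has_gpi_anchor"]),
            sites,
        )
    if not out:
        raise FormatError(f"no flag rows in {path}")
    return out


def write_flags(flags: Mapping[str, AnnotationFlags], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\thas_signal_peptide\thas_gpi_anchor\tn_glycosylation_sites\n")
        for f in flags.values():
            sites = ",".join(str(p) for p in f.n_glycosylation_sites)
            fh.write(f"{f.protein_id}\t{f.has_signal_peptide}\t{f.has_gpi_anchor}\t{sites}\n")


def _parse_bool(value) -> bool:
    text = str(value).strip().lower()
    if text in {"true", "1", "yes", "√"}:
        return True
    if text in {"false", "0", "no", "−", "-", ""}:
        return False
    raise FormatError(f"unparseable boolean {value!r}")


def read_homolog_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read an unordered homolog-pair list (columns gene_a, gene_b)."""
    df = _read_table(path)
    if not {"gene_a", "gene_b"}.issubset(df.columns):
        raise FormatError(f"pair table {path} needs columns gene_a, gene_b")
    pairs = []
    for _, row in df.iterrows():
        if row["gene_a"] == row["gene_b"]:
            raise FormatError(f"self pair {row['gene_a']!r} in {path}")
        pairs.append((row["gene_a"], row["gene_b"]))
    return pairs


def read_duplication_blocks(path: str | Path):
    """Read duplicated-block definitions.

    Expected columns: block_id, chrom_a, start_a, end_a, chrom_b, start_b,
    end_b. Returns :class:`xylptools.duplication.DuplicationBlock` objects.
    """
    from xylptools.duplication import DuplicationBlock

    df = _read_table(path)
    required = {"block_id", "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b"}
    if not required.issubset(df.columns):
        raise FormatError(f"block table {path} missing columns {required - set(df.columns)}")
    blocks = []
    for _, row in df.iterrows():
        blocks.append(DuplicationBlock(
            row["block_id"],
            row["chrom_a"], int(row["start_a"]), int(row["end_a"]),
            row["chrom_b"], int(row["start_b"]), int(row["end_b"]),
        ))
    return blocks


# ---------------------------------------------------------------------------
# packaged family table
# ---------------------------------------------------------------------------

def load_table1_fixture() -> Table1Fixture:
    """Load the packaged 21-gene rice XYLP family table."""
    text = (resources.files("xylptools") / "data" / "table1.tsv").read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    rows = []
    for line in lines[1:]:
        rec = dict(zip(header, line.split("\t")))
        chromosome = rec["location"].split(":", 1)[0]
        rows.append(Table1Row(
            gene=rec["gene"],
            clade=rec["clade"],
            rgap_locus=rec["rgap_locus"],
            rapdb_locus=rec["rapdb_locus"],
            location=rec["location"],
            chromosome=chromosome,
            size_aa=int(rec["size_aa"]),
            signal=_parse_bool(rec["signal"]),
            gpi=_parse_bool(rec["gpi"]),
            fl_cdna=_parse_bool(rec["fl_cdna"]),
            est=_parse_bool(rec["est"]),
            microarray=_parse_bool(rec["microarray"]),
            mpss=_parse_bool(rec["mpss"]),
        ))
    return Table1Fixture(tuple(rows))


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON configuration mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} must be a mapping")
    return cfg
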