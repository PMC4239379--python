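"""Digital-expression rules: EST specificity, MPSS binning, microarray
normalization and clustering, the fold-change screen, and qPCR
standard-curve quantification.

These are deliberately simple, printed rules rather than statistical
models: a gene is tissue-specific when one tissue holds more than half of
its EST counts; MPSS abundance bins at 50 and 500 tpm; microarray signals
are divided by a mean and logged before hierarchical clustering; a stress
response is a >= 2-fold change in either direction; and qPCR quantities
come from a linear standard curve of Ct against log10 template quantity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from xylptools.io import ExpressionMatrix, FormatError

logger = logging.getLogger("xylptools")

MPSS_LOW_BOUND = 50.0       # max tpm < 50  -> low
MPSS_STRONG_BOUND = 500.0   # max tpm > 500 -> strong; 50..500 -> moderate

DEFAULT_FOLD_THRESHOLD = 2.0
STANDARD_DILUTIONS = (1.0, 3.0, 9.0, 27.0)


@dataclass(frozen=True)
class EstSpecificityResult:
    gene_id: str
    counts: Mapping[str, int]
    total: int
    specific: bool
    specific_tissue: Optional[str] = None


@dataclass(frozen=True)
class MpssClass:
    gene_id: str
    tpm: Mapping[str, float]
    gene_class: str  # low | moderate | strong
    statistic: float


@dataclass
class NormalizedMatrix:
    """Gene-by-sample matrix of log expression ratios."""

    log_ratios: pd.DataFrame
    log_base: float
    mode: str  # global-mean | gene-mean


@dataclass
class ClusterTree:
    """A dendrogram over genes from agglomerative clustering."""

    linkage_matrix: np.ndarray
    gene_ids: tuple[str, ...]
    method: str
    metric: str

    def __post_init__(self) -> None:
        heights = self.linkage_matrix[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")

    def to_newick(self) -> str:
        root = hierarchy.to_tree(self.linkage_matrix)

        def render(node) -> str:
            if node.is_leaf():
                return self.gene_ids[node.id]
            left, right = node.get_left(), node.get_right()
            return (f"({render(left)}:{node.dist - left.dist:.6g},"
                    f"{render(right)}:{node.dist - right.dist:.6g})")

        return render(root) + ";"

    def flat_clusters(self, n_clusters: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")
        return dict(zip(self.gene_ids, (int(x) for x in labels)))


@dataclass(frozen=True)
class StandardCurve:
    """A qPCR calibration line: mean Ct regressed on log10(quantity)."""

    gene_id: str
    quantities: tuple[float, ...]
    mean_cts: tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    valid: bool

    def quantity(self, ct: float) -> float:
        """Template quantity implied by a Ct on this curve."""
        if not self.valid:
            raise ValueError(f"standard curve for {self.gene_id!r} is invalid "
                             "(non-negative slope)")
        return float(10.0 ** ((ct - self.intercept) / self.slope))


@dataclass(frozen=True)
class RelativeExpression:
    gene_id: str
    sample_id: str
    target_quantity: float
    reference_quantity: float
    relative_level: float


@dataclass(frozen=True)
class FoldChangeResult:
    gene_id: str
    condition: str
    control_value: float
    treated_value: float
    fold_change: float
    flagged: bool
    direction: str  # up | down | none


# ---------------------------------------------------------------------------
# EST specificity
# ---------------------------------------------------------------------------

def est_specificity(counts: ExpressionMatrix) -> list[EstSpecificityResult]:
    """Flag genes whose EST counts in one tissue exceed half their total.

    The comparison is strict (a tissue holding exactly half is not
    specific), so at most one tissue can qualify. Genes with zero total are
    non-specific.
    """
    if counts.units != "count":
        raise FormatError(f"est_specificity needs count units, got {counts.units!r}")
    values = counts.data.to_numpy()
    if not np.allclose(values, np.round(values)):
        raise FormatError("EST counts must be integers")
    out: list[EstSpecificityResult] = []
    for gene, row in counts.data.iterrows():
        total = int(row.sum())
        best_tissue = row.idxmax()
        specific = total > 0 and row[best_tissue] > total / 2.0
        out.append(EstSpecificityResult(
            gene_id=str(gene),
            counts={t: int(v) for t, v in row.items()},
            total=total,
            specific=bool(specific),
            specific_tissue=str(best_tissue) if specific else None,
        ))
    return out


# ---------------------------------------------------------------------------
# MPSS binning
# ---------------------------------------------------------------------------

def mpss_classify(tpm: ExpressionMatrix, statistic: str = "max") -> list[MpssClass]:
    """Bin genes into low / moderate / strong MPSS expression classes.

    The classifying statistic is the maximum tpm across libraries by
    default (``statistic="mean"`` is available). Boundaries: below 50 tpm
    is low, 50-500 tpm inclusive is moderate, above 500 tpm is strong.
    """
    if tpm.units != "tpm":
        raise FormatError(f"mpss_classify needs tpm units, got {tpm.units!r}")
    if statistic not in {"max", "mean"}:
        raise ValueError(f"unknown statistic {statistic!r}")
    out: list[MpssClass] = []
    for gene, row in tpm.data.iterrows():
        stat = float(row.max() if statistic == "max" else row.mean())
        if stat < MPSS_LOW_BOUND:
            cls = "low"
        elif stat <= MPSS_STRONG_BOUND:
            cls = "moderate"
        else:
            cls = "strong"
        out.append(MpssClass(str(gene), {t: float(v) for t, v in row.items()},
                             cls, stat))
    return out


# ---------------------------------------------------------------------------
# microarray normalization and clustering
# ---------------------------------------------------------------------------

def normalize_microarray(signal: ExpressionMatrix, mode: str = "global-mean",
                         log_base: float = 2.0) -> NormalizedMatrix:
    """Divide signals by a mean and take logarithms.

    ``global-mean`` divides every cell by the arithmetic grand mean of the
    whole matrix; ``gene-mean`` divides each cell by its gene's geometric
    row mean, which is exactly mean-centering each gene's log values (the
    per-gene centering of Cluster-style workflows). Signals must be
    strictly positive.
    """
    if signal.units != "signal":
        raise FormatError(f"normalize_microarray needs signal units, got {signal.units!r}")
    if mode not in {"global-mean", "gene-mean"}:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if log_base <= 1.0:
        raise ValueError("log base must exceed 1")
    values = signal.data.to_numpy(dtype=float)
    if (values <= 0).any():
        raise FormatError("microarray signals must be strictly positive")
    if mode == "global-mean":
        ratios = values / values.mean()
    else:
        geo_mean = np.exp(np.log(values).mean(axis=1, keepdims=True))
        ratios = values / geo_mean
    logged = np.log(ratios) / np.log(log_base)
    frame = pd.DataFrame(logged, index=signal.data.index, columns=signal.data.columns)
    return NormalizedMatrix(frame, log_base, mode)


def hierarchical_cluster(norm: NormalizedMatrix, linkage: str = "average",
                         distance: str = "correlation",
                         fallback_to_euclidean: bool = False) -> ClusterTree:
    """Agglomerative clustering of genes on their log-ratio profiles.

    Defaults: average linkage on 1 - Pearson correlation across samples. A
    gene with zero variance has no defined correlation; that raises unless
    ``fallback_to_euclidean`` switches the whole run to Euclidean distance.
    """
    data = norm.log_ratios.to_numpy(dtype=float)
    if data.shape[0] < 2:
        raise ValueError("clustering needs at least 2 genes")
    metric = distance
    if distance == "correlation":
        variances = data.var(axis=1)
        if np.any(variances == 0):
            if not fallback_to_euclidean:
                flat = [str(g) for g, v in zip(norm.log_ratios.index, variances) if v == 0]
                raise ValueError(
                    "zero-variance gene(s) under correlation distance: "
                    + ", ".join(flat)
                )
            metric = "euclidean"
    condensed = pdist(data, metric=metric)
    Z = hierarchy.linkage(condensed, method=linkage)
    return ClusterTree(Z, tuple(str(g) for g in norm.log_ratios.index),
                       linkage, metric)


# ---------------------------------------------------------------------------
# fold-change screen
# ---------------------------------------------------------------------------

def fold_change_filter(control: ExpressionMatrix, treated: ExpressionMatrix,
                       threshold: float = DEFAULT_FOLD_THRESHOLD) -> list[FoldChangeResult]:
    """Flag genes with at least threshold-fold change in either direction.

    Control and treated matrices must share gene and condition labels; a
    (gene, condition) cell is flagged when treated/control >= threshold or
    <= 1/threshold (boundary inclusive). Zero control values are rejected.
    """
    if threshold <= 1.0:
        raise ValueError("fold-change threshold must exceed 1")
    if list(control.data.index) != list(treated.data.index):
        raise FormatError("control and treated gene sets differ")
    if list(control.data.columns) != list(treated.data.columns):
        raise FormatError("control and treated condition sets differ")
    out: list[FoldChangeResult] = []
    for gene in control.data.index:
        for condition in control.data.columns:
            c = float(control.data.at[gene, condition])
            t = float(treated.data.at[gene, condition])
            if c == 0:
                raise FormatError(f"zero control value for gene {gene!r}, "
                                  f"condition {condition!r}")
            fold = t / c
            up = fold >= threshold
            down = fold <= 1.0 / threshold
            out.append(FoldChangeResult(
                str(gene), str(condition), c, t, fold, up or down,
                "up" if up else ("down" if down else "none"),
            ))
    return out


# ---------------------------------------------------------------------------
# qPCR standard curve
# ---------------------------------------------------------------------------

def fit_standard_curve(ct_by_dilution: Mapping[float, Sequence[float]],
                       gene_id: str = "") -> StandardCurve:
    """Fit a qPCR standard curve from a dilution series.

    Replicate Cts are averaged per dilution level, then mean Ct is
    regressed on log10(quantity). The amplification efficiency is
    10^(-1/slope) - 1 (1.0 means perfect doubling per cycle). A
    non-negative slope marks the curve invalid rather than failing
    silently.
    """
    if len(ct_by_dilution) < 3:
        raise ValueError("a standard curve needs at least 3 dilution levels")
    quantities = sorted(ct_by_dilution)
    if any(q <= 0 for q in quantities):
        raise ValueError("dilution quantities must be positive")
    mean_cts = [float(np.mean(ct_by_dilution[q])) for q in quantities]
    fit = stats.linregress(np.log10(quantities), mean_cts)
    slope, intercept = float(fit.slope), float(fit.intercept)
    valid = slope < 0
    efficiency = float(10.0 ** (-1.0 / slope) - 1.0) if valid else float("nan")
    if not valid:
        logger.warning("standard curve for %r has non-negative slope %.4g",
                       gene_id, slope)
    return StandardCurve(
        gene_id=gene_id,
        quantities=tuple(quantities),
        mean_cts=tuple(mean_cts),
        slope=slope,
        intercept=intercept,
        r_squared=float(fit.rvalue ** 2),
        efficiency=efficiency,
        valid=valid,
    )


def relative_expression(target_curve: StandardCurve, reference_curve: StandardCurve,
                        target_ct: float, reference_ct: float,
                        gene_id: str = "", sample_id: str = "") -> RelativeExpression:
    """Standard-curve quantification normalized to a housekeeping gene.

    Each Ct is converted to a template quantity on its own curve; the
    relative level is target quantity over reference quantity.
    """
    tq = target_curve.quantity(target_ct)
    rq = reference_curve.quantity(reference_ct)
    if rq <= 0:
        raise ValueError("reference quantity must be positive")
    return RelativeExpression(gene_id or target_curve.gene_id, sample_id,
                              tq, rq, tq / rq)
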