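"""Outlier-chip quality control by 1.5-IQR fences on per-chip metrics.

The native metric is relative log expression (RLE): per chip, the median
over genes of the deviation from the gene-wise median across chips.
Externally computed metrics (e.g. probe-level NUSE summaries) can be fed
through the same fence rule via :func:`iqr_flag`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class QCReport:
    metric_name: str
    per_chip_metric: pd.Series
    lower_fence: float
    upper_fence: float
    flagged: set[str] = field(default_factory=set)
    k: float = 1.5


def compute_rle(matrix: ExpressionMatrix) -> pd.Series:
    """Per-chip median relative log expression.

    RLE for chip *s* is ``median_g(x_gs - median_s'(x_gs'))``; chips whose
    expression distribution is globally shifted relative to the cohort
    stand out as large |RLE|.  Requires >= 3 chips so the gene-wise
    medians and the downstream fences are meaningful.
    """
    if matrix.n_samples() < 3:
        raise ValueError("RLE requires at least 3 chips")
    gene_medians = matrix.values.median(axis=1)
    deviations = matrix.values.sub(gene_medians, axis=0)
    return deviations.median(axis=0)


def iqr_flag(metrics: pd.Series | dict, k: float = 1.5, metric_name: str = "RLE") -> QCReport:
    """Flag chips whose metric lies strictly outside Tukey fences.

    Fences are ``Q1 - k*IQR`` and ``Q3 + k*IQR`` with quartiles by linear
    interpolation between order statistics.  Values exactly on a fence are
    kept (strict inequalities), so a constant metric flags nothing.
    """
    metrics = pd.Series(metrics, dtype=float)
    if len(metrics) == 0:
        raise ValueError("no metrics supplied")
    if len(metrics) < 3:
        raise ValueError("IQR fences need at least 3 chips")
    q1, q3 = np.percentile(metrics.to_numpy(), [25.0, 75.0], method="linear")
    iqr = q3 - q1
    lower, upper = q1 - k * iqr, q3 + k * iqr
    flagged = set(metrics.index[(metrics < lower) | (metrics > upper)])
    if flagged:
        log.warning("%s QC flagged %d chip(s): %s", metric_name, len(flagged), sorted(flagged))
    return QCReport(
        metric_name=metric_name,
        per_chip_metric=metrics,
        lower_fence=float(lower),
        upper_fence=float(upper),
        flagged=flagged,
        k=k,
    )


def apply_qc(matrix: ExpressionMatrix, report: QCReport) -> ExpressionMatrix:
    """Drop flagged chips from the matrix.

    Refuses to discard chips when the result would be unusable downstream:
    fewer than 2 tumors, or a cohort that had normal references but would
    lose all of them.
    """
    unknown = report.flagged - set(matrix.samples)
    if unknown:
        raise KeyError(f"flagged chips not present in matrix: {sorted(unknown)}")
    if not report.flagged:
        return matrix
    kept_tumors = [s for s in matrix.tumor_ids if s not in report.flagged]
    kept_normals = [s for s in matrix.normal_ids if s not in report.flagged]
    if len(kept_tumors) < 2:
        raise ValueError("QC would leave fewer than 2 tumors")
    if matrix.normal_ids and not kept_normals:
        raise ValueError("QC would discard every reference (normal) chip")
    log.warning("discarding %d chip(s): %s", len(report.flagged), sorted(report.flagged))
    return matrix.drop_samples(sorted(report.flagged))
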