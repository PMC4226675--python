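"""Reference-based Z-scores, summed-Z signature scores, and stratification.

Tumor expression is scored against the normal-prostate reference: for each
gene, Z = (x - mean_ref) / sd_ref (sd with denominator n-1).  A signature
score for a tumor is the sum of its Z-scores over the signature's genes.
Two stratification rules are provided: extreme summed-Z groups (the
"high / low AR signature" classification) and a dual-threshold rule on two
genes (the "high / low GSK-3" classification, Z of both isoforms > 0.5 or
both < -0.5).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .containers import NORMAL, ExpressionMatrix, GeneSet, SignatureScores, StratificationLabels

log = logging.getLogger(__name__)


def zscore_vs_reference(matrix: ExpressionMatrix, reference_role: str = NORMAL) -> pd.DataFrame:
    """Gene x tumor Z-score matrix against the reference samples.

    Genes whose reference standard deviation is zero carry no information
    on that scale and are dropped with a warning.  If the matrix has no
    samples in ``reference_role``, the full-cohort mean/sd is used instead
    and a loud warning is emitted (the scores are then relative to the
    cohort, not to normal tissue).
    """
    ref_ids = [s for s in matrix.samples if matrix.roles[s] == reference_role]
    tumor_ids = matrix.tumor_ids
    if not ref_ids:
        log.warning(
            "no %r reference samples: falling back to cohort mean/sd; "
            "Z-scores are relative to the whole cohort, not normal tissue",
            reference_role,
        )
        ref_ids = list(matrix.samples)
    if len(ref_ids) < 2:
        raise ValueError("need at least 2 reference samples to estimate sd")
    ref = matrix.values[ref_ids]
    mean = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        dropped = matrix.genes[degenerate].tolist()
        log.warning("dropping %d gene(s) with zero reference sd: %s", len(dropped), dropped[:10])
    keep = ~degenerate
    z = matrix.values.loc[keep, tumor_ids].sub(mean[keep], axis=0).div(sd[keep], axis=0)
    return z


def summed_zscore(z: pd.DataFrame, signature: GeneSet) -> SignatureScores:
    """Per-tumor sum of Z-scores over the signature genes present in ``z``."""
    present = [g for g in signature.genes if g in z.index]
    missing = [g for g in signature.genes if g not in z.index]
    if not present:
        raise ValueError(f"no gene of signature {signature.name!r} present in the Z matrix")
    if missing:
        log.warning("signature %r: %d gene(s) absent from matrix", signature.name, len(missing))
    scores = z.loc[present].sum(axis=0)
    return SignatureScores(
        signature=signature.name,
        per_sample_score=scores,
        n_genes_used=len(present),
        missing_genes=missing,
    )


def stratify_extremes(scores: SignatureScores, fraction: float = 1 / 3) -> StratificationLabels:
    """Label the top/bottom ``fraction`` of tumors by summed Z as high/low.

    ``k = ceil(fraction * n)`` tumors enter each group (capped at floor(n/2)
    so the groups never overlap); the rest are unclassified.  Ties at the
    cut are broken by sample id order and logged.
    """
    if not (0 < fraction <= 0.5):
        raise ValueError("fraction must be in (0, 0.5]")
    s = scores.per_sample_score
    n = len(s)
    if n < 4:
        raise ValueError("need at least 4 scored tumors to stratify")
    k = min(math.ceil(fraction * n), n // 2)
    # one stable ranking (score desc, then sample id): high = first k, low = last k;
    # k <= n//2 keeps the groups disjoint even under heavy ties
    by_desc = s.loc[sorted(s.index)].sort_values(ascending=False, kind="mergesort")
    high = list(by_desc.index[:k])
    low = list(by_desc.index[n - k:])
    if by_desc.iloc[k - 1] == by_desc.iloc[k] or by_desc.iloc[n - k] == by_desc.iloc[n - k - 1]:
        log.warning("tie at a stratification cut broken by sample id order")
    labels = pd.Series("unclassified", index=s.index)
    labels.loc[high] = "high"
    labels.loc[low] = "low"
    return StratificationLabels(
        per_sample_label=labels,
        rule=f"extremes(fraction={fraction:g}, k={k}, n={n}, stat=summed_z[{scores.signature}])",
    )


def classify_dual_threshold(
    z: pd.DataFrame,
    gene_a: str = "GSK3A",
    gene_b: str = "GSK3B",
    hi: float = 0.5,
    lo: float = -0.5,
) -> StratificationLabels:
    """high iff Z of both genes > ``hi``; low iff both < ``lo``; else unclassified.

    Inequalities are strict, so a tumor with Z exactly at a threshold is
    unclassified.
    """
    gene_a, gene_b = gene_a.upper(), gene_b.upper()
    for g in (gene_a, gene_b):
        if g not in z.index:
            raise KeyError(f"gene {g!r} absent from Z matrix")
    za, zb = z.loc[gene_a], z.loc[gene_b]
    labels = pd.Series("unclassified", index=z.columns)
    labels[(za > hi) & (zb > hi)] = "high"
    labels[(za < lo) & (zb < lo)] = "low"
    return StratificationLabels(
        per_sample_label=labels,
        rule=f"dual_threshold({gene_a},{gene_b}, hi={hi:g}, lo={lo:g})",
    )
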