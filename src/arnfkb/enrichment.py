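"""Weighted running-sum gene-set enrichment with a phenotype permutation null.

Genes are ranked by a two-sample pooled-variance t statistic between the
"high" and "low" strata.  The enrichment score (ES) of a gene set is the
signed maximum deviation of a running sum that increments at set members
(proportionally to |t|^weight) and decrements elsewhere.  Significance
comes from re-shuffling the phenotype labels (preserving group sizes),
re-ranking, and re-scoring: p is the add-one-smoothed fraction of
same-sign null scores at least as extreme as the observed one, and NES is
the observed ES divided by the mean magnitude of the same-sign null
scores.  The leading edge is the set members between the list end and the
running-sum extremum, in the direction of the enrichment; for a negative
ES in a high-vs-low contrast it is the "repressed target" subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSet, StratificationLabels

log = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Genes ordered best-to-worst by a ranking statistic."""

    genes: list[str]
    metric: pd.Series  # gene -> t, in ranked order
    group_sizes: tuple[int, int]


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    running_sum: np.ndarray
    leading_edge: GeneSet | None = None
    direction: int = 0
    p_nominal: float | None = None
    nes: float | None = None
    n_permutations: int = 0
    seed: int | None = None


def _t_stats(values: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per row (group A minus group B)."""
    a, b = values[:, idx_a], values[:, idx_b]
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    return t


def rank_by_t(matrix: ExpressionMatrix, labels: StratificationLabels) -> RankedList:
    """Rank genes by the high-minus-low pooled t statistic, descending.

    Genes with zero variance in both groups have an undefined statistic
    and are dropped with a warning.  Exact ties in t are broken by gene
    symbol, ascending, for reproducibility.
    """
    high = [s for s in labels.high_ids if s in set(matrix.samples)]
    low = [s for s in labels.low_ids if s in set(matrix.samples)]
    if len(high) < 2 or len(low) < 2:
        raise ValueError("each group needs at least 2 samples for a t statistic")
    cols = {s: i for i, s in enumerate(matrix.samples)}
    t = _t_stats(
        matrix.values.to_numpy(float),
        np.array([cols[s] for s in high]),
        np.array([cols[s] for s in low]),
    )
    finite = np.isfinite(t)
    if not finite.all():
        dropped = matrix.genes[~finite].tolist()
        log.warning("dropping %d zero-variance gene(s) from ranking: %s", len(dropped), dropped[:10])
    series = pd.Series(t[finite], index=matrix.genes[finite])
    # stable mergesort over symbol-sorted genes => ties broken by symbol asc
    ordered = series.loc[sorted(series.index)].sort_values(ascending=False, kind="mergesort")
    return RankedList(genes=list(ordered.index), metric=ordered, group_sizes=(len(high), len(low)))


def _running_sum(metric: np.ndarray, hits: np.ndarray, weight: float) -> np.ndarray:
    """Running sum along the ranked list: +|t|^w / sum_hits at hits, -1/(N-Nh) at misses."""
    n = metric.size
    n_hits = int(hits.sum())
    w = np.abs(metric) ** weight
    hit_norm = w[hits].sum()
    steps = np.where(hits, np.divide(w, hit_norm, out=np.zeros_like(w), where=hit_norm > 0),
                     -1.0 / (n - n_hits))
    if hit_norm == 0:  # all hit weights zero (e.g. weight>0 with t==0): fall back to equal steps
        steps = np.where(hits, 1.0 / n_hits, -1.0 / (n - n_hits))
    return np.cumsum(steps)


def _es_from_running(running: np.ndarray) -> tuple[float, int]:
    """Signed maximum deviation and its position (positive wins exact ties)."""
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        # clip guards against cumsum round-off pushing |es| past 1
        return float(np.clip(running[i_max], -1.0, 1.0)), i_max
    return float(np.clip(running[i_min], -1.0, 1.0)), i_min


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, weight: float = 1.0, min_overlap: int = 1
) -> EnrichmentResult:
    """ES, running sum and leading edge of ``gene_set`` on a ranked list."""
    genes = np.asarray(ranked.genes)
    hits = np.isin(genes, np.asarray(gene_set.genes, dtype=object))
    n_hits = int(hits.sum())
    if n_hits < min_overlap or n_hits < 1:
        raise ValueError(
            f"set {gene_set.name!r} overlaps the ranked list in {n_hits} gene(s); "
            f"minimum is {max(min_overlap, 1)}"
        )
    if n_hits == genes.size:
        raise ValueError("gene set covers the whole ranked list; ES undefined")
    running = _running_sum(ranked.metric.to_numpy(float), hits, weight)
    es, pos = _es_from_running(running)
    if es >= 0:
        edge = [g for g, h in zip(genes[: pos + 1], hits[: pos + 1]) if h]
    else:
        edge = [g for g, h in zip(genes[pos:], hits[pos:]) if h]
    leading = GeneSet(
        name=f"{gene_set.name}__leading_edge",
        genes=tuple(edge),
        description=f"leading edge (es={es:.4f})",
    )
    return EnrichmentResult(
        set_name=gene_set.name,
        es=es,
        running_sum=running,
        leading_edge=leading,
        direction=int(np.sign(es)) if es != 0 else 0,
    )


def permutation_test(
    matrix: ExpressionMatrix,
    labels: StratificationLabels,
    gene_set: GeneSet,
    n_permutations: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    min_overlap: int = 5,
) -> EnrichmentResult:
    """Observed ES plus phenotype-permutation p-value and NES.

    Null scores come from ``n_permutations`` independent reshuffles of the
    high/low labels over the pooled high+low samples, preserving group
    sizes.  p = (1 + #{same-sign null >= observed in magnitude}) /
    (1 + #{same-sign null}); NES = es / mean(|same-sign null es|).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    observed_rank = rank_by_t(matrix, labels)
    observed = enrichment_score(observed_rank, gene_set, weight, min_overlap)

    high = labels.high_ids
    low = labels.low_ids
    pool = high + low
    cols = {s: i for i, s in enumerate(matrix.samples)}
    pool_idx = np.array([cols[s] for s in pool])
    n_high = len(high)
    values = matrix.values.to_numpy(float)
    genes = np.asarray(matrix.genes)
    set_arr = np.asarray(gene_set.genes, dtype=object)

    rng = np.random.default_rng(seed)
    null_es = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(pool_idx)
        t = _t_stats(values, perm[:n_high], perm[n_high:])
        finite = np.isfinite(t)
        t_f, genes_f = t[finite], genes[finite]
        order = np.argsort(-t_f, kind="stable")
        hits = np.isin(genes_f[order], set_arr)
        running = _running_sum(t_f[order], hits, weight)
        null_es[i], _ = _es_from_running(running)

    es = observed.es
    same_sign = null_es > 0 if es >= 0 else null_es < 0
    m = int(same_sign.sum())
    if m == 0:
        log.warning("degenerate permutation null: no same-sign scores; p set to 1/(n+1)")
        p = 1.0 / (n_permutations + 1)
        nes = None
    else:
        extreme = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
        p = (1 + extreme) / (1 + m)
        nes = float(es / np.abs(null_es[same_sign]).mean())
    observed.p_nominal = float(p)
    observed.nes = nes
    observed.n_permutations = n_permutations
    observed.seed = seed
    return observed


def derive_repressed_targets(result: EnrichmentResult, name: str = "AR_repressed_targets") -> GeneSet:
    """Leading edge of a negative enrichment as a named, exportable gene set.

    The negative leading edge in a high-vs-low contrast collects the set
    members depleted in the "high" group — e.g. NF-kB targets repressed in
    high-AR-signature tumors.
    """
    if result.es >= 0:
        raise ValueError(
            "enrichment is non-negative; repressed targets come from a negative "
            "enrichment — run the opposite contrast"
        )
    if result.leading_edge is None:
        raise ValueError("result carries no leading edge")
    return GeneSet(
        name=name,
        genes=result.leading_edge.genes,
        description=f"negative leading edge of {result.set_name} (es={result.es:.4f})",
    )
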