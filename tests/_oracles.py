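"""Independent brute-force oracles used to check the package's fast paths.

Everything here is deliberately naive (explicit loops, textbook formulas)
and shares no code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def brute_running_sum(metrics, genes, set_genes, weight=1.0):
    """Two-loop weighted running sum along a ranked gene list."""
    set_genes = {g.upper() for g in set_genes}
    hits = [g in set_genes for g in genes]
    n = len(genes)
    n_hits = sum(hits)
    denom_hit = sum(abs(m) ** weight for m, h in zip(metrics, hits) if h)
    running = []
    total = 0.0
    for m, h in zip(metrics, hits):
        if h:
            total += (abs(m) ** weight) / denom_hit if denom_hit > 0 else 1.0 / n_hits
        else:
            total -= 1.0 / (n - n_hits)
        running.append(total)
    return running


def brute_es(metrics, genes, set_genes, weight=1.0):
    running = brute_running_sum(metrics, genes, set_genes, weight)
    best = 0.0
    for value in running:
        if abs(value) > abs(best) or (abs(value) == abs(best) and value > best):
            best = value
    return best


def brute_rle(values: np.ndarray) -> list[float]:
    """Nested-loop per-chip median relative log expression."""
    n_genes, n_chips = values.shape
    gene_medians = [float(np.median(values[g, :])) for g in range(n_genes)]
    out = []
    for s in range(n_chips):
        deviations = [values[g, s] - gene_medians[g] for g in range(n_genes)]
        out.append(float(np.median(deviations)))
    return out


def brute_zscores(values: np.ndarray, ref_cols, tumor_cols) -> np.ndarray:
    """Per-gene loop Z-scores against the reference columns (sd with n-1)."""
    out = np.empty((values.shape[0], len(tumor_cols)))
    for g in range(values.shape[0]):
        ref = [values[g, c] for c in ref_cols]
        m = sum(ref) / len(ref)
        sd = math.sqrt(sum((x - m) ** 2 for x in ref) / (len(ref) - 1))
        for j, c in enumerate(tumor_cols):
            out[g, j] = (values[g, c] - m) / sd
    return out


def brute_t(values: np.ndarray, cols_a, cols_b) -> list[float]:
    """Textbook pooled-variance two-sample t per gene (A minus B)."""
    out = []
    for g in range(values.shape[0]):
        a = [values[g, c] for c in cols_a]
        b = [values[g, c] for c in cols_b]
        na, nb = len(a), len(b)
        ma, mb = sum(a) / na, sum(b) / nb
        va = sum((x - ma) ** 2 for x in a) / (na - 1)
        vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        out.append((ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb)))
    return out


def product_limit(times, events):
    """Hand Kaplan-Meier table: returns [(event_time, S(t))]."""
    order = sorted(range(len(times)), key=lambda i: times[i])
    times = [times[i] for i in order]
    events = [events[i] for i in order]
    s = 1.0
    out = []
    distinct = sorted({t for t, e in zip(times, events) if e == 1})
    for t in distinct:
        at_risk = sum(1 for x in times if x >= t)
        deaths = sum(1 for x, e in zip(times, events) if x == t and e == 1)
        s *= 1.0 - deaths / at_risk
        out.append((t, s))
    return out


def logrank_chi_square(times, events, groups):
    """Textbook two-group log-rank: sum(O - E) over event times, squared over V."""
    labels = sorted(set(groups))
    assert len(labels) == 2
    g0 = labels[0]
    o_minus_e = 0.0
    var = 0.0
    for t in sorted({t for t, e in zip(times, events) if e == 1}):
        n = sum(1 for x in times if x >= t)
        n0 = sum(1 for x, g in zip(times, groups) if x >= t and g == g0)
        d = sum(1 for x, e in zip(times, events) if x == t and e == 1)
        d0 = sum(1 for x, e, g in zip(times, events, groups) if x == t and e == 1 and g == g0)
        o_minus_e += d0 - d * n0 / n
        if n > 1:
            var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var
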