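"""Quantitation of protein/DNA binding-array membranes and qPCR Ct tables.

Membranes: spotted transcription-factor binding-site probes, read out as
spot intensities.  Negative-control spots define the blank; the
positive-control row defines a per-membrane scale, so normalized signals
are comparable across membranes and exposures:

    signal(site) = mean over duplicate spots of max(raw - blank, 0) / (pos_mean - blank)

qPCR: relative quantification by the delta-delta-Ct method against a
housekeeping reference gene (36B4 by default), with replicate standard
deviations propagated in quadrature and reported as a fold-change range
2^-(ddCt +/- s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

NEGATIVE = "negative_control"
POSITIVE = "positive_control"


@dataclass
class TFArrayGrid:
    """One membrane: spot intensities plus control/site annotations."""

    membrane_id: str
    condition: str
    intensities: np.ndarray  # rows x cols, arbitrary units >= 0
    annotations: dict[tuple[int, int], str]  # (row, col) -> site name | control label
    saturation_ceiling: float | None = None

    def __post_init__(self) -> None:
        nr, nc = self.intensities.shape
        for (r, c) in self.annotations:
            if not (0 <= r < nr and 0 <= c < nc):
                raise ValueError(f"annotation at ({r},{c}) outside {nr}x{nc} grid")
        labels = list(self.annotations.values())
        if labels.count(NEGATIVE) < 1 or labels.count(POSITIVE) < 2:
            raise ValueError("membrane needs >= 1 negative and >= 2 positive control spots")

    def spots(self, label: str) -> np.ndarray:
        return np.array([self.intensities[pos] for pos, lab in self.annotations.items() if lab == label])


@dataclass
class CtTable:
    """Long-format qPCR Ct replicates with a designated reference gene."""

    data: pd.DataFrame  # columns: condition, gene, ct
    reference_gene: str = "36B4"
    control_condition: str = "control"

    def __post_init__(self) -> None:
        need = {"condition", "gene", "ct"}
        if not need <= set(self.data.columns):
            raise ValueError(f"Ct table needs columns {sorted(need)}")
        counts = self.data.groupby(["condition", "gene"])["ct"].count()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ValueError(f"need >= 2 replicates per (condition, gene): {bad}")
        for cond in self.data["condition"].unique():
            genes = set(self.data.loc[self.data["condition"] == cond, "gene"])
            if self.reference_gene not in genes:
                raise ValueError(f"reference gene {self.reference_gene!r} missing for {cond!r}")


def quantify_membrane(grid: TFArrayGrid) -> pd.Series:
    """Blank-subtract, clamp at zero, scale by the positive-control row.

    Raises when the blank-subtracted positive-control mean is not positive
    (saturated or failed membrane), or when a saturation ceiling is set
    and more than 5% of spots reach it.
    """
    if grid.saturation_ceiling is not None:
        frac = float((grid.intensities >= grid.saturation_ceiling).mean())
        if frac > 0.05:
            raise ValueError(f"{frac:.1%} of spots saturated; select a lower exposure")
    blank = float(grid.spots(NEGATIVE).mean())
    scale = float(grid.spots(POSITIVE).mean()) - blank
    if scale <= 0:
        raise ValueError("positive-control mean does not exceed blank; membrane unusable")
    per_site: dict[str, list[float]] = {}
    for pos, label in grid.annotations.items():
        if label in (NEGATIVE, POSITIVE):
            continue
        raw = float(grid.intensities[pos])
        per_site.setdefault(label, []).append(max(raw - blank, 0.0) / scale)
    sites = sorted(per_site)
    return pd.Series({s: float(np.mean(per_site[s])) for s in sites}, name=grid.membrane_id)


def compare_conditions(
    signals_by_condition: dict[str, list[pd.Series]], control: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-site condition-vs-control ratios with two-sample t-tests.

    ``signals_by_condition`` maps a condition label to the per-membrane
    normalized signal Series from :func:`quantify_membrane` (>= 2
    membranes per condition).  Sites with zero control mean get a missing
    ratio.  Rows: site, condition, mean, sd, control_mean, ratio, p_value,
    significant.
    """
    if control not in signals_by_condition:
        raise KeyError(f"control condition {control!r} absent")
    for cond, membranes in signals_by_condition.items():
        if len(membranes) < 2:
            raise ValueError(f"condition {cond!r} has {len(membranes)} membrane(s); need >= 2")
    ctrl = pd.concat(signals_by_condition[control], axis=1)
    rows = []
    for cond, membranes in signals_by_condition.items():
        if cond == control:
            continue
        data = pd.concat(membranes, axis=1)
        for site in data.index:
            x = data.loc[site].to_numpy(float)
            y = ctrl.loc[site].to_numpy(float) if site in ctrl.index else np.array([])
            cm = float(y.mean()) if y.size else np.nan
            ratio = float(x.mean() / cm) if y.size and cm > 0 else np.nan
            if y.size and (np.ptp(x) > 0 or np.ptp(y) > 0):
                p = float(stats.ttest_ind(x, y, equal_var=True).pvalue)
            else:
                p = 1.0 if y.size else np.nan
            rows.append(
                {
                    "site": site,
                    "condition": cond,
                    "mean": float(x.mean()),
                    "sd": float(x.std(ddof=1)),
                    "control_mean": cm,
                    "ratio": ratio,
                    "p_value": p,
                    "significant": bool(p < alpha) if np.isfinite(p) else False,
                }
            )
    return pd.DataFrame(rows).set_index(["site", "condition"])


def ddct_fold_change(table: CtTable) -> pd.DataFrame:
    """Delta-delta-Ct fold changes relative to the control condition.

    Per condition and gene: dCt = mean(Ct_gene) - mean(Ct_ref);
    ddCt = dCt - dCt_control; fold = 2^-ddCt.  Replicate sds propagate as
    s = sqrt(s_gene^2 + s_ref^2) (the treated condition's), giving the
    range [2^-(ddCt+s), 2^-(ddCt-s)].  The control condition has fold 1
    by construction.
    """
    d = table.data
    if table.control_condition not in set(d["condition"]):
        raise ValueError(f"control condition {table.control_condition!r} absent from table")
    stats_df = d.groupby(["condition", "gene"])["ct"].agg(["mean", "std"])
    rows = []
    ref = table.reference_gene
    ctrl_dct: dict[str, float] = {}
    for (cond, gene), row in stats_df.iterrows():
        if gene == ref:
            continue
        ref_row = stats_df.loc[(cond, ref)]
        dct = float(row["mean"] - ref_row["mean"])
        s = float(np.sqrt(row["std"] ** 2 + ref_row["std"] ** 2))
        rows.append({"condition": cond, "gene": gene, "delta_ct": dct, "sd_delta_ct": s})
        if cond == table.control_condition:
            ctrl_dct[gene] = dct
    out = pd.DataFrame(rows)
    missing = set(out["gene"]) - set(ctrl_dct)
    if missing:
        raise ValueError(f"genes missing from control condition: {sorted(missing)}")
    out["ddct"] = out.apply(lambda r: r["delta_ct"] - ctrl_dct[r["gene"]], axis=1)
    out["fold"] = 2.0 ** (-out["ddct"])
    out["fold_low"] = 2.0 ** (-(out["ddct"] + out["sd_delta_ct"]))
    out["fold_high"] = 2.0 ** (-(out["ddct"] - out["sd_delta_ct"]))
    return out.set_index(["condition", "gene"])
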