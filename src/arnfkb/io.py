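"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel as TSV with a leading ``gene`` column and one
column per sample id; sample metadata as TSV with columns ``sample_id``,
``role``, ``time_months``, ``event``; gene sets as standard GMT
(name TAB description TAB gene ...).  All writers round-trip with the
corresponding readers.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSet

log = logging.getLogger(__name__)


def read_expression_tsv(path, roles: pd.Series | None = None) -> ExpressionMatrix:
    """Read a gene x sample TSV; duplicate gene rows collapse to max variance.

    ``roles`` maps sample id -> tumor/normal; absent roles default to
    tumor.  Non-numeric cells (including NA) are an error that names the
    offending gene and sample.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2 or raw.columns[0] != "gene":
        raise ValueError(f"{path}: expected a 'gene' first column plus sample columns")
    if raw.shape[0] == 0:
        raise ValueError(f"{path}: empty matrix")
    raw = raw.set_index("gene")
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            gene = raw.index[bad][0]
            cell = raw.loc[gene, col]
            raise ValueError(f"{path}: non-numeric cell {cell!r} at gene {gene!r}, sample {col!r}")
        values[col] = converted.to_numpy()
    if values.index.duplicated().any():
        dups = values.index[values.index.duplicated()].unique().tolist()
        log.warning("%s: collapsing %d duplicated gene symbol(s) to max-variance row: %s",
                    path, len(dups), dups[:10])
        variance = values.var(axis=1)
        order = np.argsort(-variance.to_numpy(), kind="stable")
        values = values.iloc[order]
        values = values[~values.index.duplicated(keep="first")]
        values = values.sort_index()
    values.index.name = None
    if roles is None:
        roles = pd.Series("tumor", index=values.columns)
    return ExpressionMatrix(values, roles.reindex(values.columns).fillna("tumor"))


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_metadata_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    need = {"sample_id", "role"}
    if not need <= set(meta.columns):
        raise ValueError(f"{path}: metadata needs columns {sorted(need)}")
    return meta


def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def load_cohort_files(expression_path, metadata_path) -> tuple[ExpressionMatrix, pd.DataFrame]:
    meta = read_metadata_tsv(metadata_path)
    roles = meta.set_index("sample_id")["role"]
    return read_expression_tsv(expression_path, roles=roles), meta


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file into gene sets (genes upper-cased, de-duplicated)."""
    sets: list[GeneSet] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} field(s); need >= 3")
            sets.append(GeneSet(name=fields[0], genes=tuple(fields[2:]), description=fields[1]))
    if not sets:
        log.warning("%s: empty GMT file", path)
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description or "na", *s.genes]) + "\n")


def write_truth_json(truth: dict, path) -> None:
    out = {k: v for k, v in truth.items() if k != "config"}
    cfg = truth.get("config")
    if cfg is not None:
        out["config"] = {k: list(v) if isinstance(v, tuple) else v for k, v in cfg.__dict__.items()}
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)


def write_tfarray(grid, tsv_path, layout_path) -> None:
    """Write a membrane as a (row, column, intensity) TSV plus a layout JSON."""
    nr, nc = grid.intensities.shape
    rows = [
        {"row": r, "column": c, "intensity": float(grid.intensities[r, c])}
        for r in range(nr)
        for c in range(nc)
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    layout = {
        "membrane_id": grid.membrane_id,
        "condition": grid.condition,
        "n_rows": nr,
        "n_cols": nc,
        "annotations": {f"{r},{c}": label for (r, c), label in grid.annotations.items()},
        "saturation_ceiling": grid.saturation_ceiling,
    }
    with open(layout_path, "w") as fh:
        json.dump(layout, fh, indent=2, sort_keys=True)


def read_tfarray(tsv_path, layout_path):
    """Read a membrane written by :func:`write_tfarray`."""
    from .assays import TFArrayGrid

    spots = pd.read_csv(tsv_path, sep="\t")
    with open(layout_path) as fh:
        layout = json.load(fh)
    grid = np.zeros((layout["n_rows"], layout["n_cols"]))
    for _, row in spots.iterrows():
        grid[int(row["row"]), int(row["column"])] = float(row["intensity"])
    ann = {}
    for key, label in layout["annotations"].items():
        r, c = key.split(",")
        ann[(int(r), int(c))] = label
    return TFArrayGrid(
        membrane_id=layout["membrane_id"],
        condition=layout["condition"],
        intensities=grid,
        annotations=ann,
        saturation_ceiling=layout.get("saturation_ceiling"),
    )


def read_ct_table(path, reference_gene: str = "36B4", control_condition: str = "control"):
    from .assays import CtTable

    return CtTable(
        data=pd.read_csv(path, sep="\t"),
        reference_gene=reference_gene,
        control_condition=control_condition,
    )


def ar_repressed_nfkb_targets() -> GeneSet:
    """The packaged 29-gene AR-repressed NF-kB target set."""
    ref = resources.files("arnfkb.data").joinpath("ar_repressed_nfkb_targets.gmt")
    with resources.as_file(ref) as p:
        return read_gmt(p)[0]
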