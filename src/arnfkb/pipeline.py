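"""End-to-end orchestration: QC -> scoring -> stratification -> enrichment ->
derived gene set -> survival, with a machine-readable run report.

The chained contrasts mirror the tumor-expression analysis: tumors are
stratified by AR-signature summed Z, the NF-kB target set is tested for
(negative) enrichment in the high-vs-low AR contrast, its negative
leading edge becomes the "AR-repressed NF-kB targets" set, that set is
re-tested in the GSK3 high-vs-low contrast, and finally tumors are split
by the derived set's summed Z for Kaplan-Meier / log-rank analysis at the
configured horizons.  Identical config + seed gives a byte-identical
report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ExpressionMatrix, GeneSet
from .enrichment import derive_repressed_targets, permutation_test
from .io import (
    load_cohort_files,
    read_gmt,
    write_gmt,
)
from .qc import apply_qc, compute_rle, iqr_flag
from .scoring import classify_dual_threshold, stratify_extremes, summed_zscore, zscore_vs_reference
from .survival import group_by_signature, km_estimate, logrank_test

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    expression_tsv: str = ""
    metadata_tsv: str = ""
    gmt: str = ""                       # must contain the AR and NF-kB signatures
    ar_signature: str = "AR_signature"
    nfkb_signature: str = "NFKB_targets"
    qc_enabled: bool = True
    qc_k: float = 1.5
    reference_role: str = "normal"
    stratify_fraction: float = 1 / 3
    gsk3_hi: float = 0.5
    gsk3_lo: float = -0.5
    enrichment_weight: float = 1.0
    n_permutations: int = 1000
    min_set_size: int = 5
    use_packaged_repressed_set: bool = False
    survival_rule: str = "median"
    survival_horizons: tuple[float, ...] = (100.0, 220.0)
    out_dir: str = "results/run"
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.survival_horizons, list):
            cfg.survival_horizons = tuple(cfg.survival_horizons)
        return cfg

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    config: dict
    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)
    complete: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": self.version,
                "stages": self.stages,
                "complete": self.complete,
            },
            indent=2,
            sort_keys=True,
            default=float,
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, reason: Exception):
        super().__init__(f"stage {stage!r} failed: {reason}")
        self.stage = stage


def report_schema() -> dict:
    ref = resources.files("arnfkb.data").joinpath("run_report.schema.json")
    with resources.as_file(ref) as p:
        return json.loads(Path(p).read_text())


def validate_report(report: dict, schema: dict | None = None) -> None:
    """Minimal structural validation against the shipped report schema.

    Checks required keys and primitive types ("object", "string",
    "integer", "number", "boolean") one level into each stage; raises
    ``ValueError`` on the first violation.
    """
    schema = schema or report_schema()

    def check(obj, sch, where="report"):
        typ = sch.get("type")
        mapping = {
            "object": dict, "string": str, "integer": int,
            "number": (int, float), "boolean": bool, "array": list,
        }
        if typ and not isinstance(obj, mapping[typ]):
            raise ValueError(f"{where}: expected {typ}, got {type(obj).__name__}")
        for key in sch.get("required", []):
            if key not in obj:
                raise ValueError(f"{where}: missing required key {key!r}")
        for key, sub in sch.get("properties", {}).items():
            if key in obj:
                check(obj[key], sub, f"{where}.{key}")

    check(report, schema)


def analyze_cohort(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    ar_set: GeneSet,
    nfkb_set: GeneSet,
    config: PipelineConfig,
    out_dir: Path | None = None,
) -> RunReport:
    """Run the full chained analysis on an in-memory cohort."""
    report = RunReport(
        config=asdict(config), config_hash=config.hash(), seed=config.seed, version=__version__
    )
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - stage name must reach the caller
            report.stages[name] = {"error": str(exc), "status": "INCOMPLETE"}
            if out_dir is not None:
                (out_dir / "run_report.json").write_text(report.to_json())
            raise StageError(name, exc) from exc

    # --- QC ---------------------------------------------------------------
    def qc_stage():
        if not config.qc_enabled:
            return matrix, {"enabled": False, "discarded": []}
        rle = compute_rle(matrix)
        qc = iqr_flag(rle, k=config.qc_k, metric_name="RLE")
        cleaned = apply_qc(matrix, qc)
        return cleaned, {
            "enabled": True,
            "metric": "RLE",
            "k": config.qc_k,
            "lower_fence": qc.lower_fence,
            "upper_fence": qc.upper_fence,
            "discarded": sorted(qc.flagged),
        }

    cleaned, qc_summary = run_stage("chip_qc", qc_stage)
    report.stages["chip_qc"] = qc_summary

    # --- Z-scores and AR stratification ------------------------------------
    def score_stage():
        z = zscore_vs_reference(cleaned, reference_role=config.reference_role)
        ar_scores = summed_zscore(z, ar_set)
        labels = stratify_extremes(ar_scores, fraction=config.stratify_fraction)
        return z, ar_scores, labels

    z, ar_scores, ar_labels = run_stage("signature_scoring", score_stage)
    report.stages["signature_scoring"] = {
        "ar_signature": ar_set.name,
        "n_genes_used": ar_scores.n_genes_used,
        "missing_genes": ar_scores.missing_genes,
        "group_sizes": ar_labels.counts(),
        "rule": ar_labels.rule,
    }

    # --- NF-kB enrichment in the AR contrast --------------------------------
    def ar_enrichment_stage():
        return permutation_test(
            cleaned,
            ar_labels,
            nfkb_set,
            n_permutations=config.n_permutations,
            weight=config.enrichment_weight,
            seed=config.seed,
            min_overlap=config.min_set_size,
        )

    ar_enr = run_stage("enrichment_ar_contrast", ar_enrichment_stage)
    report.stages["enrichment_ar_contrast"] = _enrichment_summary(ar_enr)

    # --- Derived repressed-target set ---------------------------------------
    def derive_stage():
        if config.use_packaged_repressed_set:
            from .io import ar_repressed_nfkb_targets

            return ar_repressed_nfkb_targets()
        return derive_repressed_targets(ar_enr, name="AR_repressed_NFKB_targets")

    derived = run_stage("derive_repressed_targets", derive_stage)
    report.stages["derive_repressed_targets"] = {
        "name": derived.name,
        "n_genes": len(derived),
        "genes": list(derived.genes),
        "source": "packaged" if config.use_packaged_repressed_set else "negative leading edge",
    }
    if out_dir is not None:
        write_gmt([derived], out_dir / "ar_repressed_targets.gmt")

    # --- GSK3 contrast -------------------------------------------------------
    def gsk3_stage():
        gsk3_labels = classify_dual_threshold(z, "GSK3A", "GSK3B", hi=config.gsk3_hi, lo=config.gsk3_lo)
        enr = permutation_test(
            cleaned,
            gsk3_labels,
            derived,
            n_permutations=config.n_permutations,
            weight=config.enrichment_weight,
            seed=config.seed + 1,
            min_overlap=min(config.min_set_size, len(derived)),
        )
        return gsk3_labels, enr

    gsk3_labels, gsk3_enr = run_stage("enrichment_gsk3_contrast", gsk3_stage)
    report.stages["enrichment_gsk3_contrast"] = {
        "group_sizes": gsk3_labels.counts(),
        "rule": gsk3_labels.rule,
        **_enrichment_summary(gsk3_enr),
    }

    # --- Survival ------------------------------------------------------------
    def survival_stage():
        derived_scores = summed_zscore(z, derived)
        groups = group_by_signature(derived_scores, rule=config.survival_rule)
        meta = metadata.set_index("sample_id")
        records = pd.DataFrame(
            {
                "sample_id": groups.index,
                "time": meta.loc[groups.index, "time_months"].to_numpy(float),
                "event": meta.loc[groups.index, "event"].to_numpy(float),
                "group": groups.to_numpy(),
            }
        ).dropna(subset=["time", "event"])
        out = {"rule": config.survival_rule, "group_sizes": groups.value_counts().to_dict(), "horizons": {}}
        for horizon in config.survival_horizons:
            lr = logrank_test(records, horizon_months=horizon)
            out["horizons"][f"{horizon:g}"] = {
                "chi_square": lr.chi_square,
                "df": lr.df,
                "p_value": lr.p_value,
                "group_sizes": lr.group_sizes,
            }
        if out_dir is not None:
            for grp in sorted(records["group"].unique()):
                curve = km_estimate(records[records["group"] == grp])
                curve.to_frame().to_csv(out_dir / f"km_{grp}.tsv", sep="\t", index=False)
        return out

    report.stages["survival"] = run_stage("survival", survival_stage)

    report.complete = True
    if out_dir is not None:
        (out_dir / "run_report.json").write_text(report.to_json())
    validate_report(json.loads(report.to_json()))
    return report


def _enrichment_summary(result) -> dict:
    return {
        "set_name": result.set_name,
        "es": float(result.es),
        "nes": None if result.nes is None else float(result.nes),
        "p_nominal": result.p_nominal,
        "n_permutations": result.n_permutations,
        "direction": result.direction,
        "leading_edge_size": 0 if result.leading_edge is None else len(result.leading_edge),
        "seed": result.seed,
    }


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Load the configured input files and run the chained analysis."""
    matrix, metadata = load_cohort_files(config.expression_tsv, config.metadata_tsv)
    sets = {s.name: s for s in read_gmt(config.gmt)}
    for name in (config.ar_signature, config.nfkb_signature):
        if name not in sets:
            raise KeyError(f"gene set {name!r} not found in {config.gmt}")
    return analyze_cohort(
        matrix,
        metadata,
        sets[config.ar_signature],
        sets[config.nfkb_signature],
        config,
        out_dir=Path(config.out_dir),
    )
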