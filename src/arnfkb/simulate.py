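"""Synthetic cohorts, binding-array membranes, and qPCR Ct tables.

The cohort generator emulates the statistical structure the downstream
analysis assumes: two anticorrelated latent activities per tumor (AR and
NF-kB), each driving a disjoint gene program on the log2 scale; GSK3A and
GSK3B expression coupled to the AR activity; a normal-tissue reference
group with both activities at zero; optional planted outlier chips
(global log2 shifts); and exponential survival whose log-hazard rises
with the standardized NF-kB summed-Z score, under uniform administrative
censoring.  Everything is driven by one integer seed and is bit-identical
across runs with the same configuration.

Model, for gene g and sample s:

    x_gs = mu_g + beta * (a_s * [g in AR set] + b_s * [g in NFkB set])
           + kappa * a_s * [g in {GSK3A, GSK3B}] + eps_gs

with a_s ~ N(0,1), b_s = -rho * a_s + sqrt(1 - rho^2) * eta_s for tumors
and a_s = b_s = 0 for normals; eps ~ N(0, noise_sd^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assays import CtTable, NEGATIVE, POSITIVE, TFArrayGrid
from .containers import ExpressionMatrix, GeneSet
from .scoring import summed_zscore, zscore_vs_reference


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generator settings; defaults define the package's study conditions."""

    n_tumors: int = 100
    n_normals: int = 20
    n_genes: int = 2000
    n_program_genes: int = 30
    effect_size_beta: float = 1.0          # log2 shift per unit latent activity
    anticorrelation_rho: float = 0.6       # corr(a, b) = -rho
    gsk3_coupling: float = 0.5             # log2 shift of GSK3A/B per unit AR activity
    baseline_mean_sd: tuple[float, float] = (7.0, 1.0)
    noise_sd: float = 0.5
    hazard_gamma: float = 0.8              # log-hazard per sd of NF-kB summed Z
    censor_rate: float = 0.3
    median_survival_months: float = 60.0   # baseline exponential hazard scale
    max_followup_months: float = 220.0
    outlier_chips: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tumors", "n_normals", "n_genes", "n_program_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if 2 * self.n_program_genes + 2 > self.n_genes:
            raise ValueError("program genes (plus GSK3A/GSK3B) exceed n_genes")
        if not -1.0 <= self.anticorrelation_rho <= 1.0:
            raise ValueError("anticorrelation_rho must lie in [-1, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    metadata: pd.DataFrame  # sample_id, role, time_months, event
    truth: dict = field(default_factory=dict)

    @property
    def ar_set(self) -> GeneSet:
        return GeneSet("AR_signature", tuple(self.truth["ar_genes"]), "synthetic AR program")

    @property
    def nfkb_set(self) -> GeneSet:
        return GeneSet("NFKB_targets", tuple(self.truth["nfkb_genes"]), "synthetic NF-kB program")


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one synthetic tumor/normal cohort under ``config``."""
    rng = np.random.default_rng(config.seed)
    nt, nn, ng = config.n_tumors, config.n_normals, config.n_genes
    npg = config.n_program_genes
    tumors = [f"T{i + 1:04d}" for i in range(nt)]
    normals = [f"N{i + 1:04d}" for i in range(nn)]
    samples = tumors + normals

    plain = [f"G{i + 1:05d}" for i in range(ng - 2)]
    genes = plain + ["GSK3A", "GSK3B"]
    program_idx = rng.choice(ng - 2, size=2 * npg, replace=False)
    ar_genes = sorted(plain[i] for i in program_idx[:npg])
    nfkb_genes = sorted(plain[i] for i in program_idx[npg:])

    rho = config.anticorrelation_rho
    a = np.zeros(nt + nn)
    b = np.zeros(nt + nn)
    a[:nt] = rng.standard_normal(nt)
    eta = rng.standard_normal(nt)
    b[:nt] = -rho * a[:nt] + math.sqrt(1.0 - rho ** 2) * eta

    mu = rng.normal(config.baseline_mean_sd[0], config.baseline_mean_sd[1], size=ng)
    x = np.tile(mu[:, None], (1, nt + nn))
    gene_pos = {g: i for i, g in enumerate(genes)}
    ar_rows = [gene_pos[g] for g in ar_genes]
    nfkb_rows = [gene_pos[g] for g in nfkb_genes]
    beta = config.effect_size_beta
    x[ar_rows, :] += beta * a[None, :]
    x[nfkb_rows, :] += beta * b[None, :]
    x[gene_pos["GSK3A"], :] += config.gsk3_coupling * a
    x[gene_pos["GSK3B"], :] += config.gsk3_coupling * a
    x += rng.normal(0.0, config.noise_sd, size=x.shape)

    values = pd.DataFrame(x, index=genes, columns=samples)
    roles = pd.Series(["tumor"] * nt + ["normal"] * nn, index=samples)
    matrix = ExpressionMatrix(values, roles)

    # survival from the pre-outlier matrix: hazard follows the NF-kB summed Z
    z = zscore_vs_reference(matrix)
    nfkb_score = summed_zscore(z, GeneSet("NFKB_targets", tuple(nfkb_genes))).per_sample_score
    std = nfkb_score.std(ddof=1)
    z_std = (nfkb_score - nfkb_score.mean()) / (std if std > 0 else 1.0)
    lam0 = math.log(2.0) / config.median_survival_months
    lam = lam0 * np.exp(config.hazard_gamma * z_std.loc[tumors].to_numpy())
    t_event = rng.exponential(1.0 / lam)
    censored_early = rng.random(nt) < config.censor_rate
    c_time = np.where(
        censored_early,
        rng.uniform(0.0, config.max_followup_months, size=nt),
        config.max_followup_months,
    )
    time = np.minimum(t_event, c_time)
    event = (t_event <= c_time).astype(int)
    time = np.maximum(time, 1e-6)  # strictly positive months

    metadata = pd.DataFrame(
        {
            "sample_id": samples,
            "role": roles.to_numpy(),
            "time_months": np.concatenate([time, np.full(nn, np.nan)]),
            "event": np.concatenate([event.astype(float), np.full(nn, np.nan)]),
        }
    )

    outliers = []
    for sid, shift in config.outlier_chips:
        if sid not in values.columns:
            raise KeyError(f"outlier chip {sid!r} not a sample of this cohort")
        matrix.values[sid] += float(shift)
        outliers.append(sid)

    truth = {
        "ar_activity": dict(zip(samples, a.tolist())),
        "nfkb_activity": dict(zip(samples, b.tolist())),
        "ar_genes": ar_genes,
        "nfkb_genes": nfkb_genes,
        "outliers": outliers,
        "config": config,
    }
    return SyntheticCohort(expression=matrix, metadata=metadata, truth=truth)


def generate_tfarray_fixture(
    true_signals: dict[str, tuple[float, float]],
    noise_sd: float = 5.0,
    n_membranes: int = 2,
    sites_per_row: int = 5,
    blank_level: float = 50.0,
    positive_level: float = 350.0,
    condition_labels: tuple[str, str] = ("control", "silenced"),
    seed: int = 0,
) -> tuple[list[TFArrayGrid], list[TFArrayGrid]]:
    """Membrane pairs (control vs perturbed condition) with planted signals.

    ``true_signals`` maps each binding-site name to its normalized signal
    (units of the positive-control scale) under the two conditions.  Each
    site is spotted in duplicate (adjacent columns); one row of negative
    controls surrounds the blank level and one full row of positive
    controls surrounds the membrane scale.  Raw intensity for a spot of
    signal v is ``blank + v * (positive - blank) + noise``.
    """
    sites = sorted(true_signals)
    n_cols = 2 * sites_per_row
    site_rows = math.ceil(len(sites) / sites_per_row)
    n_rows = site_rows + 2  # + negative-control row + positive-control row
    rng = np.random.default_rng(seed)

    def build(mem_id: str, condition: str, which: int) -> TFArrayGrid:
        raw = np.full((n_rows, n_cols), blank_level, dtype=float)
        ann: dict[tuple[int, int], str] = {}
        for k, site in enumerate(sites):
            r, j = divmod(k, sites_per_row)
            level = blank_level + true_signals[site][which] * (positive_level - blank_level)
            for c in (2 * j, 2 * j + 1):
                raw[r, c] = level
                ann[(r, c)] = site
        neg_row, pos_row = site_rows, site_rows + 1
        for c in range(4):
            ann[(neg_row, c)] = NEGATIVE
        for c in range(n_cols):
            raw[pos_row, c] = positive_level
            ann[(pos_row, c)] = POSITIVE
        if noise_sd > 0:
            raw = raw + rng.normal(0.0, noise_sd, size=raw.shape)
        return TFArrayGrid(membrane_id=mem_id, condition=condition, intensities=raw, annotations=ann)

    control = [build(f"{condition_labels[0]}_m{m + 1}", condition_labels[0], 0) for m in range(n_membranes)]
    treated = [build(f"{condition_labels[1]}_m{m + 1}", condition_labels[1], 1) for m in range(n_membranes)]
    return control, treated


def generate_ct_table(
    true_folds: dict[str, dict[str, float]],
    ct_ref: float = 18.0,
    gene_baseline_ct: float = 24.0,
    replicate_sd: float = 0.2,
    n_reps: int = 3,
    reference_gene: str = "36B4",
    control_condition: str = "control",
    seed: int = 0,
) -> CtTable:
    """qPCR Ct replicates with planted fold changes vs a control condition.

    ``true_folds[condition][gene]`` is the expression fold change of the
    gene in that condition relative to control; the control condition is
    generated automatically with fold 1 for every gene.  A fold f lowers
    the gene's Ct by log2(f); the reference gene sits at ``ct_ref`` in
    every condition.  With ``replicate_sd = 0`` the downstream ddCt folds
    recover the planted values exactly.
    """
    if n_reps < 2:
        raise ValueError("need n_reps >= 2")
    rng = np.random.default_rng(seed)
    genes = sorted({g for folds in true_folds.values() for g in folds})
    conditions = [control_condition] + sorted(true_folds)
    rows = []
    for cond in conditions:
        for gene in genes + [reference_gene]:
            if gene == reference_gene:
                base = ct_ref
            else:
                fold = 1.0 if cond == control_condition else true_folds[cond].get(gene, 1.0)
                base = gene_baseline_ct - math.log2(fold)
            for _ in range(n_reps):
                noise = rng.normal(0.0, replicate_sd) if replicate_sd > 0 else 0.0
                rows.append({"condition": cond, "gene": gene, "ct": base + noise})
    return CtTable(
        data=pd.DataFrame(rows),
        reference_gene=reference_gene,
        control_condition=control_condition,
    )
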