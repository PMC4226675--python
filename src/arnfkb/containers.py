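"""Core in-memory containers: expression matrices, gene sets, scores, labels.

Expression values are assumed to be on a normalized log2 scale throughout;
nothing in the package re-normalizes raw intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) with per-sample roles.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene symbols with one column per
        unique sample id.
    roles
        Series mapping every sample id to ``"tumor"`` or ``"normal"``.
    """

    values: pd.DataFrame
    roles: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups[:5]}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        self.roles = self.roles.reindex(self.values.columns)
        if self.roles.isna().any():
            missing = self.roles.index[self.roles.isna()].tolist()
            raise ValueError(f"samples missing a role: {missing[:5]}")
        bad = set(self.roles.unique()) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        if (self.roles == TUMOR).sum() < 1:
            raise ValueError("matrix must contain at least one tumor sample")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def tumor_ids(self) -> list[str]:
        return [s for s in self.samples if self.roles[s] == TUMOR]

    @property
    def normal_ids(self) -> list[str]:
        return [s for s in self.samples if self.roles[s] == NORMAL]

    def drop_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        unknown = set(sample_ids) - set(self.samples)
        if unknown:
            raise KeyError(f"samples not in matrix: {sorted(unknown)}")
        keep = [s for s in self.samples if s not in set(sample_ids)]
        return ExpressionMatrix(self.values[keep], self.roles[keep])

    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols (upper-cased, order-preserving unique)."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(str(g).strip().upper(), None)
        seen.pop("", None)
        object.__setattr__(self, "genes", tuple(seen))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return str(symbol).upper() in set(self.genes)


@dataclass
class SignatureScores:
    """Per-tumor summed Z-scores for one signature."""

    signature: str
    per_sample_score: pd.Series
    n_genes_used: int
    missing_genes: list[str] = field(default_factory=list)


@dataclass
class StratificationLabels:
    """high / low / unclassified labels for every scored tumor."""

    per_sample_label: pd.Series
    rule: str

    def __post_init__(self) -> None:
        bad = set(self.per_sample_label.unique()) - {"high", "low", "unclassified"}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    @property
    def high_ids(self) -> list[str]:
        return list(self.per_sample_label.index[self.per_sample_label == "high"])

    @property
    def low_ids(self) -> list[str]:
        return list(self.per_sample_label.index[self.per_sample_label == "low"])

    def counts(self) -> dict[str, int]:
        c = self.per_sample_label.value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in ("high", "low", "unclassified")}
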