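"""Score tumors against the normal reference and stratify them.

Computes gene-wise Z-scores of every tumor against the normal-prostate
chips, the per-tumor summed Z over the AR signature, the tertile
high/low AR-signature labels, and the dual-threshold GSK-3 classes
(Z of GSK3A and GSK3B both > 0.5 -> high; both < -0.5 -> low).
"""

import pathlib

import pandas as pd

from arnfkb import io
from arnfkb.scoring import (
    classify_dual_threshold,
    stratify_extremes,
    summed_zscore,
    zscore_vs_reference,
)

COHORT = pathlib.Path("results/cohort")
QC = pathlib.Path("results/qc")
OUT = pathlib.Path("results/scores")


def main() -> None:
    matrix, _ = io.load_cohort_files(QC / "expression_clean.tsv", COHORT / "metadata.tsv")
    sets = {s.name: s for s in io.read_gmt(COHORT / "signatures.gmt")}

    z = zscore_vs_reference(matrix)
    ar_scores = summed_zscore(z, sets["AR_signature"])
    ar_labels = stratify_extremes(ar_scores, fraction=1 / 3)
    gsk3_labels = classify_dual_threshold(z, "GSK3A", "GSK3B", hi=0.5, lo=-0.5)

    OUT.mkdir(parents=True, exist_ok=True)
    z.to_csv(OUT / "zscores.tsv", sep="\t", index_label="gene")
    pd.DataFrame(
        {
            "ar_summed_z": ar_scores.per_sample_score,
            "ar_label": ar_labels.per_sample_label,
            "gsk3_label": gsk3_labels.per_sample_label,
        }
    ).to_csv(OUT / "stratification.tsv", sep="\t", index_label="sample_id")

    print(f"AR signature: {ar_scores.n_genes_used} genes used, rule {ar_labels.rule}")
    print(f"AR groups: {ar_labels.counts()}")
    print(f"GSK-3 groups ({gsk3_labels.rule}): {gsk3_labels.counts()}")
    print(f"wrote {OUT}/zscores.tsv and stratification.tsv")


if __name__ == "__main__":
    main()
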