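"""Quantify simulated TF binding-site membranes and a qPCR Ct table.

Demonstrates the two bench-assay quantitation paths on planted inputs:
a protein/DNA binding-site array pair in which the NFKB site doubles in
the perturbed condition (negative controls as blank, positive-control
row as scale), and a ddCt table in which IL6 is planted at 2-fold with
replicate noise.  Both recover the planted values.
"""

import pathlib
import sys

from arnfkb import io
from arnfkb.assays import compare_conditions, ddct_fold_change, quantify_membrane
from arnfkb.simulate import generate_ct_table, generate_tfarray_fixture

OUT = pathlib.Path("results/assays")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    true_signals = {"NFKB": (0.3, 0.6), "AP1": (0.4, 0.4), "SP1": (0.25, 0.25)}
    control, perturbed = generate_tfarray_fixture(
        true_signals, noise_sd=2.0, n_membranes=2, seed=SEED
    )
    for grid in control + perturbed:
        io.write_tfarray(grid, OUT / f"{grid.membrane_id}.tsv", OUT / f"{grid.membrane_id}.json")
    comparison = compare_conditions(
        {
            "control": [quantify_membrane(g) for g in control],
            "silenced": [quantify_membrane(g) for g in perturbed],
        },
        control="control",
    )
    comparison.to_csv(OUT / "tfarray_comparison.tsv", sep="\t")
    print("TF array, silenced vs control:")
    print(comparison[["ratio", "p_value", "significant"]].to_string())

    table = generate_ct_table(
        {"GSK3B_shRNA": {"IL6": 2.0, "MMP9": 1.6, "BCL3": 1.0}},
        replicate_sd=0.2, n_reps=3, seed=SEED,
    )
    table.data.to_csv(OUT / "ct_table.tsv", sep="\t", index=False)
    folds = ddct_fold_change(table)
    folds.to_csv(OUT / "qpcr_folds.tsv", sep="\t")
    print("\nqPCR ddCt folds (vs control, reference 36B4):")
    print(folds[["fold", "fold_low", "fold_high"]].to_string())
    print(f"\nwrote membrane tables and {OUT}/qpcr_folds.tsv")


if __name__ == "__main__":
    main()
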