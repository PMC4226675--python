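"""Generate the default synthetic tumor cohort and write its input files.

The cohort carries the structure every later step assumes: 100 tumors and
20 normal-prostate references over 2000 genes; a 30-gene AR program and a
30-gene NF-kB program driven by latent activities with correlation -0.6;
GSK3A/GSK3B coupled to the AR activity; exponential survival whose hazard
rises with the NF-kB score; and two planted outlier chips (+2.0 log2)
for the QC step to find.

Outputs under results/cohort/: expression.tsv, metadata.tsv,
signatures.gmt, truth.json.
"""

import pathlib
import sys

from arnfkb import io
from arnfkb.simulate import SimulationConfig, generate_cohort

OUT = pathlib.Path("results/cohort")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    config = SimulationConfig(
        seed=SEED,
        outlier_chips=(("T0001", 2.0), ("T0002", 2.0)),
    )
    cohort = generate_cohort(config)
    OUT.mkdir(parents=True, exist_ok=True)
    io.write_expression_tsv(cohort.expression, OUT / "expression.tsv")
    io.write_metadata_tsv(cohort.metadata, OUT / "metadata.tsv")
    io.write_gmt([cohort.ar_set, cohort.nfkb_set], OUT / "signatures.gmt")
    io.write_truth_json(cohort.truth, OUT / "truth.json")

    n_t, n_n = len(cohort.expression.tumor_ids), len(cohort.expression.normal_ids)
    print(f"cohort: {n_t} tumors + {n_n} normals x {len(cohort.expression.genes)} genes")
    print(f"planted outlier chips: {cohort.truth['outliers']}")
    print(f"wrote {OUT}/expression.tsv, metadata.tsv, signatures.gmt, truth.json")


if __name__ == "__main__":
    main()
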