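#!/usr/bin/env python
"""Generate every input the downstream stages need.

Writes, under results/sim/: a ground-truth calibration set (oestradiol-
stimulated vs deprived expression profiles), an endometrial cohort with the
published group composition (4 proliferative / 20 hyperplasia / 57 EEC I /
12 EEC II-IV / 14 USC) including clinical annotations and outcomes, and a
qPCR Cq table emulating FFPE measurement of the same cohort.
"""

from pathlib import Path

from erpathway.io import write_clinical, write_expression_matrix
from erpathway.simulate import (
    GeneratorConfig,
    generate_calibration_set,
    generate_cohort,
    to_qpcr_records,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = GeneratorConfig(seed=1)
    config.to_yaml(OUT / "generator_config.yaml")

    calib = generate_calibration_set(config)
    write_expression_matrix(calib.matrix, OUT / "calibration_matrix.tsv")
    calib.labels.rename("label").to_csv(
        OUT / "calibration_labels.csv", index_label="sample_id"
    )
    print(
        f"calibration set: {calib.matrix.n_samples} samples x "
        f"{calib.matrix.n_genes} genes (25 active / 25 inactive)"
    )

    matrix, clinical = generate_cohort(config)
    write_expression_matrix(matrix, OUT / "cohort_expression.tsv")
    write_clinical(clinical, OUT / "clinical.csv")
    sizes = clinical["tissue"].value_counts().to_dict()
    print(f"cohort: {matrix.n_samples} samples, composition {sizes}")

    records = to_qpcr_records(matrix, config)
    records.to_csv(OUT / "cohort_qpcr.csv", index=False, float_format="%.6g")
    print(f"qPCR table: {len(records)} Cq measurements -> {OUT}")


if __name__ == "__main__":
    main()
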