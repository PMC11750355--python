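#!/usr/bin/env python
"""Cohort-level statistics over the 26 synthetic lineages.

Tests whether the punctuational verdict is more common in metastatic
lineages (continuity-corrected chi-squared, Fisher's exact as a
sensitivity check), whether it associates with the mouse-model
background, and whether deviations from gradualism (rho) increase with
the punctuational contribution (OLS).  Writes
``results/cohort_statistics.json``.
"""

import json
import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(__file__))
from cohort_common import RESULTS_DIR

from punctevo import cohort_contingency_test, cohort_deviation_model


def main() -> None:
    cls_path = os.path.join(RESULTS_DIR, "lineage_classifications.tsv")
    table = pd.read_csv(cls_path, sep="\t")
    disp_path = os.path.join(RESULTS_DIR, "dispersion.tsv")
    if os.path.exists(disp_path):
        disp = pd.read_csv(disp_path, sep="\t")
        table = table.merge(disp[["lineage_id", "d_mean"]], on="lineage_id",
                            how="left")

    out: dict = {}
    chi2 = cohort_contingency_test(table, "metastatic", method="chi2")
    fisher = cohort_contingency_test(table, "metastatic", method="fisher")
    out["metastatic_vs_punctuational"] = {
        "chi2_yates": chi2.to_dict(),
        "fisher": fisher.to_dict(),
    }
    print(
        f"punctuational vs metastatic: counts {chi2.table}, "
        f"chi2 Yates p = {chi2.p_value:.4f}, Fisher p = {fisher.p_value:.4f}"
    )
    model = cohort_contingency_test(table, "mouse_model", method="chi2")
    out["mouse_model_vs_punctuational"] = model.to_dict()
    print(f"punctuational vs mouse model: p = {model.p_value:.3f}")

    slope, p, res = cohort_deviation_model(table)
    out["deviation_vs_contribution"] = {
        "slope": slope,
        "p_value": p,
        "n_lineages": int(res.nobs),
    }
    print(
        f"rho ~ PC across {int(res.nobs)} lineages: "
        f"slope = {slope:.2f}, p = {p:.2g}"
    )

    path = os.path.join(RESULTS_DIR, "cohort_statistics.json")
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
    print(f"\ncohort statistics -> {path}")


if __name__ == "__main__":
    main()
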