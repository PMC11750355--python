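#!/usr/bin/env python
"""Location-partitioned punctuational contributions for metastatic
punctuational lineages.

For every qualifying posterior tree of each metastatic punctuational
lineage: fit the two-state location model with kappa, reconstruct
marginal ancestral states, categorize branches, and convert the shared
slope into PC_P and PC_M.  The paired posterior samples are compared by
Wilcoxon tests with Bonferroni correction across lineages.  Writes
``results/location_contrasts.tsv``.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(__file__))
from cohort_common import RESULTS_DIR, SCRATCH_DIR, meta_path, tree_path

from punctevo import PipelineConfig, read_metadata, read_trees
from punctevo.asr import compare_location_contributions
from punctevo.pipeline import location_contrast_for_lineage


def main() -> None:
    cls_path = os.path.join(RESULTS_DIR, "lineage_classifications.tsv")
    classifications = pd.read_csv(cls_path, sep="\t")
    punct_met = classifications.query("metastatic and verdict == 'punctuational'")
    print(f"{len(punct_met)} metastatic punctuational lineages to partition")
    config = PipelineConfig(min_qualifying_trees=15)
    contrasts = []
    fits_dir = os.path.join(SCRATCH_DIR, "fits")
    for lineage_id in punct_met["lineage_id"]:
        trees = read_trees(tree_path(lineage_id), format="nexus",
                           lineage_id=lineage_id)
        meta = read_metadata(meta_path(lineage_id))
        fits = pd.read_csv(os.path.join(fits_dir, f"{lineage_id}.tsv"), sep="\t")
        contrasts.append(
            location_contrast_for_lineage(trees, meta, fits, config)
        )
        c = contrasts[-1]
        if c.n_qualifying:
            print(
                f"{lineage_id}: {c.n_qualifying} qualifying trees, "
                f"mean PC_P={c.pc_p.mean():.3f}, mean PC_M={c.pc_m.mean():.3f}"
            )
        else:
            print(f"{lineage_id}: no qualifying trees")
    out_table = compare_location_contributions(
        contrasts, alpha=0.05, min_trees=config.min_qualifying_trees
    )
    for c in contrasts:
        sel = out_table["lineage_id"] == c.lineage_id
        out_table.loc[sel, "pc_p_mean"] = c.pc_p.mean() if c.n_qualifying else None
        out_table.loc[sel, "pc_m_mean"] = c.pc_m.mean() if c.n_qualifying else None
    out = os.path.join(RESULTS_DIR, "location_contrasts.tsv")
    out_table.to_csv(out, sep="\t", index=False)
    n_sig = int((out_table["significant"] & (out_table["direction"] == "M>P")).sum())
    print(
        f"\nPC_M > PC_P at the Bonferroni-adjusted level in {n_sig} of "
        f"{int(out_table['testable'].sum())} testable lineages; table -> {out}"
    )


if __name__ == "__main__":
    main()
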