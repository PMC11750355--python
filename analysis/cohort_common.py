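"""Shared definition of the synthetic study cohort used by the numbered
analysis scripts.

The cohort mirrors the structure of the mouse lineage-tracing study the
pipeline is designed for: 26 lineages from three engineered mouse-model
backgrounds (KP, KPL, KPA), 11 metastatic and 15 non-metastatic.
Punctuational evolution is enriched among the metastatic lineages (7 of
11 generated with a punctuational share of 6-12%, some with faster-
diversifying metastatic clades) while most non-metastatic lineages are
gradual; two lineages carry an injected node-density deformation so the
artefact screen has something to catch.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from punctevo import SimulationConfig

RESULTS_DIR = os.path.join(os.path.dirname(__file__), "..", "results")
SCRATCH_DIR = os.path.join(os.path.dirname(__file__), "..", "scratch", "cohort")

COHORT_SEED = 20250923
N_POSTERIOR = 25
#: within the 247-1612 cell range of the lineages the pipeline targets
N_TIPS = 300


@dataclass
class LineageSpec:
    lineage_id: str
    mouse_model: str
    metastatic: bool
    config: SimulationConfig


def cohort_specs(seed: int = COHORT_SEED) -> list[LineageSpec]:
    specs: list[LineageSpec] = []
    models = ["KP"] + ["KPL"] * 7 + ["KPA"] * 2

    def cfg(k, **kw):
        base = dict(
            n_tips=N_TIPS,
            n_posterior=N_POSTERIOR,
            rng_seed=(seed + 613 * k) % (2**31),
        )
        base.update(kw)
        return SimulationConfig(**base)

    k = 0
    # 11 metastatic lineages: 7 punctuational (mixed seeding, all with a
    # metastatically concentrated punctuational share: the metastatic
    # subpopulation diversifies faster and jumps harder), 3 gradual,
    # 1 artefact-injected
    for i in range(7):
        pc = (0.06, 0.09, 0.12)[i % 3]
        mode = ("monophyletic", "polyphyletic", "reseeding")[i % 3]
        specs.append(
            LineageSpec(
                f"met{i:02d}",
                models[i % len(models)],
                True,
                cfg(
                    k,
                    target_pc=pc,
                    seeding_mode=mode,
                    q_pm=0.08,
                    q_mp=0.02 if mode == "reseeding" else 0.0,
                    met_branch_scale=(1 / 3, 1 / 2, 2 / 3)[i % 3],
                    met_jump_scale=(3.0, 2.5, 2.0)[i % 3],
                ),
            )
        )
        k += 1
    for i in range(3):
        specs.append(
            LineageSpec(
                f"met{7 + i:02d}", models[(7 + i) % len(models)], True,
                cfg(k, q_pm=0.08),
            )
        )
        k += 1
    specs.append(
        LineageSpec(
            "met10", "KPL", True,
            cfg(k, target_pc=0.10, q_pm=0.08, delta_true=2.0),
        )
    )
    k += 1
    # 15 non-metastatic lineages: 3 punctuational, 11 gradual, 1 artefact
    for i in range(3):
        specs.append(
            LineageSpec(
                f"non{i:02d}", models[i % len(models)], False,
                cfg(k, target_pc=0.08),
            )
        )
        k += 1
    for i in range(11):
        specs.append(
            LineageSpec(
                f"non{3 + i:02d}", models[(3 + i) % len(models)], False, cfg(k)
            )
        )
        k += 1
    specs.append(
        LineageSpec("non14", "KPL", False, cfg(k, target_pc=0.10, delta_true=2.0))
    )
    return specs


def tree_path(lineage_id: str) -> str:
    return os.path.join(SCRATCH_DIR, f"{lineage_id}.trees.nex")


def meta_path(lineage_id: str) -> str:
    return os.path.join(SCRATCH_DIR, f"{lineage_id}.meta.tsv")
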