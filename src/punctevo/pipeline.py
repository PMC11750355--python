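"""Per-lineage orchestration and cohort-level statistics.

``run_lineage`` sequences the analysis for one lineage: posterior-wide
punctuation tests, artefact classification, punctuational contribution
and rho for punctuational lineages, ancestral-state branch partitioning
with the paired location contrast for metastatic punctuational lineages,
and phylogenetic dispersion D for metastatic lineages.  Lineages
classified as node-density artefacts are excluded from all downstream
statistics.

Cohort statistics compare the prevalence of punctuational verdicts
between groups (metastatic vs non-metastatic, or mouse model) and relate
per-lineage deviations from gradualism (rho) to punctuational
contributions (PC) by ordinary least squares — each lineage arises from
an independent engineered stem cell, so no cross-lineage tree exists
that would justify a phylogenetic regression there.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from . import asr
from .dispersion import posterior_mean_d
from .errors import DegenerateDataError, ParameterError
from .punctuation import (
    classify_lineage,
    run_punctuation_test,
    summarize_punctuation,
)
from .treeio import PosteriorTreeSet, scale_to_mean_branch_length

__all__ = [
    "PipelineConfig",
    "LineageReport",
    "run_lineage",
    "location_contrast_for_lineage",
    "cohort_table",
    "cohort_contingency_test",
    "ContingencyResult",
    "cohort_deviation_model",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Analysis thresholds; defaults are the study's conventions."""

    alpha: float = 0.05
    posterior_fraction: float = 0.5
    mean_branch: float = 0.1
    min_location_branches: int = 10
    pc_max: float = 1.0
    terminal_policy: str = "exclude"
    min_qualifying_trees: int = 20
    bonferroni_alpha: float = 0.05
    d_n_perm: int = 1000
    d_n_bm: int = 1000
    d_max_trees: int | None = None
    asr_max_trees: int | None = None
    rng_seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LineageReport:
    """End-to-end result for one lineage."""

    lineage_id: str
    n_trees: int
    metastatic: bool
    verdict: str
    classification: dict
    pc: float | None = None
    rho: float | None = None
    beta: float | None = None
    d_mean: float | None = None
    location_contrast: dict | None = None
    exclusions: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def location_contrast_for_lineage(
    trees: PosteriorTreeSet,
    meta: pd.DataFrame,
    fits: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
) -> asr.LocationContrast:
    """Paired per-tree (PC_P, PC_M) sample for one metastatic lineage.

    For each estimable posterior tree: scale, fit the two-state location
    model with kappa, reconstruct marginal ancestral states, categorize
    branches, and convert the tree's shared punctuational slope into
    location-specific contributions.  Trees failing the branch-count or
    PC < 1 filters are dropped with their reason logged.
    """
    ok = fits[fits["status"] == "ok"]
    use = ok if config.asr_max_trees is None else ok.iloc[: config.asr_max_trees]
    pcp, pcm = [], []
    n_total = 0
    for row in use.itertuples():
        tree = scale_to_mean_branch_length(trees[row.tree], config.mean_branch)
        states = asr.states_from_meta(tree, meta)
        n_total += 1
        fit = asr.fit_mk2(tree, states)
        marg = asr.marginal_states(tree, fit, states)
        part = asr.categorize_branches(tree, marg, states)
        contrib = asr.location_contribution(
            part,
            row.beta,
            terminal_policy=config.terminal_policy,
            min_branches=config.min_location_branches,
            pc_max=config.pc_max,
        )
        if contrib.included:
            pcp.append(contrib.pc_p)
            pcm.append(contrib.pc_m)
        else:
            logger.info(
                "tree %d of %s excluded from location contrast: %s",
                row.tree,
                trees.lineage_id,
                contrib.exclusion_reason,
            )
    return asr.LocationContrast(
        lineage_id=trees.lineage_id,
        pc_p=np.asarray(pcp),
        pc_m=np.asarray(pcm),
        n_total_trees=n_total,
    )


def run_lineage(
    trees: PosteriorTreeSet,
    meta: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
) -> LineageReport:
    """Run the full per-lineage analysis; see the module docstring."""
    rng = np.random.default_rng(config.rng_seed)
    fits = run_punctuation_test(
        trees, meta, alpha=config.alpha, mean_branch=config.mean_branch
    )
    cls = classify_lineage(fits, posterior_fraction=config.posterior_fraction)
    locs = meta.set_index("cell_id").loc[list(trees.tip_labels), "location"]
    metastatic = bool((locs == "M").any() and (locs == "P").any())
    report = LineageReport(
        lineage_id=trees.lineage_id,
        n_trees=len(trees),
        metastatic=metastatic,
        verdict=cls.verdict,
        classification=cls.to_dict(),
        config=config.to_dict(),
        seed=config.rng_seed,
    )
    if cls.verdict == "node_density_artefact":
        report.exclusions.append(
            "node-density artefact: excluded from downstream statistics"
        )
        return report
    if cls.verdict == "punctuational":
        summary = summarize_punctuation(fits, trees)
        report.pc = summary.pc
        report.rho = summary.rho
        report.beta = summary.beta
        if metastatic:
            contrast = location_contrast_for_lineage(trees, meta, fits, config)
            comparison = asr.compare_location_contributions(
                [contrast],
                alpha=config.bonferroni_alpha,
                min_trees=config.min_qualifying_trees,
            )
            report.location_contrast = {
                "n_qualifying": contrast.n_qualifying,
                "pc_p_mean": float(np.mean(contrast.pc_p)) if contrast.n_qualifying else None,
                "pc_m_mean": float(np.mean(contrast.pc_m)) if contrast.n_qualifying else None,
                **comparison.iloc[0][
                    ["testable", "median_diff", "direction", "p_value"]
                ].to_dict(),
            }
    if metastatic:
        d_mean, _ = posterior_mean_d(
            trees,
            meta,
            n_perm=config.d_n_perm,
            n_bm=config.d_n_bm,
            rng=rng,
            max_trees=config.d_max_trees,
        )
        report.d_mean = d_mean
    return report


# ---------------------------------------------------------------------------
# Cohort statistics
# ---------------------------------------------------------------------------

def cohort_table(
    reports: list[LineageReport],
    mouse_model: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per lineage: verdict, metastatic flag, PC, rho, D."""
    rows = []
    for r in reports:
        rows.append(
            dict(
                lineage_id=r.lineage_id,
                verdict=r.verdict,
                metastatic=r.metastatic,
                mouse_model=(mouse_model or {}).get(r.lineage_id, "NA"),
                pc=r.pc,
                rho=r.rho,
                d_mean=r.d_mean,
            )
        )
    return pd.DataFrame(rows)


@dataclass
class ContingencyResult:
    statistic: float
    p_value: float
    method: str
    table: list[list[int]]

    def to_dict(self) -> dict:
        return asdict(self)


def cohort_contingency_test(
    table: pd.DataFrame,
    grouping: str = "metastatic",
    method: str = "chi2",
    drop_artefacts: bool = True,
) -> ContingencyResult:
    """Is the punctuational verdict more common in one group?

    2x2 tables (e.g. metastatic vs non-metastatic) use Pearson
    chi-squared with Yates continuity correction; larger tables (mouse
    model) use plain Pearson chi-squared.  ``method='fisher'`` switches
    2x2 tables to Fisher's exact test.
    """
    if grouping not in table.columns:
        raise ParameterError(f"grouping column '{grouping}' not in table")
    df = table
    if drop_artefacts:
        df = df[df["verdict"] != "node_density_artefact"]
    groups = sorted(df[grouping].unique(), reverse=True)
    if len(groups) < 2:
        raise ParameterError("need at least two groups with lineages")
    counts = []
    for g in groups:
        sub = df[df[grouping] == g]
        if len(sub) == 0:
            raise ParameterError(f"empty group {g!r}")
        k = int((sub["verdict"] == "punctuational").sum())
        counts.append([k, len(sub) - k])
    ct = np.array(counts)
    if method == "fisher":
        if ct.shape != (2, 2):
            raise ParameterError("Fisher's exact test requires a 2x2 table")
        res = sps.fisher_exact(ct, alternative="two-sided")
        return ContingencyResult(float(res.statistic), float(res.pvalue),
                                 "fisher_exact", ct.tolist())
    correction = ct.shape == (2, 2)
    res = sps.chi2_contingency(ct, correction=correction)
    name = "chi2_yates" if correction else "chi2"
    return ContingencyResult(float(res.statistic), float(res.pvalue), name,
                             ct.tolist())


def cohort_deviation_model(table: pd.DataFrame):
    """OLS of the deviation from gradualism (rho) on the punctuational
    contribution (PC) across lineages; D annotates, it does not enter.

    Returns (slope, p_value, fitted statsmodels results).
    """
    df = table.dropna(subset=["pc", "rho"])
    if len(df) < 3:
        raise ParameterError("need at least 3 lineages with both PC and rho")
    x = df["pc"].to_numpy(dtype=float)
    y = df["rho"].to_numpy(dtype=float)
    if np.ptp(x) <= 0:
        raise DegenerateDataError("PC constant across lineages; slope not estimable")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return float(res.params[1]), float(res.pvalues[1]), res
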