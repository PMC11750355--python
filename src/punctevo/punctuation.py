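"""Per-lineage punctuational-evolution test battery.

For every tree in a posterior sample the lineage divergence of each cell
(LD, root-to-tip substitutions) is regressed on its diversification
count (DE) by PGLS; the curvilinear delta model screens for the
node-density reconstruction artefact; and the fitted slope is converted
into the punctuational contribution PC = 2(c-1) beta / T (the share of
total tree length attributable to bursts at diversification events) and
the deviation-from-gradualism correlation rho.

Classification follows the posterior-majority rules: a parameter is
significant overall iff it is significant at the 5% level in at least
50% of the posterior trees; a lineage shows the node-density artefact if
beta is significantly positive with delta > 1 in at least half the
trees, and punctuational evolution if beta is significantly positive
with delta <= 1 in at least half the trees and the posterior-average
delta is below 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDataError,
    DegenerateDesignError,
    MetadataError,
    ParameterError,
)
from .pgls import PhyloGLSWorkspace, fit_delta, fit_pgls
from .treeio import LineageTree, PosteriorTreeSet, path_table, scale_to_mean_branch_length

__all__ = [
    "run_punctuation_test",
    "classify_lineage",
    "LineageClassification",
    "punctuational_contribution",
    "rho_deviation",
    "summarize_punctuation",
    "PunctuationSummary",
    "fit_with_cnv",
    "test_slope_heterogeneity",
    "aggregate_significance",
]

logger = logging.getLogger(__name__)

#: columns of the per-tree fit table produced by run_punctuation_test
FIT_COLUMNS = [
    "tree",
    "status",
    "beta",
    "se_beta",
    "p_beta",
    "lam",
    "sigma2_g",
    "delta",
    "beta_delta",
    "p_beta_delta",
    "lam_delta",
    "pc",
    "rho",
    "sig_linear",
    "sig_delta",
]


def _fit_one_tree(tree: LineageTree, mean_branch: float, alpha: float):
    scaled = scale_to_mean_branch_length(tree, mean_branch)
    pt = path_table(scaled)
    ld = pt["LD"].to_numpy()
    de = pt["DE"].to_numpy(dtype=float)
    ws = PhyloGLSWorkspace(scaled)
    lin = fit_pgls(ld, de, ws, names=["intercept", "DE"])
    dl = fit_delta(ld, de, ws)
    pc = punctuational_contribution(lin.beta, scaled)
    sigma2_n = float(np.var(de, ddof=1))
    rho = rho_deviation(lin.beta, sigma2_n, lin.sigma2_marginal)
    return lin, dl, pc, rho


def run_punctuation_test(
    trees: PosteriorTreeSet,
    meta: pd.DataFrame | None = None,
    alpha: float = 0.05,
    mean_branch: float = 0.1,
) -> pd.DataFrame:
    """Fit the linear PGLS and the delta model to every posterior tree.

    Returns one row per tree with slope, significance, lambda, delta,
    punctuational contribution and rho; trees whose design is degenerate
    are recorded with a non-ok status instead of raising.
    """
    if trees[0].n_tips < 4:
        raise ParameterError("need at least 4 tips")
    rows = []
    for k, tree in enumerate(trees):
        try:
            lin, dl, pc, rho = _fit_one_tree(tree, mean_branch, alpha)
            rows.append(
                dict(
                    tree=k,
                    status="ok",
                    beta=lin.beta,
                    se_beta=lin["DE"]["se"],
                    p_beta=lin.p_beta,
                    lam=lin.lam,
                    sigma2_g=lin.sigma2_marginal,
                    delta=dl.delta,
                    beta_delta=dl.beta,
                    p_beta_delta=dl.p_beta,
                    lam_delta=dl.lam,
                    pc=pc,
                    rho=rho,
                    sig_linear=bool(lin.significant_positive(alpha=alpha)),
                    sig_delta=bool(dl.significant_positive(alpha=alpha)),
                )
            )
        except (DegenerateDataError, DegenerateDesignError) as exc:
            logger.warning("tree %d of %s non-estimable: %s", k, trees.lineage_id, exc)
            rows.append(
                dict(tree=k, status=f"non_estimable: {exc}", sig_linear=False,
                     sig_delta=False)
            )
    fits = pd.DataFrame(rows).reindex(columns=FIT_COLUMNS)
    fits.attrs["lineage_id"] = trees.lineage_id
    fits.attrs["alpha"] = alpha
    return fits


def aggregate_significance(p_values: np.ndarray, alpha: float = 0.05,
                           posterior_fraction: float = 0.5) -> bool:
    """Posterior-majority rule: significant overall iff significant at
    level alpha in at least ``posterior_fraction`` of the trees."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        return False
    return bool(np.mean(p < alpha) >= posterior_fraction)


@dataclass
class LineageClassification:
    """Posterior-level verdict for one lineage."""

    lineage_id: str
    n_trees: int
    n_ok: int
    frac_sig_linear: float
    frac_artefact: float
    frac_punctuational: float
    mean_delta: float
    verdict: str  # node_density_artefact | punctuational | gradual
    alpha: float = 0.05
    posterior_fraction: float = 0.5

    def to_dict(self) -> dict:
        return asdict(self)


def classify_lineage(
    fits: pd.DataFrame,
    posterior_fraction: float = 0.5,
    alpha: float | None = None,
) -> LineageClassification:
    """Apply the posterior-majority classification rules to per-tree fits.

    Verdict ``node_density_artefact`` when beta is significantly positive
    with delta > 1 in at least ``posterior_fraction`` of the trees;
    otherwise ``punctuational`` when beta is significantly positive with
    delta <= 1 in at least that fraction of trees and the mean delta is
    below 1; otherwise ``gradual``.
    """
    if fits is None or len(fits) == 0:
        raise ParameterError("empty fit table")
    alpha = float(fits.attrs.get("alpha", 0.05)) if alpha is None else alpha
    ok = fits["status"] == "ok"
    n_ok = int(ok.sum())
    if n_ok < 0.5 * len(fits):
        raise DegenerateDataError(
            f"more than half of the posterior trees are non-estimable "
            f"({len(fits) - n_ok}/{len(fits)})"
        )
    sub = fits.loc[ok]
    sig = sub["sig_delta"].to_numpy(dtype=bool)
    delta = sub["delta"].to_numpy(dtype=float)
    frac_art = float(np.mean(sig & (delta > 1)))
    frac_pun = float(np.mean(sig & (delta <= 1)))
    mean_delta = float(np.mean(delta))
    frac_lin = float(np.mean(sub["sig_linear"].to_numpy(dtype=bool)))
    if frac_art >= posterior_fraction:
        verdict = "node_density_artefact"
    elif frac_pun >= posterior_fraction and mean_delta < 1:
        verdict = "punctuational"
    else:
        verdict = "gradual"
    return LineageClassification(
        lineage_id=str(fits.attrs.get("lineage_id", "lineage")),
        n_trees=len(fits),
        n_ok=n_ok,
        frac_sig_linear=frac_lin,
        frac_artefact=frac_art,
        frac_punctuational=frac_pun,
        mean_delta=mean_delta,
        verdict=verdict,
        alpha=alpha,
        posterior_fraction=posterior_fraction,
    )


def punctuational_contribution(beta: float, tree: LineageTree) -> float:
    """Share of total tree length attributed to punctuational bursts:
    2(c-1) beta / T for a bifurcating tree of c tips and length T.

    ``beta`` must come from a fit on the identically scaled tree.
    """
    T = tree.total_length
    if T <= 0:
        raise DegenerateDataError("total tree length is zero")
    c = tree.n_tips
    if c < 2:
        raise ParameterError("tree must have at least 2 tips")
    return float(2.0 * (c - 1) * beta / T)


def rho_deviation(beta: float, sigma2_n: float, sigma2_g: float) -> float:
    """Correlation between LD and DE implied by the fitted slope and
    variance components: rho = beta sigma_n / sqrt(beta^2 sigma_n^2 +
    sigma_g^2), the gradual-punctuational covariance being taken as zero.

    Returns NaN (non-estimable) when the DE variance is zero.
    """
    if sigma2_g < 0:
        raise ParameterError("sigma2_g must be >= 0")
    if sigma2_n <= 0:
        return float("nan")
    denom = np.sqrt(beta * beta * sigma2_n + sigma2_g)
    if denom == 0.0:
        return 0.0
    return float(beta * np.sqrt(sigma2_n) / denom)


@dataclass
class PunctuationSummary:
    """Posterior-mean punctuational statistics for one lineage."""

    lineage_id: str
    c: int
    total_length: float
    beta: float
    pc: float
    rho: float
    sigma2_n: float
    sigma2_g: float
    n_trees_used: int
    n_pc_excluded: int

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_punctuation(
    fits: pd.DataFrame, trees: PosteriorTreeSet
) -> PunctuationSummary:
    """Posterior means of beta, PC and rho over estimable trees.

    PC values >= 1 are flagged and excluded from the mean (they indicate
    a slope larger than the tree can accommodate), mirroring the filter
    used for the location-specific contributions.
    """
    ok = fits["status"] == "ok"
    sub = fits.loc[ok]
    if len(sub) == 0:
        raise DegenerateDataError("no estimable trees to summarise")
    pc = sub["pc"].to_numpy(dtype=float)
    keep = pc < 1.0
    n_excl = int((~keep).sum())
    if n_excl:
        logger.info("excluding %d trees with PC >= 1 from the summary", n_excl)
    de = path_table(trees[0])["DE"].to_numpy(dtype=float)
    return PunctuationSummary(
        lineage_id=str(fits.attrs.get("lineage_id", "lineage")),
        c=trees[0].n_tips,
        total_length=float(np.mean([t.total_length for t in trees])),
        beta=float(sub["beta"].mean()),
        pc=float(pc[keep].mean()) if keep.any() else float("nan"),
        rho=float(sub["rho"].mean()),
        sigma2_n=float(np.var(de, ddof=1)),
        sigma2_g=float(sub["sigma2_g"].mean()),
        n_trees_used=int(keep.sum()),
        n_pc_excluded=n_excl,
    )


def fit_with_cnv(
    trees: PosteriorTreeSet,
    meta: pd.DataFrame,
    alpha: float = 0.05,
    mean_branch: float = 0.1,
    min_cnv_fraction: float = 0.95,
) -> pd.DataFrame:
    """Per-tree PGLS of LD on DE plus the per-cell CNV count.

    Cells without a CNV call are dropped (with a log record) and the tree
    pruned accordingly; the CNV column must be present for at least
    ``min_cnv_fraction`` of the cells.  When the CNV covariate is
    constant its coefficient is reported non-estimable and the fit falls
    back to the DE-only model.
    """
    from .treeio import prune_to_tips, _check_metadata

    meta = _check_metadata(meta)
    if meta["cnv_count"].isna().all():
        raise MetadataError("cnv_count column is entirely absent")
    m = meta.set_index("cell_id")
    labels = list(trees.tip_labels)
    have = [t for t in labels if not pd.isna(m.loc[t, "cnv_count"])]
    frac = len(have) / len(labels)
    if frac < min_cnv_fraction:
        raise MetadataError(
            f"CNV counts available for only {frac:.1%} of cells "
            f"(minimum {min_cnv_fraction:.0%})"
        )
    if len(have) < len(labels):
        logger.info("dropping %d cells without CNV counts", len(labels) - len(have))
    rows = []
    for k, tree in enumerate(trees):
        t = prune_to_tips(tree, have) if len(have) < len(labels) else tree
        scaled = scale_to_mean_branch_length(t, mean_branch)
        pt = path_table(scaled)
        ld = pt["LD"].to_numpy()
        de = pt["DE"].to_numpy(dtype=float)
        cnv = m.loc[list(scaled.tip_labels), "cnv_count"].to_numpy(dtype=float)
        ws = PhyloGLSWorkspace(scaled)
        try:
            fit = fit_pgls(
                ld,
                np.column_stack([de, cnv]),
                ws,
                names=["intercept", "DE", "CNV"],
            )
            rows.append(
                dict(
                    tree=k,
                    status="ok",
                    beta=fit.beta,
                    p_beta=fit.p_beta,
                    gamma=fit["CNV"]["coef"],
                    p_gamma=fit["CNV"]["p"],
                    lam=fit.lam,
                    sig_beta=bool(fit.significant_positive(alpha=alpha)),
                    sig_gamma=bool(fit["CNV"]["p"] < alpha),
                )
            )
        except DegenerateDesignError:
            # constant CNV column: report beta from the DE-only model
            fit = fit_pgls(ld, de, ws, names=["intercept", "DE"])
            rows.append(
                dict(
                    tree=k,
                    status="gamma_non_estimable",
                    beta=fit.beta,
                    p_beta=fit.p_beta,
                    gamma=float("nan"),
                    p_gamma=float("nan"),
                    lam=fit.lam,
                    sig_beta=bool(fit.significant_positive(alpha=alpha)),
                    sig_gamma=False,
                )
            )
    out = pd.DataFrame(rows)
    out.attrs["lineage_id"] = trees.lineage_id
    out.attrs["alpha"] = alpha
    return out


def test_slope_heterogeneity(
    trees: PosteriorTreeSet,
    meta: pd.DataFrame,
    alpha: float = 0.05,
    mean_branch: float = 0.1,
) -> pd.DataFrame:
    """Per-tree fit of LD ~ DE + I_M + DE x I_M: does the metastatic
    slope differ from the primary slope within the lineage?

    Returns per-tree interaction estimates; ``fits.attrs['applicable']``
    is False for single-location lineages (no rows in that case).
    """
    from .treeio import _check_metadata

    meta = _check_metadata(meta)
    m = meta.set_index("cell_id")
    locs = m.loc[list(trees.tip_labels), "location"]
    applicable = locs.nunique() == 2
    rows = []
    if applicable:
        for k, tree in enumerate(trees):
            scaled = scale_to_mean_branch_length(tree, mean_branch)
            pt = path_table(scaled)
            ld = pt["LD"].to_numpy()
            de = pt["DE"].to_numpy(dtype=float)
            im = (m.loc[list(scaled.tip_labels), "location"] == "M").to_numpy(dtype=float)
            X = np.column_stack([de, im, de * im])
            try:
                fit = fit_pgls(
                    ld, X, scaled, names=["intercept", "DE", "I_M", "DExI_M"]
                )
                r = fit["DExI_M"]
                rows.append(
                    dict(
                        tree=k,
                        status="ok",
                        beta=fit.beta,
                        interaction=r["coef"],
                        p_interaction=r["p"],
                        sig_interaction=bool(r["p"] < alpha),
                    )
                )
            except (DegenerateDataError, DegenerateDesignError) as exc:
                rows.append(
                    dict(tree=k, status=f"non_estimable: {exc}",
                         sig_interaction=False)
                )
    out = pd.DataFrame(
        rows,
        columns=["tree", "status", "beta", "interaction", "p_interaction",
                 "sig_interaction"],
    )
    out.attrs["lineage_id"] = trees.lineage_id
    out.attrs["alpha"] = alpha
    out.attrs["applicable"] = bool(applicable)
    return out
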