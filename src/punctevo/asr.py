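"""Two-state ancestral-state reconstruction of anatomical location.

A continuous-time Markov chain over {P (primary tumour), M (distal
metastasis)} runs along the tree with rates q_PM and q_MP; the root is
fixed in state P (every lineage starts in the primary tumour).  Branch
lengths are power-transformed by kappa, estimated jointly with the rates
by maximum likelihood (kappa -> 0 approaches a punctuational tree in
which only the number of nodes matters).  Marginal node-state
probabilities come from the standard up-down (inside-outside) pass of
Felsenstein's pruning algorithm.

Branches are then categorized by their endpoint states (P, M,
transition, or undefined), and the per-location punctuational
contributions PC_P = N_P beta / T_P and PC_M = N_M beta / T_M are
compared across the posterior by a paired Wilcoxon test with Bonferroni
correction across lineages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ParameterError
from .treeio import LineageTree

__all__ = [
    "Mk2Fit",
    "fit_mk2",
    "mk2_loglik",
    "marginal_states",
    "BranchPartition",
    "categorize_branches",
    "LocationContribution",
    "location_contribution",
    "LocationContrast",
    "compare_location_contributions",
    "states_from_meta",
]

logger = logging.getLogger(__name__)

_P, _M = 0, 1
UNDEFINED = -1

_RATE_BOUNDS = (np.log(1e-6), np.log(1e4))
_KAPPA_BOUNDS = (0.0, 3.0)


def states_from_meta(tree: LineageTree, meta: pd.DataFrame) -> np.ndarray:
    """0/1 (P/M) tip-state vector aligned to the tree's tip order."""
    m = meta.set_index("cell_id")["location"]
    missing = [t for t in tree.tip_labels if t not in m.index]
    if missing:
        from .errors import MetadataError

        raise MetadataError(f"tips missing from metadata: {missing[:10]}")
    return (m.loc[list(tree.tip_labels)] == "M").to_numpy(dtype=np.int64)


def _transition_matrices(bl: np.ndarray, q01: float, q10: float) -> np.ndarray:
    """Closed-form 2-state CTMC transition matrices for each branch.

    Returns array of shape (n, 2, 2) with entry [e, i, j] = P(j | i, t_e).
    """
    s = q01 + q10
    n = bl.shape[0]
    out = np.empty((n, 2, 2))
    if s <= 0:
        out[:] = np.eye(2)
        return out
    e = np.exp(-s * bl)
    pi0, pi1 = q10 / s, q01 / s
    out[:, 0, 0] = pi0 + pi1 * e
    out[:, 0, 1] = pi1 * (1.0 - e)
    out[:, 1, 0] = pi0 * (1.0 - e)
    out[:, 1, 1] = pi1 + pi0 * e
    return out


def _up_pass(tree: LineageTree, tip_states: np.ndarray, Pm: np.ndarray):
    """Pruning partials (normalized) and total log-likelihood scale.

    up[v, s] ∝ P(tip data below v | state(v) = s); the root likelihood in
    state P is up[root, 0] * exp(log_scale).
    """
    n = tree.n_nodes
    up = np.zeros((n, 2))
    up[np.arange(tree.n_tips), tip_states] = 1.0
    log_scale = 0.0
    ch = tree.children()
    for v in tree.postorder():
        if v < tree.n_tips:
            continue
        prod = np.ones(2)
        for c in ch[v]:
            prod *= Pm[c] @ up[c]
        tot = prod.sum()
        if tot <= 0:
            return up, -np.inf
        up[v] = prod / tot
        log_scale += np.log(tot)
    return up, log_scale


def mk2_loglik(
    tree: LineageTree,
    tip_states: np.ndarray,
    q_pm: float,
    q_mp: float,
    kappa: float = 1.0,
) -> float:
    """Log-likelihood of the tip states with the root fixed in state P."""
    if q_pm < 0 or q_mp < 0:
        raise ParameterError("rates must be >= 0")
    bl = tree.length.copy()
    pos = bl > 0
    if kappa != 1.0:
        bl[pos] = bl[pos] ** kappa
    Pm = _transition_matrices(bl, q_pm, q_mp)
    up, log_scale = _up_pass(tree, np.asarray(tip_states, dtype=np.int64), Pm)
    lik_root = up[tree.root, _P]
    if lik_root <= 0 or not np.isfinite(log_scale):
        return -np.inf
    return float(np.log(lik_root) + log_scale)


@dataclass
class Mk2Fit:
    """ML estimates of the two-state location model."""

    q_pm: float
    q_mp: float
    kappa: float
    loglik: float
    converged: bool
    boundary: bool
    n_tips: int

    def to_dict(self) -> dict:
        return asdict(self)


def fit_mk2(
    tree: LineageTree,
    tip_states: np.ndarray,
    estimate_kappa: bool = True,
    kappa: float | None = None,
    tol: float = 1e-6,
) -> Mk2Fit:
    """Maximum-likelihood fit of (q_PM, q_MP, kappa) with root fixed at P.

    The tree should already be scaled to the analysis mean branch length.
    Rates are optimized on the log scale from several starting points;
    kappa is bounded to [0, 3] (fixed via ``kappa`` or when
    ``estimate_kappa`` is False, in which case kappa = 1).
    """
    tip_states = np.asarray(tip_states, dtype=np.int64)
    if tip_states.shape[0] != tree.n_tips:
        raise ParameterError("tip_states not aligned with tips")
    if not np.all(np.isin(tip_states, [0, 1])):
        raise ParameterError("tip states must be 0 (P) or 1 (M)")
    monomorphic = np.all(tip_states == tip_states[0])
    fixed_kappa = kappa if kappa is not None else (None if estimate_kappa else 1.0)

    def objective(x: np.ndarray) -> float:
        q01, q10 = np.exp(x[0]), np.exp(x[1])
        kap = x[2] if fixed_kappa is None else fixed_kappa
        return -mk2_loglik(tree, tip_states, q01, q10, kap)

    n_params = 3 if fixed_kappa is None else 2
    bounds = [_RATE_BOUNDS, _RATE_BOUNDS] + (
        [_KAPPA_BOUNDS] if fixed_kappa is None else []
    )
    height = max(tree.tip_depths().mean(), 1e-12)
    base = 1.0 / height
    starts = []
    for f01 in (0.3, 3.0):
        for f10 in (0.3, 3.0):
            starts.append([np.log(base * f01), np.log(base * f10)])
    if monomorphic:
        starts = [[_RATE_BOUNDS[0], _RATE_BOUNDS[0]]]
    best = None
    for s in starts:
        x0 = np.array(s + ([1.0] if fixed_kappa is None else []))[:n_params]
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    q01, q10 = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
    kap = float(best.x[2]) if fixed_kappa is None else float(fixed_kappa)
    at_bound = bool(
        best.x[0] <= _RATE_BOUNDS[0] + 1e-9 or best.x[1] <= _RATE_BOUNDS[0] + 1e-9
    )
    if monomorphic:
        logger.warning(
            "all tips share one state; rate estimates lie at the lower bound"
        )
    return Mk2Fit(
        q_pm=q01,
        q_mp=q10,
        kappa=kap,
        loglik=float(-best.fun),
        converged=bool(best.success),
        boundary=at_bound or monomorphic,
        n_tips=tree.n_tips,
    )


def marginal_states(
    tree: LineageTree,
    fit: Mk2Fit,
    tip_states: np.ndarray,
    tie_tol: float = 0.0,
) -> pd.DataFrame:
    """Marginal state probabilities for every internal node.

    Up-down pass under the fitted model with the root fixed in state P.
    Returns a DataFrame indexed by node id with columns ``prob_P`` and
    ``state`` (0 = P, 1 = M, -1 = undefined on an exact tie; ``tie_tol``
    widens the tie band).  The root has prob_P = 1 by construction.
    """
    tip_states = np.asarray(tip_states, dtype=np.int64)
    bl = tree.length.copy()
    pos = bl > 0
    if fit.kappa != 1.0:
        bl[pos] = bl[pos] ** fit.kappa
    Pm = _transition_matrices(bl, fit.q_pm, fit.q_mp)
    up, _ = _up_pass(tree, tip_states, Pm)
    n = tree.n_nodes
    root = tree.root
    ch = tree.children()
    down = np.zeros((n, 2))
    down[root] = [1.0, 0.0]  # root prior fixed on P
    for u in tree.preorder():
        if u < tree.n_tips:
            continue
        kids = ch[u]
        msgs = {c: Pm[c] @ up[c] for c in kids}
        for c in kids:
            sib_msg = np.ones(2)
            for w in kids:
                if w != c:
                    sib_msg *= msgs[w]
            contrib = (down[u] * sib_msg) @ Pm[c]
            tot = contrib.sum()
            down[c] = contrib / tot if tot > 0 else 0.5
    marg = up * down
    tot = marg.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        marg = np.where(tot > 0, marg / tot, 0.5)
    internal = np.array([v for v in range(n) if v >= tree.n_tips])
    prob_p = marg[internal, _P]
    state = np.where(
        np.abs(prob_p - 0.5) <= tie_tol,
        UNDEFINED,
        np.where(prob_p > 0.5, _P, _M),
    )
    # exact-equality tie -> undefined even with tie_tol = 0
    state[prob_p == 0.5] = UNDEFINED
    out = pd.DataFrame({"node": internal, "prob_P": prob_p, "state": state})
    out.loc[out["node"] == root, ["prob_P", "state"]] = [1.0, _P]
    return out.set_index("node")


@dataclass
class BranchPartition:
    """Per-branch location categories and per-category tallies."""

    category: np.ndarray  # per node (its parent branch); root entry ignored
    tree: LineageTree = field(repr=False)

    CAT_P = 0
    CAT_M = 1
    CAT_TRANSITION = 2
    CAT_UNDEFINED = 3

    def counts(self, terminal_policy: str = "exclude") -> dict[str, float]:
        """Branch counts and summed lengths per category.

        ``terminal_policy='exclude'`` restricts to internal branches
        (terminal branches are short and would bias the per-location
        contribution); 'include' uses all branches.
        """
        if terminal_policy not in ("exclude", "include"):
            raise ParameterError("terminal_policy must be 'exclude' or 'include'")
        t = self.tree
        idx = np.arange(t.n_nodes)
        mask = idx != t.root
        if terminal_policy == "exclude":
            mask &= idx >= t.n_tips
        out: dict[str, float] = {}
        for name, cat in (
            ("P", self.CAT_P),
            ("M", self.CAT_M),
            ("transition", self.CAT_TRANSITION),
            ("undefined", self.CAT_UNDEFINED),
        ):
            sel = mask & (self.category == cat)
            out[f"N_{name}"] = int(sel.sum())
            out[f"T_{name}"] = float(t.length[sel].sum())
        return out


def categorize_branches(
    tree: LineageTree,
    node_states: pd.DataFrame,
    tip_states: np.ndarray,
) -> BranchPartition:
    """Assign each branch a location category from its endpoint states.

    Both endpoints P -> P; both M -> M; differing -> transition; either
    endpoint undefined -> undefined.  Tips use their observed locations.
    """
    tip_states = np.asarray(tip_states, dtype=np.int64)
    n = tree.n_nodes
    state = np.full(n, UNDEFINED, dtype=np.int64)
    state[: tree.n_tips] = tip_states
    state[node_states.index.to_numpy()] = node_states["state"].to_numpy(dtype=np.int64)
    cat = np.full(n, BranchPartition.CAT_UNDEFINED, dtype=np.int64)
    for v in range(n):
        p = tree.parent[v]
        if p < 0:
            continue
        a, b = state[p], state[v]
        if a == UNDEFINED or b == UNDEFINED:
            cat[v] = BranchPartition.CAT_UNDEFINED
        elif a == b:
            cat[v] = BranchPartition.CAT_P if a == _P else BranchPartition.CAT_M
        else:
            cat[v] = BranchPartition.CAT_TRANSITION
    return BranchPartition(category=cat, tree=tree)


@dataclass
class LocationContribution:
    """Per-tree location-specific punctuational contributions."""

    pc_p: float
    pc_m: float
    n_p: int
    n_m: int
    t_p: float
    t_m: float
    included: bool
    exclusion_reason: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def location_contribution(
    partition: BranchPartition,
    beta: float,
    terminal_policy: str = "exclude",
    min_branches: int = 10,
    pc_max: float = 1.0,
) -> LocationContribution:
    """PC_P = N_P beta / T_P and PC_M = N_M beta / T_M.

    The per-location contribution is the punctuational length attributed
    to that location's branches (one burst of mean beta per branch) over
    that location's share of tree length.  A tree enters the paired
    contrast only when both locations have at least ``min_branches``
    branches and both contributions are below ``pc_max``.
    """
    c = partition.counts(terminal_policy)
    n_p, n_m = int(c["N_P"]), int(c["N_M"])
    t_p, t_m = float(c["T_P"]), float(c["T_M"])
    reason = None
    if n_p < min_branches or n_m < min_branches:
        reason = f"fewer than {min_branches} branches in one location (N_P={n_p}, N_M={n_m})"
    if t_p <= 0 or t_m <= 0:
        reason = "zero total branch length in one location"
        return LocationContribution(
            float("nan"), float("nan"), n_p, n_m, t_p, t_m, False, reason
        )
    pc_p = n_p * beta / t_p
    pc_m = n_m * beta / t_m
    if reason is None and (pc_p >= pc_max or pc_m >= pc_max):
        reason = f"contribution >= {pc_max} (PC_P={pc_p:.3f}, PC_M={pc_m:.3f})"
    return LocationContribution(
        float(pc_p), float(pc_m), n_p, n_m, t_p, t_m, reason is None, reason
    )


@dataclass
class LocationContrast:
    """Posterior sample of paired per-location contributions."""

    lineage_id: str
    pc_p: np.ndarray
    pc_m: np.ndarray
    n_total_trees: int

    @property
    def n_qualifying(self) -> int:
        return int(len(self.pc_p))


def compare_location_contributions(
    contrasts: list[LocationContrast],
    alpha: float = 0.05,
    min_trees: int = 20,
) -> pd.DataFrame:
    """Paired two-sided Wilcoxon test of PC_M vs PC_P per lineage, with
    Bonferroni correction across the lineages tested.

    Lineages with fewer than ``min_trees`` qualifying posterior trees are
    reported untestable and do not count toward the correction.
    """
    testable = [c for c in contrasts if c.n_qualifying >= min_trees]
    L = len(testable)
    adj_alpha = alpha / L if L else float("nan")
    rows = []
    for c in contrasts:
        if c.n_qualifying < min_trees:
            rows.append(
                dict(
                    lineage_id=c.lineage_id,
                    n_qualifying=c.n_qualifying,
                    testable=False,
                    median_diff=float("nan"),
                    direction="untestable",
                    p_value=float("nan"),
                    adjusted_alpha=adj_alpha,
                    significant=False,
                )
            )
            continue
        diff = np.asarray(c.pc_m) - np.asarray(c.pc_p)
        if np.allclose(diff, 0.0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(c.pc_m, c.pc_p, alternative="two-sided").pvalue)
        med = float(np.median(diff))
        rows.append(
            dict(
                lineage_id=c.lineage_id,
                n_qualifying=c.n_qualifying,
                testable=True,
                median_diff=med,
                direction="M>P" if med > 0 else ("M<P" if med < 0 else "none"),
                p_value=p,
                adjusted_alpha=adj_alpha,
                significant=bool(p < adj_alpha),
            )
        )
    return pd.DataFrame(rows)
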