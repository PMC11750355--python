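"""Fritz-Purvis phylogenetic dispersion D for a binary tip trait.

Used here as the "metastatic complexity" of a lineage: D near 1 means
metastatic cells are scattered over the tree as if labelled at random
(polyphyletic seeding and reseeding), D near 0 or below means they are
clumped in few clades (a single monophyletic seeding event).

Construction: nodal trait values are estimated tips-rootward by
branch-length-weighted averaging of daughter values; the observed
statistic d_obs is the sum over internal nodes of the absolute
difference between daughter values.  d_obs is calibrated against two
nulls — random shuffles of the tip states (phylogenetically random,
expectation d_r) and threshold-Brownian simulations matched to the
observed prevalence (maximally heritable, expectation d_b) — giving

    D = (d_obs - mean d_b) / (mean d_r - mean d_b).

Because every nodal value is a fixed linear combination of tip states,
the whole construction reduces to one sparse-weights matrix per tree and
each null replicate to a matrix-vector product.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ParameterError
from .pgls import phylo_covariance
from .treeio import LineageTree, PosteriorTreeSet

__all__ = [
    "sum_sister_differences",
    "phylo_d",
    "posterior_mean_d",
    "DResult",
]

#: relative floor applied to zero-length branches inside nodal averaging
_ZERO_BRANCH_FLOOR = 1e-8


def _sister_weight_matrix(tree: LineageTree) -> np.ndarray:
    """Rows: internal nodes; row v maps tip states to the difference of
    the two daughter nodal values at v (nodal values are inverse-branch-
    length weighted averages propagated rootward)."""
    n, nt = tree.n_nodes, tree.n_tips
    floor = _ZERO_BRANCH_FLOOR * max(tree.mean_branch_length, 1e-300)
    vec = np.zeros((n, nt))
    vec[np.arange(nt), np.arange(nt)] = 1.0
    rows = np.zeros((n - nt, nt))
    ch = tree.children()
    internal = {}
    k = 0
    for v in tree.postorder():
        if v < nt:
            continue
        c1, c2 = ch[v]
        w1 = 1.0 / max(float(tree.length[c1]), floor)
        w2 = 1.0 / max(float(tree.length[c2]), floor)
        vec[v] = (w1 * vec[c1] + w2 * vec[c2]) / (w1 + w2)
        rows[k] = vec[c1] - vec[c2]
        internal[v] = k
        k += 1
    return rows


def sum_sister_differences(tree: LineageTree, states: np.ndarray) -> float:
    """Observed dispersion statistic: sum over internal nodes of the
    absolute difference between daughter nodal values."""
    states = np.asarray(states, dtype=np.float64)
    if states.shape[0] != tree.n_tips:
        raise ParameterError("states not aligned with tips")
    u = np.unique(states)
    if u.size < 2:
        raise DegenerateDataError("trait is monomorphic; dispersion undefined")
    A = _sister_weight_matrix(tree)
    return float(np.abs(A @ states).sum())


@dataclass
class DResult:
    """Dispersion statistic with its two calibration nulls."""

    d_obs: float
    mean_d_random: float
    mean_d_brownian: float
    D: float
    n_perm: int
    n_bm: int
    estimable: bool

    def to_dict(self) -> dict:
        return asdict(self)


def phylo_d(
    tree: LineageTree,
    states: np.ndarray,
    n_perm: int = 1000,
    n_bm: int = 1000,
    rng=None,
) -> DResult:
    """Fritz-Purvis D for binary tip states on one tree.

    The permutation null shuffles tip states preserving prevalence; the
    Brownian null simulates Brownian values under the tree covariance and
    thresholds them at the observed prevalence (rank cut).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    states = np.asarray(states)
    if states.dtype.kind in "UO":  # allow 'P'/'M' labels
        states = (states == "M").astype(np.int64)
    states = states.astype(np.float64)
    if not np.all(np.isin(states, [0.0, 1.0])):
        raise ParameterError("states must be binary 0/1 (or P/M labels)")
    if n_perm < 1 or n_bm < 1:
        raise ParameterError("n_perm and n_bm must be >= 1")
    n = tree.n_tips
    if states.shape[0] != n:
        raise ParameterError("states not aligned with tips")
    if np.unique(states).size < 2:
        raise DegenerateDataError("trait is monomorphic; dispersion undefined")
    A = _sister_weight_matrix(tree)
    d_obs = float(np.abs(A @ states).sum())

    S = np.tile(states[:, None], (1, n_perm))
    S = rng.permuted(S, axis=0)
    d_r = np.abs(A @ S).sum(axis=0)

    V = phylo_covariance(tree)
    jitter = 1e-10 * max(float(np.diag(V).max()), 1.0)
    L = np.linalg.cholesky(V + jitter * np.eye(n))
    Z = L @ rng.standard_normal((n, n_bm))
    k = int(states.sum())
    # rank-based threshold: the k largest Brownian values become state 1
    order = np.argsort(Z, axis=0)
    B = np.zeros_like(Z)
    np.put_along_axis(B, order[n - k :, :], 1.0, axis=0)
    d_b = np.abs(A @ B).sum(axis=0)

    mean_r, mean_b = float(d_r.mean()), float(d_b.mean())
    denom = mean_r - mean_b
    estimable = abs(denom) > 1e-12 * max(abs(mean_r), abs(mean_b), 1.0)
    D = (d_obs - mean_b) / denom if estimable else float("nan")
    return DResult(
        d_obs=d_obs,
        mean_d_random=mean_r,
        mean_d_brownian=mean_b,
        D=float(D),
        n_perm=n_perm,
        n_bm=n_bm,
        estimable=estimable,
    )


def posterior_mean_d(
    trees: PosteriorTreeSet,
    meta: pd.DataFrame,
    n_perm: int = 1000,
    n_bm: int = 1000,
    rng=None,
    max_trees: int | None = None,
) -> tuple[float, pd.DataFrame]:
    """Mean D across posterior trees (nulls re-simulated per tree with
    child seeds).  Returns the posterior mean and the per-tree table."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    m = meta.set_index("cell_id")["location"]
    use = trees.trees if max_trees is None else trees.trees[:max_trees]
    rows = []
    for k, t in enumerate(use):
        states = (m.loc[list(t.tip_labels)] == "M").to_numpy(dtype=np.int64)
        r = phylo_d(t, states, n_perm=n_perm, n_bm=n_bm, rng=rng)
        rows.append(dict(tree=k, **r.to_dict()))
    df = pd.DataFrame(rows)
    ok = df["estimable"]
    return float(df.loc[ok, "D"].mean()), df
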