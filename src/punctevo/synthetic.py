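"""Synthetic lineage-tracing data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: Yule topologies; branch lengths that mix a gradual clock
component (``g_rate`` expected substitutions per unit time) with
non-negative punctuational jumps of mean ``punct_size`` drawn once per
branch (one burst per daughter lineage of each diversification event);
tip anatomical locations from a two-state continuous-time Markov process
rooted in the primary state; Poisson copy-number counts accumulated along
paths; and pseudo-posterior tree samples built from multiplicative
log-normal branch jitter plus occasional nearest-neighbour interchanges.

Every stochastic quantity is recorded in a truth record so that
parameter-recovery experiments can compare estimates against the values
actually realised, not just against the configured means.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ParameterError
from .treeio import LineageTree, PosteriorTreeSet

__all__ = [
    "SimulationConfig",
    "SyntheticLineage",
    "simulate_topology",
    "balanced_tree",
    "apply_molecular_clock",
    "inject_node_density_artefact",
    "simulate_locations",
    "simulate_cnv",
    "make_posterior",
    "punct_size_for_contribution",
    "make_lineage",
]

_MET_SITES = ("lymph node", "liver", "bone")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic lineage.

    Defaults mirror the analysis regime the pipeline is designed for:
    a few hundred cells per lineage, a posterior of branch-jittered
    trees, and punctuational jumps whose share of total tree length is
    set through ``target_pc``.
    """

    n_tips: int = 300
    birth_rate: float = 1.0
    g_rate: float = 1.0
    #: mean punctuational jump per branch (substitutions); overridden by
    #: target_pc when that is set.
    punct_size: float = 0.0
    #: expected punctuational fraction of total tree length.
    target_pc: float | None = None
    #: coefficient of variation of the gamma-distributed jumps.
    punct_noise: float = 0.5
    #: node-density deformation strength; 1 = no artefact.
    delta_true: float = 1.0
    q_pm: float = 0.0
    q_mp: float = 0.0
    seeding_mode: str = "polyphyletic"
    #: time-branch scaling inside the metastatic clade (< 1 = the
    #: metastatic subpopulation diversifies faster than the primary).
    met_branch_scale: float = 1.0
    #: multiplier on jump means for branches whose child is metastatic.
    met_jump_scale: float = 1.0
    cnv_rate: float = 1.0
    #: extra expected CNV gains per unit punctuational jump length.
    cnv_per_jump: float = 0.0
    n_posterior: int = 100
    jitter_sd: float = 0.1
    nni_fraction: float = 0.02
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_tips < 4:
            raise ParameterError("n_tips must be >= 4")
        if self.n_posterior < 1:
            raise ParameterError("n_posterior must be >= 1")
        for name in ("birth_rate", "g_rate", "punct_size", "punct_noise",
                     "q_pm", "q_mp", "cnv_rate", "cnv_per_jump", "jitter_sd",
                     "nni_fraction", "met_branch_scale", "met_jump_scale"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.delta_true < 1:
            raise ParameterError("delta_true must be >= 1")
        if self.target_pc is not None and not (0.0 <= self.target_pc < 1.0):
            raise ParameterError("target_pc must lie in [0, 1)")
        if self.seeding_mode not in ("monophyletic", "polyphyletic", "reseeding"):
            raise ParameterError(f"unknown seeding_mode '{self.seeding_mode}'")


@dataclass
class SyntheticLineage:
    """A generated lineage plus its ground truth."""

    posterior: PosteriorTreeSet
    meta: pd.DataFrame
    truth: dict
    config: SimulationConfig


def simulate_topology(n_tips: int, birth_rate: float = 1.0, rng=None) -> LineageTree:
    """Yule (pure-birth) tree with ``n_tips`` tips, branch lengths in time
    units, extended to a common present (ultrametric)."""
    rng = _rng(rng)
    if n_tips < 2:
        raise ParameterError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ParameterError("birth_rate must be positive")
    parent_rec: list[int] = [-1, -1]
    t0 = [0.0, 0.0]
    t1: list[float | None] = [None, None]
    active = [0, 1]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        j = int(rng.integers(k))
        i = active.pop(j)
        t1[i] = t
        for _ in range(2):
            parent_rec.append(i)
            t0.append(t)
            t1.append(None)
            active.append(len(parent_rec) - 1)
    t_end = t + rng.exponential(1.0 / (n_tips * birth_rate))
    for i in active:
        t1[i] = t_end

    tips = [i for i, x in enumerate(t1) if i in set(active)]
    # preserve record order for tips and internals
    tip_set = set(active)
    tips = [i for i in range(len(parent_rec)) if i in tip_set]
    internals = [i for i in range(len(parent_rec)) if i not in tip_set]
    n = n_tips
    node_of = {}
    for k, i in enumerate(tips):
        node_of[i] = k
    for k, i in enumerate(internals):
        node_of[i] = n + k
    root = n + len(internals)  # the virtual root joining records 0 and 1
    parent = np.full(root + 1, -1, dtype=np.int64)
    length = np.zeros(root + 1)
    for i in range(len(parent_rec)):
        v = node_of[i]
        parent[v] = node_of[parent_rec[i]] if parent_rec[i] >= 0 else root
        length[v] = float(t1[i] - t0[i])
    labels = [f"c{k:04d}" for k in range(n_tips)]
    return LineageTree(parent, length, labels)


def balanced_tree(n_tips: int, branch_length: float = 1.0) -> LineageTree:
    """Fully balanced bifurcating tree (n_tips must be a power of two)."""
    if n_tips < 2 or (n_tips & (n_tips - 1)) != 0:
        raise ParameterError("n_tips must be a power of two >= 2")
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    length = np.full(n_nodes, float(branch_length))
    # internal nodes n_tips .. n_nodes-1; root is the last one
    nodes = list(range(n_tips))
    nxt = n_tips
    while len(nodes) > 1:
        nxt_nodes = []
        for a, b in zip(nodes[::2], nodes[1::2]):
            parent[a] = nxt
            parent[b] = nxt
            nxt_nodes.append(nxt)
            nxt += 1
        nodes = nxt_nodes
    length[nodes[0]] = 0.0
    return LineageTree(parent, length, [f"c{k:04d}" for k in range(n_tips)])


def punct_size_for_contribution(
    tree: LineageTree,
    g_rate: float,
    pc: float,
    jump_scale: np.ndarray | None = None,
) -> float:
    """Mean jump size giving an expected punctuational fraction ``pc``.

    Solves pc = S*beta / (S*beta + G) for beta, where G is the expected
    gradual length g_rate * total time and S the summed per-branch jump
    multipliers (2(c-1) when uniform).
    """
    if not (0.0 <= pc < 1.0):
        raise ParameterError("pc must lie in [0, 1)")
    if pc == 0.0:
        return 0.0
    G = g_rate * tree.total_length
    if jump_scale is None:
        S = float(tree.n_nodes - 1)
    else:
        s = np.asarray(jump_scale, dtype=np.float64).copy()
        s[tree.root] = 0.0
        S = float(s.sum())
    if G <= 0 or S <= 0:
        raise DegenerateDataError("gradual length and jump weights must be positive")
    return pc * G / ((1.0 - pc) * S)


def apply_molecular_clock(
    tree: LineageTree,
    g_rate: float,
    punct_size: float,
    punct_noise: float = 0.5,
    rng=None,
    jump_scale: np.ndarray | None = None,
) -> tuple[LineageTree, dict]:
    """Convert a time tree to a substitution tree: gradual clock plus
    per-branch punctuational jumps.

    Each non-root branch length becomes ``g_rate * time + J`` where J is a
    gamma jump with mean ``punct_size`` (optionally scaled per branch via
    ``jump_scale``) and coefficient of variation ``punct_noise``.  The
    returned truth record stores every jump and the realised punctuational
    fraction ``pc_true = sum(J) / total length``.
    """
    rng = _rng(rng)
    if g_rate < 0 or punct_size < 0 or punct_noise < 0:
        raise ParameterError("rates and jump parameters must be >= 0")
    nb = tree.n_nodes
    root = tree.root
    gradual = g_rate * tree.length
    gradual[root] = 0.0
    means = np.full(nb, punct_size)
    if jump_scale is not None:
        means = means * np.asarray(jump_scale, dtype=np.float64)
    means[root] = 0.0
    if punct_size == 0.0:
        jumps = np.zeros(nb)
    elif punct_noise == 0.0:
        jumps = means.copy()
    else:
        shape = 1.0 / punct_noise**2
        jumps = np.where(
            means > 0, rng.gamma(shape, 1.0, size=nb) * means / shape, 0.0
        )
    new = gradual + jumps
    total = float(new.sum())
    truth = {
        "jumps": jumps,
        "gradual": gradual,
        "pc_true": float(jumps.sum() / total) if total > 0 else 0.0,
    }
    return tree.with_lengths(new), truth


def inject_node_density_artefact(tree: LineageTree, delta_true: float, rng=None) -> LineageTree:
    """Stylised node-density deformation of branch lengths.

    Each tip path is shrunk toward ``LD ~ DE**(1 - 1/delta_true)`` — a
    concave increasing LD-DE relation that mimics the systematic
    underestimation of branch lengths in sparsely noded regions of
    reconstructed trees.  ``delta_true = 1`` is the identity; for
    ``delta_true > 1`` every multiplier is <= 1 so total length shrinks.
    The deformation is applied per branch as the mean multiplier of its
    descendant tips.
    """
    if delta_true < 1:
        raise ParameterError("delta_true must be >= 1")
    if delta_true == 1.0:
        return tree.copy()
    de = tree.tip_path_node_counts().astype(np.float64)
    m_tip = (de / de.max()) ** (1.0 - 1.0 / delta_true)
    factor = np.ones(tree.n_nodes)
    tipsets = tree.subtree_tips()
    for v in range(tree.n_nodes):
        if v != tree.root:
            factor[v] = float(m_tip[tipsets[v]].mean())
    return tree.with_lengths(tree.length * factor)


def _ctmc_branch_end_state(state: int, t: float, q01: float, q10: float,
                           rng: np.random.Generator) -> int:
    rates = (q01, q10)
    remain = t
    while True:
        r = rates[state]
        if r <= 0:
            return state
        w = rng.exponential(1.0 / r)
        if w >= remain:
            return state
        remain -= w
        state = 1 - state


def simulate_locations(
    tree: LineageTree,
    q_pm: float,
    q_mp: float,
    seeding_mode: str = "polyphyletic",
    rng=None,
    clade_frac: tuple[float, float] = (0.15, 0.5),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Anatomical locations under a two-state CTMC rooted in P (state 0).

    Modes: ``monophyletic`` forces a single P-to-M transition at one
    internal node (its whole subtree becomes M); ``polyphyletic`` runs the
    CTMC with the return rate forced to 0; ``reseeding`` runs the CTMC
    with both rates.  Returns the tip metadata table and the true state
    (0 = P, 1 = M) of every node.
    """
    rng = _rng(rng)
    if q_pm < 0 or q_mp < 0:
        raise ParameterError("transition rates must be >= 0")
    n = tree.n_nodes
    states = np.zeros(n, dtype=np.int64)
    root = tree.root
    if seeding_mode == "monophyletic":
        sizes = np.array([len(s) for s in tree.subtree_tips()])
        lo = max(2, int(np.ceil(clade_frac[0] * tree.n_tips)))
        hi = max(lo, int(np.floor(clade_frac[1] * tree.n_tips)))
        cand = [
            v
            for v in range(tree.n_tips, n)
            if v != root and lo <= sizes[v] <= hi
        ]
        if not cand:
            cand = [int(np.argmin(np.abs(sizes[tree.n_tips:] - lo))) + tree.n_tips]
        seed_node = int(cand[int(rng.integers(len(cand)))])
        stack = [seed_node]
        ch = tree.children()
        while stack:
            v = stack.pop()
            states[v] = 1
            stack.extend(ch[v])
    else:
        q10 = 0.0 if seeding_mode == "polyphyletic" else q_mp
        for v in tree.preorder():
            p = tree.parent[v]
            if p < 0:
                states[v] = 0
                continue
            states[v] = _ctmc_branch_end_state(
                int(states[p]), float(tree.length[v]), q_pm, q10, rng
            )
    loc = np.where(states[: tree.n_tips] == 1, "M", "P")
    site = [
        _MET_SITES[int(rng.integers(len(_MET_SITES)))] if s == "M" else "primary"
        for s in loc
    ]
    meta = pd.DataFrame(
        {
            "cell_id": list(tree.tip_labels),
            "location": loc,
            "site": site,
            "cnv_count": np.nan,
        }
    )
    return meta, states


def simulate_cnv(
    tree: LineageTree,
    cnv_rate: float,
    rng=None,
    extra_branch_mean: np.ndarray | None = None,
) -> np.ndarray:
    """Per-tip CNV counts: independent Poisson gains on each branch
    (mean ``cnv_rate`` x branch time, plus any extra per-branch mean),
    summed along the root-to-tip path."""
    rng = _rng(rng)
    if cnv_rate < 0:
        raise ParameterError("cnv_rate must be >= 0")
    mean = cnv_rate * tree.length
    if extra_branch_mean is not None:
        mean = mean + np.asarray(extra_branch_mean, dtype=np.float64)
    mean[tree.root] = 0.0
    gains = rng.poisson(np.maximum(mean, 0.0))
    counts = np.zeros(tree.n_nodes, dtype=np.int64)
    for v in tree.preorder():
        p = tree.parent[v]
        counts[v] = (counts[p] if p >= 0 else 0) + gains[v]
    return counts[: tree.n_tips]


def _nni(tree: LineageTree, rng: np.random.Generator) -> LineageTree:
    """One random nearest-neighbour interchange; returns a new tree.

    Branch lengths of the swapped subtrees are compensated so that
    root-to-tip divergences are preserved: posterior trees with similar
    likelihoods place nearly the same total divergence on each tip even
    when local topology differs.  An uncompensated swap would shift LD
    and DE together and inject a spurious punctuational signal.
    """
    root = tree.root
    internal = [
        v for v in range(tree.n_tips, tree.n_nodes) if v != root and tree.parent[v] >= 0
    ]
    if not internal:
        return tree
    v = int(internal[int(rng.integers(len(internal)))])
    p = int(tree.parent[v])
    ch = tree.children()
    sib = [c for c in ch[p] if c != v][0]
    c = int(ch[v][int(rng.integers(2))])
    parent = tree.parent.copy()
    parent[sib] = v
    parent[c] = p
    length = tree.length.copy()
    bv = length[v]
    length[c] = length[c] + bv  # c moved one level up: path length preserved
    # sib moved one level down: remove bv from every root-to-tip path through
    # it, pushing any deficit a branch cannot absorb down to its children
    stack = [(sib, bv)]
    while stack:
        node, amount = stack.pop()
        take = min(length[node], amount)
        length[node] -= take
        rem = amount - take
        if rem > 1e-15 and node >= tree.n_tips:
            stack.extend((child, rem) for child in ch[node])
    return LineageTree(parent, length, tree.tip_labels, validate=False)


def make_posterior(
    tree: LineageTree,
    n_posterior: int,
    jitter_sd: float = 0.1,
    rng=None,
    nni_fraction: float = 0.0,
) -> PosteriorTreeSet:
    """Pseudo-posterior sample: multiplicative log-normal branch jitter
    (median-preserving) plus NNI moves on a small fraction of internal
    edges.  With jitter_sd = 0 and no NNIs all replicates equal the
    source tree.

    The log-sd of branch e is ``jitter_sd * sqrt(mean_branch / b_e)``
    (capped at 5x jitter_sd): short branches are estimated from fewer
    substitutions and carry proportionally more posterior uncertainty.
    This makes the root-to-tip divergence noise variance proportional to
    path length — the Brownian structure a reconstruction posterior
    induces and the PGLS stage assumes; a constant log-sd would instead
    concentrate noise on long-branch paths and miscalibrate every
    downstream test.  ``jitter_sd`` is the log-sd of an average-length
    branch.
    """
    rng = _rng(rng)
    if n_posterior < 1:
        raise ParameterError("n_posterior must be >= 1")
    if jitter_sd < 0 or nni_fraction < 0:
        raise ParameterError("jitter_sd and nni_fraction must be >= 0")
    n_internal_edges = max(tree.n_nodes - tree.n_tips - 1, 0)
    bl = tree.length
    bbar = tree.mean_branch_length
    with np.errstate(divide="ignore"):
        rel = np.sqrt(np.where(bl > 0, bbar / bl, np.inf))
    sd_e = jitter_sd * np.minimum(rel, 5.0)
    trees = []
    for _ in range(n_posterior):
        t = tree
        n_moves = int(round(nni_fraction * n_internal_edges))
        for _ in range(n_moves):
            t = _nni(t, rng)
        if jitter_sd > 0:
            mult = np.exp(rng.normal(0.0, 1.0, size=tree.n_nodes) * sd_e)
            t = t.with_lengths(t.length * mult)
        elif t is tree:
            t = tree.copy()
        trees.append(t)
    return PosteriorTreeSet(trees, lineage_id="synthetic")


def make_lineage(config: SimulationConfig) -> SyntheticLineage:
    """Generate one full synthetic lineage from a configuration.

    Steps: Yule topology -> locations (CTMC or forced clade) -> optional
    faster diversification inside the metastatic clade -> molecular clock
    with punctuational jumps (optionally larger on metastatic branches)
    -> optional node-density deformation -> CNV counts -> pseudo-posterior.
    Deterministic given ``config.rng_seed``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.rng_seed)
    r_topo, r_loc, r_clock, r_art, r_cnv, r_post = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    topo = simulate_topology(config.n_tips, config.birth_rate, r_topo)
    meta, states = simulate_locations(
        topo, config.q_pm, config.q_mp, config.seeding_mode, r_loc
    )
    if config.met_branch_scale != 1.0:
        bl = topo.length.copy()
        is_m = states == 1
        bl[is_m] = bl[is_m] * config.met_branch_scale
        topo = topo.with_lengths(bl)
    jump_scale = np.where(states == 1, config.met_jump_scale, 1.0)
    if config.target_pc is not None:
        beta_true = punct_size_for_contribution(
            topo, config.g_rate, config.target_pc, jump_scale
        )
    else:
        beta_true = config.punct_size
    clock, truth = apply_molecular_clock(
        topo, config.g_rate, beta_true, config.punct_noise, r_clock, jump_scale
    )
    clock = inject_node_density_artefact(clock, config.delta_true, r_art)
    extra = None
    if config.cnv_per_jump > 0:
        extra = config.cnv_per_jump * truth["jumps"]
    meta = meta.copy()
    meta["cnv_count"] = simulate_cnv(topo, config.cnv_rate, r_cnv, extra)
    posterior = make_posterior(
        clock, config.n_posterior, config.jitter_sd, r_post, config.nni_fraction
    )
    truth = dict(truth)
    truth.update(
        {
            "time_tree": topo,
            "clock_tree": clock,
            "node_states": states,
            "beta_true": float(beta_true),
        }
    )
    return SyntheticLineage(posterior=posterior, meta=meta, truth=truth, config=config)
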