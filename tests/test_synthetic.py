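"""Generator correctness: topology, clock, artefact, locations, posteriors."""

import numpy as np
import pytest

from punctevo import (
    ParameterError,
    SimulationConfig,
    apply_molecular_clock,
    inject_node_density_artefact,
    make_lineage,
    make_posterior,
    path_table,
    punct_size_for_contribution,
    scale_to_mean_branch_length,
    simulate_cnv,
    simulate_locations,
    simulate_topology,
)
from punctevo.pgls import fit_delta
from conftest import SEED


def _mean_depth_split_oracle(n_tips, n_rep, rng):
    """Mean root-to-tip node count under the Yule (Markov) topology model,
    simulated independently through recursive uniform clade splits."""
    totals = []
    for _ in range(n_rep):
        total_depth = 0
        stack = [(n_tips, 0)]
        while stack:
            size, depth = stack.pop()
            if size == 1:
                total_depth += depth
                continue
            left = int(rng.integers(1, size))
            stack.append((left, depth + 1))
            stack.append((size - left, depth + 1))
        totals.append(total_depth / n_tips)
    return float(np.mean(totals))


class TestTopology:
    def test_two_tip_cherry(self):
        t = simulate_topology(2, 1.0, np.random.default_rng(SEED))
        assert t.n_tips == 2 and t.n_nodes == 3

    def test_determinism(self):
        a = simulate_topology(30, 1.0, np.random.default_rng(SEED))
        b = simulate_topology(30, 1.0, np.random.default_rng(SEED))
        np.testing.assert_array_equal(a.parent, b.parent)
        np.testing.assert_array_equal(a.length, b.length)

    def test_ultrametric(self):
        t = simulate_topology(50, 2.0, np.random.default_rng(SEED))
        assert np.ptp(t.tip_depths()) < 1e-9

    def test_mean_node_depth_matches_split_oracle(self):
        rng = np.random.default_rng(SEED)
        n, reps = 64, 300
        sim = np.mean(
            [
                simulate_topology(n, 1.0, rng).tip_path_node_counts().mean()
                for _ in range(reps)
            ]
        )
        oracle = _mean_depth_split_oracle(n, reps, rng)
        # both estimate the same Yule expectation (~2 H_n - 2)
        assert sim == pytest.approx(oracle, rel=0.05)


class TestClock:
    def test_gradual_limit_exact(self):
        t = simulate_topology(20, 1.0, np.random.default_rng(SEED))
        clock, truth = apply_molecular_clock(t, 2.5, 0.0, 0.5, np.random.default_rng(1))
        np.testing.assert_allclose(clock.length, 2.5 * t.length, atol=1e-15)
        assert truth["pc_true"] == 0.0

    def test_punctuational_limit(self):
        t = simulate_topology(20, 1.0, np.random.default_rng(SEED))
        clock, truth = apply_molecular_clock(t, 0.0, 0.3, 0.5, np.random.default_rng(1))
        assert truth["pc_true"] == 1.0
        # tip LD is exactly the sum of jumps on its path
        ld = clock.tip_depths()
        jumps = truth["jumps"]
        for i in range(t.n_tips):
            v, s = i, 0.0
            while t.parent[v] >= 0:
                s += jumps[v]
                v = t.parent[v]
            assert ld[i] == pytest.approx(s, rel=1e-12)

    def test_truth_conservation(self):
        t = simulate_topology(40, 1.0, np.random.default_rng(SEED))
        clock, truth = apply_molecular_clock(t, 1.0, 0.1, 0.5, np.random.default_rng(2))
        assert truth["jumps"].sum() + truth["gradual"].sum() == pytest.approx(
            clock.total_length, abs=1e-9
        )

    def test_target_pc_self_check(self):
        # realized punctuational fraction stays near the target across seeds
        pcs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            t = simulate_topology(500, 1.0, rng)
            beta = punct_size_for_contribution(t, 1.0, 0.06)
            _, truth = apply_molecular_clock(t, 1.0, beta, 0.5, rng)
            pcs.append(truth["pc_true"])
        assert all(0.03 <= p <= 0.09 for p in pcs)


class TestArtefact:
    def test_identity_at_one(self):
        t = simulate_topology(30, 1.0, np.random.default_rng(SEED))
        out = inject_node_density_artefact(t, 1.0)
        np.testing.assert_array_equal(out.length, t.length)

    def test_total_length_shrinks(self):
        rng = np.random.default_rng(SEED)
        for _ in range(20):
            t = simulate_topology(int(rng.integers(8, 64)), 1.0, rng)
            out = inject_node_density_artefact(t, float(rng.uniform(1.1, 3.0)))
            assert out.total_length <= t.total_length + 1e-12

    def test_delta_recovered_above_one(self):
        # deform gradual trees; the curvilinear fit should report delta > 1
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            t = simulate_topology(200, 1.0, rng)
            clock, _ = apply_molecular_clock(t, 1.0, 0.0, 0.0, rng)
            warped = inject_node_density_artefact(clock, 2.0)
            jittered = make_posterior(warped, 1, jitter_sd=0.05, rng=rng)[0]
            s = scale_to_mean_branch_length(jittered, 0.1)
            pt = path_table(s)
            d = fit_delta(pt["LD"].to_numpy(), pt["DE"].to_numpy(dtype=float), s)
            hits += d.delta > 1
        assert hits >= 8

    def test_delta_below_one_rejected(self):
        t = simulate_topology(10, 1.0, np.random.default_rng(SEED))
        with pytest.raises(ParameterError):
            inject_node_density_artefact(t, 0.8)


class TestLocations:
    def test_absorbing_start(self):
        t = simulate_topology(30, 1.0, np.random.default_rng(SEED))
        meta, states = simulate_locations(t, 0.0, 0.0, "polyphyletic",
                                          np.random.default_rng(1))
        assert (meta["location"] == "P").all() and states.sum() == 0

    def test_monophyletic_single_clade(self):
        rng = np.random.default_rng(SEED)
        t = simulate_topology(64, 1.0, rng)
        meta, states = simulate_locations(t, 1.0, 0.0, "monophyletic", rng)
        m_tips = np.flatnonzero(states[: t.n_tips] == 1)
        assert len(m_tips) >= 2
        # the M tips must be exactly the tip set of one node's subtree
        tipsets = t.subtree_tips()
        assert any(
            np.array_equal(np.sort(tipsets[v]), m_tips)
            for v in range(t.n_tips, t.n_nodes)
        )

    def test_reseeding_allows_return(self):
        rng = np.random.default_rng(SEED)
        t = simulate_topology(200, 1.0, rng)
        _, states = simulate_locations(t, 2.0, 2.0, "reseeding", rng)
        # with both rates high some M->P transitions occur along branches
        trans_back = sum(
            states[t.parent[v]] == 1 and states[v] == 0
            for v in range(t.n_nodes)
            if t.parent[v] >= 0
        )
        assert trans_back > 0


class TestCnv:
    def test_zero_rate(self):
        t = simulate_topology(20, 1.0, np.random.default_rng(SEED))
        assert simulate_cnv(t, 0.0, np.random.default_rng(1)).sum() == 0

    def test_mean_within_three_se(self):
        from punctevo import phylo_covariance

        rng = np.random.default_rng(SEED)
        t = simulate_topology(200, 1.0, rng)
        rate = 2.0
        counts = simulate_cnv(t, rate, rng)
        mu = rate * t.tip_depths().mean()
        # counts are phylogenetically correlated: Var(mean over tips)
        # = rate * mean of the shared-path (time) covariance matrix
        se = np.sqrt(rate * phylo_covariance(t).mean())
        assert abs(counts.mean() - mu) < 3 * se

    def test_mean_unbiased_across_seeds(self):
        rng = np.random.default_rng(SEED)
        t = simulate_topology(100, 1.0, rng)
        mu = 2.0 * t.tip_depths().mean()
        means = [
            simulate_cnv(t, 2.0, np.random.default_rng(s)).mean()
            for s in range(30)
        ]
        assert np.mean(means) == pytest.approx(mu, rel=0.1)


class TestPosterior:
    def test_identity_when_no_jitter(self):
        t = simulate_topology(20, 1.0, np.random.default_rng(SEED))
        post = make_posterior(t, 5, jitter_sd=0.0, rng=np.random.default_rng(1))
        for rep in post:
            np.testing.assert_array_equal(rep.length, t.length)
            np.testing.assert_array_equal(rep.parent, t.parent)

    def test_geometric_mean_preserved(self):
        rng = np.random.default_rng(SEED)
        t = simulate_topology(10, 1.0, rng)
        post = make_posterior(t, 1000, jitter_sd=0.1, rng=rng)
        logs = np.mean(
            [np.log(np.maximum(rep.length, 1e-300)) for rep in post], axis=0
        )
        sel = (t.length > 0) & (np.arange(t.n_nodes) != t.root)
        np.testing.assert_allclose(np.exp(logs[sel]), t.length[sel], rtol=0.02)

    def test_shared_tip_set_and_determinism(self):
        cfg = SimulationConfig(n_tips=40, target_pc=0.06, n_posterior=6, rng_seed=SEED)
        a = make_lineage(cfg)
        b = make_lineage(cfg)
        assert a.posterior.tip_labels == b.posterior.tip_labels
        for ta, tb in zip(a.posterior, b.posterior):
            np.testing.assert_array_equal(ta.length, tb.length)
            np.testing.assert_array_equal(ta.parent, tb.parent)
        assert a.meta.equals(b.meta)
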