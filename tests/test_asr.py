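"""Ancestral-state reconstruction: pruning vs enumeration, categories,
location contributions."""

import numpy as np
import pandas as pd
import pytest

from punctevo import (
    BranchPartition,
    LineageTree,
    balanced_tree,
    categorize_branches,
    compare_location_contributions,
    fit_mk2,
    location_contribution,
    marginal_states,
    scale_to_mean_branch_length,
    simulate_locations,
    simulate_topology,
)
from punctevo.asr import LocationContrast, Mk2Fit, mk2_loglik
from punctevo.oracles import mk2_likelihood_enumerate, mk2_marginals_enumerate
from conftest import SEED


class TestLikelihood:
    def test_matches_enumeration(self):
        rng = np.random.default_rng(SEED)
        for _ in range(20):
            nt = int(rng.integers(3, 7))
            t = scale_to_mean_branch_length(simulate_topology(nt, 1.0, rng), 0.1)
            states = rng.integers(0, 2, nt)
            if states.sum() in (0, nt):
                states[0] = 1 - states[0]
            q1, q2 = rng.uniform(0.1, 8.0, 2)
            kap = float(rng.uniform(0.2, 2.0))
            ll = mk2_loglik(t, states, q1, q2, kap)
            oracle = np.log(mk2_likelihood_enumerate(t, states, q1, q2, kap))
            assert ll == pytest.approx(oracle, abs=1e-10)

    def test_monomorphic_boundary(self):
        t = LineageTree.from_newick("(A:0.1,B:0.1);")
        fit = fit_mk2(t, [0, 0])
        assert fit.boundary
        assert fit.q_pm < 1e-4
        assert fit.loglik == pytest.approx(0.0, abs=1e-3)

    def test_rate_recovery_within_factor_two(self):
        hits = 0
        n_rep = 15
        for k in range(n_rep):
            rng = np.random.default_rng(SEED + k)
            t = simulate_topology(500, 1.0, rng)
            _, states = simulate_locations(t, 0.5, 0.1, "reseeding", rng)
            tips = states[: t.n_tips]
            if 0 < tips.sum() < t.n_tips:
                scaled = scale_to_mean_branch_length(t, 0.1)
                f = 0.1 / t.mean_branch_length  # rates rescale inversely
                fit = fit_mk2(scaled, tips, estimate_kappa=False)
                q_pm = fit.q_pm * f
                hits += 0.25 <= q_pm / 0.5 <= 4.0
            else:
                n_rep -= 1
        assert hits >= 0.8 * n_rep

    def test_kappa_recovered_near_one(self):
        # kappa is weakly identified per replicate; the median over 20
        # undistorted simulations should sit near 1
        meds = []
        for k in range(20):
            rng = np.random.default_rng(SEED + 100 + k)
            t = simulate_topology(300, 1.0, rng)
            _, states = simulate_locations(t, 0.6, 0.2, "reseeding", rng)
            tips = states[: t.n_tips]
            if 0 < tips.sum() < t.n_tips:
                fit = fit_mk2(scale_to_mean_branch_length(t, 0.1), tips)
                meds.append(fit.kappa)
        assert 0.7 <= np.median(meds) <= 1.3


class TestMarginals:
    def test_root_fixed_primary(self):
        rng = np.random.default_rng(SEED)
        t = scale_to_mean_branch_length(simulate_topology(10, 1.0, rng), 0.1)
        states = np.zeros(10, dtype=int)
        states[:4] = 1
        fit = fit_mk2(t, states)
        marg = marginal_states(t, fit, states)
        assert marg.loc[t.root, "prob_P"] == 1.0
        assert marg.loc[t.root, "state"] == 0

    def test_symmetric_cherry_tie_undefined(self):
        # a (P, M) cherry with equal branches and symmetric rates carries
        # no information about its parent; placing the parent far from
        # the P-fixed root (at stationarity, pi = 1/2) makes the marginal
        # an exact tie, which must be reported as 'undefined'
        fit = Mk2Fit(q_pm=0.5, q_mp=0.5, kappa=1.0, loglik=0.0, converged=True,
                     boundary=False, n_tips=4)
        t2 = LineageTree.from_newick("((A:1,B:1):50,(C:1,D:1):50);")
        states2 = np.array(
            [
                {"A": 0, "B": 1, "C": 0, "D": 1}[lab]
                for lab in t2.tip_labels
            ]
        )
        m2 = marginal_states(t2, fit, states2)
        cherry_parents = [v for v in range(t2.n_tips, t2.n_nodes) if v != t2.root]
        for v in cherry_parents:
            assert m2.loc[v, "prob_P"] == pytest.approx(0.5, abs=1e-12)
            assert m2.loc[v, "state"] == -1  # undefined

    def test_matches_enumeration(self):
        rng = np.random.default_rng(SEED + 3)
        for _ in range(15):
            nt = int(rng.integers(3, 7))
            t = scale_to_mean_branch_length(simulate_topology(nt, 1.0, rng), 0.1)
            states = rng.integers(0, 2, nt)
            if states.sum() in (0, nt):
                states[0] = 1 - states[0]
            q1, q2 = rng.uniform(0.1, 8.0, 2)
            fit = Mk2Fit(q_pm=q1, q_mp=q2, kappa=1.0, loglik=0.0, converged=True,
                         boundary=False, n_tips=nt)
            marg = marginal_states(t, fit, states)
            oracle = mk2_marginals_enumerate(t, states, q1, q2, 1.0)
            for node, row in marg.iterrows():
                assert row["prob_P"] == pytest.approx(oracle[node], abs=1e-10)


class TestCategories:
    def _partition(self):
        t = balanced_tree(4)
        # nodes: tips 0..3; internals 4 (0,1), 5 (2,3), 6 root
        node_states = pd.DataFrame(
            {"node": [4, 5, 6], "prob_P": [0.9, 0.2, 1.0], "state": [0, 1, 0]}
        ).set_index("node")
        tips = np.array([0, 0, 1, 1])
        return t, categorize_branches(t, node_states, tips)

    def test_endpoint_rules(self):
        t, part = self._partition()
        cat = part.category
        assert cat[0] == BranchPartition.CAT_P  # P parent, P tip
        assert cat[2] == BranchPartition.CAT_M  # M parent, M tip
        assert cat[4] == BranchPartition.CAT_P  # root P -> node P
        assert cat[5] == BranchPartition.CAT_TRANSITION  # root P -> node M

    def test_undefined_propagates(self):
        t = balanced_tree(4)
        node_states = pd.DataFrame(
            {"node": [4, 5, 6], "prob_P": [0.5, 0.2, 1.0], "state": [-1, 1, 0]}
        ).set_index("node")
        part = categorize_branches(t, node_states, np.array([0, 0, 1, 1]))
        assert part.category[4] == BranchPartition.CAT_UNDEFINED
        assert part.category[0] == BranchPartition.CAT_UNDEFINED

    def test_partition_is_complete(self):
        t, part = self._partition()
        c = part.counts("include")
        total = c["N_P"] + c["N_M"] + c["N_transition"] + c["N_undefined"]
        assert total == t.n_nodes - 1

    def test_category_accuracy_single_transition(self):
        hits = []
        for k in range(10):
            rng = np.random.default_rng(SEED + 200 + k)
            t = simulate_topology(300, 1.0, rng)
            meta, states = simulate_locations(t, 1.0, 0.0, "monophyletic", rng)
            tips = states[: t.n_tips]
            scaled = scale_to_mean_branch_length(t, 0.1)
            fit = fit_mk2(scaled, tips, estimate_kappa=False)
            marg = marginal_states(scaled, fit, tips)
            part = categorize_branches(scaled, marg, tips)
            truly_m = [
                v
                for v in range(t.n_nodes)
                if t.parent[v] >= 0 and states[v] == 1 and states[t.parent[v]] == 1
            ]
            got = np.mean(
                [part.category[v] == BranchPartition.CAT_M for v in truly_m]
            )
            hits.append(got)
        assert np.mean(hits) >= 0.9


class TestLocationContribution:
    def _make_partition(self, n_p, n_m, t_p, t_m):
        # craft a partition over a star-ish tree with controlled tallies
        class _FakeTree:
            pass

        part = BranchPartition.__new__(BranchPartition)
        counts = {
            "N_P": n_p, "N_M": n_m, "T_P": t_p, "T_M": t_m,
            "N_transition": 0, "T_transition": 0.0,
            "N_undefined": 0, "T_undefined": 0.0,
        }
        part.counts = lambda policy="exclude": counts  # type: ignore
        return part

    def test_direct_ratio(self):
        part = self._make_partition(20, 20, 10.0, 5.0)
        out = location_contribution(part, beta=0.1)
        assert out.pc_m == pytest.approx(0.4)
        assert out.pc_p == pytest.approx(0.2)
        assert out.included

    def test_min_branch_filter(self):
        part = self._make_partition(20, 8, 10.0, 5.0)
        out = location_contribution(part, beta=0.1)
        assert not out.included and "fewer than 10" in out.exclusion_reason

    def test_pc_above_one_excluded(self):
        part = self._make_partition(20, 20, 10.0, 1.0)
        out = location_contribution(part, beta=0.1)
        assert out.pc_m == pytest.approx(2.0)
        assert not out.included


class TestComparison:
    def test_null_identity_not_significant(self):
        rng = np.random.default_rng(SEED)
        x = rng.uniform(0.02, 0.2, 40)
        c = LocationContrast("lin", pc_p=x, pc_m=x.copy(), n_total_trees=40)
        out = compare_location_contributions([c])
        assert not out["significant"].iloc[0]
        assert out["p_value"].iloc[0] == 1.0

    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(SEED)
        cs = [
            LocationContrast(
                f"l{k}",
                pc_p=rng.uniform(0, 0.1, 25),
                pc_m=rng.uniform(0, 0.1, 25),
                n_total_trees=25,
            )
            for k in range(7)
        ]
        out = compare_location_contributions(cs, alpha=0.05)
        assert out["adjusted_alpha"].iloc[0] == pytest.approx(0.05 / 7)

    def test_untestable_below_min_trees(self):
        c = LocationContrast("lin", pc_p=np.ones(5), pc_m=np.ones(5), n_total_trees=30)
        out = compare_location_contributions([c], min_trees=20)
        assert not out["testable"].iloc[0]
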