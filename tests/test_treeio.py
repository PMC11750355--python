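"""Tree I/O, branch transforms, path tables and alignment assembly."""

import numpy as np
import pandas as pd
import pytest

from punctevo import (
    DegenerateDataError,
    LineageTree,
    MetadataError,
    ParameterError,
    TreeStructureError,
    assemble_alignment,
    kappa_transform,
    make_posterior,
    path_table,
    prune_to_tips,
    read_metadata,
    read_trees,
    scale_to_mean_branch_length,
    simulate_topology,
    write_metadata,
    write_trees,
)
from punctevo.oracles import tip_paths_bruteforce
from conftest import SEED, random_trees


class TestReadWrite:
    def test_parse_two_tip_tree(self):
        t = LineageTree.from_newick("(A:1,B:1);")
        assert t.n_tips == 2
        assert sorted(t.tip_labels) == ["A", "B"]
        assert sorted(t.length[:2]) == [1.0, 1.0]

    @pytest.mark.parametrize("fmt", ["newick", "nexus"])
    def test_round_trip_identity(self, tmp_path, fmt):
        rng = np.random.default_rng(SEED)
        trees = [simulate_topology(20, 1.0, rng) for _ in range(5)]
        p = str(tmp_path / f"trees.{fmt}")
        write_trees(trees, p, format=fmt)
        back = read_trees(p, format=fmt)
        assert len(back) == 5
        for a, b in zip(trees, back):
            pa, pb = path_table(a), path_table(b)
            pb = pb.loc[pa.index]
            np.testing.assert_allclose(pa["LD"], pb["LD"], atol=1e-12)
            np.testing.assert_array_equal(pa["DE"], pb["DE"])

    def test_posterior_size_matches_generator(self, tmp_path):
        rng = np.random.default_rng(SEED)
        base = simulate_topology(12, 1.0, rng)
        post = make_posterior(base, 50, jitter_sd=0.05, rng=rng)
        p = str(tmp_path / "post.nex")
        write_trees(post, p, format="nexus")
        assert len(read_trees(p, format="nexus")) == 50

    def test_polytomy_rejected_unless_resolved(self, tmp_path):
        p = str(tmp_path / "poly.nwk")
        with open(p, "w") as fh:
            fh.write("(A:1,B:1,C:1);\n")
        with pytest.raises(TreeStructureError):
            read_trees(p)
        t = read_trees(p, resolve_polytomies=True)[0]
        assert t.n_tips == 3
        assert t.validate() is None

    def test_mismatched_tip_sets_rejected(self, tmp_path):
        p = str(tmp_path / "bad.nwk")
        with open(p, "w") as fh:
            fh.write("(A:1,B:1);\n(A:1,C:1);\n")
        from punctevo import ConsistencyError

        with pytest.raises(ConsistencyError):
            read_trees(p)


class TestTransforms:
    def test_scale_to_mean_examples(self):
        t = LineageTree.from_newick("((A:1,B:2):3,C:0);")
        s = scale_to_mean_branch_length(t, 0.1)
        # branches {1,2,3,0}: mean 1.5 -> factor 1/15
        assert s.mean_branch_length == pytest.approx(0.1, abs=1e-12)
        np.testing.assert_allclose(
            sorted(s.length), sorted(np.array([0.0, 1, 2, 3, 0]) / 15), atol=1e-12
        )

    @pytest.mark.parametrize("tree", random_trees(5))
    def test_scale_defining_property(self, tree):
        s = scale_to_mean_branch_length(tree, 0.1)
        assert s.mean_branch_length == pytest.approx(0.1, abs=1e-12)
        # LD scales by the common factor, DE unchanged
        f = 0.1 / tree.mean_branch_length
        np.testing.assert_allclose(s.tip_depths(), tree.tip_depths() * f, rtol=1e-12)
        np.testing.assert_array_equal(
            s.tip_path_node_counts(), tree.tip_path_node_counts()
        )

    def test_scale_all_zero_degenerate(self):
        t = LineageTree.from_newick("(A:0,B:0);")
        with pytest.raises(DegenerateDataError):
            scale_to_mean_branch_length(t, 0.1)

    def test_kappa_examples(self):
        t = LineageTree.from_newick("(A:4,B:0.25);")
        assert kappa_transform(t, 1.0).length[:2] == pytest.approx(t.length[:2])
        half = kappa_transform(t, 0.5)
        assert sorted(half.length[:2]) == pytest.approx([0.5, 2.0])
        punct = kappa_transform(t, 0.0)
        assert sorted(punct.length[:2]) == pytest.approx([1.0, 1.0])

    def test_kappa_monotone_and_bounds(self):
        t = LineageTree.from_newick("(A:4,B:2);")
        k1 = kappa_transform(t, 0.7)
        k2 = kappa_transform(t, 0.7)
        np.testing.assert_array_equal(k1.length, k2.length)
        a = kappa_transform(t, 0.3).length[:2]
        b = kappa_transform(t, 0.9).length[:2]
        assert np.all((a > 0) & (b > 0))
        with pytest.raises(ParameterError):
            kappa_transform(t, 3.5)


class TestTransformProperties:
    from hypothesis import given, settings, strategies as st

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1e6, allow_nan=False),
                 min_size=14, max_size=14),
        st.floats(min_value=0.05, max_value=2.9),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_and_kappa_invariants(self, lengths, kappa):
        # arbitrary non-negative branch lengths on a fixed 8-tip shape
        base = LineageTree.from_newick(
            "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
        )
        bl = np.zeros(base.n_nodes)
        nonroot = [v for v in range(base.n_nodes) if v != base.root]
        bl[nonroot] = lengths
        tree = base.with_lengths(bl)
        if tree.total_length > 0:
            s = scale_to_mean_branch_length(tree, 0.1)
            assert s.mean_branch_length == pytest.approx(0.1, rel=1e-9)
        k = kappa_transform(tree, kappa)
        # kappa transform is monotone per branch and preserves zeros
        order = np.argsort(tree.length[nonroot])
        assert np.all(np.diff(k.length[nonroot][order]) >= -1e-9)
        assert np.all(k.length[nonroot][tree.length[nonroot] == 0] == 0)


class TestPathTable:
    def test_worked_example(self, tree3):
        pt = path_table(tree3)
        assert pt.loc["A", "LD"] == 2 and pt.loc["A", "DE"] == 2
        assert pt.loc["B", "LD"] == 3 and pt.loc["B", "DE"] == 2
        assert pt.loc["C", "LD"] == 4 and pt.loc["C", "DE"] == 1

    def test_two_tip_de_is_one(self):
        pt = path_table(LineageTree.from_newick("(A:5,B:7);"))
        assert list(pt["DE"]) == [1, 1]

    @pytest.mark.parametrize("tree", random_trees(6, tip_range=(4, 128)))
    def test_against_bruteforce_walk(self, tree):
        ld, de = tip_paths_bruteforce(tree)
        pt = path_table(tree)
        np.testing.assert_allclose(pt["LD"], ld, atol=1e-10)
        np.testing.assert_array_equal(pt["DE"], de)
        assert de.min() >= 1 and de.max() <= tree.n_tips - 1
        assert pt["LD"].max() <= tree.total_length + 1e-9

    @pytest.mark.parametrize("tree", random_trees(4, tip_range=(4, 64), seed=SEED + 2))
    def test_ld_sum_identity(self, tree):
        # sum of tip LD equals sum over branches of length x descendant tips
        tipsets = tree.subtree_tips()
        expect = sum(
            float(tree.length[v]) * len(tipsets[v])
            for v in range(tree.n_nodes)
            if v != tree.root
        )
        assert path_table(tree)["LD"].sum() == pytest.approx(expect, rel=1e-10)

    def test_missing_metadata_raises(self, tree3):
        meta = pd.DataFrame(
            {"cell_id": ["A", "B"], "location": ["P", "M"]}
        )
        with pytest.raises(MetadataError, match="C"):
            path_table(tree3, meta)


class TestPrune:
    def test_prune_preserves_paths(self):
        rng = np.random.default_rng(SEED)
        tree = simulate_topology(32, 1.0, rng)
        keep = list(tree.tip_labels[::2])
        sub = prune_to_tips(tree, keep)
        assert sorted(sub.tip_labels) == sorted(keep)
        full = path_table(tree).loc[list(sub.tip_labels)]
        pruned = path_table(sub)
        np.testing.assert_allclose(pruned["LD"], full["LD"], rtol=1e-10)
        sub.validate()


class TestMetadata:
    def test_round_trip(self, tmp_path):
        meta = pd.DataFrame(
            {
                "cell_id": ["c1", "c2"],
                "location": ["P", "M"],
                "site": ["primary", "liver"],
                "cnv_count": [3, 5],
            }
        )
        p = str(tmp_path / "meta.tsv")
        write_metadata(meta, p)
        back = read_metadata(p)
        pd.testing.assert_frame_equal(
            back[meta.columns], meta, check_dtype=False
        )

    def test_bad_location_rejected(self, tmp_path):
        p = str(tmp_path / "meta.tsv")
        with open(p, "w") as fh:
            fh.write("cell_id\tlocation\nc1\tX\n")
        with pytest.raises(MetadataError):
            read_metadata(p)


class TestAlignment:
    def _site(self, fill="A"):
        return "G" * 34 + fill * 262

    def test_single_site_slice(self):
        df = pd.DataFrame(
            {"cell_id": ["c1"], "barcode": ["BC01"], "sequence": [self._site()]}
        )
        rows, nexus = assemble_alignment(df)
        assert rows["c1"] == self._site()[34:]
        assert len(rows["c1"]) == 262
        assert "NCHAR=262" in nexus and "MISSING=?" in nexus

    def test_missing_site_blank_filled(self):
        df = pd.DataFrame(
            {
                "cell_id": ["c1", "c1", "c2"],
                "barcode": ["BC01", "BC02", "BC01"],
                "sequence": [self._site("A"), self._site("C"), self._site("T")],
            }
        )
        rows, _ = assemble_alignment(df)
        # cell2 lacks BC02: characters 263-524 (1-based) are all '?'
        assert rows["c2"][262:524] == "?" * 262
        assert rows["c2"][:262] == self._site("T")[34:]

    def test_concatenated_length_and_reference(self):
        cells, bcs = ["c1"], [f"BC{k:02d}" for k in range(10)]
        df = pd.DataFrame(
            {
                "cell_id": cells * 10,
                "barcode": bcs,
                "sequence": [self._site()] * 10,
            }
        )
        rows, nexus = assemble_alignment(df, reference=self._site("G"))
        assert len(rows["c1"]) == 2620
        assert len(rows["reference"]) == 2620
        assert "NCHAR=2620" in nexus

    def test_wrong_length_rejected(self):
        df = pd.DataFrame(
            {"cell_id": ["c1"], "barcode": ["BC01"], "sequence": ["ACGT"]}
        )
        with pytest.raises(MetadataError, match="296"):
            assemble_alignment(df)
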