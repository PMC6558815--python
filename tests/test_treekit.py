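import io

import numpy as np
import pytest

from paleotrait.treekit import (
    DatedTree,
    NewickParseError,
    StratRange,
    TreeError,
    phylo_covariance,
    prune_to_taxa,
    read_trees,
    rescale_unit_height,
    sample_fossil_tip_ages,
    timescale_mbl,
    write_trees,
)


class TestReadTrees:
    def test_ultrametric_three_tips(self):
        t = DatedTree.from_newick("((A:1,B:1):1,C:2);")
        assert t.n_tips == 3
        assert t.height == pytest.approx(2.0)
        assert all(a == 0.0 for a in t.tip_ages.values())

    def test_extinct_tip_age(self):
        t = DatedTree.from_newick("((A:1,B:0.5):1,C:2);")
        assert t.tip_ages["B"] == pytest.approx(0.5)
        assert t.tip_ages["A"] == 0.0
        assert t.tip_ages["C"] == 0.0
        assert t.extinct_labels() == ["B"]

    def test_multi_tree_order_preserved(self, tmp_path):
        lines = [f"((A:1,B:1):{i + 1},C:{i + 2});" for i in range(50)]
        p = tmp_path / "many.tre"
        p.write_text("\n".join(lines) + "\n")
        trees = read_trees(p)
        assert len(trees) == 50
        assert [t.height for t in trees] == [pytest.approx(i + 2) for i in range(50)]

    def test_missing_branch_length_errors(self):
        with pytest.raises(NewickParseError, match="branch length"):
            DatedTree.from_newick("((A:1,B),C:2);")

    def test_unreadable_file(self, tmp_path):
        with pytest.raises(NewickParseError):
            read_trees(tmp_path / "nope.tre")

    def test_polytomy_resolved_binary(self):
        t = DatedTree.from_newick("(A:1,B:1,C:1,D:1);")
        assert t.n_tips == 4
        assert all(len(n.children) == 2 for n in t.nodes if not n.is_tip)
        assert len(t.resolution_log) == 2

    def test_node_age_consistency(self):
        t = DatedTree.from_newick("((A:1,B:0.5):1,(C:2,D:1.7):0.1);")
        for node in t.nodes:
            if node.parent is not None:
                assert t.age(node) + node.length == pytest.approx(
                    t.age(node.parent), abs=1e-9
                )

    def test_roundtrip(self, tmp_path):
        t = DatedTree.from_newick("((A:1,B:0.5):1,C:2);")
        p = tmp_path / "out.tre"
        write_trees([t], p)
        t2 = read_trees(p)[0]
        assert t2.tip_labels == t.tip_labels
        assert t2.height == pytest.approx(t.height)


class TestTimescaleMBL:
    def test_noop_on_valid_tree(self, three_tip_tree):
        out = timescale_mbl(three_tip_tree, min_bl=1.0)
        assert out.to_newick() == three_tip_tree.to_newick()
        assert out.mbl_log == []

    def test_cascading_shift(self):
        # parent age 10 with extinct child pushed to age 10 -> parent 11;
        # grandparent at 10.5 cascades to 12
        t = DatedTree.from_newick("((F:0.0,A:10):0.5,B:10.5);")
        out = timescale_mbl(t, tip_ages={"F": 10.0}, min_bl=1.0)
        assert out.tip_ages["F"] == pytest.approx(10.0)
        parent = [n for n in out.nodes if not n.is_tip and n.parent is not None][0]
        assert out.age(parent) == pytest.approx(11.0)
        assert out.age(out.root) == pytest.approx(12.0)
        assert len(out.mbl_log) == 2

    def test_min_bl_zero_unchanged(self, three_tip_tree):
        out = timescale_mbl(three_tip_tree, min_bl=0.0)
        assert out.to_newick() == three_tip_tree.to_newick()

    def test_negative_min_bl_rejected(self, three_tip_tree):
        with pytest.raises(TreeError):
            timescale_mbl(three_tip_tree, min_bl=-1.0)

    def test_output_satisfies_floor(self):
        t = DatedTree.from_newick("((F:0.2,A:6):0.5,(B:6.5,C:6.5):0);")
        out = timescale_mbl(t, tip_ages={"F": 5.9}, min_bl=1.0)
        for node in out.nodes:
            if node.parent is not None:
                assert node.length >= 1.0 - 1e-9

    def test_epsilon_identity_on_valid_tree(self):
        t = DatedTree.from_newick("((A:3,B:2):4,(C:5,D:6):1.5);")
        out = timescale_mbl(t, min_bl=1e-9)
        np.testing.assert_allclose(
            [n.length for n in out.nodes if n.parent is not None],
            [n.length for n in t.nodes if n.parent is not None],
        )


class TestSampleFossilTipAges:
    def test_bounds(self):
        t = DatedTree.from_newick("((F:5,A:120):5,B:125);")
        reps = sample_fossil_tip_ages(
            t, [StratRange("F", fad=120, lad=110)], 20, seed=1
        )
        for r in reps:
            assert 110 <= r.tip_ages["F"] <= 120

    def test_degenerate_interval(self):
        t = DatedTree.from_newick("((F:5,A:120):5,B:125);")
        reps = sample_fossil_tip_ages(
            t, [StratRange("F", fad=100, lad=100)], 5, seed=1
        )
        assert all(r.tip_ages["F"] == pytest.approx(100.0) for r in reps)

    def test_determinism(self):
        t = DatedTree.from_newick("((F:5,A:120):5,B:125);")
        rs = [StratRange("F", fad=120, lad=110)]
        a = sample_fossil_tip_ages(t, rs, 5, seed=42)
        b = sample_fossil_tip_ages(t, rs, 5, seed=42)
        assert [x.to_newick() for x in a] == [x.to_newick() for x in b]

    def test_missing_range_errors(self):
        t = DatedTree.from_newick("((F:5,A:120):5,B:125);")
        with pytest.raises(TreeError, match="F"):
            sample_fossil_tip_ages(t, [], 5, seed=1)

    def test_mean_age_near_interval_midpoint(self):
        t = DatedTree.from_newick("((F:5,A:120):5,B:125);")
        reps = sample_fossil_tip_ages(
            t, [StratRange("F", fad=120, lad=110)], 1000, seed=9
        )
        ages = np.array([r.tip_ages["F"] for r in reps])
        se = (10 / np.sqrt(12)) / np.sqrt(1000)
        assert abs(ages.mean() - 115.0) < 3 * se


class TestPrune:
    def test_prune_to_pair(self, three_tip_tree):
        sub = prune_to_taxa(three_tip_tree, {"A", "B"})
        assert sorted(sub.tip_labels) == ["A", "B"]
        assert sub.height == pytest.approx(1.0)  # MRCA(A,B) is the new root

    def test_prune_all_is_identity(self, three_tip_tree):
        sub = prune_to_taxa(three_tip_tree, set(three_tip_tree.tip_labels))
        assert sub.to_newick() == three_tip_tree.to_newick()

    def test_unknown_label(self, three_tip_tree):
        with pytest.raises(TreeError):
            prune_to_taxa(three_tip_tree, {"A", "Z"})

    def test_too_few(self, three_tip_tree):
        with pytest.raises(TreeError):
            prune_to_taxa(three_tip_tree, {"A"})

    def test_path_lengths_preserved(self, bd_tree_128):
        rng = np.random.default_rng(0)
        keep = list(rng.choice(bd_tree_128.tip_labels, size=20, replace=False))
        sub = prune_to_taxa(bd_tree_128, keep)
        d0 = dict(zip(bd_tree_128.tip_labels, bd_tree_128.tip_depth_vector()))
        d1 = dict(zip(sub.tip_labels, sub.tip_depth_vector()))
        offsets = {k: d0[k] - d1[k] for k in keep}
        assert max(offsets.values()) - min(offsets.values()) < 1e-9


class TestRescaleUnitHeight:
    def test_height_443(self):
        t = DatedTree.from_newick("((A:221.5,B:443):0,C:443);")
        out = rescale_unit_height(t)
        assert out.height == pytest.approx(1.0, abs=1e-12)
        assert out.tip_ages["A"] == pytest.approx(221.5 / 443)

    def test_idempotent(self, three_tip_tree):
        once = rescale_unit_height(three_tip_tree)
        twice = rescale_unit_height(once)
        np.testing.assert_allclose(
            [n.length for n in twice.nodes if n.parent is not None],
            [n.length for n in once.nodes if n.parent is not None],
        )

    def test_zero_height_errors(self):
        t = DatedTree.from_newick("(A:0,B:0);")
        with pytest.raises(TreeError):
            rescale_unit_height(t)


class TestPhyloCovariance:
    def test_hand_example(self, three_tip_tree):
        S, T = phylo_covariance(three_tip_tree)
        np.testing.assert_allclose(T, [2, 2, 2])
        np.testing.assert_allclose(S, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_star_tree(self):
        t = DatedTree.from_newick("(A:1,B:1,C:1,D:1);")
        S, _ = phylo_covariance(t)
        off = S - np.diag(np.diag(S))
        assert np.abs(off).max() == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_positive_semidefinite_random(self, seed):
        from paleotrait.synth import SynthConfig, simulate_tree
        from paleotrait.contmodels import ContModelSpec, ContParams

        cfg = SynthConfig(n_extant=10, death_rate=0.2, seed=seed,
                          trait_model=ContModelSpec("BM"),
                          trait_params=ContParams(theta0=0, sigma2=1))
        tree, _, _ = simulate_tree(cfg)
        S, T = phylo_covariance(tree)
        assert np.linalg.eigvalsh(S).min() > -1e-9
        assert np.all(S <= np.minimum.outer(T, T) + 1e-12)

    def test_ultrametric_constant_diagonal(self, bd_tree_128):
        S, T = phylo_covariance(bd_tree_128)
        np.testing.assert_allclose(np.diag(S), T)
        np.testing.assert_allclose(T, T[0], atol=1e-9)
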