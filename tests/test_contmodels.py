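import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paleotrait.contmodels import (
    MODEL_K,
    ContModelSpec,
    ContParams,
    FitResult,
    ModelError,
    akaike_compare,
    akaike_weights_from_aic,
    ancestral_states,
    fit_ml,
    loglik,
    model_moments,
    simulate_traits,
)
from conftest import trait_vector


class TestModelMoments:
    def test_bm_hand_example(self, three_tip_tree):
        mu, V = model_moments(ContModelSpec("BM"),
                              ContParams(theta0=0.0, sigma2=2.0), three_tip_tree)
        np.testing.assert_allclose(V, 2 * np.array([[2, 1, 0], [1, 2, 0], [0, 0, 2]]))
        np.testing.assert_allclose(mu, 0.0)

    def test_ou_small_alpha_is_bm(self, three_tip_tree):
        _, Vbm = model_moments(ContModelSpec("BM"),
                               ContParams(theta0=1.0, sigma2=3.0), three_tip_tree)
        mu, Vou = model_moments(
            ContModelSpec("OU"),
            ContParams(theta0=1.0, sigma2=3.0, theta1=5.0, alpha=1e-10),
            three_tip_tree,
        )
        np.testing.assert_allclose(Vou, Vbm, rtol=1e-6)
        np.testing.assert_allclose(mu, 1.0, rtol=1e-6)

    def test_eb_tip_variance_table_values(self, bd_tree_128):
        # unit-height ultrametric tree: tip variance is sigma2*(1-e^beta)/(-beta)
        sigma2, beta = 4708.20, -5.04
        _, V = model_moments(ContModelSpec("EB"),
                             ContParams(theta0=0.0, sigma2=sigma2, beta=beta),
                             bd_tree_128)
        expect = sigma2 * (1 - math.exp(beta)) / (-beta)
        np.testing.assert_allclose(np.diag(V), expect, rtol=1e-9)

    def test_trend_mean(self, three_tip_tree):
        mu, _ = model_moments(ContModelSpec("TREND"),
                              ContParams(theta0=1.0, sigma2=1.0, trend=-0.5),
                              three_tip_tree)
        np.testing.assert_allclose(mu, 1.0 - 0.5 * 2.0)

    def test_wn_identity(self, three_tip_tree):
        _, V = model_moments(ContModelSpec("WN"),
                             ContParams(theta0=0.0, sigma2=2.5), three_tip_tree)
        np.testing.assert_allclose(V, 2.5 * np.eye(3))

    def test_nonfinite_rejected(self, three_tip_tree):
        with pytest.raises(ModelError):
            model_moments(ContModelSpec("BM"),
                          ContParams(theta0=np.nan, sigma2=1.0), three_tip_tree)


class TestLoglik:
    def test_wn_closed_form(self, three_tip_tree):
        tv = trait_vector(three_tip_tree, [1, 2, 3])
        val = loglik(ContModelSpec("WN"),
                     ContParams(theta0=2.0, sigma2=2 / 3), three_tip_tree, tv)
        assert val == pytest.approx(-3.6486, abs=1e-4)

    def test_bm_star_tree(self, cherry_tree):
        tv = trait_vector(cherry_tree, [0, 2])
        val = loglik(ContModelSpec("BM"),
                     ContParams(theta0=1.0, sigma2=1.0), cherry_tree, tv)
        assert val == pytest.approx(-math.log(2 * math.pi) - 1, abs=1e-12)

    def test_eb_zero_beta_equals_bm(self, fossil_tree_100):
        tree, _ = fossil_tree_100
        rng = np.random.default_rng(3)
        tv = trait_vector(tree, rng.normal(size=tree.n_tips))
        a = loglik(ContModelSpec("EB"),
                   ContParams(theta0=0.2, sigma2=1.3, beta=0.0), tree, tv)
        b = loglik(ContModelSpec("BM"),
                   ContParams(theta0=0.2, sigma2=1.3), tree, tv)
        assert a == pytest.approx(b, abs=1e-9)

    def test_tip_permutation_invariant(self, three_tip_tree):
        from paleotrait.treekit import DatedTree

        reordered = DatedTree.from_newick("(C:2,(B:1,A:1):1);")
        p = ContParams(theta0=0.5, sigma2=2.0)
        tv1 = trait_vector(three_tip_tree, [1, 2, 3])  # A,B,C
        tv2 = trait_vector(reordered, [3, 2, 1])       # C,B,A
        assert loglik(ContModelSpec("BM"), p, three_tip_tree, tv1) == pytest.approx(
            loglik(ContModelSpec("BM"), p, reordered, tv2), abs=1e-9
        )


class TestFitML:
    def test_wn_closed_form(self, three_tip_tree):
        f = fit_ml(ContModelSpec("WN"), three_tip_tree,
                   trait_vector(three_tip_tree, [1, 2, 3]))
        assert f.params.theta0 == pytest.approx(2.0)
        assert f.params.sigma2 == pytest.approx(2 / 3)
        assert f.aic == pytest.approx(2 * 2 - 2 * f.lnL)

    def test_bm_recovery(self, bd_tree_128):
        spec = ContModelSpec("BM")
        p = ContParams(theta0=0.0, sigma2=4.0)
        X = simulate_traits(spec, p, bd_tree_128, 100, 7)
        s2 = []
        th = []
        for i in range(100):
            f = fit_ml(spec, bd_tree_128, trait_vector(bd_tree_128, X[i]))
            s2.append(f.params.sigma2)
            th.append(f.params.theta0)
        assert abs(np.median(s2) - 4.0) / 4.0 < 0.10
        assert abs(np.median(th)) < 0.5

    @pytest.mark.parametrize("name,params,checks", [
        ("EB", dict(theta0=5.0, sigma2=10.0, beta=-4.0),
         dict(beta=("abs", 0.6), sigma2=("rel", 0.35))),
        ("TREND", dict(theta0=5.0, sigma2=2.0, trend=-3.0),
         dict(trend=("abs", 0.8), sigma2=("rel", 0.15))),
        ("OU", dict(theta0=2.0, sigma2=5.0, theta1=6.0, alpha=3.0),
         dict(alpha=("abs", 1.2), theta1=("abs", 0.8))),
    ])
    def test_shape_param_recovery(self, fossil_tree_100, name, params, checks):
        tree, _ = fossil_tree_100
        spec = ContModelSpec(name)
        p = ContParams(**params)
        X = simulate_traits(spec, p, tree, 60, 11)
        est = {k: [] for k in checks}
        for i in range(60):
            f = fit_ml(spec, tree, trait_vector(tree, X[i]))
            for k in checks:
                est[k].append(getattr(f.params, k))
        for k, (kind, tol) in checks.items():
            med = np.median(est[k])
            truth = params[k]
            if kind == "rel":
                assert abs(med - truth) / abs(truth) < tol, (k, med)
            else:
                assert abs(med - truth) < tol, (k, med)

    def test_nesting_properties(self, fossil_tree_100):
        tree, _ = fossil_tree_100
        rng = np.random.default_rng(5)
        for _ in range(5):
            tv = trait_vector(tree, rng.normal(5, 2, size=tree.n_tips))
            bm = fit_ml(ContModelSpec("BM"), tree, tv)
            assert fit_ml(ContModelSpec("EB"), tree, tv).lnL >= bm.lnL - 1e-6
            assert fit_ml(ContModelSpec("TREND"), tree, tv).lnL >= bm.lnL - 1e-6

    def test_constant_trait_warns_not_errors(self, three_tip_tree):
        with pytest.warns(RuntimeWarning, match="constant"):
            f = fit_ml(ContModelSpec("BM"), three_tip_tree,
                       trait_vector(three_tip_tree, [3, 3, 3]))
        assert f.params.sigma2 <= 1e-11

    def test_two_tips_bm_wn_only(self, cherry_tree):
        tv = trait_vector(cherry_tree, [0, 2])
        fit_ml(ContModelSpec("BM"), cherry_tree, tv)
        fit_ml(ContModelSpec("WN"), cherry_tree, tv)
        with pytest.raises(ModelError):
            fit_ml(ContModelSpec("OU"), cherry_tree, tv)


class TestAkaike:
    def test_printed_table_weights(self):
        aic = {"BM": 2752.83, "EB": 2510.55, "OU": 2709.67,
               "TREND": 2754.75, "WN": 2903.84}
        w = dict(zip(aic, akaike_weights_from_aic(list(aic.values()))))
        assert w["BM"] == pytest.approx(2.45e-53, rel=5e-3)
        assert w["EB"] == pytest.approx(1.00, abs=1e-9)
        assert w["OU"] == pytest.approx(5.80e-44, rel=5e-3)
        assert w["TREND"] == pytest.approx(9.40e-54, rel=5e-3)
        assert w["WN"] == pytest.approx(3.97e-86, rel=5e-3)

    def test_single_model(self, three_tip_tree):
        f = fit_ml(ContModelSpec("WN"), three_tip_tree,
                   trait_vector(three_tip_tree, [1, 2, 3]))
        cmp = akaike_compare([f])
        assert cmp.akaike_weight[0] == pytest.approx(1.0)

    def test_equal_aic_split(self):
        w = akaike_weights_from_aic([100.0, 100.0])
        np.testing.assert_allclose(w, [0.5, 0.5])

    def test_mismatched_trees_rejected(self, three_tip_tree, cherry_tree):
        f1 = fit_ml(ContModelSpec("WN"), three_tip_tree,
                    trait_vector(three_tip_tree, [1, 2, 3]), tree_id=1)
        f2 = fit_ml(ContModelSpec("WN"), cherry_tree,
                    trait_vector(cherry_tree, [1, 2]), tree_id=2)
        with pytest.raises(ModelError):
            akaike_compare([f1, f2])

    @given(st.lists(st.floats(min_value=0, max_value=3000), min_size=1, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_weights_sum_to_one_and_monotone(self, aics):
        w = akaike_weights_from_aic(aics)
        assert np.sum(w) == pytest.approx(1.0, abs=1e-12)
        order = np.argsort(aics)
        assert np.all(np.diff(w[order]) <= 1e-12)

    def test_aic_bookkeeping_matches_k(self, three_tip_tree, fossil_tree_100):
        tree, _ = fossil_tree_100
        tv = trait_vector(tree, np.random.default_rng(0).normal(5, 2, tree.n_tips))
        for name, k in MODEL_K.items():
            f = fit_ml(ContModelSpec(name), tree, tv)
            assert f.aic == pytest.approx(2 * k - 2 * f.lnL, abs=1e-9)


class TestSimulateTraits:
    def test_bm_tip_variance(self, bd_tree_128):
        spec = ContModelSpec("BM")
        p = ContParams(theta0=0.0, sigma2=1.0)
        X = simulate_traits(spec, p, bd_tree_128, 2000, 123)
        T = bd_tree_128.tip_depth_vector()
        v = X.var(axis=0)
        se = T * math.sqrt(2 / 2000)  # var of sample variance of normal
        assert np.all(np.abs(v - T) < 4 * se + 1e-9)

    def test_zero_variance_degenerate(self, three_tip_tree):
        p = ContParams(theta0=7.0, sigma2=1e-300)
        X = simulate_traits(ContModelSpec("BM"), p, three_tip_tree, 5, 0)
        np.testing.assert_allclose(X, 7.0, atol=1e-140)

    def test_seed_determinism(self, three_tip_tree):
        p = ContParams(theta0=0.0, sigma2=1.0)
        a = simulate_traits(ContModelSpec("BM"), p, three_tip_tree, 4, 9)
        b = simulate_traits(ContModelSpec("BM"), p, three_tip_tree, 4, 9)
        np.testing.assert_array_equal(a, b)


class TestAncestralStates:
    def test_two_tip_root_mean(self, cherry_tree):
        tv = trait_vector(cherry_tree, [0, 2])
        f = fit_ml(ContModelSpec("BM"), cherry_tree, tv)
        anc = ancestral_states(f, cherry_tree, tv)
        assert anc[cherry_tree.root.index] == pytest.approx(1.0)

    def test_constant_trait_invariance(self, bd_tree_128):
        tv = trait_vector(bd_tree_128, np.full(bd_tree_128.n_tips, 4.0))
        with pytest.warns(RuntimeWarning):
            f = fit_ml(ContModelSpec("BM"), bd_tree_128, tv)
        anc = ancestral_states(f, bd_tree_128, tv)
        np.testing.assert_allclose(list(anc.values()), 4.0, atol=1e-6)

    def test_eb_beta_zero_matches_bm(self, fossil_tree_100):
        tree, _ = fossil_tree_100
        rng = np.random.default_rng(8)
        tv = trait_vector(tree, rng.normal(3, 1, tree.n_tips))
        bm = fit_ml(ContModelSpec("BM"), tree, tv)
        eb_spec = ContModelSpec("EB")
        eb = FitResult(eb_spec, ContParams(theta0=bm.params.theta0,
                                           sigma2=bm.params.sigma2, beta=0.0),
                       bm.lnL, 2 * 3 - 2 * bm.lnL, True, 0)
        a = ancestral_states(bm, tree, tv)
        b = ancestral_states(eb, tree, tv)
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-9)

    def test_unsupported_models_rejected(self, three_tip_tree):
        tv = trait_vector(three_tip_tree, [1, 2, 3])
        f = fit_ml(ContModelSpec("WN"), three_tip_tree, tv)
        with pytest.raises(ModelError):
            ancestral_states(f, three_tip_tree, tv)
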