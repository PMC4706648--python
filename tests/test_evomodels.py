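import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from phylosize.evomodels import (
    MODELS,
    ModelComparison,
    ModelFit,
    bm_ancestral_states,
    fit_model_set,
    fit_trait_model,
    model_covariance,
    pgls_regression,
)
from phylosize.signal import align_to_tips
from phylosize.synthetic import simulate_trait
from phylosize.tree import parse_newick


class TestModelCovariance:
    @pytest.fixture
    def C(self, random_tree_factory):
        return random_tree_factory(8, seed=1).covariance()

    def test_lambda_one_is_bm(self, C):
        np.testing.assert_allclose(model_covariance("lambda", 1.0, C, C.max()), C)

    def test_lambda_zero_is_diagonal(self, C):
        V = model_covariance("lambda", 0.0, C, C.max())
        np.testing.assert_allclose(V, np.diag(np.diag(C)))

    def test_bm_nesting_limits(self, C):
        T = C.diagonal().max()
        np.testing.assert_allclose(model_covariance("delta", 1.0, C, T), C)
        np.testing.assert_allclose(
            model_covariance("EB", -1e-10, C, T), C, rtol=1e-6,
        )
        np.testing.assert_allclose(
            model_covariance("SSP", 1e-10, C, T), C, rtol=1e-6,
        )

    def test_wn_is_identity(self, C):
        np.testing.assert_allclose(model_covariance("WN", None, C, 1.0), np.eye(len(C)))

    def test_ssp_stationary_variance_at_large_alpha(self, C):
        T = C.diagonal().max()
        al = 50.0 / T
        V = model_covariance("SSP", al, C, T)
        # ultrametric diagonal approaches 1/(2 alpha)
        assert V.max() <= 1.0 / (2 * al) + 1e-12

    def test_delta_rescaled_to_depth(self, C):
        T = C.diagonal().max()
        for d in (0.3, 2.5):
            V = model_covariance("delta", d, C, T)
            assert V.diagonal().max() == pytest.approx(T)


class TestFitTraitModel:
    def test_wn_closed_form(self, random_tree_factory):
        t = random_tree_factory(12, seed=2)
        x = np.random.default_rng(2).normal(2.0, 0.7, size=12)
        fit = fit_trait_model(t, x, model="WN")
        assert fit.z0 == pytest.approx(x.mean(), abs=1e-6)
        assert fit.sigma2 == pytest.approx(np.var(x), rel=1e-5)
        oracle = stats.norm(x.mean(), np.sqrt(np.var(x))).logpdf(x).sum()
        assert fit.log_lik == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("model", ["EB", "delta", "SSP", "lambda"])
    def test_general_models_nest_bm(self, model, random_tree_factory):
        t = random_tree_factory(15, seed=5)
        x = simulate_trait(t, "BM", sigma2=0.02, z0=1.0, seed=5)
        bm = fit_trait_model(t, x, model="BM")
        gen = fit_trait_model(t, x, model=model)
        # EB's shape is bounded away from the BM limit (a <= -1e-6), so its
        # likelihood can sit a hair below BM's; the others nest exactly
        tol = 1e-4 if model == "EB" else 1e-6
        assert gen.log_lik >= bm.log_lik - tol

    @pytest.mark.parametrize("model", MODELS)
    def test_loglik_matches_direct_mvn_oracle(self, model, random_tree_factory):
        t = random_tree_factory(6, seed=7)
        x = simulate_trait(t, "BM", sigma2=0.05, z0=0.0, seed=8)
        se = np.full(6, 0.1)
        fit = fit_trait_model(t, x, se=se, model=model)
        V = fit.sigma2 * model_covariance(
            model, fit.shape, t.covariance(), t.depth,
        ) + np.diag(se**2)
        xv = align_to_tips(t, x)
        oracle = stats.multivariate_normal(np.full(6, fit.z0), V).logpdf(xv)
        assert fit.log_lik == pytest.approx(oracle, abs=1e-8)

    def test_lambda_near_one_for_bm_data_and_low_when_shuffled(self, random_tree_factory):
        t = random_tree_factory(120, seed=9)
        x = simulate_trait(t, "BM", sigma2=0.01, seed=9)
        lam_bm = fit_trait_model(t, x, model="lambda").shape
        rng = np.random.default_rng(10)
        lam_shuf = fit_trait_model(t, rng.permutation(x), model="lambda").shape
        assert lam_bm > 0.8
        assert lam_shuf < 0.3

    def test_eb_bound_flagged(self, random_tree_factory):
        # white-noise-like data pushes EB's a to its upper (near-zero) bound
        t = random_tree_factory(20, seed=12)
        x = np.random.default_rng(12).normal(size=20)
        fit = fit_trait_model(t, x, model="EB")
        if fit.at_bound:
            assert fit.shape == pytest.approx(-1e-6, rel=1e-3) or fit.shape < 0

    def test_small_n_rejected(self):
        t = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            fit_trait_model(t, [1.0, 2.0], model="BM")


class TestModelComparison:
    def test_aicc_arithmetic_from_printed_row(self):
        # lnLik = -1057.3, k = 2, n = 774
        aicc = -2 * (-1057.3) + 2 * 2 + 2 * 2 * 3 / (774 - 3)
        assert aicc == pytest.approx(2118.62, abs=0.01)
        fit = ModelFit(model="WN", sigma2=0.9, z0=1.9, shape=None,
                       log_lik=-1057.3, k=2, n=774, aicc=aicc)
        assert fit.aicc == pytest.approx(2118.7, abs=0.2)

    def test_weights_sum_to_one(self, random_tree_factory):
        t = random_tree_factory(20, seed=3)
        x = simulate_trait(t, "BM", sigma2=0.02, seed=3)
        comp = fit_model_set(t, x, models=["BM", "lambda", "WN"])
        assert comp.summary()["akaike_weight"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_model_weight_one(self):
        f = ModelFit("BM", 0.1, 0.0, None, -10.0, 2, 50, 24.3)
        comp = ModelComparison([f])
        assert comp.fits[0].akaike_weight == pytest.approx(1.0)

    def test_equal_aicc_half_half(self):
        f1 = ModelFit("BM", 0.1, 0.0, None, -10.0, 2, 50, 24.0)
        f2 = ModelFit("WN", 0.1, 0.0, None, -10.0, 2, 50, 24.0)
        comp = ModelComparison([f1, f2])
        for f in comp.fits:
            assert f.akaike_weight == pytest.approx(0.5)

    def test_favoured_prefers_simpler_within_two_units(self):
        simple = ModelFit("BM", 0.1, 0.0, None, -10.0, 2, 50, 25.5)
        complex_best = ModelFit("SSP", 0.1, 0.0, 0.5, -8.0, 3, 50, 24.0)
        comp = ModelComparison([simple, complex_best])
        assert comp.favoured.model == "BM"
        far = ModelFit("BM", 0.1, 0.0, None, -14.0, 2, 50, 33.0)
        comp2 = ModelComparison([far, complex_best])
        assert comp2.favoured.model == "SSP"

    def test_aicc_undefined_for_tiny_n(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        x = [1.0, 2.0, 3.0, 4.0]
        with pytest.raises(ValueError, match="AICc undefined"):
            fit_trait_model(t, x, model="lambda")  # n=4, k=3


class TestAncestralStates:
    def test_two_tips_equal_branches_root_is_mean(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        x = {"A": 1.0, "B": 3.0, "C": 1.0, "D": 3.0}
        anc = bm_ancestral_states(t, x)
        assert anc.root_state == pytest.approx(2.0, abs=1e-8)

    def test_two_tip_closed_form(self):
        v1, v2 = 1.0, 3.0
        t = parse_newick(f"(A:{v1},B:{v2});")
        x1, x2 = 2.0, 6.0
        anc = bm_ancestral_states(t, {"A": x1, "B": x2})
        expected = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2)
        assert anc.root_state == pytest.approx(expected, abs=1e-10)

    def test_root_within_data_range(self, random_tree_factory):
        t = random_tree_factory(25, seed=14)
        x = simulate_trait(t, "BM", sigma2=0.02, z0=1.0, seed=14)
        anc = bm_ancestral_states(t, x)
        assert x.min() - 1e-9 <= anc.root_state <= x.max() + 1e-9
        assert len(anc.states) == t.n_nodes - t.n_tips


class TestPgls:
    def test_perfect_linear_relation(self, random_tree_factory):
        t = random_tree_factory(12, seed=15)
        x = simulate_trait(t, "BM", sigma2=0.05, seed=15)
        y = 2.0 * x + 1e-9 * np.random.default_rng(0).normal(size=12)
        res = pgls_regression(t, y, x)
        assert res.slope == pytest.approx(2.0, abs=1e-6)
        assert res.p < 1e-10

    def test_star_tree_equals_ols(self):
        t = parse_newick("(A:1,B:1,C:1,D:1,E:1,F:1);")
        rng = np.random.default_rng(4)
        x = rng.normal(size=6)
        y = 0.5 * x + rng.normal(size=6)
        res = pgls_regression(t, y, x)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.slope == pytest.approx(ols.params[1], abs=1e-10)
        assert res.se == pytest.approx(ols.bse[1], abs=1e-10)
        assert res.p == pytest.approx(ols.pvalues[1], abs=1e-10)

    def test_type_one_error_near_nominal(self, random_tree_factory):
        reps, n = 200, 40
        rejected = 0
        for i in range(reps):
            t = random_tree_factory(n, seed=3000 + i)
            x = simulate_trait(t, "BM", sigma2=0.01, seed=20_000 + i)
            y = simulate_trait(t, "BM", sigma2=0.01, seed=40_000 + i)
            if pgls_regression(t, y, x).p < 0.05:
                rejected += 1
        rate = rejected / reps
        assert abs(rate - 0.05) < 4 * np.sqrt(0.05 * 0.95 / reps)

    def test_constant_predictor_rejected(self, random_tree_factory):
        t = random_tree_factory(6, seed=1)
        with pytest.raises(ValueError, match="constant"):
            pgls_regression(t, np.arange(6.0), np.ones(6))
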