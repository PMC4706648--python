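import math

import numpy as np
import pytest
import statsmodels.api as sm

from phylosize.macrocaic import (
    RichnessContrasts,
    origin_regression,
    parametric_bootstrap_test,
    richness_contrasts,
)
from phylosize.tipdist import TipDistribution
from phylosize.tree import parse_newick


@pytest.fixture
def cherry_pair():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


class TestRichnessContrasts:
    def test_equal_richness_zero_contrast(self):
        t = parse_newick("(A:1,B:1);")
        rows = richness_contrasts(t, {"A": 3.0, "B": 1.0}, {"A": 10, "B": 10})
        assert rows[0].rrd == pytest.approx(0.0)
        assert rows[0].pdi == pytest.approx(0.0)
        assert rows[0].trait_contrast == pytest.approx(2 / math.sqrt(2))

    def test_rrd_definition_with_e_ratio(self):
        t = parse_newick("(A:1,B:1);")
        rows = richness_contrasts(
            t, {"A": 3.0, "B": 1.0}, {"A": 2 * math.e, "B": 2.0},
        )
        assert rows[0].rrd == pytest.approx(1.0)

    def test_orientation_invariance_under_daughter_swap(self):
        t1 = parse_newick("((A:1,B:1):1,C:2);")
        t2 = parse_newick("((B:1,A:1):1,C:2);")
        x = {"A": 3.0, "B": 1.0, "C": 2.0}
        n = {"A": 5, "B": 9, "C": 4}
        r1 = richness_contrasts(t1, x, n)
        r2 = richness_contrasts(t2, x, n)
        for a, b in zip(r1, r2):
            assert a.trait_contrast == pytest.approx(b.trait_contrast)
            assert a.rrd == pytest.approx(b.rrd)
            assert (a.n_larger, a.n_smaller) == (b.n_larger, b.n_smaller)

    def test_internal_richness_is_descendant_sum(self, cherry_pair):
        x = {"A": 1.0, "B": 2.0, "C": 5.0, "D": 6.0}
        n = {"A": 1, "B": 2, "C": 3, "D": 4}
        rows = richness_contrasts(cherry_pair, x, n)
        root_row = [r for r in rows if r.n_larger + r.n_smaller == 10][0]
        assert {root_row.n_larger, root_row.n_smaller} == {3, 7}
        assert root_row.n_larger == 7  # C+D clade has larger trait values

    def test_rrd_antisymmetry_under_trait_negation(self, random_tree_factory):
        t = random_tree_factory(10, seed=6)
        rng = np.random.default_rng(6)
        x = rng.normal(size=10)
        n = rng.integers(1, 50, size=10)
        r_pos = richness_contrasts(t, x, n)
        r_neg = richness_contrasts(t, -x, n)
        for a, b in zip(r_pos, r_neg):
            assert b.rrd == pytest.approx(-a.rrd)
            assert b.pdi == pytest.approx(-a.pdi)

    def test_pdi_bounds_and_sign_agreement(self, random_tree_factory):
        t = random_tree_factory(20, seed=8)
        rng = np.random.default_rng(8)
        rows = richness_contrasts(
            t, rng.normal(size=20), rng.integers(1, 100, size=20),
        )
        for r in rows:
            assert -0.5 <= r.pdi <= 0.5
            assert np.sign(r.pdi) == np.sign(r.rrd)

    def test_zero_richness_rejected(self):
        t = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            richness_contrasts(t, {"A": 1.0, "B": 2.0}, {"A": 0, "B": 1})


class TestOriginRegression:
    def test_exact_proportionality(self):
        x = np.array([1.0, 2.0, -1.5, 0.5])
        reg = origin_regression(x, 4.0 * x)
        assert reg.slope == pytest.approx(4.0)
        assert reg.p == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_no_intercept(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=30)
        y = 1.3 * x + rng.normal(size=30)
        reg = origin_regression(x, y)
        ols = sm.OLS(y, x[:, None]).fit()
        assert reg.slope == pytest.approx(ols.params[0], abs=1e-12)
        assert reg.se == pytest.approx(ols.bse[0], abs=1e-12)
        assert reg.t == pytest.approx(ols.tvalues[0], abs=1e-10)
        assert reg.p == pytest.approx(ols.pvalues[0], abs=1e-12)
        assert reg.adj_r2 == pytest.approx(ols.rsquared_adj, abs=1e-12)

    def test_slope_matches_grid_search_minimizer(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        grid = np.linspace(-5, 5, 200001)
        rss = ((y[None, :] - grid[:, None] * x[None, :]) ** 2).sum(axis=1)
        assert origin_regression(x, y).slope == pytest.approx(
            grid[rss.argmin()], abs=1e-4,
        )

    def test_single_pair_flagged(self):
        with pytest.warns(UserWarning, match="df = 0"):
            reg = origin_regression([2.0], [1.0])
        assert reg.slope == pytest.approx(0.5)
        assert math.isnan(reg.p)

    def test_zero_predictor_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            origin_regression([0.0, 0.0], [1.0, 2.0])


def _tips_for(tree, means, sds, richness):
    return [
        TipDistribution(l, means[i], sds[i], richness[i] + 2,
                        sds[i] / math.sqrt(richness[i] + 2) or 1e-6)
        for i, l in enumerate(tree.tip_labels)
    ]


class TestParametricBootstrap:
    def test_zero_sd_degenerates_to_observed_slope(self, random_tree_factory):
        t = random_tree_factory(8, seed=3)
        rng = np.random.default_rng(3)
        tips = _tips_for(t, rng.normal(2, 1, 8), np.zeros(8),
                         rng.integers(1, 40, 8))
        res = parametric_bootstrap_test(t, tips, n_reps=100, seed=0)
        assert res.obs_qr[0] == pytest.approx(res.observed_slope, abs=1e-12)
        assert res.obs_qr[1] == pytest.approx(res.observed_slope, abs=1e-12)

    def test_seed_determinism(self, random_tree_factory):
        t = random_tree_factory(10, seed=4)
        rng = np.random.default_rng(4)
        tips = _tips_for(t, rng.normal(2, 1, 10), rng.uniform(0.1, 1, 10),
                         rng.integers(1, 40, 10))
        r1 = parametric_bootstrap_test(t, tips, n_reps=500, seed=99)
        r2 = parametric_bootstrap_test(t, tips, n_reps=500, seed=99)
        assert r1 == r2

    def test_too_few_reps_rejected(self, random_tree_factory):
        t = random_tree_factory(6, seed=5)
        rng = np.random.default_rng(5)
        tips = _tips_for(t, rng.normal(2, 1, 6), rng.uniform(0.1, 1, 6),
                         rng.integers(1, 40, 6))
        with pytest.raises(ValueError, match="too small"):
            parametric_bootstrap_test(t, tips, n_reps=20, seed=0)

    def test_model_object_matches_function(self, random_tree_factory):
        t = random_tree_factory(12, seed=7)
        rng = np.random.default_rng(7)
        tips = _tips_for(t, rng.normal(2, 1, 12), rng.uniform(0.1, 1, 12),
                         rng.integers(1, 40, 12))
        model = RichnessContrasts(t, tips, metric="rrd")
        fit = model.fit()
        assert fit.regression.n == 11
        boot = model.parametric_bootstrap(n_reps=200, seed=1)
        assert boot.observed_slope == pytest.approx(fit.regression.slope)

    def test_null_interval_covers_observed_under_independence(
            self, random_tree_factory):
        # richness assigned independently of trait: the observed slope
        # should usually fall inside the null interval
        inside = 0
        reps = 40
        for i in range(reps):
            t = random_tree_factory(15, seed=600 + i)
            rng = np.random.default_rng(900 + i)
            tips = _tips_for(t, rng.normal(2, 0.8, 15),
                             rng.uniform(0.05, 0.5, 15),
                             rng.integers(1, 60, 15))
            res = parametric_bootstrap_test(t, tips, n_reps=400, seed=i)
            if res.null_qr[0] <= res.observed_slope <= res.null_qr[1]:
                inside += 1
        assert inside / reps >= 0.8
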