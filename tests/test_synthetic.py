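import numpy as np
import pytest

from phylosize.synthetic import (
    aggregate_to_families,
    parameter_recovery_experiment,
    simulate_trait,
    simulate_yule_tree,
)


class TestYuleTree:
    def test_tip_count_and_ultrametricity(self):
        t = simulate_yule_tree(50, birth_rate=0.1, seed=0)
        assert t.n_tips == 50
        assert t.is_ultrametric(rtol=1e-9)
        assert t.is_bifurcating()

    def test_seed_determinism(self):
        a = simulate_yule_tree(20, 0.2, seed=7).to_newick()
        b = simulate_yule_tree(20, 0.2, seed=7).to_newick()
        assert a == b

    def test_crown_age_matches_analytic_expectation(self):
        lam, n, reps = 0.5, 8, 1500
        ages = [simulate_yule_tree(n, lam, seed=s).depth for s in range(reps)]
        expected = sum(1.0 / (lam * k) for k in range(2, n + 1))
        # per-replicate sd of a sum of independent exponentials
        sd = np.sqrt(sum(1.0 / (lam * k) ** 2 for k in range(2, n + 1)))
        assert abs(np.mean(ages) - expected) < 4 * sd / np.sqrt(reps)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_yule_tree(1, 0.1, seed=0)
        with pytest.raises(ValueError):
            simulate_yule_tree(10, 0.0, seed=0)


class TestSimulateTrait:
    def test_bm_tip_variance_scales_with_depth(self):
        tree = simulate_yule_tree(30, 0.2, seed=1)
        sigma2 = 0.04
        draws = np.array([
            simulate_trait(tree, "BM", sigma2=sigma2, z0=0.0, seed=s)
            for s in range(1000)
        ])
        emp = draws.var(axis=0).mean()
        expected = sigma2 * tree.tip_depths().mean()
        assert emp == pytest.approx(expected, rel=0.1)

    def test_ssp_stationary_variance_at_large_alpha(self):
        tree = simulate_yule_tree(30, 0.2, seed=2)
        sigma2, alpha = 0.5, 2.0
        draws = np.array([
            simulate_trait(tree, "SSP", sigma2=sigma2, shape=alpha, seed=s)
            for s in range(1000)
        ])
        emp = draws.var(axis=0).mean()
        assert emp == pytest.approx(sigma2 / (2 * alpha), rel=0.1)

    def test_zero_rate_collapses_to_root_state(self):
        tree = simulate_yule_tree(10, 0.2, seed=3)
        x = simulate_trait(tree, "BM", sigma2=0.0, z0=1.7, seed=3)
        np.testing.assert_allclose(x, 1.7)
        y = simulate_trait(tree, "BM", sigma2=0.0, z0=0.0, se=0.5, seed=4)
        assert y.std() > 0  # only observation noise remains

    def test_seed_determinism(self):
        tree = simulate_yule_tree(10, 0.2, seed=4)
        a = simulate_trait(tree, "lambda", sigma2=0.1, shape=0.6, seed=11)
        b = simulate_trait(tree, "lambda", sigma2=0.1, shape=0.6, seed=11)
        np.testing.assert_array_equal(a, b)


class TestAggregateToFamilies:
    @pytest.fixture
    def dataset(self):
        tree = simulate_yule_tree(120, 0.2, seed=5)
        trait = simulate_trait(tree, "BM", sigma2=0.02, z0=2.0, seed=5)
        return tree, trait, aggregate_to_families(
            tree, trait, slice_age=0.4 * tree.depth, seed=6,
        )

    def test_richness_sums_to_species_count(self, dataset):
        tree, _, ds = dataset
        assert sum(r.richness for r in ds.family_records) == tree.n_tips
        assert len(ds.family_of) == tree.n_tips

    def test_min_max_exactly_from_member_traits(self, dataset):
        tree, trait, ds = dataset
        by_fam: dict[str, list[float]] = {}
        for lbl, fam in ds.family_of.items():
            by_fam.setdefault(fam, []).append(trait[tree.tip_labels.index(lbl)])
        for rec in ds.family_records:
            vals = np.array(by_fam[rec.taxon])
            assert np.log(rec.min_mm) == pytest.approx(vals.min(), abs=1e-12)
            assert np.log(rec.max_mm) == pytest.approx(vals.max(), abs=1e-12)

    def test_family_tree_ultrametric_with_full_depth(self, dataset):
        tree, _, ds = dataset
        assert ds.family_tree.n_tips == len(ds.family_records)
        assert ds.family_tree.is_ultrametric(rtol=1e-9)
        assert ds.family_tree.depth == pytest.approx(tree.depth)
        assert set(ds.family_tree.tip_labels) == {
            r.taxon for r in ds.family_records
        }

    def test_families_pass_record_invariants(self, dataset):
        _, _, ds = dataset
        for rec in ds.family_records:
            assert 0 < rec.min_mm <= rec.max_mm
            assert rec.richness >= 1
            assert rec.clade.startswith("clade_")

    def test_shallow_slice_yields_root_daughters(self):
        tree = simulate_yule_tree(30, 0.2, seed=7)
        eps = 1e-9
        with pytest.raises(ValueError, match="families"):
            # slicing just below the root crosses only the two basal branches
            aggregate_to_families(
                tree, np.zeros(30), slice_age=tree.depth - eps, seed=0,
            )

    def test_bad_slice_age(self):
        tree = simulate_yule_tree(10, 0.2, seed=8)
        with pytest.raises(ValueError):
            aggregate_to_families(tree, np.zeros(10), slice_age=2 * tree.depth)


class TestParameterRecovery:
    def test_report_is_deterministic(self):
        cfg = {"n_species": 40, "n_replicates": 3, "fit_models": [],
               "run_signal": True}
        a = parameter_recovery_experiment(cfg, seed=3)
        b = parameter_recovery_experiment(cfg, seed=3)
        assert a == b

    def test_bm_generator_recovers_bm_like_models(self):
        cfg = {"n_species": 60, "n_replicates": 6,
               "fit_models": ["BM", "lambda", "WN"], "run_signal": True}
        rep = parameter_recovery_experiment(cfg, seed=1)
        freq = rep["summary"]["model_selection_freq"]
        # BM itself should win (lambda matches its likelihood but pays a
        # parameter; WN should essentially never win)
        assert freq.get("BM", 0.0) >= 0.5
        assert rep["summary"]["mean_K"] > 0.5

    def test_family_mode_runs_full_pipeline(self):
        cfg = {"n_species": 80, "n_replicates": 2, "mode": "family",
               "fit_models": ["BM", "WN"], "run_macrocaic": True,
               "n_boot": 200, "z0": 2.0}
        rep = parameter_recovery_experiment(cfg, seed=2)
        assert "macrocaic_significant_rate" in rep["summary"]
        assert all("n_families" in r for r in rep["replicates"])

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValueError, match="unknown config"):
            parameter_recovery_experiment({"n_specie": 10}, seed=0)
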