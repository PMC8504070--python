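"""Synthetic-data generator and the FDR/power benchmark runner."""

import numpy as np
import pytest
from scipy import stats

from contrastfdr import (
    GroundTruth,
    SimulationConfig,
    evaluate_fdp_power,
    generate_dataset,
    run_benchmark,
)


class TestGenerateDataset:
    def test_shapes_counts_and_determinism(self):
        cfg = SimulationConfig(d=1000, design=(3, 3), family="gaussian", pi1=0.1, seed=1)
        pair, truth = generate_dataset(cfg)
        assert pair.x.shape == (1000, 3) and pair.y.shape == (1000, 3)
        assert truth.n_interesting == 100
        pair2, truth2 = generate_dataset(cfg)
        np.testing.assert_array_equal(pair.x, pair2.x)
        np.testing.assert_array_equal(truth.interesting, truth2.interesting)
        pair3, _ = generate_dataset(SimulationConfig(d=1000, seed=2))
        assert not np.array_equal(pair.x, pair3.x)

    def test_pi1_zero_means_every_discovery_is_false(self):
        cfg = SimulationConfig(d=200, pi1=0.0, seed=3)
        _, truth = generate_dataset(cfg)
        assert truth.n_interesting == 0
        fdp, power = evaluate_fdp_power(np.array([0, 5, 7]), truth)
        assert fdp == 1.0 and power == 0.0

    def test_uninteresting_features_have_equal_means(self):
        for mode in ("enrichment", "differential"):
            cfg = SimulationConfig(d=500, family="poisson", mode=mode, seed=4)
            _, truth = generate_dataset(cfg)
            null = ~truth.interesting
            np.testing.assert_array_equal(truth.mu_x[null], truth.mu_y[null])
            assert np.all(truth.mu_x[truth.interesting] != truth.mu_y[truth.interesting])

    @pytest.mark.parametrize("family", ["gaussian", "poisson", "negbin"])
    def test_null_halves_identically_distributed(self, family):
        """On uninteresting features the pooled X and Y values are draws from
        one distribution: two-sample rank test across the pooled halves."""
        cfg = SimulationConfig(d=3000, design=(3, 3), family=family, pi1=0.0, seed=5)
        pair, _ = generate_dataset(cfg)
        res = stats.mannwhitneyu(pair.x.ravel(), pair.y.ravel())
        assert res.pvalue > 0.001

    def test_homogeneous_background_single_mean(self):
        cfg = SimulationConfig(d=300, family="poisson", background="homogeneous", seed=6)
        _, truth = generate_dataset(cfg)
        assert np.unique(truth.mu_y).size == 1

    def test_outliers_inflate_some_entries(self):
        base = SimulationConfig(d=2000, family="gaussian", seed=7)
        spiked = SimulationConfig(
            d=2000, family="gaussian", seed=7, outlier_rate=0.05, outlier_factor=10.0
        )
        pair0, _ = generate_dataset(base)
        pair1, _ = generate_dataset(spiked)
        changed = (pair0.x != pair1.x).any(axis=1) | (pair0.y != pair1.y).any(axis=1)
        assert 0.02 < changed.mean() < 0.09  # ~5% of features hit, one replicate each

    def test_block_correlation_preserves_marginals_and_couples_features(self):
        cfg = SimulationConfig(
            d=10000, design=(1, 1), family="gaussian", background="homogeneous",
            pi1=0.0, correlation=0.8, block_size=50, seed=8,
        )
        pair, _ = generate_dataset(cfg)
        vals = pair.x[:, 0]
        # one feature per block: independent draws, marginal must stay N(0,1)
        assert stats.kstest(vals[::50], "norm").pvalue > 0.001
        blocks = vals.reshape(-1, 50)
        # correlation between two features of the same block, across blocks
        assert np.corrcoef(blocks[:, 0], blocks[:, 1])[0, 1] > 0.5

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(pi1=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(family="lognormal")
        with pytest.raises(ValueError):
            SimulationConfig(effect=0.0)


class TestEvaluateFdpPower:
    def test_worked_examples(self):
        truth = GroundTruth(
            interesting=np.array([False, True, True, False, False]),
            mu_x=np.zeros(5), mu_y=np.zeros(5),
        )
        assert evaluate_fdp_power(np.array([1, 2, 3]), truth) == (1 / 3, 1.0)
        assert evaluate_fdp_power(np.array([], dtype=int), truth) == (0.0, 0.0)
        assert evaluate_fdp_power(np.array([1, 2]), truth) == (0.0, 1.0)

    def test_out_of_range_indices_rejected(self):
        truth = GroundTruth(np.array([True]), np.zeros(1), np.zeros(1))
        with pytest.raises(IndexError):
            evaluate_fdp_power(np.array([5]), truth)


class TestRunBenchmark:
    def test_single_rep_table_in_unit_range(self):
        cfg = SimulationConfig(d=400, design=(3, 3), family="gaussian", seed=1)
        tab = run_benchmark(cfg, methods=["clipper", "BH-pair"], q_grid=[0.05, 0.1], n_reps=1)
        assert len(tab) == 4
        assert tab.mean_FDP.between(0, 1).all() and tab.mean_power.between(0, 1).all()
        assert (tab.n_reps == 1).all()

    def test_method_failure_recorded_not_fatal(self):
        # no correctly-specified paired test exists for negbin: cells are NaN
        cfg = SimulationConfig(d=100, design=(3, 3), family="negbin", seed=1)
        tab = run_benchmark(cfg, methods=["BH-pair", "clipper"], q_grid=[0.05], n_reps=2)
        pair_row = tab[tab.method == "BH-pair"].iloc[0]
        assert pair_row.n_reps == 0 and np.isnan(pair_row.mean_FDP)
        assert tab[tab.method == "clipper"].iloc[0].n_reps == 2

    def test_per_replicate_seeds_are_base_plus_index(self):
        cfg = SimulationConfig(d=300, design=(3, 3), family="gaussian", seed=10)
        tab1 = run_benchmark(cfg, methods=["clipper"], q_grid=[0.05], n_reps=2)
        # rep 1 of a base-10 run equals rep 0 of a base-11 run
        cfg11 = SimulationConfig(d=300, design=(3, 3), family="gaussian", seed=11)
        tab2 = run_benchmark(cfg11, methods=["clipper"], q_grid=[0.05], n_reps=1)
        pair_a, _ = generate_dataset(SimulationConfig(d=300, design=(3, 3), family="gaussian", seed=11))
        pair_b, _ = generate_dataset(SimulationConfig(d=300, design=(3, 3), family="gaussian", seed=11))
        np.testing.assert_array_equal(pair_a.x, pair_b.x)
        assert isinstance(tab1, type(tab2))

    def test_pi1_robustness_of_fdr_control(self):
        """Contrast-score FDR control is insensitive to the interesting fraction."""
        for pi1 in (0.1, 0.2, 0.4):
            cfg = SimulationConfig(d=1000, design=(3, 3), family="gaussian", pi1=pi1, seed=1)
            tab = run_benchmark(cfg, methods=["clipper"], q_grid=[0.05], n_reps=30)
            row = tab.iloc[0]
            assert row.mean_FDP <= 0.05 + 3 * row.mc_se_FDP

    def test_correlated_features_still_controlled(self):
        cfg = SimulationConfig(
            d=1000, design=(3, 3), family="gaussian", correlation=0.5, seed=1
        )
        tab = run_benchmark(cfg, methods=["clipper"], q_grid=[0.05], n_reps=30)
        row = tab.iloc[0]
        assert row.mean_FDP <= 0.05 + 3 * row.mc_se_FDP
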