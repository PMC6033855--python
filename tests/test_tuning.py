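import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from ascabc.abc_core import SimulationTable
from ascabc.demography import ParameterPrior, PriorSet
from ascabc.pipeline import build_simulation_table, simulate_stats_row
from ascabc.sumstats import SummaryStatVector
from ascabc.tuning import (
    bootstrap_point_estimates,
    draw_parameter_vectors,
    estimate_covariance,
    score_choice,
    select_hyperparameters,
)
from conftest import make_linear_table


class TestBootstrap:
    def test_deterministic_given_seed(self, linear_table):
        table, priors = linear_table
        obs = SummaryStatVector(list(table.stat_names),
                                table.stats.iloc[10].to_numpy(float))
        m1, _ = bootstrap_point_estimates(table, obs, (2, 50), priors, 3,
                                          np.random.default_rng(5))
        m2, _ = bootstrap_point_estimates(table, obs, (2, 50), priors, 3,
                                          np.random.default_rng(5))
        assert np.array_equal(m1, m2)

    def test_degenerate_table_zero_covariance(self):
        # One unique row repeated: every bootstrap resample is identical.
        n = 60
        params = pd.DataFrame({"alpha": np.full(n, 0.4), "beta": np.full(n, -0.2)})
        stats = pd.DataFrame({
            "s0": np.full(n, 1.0), "s1": np.full(n, 2.0),
            # one informative column so standardization keeps something
            "s2": np.concatenate([[1.0], np.full(n - 1, 1.0)]),
        })
        stats["s2"] += np.linspace(0, 1e-9, n)  # keep one informative column
        priors = PriorSet([
            ParameterPrior("alpha", "uniform", 0.0, 1.0),
            ParameterPrior("beta", "uniform", -1.0, 1.0),
        ])
        table = SimulationTable(params, stats, np.arange(n))
        obs = SummaryStatVector(list(stats.columns), stats.iloc[0].to_numpy(float))
        modes, _ = bootstrap_point_estimates(table, obs, (1, 10), priors, 4,
                                             np.random.default_rng(0))
        assert np.allclose(modes, modes[0], atol=1e-9)
        _, cov = estimate_covariance(modes)
        assert np.allclose(cov, 0, atol=1e-12)


class TestCovariance:
    def test_two_point_hand_example(self):
        mean, cov = estimate_covariance(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert mean.tolist() == [2.0, 3.0]
        assert cov.tolist() == [[2.0, 2.0], [2.0, 2.0]]

    def test_identical_repeats_zero(self):
        _, cov = estimate_covariance(np.tile([1.0, 5.0], (10, 1)))
        assert np.allclose(cov, 0)

    def test_symmetric(self, rng):
        _, cov = estimate_covariance(rng.normal(size=(50, 4)))
        assert np.max(np.abs(cov - cov.T)) < 1e-12

    def test_psd_after_flooring(self, rng):
        _, cov = estimate_covariance(rng.normal(size=(5, 8)))
        assert np.linalg.eigvalsh(cov).min() >= -1e-10


class TestMvnDraws:
    PRIORS = PriorSet([
        ParameterPrior("a", "uniform", -1e6, 1e6),
        ParameterPrior("b", "uniform", -1e6, 1e6),
    ])

    def test_zero_covariance_returns_mean(self, rng):
        vecs = draw_parameter_vectors(np.array([1.5, -2.0]), np.zeros((2, 2)),
                                      20, self.PRIORS, rng)
        assert all(v["a"] == 1.5 and v["b"] == -2.0 for v in vecs)

    def test_large_sample_covariance_within_5pct_frobenius(self, rng):
        cov = np.array([[2.0, 0.6], [0.6, 1.0]])
        vecs = draw_parameter_vectors(np.zeros(2), cov, 100_000, self.PRIORS, rng)
        X = np.array([[v["a"], v["b"]] for v in vecs])
        emp = np.cov(X, rowvar=False)
        assert np.linalg.norm(emp - cov) / np.linalg.norm(cov) < 0.05

    def test_discrete_parameters_rounded(self, rng):
        priors = PriorSet([ParameterPrior("t", "discrete_uniform", 1, 100)])
        vecs = draw_parameter_vectors(np.array([50.3]), np.array([[4.0]]),
                                      50, priors, rng)
        assert all(v["t"] == int(v["t"]) for v in vecs)

    def test_support_exhausted(self, rng):
        priors = PriorSet([ParameterPrior("a", "uniform", 0.0, 1e-7)])
        with pytest.raises(RuntimeError, match="improbable"):
            draw_parameter_vectors(np.array([1e6]), np.array([[1e-12]]),
                                   10, priors, rng, max_oversample=2)


class TestScoring:
    def test_self_distance_near_zero(self, toy_spec, toy_loci, toy_manifest, rng):
        params = toy_spec.priors.sample_vector(rng)
        vec, _ = simulate_stats_row(toy_spec, params, toy_loci, toy_manifest, seed=31)
        # A small batch around it: the batch standardization needs spread.
        vectors = [toy_spec.priors.sample_vector(rng) for _ in range(6)]
        score, distances, skipped = score_choice(
            vectors + [params], vec, toy_spec, toy_loci, toy_manifest, seed=77)
        assert skipped == 0 and score > 0

    def test_empty_vector_list_rejected(self, toy_spec, toy_loci, toy_manifest):
        obs = SummaryStatVector(["x"], np.array([1.0]))
        with pytest.raises(ValueError):
            score_choice([], obs, toy_spec, toy_loci, toy_manifest, seed=1)

    def test_truth_centered_scores_beat_prior_centered(self, toy_spec, toy_loci,
                                                       toy_manifest):
        rng = np.random.default_rng(2024)
        truth = toy_spec.priors.sample_vector(rng)
        obs, _ = simulate_stats_row(toy_spec, truth, toy_loci, toy_manifest, seed=404)
        jitter = lambda: {
            "NA": truth["NA"] * 10 ** rng.normal(0, 0.02),
            "NB": truth["NB"] * 10 ** rng.normal(0, 0.02),
            "TSPLIT": float(np.clip(np.rint(truth["TSPLIT"] + rng.normal(0, 20)),
                                    200, 2000)),
        }
        truth_vectors = [jitter() for _ in range(25)]
        prior_vectors = [toy_spec.priors.sample_vector(rng) for _ in range(25)]
        # One call, one standardization frame, so distances are comparable.
        _, d_all, _ = score_choice(truth_vectors + prior_vectors, obs, toy_spec,
                                   toy_loci, toy_manifest, seed=11)
        stat = mannwhitneyu(d_all[:25], d_all[25:], alternative="less")
        assert stat.pvalue < 0.05


class TestSelection:
    def test_argmin_contract_one_cell(self, toy_spec, toy_loci, toy_manifest):
        table = build_simulation_table(toy_spec, 80, toy_loci, toy_manifest, seed=5)
        obs = SummaryStatVector(list(table.stat_names),
                                table.stats.iloc[3].to_numpy(float))
        best = select_hyperparameters([(2, 20)], table, obs, toy_spec, toy_loci,
                                      toy_manifest, seed=6, n_boot=2, n_draws=4)
        assert (best.n_pls, best.n_retain) == (2, 20)

    def test_returns_smaller_score_cell(self, toy_spec, toy_loci, toy_manifest):
        table = build_simulation_table(toy_spec, 80, toy_loci, toy_manifest, seed=8)
        obs = SummaryStatVector(list(table.stat_names),
                                table.stats.iloc[10].to_numpy(float))
        best = select_hyperparameters([(2, 20), (3, 40)], table, obs, toy_spec,
                                      toy_loci, toy_manifest, seed=9,
                                      n_boot=2, n_draws=4)
        assert (best.n_pls, best.n_retain) in {(2, 20), (3, 40)}
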