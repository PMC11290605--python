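"""Source-item MPT: category probabilities, likelihood, estimators, G²."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sourcemem.mpt_model import (MPTParams, category_probabilities,
                                 category_probabilities_array, fit_mle,
                                 g_squared, log_likelihood, moment_estimator,
                                 EstimationError)
from sourcemem.task_data import FrequencyTable

unit = st.floats(0.0, 1.0, allow_nan=False)
interior = st.floats(0.05, 0.95)
params_strategy = st.builds(MPTParams, unit, unit, unit, unit, unit, unit)
interior_params = st.builds(MPTParams, interior, interior, interior,
                            interior, interior, interior)


def brute_force_loglik(freq: FrequencyTable, params: MPTParams) -> float:
    """Independent oracle: plain Python loop over cells."""
    probs = category_probabilities(params)
    total = 0.0
    for i in range(3):
        for j in range(3):
            n = int(freq.counts[i, j])
            if n == 0:
                continue
            p = probs[i, j]
            if p == 0.0:
                return -math.inf
            total += n * math.log(p)
    return total


class TestCategoryProbabilities:
    def test_hand_derived_up_tree(self):
        p = MPTParams(s_up=0.5, s_down=0.5, i_up=0.4, i_down=0.4, o=0.2, g=0.6)
        row = category_probabilities(p)[0]
        assert row == pytest.approx([0.656, 0.104, 0.240], abs=1e-12)

    def test_no_memory_no_guessing_forces_new(self):
        p = MPTParams(0, 0, 0, 0, 0, 0.5)
        probs = category_probabilities(p)
        assert probs[:, 2] == pytest.approx([1, 1, 1])

    def test_certain_recollection(self):
        p = MPTParams(s_up=1.0, s_down=0.3, i_up=0.9, i_down=0.1, o=0.7, g=0.2)
        assert category_probabilities(p)[0, 0] == 1.0

    def test_new_tree_is_pure_guessing(self):
        p = MPTParams(0.5, 0.5, 0.5, 0.5, o=0.3, g=0.7)
        assert category_probabilities(p)[2] == pytest.approx([0.21, 0.09, 0.70])

    @given(params_strategy)
    def test_rows_sum_to_one(self, p):
        probs = category_probabilities(p)
        assert probs.sum(axis=1) == pytest.approx([1, 1, 1], abs=1e-12)
        assert (probs >= 0).all() and (probs <= 1).all()

    @given(interior_params, st.floats(0.01, 0.2))
    def test_increasing_o_decreases_p_new_in_every_tree(self, p, eps):
        if p.o + eps > 1:
            eps = 1 - p.o
        p2 = MPTParams(p.s_up, p.s_down, p.i_up, p.i_down, p.o + eps, p.g)
        assert (category_probabilities(p2)[:, 2]
                < category_probabilities(p)[:, 2]).all()

    def test_vectorised_matches_scalar(self, rng):
        theta = rng.random((20, 6))
        batch = category_probabilities_array(theta)
        for k in range(20):
            single = category_probabilities(MPTParams.from_array(theta[k]))
            assert batch[k] == pytest.approx(single)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            MPTParams(1.2, 0, 0, 0, 0, 0)


class TestLogLikelihood:
    def test_empty_table_gives_zero(self):
        ft = FrequencyTable(np.zeros((3, 3)))
        p = MPTParams(0.3, 0.3, 0.3, 0.3, 0.3, 0.3)
        assert log_likelihood(ft, p) == 0.0

    def test_certain_event_gives_zero(self):
        counts = np.zeros((3, 3)); counts[0, 0] = 1
        p = MPTParams(1.0, 0.5, 0.5, 0.5, 0.5, 0.5)
        assert log_likelihood(FrequencyTable(counts), p) == 0.0

    def test_impossible_count_gives_neg_inf(self):
        counts = np.zeros((3, 3)); counts[2, 0] = 1
        p = MPTParams(0.5, 0.5, 0.5, 0.5, o=0.0, g=0.5)
        assert log_likelihood(FrequencyTable(counts), p) == -np.inf

    @given(interior_params)
    def test_matches_brute_force_oracle(self, p):
        rng = np.random.default_rng(99)
        ft = FrequencyTable(rng.integers(0, 50, size=(3, 3)))
        assert log_likelihood(ft, p) == pytest.approx(brute_force_loglik(ft, p))


class TestMomentEstimator:
    def test_new_tree_inversion(self):
        ft = FrequencyTable([[10, 10, 10], [10, 10, 10], [12, 8, 80]])
        est = moment_estimator(ft).params
        assert est.o == pytest.approx(0.2)
        assert est.g == pytest.approx(0.6)

    def test_up_tree_inversion(self, exact_table):
        est = moment_estimator(exact_table)
        assert not est.clipped
        assert est.params.as_array() == pytest.approx(
            [0.5, 0.5, 0.4, 0.4, 0.2, 0.6], abs=1e-12)

    @given(interior_params)
    def test_round_trip_on_noiseless_counts(self, p):
        probs = category_probabilities(p)
        counts = probs * 1_000_000
        est = moment_estimator(FrequencyTable(np.round(counts)))
        assert est.params.as_array() == pytest.approx(p.as_array(), abs=1e-3)

    def test_degenerate_new_tree_raises(self):
        ft = FrequencyTable([[10, 10, 10], [10, 10, 10], [0, 0, 0]])
        with pytest.raises(EstimationError):
            moment_estimator(ft)

    def test_clipping_flagged(self):
        # old_down cell of the UP tree larger than consistent with the model
        ft = FrequencyTable([[10, 600, 10], [10, 10, 10], [10, 10, 500]])
        assert moment_estimator(ft).clipped


class TestMLE:
    def test_equals_moment_estimator_on_exact_table(self, exact_table):
        fit = fit_mle(exact_table, seed=0)
        me = moment_estimator(exact_table).params
        assert fit.params.as_array() == pytest.approx(me.as_array(), abs=1e-6)
        assert fit.g_squared <= 1e-6

    def test_equals_moment_estimator_on_noisy_table(self, rng):
        p = MPTParams(0.55, 0.45, 0.35, 0.5, 0.3, 0.55)
        probs = category_probabilities(p)
        counts = np.stack([rng.multinomial(800, probs[i]) for i in range(3)])
        ft = FrequencyTable(counts)
        fit = fit_mle(ft, seed=4)
        me = moment_estimator(ft).params
        assert fit.params.as_array() == pytest.approx(me.as_array(), abs=1e-6)

    def test_all_new_boundary(self):
        ft = FrequencyTable([[0, 0, 80], [0, 0, 80], [0, 0, 80]])
        fit = fit_mle(ft, seed=0)
        assert fit.params.o == pytest.approx(0.0, abs=1e-6)
        assert "o" in fit.boundary

    def test_report_records_starts_and_seed(self, exact_table):
        fit = fit_mle(exact_table, n_starts=5, seed=42)
        assert fit.n_starts == 5
        assert fit.seed == 42
        assert fit.converged


class TestGSquared:
    def test_zero_at_exact_expectation(self, exact_table):
        p = MPTParams(0.5, 0.5, 0.4, 0.4, 0.2, 0.6)
        assert g_squared(exact_table, p) == pytest.approx(0.0, abs=1e-9)

    @given(interior_params, interior_params)
    def test_matches_independent_recomputation(self, p_true, p_fit):
        probs = category_probabilities(p_true)
        ft = FrequencyTable(np.round(probs * 500))
        expected_probs = category_probabilities(p_fit)
        total = 0.0
        for i in range(3):
            row_n = ft.counts[i].sum()
            for j in range(3):
                obs = ft.counts[i, j]
                if obs > 0:
                    total += 2 * obs * math.log(obs / (expected_probs[i, j] * row_n))
        assert g_squared(ft, p_fit) == pytest.approx(total)
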