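"""Gibbs-sampler moves: conditional weights, M-H primitive, sampling
distributions, chain reproducibility, posterior aggregation, MAP rule, and
the exact-enumeration oracle."""

import math

import numpy as np
import pytest

from hdpclust.core import (
    ChainConfig,
    ExpressionMatrix,
    Hyperparameters,
    ObservationModel,
    init_state,
    validate_state,
)
from hdpclust.marginals import PredictiveQuery, dish_predictive, prior_predictive
from hdpclust.sampler import (
    ChainTrace,
    Snapshot,
    aggregate_posterior,
    dish_weights,
    exact_posterior_small,
    gibbs_sweep,
    map_assignment,
    mh_acceptance,
    mh_step,
    partition_frequencies,
    run_chain,
    sample_concentrations,
    sample_dish,
    sample_table,
    table_weights,
    total_variation,
)
from hdpclust.synthetic import gen_gaussian_clusters, worked_example


def _single_cell(value=0.0):
    return ExpressionMatrix(values=np.array([[value]]), gene_ids=("g",),
                            experiment_ids=("e",))


class TestTableWeights:
    def test_requires_unseated_customer(self, two_gene_instance):
        data, state, model, hyper = two_gene_instance
        with pytest.raises(ValueError, match="unseated"):
            table_weights(0, 0, state, data, model, hyper)

    def test_empty_restaurant_single_new_weight(self, std_model, unit_hyper):
        data = _single_cell(0.0)
        state = init_state(data, mode="each-own-table")
        state.unseat(0, 0, 0.0)
        tables, weights, new_w = table_weights(0, 0, state, data, std_model,
                                               unit_hyper)
        assert tables == [] and weights == []
        assert new_w == pytest.approx(
            unit_hyper.alpha0 * prior_predictive(0.0, std_model), abs=1e-12)

    def test_occupied_weight_is_count_times_predictive(self, two_gene_instance):
        data, state, model, hyper = two_gene_instance
        state.unseat(0, 0, 0.0)  # leaves table with g12=1 on dish 1
        tables, weights, _ = table_weights(0, 0, state, data, model, hyper)
        assert len(tables) == 1
        f = dish_predictive(PredictiveQuery(0.0, (1.0,), model))
        assert weights[0] == pytest.approx(1 * f, abs=1e-12)

    def test_new_weight_mixes_all_served_dishes(self, two_gene_instance):
        data, state, model, hyper = two_gene_instance
        state.unseat(0, 0, 0.0)
        _, _, new_w = table_weights(0, 0, state, data, model, hyper)
        # after removal: dish 1 holds {1}, dish 2 holds {-1, 2}; D = 3 tables
        f1 = dish_predictive(PredictiveQuery(0.0, (1.0,), model))
        f2 = dish_predictive(PredictiveQuery(0.0, (-1.0, 2.0), model))
        p0 = prior_predictive(0.0, model)
        expected = 1.0 * (1 * f1 + 2 * f2 + 1.0 * p0) / (3 + 1.0)
        assert new_w == pytest.approx(expected, abs=1e-12)


class TestDishWeights:
    def test_requires_occupied_table(self, two_gene_instance):
        data, state, model, hyper = two_gene_instance
        with pytest.raises(ValueError, match="unoccupied"):
            dish_weights(0, 99, state, data, model, hyper)

    def test_weights_for_detached_singleton_table(self, two_gene_instance):
        data, state, model, hyper = two_gene_instance
        t = state.phi[(0, 0)]
        state.detach_table_from_dish(0, t, 0.0, 1)
        dishes, weights, new_w = dish_weights(0, t, state, data, model, hyper)
        # remaining: dish 1 holds {1} on 1 table, dish 2 holds {-1,2} on 2 tables
        f1 = dish_predictive(PredictiveQuery(0.0, (1.0,), model))
        f2 = dish_predictive(PredictiveQuery(0.0, (-1.0, 2.0), model))
        assert weights == pytest.approx([1 * f1, 2 * f2], abs=1e-12)
        assert new_w == pytest.approx(prior_predictive(0.0, model), abs=1e-12)

    def test_sole_dish_conditional_is_prior_of_table_data(self, std_model,
                                                          unit_hyper):
        # one row, one table holding everything; after detaching, the dish
        # retains no data, so its conditional equals the prior predictive
        data = ExpressionMatrix(values=np.array([[0.5, -0.5]]),
                                gene_ids=("a", "b"), experiment_ids=("e",))
        state = init_state(data, mode="single-table")
        t = state.tables_in_row(0)[0]
        state.detach_table_from_dish(0, t, 0.0, 2)
        dishes, weights, new_w = dish_weights(0, t, state, data, std_model,
                                              unit_hyper)
        assert dishes == []  # the only dish was garbage-collected
        assert new_w > 0


class TestMHStep:
    @pytest.mark.parametrize("cand,cur,expected", [
        (0.1483, 0.22971, 0.1483 / 0.22971),
        (0.282095, 0.45942, 0.282095 / 0.45942),
        (2.0, 1.0, 1.0),
        (1.0, 0.0, 1.0),
    ])
    def test_acceptance_probability(self, cand, cur, expected):
        assert mh_acceptance(cand, cur) == pytest.approx(expected, abs=1e-9)

    def test_always_accepts_uphill(self):
        rng = np.random.default_rng(0)
        assert all(mh_step(2.0, 1.0, rng) for _ in range(100))

    def test_empirical_acceptance_rate(self):
        rng = np.random.default_rng(1)
        n = 20_000
        accepted = sum(mh_step(0.3, 1.0, rng) for _ in range(n))
        se = math.sqrt(0.3 * 0.7 / n)
        assert abs(accepted / n - 0.3) < 4 * se


class TestSampleTable:
    def test_single_customer_reseats_deterministically(self, std_model,
                                                       unit_hyper):
        data = _single_cell(1.0)
        state = init_state(data, mode="each-own-table")
        rng = np.random.default_rng(0)
        sample_table(0, 0, state, data, std_model, unit_hyper, rng)
        assert state.total_tables == 1 and state.n_dishes == 1
        assert validate_state(state, data) == []

    def test_small_alpha0_shares_table(self, std_model):
        # two identical observations in one row: as alpha0 -> 0 they share
        data = ExpressionMatrix(values=np.array([[1.0, 1.0]]),
                                gene_ids=("a", "b"), experiment_ids=("e",))
        hyper = Hyperparameters(alpha0=1e-6, alpha1=1.0)
        rng = np.random.default_rng(2)
        together = 0
        n = 2000
        for _ in range(n):
            state = init_state(data, mode="each-own-table")
            sample_table(0, 1, state, data, std_model, hyper, rng)
            together += state.total_tables == 1
        assert together / n > 0.999

    def test_direct_draw_matches_weights(self, two_gene_instance):
        data, _, model, hyper = two_gene_instance
        rng = np.random.default_rng(7)
        # weight vector computed once on the frozen post-removal state
        probe = init_state(data, mode="each-own-table")
        probe.unseat(0, 0, 0.0)
        tables, weights, new_w = table_weights(0, 0, probe, data, model, hyper)
        w = np.array(weights + [new_w])
        p = w / w.sum()
        n = 30_000
        counts = np.zeros(len(w))
        for _ in range(n):
            state = init_state(data, mode="each-own-table")
            sample_table(0, 0, state, data, model, hyper, rng)
            t = state.phi[(0, 0)]
            counts[tables.index(t) if t in tables else -1] += 1
        freq = counts / n
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(freq - p) < 4 * se + 1e-9)


class TestSampleDish:
    def test_sole_table_always_gets_fresh_dish(self, std_model):
        # a table holding ALL of its dish's data: on detach the dish is
        # garbage-collected, leaving "new dish" as the only option, and the
        # old label is never reused
        data = ExpressionMatrix(values=np.array([[0.4, 0.6]]),
                                gene_ids=("a", "b"), experiment_ids=("e",))
        hyper = Hyperparameters(alpha0=1.0, alpha1=1.0)
        rng = np.random.default_rng(3)
        for _ in range(50):
            state = init_state(data, mode="single-table")
            t = state.tables_in_row(0)[0]
            k_before = state.lam[(0, t)]
            sample_dish(0, t, state, data, std_model, hyper, rng)
            assert state.lam[(0, t)] != k_before
            assert validate_state(state, data) == []

    def test_two_point_support_frequencies(self, std_model):
        # two rows share one dish; resampling the second row's table chooses
        # between "keep the shared dish" (weight D_k * f(G|other data)) and
        # "fresh dish" (weight alpha1 * m(G)); empirical frequencies must
        # match the normalized weights
        data = ExpressionMatrix(values=np.array([[0.2], [0.5]]),
                                gene_ids=("g",), experiment_ids=("e1", "e2"))
        hyper = Hyperparameters(alpha0=1.0, alpha1=1.0)
        probe = init_state(data, mode="single-table")
        tb = probe.tables_in_row(1)[0]
        probe.detach_table_from_dish(1, tb, 0.5, 1)
        dishes, weights, new_w = dish_weights(1, tb, probe, data, std_model,
                                              hyper)
        assert len(dishes) == 1
        p_keep = weights[0] / (weights[0] + new_w)
        rng = np.random.default_rng(9)
        n = 20_000
        kept = 0
        for _ in range(n):
            state = init_state(data, mode="single-table")
            t = state.tables_in_row(1)[0]
            k_before = state.lam[(1, t)]
            sample_dish(1, t, state, data, std_model, hyper, rng)
            kept += state.lam[(1, t)] == k_before
        se = math.sqrt(p_keep * (1 - p_keep) / n)
        assert abs(kept / n - p_keep) < 4 * se

    def test_small_alpha1_merges_dishes(self, std_model):
        # two rows with identical single observations: as alpha1 -> 0 the two
        # tables end up sharing one dish almost surely
        data = ExpressionMatrix(values=np.array([[0.0], [0.0]]),
                                gene_ids=("g",), experiment_ids=("e1", "e2"))
        hyper = Hyperparameters(alpha0=1.0, alpha1=1e-6)
        rng = np.random.default_rng(4)
        merged = 0
        n = 2000
        for _ in range(n):
            state = init_state(data, mode="each-own-table")
            for j in (0, 1):
                t = state.tables_in_row(j)[0]
                sample_dish(j, t, state, data, std_model, hyper, rng)
            merged += state.n_dishes == 1
        assert merged / n > 0.999


class TestSampleConcentrations:
    def test_disabled_is_identity(self):
        hyper = Hyperparameters(alpha0=2.0, alpha1=3.0)
        rng = np.random.default_rng(0)
        assert sample_concentrations(hyper, rng) is hyper

    def test_gamma_mean_and_positivity(self):
        hyper = Hyperparameters(gamma_shape=2.0, gamma_rate=4.0,
                                resample_concentrations=True)
        rng = np.random.default_rng(5)
        draws = np.array([sample_concentrations(hyper, rng).alpha0
                          for _ in range(20_000)])
        assert np.all(draws > 0)
        # shape-rate convention: mean = a/b = 0.5
        assert draws.mean() == pytest.approx(0.5, abs=4 * draws.std()
                                             / math.sqrt(draws.size))


class TestGibbsSweepAndChain:
    def test_sweep_preserves_invariants(self, two_gene_instance):
        data, state, model, hyper = two_gene_instance
        rng = np.random.default_rng(6)
        for _ in range(20):
            hyper = gibbs_sweep(state, data, model, hyper, rng)
            assert validate_state(state, data) == []

    def test_single_cell_sweep_trivial(self, std_model, unit_hyper):
        data = _single_cell(2.0)
        state = init_state(data, mode="single-table")
        rng = np.random.default_rng(0)
        gibbs_sweep(state, data, std_model, unit_hyper, rng)
        assert state.total_tables == 1 and state.n_dishes == 1

    def test_chain_reproducible_under_seed(self, two_gene_instance):
        data, _, model, hyper = two_gene_instance
        cfg = ChainConfig(burnin=10, samples=25, seed=42)
        t1 = run_chain(data, model, hyper, cfg)
        t2 = run_chain(data, model, hyper, cfg)
        assert len(t1) == len(t2) == 25
        for a, b in zip(t1.snapshots, t2.snapshots):
            assert np.array_equal(a.z, b.z) and np.array_equal(a.tables, b.tables)

    def test_trace_length_respects_thinning(self, two_gene_instance):
        data, _, model, hyper = two_gene_instance
        cfg = ChainConfig(burnin=5, samples=7, thinning=3, seed=0)
        assert len(run_chain(data, model, hyper, cfg)) == 7

    def test_recovers_three_separated_clusters(self):
        data, truth = gen_gaussian_clusters(3, [8, 8, 8], [-5.0, 0.0, 5.0],
                                            0.5, 3, seed=0)
        trace = run_chain(data, ObservationModel(), Hyperparameters(),
                          ChainConfig(burnin=50, samples=100, seed=1))
        counts = np.bincount(trace.dish_counts())
        assert counts.argmax() == 3


def _toy_trace(z_list):
    snaps = [Snapshot(z=np.asarray(z), tables=np.ones_like(np.asarray(z)),
                      alpha0=1.0, alpha1=1.0) for z in z_list]
    return ChainTrace(snapshots=snaps, config=ChainConfig(burnin=0, samples=len(snaps)))


class TestAggregateAndMAP:
    def test_identical_snapshots_give_hard_posterior(self):
        trace = _toy_trace([[[1, 2], [1, 2]]] * 5)
        post = aggregate_posterior(trace)
        assert np.all(np.isin(post.cell_probs, [0.0, 1.0]))

    def test_alternating_snapshots_give_half(self):
        trace = _toy_trace([[[1, 1], [1, 1]], [[1, 2], [1, 2]]] * 10)
        post = aggregate_posterior(trace)
        assert post.cell_probs[0, 1, 0] == pytest.approx(0.5)
        assert post.cell_probs[0, 1, 1] == pytest.approx(0.5)

    def test_hand_counted_three_snapshot_tally(self):
        trace = _toy_trace([[[1, 1]], [[1, 2]], [[1, 2]]])
        post = aggregate_posterior(trace)
        assert post.cell_probs[0, 1, 0] == pytest.approx(1 / 3)
        assert post.cell_probs[0, 1, 1] == pytest.approx(2 / 3)

    def test_map_sums_across_experiments(self):
        # per-row distributions (0.6, 0.4) and (0.3, 0.7): sums 0.9 vs 1.1
        trace = _toy_trace(
            [[[1], [2]]] * 3 + [[[1], [1]]] * 3 + [[[2], [2]]] * 4)
        post = aggregate_posterior(trace)
        # row 0: P(1)=0.6, row 1: P(1)=0.3 -> label 2 wins 1.1 vs 0.9
        assert post.gene_scores[0, 0] == pytest.approx(0.9)
        assert post.gene_scores[0, 1] == pytest.approx(1.1)
        part = map_assignment(post)
        assert part.n_clusters() == 1  # single gene
        assert part[post.gene_ids[0]] == 1  # renumbered by first appearance

    def test_map_tie_breaks_to_smaller_label(self):
        trace = _toy_trace([[[1, 1]], [[1, 2]]])  # gene 2: 0.5 / 0.5
        part = map_assignment(aggregate_posterior(trace))
        assert part["g1"] == part["g2"] == 1

    def test_unanimous_posterior_returns_that_label(self):
        trace = _toy_trace([[[1, 2, 2]]] * 4)
        part = map_assignment(aggregate_posterior(trace))
        assert part["g1"] == 1 and part["g2"] == part["g3"] == 2

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            aggregate_posterior(ChainTrace(snapshots=[],
                                           config=ChainConfig()))


class TestExactPosterior:
    def test_single_cell_certain(self, std_model, unit_hyper):
        post = exact_posterior_small(_single_cell(0.5), std_model, unit_hyper)
        assert post == {(1,): pytest.approx(1.0)}

    def test_normalizes(self, two_gene_instance):
        data, _, model, hyper = two_gene_instance
        post = exact_posterior_small(data, model, hyper)
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-10)

    def test_equal_observations_more_likely_together(self, std_model,
                                                     unit_hyper):
        close = ExpressionMatrix(values=np.array([[1.0, 1.0]]),
                                 gene_ids=("a", "b"), experiment_ids=("e",))
        far = ExpressionMatrix(values=np.array([[-3.0, 3.0]]),
                               gene_ids=("a", "b"), experiment_ids=("e",))
        p_close = exact_posterior_small(close, std_model, unit_hyper)[(1, 1)]
        p_far = exact_posterior_small(far, std_model, unit_hyper)[(1, 1)]
        assert p_close > p_far

    def test_rejects_large_instance(self, std_model, unit_hyper):
        data = ExpressionMatrix(values=np.zeros((3, 3)),
                                gene_ids=("a", "b", "c"),
                                experiment_ids=("x", "y", "z"))
        with pytest.raises(ValueError, match="too large"):
            exact_posterior_small(data, std_model, unit_hyper)


class TestTotalVariation:
    def test_disjoint_supports(self):
        assert total_variation({"a": 1.0}, {"b": 1.0}) == pytest.approx(1.0)

    def test_identical(self):
        p = {"a": 0.3, "b": 0.7}
        assert total_variation(p, dict(p)) == 0.0
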