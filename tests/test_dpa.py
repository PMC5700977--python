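"""Doubly-preferential attachment model: probabilities, growth, calibration."""

import copy
import math

import numpy as np
import pytest
from scipy.optimize import curve_fit

from ccdyn import (
    DPAParams,
    adjusted_initial_edges,
    calibrate_C,
    edge_probability,
    expected_new_edges,
    fit_exponential,
    initial_graph,
    simulate,
    simulate_step,
)


class TestFitExponential:
    def test_exact_exponential_recovered(self):
        k = np.arange(1, 101)
        y = 50 * np.exp(0.02 * k)
        A, B, r2 = fit_exponential(y)
        assert A == pytest.approx(50, rel=1e-9)
        assert B == pytest.approx(0.02, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_constant_counts_give_zero_rate(self):
        A, B, r2 = fit_exponential([7, 7, 7, 7, 7])
        assert B == pytest.approx(0.0, abs=1e-12)
        assert A == pytest.approx(7.0)

    def test_matches_independent_log_scale_regression(self):
        """Multiplicative noise: agree with a generic nonlinear least-squares
        fit of the same log-scale objective to 6 digits."""
        rng = np.random.default_rng(0)
        k = np.arange(1, 201, dtype=float)
        y = 30 * np.exp(0.01 * k) * np.exp(rng.normal(0, 0.05, size=200))
        A, B, _ = fit_exponential(y, k)
        popt, _ = curve_fit(
            lambda kk, lnA, b: lnA + b * kk, k, np.log(y), p0=(0.0, 0.0)
        )
        assert A == pytest.approx(math.exp(popt[0]), rel=1e-6)
        assert B == pytest.approx(popt[1], rel=1e-6)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            fit_exponential([1, 2])
        with pytest.raises(ValueError):
            fit_exponential([1, 0, 2])


class TestEdgeProbability:
    def test_zero_degree_pair_without_constant(self):
        p = DPAParams(C=0.0)
        assert edge_probability(0, 0, p) == 0.0

    def test_saturated_degrees_give_exactly_B(self):
        p = DPAParams(C=0.0)
        assert edge_probability(p.N - 1, p.N - 1, p) == pytest.approx(p.B)

    def test_direct_arithmetic(self):
        p = DPAParams(N=1015, B=0.014, C=7.6e-7)
        expected = 0.014 / 2028 * 15 + 7.6e-7
        assert edge_probability(10, 5, p) == pytest.approx(expected, rel=1e-12)

    def test_negative_degree_rejected(self):
        with pytest.raises(ValueError):
            edge_probability(-1, 0, DPAParams())


class TestAdjustedInitialEdges:
    def test_no_constant_term(self):
        assert adjusted_initial_edges(46.37, 0.014, 0.0, 1015) == 46

    def test_reference_parameters(self):
        # binom(1015,2) = 514605; 46.37 - 514605*(7.6e-7/0.014) + 0.5 = 18.93
        assert adjusted_initial_edges(46.37, 0.014, 7.6e-7, 1015) == 18

    def test_floored_at_zero(self):
        assert adjusted_initial_edges(1.0, 0.014, 1e-3, 1015) == 0


class TestInitialGraph:
    def test_empty_and_complete(self):
        assert initial_graph(0, 10, 20, seed=1).n_edges == 0
        full = initial_graph(45, 10, 20, seed=1)
        assert full.n_edges == 45
        nodes = {x for e in full.edges() for x in e}
        assert len(nodes) == 10

    @pytest.mark.parametrize("m,D", [(1, 2), (5, 5), (17, 12)])
    def test_edge_count_exact(self, m, D):
        state = initial_graph(m, D, 30, seed=3)
        assert state.n_edges == m == len(state.edges())

    def test_too_many_edges_rejected(self):
        with pytest.raises(ValueError):
            initial_graph(46, 10, 20, seed=0)


class TestSimulateStep:
    def test_empty_graph_stays_empty_without_constant(self):
        params = DPAParams(N=20, C=0.0, D=5, steps=1)
        state = initial_graph(0, 5, 20, seed=0)
        rng = np.random.default_rng(0)
        for _ in range(50):
            simulate_step(state, params, rng)
        assert state.n_edges == 0

    def test_mean_additions_match_exhaustive_expectation(self):
        """Per-step additions on N=6 match the sum of per-pair inclusion
        probabilities from exhaustive enumeration, within 3 standard errors
        over 10^4 Monte-Carlo repetitions of the same step."""
        N = 6
        params = DPAParams(N=N, A=3.0, B=0.3, C=0.02, D=N, steps=1)
        base = initial_graph(3, N, N, seed=5)
        iu, iv = np.triu_indices(N, k=1)
        idx = base.present.copy()
        p_pair = params.B / (2 * (N - 1)) * (base.deg[iu] + base.deg[iv]) + params.C
        p_pair = np.clip(p_pair, 0, 1)
        p_pair[idx] = 0.0
        expect = p_pair.sum()
        var = (p_pair * (1 - p_pair)).sum()

        reps = 10_000
        rng = np.random.default_rng(42)
        total = 0
        for _ in range(reps):
            state = copy.deepcopy(base)
            simulate_step(state, params, rng)
            total += state.new_edge_log[-1]
        mean = total / reps
        se = math.sqrt(var / reps)
        assert abs(mean - expect) <= 3 * se

    def test_isolated_and_degree_bookkeeping_small_run(self):
        """Re-derive new/new-isolated counts from logged edge-set snapshots
        and check degree consistency after every step."""
        N = 40
        params = DPAParams(N=N, A=4.0, B=0.2, C=0.004, D=10, steps=1)
        state = initial_graph(4, 10, N, seed=9)
        rng = np.random.default_rng(9)
        prev_edges = state.edges()
        for _ in range(25):
            simulate_step(state, params, rng)
            edges = state.edges()
            assert edges >= prev_edges  # monotone growth
            assert int(state.deg.sum()) == 2 * state.n_edges
            new = edges - prev_edges
            assert len(new) == state.new_edge_log[-1]
            # brute-force isolation against the full post-step graph
            deg = {}
            for u, v in edges:
                deg[u] = deg.get(u, 0) + 1
                deg[v] = deg.get(v, 0) + 1
            iso = sum(1 for u, v in new if deg[u] == 1 and deg[v] == 1)
            assert iso == state.new_isolated_log[-1]
            prev_edges = edges


class TestExpectedNewEdges:
    def test_path_graph_closed_form(self):
        # path a-b-c on N=4: exhaustive pair sum over all 6 pairs = 2B
        params = DPAParams(N=4, B=0.1, C=0.0, D=4, steps=1)
        state = initial_graph(0, 4, 4, seed=0)
        state.add_edges(np.array([0, 1]), np.array([1, 2]))
        assert expected_new_edges(state, params) == pytest.approx(0.2)

    def test_empty_and_complete(self):
        params = DPAParams(N=8, B=0.05, C=0.0, D=8, steps=1)
        empty = initial_graph(0, 8, 8, seed=0)
        assert expected_new_edges(empty, params) == 0.0
        full = initial_graph(28, 8, 8, seed=0)
        assert expected_new_edges(full, params) == pytest.approx(0.05 * 28)


class TestSimulate:
    def test_identical_seeds_identical_curves(self):
        params = DPAParams(N=60, A=5.0, B=0.05, C=1e-4, D=12, steps=30, seed=7)
        r1 = simulate(params, runs=2)
        r2 = simulate(params, runs=2)
        assert np.array_equal(r1.edge_counts, r2.edge_counts)
        assert np.array_equal(r1.new_isolated, r2.new_isolated)

    def test_growth_factor_close_to_one_plus_B(self):
        """With C=0 and a nonempty start the per-step growth factor of the
        mean edge count is ~1+B while the graph is far from dense."""
        params = DPAParams(N=300, A=40.0, B=0.05, C=0.0, D=40, steps=40, seed=3)
        res = simulate(params, runs=20)
        counts = res.mean_edge_count
        factors = counts[1:] / counts[:-1]
        assert abs(factors.mean() - 1.05) < 0.01

    def test_edge_curve_tracks_exponential_at_reference_scale(self):
        """With C=0 at N=1015 the mean edge count follows 46*exp(0.014k) to
        within a few percent early on; by step 418 it falls ~20% short,
        because the expected-growth identity B|E| sums over all vertex
        pairs while the simulation can only add currently absent ones."""
        params = DPAParams(N=1015, A=46.37, B=0.014, C=0.0, D=60,
                           steps=418, seed=3)
        res = simulate(params, runs=2)
        k = np.arange(1, 419)
        ratio = res.mean_edge_count / (46 * np.exp(0.014 * k))
        assert np.all(ratio <= 1.05)
        assert np.all(ratio >= 0.75)
        assert ratio[:50].min() >= 0.85  # early steps track closely

    def test_mean_curves_lie_within_run_envelope(self):
        params = DPAParams(N=80, A=6.0, B=0.08, C=5e-5, D=15, steps=25, seed=1)
        res = simulate(params, runs=5)
        assert np.all(res.mean_edge_count >= res.edge_counts.min(axis=0))
        assert np.all(res.mean_edge_count <= res.edge_counts.max(axis=0))
        frame = res.to_frame()
        assert len(frame) == 25
        assert frame["cumulative_isolated"].is_monotonic_increasing


class TestCalibrateC:
    def test_on_target_returns_unchanged(self):
        params = DPAParams(N=300, A=8.0, B=0.05, C=3e-6, D=15, steps=80, seed=11)
        total = simulate(params, runs=8).final_isolated_total
        assert total > 0
        got = calibrate_C(params, total, runs=8)
        assert got == params.C  # first iteration ratio is 1 within tolerance

    def test_doubling_target_roughly_doubles_C(self):
        params = DPAParams(N=300, A=8.0, B=0.05, C=3e-6, D=15, steps=80, seed=13)
        base = simulate(params, runs=10).final_isolated_total
        c1 = calibrate_C(params, base, runs=10)
        c2 = calibrate_C(params, 2 * base, runs=10)
        assert c2 / c1 == pytest.approx(2.0, rel=0.2)

    def test_rejects_bad_inputs(self):
        params = DPAParams(N=50, A=4.0, B=0.05, C=0.0, D=10, steps=10)
        with pytest.raises(ValueError):
            calibrate_C(params, 10.0)
        with pytest.raises(ValueError):
            calibrate_C(DPAParams(N=50, A=4.0, B=0.05, C=1e-4, D=10, steps=10), -1)


def test_params_validation():
    with pytest.raises(ValueError):
        DPAParams(B=0.0)
    with pytest.raises(ValueError):
        DPAParams(C=-1e-9)
    with pytest.raises(ValueError):
        DPAParams(D=1)
    with pytest.raises(ValueError):
        DPAParams(steps=0)
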