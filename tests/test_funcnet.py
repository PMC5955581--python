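"""Partial correlations, cross-correlogram lags and graph assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from v1motifs import funcnet as fn
from v1motifs import preprocessing as pp
from v1motifs import synthetic
from v1motifs.preprocessing import DffTraces
from v1motifs.synthetic import SimConfig, make_schedule, simulate_population


def residual_regression_partial(x, y, controls):
    """Independent oracle: correlate OLS residuals of x and y on the controls."""
    Z = np.column_stack([np.ones(len(x))] + list(controls))
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    return np.corrcoef(rx, ry)[0, 1]


class TestPartialCorr:
    def test_orthogonal_controls_reduce_to_plain_r(self):
        # controls built exactly orthogonal to x and y
        rng = np.random.default_rng(0)
        T = 128
        base = rng.standard_normal((2, T))
        x, y = base
        # project each control onto the orthogonal complement of span{1, x, y}
        Q, _ = np.linalg.qr(np.column_stack([np.ones(T), x, y]))
        controls = []
        for _ in range(3):
            z = rng.standard_normal(T)
            controls.append(z - Q @ (Q.T @ z))
        got = fn.partial_corr(x, y, controls)
        assert got == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_residual_regression_oracle(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(50, 500))
        x, y, *controls = rng.standard_normal((5, T))
        got = fn.partial_corr(x, y, controls)
        want = residual_regression_partial(x, y, controls)
        assert got == pytest.approx(want, abs=1e-8)

    def test_control_equal_to_x_is_degenerate(self):
        rng = np.random.default_rng(1)
        x, y, z2, z3 = rng.standard_normal((4, 100))
        with pytest.raises(fn.DegenerateInputError):
            fn.partial_corr(x, y, [x, z2, z3])

    def test_short_or_degenerate_inputs_raise(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            fn.partial_corr(np.ones(5), np.ones(5), [np.ones(5)] * 3)
        x, y, z1, z2 = rng.standard_normal((4, 50))
        with pytest.raises(ValueError):
            fn.partial_corr(x, y, [z1, z2, np.zeros(50)])


class TestBlockPartialMatrix:
    def test_symmetric_and_matches_per_pair_oracle(self, small_dff, small_schedule):
        P = fn.block_partial_matrix(small_dff, small_schedule)
        assert np.allclose(P, P.T, equal_nan=True)
        X = fn._blocked_traces(small_dff, small_schedule, "all")
        B, n = len(X), small_dff.n_neurons
        rng = np.random.default_rng(0)
        for i, j in [(0, 1), (2, 9), (5, 14)]:
            vals = []
            for b in range(B):
                others = [b2 for b2 in range(B) if b2 != b]
                mi = np.mean([X[b2][i] for b2 in others], axis=0)
                mj = np.mean([X[b2][j] for b2 in others], axis=0)
                pop = np.mean([X[b][k] for k in range(n) if k not in (i, j)], axis=0)
                vals.append(fn.partial_corr(X[b][i], X[b][j], [mi, mj, pop]))
            assert P[i, j] == pytest.approx(np.mean(vals), abs=1e-10)

    def test_permutation_equivariance(self, small_dff, small_schedule):
        P = fn.block_partial_matrix(small_dff, small_schedule)
        rng = np.random.default_rng(4)
        perm = rng.permutation(small_dff.n_neurons)
        dff_p = DffTraces(small_dff.dff[perm], small_dff.baseline_f0[perm],
                          small_dff.frame_rate_hz)
        P_p = fn.block_partial_matrix(dff_p, small_schedule)
        np.testing.assert_allclose(P_p, P[np.ix_(perm, perm)], atol=1e-10)

    def test_population_control_absorbs_shared_latent(self):
        # Neurons driven only by a moderate shared latent (no coupling):
        # the within-block population mean is then a linear proxy for the
        # latent and partialing it out should shrink pair correlations far
        # below the plain ones.  (At very strong modulation the softplus
        # nonlinearity distorts each neuron's latent response differently
        # and a single linear control cannot cancel it exactly.)
        sch = make_schedule(3, 6, 2, 2.0, 1.0, 20.0, seed=0)
        cfg = SimConfig(
            n_neurons=50, tuned_fraction=0.0, conn_base_prob=0.0,
            weight_scale=0.0, latent_strength=3.0, n_latent_factors=0,
            latent_factor_strength=0.0, baseline_rate_hz=(1.0, 1.0),
        )
        _, rec = simulate_population(cfg, sch, seed=3)
        dff = pp.preprocess(rec)
        P = fn.block_partial_matrix(dff, sch)
        X = fn._blocked_traces(dff, sch, "all")
        plain = np.mean([np.corrcoef(Xb) for Xb in X], axis=0)
        iu, ju = np.triu_indices(50, k=1)
        assert np.abs(P[iu, ju]).mean() < np.abs(plain[iu, ju]).mean()
        assert np.abs(P[iu, ju]).mean() < 0.1

    def test_private_shared_noise_survives_controls(self):
        # noise shared by just two neurons is invisible to the three controls
        sch = make_schedule(2, 4, 1, 2.0, 1.0, 20.0, seed=0)
        T = sch.n_frames
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            traces = rng.standard_normal((10, T))
            private = rng.standard_normal(T)
            traces[0] += 0.8 * private
            traces[1] += 0.8 * private
            dff = DffTraces(traces, np.ones((10, T)), 20.0)
            P = fn.block_partial_matrix(dff, sch)
            hits += P[0, 1] > 0
        assert hits >= 19

    def test_too_few_blocks_raises(self, small_dff):
        sch1 = make_schedule(1, 8, 2, 2.0, 1.5, 20.0, seed=7)
        with pytest.raises(ValueError):
            fn.block_partial_matrix(small_dff, sch1)


class TestEdgeLag:
    def test_constructed_shift_recovered(self):
        rng = np.random.default_rng(0)
        xb = [rng.standard_normal(400) for _ in range(3)]
        for k in [1, 4, 10]:
            yb = [np.roll(x, k) for x in xb]
            t_max, direction = fn.edge_lag(xb, yb, frame_rate_hz=30.0)
            assert (t_max, direction) == (k, "x->y")
            t_rev, direction_rev = fn.edge_lag(yb, xb, frame_rate_hz=30.0)
            assert (t_rev, direction_rev) == (-k, "y->x")

    def test_identical_traces_bidirectional(self):
        rng = np.random.default_rng(1)
        xb = [rng.standard_normal(300) for _ in range(2)]
        assert fn.edge_lag(xb, xb, 30.0) == (0, "bidirectional")

    def test_lag_beyond_cutoff_is_no_edge(self):
        rng = np.random.default_rng(2)
        xb = [rng.standard_normal(500) for _ in range(3)]
        yb = [np.roll(x, 20) for x in xb]  # 20 frames > 15-frame cutoff at 30 Hz
        t_max, direction = fn.edge_lag(xb, yb, 30.0)
        assert direction == "none" and abs(t_max) > 15

    def test_zero_variance_blocks_excluded(self):
        rng = np.random.default_rng(3)
        xb = [np.zeros(300), rng.standard_normal(300)]
        yb = [np.zeros(300), np.roll(xb[1], 2)]
        assert fn.edge_lag(xb, yb, 30.0) == (2, "x->y")
        assert fn.edge_lag([np.zeros(300)], [np.zeros(300)], 30.0) == (0, "none")

    def test_batch_decisions_match_single_pair(self, small_dff, small_schedule):
        stack, valid = fn.cross_correlograms(small_dff, small_schedule)
        t_max, has_edge = fn.lag_decisions(stack, valid, small_dff.frame_rate_hz)
        X = fn._blocked_traces(small_dff, small_schedule, "all")
        fs = small_dff.frame_rate_hz
        for i, j in [(0, 1), (3, 7), (2, 12), (10, 15)]:
            xb = [Xb[i] for Xb in X]
            yb = [Xb[j] for Xb in X]
            t_single, direction = fn.edge_lag(xb, yb, fs)
            assert t_max[i, j] == t_single
            assert has_edge[i, j] == (direction != "none")


class TestBuildGraph:
    def _simple_inputs(self, n=6):
        rng = np.random.default_rng(0)
        P = rng.uniform(-0.5, 0.5, (n, n))
        P = (P + P.T) / 2
        np.fill_diagonal(P, 0.0)
        return P

    def test_all_bidirectional_gives_symmetric_w(self):
        P = self._simple_inputs()
        n = P.shape[0]
        t_max = np.zeros((n, n), dtype=int)
        has_edge = ~np.eye(n, dtype=bool)
        g = fn.build_graph(P, t_max, has_edge, 30.0)
        assert np.allclose(g.W, g.W.T)
        assert (g.W[~np.eye(n, dtype=bool)] != 0).all()

    def test_all_none_gives_empty_graph(self):
        P = self._simple_inputs()
        n = P.shape[0]
        g = fn.build_graph(P, np.zeros((n, n), int), np.zeros((n, n), bool), 30.0)
        assert not g.W.any()
        assert g.edge_table().empty

    def test_zero_edge_fraction_bookkeeping(self, small_dff, small_schedule):
        P = fn.block_partial_matrix(small_dff, small_schedule)
        stack, valid = fn.cross_correlograms(small_dff, small_schedule)
        t_max, has_edge = fn.lag_decisions(stack, valid, small_dff.frame_rate_hz)
        g = fn.build_graph(P, t_max, has_edge, small_dff.frame_rate_hz)
        n = small_dff.n_neurons
        iu, ju = np.triu_indices(n, k=1)
        no_edge_pairs = ((g.W[iu, ju] == 0) & (g.W[ju, iu] == 0)).mean()
        expected = (~has_edge[iu, ju] | np.isnan(P[iu, ju]) | (P[iu, ju] == 0)).mean()
        assert no_edge_pairs == pytest.approx(expected)

    def test_weight_floor_drops_weak_edges(self):
        P = self._simple_inputs()
        n = P.shape[0]
        t_max = np.zeros((n, n), dtype=int)
        has_edge = ~np.eye(n, dtype=bool)
        g = fn.build_graph(P, t_max, has_edge, 30.0, weight_floor=0.25)
        nz = np.abs(g.W[g.W != 0])
        assert (nz > 0.25).all()


class TestConditionCorrelations:
    def _make_tr(self, grating, dirs, grey):
        rows = [(k // 36, "grating", d, 0, 1) for k, d in enumerate(dirs)]
        rows += [(0, "grey", None, 0, 1)] * grey.shape[1]
        meta = pd.DataFrame(rows, columns=["block", "kind", "direction", "onset", "offset"])
        return pp.TrialResponses(np.hstack([grating, grey]), meta, 5000.0, 1500.0)

    def test_identical_vectors_give_unit_r(self):
        dirs = np.tile(np.arange(12) * 30.0, 30)  # 12 directions x 30 trials
        base = np.sin(np.arange(dirs.size))
        tr = self._make_tr(np.vstack([base, base]), dirs, np.ones((2, 20)))
        assert dirs.size == 360  # the full-regime response-vector length
        pc, _ = fn.condition_correlations(tr)
        assert pc.grating_r[0, 1] == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(0)
        dirs = np.tile(np.arange(12) * 30.0, 30)
        resp = rng.standard_normal((15, 360))
        tr = self._make_tr(resp, dirs, rng.standard_normal((15, 60)))
        pc, _ = fn.condition_correlations(tr)
        iu, ju = np.triu_indices(15, k=1)
        assert np.abs(pc.grating_r[iu, ju].mean()) < 0.05

    def test_class_summaries_and_delta_pref(self):
        rng = np.random.default_rng(1)
        dirs = np.tile(np.arange(12) * 30.0, 10)
        n = 8
        resp = rng.standard_normal((n, dirs.size))
        tr = self._make_tr(resp, dirs, rng.standard_normal((n, 20)))
        classes = np.array(["tuned"] * 4 + ["untuned"] * 4)
        prefs = np.array([0.0, 90.0, 180.0, 270.0] + [np.nan] * 4)
        pc, summary = fn.condition_correlations(tr, classes, prefs)
        for cond in ("grating", "grey"):
            assert set(summary[cond]) == {"within_tuned", "within_untuned", "between"}
        assert len(summary["delta_pref_bins_deg"]) == 6


class TestGraphStats:
    def test_fully_bidirectional_fraction_one(self):
        n = 10
        W = np.full((n, n), 0.3)
        np.fill_diagonal(W, 0.0)
        g = fn.FunctionalGraph(W, np.zeros((n, n), int), 30.0,
                               positions_um=np.random.default_rng(0).random((n, 2)) * 100)
        stats = fn.graph_stats(g, thresholds=np.array([0.0]))
        # every connected pair is bidirectional; ratio = 1 / q^2 with q = 1
        assert stats["bidirectional_ratio"][0] == pytest.approx(1.0)
        assert stats["connection_probability"][0] == pytest.approx(1.0)

    def test_random_directed_graph_ratio_near_one(self):
        # independent edge placement: observed bidirectional fraction ~ q^2
        rng = np.random.default_rng(5)
        n = 120
        ratios = []
        for _ in range(30):
            A = rng.random((n, n)) < 0.3
            np.fill_diagonal(A, False)
            W = np.where(A, 0.5, 0.0)
            g = fn.FunctionalGraph(W, np.zeros((n, n), int), 30.0)
            stats = fn.graph_stats(g, thresholds=np.array([0.0]))
            ratios.append(stats["bidirectional_ratio"][0])
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios) - 1.0) < 3 * se + 0.02

    def test_lag_speed_recovered_from_constructed_lags(self):
        rng = np.random.default_rng(7)
        n = 40
        pos = rng.random((n, 2)) * 700.0
        fs = 30.0
        speed_mm_s = 1.0  # slow enough that integer-frame lags resolve the slope
        W = np.zeros((n, n))
        lag = np.zeros((n, n), dtype=int)
        iu, ju = np.triu_indices(n, k=1)
        d_mm = np.linalg.norm(pos[iu] - pos[ju], axis=1) / 1000.0
        lag_frames = np.rint(d_mm / speed_mm_s * fs).astype(int)
        for (i, j, lf) in zip(iu, ju, lag_frames):
            W[i, j] = 0.2
            lag[i, j] = lf
        g = fn.FunctionalGraph(W, lag, fs, positions_um=pos)
        stats = fn.graph_stats(g, n_dist_bins=6)
        assert stats["lag_speed_mm_s"] == pytest.approx(speed_mm_s, rel=0.05)
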