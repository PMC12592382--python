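"""CCA family: standard, regularized, kernel, multiset, temporally embedded."""

import numpy as np
import pytest

from nvfuse.cca import (
    ChannelGraph,
    KernelConfig,
    MultisetConfig,
    PenaltyConfig,
    build_channel_graph,
    fit_cca,
    fit_kcca,
    fit_mcca,
    fit_regularized_cca,
    fit_ssmcca,
    fit_tcca,
)
from nvfuse.core import EmbeddingConfig, compute_covariances
from conftest import make_cts


def brute_force_cca_2x2(x, y, step_deg=0.5):
    """Exhaustive search over unit-norm filter angles for 2x2 problems."""
    cov = compute_covariances(x, y)
    ang = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    u = np.vstack([np.cos(ang), np.sin(ang)])  # 2 x A
    num = np.abs(u.T @ cov.cxy @ u)
    vx = np.einsum("ia,ij,ja->a", u, cov.cx, u)
    vy = np.einsum("ia,ij,ja->a", u, cov.cy, u)
    corr = num / np.sqrt(np.outer(vx, vy))
    return float(corr.max())


def shared_source_pair(rng, snr_db=10.0, t=5000):
    s = rng.standard_normal(t)
    gain = 10 ** (-snr_db / 20.0)
    x = np.vstack([s + gain * rng.standard_normal(t), gain * rng.standard_normal(t)])
    y = np.vstack([s + gain * rng.standard_normal(t), gain * rng.standard_normal(t)])
    return make_cts(x), make_cts(y, modality="fnirs-hbo")


class TestStandardCCA:
    def test_copy_has_unit_correlation(self, rng):
        x = make_cts(rng.standard_normal((1, 500)))
        model = fit_cca(x, x.copy(), k=1, shrinkage=0.0)
        assert model.correlations[0] == pytest.approx(1.0, abs=1e-10)

    def test_null_correlation_is_small_on_average(self):
        corrs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = make_cts(rng.standard_normal((2, 2000)))
            y = make_cts(rng.standard_normal((2, 2000)), modality="fnirs-hbo")
            corrs.append(fit_cca(x, y).correlations[0])
        assert np.mean(corrs) < 0.15

    def test_matches_exhaustive_angle_search(self, rng):
        x, y = shared_source_pair(rng)
        model = fit_cca(x, y)
        assert model.correlations[0] >= 0.9
        oracle = brute_force_cca_2x2(x, y, step_deg=0.5)
        assert model.correlations[0] == pytest.approx(oracle, abs=1e-3)

    def test_invariant_to_invertible_channel_mixing(self, rng):
        x, y = shared_source_pair(rng)
        r0 = fit_cca(x, y).correlations[0]
        mix = np.array([[1.0, 0.7], [-0.2, 2.0]])
        xm = make_cts(mix @ x.data)
        r1 = fit_cca(xm, y).correlations[0]
        assert abs(r0 - r1) < 1e-8

    def test_first_correlation_bounds_single_channel_pairs(self, rng):
        x, y = shared_source_pair(rng, snr_db=0.0)
        model = fit_cca(x, y)
        best_pair = max(
            abs(np.corrcoef(x.data[i], y.data[j])[0, 1])
            for i in range(2)
            for j in range(2)
        )
        assert model.correlations[0] >= best_pair - 1e-8

    def test_correlations_sorted_and_bounded(self, rng):
        x = make_cts(rng.standard_normal((4, 3000)))
        y = make_cts(rng.standard_normal((4, 3000)), modality="fnirs-hbo")
        model = fit_cca(x, y, k=3)
        c = model.correlations
        assert np.all(np.diff(c) <= 1e-12)
        assert np.all((c >= 0) & (c <= 1 + 1e-8))
        # unit-variance constraints
        cov = compute_covariances(x, y)
        for k in range(3):
            assert model.wx[:, k] @ cov.cx @ model.wx[:, k] == pytest.approx(1.0, abs=1e-8)

    def test_k_too_large_raises(self, rng):
        x = make_cts(rng.standard_normal((2, 100)))
        with pytest.raises(ValueError, match="k=3"):
            fit_cca(x, x.copy(), k=3)


class TestRegularizedCCA:
    def test_zero_penalties_reduce_to_cca(self, rng):
        x, y = shared_source_pair(rng)
        base = fit_cca(x, y).correlations[0]
        reg = fit_regularized_cca(x, y, penalties=PenaltyConfig())
        assert reg.correlations[0] == pytest.approx(base, abs=1e-6)

    def test_l1_concentrates_support_on_informative_channel(self, rng):
        t = 4000
        s = rng.standard_normal(t)
        x = 0.15 * rng.standard_normal((6, t))
        y = 0.15 * rng.standard_normal((6, t))
        x[0] += s
        y[0] += s
        model = fit_regularized_cca(
            make_cts(x),
            make_cts(y, modality="fnirs-hbo"),
            penalties=PenaltyConfig(l1_x=0.2, l1_y=0.2),
        )
        for w in (model.wx[:, 0], model.wy[:, 0]):
            assert np.argmax(np.abs(w)) == 0
            assert abs(w[0]) == np.max(np.abs(w))
            assert np.sum(w[1:] == 0.0) >= 3

    def test_graph_penalty_pulls_connected_weights_together(self, rng):
        pos = np.array([[0, 0, 0], [5, 0, 0], [100, 0, 0], [200, 0, 0]], float)
        graph = build_channel_graph(pos, "distance_threshold", 25.0)
        t = 2000
        s = rng.standard_normal(t)
        x = 0.5 * rng.standard_normal((4, t))
        x[0] += s
        x[1] += s
        y = 0.5 * rng.standard_normal((2, t))
        y[0] += s
        xc, yc = make_cts(x), make_cts(y, modality="fnirs-hbo")
        free = fit_regularized_cca(
            xc, yc, penalties=PenaltyConfig(constraint_mode="identity")
        )
        pen = fit_regularized_cca(
            xc, yc, penalties=PenaltyConfig(graph_x=5.0), graphs=(graph, None)
        )

        def spread(w):
            return abs(w[0] - w[1]) / max(abs(w[0]), abs(w[1]))

        assert spread(pen.wx[:, 0]) < spread(free.wx[:, 0])

    def test_objective_history_is_monotone(self, rng):
        x, y = shared_source_pair(rng, snr_db=0.0)
        model = fit_regularized_cca(
            x, y, penalties=PenaltyConfig(l1_x=0.3, l1_y=0.3)
        )
        assert np.all(np.diff(model.objective_history) >= -1e-9)
        assert model.constraint_mode == "identity"

    def test_sparsity_non_increasing_along_l1_ladder(self, rng):
        t = 3000
        s = rng.standard_normal(t)
        x = 0.4 * rng.standard_normal((8, t))
        x[0] += s
        y = 0.4 * rng.standard_normal((8, t))
        y[0] += s
        xc, yc = make_cts(x), make_cts(y, modality="fnirs-hbo")
        nnz = []
        for l1 in (0.05, 0.2, 0.5):
            m = fit_regularized_cca(xc, yc, penalties=PenaltyConfig(l1_x=l1, l1_y=l1))
            nnz.append(int(np.sum(m.wx[:, 0] != 0)))
        assert nnz[0] >= nnz[1] >= nnz[2]

    def test_missing_graph_raises(self, rng):
        x, y = shared_source_pair(rng)
        with pytest.raises(ValueError, match="graph_x"):
            fit_regularized_cca(x, y, penalties=PenaltyConfig(graph_x=1.0))


class TestChannelGraph:
    def test_two_close_channels_give_pair_laplacian(self):
        pos = np.array([[0, 0, 0], [10, 0, 0]], float)
        g = build_channel_graph(pos, "distance_threshold", 25.0)
        np.testing.assert_allclose(g.laplacian, [[1, -1], [-1, 1]])

    def test_two_far_channels_give_zero_laplacian(self):
        pos = np.array([[0, 0, 0], [80, 0, 0]], float)
        g = build_channel_graph(pos, "distance_threshold", 60.0)
        np.testing.assert_array_equal(g.laplacian, np.zeros((2, 2)))

    def test_default_eeg_montage_laplacian_is_psd(self, default_montage):
        g = build_channel_graph(
            default_montage.eeg_positions, "distance_threshold", 60.0
        )
        evals = np.linalg.eigvalsh(g.laplacian)
        assert evals.min() >= -1e-8
        np.testing.assert_allclose(g.laplacian.sum(axis=1), 0.0, atol=1e-10)

    def test_gaussian_and_knn_rules(self, default_montage):
        pos = default_montage.channel_midpoints()
        for rule, param in (("gaussian", 20.0), ("knn", 4)):
            g = build_channel_graph(pos, rule, param)
            assert np.linalg.eigvalsh(g.laplacian).min() >= -1e-8

    def test_asymmetric_adjacency_rejected(self):
        b = np.array([[0.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ChannelGraph(adjacency=b)


class TestKernelCCA:
    def test_linear_kernel_recovers_cca(self, rng):
        x, y = shared_source_pair(rng, t=400)
        base = fit_cca(x, y).correlations[0]
        cfg = KernelConfig(kind="linear", ridge=1e-4)
        model = fit_kcca(x, y, kernels=(cfg, cfg))
        assert model.correlations[0] == pytest.approx(base, abs=0.02)

    def test_gaussian_kernel_detects_quadratic_relation(self, rng):
        t = 500
        x = rng.standard_normal((1, t))
        y = x**2 - (x**2).mean()
        xc = make_cts(x)
        yc = make_cts(y, modality="fnirs-hbo")
        assert fit_cca(xc, yc).correlations[0] <= 0.3
        cfg = KernelConfig(kind="gaussian")
        model = fit_kcca(xc, yc, kernels=(cfg, cfg))
        assert model.correlations[0] >= 0.8
        assert model.patterns is None
        assert model.extras["dual"]

    def test_correlation_vanishes_monotonically_with_ridge(self, rng):
        x, y = shared_source_pair(rng, t=300)
        corrs = []
        for ridge in (0.1, 10.0, 1e3, 1e6):
            cfg = KernelConfig(kind="gaussian", ridge=ridge)
            corrs.append(float(fit_kcca(x, y, kernels=(cfg, cfg)).correlations[0]))
        assert np.all(np.diff(corrs) < 0)
        assert corrs[-1] < 0.01

    def test_projection_of_training_data_matches_variates(self, rng):
        from nvfuse.cca import kcca_project

        x, y = shared_source_pair(rng, t=300)
        cfg = KernelConfig(kind="gaussian", ridge=0.1)
        model = fit_kcca(x, y, kernels=(cfg, cfg))
        proj = kcca_project(model, x, side="x")
        r = abs(np.corrcoef(proj[0], y.data[0])[0, 1])
        assert r > 0.5  # projections carry the shared source

    def test_zero_bandwidth_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            KernelConfig(kind="gaussian", bandwidth=0.0)


class TestMultisetCCA:
    def _three_sets(self, rng, n_ch=4, t=4000):
        s = rng.standard_normal(t)
        out = []
        for i in range(3):
            z = 0.3 * rng.standard_normal((n_ch, t))
            z[i % n_ch] += s
            out.append(make_cts(z))
        return out

    def test_two_sets_reduce_to_cca(self, rng):
        ds = self._three_sets(rng)[:2]
        m2 = fit_mcca(ds)
        base = fit_cca(ds[0], ds[1]).correlations[0]
        assert m2.correlations[0] == pytest.approx(base, abs=1e-6)

    def test_shared_source_yields_high_pairwise_correlations(self, rng):
        ds = self._three_sets(rng)
        model = fit_mcca(ds)
        filters = model.extras["all_filters"]
        for i in range(3):
            for j in range(i + 1, 3):
                vi = filters[i][:, 0] @ ds[i].data
                vj = filters[j][:, 0] @ ds[j].data
                assert abs(np.corrcoef(vi, vj)[0, 1]) >= 0.9

    def test_deflation_imposes_filter_orthogonality(self, rng):
        ds = self._three_sets(rng)
        model = fit_mcca(ds, MultisetConfig(k=2))
        for w in model.extras["all_filters"]:
            assert abs(w[:, 0] @ w[:, 1]) <= 1e-8

    def test_too_few_channels_raises(self, rng):
        ds = self._three_sets(rng, n_ch=2)
        with pytest.raises(ValueError, match="k=3"):
            fit_mcca(ds, MultisetConfig(k=3))


class TestStructuredSparseMultisetCCA:
    def test_zero_penalties_match_pls(self, rng):
        t = 3000
        s = rng.standard_normal(t)
        ds = []
        for _ in range(2):
            z = 0.3 * rng.standard_normal((5, t))
            z[0] += s
            ds.append(make_cts(z))
        model = fit_ssmcca(ds)
        x0 = ds[0].data - ds[0].data.mean(1, keepdims=True)
        y0 = ds[1].data - ds[1].data.mean(1, keepdims=True)
        pls = np.linalg.svd(x0 @ y0.T / t, compute_uv=False)[0]
        # objective sums both ordered pairs
        assert model.objective_history[-1] / 2 == pytest.approx(pls, abs=1e-6)

    def test_sparse_recovery_finds_true_channel_in_all_sets(self, rng):
        t = 3000
        s = rng.standard_normal(t)
        ds = []
        for _ in range(3):
            z = 0.3 * rng.standard_normal((8, t))
            z[2] += s
            ds.append(make_cts(z))
        model = fit_ssmcca(ds, penalties=[PenaltyConfig(l1_x=0.2)] * 3)
        for w in model.extras["all_filters"]:
            assert np.argmax(np.abs(w[:, 0])) == 2

    def test_objective_invariant_to_sign_flip_of_one_dataset(self, rng):
        t = 2000
        s = rng.standard_normal(t)
        ds = []
        for _ in range(3):
            z = 0.4 * rng.standard_normal((4, t))
            z[0] += s
            ds.append(make_cts(z))
        m1 = fit_ssmcca(ds, penalties=[PenaltyConfig(l1_x=0.1)] * 3)
        flipped = [ds[0], make_cts(-ds[1].data), ds[2]]
        m2 = fit_ssmcca(flipped, penalties=[PenaltyConfig(l1_x=0.1)] * 3)
        assert m1.objective_history[-1] == pytest.approx(
            m2.objective_history[-1], abs=1e-9
        )


class TestTemporallyEmbeddedCCA:
    def test_recovers_constructed_two_second_delay(self, rng):
        t = 600
        x = rng.standard_normal((1, t))
        y = np.zeros((1, t))
        y[0, 4:] = x[0, :-4]  # 2 s at 2 Hz
        xc = make_cts(x, rate=2.0, modality="eeg-bandpower")
        yc = make_cts(y, rate=2.0, modality="fnirs-hbo")
        model = fit_tcca(xc, yc, lags=EmbeddingConfig(lags=[1.0, 2.0, 3.0, 4.0]))
        assert model.correlations[0] >= 0.99
        assert model.extras["dominant_lag"][0] == 2.0
        # without the matching lag the correlation is strictly lower
        base = fit_tcca(xc, yc, lags=EmbeddingConfig(lags=[0.0]))
        assert base.correlations[0] < model.correlations[0]

    def test_lag_grid_expands_feature_dimension(self, rng):
        x = make_cts(rng.standard_normal((24, 200)), rate=2.0, modality="eeg-bandpower")
        y = make_cts(rng.standard_normal((3, 200)), rate=2.0, modality="fnirs-hbo")
        model = fit_tcca(x, y, lags=EmbeddingConfig(lags=[1.0, 2.0, 3.0, 4.0]))
        assert model.wx.shape[0] == 96
        assert model.extras["wx_lagged"].shape == (24, 4, 1)
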