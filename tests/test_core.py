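"""Covariance machinery, temporal embedding, patterns, whitening, bandpower."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nvfuse.core import (
    ChannelTimeSeries,
    EmbeddingConfig,
    FilterSet,
    apply_filters,
    bandpower_series,
    compute_covariances,
    estimate_patterns,
    temporal_embed,
    whiten,
)
from conftest import make_cts


class TestComputeCovariances:
    def test_identical_unit_variance_single_channel(self, rng):
        s = rng.standard_normal(5000)
        s = (s - s.mean()) / s.std()
        x = make_cts(s)
        cov = compute_covariances(x, x, shrinkage=0.0)
        np.testing.assert_allclose(cov.cx, [[1.0]], atol=1e-12)
        np.testing.assert_allclose(cov.cxy, [[1.0]], atol=1e-12)

    def test_independent_noise_has_small_cross_covariance(self, rng):
        t = 100_000
        x = make_cts(rng.standard_normal((2, t)))
        y = make_cts(rng.standard_normal((2, t)), modality="fnirs-hbo")
        cov = compute_covariances(x, y)
        assert np.all(np.abs(cov.cxy) < 0.05)

    def test_shrinkage_adds_trace_scaled_diagonal(self, rng):
        x = make_cts(rng.standard_normal((2, 500)))
        y = make_cts(rng.standard_normal((2, 500)))
        c0 = compute_covariances(x, y, shrinkage=0.0)
        c1 = compute_covariances(x, y, shrinkage=0.1)
        expected = c0.cx + 0.1 * (np.trace(c0.cx) / 2) * np.eye(2)
        np.testing.assert_allclose(c1.cx, expected, atol=1e-12)

    def test_errors_name_both_lengths_and_reject_tiny_series(self, rng):
        x = make_cts(rng.standard_normal((2, 100)))
        y = make_cts(rng.standard_normal((2, 90)))
        with pytest.raises(ValueError, match="100.*90"):
            compute_covariances(x, y)
        with pytest.raises(ValueError, match="2 samples"):
            compute_covariances(make_cts([[1.0]]), make_cts([[1.0]]))


class TestTemporalEmbed:
    def test_zero_lag_is_identity(self, rng):
        x = make_cts(rng.standard_normal((3, 50)))
        out = temporal_embed(x, EmbeddingConfig(lags=[0.0]))
        np.testing.assert_array_equal(out.data, x.data)

    def test_feature_count_is_lags_times_channels(self, rng):
        x = make_cts(rng.standard_normal((3, 100)), rate=1.0)
        out = temporal_embed(x, EmbeddingConfig(lags=[0.0, 1.0, 2.0]))
        assert out.n_channels == 9
        assert out.n_samples == 100
        # lag-0 block equals the input exactly
        np.testing.assert_array_equal(out.data[:3], x.data)

    def test_impulse_shifts_by_lag_samples(self):
        data = np.zeros((1, 30))
        data[0, 10] = 1.0
        x = make_cts(data, rate=2.0)
        out = temporal_embed(x, EmbeddingConfig(lags=[0.0, 1.0]))
        assert out.data[1, 12] == 1.0
        assert out.data[1].sum() == 1.0

    def test_unrepresentable_lag_raises(self, rng):
        x = make_cts(rng.standard_normal((1, 50)), rate=2.0)
        with pytest.raises(ValueError, match="not representable"):
            temporal_embed(x, EmbeddingConfig(lags=[0.3]))

    def test_edge_padding_repeats_first_sample(self, rng):
        x = make_cts(rng.standard_normal((1, 20)), rate=1.0)
        out = temporal_embed(x, EmbeddingConfig(lags=[0.0, 2.0], padding="edge"))
        assert out.data[1, 0] == out.data[1, 1] == x.data[0, 0]


class TestApplyFilters:
    def test_identity_filter_returns_input(self, rng):
        x = make_cts(rng.standard_normal((3, 40)))
        f = FilterSet(wx=np.eye(3), wy=np.eye(3))
        out = apply_filters(f, x, side="x")
        np.testing.assert_array_equal(out.data, x.data)

    def test_difference_filter_cancels_common_noise(self, rng):
        s = rng.standard_normal(200)
        n = rng.standard_normal(200)
        x = make_cts(np.vstack([s + n, n]))
        f = FilterSet(wx=np.array([[1.0], [-1.0]]), wy=np.array([[1.0], [-1.0]]))
        out = apply_filters(f, x)
        np.testing.assert_allclose(out.data[0], s, atol=1e-12)

    @given(scale=st.floats(min_value=-5, max_value=5, allow_nan=False))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_linearity(self, scale):
        rng = np.random.default_rng(0)
        x = make_cts(rng.standard_normal((4, 30)))
        w = rng.standard_normal((4, 2))
        f = FilterSet(wx=w, wy=w)
        a = apply_filters(f, make_cts(scale * x.data)).data
        b = scale * apply_filters(f, x).data
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_dimension_mismatch_names_both(self, rng):
        x = make_cts(rng.standard_normal((3, 40)))
        f = FilterSet(wx=np.ones((5, 1)), wy=np.ones((5, 1)))
        with pytest.raises(ValueError, match="5.*3"):
            apply_filters(f, x)


class TestEstimatePatterns:
    def test_orthonormal_filters_under_identity_cov(self, rng):
        t = 200_000
        x = make_cts(rng.standard_normal((3, t)))
        cov = compute_covariances(x, x)
        q, _ = np.linalg.qr(rng.standard_normal((3, 2)))
        f = FilterSet(wx=q, wy=q)
        pat = estimate_patterns(f, cov)
        np.testing.assert_allclose(pat.ax, q, atol=0.02)

    def test_filter_rescaling_leaves_reconstruction_invariant(self, rng):
        x = make_cts(rng.standard_normal((4, 1000)))
        cov = compute_covariances(x, x)
        w = rng.standard_normal((4, 1))
        p1 = estimate_patterns(FilterSet(wx=w, wy=w), cov)
        p2 = estimate_patterns(FilterSet(wx=2 * w, wy=2 * w), cov)
        np.testing.assert_allclose(p2.ax, 0.5 * p1.ax, atol=1e-12)
        # product pattern @ source unchanged: a1 (w'x) == a2 (2w)'x
        s1 = p1.ax @ (w.T @ x.data)
        s2 = p2.ax @ ((2 * w).T @ x.data)
        np.testing.assert_allclose(s1, s2, atol=1e-10)

    def test_pattern_recovery_from_noisy_rank_one_model(self, rng):
        t = 20_000
        a = rng.standard_normal(6)
        s = rng.standard_normal(t)
        noise = rng.standard_normal((6, t))
        gain = np.sqrt((np.outer(a, s) ** 2).mean() / (noise**2).mean() / 100)
        x = make_cts(np.outer(a, s) + gain * noise)
        cov = compute_covariances(x, x)
        w = np.linalg.solve(cov.cx, a)
        w = (w / np.linalg.norm(w))[:, None]
        pat = estimate_patterns(FilterSet(wx=w, wy=w), cov)
        r = np.corrcoef(pat.ax[:, 0], a)[0, 1]
        assert abs(r) >= 0.95

    def test_noiseless_forward_model_recovered_exactly(self, rng):
        # pseudoinverse filters on X = A S recover A up to column scale
        a = rng.standard_normal((5, 2))
        s = rng.standard_normal((2, 2000))
        x = make_cts(a @ s)
        cov = compute_covariances(x, x, shrinkage=1e-9)
        w = np.linalg.pinv(a).T
        pat = estimate_patterns(FilterSet(wx=w, wy=w), cov)
        for k in range(2):
            r = np.corrcoef(pat.ax[:, k], a[:, k])[0, 1]
            assert abs(r) >= 0.999

    def test_singular_product_suggests_shrinkage(self, rng):
        x = make_cts(rng.standard_normal((3, 500)))
        cov = compute_covariances(x, x)
        w = np.column_stack([np.ones(3), np.ones(3)])  # rank-1 W
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            estimate_patterns(FilterSet(wx=w, wy=w), cov)


class TestWhiten:
    def test_output_covariance_is_identity(self, rng):
        mix = np.array([[2.0, 0.3], [0.0, 1.0]])
        x = make_cts(mix @ rng.standard_normal((2, 20_000)))
        out, _ = whiten(x)
        cov = compute_covariances(out, out)
        np.testing.assert_allclose(cov.cx, np.eye(2), atol=1e-6)

    def test_idempotent_up_to_rotation(self, rng):
        x = make_cts(np.diag([2.0, 1.0]) @ rng.standard_normal((2, 10_000)))
        w1, _ = whiten(x)
        w2, _ = whiten(w1)
        cov = compute_covariances(w2, w2)
        np.testing.assert_allclose(cov.cx, np.eye(2), atol=1e-6)

    def test_rank_deficient_reports_rank(self, rng):
        base = rng.standard_normal(1000)
        x = make_cts(np.vstack([base, 2 * base, rng.standard_normal(1000)]))
        with pytest.raises(np.linalg.LinAlgError, match="rank 2"):
            whiten(x)

    def test_whitened_cca_reduces_to_pls(self, rng):
        # after whitening, CCA equals PLS: SVD of the cross-covariance
        from nvfuse.cca import fit_cca

        mix_x = rng.standard_normal((3, 3))
        mix_y = rng.standard_normal((3, 3))
        shared = rng.standard_normal(8000)
        zx = rng.standard_normal((3, 8000))
        zy = rng.standard_normal((3, 8000))
        zx[0] += shared
        zy[0] += shared
        x, _ = whiten(make_cts(mix_x @ zx))
        y, _ = whiten(make_cts(mix_y @ zy, modality="fnirs-hbo"))
        model = fit_cca(x, y, k=1)
        cov = compute_covariances(x, y)
        pls = np.linalg.svd(cov.cxy, compute_uv=False)[0]
        assert model.correlations[0] == pytest.approx(pls, abs=1e-6)


class TestBandpower:
    def test_constant_signal_is_zero(self):
        x = make_cts(np.full((1, 100), 3.0), rate=10.0)
        out = bandpower_series(x, 1.0)
        np.testing.assert_array_equal(out.data, 0.0)
        assert out.modality == "eeg-bandpower"

    def test_unit_sine_gives_half_per_window(self):
        rate = 100.0
        t = np.arange(0, 10, 1 / rate)
        x = make_cts(np.sin(2 * np.pi * 5 * t), rate=rate)
        out = bandpower_series(x, 1.0)  # 5 full cycles per window
        np.testing.assert_allclose(out.data, 0.5, atol=1e-3)
        assert out.rate == 1.0

    def test_white_noise_mean_matches_variance(self, rng):
        x = make_cts(2.0 * rng.standard_normal((1, 10_000)), rate=100.0)
        out = bandpower_series(x, 1.0)  # 100 windows
        assert out.n_samples == 100
        assert abs(out.data.mean() - 4.0) < 0.4

    @given(n=st.integers(min_value=4, max_value=200))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_output_length_is_floor_division(self, n):
        rng = np.random.default_rng(n)
        x = make_cts(rng.standard_normal((1, n)), rate=4.0)
        out = bandpower_series(x, 0.5)
        assert out.n_samples == n // 2

    def test_window_longer_than_series_raises(self, rng):
        x = make_cts(rng.standard_normal((1, 10)), rate=10.0)
        with pytest.raises(ValueError, match="longer than series"):
            bandpower_series(x, 2.0)


def test_channel_time_series_validation(rng):
    with pytest.raises(ValueError, match="finite"):
        ChannelTimeSeries(np.array([[np.nan, 1.0]]), 1.0, ["a"], "eeg")
    with pytest.raises(ValueError, match="rate"):
        make_cts(rng.standard_normal((1, 5)), rate=0.0)
    with pytest.raises(ValueError, match="channel_ids"):
        ChannelTimeSeries(np.ones((2, 5)), 1.0, ["a"], "eeg")
    with pytest.raises(ValueError, match="modality"):
        ChannelTimeSeries(np.ones((1, 5)), 1.0, ["a"], "meg")
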