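"""Shared linear forward/backward source-model machinery.

Multimodal source-decomposition methods assume the linear generative model

    x(t) = A_x s_x(t) + eps_x(t),    y(t) = A_y s_y(t) + eps_y(t),

where ``x`` and ``y`` are multichannel EEG and fNIRS observations, ``s`` are
latent sources and the columns of ``A`` are spatial activation patterns.
Sources are reconstructed through a linear backward model ``s_hat = W^T x``;
the spatial patterns of the corresponding forward model are recovered from
the filters via ``A_hat = C W (W^T C W)^{-1}`` with ``C`` the channel
covariance.

This module holds the containers (:class:`ChannelTimeSeries`,
:class:`CovarianceSet`, :class:`FilterSet`, :class:`PatternSet`) and the
operations every decomposition method builds on: covariance estimation with
trace-scaled shrinkage, temporal embedding (time-shifted feature copies for
delayed cross-modal coupling), filter application, pattern estimation,
whitening, and windowed bandpower.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

Modality = Literal["eeg", "eeg-bandpower", "fnirs-hbo", "fnirs-hbr", "fnirs-od"]

_MODALITIES = ("eeg", "eeg-bandpower", "fnirs-hbo", "fnirs-hbr", "fnirs-od")

#: Default shrinkage: guarantees invertibility without visibly biasing
#: small-problem results; scaled by tr(C)/N so it is unit-free.
DEFAULT_SHRINKAGE = 1e-9


@dataclass
class ChannelTimeSeries:
    """Uniformly sampled multichannel signal with a modality tag.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
    rate : float
        Sampling rate in Hz.
    channel_ids : sequence of str
        Ordered channel labels, one per row of ``data``.
    modality : {"eeg", "eeg-bandpower", "fnirs-hbo", "fnirs-hbr", "fnirs-od"}
    t0 : float
        Time of the first sample in seconds.
    """

    data: np.ndarray
    rate: float
    channel_ids: Sequence[str]
    modality: str
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ChannelTimeSeries data must be finite")
        if not self.rate > 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        self.channel_ids = list(self.channel_ids)
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_ids)} channel_ids for "
                f"{self.data.shape[0]} data rows"
            )
        if self.modality not in _MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate

    def copy(self) -> "ChannelTimeSeries":
        return ChannelTimeSeries(
            self.data.copy(), self.rate, list(self.channel_ids), self.modality, self.t0
        )

    def crop(self, start: int, stop: int) -> "ChannelTimeSeries":
        """Slice by sample index, keeping the time origin consistent."""
        return ChannelTimeSeries(
            self.data[:, start:stop].copy(),
            self.rate,
            list(self.channel_ids),
            self.modality,
            self.t0 + start / self.rate,
        )


@dataclass
class CovarianceSet:
    """Within- and cross-modality covariance matrices (1/T convention)."""

    cx: np.ndarray
    cy: np.ndarray
    cxy: np.ndarray
    cross: dict | None = None
    shrinkage: float = 0.0

    def __post_init__(self) -> None:
        for name, c in (("cx", self.cx), ("cy", self.cy)):
            if not np.allclose(c, c.T, atol=1e-10):
                raise ValueError(f"{name} is not symmetric within 1e-10")
        nx, ny = self.cx.shape[0], self.cy.shape[0]
        if self.cxy.shape != (nx, ny):
            raise ValueError(
                f"cxy shape {self.cxy.shape} inconsistent with ({nx}, {ny})"
            )


@dataclass
class EmbeddingConfig:
    """Temporal embedding: concatenate time-shifted copies along features.

    ``lags`` are in seconds and must be strictly increasing.  ``direction``
    names the modality that is *embedded* (the other one is treated as the
    delayed modality).
    """

    lags: Sequence[float]
    padding: Literal["zero", "edge"] = "zero"
    direction: str = "x"

    def __post_init__(self) -> None:
        self.lags = [float(l) for l in self.lags]
        if len(self.lags) < 1:
            raise ValueError("need at least one lag")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if self.padding not in ("zero", "edge"):
            raise ValueError(f"unknown padding {self.padding!r}")

    @property
    def n_lags(self) -> int:
        return len(self.lags)


@dataclass
class FilterSet:
    """Backward-model filters, one column per component."""

    wx: np.ndarray
    wy: np.ndarray
    constraint_mode: Literal["covariance", "identity"] = "covariance"

    def __post_init__(self) -> None:
        self.wx = np.atleast_2d(np.asarray(self.wx, dtype=float))
        self.wy = np.atleast_2d(np.asarray(self.wy, dtype=float))
        if self.wx.shape[1] != self.wy.shape[1]:
            raise ValueError("wx and wy must have the same component count")
        for name, w in (("wx", self.wx), ("wy", self.wy)):
            if np.any(np.all(w == 0, axis=0)):
                raise ValueError(f"{name} has an all-zero column")

    @property
    def k(self) -> int:
        return self.wx.shape[1]


@dataclass
class PatternSet:
    """Forward-model spatial patterns, one column per component."""

    ax: np.ndarray
    ay: np.ndarray


def _center(data: np.ndarray) -> np.ndarray:
    return data - data.mean(axis=1, keepdims=True)


def shrink_cov(c: np.ndarray, shrinkage: float) -> np.ndarray:
    """Add trace-scaled ridge: ``C + shrinkage * (tr(C)/N) * I``."""
    n = c.shape[0]
    return c + shrinkage * (np.trace(c) / n) * np.eye(n)


def compute_covariances(
    x: ChannelTimeSeries,
    y: ChannelTimeSeries,
    shrinkage: float = 0.0,
) -> CovarianceSet:
    """Estimate Cx, Cy and the cross-modality covariance Cxy.

    Channels are mean-centered first.  The estimator uses the 1/T convention
    and trace-scaled diagonal shrinkage on the within-modality matrices.
    """
    if x.n_samples != y.n_samples:
        raise ValueError(
            f"sample counts differ: x has {x.n_samples}, y has {y.n_samples}"
        )
    t = x.n_samples
    if t < 2:
        raise ValueError(f"need at least 2 samples, got {t}")
    xd = _center(x.data)
    yd = _center(y.data)
    cx = xd @ xd.T / t
    cy = yd @ yd.T / t
    cxy = xd @ yd.T / t
    cx = 0.5 * (cx + cx.T)
    cy = 0.5 * (cy + cy.T)
    return CovarianceSet(
        cx=shrink_cov(cx, shrinkage),
        cy=shrink_cov(cy, shrinkage),
        cxy=cxy,
        shrinkage=shrinkage,
    )


def lag_to_samples(lag_s: float, rate: float, tol: float = 1e-6) -> int:
    """Convert a lag in seconds to samples, refusing silent rounding."""
    frac = lag_s * rate
    n = int(round(frac))
    if abs(frac - n) > tol * max(1.0, abs(frac)):
        raise ValueError(
            f"lag {lag_s} s is not representable at {rate} Hz "
            f"({frac} samples); no silent rounding"
        )
    return n


def temporal_embed(x: ChannelTimeSeries, cfg: EmbeddingConfig) -> ChannelTimeSeries:
    """Concatenate time-shifted copies of ``x`` along the feature dimension.

    The block for lag ``tau`` holds ``x(t - tau)`` so that a modality delayed
    by ``tau`` aligns with that block; the number of samples is preserved via
    the configured padding (zero or edge).  Channel labels encode
    ``(original channel, lag)``.
    """
    shifts = [lag_to_samples(l, x.rate) for l in cfg.lags]
    if any(s >= x.n_samples for s in shifts):
        raise ValueError("lag exceeds series length")
    blocks = []
    labels = []
    for lag_s, n in zip(cfg.lags, shifts):
        if n == 0:
            block = x.data.copy()
        else:
            pad = (
                np.zeros((x.n_channels, n))
                if cfg.padding == "zero"
                else np.repeat(x.data[:, :1], n, axis=1)
            )
            block = np.concatenate([pad, x.data[:, :-n]], axis=1)
        blocks.append(block)
        labels.extend(f"{ch}|lag={lag_s:g}s" for ch in x.channel_ids)
    return ChannelTimeSeries(
        np.concatenate(blocks, axis=0), x.rate, labels, x.modality, x.t0
    )


def apply_filters(
    f: FilterSet, x: ChannelTimeSeries, side: Literal["x", "y"] = "x"
) -> ChannelTimeSeries:
    """Reconstruct sources via the backward model ``s_hat = W^T x``."""
    w = f.wx if side == "x" else f.wy
    if w.shape[0] != x.n_channels:
        raise ValueError(
            f"filter expects {w.shape[0]} channels, data has {x.n_channels}"
        )
    return ChannelTimeSeries(
        w.T @ x.data,
        x.rate,
        [f"component{i + 1}" for i in range(w.shape[1])],
        x.modality,
        x.t0,
    )


def estimate_patterns(f: FilterSet, cov: CovarianceSet) -> PatternSet:
    """Recover forward-model patterns: ``A_hat = C W (W^T C W)^{-1}``.

    The product ``A_hat @ s_hat`` is invariant to any rescaling of the
    filters.
    """

    def one(c: np.ndarray, w: np.ndarray) -> np.ndarray:
        m = w.T @ c @ w
        try:
            minv = np.linalg.inv(m)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "W^T C W is singular; increase covariance shrinkage"
            ) from err
        cond = np.linalg.cond(m)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"W^T C W is ill-conditioned (cond={cond:.2e}); "
                "increase covariance shrinkage"
            )
        return c @ w @ minv

    return PatternSet(ax=one(cov.cx, f.wx), ay=one(cov.cy, f.wy))


def whiten(
    x: ChannelTimeSeries,
    shrinkage: float = 0.0,
    rank_tol: float = 1e-10,
) -> tuple[ChannelTimeSeries, np.ndarray]:
    """Decorrelate channels to unit covariance (symmetric/ZCA whitening).

    Returns the whitened series and the transform ``W`` with
    ``x_white = W @ x_centered``.  Raises on rank-deficient covariance with
    a rank report.
    """
    cov = compute_covariances(x, x, shrinkage=shrinkage)
    evals, evecs = np.linalg.eigh(cov.cx)
    rank = int(np.sum(evals > rank_tol * evals.max()))
    if rank < x.n_channels:
        raise np.linalg.LinAlgError(
            f"covariance is rank deficient: rank {rank} < {x.n_channels} channels"
        )
    w = evecs @ np.diag(evals**-0.5) @ evecs.T
    data = w @ _center(x.data)
    out = ChannelTimeSeries(data, x.rate, list(x.channel_ids), x.modality, x.t0)
    return out, w


def bandpower_series(
    x: ChannelTimeSeries,
    window_s: float,
    demean: Literal["window", "global"] = "window",
) -> ChannelTimeSeries:
    """Per-window variance of a (band-filtered) signal.

    Splits the series into non-overlapping windows of ``window_s`` seconds
    and returns one sample per complete window (trailing partial window is
    dropped).  By default the mean is removed per window; ``demean="global"``
    removes only the per-channel global mean.
    """
    n_win = lag_to_samples(window_s, x.rate)
    if n_win < 2:
        raise ValueError(f"window must span >= 2 samples, got {n_win}")
    if n_win > x.n_samples:
        raise ValueError(
            f"window ({n_win} samples) longer than series ({x.n_samples})"
        )
    n_full = x.n_samples // n_win
    data = x.data[:, : n_full * n_win]
    if demean == "global":
        data = _center(data)
    segs = data.reshape(x.n_channels, n_full, n_win)
    if demean == "window":
        bp = segs.var(axis=2)
    else:
        bp = (segs**2).mean(axis=2)
    return ChannelTimeSeries(
        bp, 1.0 / window_s, list(x.channel_ids), "eeg-bandpower", x.t0
    )


@dataclass
class DecompositionModel:
    """A fitted source-decomposition model.

    Holds the backward-model filters, the estimated forward-model patterns,
    the component association strengths (canonical correlations or the
    method's analogous score, sorted descending), and convergence metadata.
    Method-specific extras (temporal filter ``w_tau`` for mSPoC, dual
    coefficients for kernel CCA, embedding layout for tCCA, ...) live in
    ``extras``.
    """

    method: str
    filters: FilterSet
    patterns: PatternSet | None
    correlations: np.ndarray
    converged: bool = True
    n_iter: int = 0
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    constraint_mode: str = "covariance"
    train_tag: str | None = None
    extras: dict = field(default_factory=dict)

    @property
    def wx(self) -> np.ndarray:
        return self.filters.wx

    @property
    def wy(self) -> np.ndarray:
        return self.filters.wy

    @property
    def ax(self) -> np.ndarray | None:
        return None if self.patterns is None else self.patterns.ax

    @property
    def ay(self) -> np.ndarray | None:
        return None if self.patterns is None else self.patterns.ay


def fix_filter_signs(
    filters: FilterSet, patterns: PatternSet
) -> tuple[FilterSet, PatternSet]:
    """Flip each component so its largest-|.| pattern coefficient is positive."""
    wx, wy = filters.wx.copy(), filters.wy.copy()
    ax, ay = patterns.ax.copy(), patterns.ay.copy()
    for w, a in ((wx, ax), (wy, ay)):
        for k in range(a.shape[1]):
            j = int(np.argmax(np.abs(a[:, k])))
            if a[j, k] < 0:
                a[:, k] *= -1
                w[:, k] *= -1
    return (
        dataclasses.replace(filters, wx=wx, wy=wy),
        PatternSet(ax=ax, ay=ay),
    )
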