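"""Multimodal Source Power Co-modulation (mSPoC).

mSPoC couples the *bandpower* of a latent EEG source to a latent fNIRS
source.  The band-filtered EEG is cut into non-overlapping windows (one
fNIRS sample per window); the source bandpower in window ``e`` is
``Phi(e) = wx' Cx(e) wx`` with ``Cx(e)`` the within-window covariance.
Hemodynamic delay is modelled by a finite impulse response filter ``w_tau``
over past windows, ``h(Phi)(e) = sum_i w_tau_i Phi(e - tau_i)``, and the
method maximizes ``Cov(h(Phi)(e), s_hat_y(e))`` under the unit constraints
``wx' Cx wx = wy' Cy wy = w_tau' w_tau = 1``.  The coupled problem is solved
by alternating steps that are each optimal given the others, with several
random restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    ChannelTimeSeries,
    CovarianceSet,
    DecompositionModel,
    FilterSet,
    PatternSet,
    fix_filter_signs,
    lag_to_samples,
)


@dataclass
class EpochedCovariances:
    """Stack of within-window covariance matrices Cx(e), shape (E, N, N)."""

    covs: np.ndarray
    window_s: float
    epoch_rate: float

    def __post_init__(self) -> None:
        if self.covs.ndim != 3 or self.covs.shape[1] != self.covs.shape[2]:
            raise ValueError("covs must be a stack of square matrices")

    @property
    def n_epochs(self) -> int:
        return self.covs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.covs.shape[1]


@dataclass
class MspocConfig:
    """mSPoC solver settings.

    ``n_lags`` is the FIR length in epochs (lags ``0 .. n_lags-1`` times
    ``lag_step``); ``l2_x`` regularizes the EEG filter step (trace-scaled);
    ``pca_explained_variance`` pre-projects the EEG to the leading principal
    subspace.  ``n_restarts`` random initializations plus one deterministic
    one are run; the best objective wins.
    """

    n_lags: int = 8
    lag_step: int = 1
    l2_x: float = 0.8
    pca_explained_variance: float = 0.99
    max_iter: int = 200
    tol: float = 1e-5
    n_restarts: int = 10
    seed: int = 0
    fix_wt: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_lags < 1:
            raise ValueError("n_lags must be >= 1")
        if not 0 < self.pca_explained_variance <= 1:
            raise ValueError("pca_explained_variance must be in (0, 1]")


def epoch_covariances(x: ChannelTimeSeries, window_s: float) -> EpochedCovariances:
    """Within-window covariance stack over non-overlapping windows.

    Windows are mean-centered individually so that ``w' Cx(e) w`` equals the
    variance of the filtered source within window ``e`` for any ``w``.
    """
    n_win = lag_to_samples(window_s, x.rate)
    if n_win < 2:
        raise ValueError(f"window must span >= 2 samples, got {n_win}")
    mean_frac = np.abs(x.data.mean(axis=1))
    stds = x.data.std(axis=1)
    big = stds > 0
    if np.any(mean_frac[big] > 1e-2 * stds[big]):
        warnings.warn(
            "input does not look mean-free; mSPoC assumes band-filtered, "
            "mean-free EEG",
            RuntimeWarning,
            stacklevel=2,
        )
    n_epochs = x.n_samples // n_win
    segs = x.data[:, : n_epochs * n_win].reshape(x.n_channels, n_epochs, n_win)
    segs = segs - segs.mean(axis=2, keepdims=True)
    covs = np.einsum("cet,det->ecd", segs, segs) / n_win
    return EpochedCovariances(covs=covs, window_s=window_s, epoch_rate=1.0 / window_s)


def _pca_project(covs: np.ndarray, explained: float) -> tuple[np.ndarray, np.ndarray, float]:
    cbar = covs.mean(axis=0)
    evals, evecs = np.linalg.eigh(cbar)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.maximum(evals, 0.0)
    cum = np.cumsum(evals) / max(evals.sum(), 1e-300)
    n_keep = int(np.searchsorted(cum, explained) + 1)
    v = evecs[:, :n_keep]
    projected = np.einsum("nk,enm,ml->ekl", v, covs, v)
    return projected, v, float(cum[n_keep - 1])


def fit_mspoc(
    x: ChannelTimeSeries,
    y: ChannelTimeSeries,
    cfg: MspocConfig | None = None,
) -> DecompositionModel:
    """Fit mSPoC on band-filtered EEG ``x`` and window-rate fNIRS ``y``.

    ``y`` must hold exactly one sample per EEG window (its rate defines the
    window length).  Returns a model whose filters satisfy the three unit
    constraints; ``extras['wt']`` holds the temporal FIR filter, and
    ``extras['pca_basis']`` the PCA pre-projection when enabled.
    """
    cfg = cfg or MspocConfig()
    window_s = 1.0 / y.rate
    ec = epoch_covariances(x, window_s)
    e_total = min(ec.n_epochs, y.n_samples)
    if y.n_samples != ec.n_epochs:
        warnings.warn(
            f"aligning {ec.n_epochs} EEG windows with {y.n_samples} fNIRS "
            f"samples; truncating to {e_total}",
            RuntimeWarning,
            stacklevel=2,
        )
    n_tau = cfg.n_lags
    if e_total <= n_tau:
        raise ValueError(f"need more epochs ({e_total}) than lags ({n_tau})")

    covs = ec.covs[:e_total]
    yd = y.data[:, :e_total]
    yd = yd - yd.mean(axis=1, keepdims=True)
    cy = yd @ yd.T / e_total
    cy = 0.5 * (cy + cy.T)
    cy_reg = cy + 1e-9 * (np.trace(cy) / cy.shape[0]) * np.eye(cy.shape[0])
    cy_inv = np.linalg.inv(cy_reg)

    if cfg.pca_explained_variance < 1:
        covs_p, basis, ev = _pca_project(covs, cfg.pca_explained_variance)
    else:
        covs_p, basis, ev = covs, np.eye(covs.shape[1]), 1.0
    n = covs_p.shape[1]
    cbar = covs_p.mean(axis=0)
    cbar_reg = cbar + cfg.l2_x * (np.trace(cbar) / n) * np.eye(n)

    taus = np.arange(n_tau) * cfg.lag_step
    e_valid = np.arange(taus.max(), e_total)  # epochs with full lag history
    # lagged covariance stacks: lag_covs[i] = Cx(e - tau_i) for e in e_valid
    lag_covs = np.stack([covs_p[e_valid - tau] for tau in taus])  # (Nt, Ev, n, n)

    rng = np.random.default_rng(cfg.seed)
    best = None
    for restart in range(cfg.n_restarts + 1):
        if restart == 0:
            # deterministic init: leading eigenvector of the mean covariance
            wx = np.linalg.eigh(cbar)[1][:, -1]
        else:
            wx = rng.standard_normal(n)
        wx = wx / np.sqrt(max(wx @ cbar @ wx, 1e-30))
        wt = (
            cfg.fix_wt.astype(float)
            if cfg.fix_wt is not None
            else np.ones(n_tau)
        )
        wt = wt / np.linalg.norm(wt)
        wy = None
        obj_prev = -np.inf
        history = []
        converged = False
        for it in range(1, cfg.max_iter + 1):
            # bandpower of the current source at each lag
            phi_lag = np.einsum("tenm,n,m->te", lag_covs, wx, wx)  # (Nt, Ev)
            phi_lag_c = phi_lag - phi_lag.mean(axis=1, keepdims=True)
            if wy is None:
                # initialize s_y from the FIR-filtered bandpower
                h_phi = wt @ phi_lag
                h_phi_c = h_phi - h_phi.mean()
                wy_vec = cy_inv @ (yd[:, e_valid] @ h_phi_c) / len(e_valid)
                wy = wy_vec / np.sqrt(max(wy_vec @ cy @ wy_vec, 1e-30))
            sy = wy @ yd[:, e_valid]
            sy_c = sy - sy.mean()
            # w_tau step: maximize Cov(wt' Phi_lag, s_y) under ||wt|| = 1
            if cfg.fix_wt is None:
                wt_new = phi_lag_c @ sy_c
                nrm = np.linalg.norm(wt_new)
                if nrm > 1e-15:
                    wt = wt_new / nrm
            # wx step: generalized eigenproblem on the s_y-weighted lagged covs
            h_covs = np.einsum("t,tenm->enm", wt, lag_covs)
            h_covs_c = h_covs - h_covs.mean(axis=0)
            m = np.einsum("e,enm->nm", sy_c, h_covs_c) / len(e_valid)
            m = 0.5 * (m + m.T)
            evals, evecs = _gen_eigh(m, cbar_reg)
            wx = evecs[:, -1]
            wx = wx / np.sqrt(max(wx @ cbar @ wx, 1e-30))
            # wy step: closed form given h(Phi)
            phi_lag = np.einsum("tenm,n,m->te", lag_covs, wx, wx)
            h_phi = wt @ phi_lag
            h_phi_c = h_phi - h_phi.mean()
            wy_vec = cy_inv @ (yd[:, e_valid] @ h_phi_c) / len(e_valid)
            nrm = np.sqrt(max(wy_vec @ cy @ wy_vec, 1e-30))
            if nrm > 1e-15:
                wy = wy_vec / nrm
            sy = wy @ yd[:, e_valid]
            sy_c = sy - sy.mean()
            obj = float(h_phi_c @ sy_c) / len(e_valid)
            if obj < obj_prev - 1e-12:
                converged = True  # step would decrease objective; stop
                break
            history.append(obj)
            if obj - obj_prev < cfg.tol * max(1.0, abs(obj)):
                converged = True
                obj_prev = obj
                break
            obj_prev = obj
        cand = {
            "obj": history[-1] if history else -np.inf,
            "wx": wx,
            "wy": wy,
            "wt": wt,
            "history": np.asarray(history),
            "converged": converged,
            "n_iter": it,
        }
        if best is None or cand["obj"] > best["obj"]:
            best = cand

    if not best["converged"]:
        warnings.warn(
            f"mSPoC did not converge in {cfg.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )

    wx_full = basis @ best["wx"]
    cx_full = covs.mean(axis=0)
    # renormalize in the full channel space
    wx_full = wx_full / np.sqrt(max(wx_full @ cx_full @ wx_full, 1e-30))
    filters = FilterSet(
        wx=wx_full[:, None], wy=best["wy"][:, None], constraint_mode="covariance"
    )
    cov = CovarianceSet(
        cx=cx_full, cy=cy, cxy=np.zeros((cx_full.shape[0], cy.shape[0]))
    )
    ax = cx_full @ wx_full / float(wx_full @ cx_full @ wx_full)
    ay = cy @ best["wy"] / float(best["wy"] @ cy @ best["wy"])
    patterns = PatternSet(ax=ax[:, None], ay=ay[:, None])
    filters, patterns = fix_filter_signs(filters, patterns)
    sy = best["wy"] @ yd[:, e_valid]
    phi_lag = np.einsum(
        "tenm,n,m->te",
        np.stack([covs[e_valid - tau] for tau in taus]),
        filters.wx[:, 0],
        filters.wx[:, 0],
    )
    h_phi = best["wt"] @ phi_lag
    corr = _safe_corr(h_phi, sy)
    return DecompositionModel(
        method="mspoc",
        filters=filters,
        patterns=patterns,
        correlations=np.asarray([abs(corr)]),
        converged=best["converged"],
        n_iter=best["n_iter"],
        objective_history=best["history"],
        constraint_mode="covariance",
        extras={
            "wt": best["wt"],
            "taus_epochs": taus,
            "window_s": window_s,
            "pca_basis": basis,
            "pca_explained": ev,
            "objective": best["obj"],
            "cx": cx_full,
            "cy": cy,
        },
    )


def _gen_eigh(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Generalized symmetric eigenproblem a v = lambda b v, ascending."""
    from scipy.linalg import eigh

    evals, evecs = eigh(a, b)
    return evals, evecs


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def mspoc_constraint_residuals(
    model: DecompositionModel,
) -> tuple[float, float, float]:
    """Residuals of the three unit constraints (wx'Cx wx, wy'Cy wy, wt'wt)."""
    cx = model.extras["cx"]
    cy = model.extras["cy"]
    wx = model.wx[:, 0]
    wy = model.wy[:, 0]
    wt = model.extras["wt"]
    return (
        abs(float(wx @ cx @ wx) - 1.0),
        abs(float(wy @ cy @ wy) - 1.0),
        abs(float(wt @ wt) - 1.0),
    )
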