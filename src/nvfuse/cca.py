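"""The CCA family for symmetric two- and multi-set fusion.

Standard CCA maximizes ``wx' Cxy wy`` under unit source variance
(``wx' Cx wx = wy' Cy wy = 1``) and is solved here as an SVD of the
shrinkage-whitened cross-covariance.  Regularized variants add convex
penalties (L1 for sparsity, L2/Ridge, and a channel-graph GraphNet term
``w' L w`` that encourages spatially smooth filters); kernel CCA maps both
datasets through kernels; multiset CCA (SUMCOR) couples more than two
datasets; structured-sparse multiset CCA combines both.  Temporally embedded
CCA (tCCA) handles the hemodynamic delay by concatenating time-shifted
copies of the fast modality along the feature axis before fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import (
    DEFAULT_SHRINKAGE,
    ChannelTimeSeries,
    CovarianceSet,
    DecompositionModel,
    EmbeddingConfig,
    FilterSet,
    PatternSet,
    compute_covariances,
    estimate_patterns,
    fix_filter_signs,
    shrink_cov,
    temporal_embed,
)

logger = logging.getLogger(__name__)


@dataclass
class PenaltyConfig:
    """Penalty weights for regularized CCA (Lagrangian form).

    ``l1_*`` induce sparsity by soft-thresholding, ``l2_*`` are Ridge
    weights, ``graph_*`` weight the GraphNet term ``w' L w``.  When any L1 or
    graph penalty is active the unit-variance constraints are replaced by
    unit-norm constraints (identity mode), following common practice of
    substituting identity for the covariance in penalized CCA; pure-Ridge
    fits keep covariance constraints.
    """

    l1_x: float = 0.0
    l1_y: float = 0.0
    l2_x: float = 0.0
    l2_y: float = 0.0
    graph_x: float = 0.0
    graph_y: float = 0.0
    constraint_mode: Literal["auto", "covariance", "identity"] = "auto"

    def __post_init__(self) -> None:
        for name in ("l1_x", "l1_y", "l2_x", "l2_y", "graph_x", "graph_y"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    @property
    def any_nonsmooth(self) -> bool:
        return (
            self.l1_x > 0 or self.l1_y > 0 or self.graph_x > 0 or self.graph_y > 0
        )

    @property
    def all_zero(self) -> bool:
        return not self.any_nonsmooth and self.l2_x == 0 and self.l2_y == 0

    def resolved_mode(self) -> str:
        if self.constraint_mode != "auto":
            return self.constraint_mode
        return "identity" if self.any_nonsmooth else "covariance"


@dataclass
class ChannelGraph:
    """Undirected weighted channel graph with its Laplacian ``L = D - B``."""

    adjacency: np.ndarray
    rule: str = "distance_threshold"
    param: float = 0.0
    degree: np.ndarray = field(init=False)
    laplacian: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        b = np.asarray(self.adjacency, dtype=float)
        if not np.allclose(b, b.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if np.any(b < 0):
            raise ValueError("adjacency weights must be >= 0")
        np.fill_diagonal(b, 0.0)
        self.adjacency = b
        self.degree = np.diag(b.sum(axis=1))
        self.laplacian = self.degree - b

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]


def build_channel_graph(
    positions: np.ndarray,
    rule: Literal["knn", "distance_threshold", "gaussian"] = "distance_threshold",
    param: float = 25.0,
) -> ChannelGraph:
    """Build a channel graph from positions (mm).

    ``distance_threshold``: binary edges where channels are closer than
    ``param`` mm.  ``knn``: symmetrized binary k-nearest-neighbour edges.
    ``gaussian``: weights ``exp(-d^2 / (2 param^2))``.
    Isolated nodes are allowed (logged, not an error).
    """
    pos = np.asarray(positions, dtype=float)
    d = squareform(pdist(pos))
    n = pos.shape[0]
    if rule == "distance_threshold":
        b = (d < param).astype(float)
        np.fill_diagonal(b, 0.0)
    elif rule == "knn":
        k = int(param)
        b = np.zeros((n, n))
        order = np.argsort(d, axis=1)
        for i in range(n):
            b[i, order[i, 1 : k + 1]] = 1.0
        b = np.maximum(b, b.T)
    elif rule == "gaussian":
        b = np.exp(-(d**2) / (2 * param**2))
        np.fill_diagonal(b, 0.0)
    else:
        raise ValueError(f"unknown graph rule {rule!r}")
    iso = np.where(b.sum(axis=1) == 0)[0]
    if iso.size:
        logger.info("channel graph has %d isolated node(s)", iso.size)
    return ChannelGraph(adjacency=b, rule=rule, param=float(param))


@dataclass
class KernelConfig:
    """Kernel choice for kernel CCA.

    ``ridge`` regularizes the (otherwise ill-posed) dual problem; gaussian
    bandwidth ``None`` means the median pairwise distance heuristic.
    """

    kind: Literal["linear", "polynomial", "gaussian"] = "linear"
    bandwidth: float | None = None
    degree: int = 2
    ridge: float = 0.1
    centered: bool = True

    def __post_init__(self) -> None:
        if self.kind in ("polynomial", "gaussian") and not self.ridge > 0:
            raise ValueError(f"{self.kind} kCCA requires ridge > 0")
        if self.kind == "gaussian" and self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("gaussian bandwidth must be > 0")


@dataclass
class MultisetConfig:
    """Multiset-CCA settings (SUMCOR objective, filter-orthogonal deflation)."""

    objective: Literal["SUMCOR", "SSQCOR"] = "SUMCOR"
    k: int = 1
    deflation: Literal["filter_orthogonal"] = "filter_orthogonal"
    max_iter: int = 500
    tol: float = 1e-10


def _inv_sqrt(c: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    evals, evecs = np.linalg.eigh(c)
    evals = np.maximum(evals, floor * evals.max())
    return evecs @ np.diag(evals**-0.5) @ evecs.T


def fit_cca(
    x: ChannelTimeSeries,
    y: ChannelTimeSeries,
    k: int = 1,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> DecompositionModel:
    """Standard CCA via whitened cross-covariance SVD.

    Filters satisfy ``w' C w = 1``; canonical correlations are the singular
    values of ``Cx^{-1/2} Cxy Cy^{-1/2}``, sorted descending.
    """
    if k > min(x.n_channels, y.n_channels):
        raise ValueError(
            f"k={k} exceeds min channel count {min(x.n_channels, y.n_channels)}"
        )
    cov = compute_covariances(x, y, shrinkage=shrinkage)
    return _cca_from_cov(cov, k, method="cca")


def _cca_from_cov(cov: CovarianceSet, k: int, method: str = "cca") -> DecompositionModel:
    try:
        cx_is = _inv_sqrt(cov.cx)
        cy_is = _inv_sqrt(cov.cy)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "degenerate covariance; increase shrinkage"
        ) from err
    u, s, vt = np.linalg.svd(cx_is @ cov.cxy @ cy_is)
    wx = cx_is @ u[:, :k]
    wy = cy_is @ vt[:k].T
    corr = np.clip(s[:k], 0.0, None)
    filters = FilterSet(wx=wx, wy=wy, constraint_mode="covariance")
    patterns = estimate_patterns(filters, cov)
    filters, patterns = fix_filter_signs(filters, patterns)
    return DecompositionModel(
        method=method,
        filters=filters,
        patterns=patterns,
        correlations=corr,
        constraint_mode="covariance",
        extras={"covariances": cov},
    )


def _soft_threshold(v: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - thr, 0.0)


def _penalized_update(
    c: np.ndarray,
    l1: float,
    l2: float,
    graph: float,
    laplacian: np.ndarray | None,
    prev: np.ndarray,
) -> np.ndarray:
    """One penalized power-iteration half-step under unit-norm constraint.

    Quadratic terms act through the normalization matrix
    ``(1 + l2) I + graph * L``; L1 acts by soft-thresholding at
    ``l1 * max|w|`` (scale-free threshold).  Falls back to the previous
    iterate if thresholding removes all support.
    """
    n = c.shape[0]
    if l2 > 0 or (graph > 0 and laplacian is not None):
        m = (1.0 + l2) * np.eye(n)
        if graph > 0 and laplacian is not None:
            m = m + graph * laplacian
        w = np.linalg.solve(m, c)
    else:
        w = c.copy()
    if l1 > 0:
        w = _soft_threshold(w, l1 * np.max(np.abs(w)))
    nrm = np.linalg.norm(w)
    if nrm == 0:
        return prev
    return w / nrm


def fit_regularized_cca(
    x: ChannelTimeSeries,
    y: ChannelTimeSeries,
    k: int = 1,
    penalties: PenaltyConfig | None = None,
    graphs: tuple[ChannelGraph | None, ChannelGraph | None] | None = None,
    shrinkage: float = DEFAULT_SHRINKAGE,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> DecompositionModel:
    """Regularized CCA: Ridge, sparse (L1), ElasticNet, and GraphNet (ssCCA).

    Pure-Ridge (and unpenalized) fits keep the covariance constraints and are
    solved in closed form by whitening with ``C + l2 (tr C / N) I``.  When an
    L1 or graph penalty is active, constraints switch to unit norm (identity
    mode) and the fit alternates penalized power iterations initialized from
    the leading SVD pair of Cxy, stopping when the recorded objective
    ``wx' Cxy wy`` stalls or would decrease (the history is therefore
    monotone non-decreasing).  Non-convergence returns the model with
    ``converged=False`` and a logged warning, never silently.
    """
    pen = penalties or PenaltyConfig()
    mode = pen.resolved_mode()
    gx = gy = None
    if graphs is not None:
        gx, gy = graphs
    if pen.graph_x > 0 and (gx is None or gx.n != x.n_channels):
        raise ValueError("graph_x penalty requires a matching x-side ChannelGraph")
    if pen.graph_y > 0 and (gy is None or gy.n != y.n_channels):
        raise ValueError("graph_y penalty requires a matching y-side ChannelGraph")

    cov = compute_covariances(x, y, shrinkage=shrinkage)

    if mode == "covariance":
        # Ridge acts through the whitening matrices; closed form.
        cov_r = CovarianceSet(
            cx=shrink_cov(cov.cx, pen.l2_x),
            cy=shrink_cov(cov.cy, pen.l2_y),
            cxy=cov.cxy,
            shrinkage=shrinkage,
        )
        model = _cca_from_cov(cov_r, k, method="regularized-cca")
        model.extras["penalties"] = pen
        model.extras["covariances"] = cov
        # report patterns/correlations w.r.t. the unshrunk covariances
        model.patterns = estimate_patterns(model.filters, cov)
        return model

    # identity mode: alternating penalized power iterations, deflated per k
    cxy = cov.cxy.copy()
    wx_all, wy_all, corrs = [], [], []
    converged = True
    history_all = []
    n_iter_total = 0
    lap_x = gx.laplacian if gx is not None else None
    lap_y = gy.laplacian if gy is not None else None
    for _ in range(k):
        u, s, vt = np.linalg.svd(cxy)
        wx = u[:, 0]
        wy = vt[0]
        obj_prev = -np.inf
        history = []
        it = 0
        comp_converged = False
        for it in range(1, max_iter + 1):
            wx_new = _penalized_update(cxy @ wy, pen.l1_x, pen.l2_x, pen.graph_x, lap_x, wx)
            wy_new = _penalized_update(cxy.T @ wx_new, pen.l1_y, pen.l2_y, pen.graph_y, lap_y, wy)
            obj = float(wx_new @ cxy @ wy_new)
            if obj < obj_prev - 1e-12:
                comp_converged = True  # stalled; keep previous iterate
                break
            wx, wy = wx_new, wy_new
            history.append(obj)
            if obj - obj_prev < tol * max(1.0, abs(obj)):
                comp_converged = True
                obj_prev = obj
                break
            obj_prev = obj
        if not comp_converged:
            converged = False
            warnings.warn(
                f"regularized CCA did not converge in {max_iter} iterations",
                RuntimeWarning,
                stacklevel=2,
            )
        n_iter_total += it
        history_all.extend(history)
        wx_all.append(wx)
        wy_all.append(wy)
        corrs.append(_unit_variance_corr(wx, wy, cov))
        # rank-one projection deflation in filter space
        px = np.eye(cxy.shape[0]) - np.outer(wx, wx)
        py = np.eye(cxy.shape[1]) - np.outer(wy, wy)
        cxy = px @ cxy @ py

    filters = FilterSet(
        wx=np.column_stack(wx_all), wy=np.column_stack(wy_all), constraint_mode="identity"
    )
    patterns = estimate_patterns(filters, cov)
    filters, patterns = fix_filter_signs(filters, patterns)
    order = np.argsort(corrs)[::-1]
    return DecompositionModel(
        method="regularized-cca",
        filters=FilterSet(
            wx=filters.wx[:, order], wy=filters.wy[:, order], constraint_mode="identity"
        ),
        patterns=PatternSet(ax=patterns.ax[:, order], ay=patterns.ay[:, order]),
        correlations=np.asarray(corrs)[order],
        converged=converged,
        n_iter=n_iter_total,
        objective_history=np.asarray(history_all),
        constraint_mode="identity",
        extras={"penalties": pen, "covariances": cov},
    )


def _unit_variance_corr(wx: np.ndarray, wy: np.ndarray, cov: CovarianceSet) -> float:
    """Pearson correlation of the variates implied by filters and covariances."""
    vx = float(wx @ cov.cx @ wx)
    vy = float(wy @ cov.cy @ wy)
    if vx <= 0 or vy <= 0:
        return 0.0
    return abs(float(wx @ cov.cxy @ wy)) / np.sqrt(vx * vy)


def _kernel_matrix(data: np.ndarray, cfg: KernelConfig) -> np.ndarray:
    """Gram matrix over samples (columns of the channel-by-time data)."""
    xt = data.T  # samples x features
    if cfg.kind == "linear":
        k = xt @ xt.T
    elif cfg.kind == "polynomial":
        k = (1.0 + xt @ xt.T) ** cfg.degree
    elif cfg.kind == "gaussian":
        d2 = squareform(pdist(xt, metric="sqeuclidean"))
        bw = cfg.bandwidth
        if bw is None:
            med = np.median(squareform(d2))
            bw = np.sqrt(med) if med > 0 else 1.0
        if bw <= 0:
            raise ValueError("gaussian bandwidth must be > 0")
        k = np.exp(-d2 / (2 * bw**2))
    else:
        raise ValueError(f"unknown kernel {cfg.kind!r}")
    if cfg.centered:
        t = k.shape[0]
        h = np.eye(t) - np.ones((t, t)) / t
        k = h @ k @ h
    return k


def fit_kcca(
    x: ChannelTimeSeries,
    y: ChannelTimeSeries,
    k: int = 1,
    kernels: tuple[KernelConfig, KernelConfig] | None = None,
) -> DecompositionModel:
    """Kernel CCA in the dual: maximize ``a' Kx Ky b`` under
    ``a' (Kx^2 + ridge I) a = b' (Ky^2 + ridge I) b = 1``.

    Dual coefficients are returned in place of channel filters (see
    ``extras``); projections for new samples go through the kernel against
    the stored training samples.  The ridge is scaled by ``tr(K^2)/T`` so the
    nominal value is unit-free.
    """
    kx_cfg, ky_cfg = kernels or (KernelConfig(), KernelConfig())
    xd = x.data - x.data.mean(axis=1, keepdims=True)
    yd = y.data - y.data.mean(axis=1, keepdims=True)
    kx = _kernel_matrix(xd, kx_cfg)
    ky = _kernel_matrix(yd, ky_cfg)
    t = kx.shape[0]

    def reg(km: np.ndarray, ridge: float) -> np.ndarray:
        k2 = km @ km
        scale = np.trace(k2) / t
        return k2 + ridge * scale * np.eye(t)

    rx_is = _inv_sqrt(reg(kx, kx_cfg.ridge))
    ry_is = _inv_sqrt(reg(ky, ky_cfg.ridge))
    u, s, vt = np.linalg.svd(rx_is @ kx @ ky @ ry_is)
    alpha = rx_is @ u[:, :k]
    beta = ry_is @ vt[:k].T
    corr = np.clip(s[:k], 0.0, None)
    # dual coefficients stand in for filters; patterns are undefined in the dual
    filters = FilterSet(wx=alpha, wy=beta, constraint_mode="identity")
    return DecompositionModel(
        method="kcca",
        filters=filters,
        patterns=None,
        correlations=corr,
        constraint_mode="identity",
        extras={
            "dual": True,
            "alpha": alpha,
            "beta": beta,
            "kernel_x": kx_cfg,
            "kernel_y": ky_cfg,
            "x_train": xd,
            "y_train": yd,
        },
    )


def kcca_project(
    model: DecompositionModel, new: ChannelTimeSeries, side: Literal["x", "y"] = "x"
) -> np.ndarray:
    """Project new samples onto kCCA variates via kernels against training data."""
    if not model.extras.get("dual"):
        raise ValueError("model does not carry dual kCCA coefficients")
    cfg = model.extras["kernel_x" if side == "x" else "kernel_y"]
    train = model.extras["x_train" if side == "x" else "y_train"]
    coef = model.extras["alpha" if side == "x" else "beta"]
    nd = new.data - new.data.mean(axis=1, keepdims=True)
    if cfg.kind == "linear":
        kn = nd.T @ train
    elif cfg.kind == "polynomial":
        kn = (1.0 + nd.T @ train) ** cfg.degree
    else:
        d2 = (
            (nd.T**2).sum(1)[:, None]
            + (train.T**2).sum(1)[None, :]
            - 2 * nd.T @ train
        )
        bw = cfg.bandwidth
        if bw is None:
            full = squareform(pdist(train.T, metric="sqeuclidean"))
            med = np.median(squareform(full))
            bw = np.sqrt(med) if med > 0 else 1.0
        kn = np.exp(-d2 / (2 * bw**2))
    if cfg.centered:
        t = train.shape[1]
        kfull = _kernel_matrix(train, KernelConfig(kind=cfg.kind, bandwidth=cfg.bandwidth, degree=cfg.degree, ridge=cfg.ridge, centered=False))
        kn = kn - kn.mean(axis=1, keepdims=True) - kfull.mean(axis=0)[None, :] + kfull.mean()
    return (kn @ coef).T


def fit_mcca(
    datasets: Sequence[ChannelTimeSeries],
    cfg: MultisetConfig | None = None,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> DecompositionModel:
    """Multiset CCA with the SUMCOR objective.

    Alternating per-dataset updates ``w_i <- C_i^{-1} sum_j C_ij w_j`` under
    ``w_i' C_i w_i = 1``; SUMCOR is non-decreasing across sweeps.  With two
    datasets this reduces to standard CCA.  Additional components are
    obtained by deflation with plain filter-space orthogonality.
    """
    cfg = cfg or MultisetConfig()
    d = len(datasets)
    if d < 2:
        raise ValueError("need at least 2 datasets")
    t = datasets[0].n_samples
    if any(ds.n_samples != t for ds in datasets):
        raise ValueError("all datasets must have equal sample counts")
    if any(ds.n_channels < cfg.k for ds in datasets):
        raise ValueError(f"every dataset needs at least k={cfg.k} channels")

    xs = [ds.data - ds.data.mean(axis=1, keepdims=True) for ds in datasets]
    covs = [shrink_cov(xd @ xd.T / t, shrinkage) for xd in xs]
    cross = {
        (i, j): xs[i] @ xs[j].T / t for i in range(d) for j in range(d) if i != j
    }
    cov_inv = [np.linalg.inv(c) for c in covs]

    ws: list[list[np.ndarray]] = [[] for _ in range(d)]
    sumcors = []
    history_all = []
    n_iter_total = 0
    for comp in range(cfg.k):
        # deterministic init: leading SVD pair of the (0,1) cross-covariance
        u, _, vt = np.linalg.svd(cross[(0, 1)])
        w = [u[:, min(comp, u.shape[1] - 1)].copy() for _ in range(d)]
        w[1] = vt[min(comp, vt.shape[0] - 1)].copy()
        for i in range(d):
            if i > 1:
                w[i] = np.ones(datasets[i].n_channels)
            w[i] = _orth_project(w[i], ws[i])
            w[i] = w[i] / np.sqrt(max(w[i] @ covs[i] @ w[i], 1e-30))
        obj_prev = -np.inf
        history = []
        for it in range(1, cfg.max_iter + 1):
            for i in range(d):
                target = np.zeros(datasets[i].n_channels)
                for j in range(d):
                    if j != i:
                        target += cross[(i, j)] @ w[j]
                wi = cov_inv[i] @ target
                wi = _orth_project(wi, ws[i])
                nrm = np.sqrt(max(wi @ covs[i] @ wi, 1e-30))
                if nrm > 1e-15:
                    w[i] = wi / nrm
            obj = _sumcor(w, cross, covs, cfg.objective)
            history.append(obj)
            if obj - obj_prev < cfg.tol * max(1.0, abs(obj)):
                break
            obj_prev = obj
        n_iter_total += it
        history_all.extend(history)
        for i in range(d):
            ws[i].append(w[i])
        pair_corrs = [
            _pair_corr(w[i], w[j], cross[(i, j)], covs[i], covs[j])
            for i in range(d)
            for j in range(i + 1, d)
        ]
        sumcors.append(float(np.mean(pair_corrs)))

    wmats = [np.column_stack(ws[i]) for i in range(d)]
    filters = FilterSet(wx=wmats[0], wy=wmats[1], constraint_mode="covariance")
    cov01 = CovarianceSet(cx=covs[0], cy=covs[1], cxy=cross[(0, 1)])
    patterns = estimate_patterns(filters, cov01)
    model = DecompositionModel(
        method="mcca",
        filters=filters,
        patterns=patterns,
        correlations=np.asarray(sumcors),
        n_iter=n_iter_total,
        objective_history=np.asarray(history_all),
        constraint_mode="covariance",
        extras={
            "all_filters": wmats,
            "covariances": covs,
            "cross_covariances": cross,
            "objective": cfg.objective,
        },
    )
    return model


def _orth_project(w: np.ndarray, prev: Sequence[np.ndarray]) -> np.ndarray:
    for p in prev:
        pn = p / np.linalg.norm(p)
        w = w - (w @ pn) * pn
    return w


def _pair_corr(wi, wj, cij, ci, cj) -> float:
    num = abs(float(wi @ cij @ wj))
    den = np.sqrt(float(wi @ ci @ wi) * float(wj @ cj @ wj))
    return num / den if den > 0 else 0.0


def _sumcor(w, cross, covs, objective: str) -> float:
    d = len(w)
    total = 0.0
    for i in range(d):
        for j in range(d):
            if i != j:
                v = float(w[i] @ cross[(i, j)] @ w[j])
                total += v**2 if objective == "SSQCOR" else v
    return total


def fit_ssmcca(
    datasets: Sequence[ChannelTimeSeries],
    cfg: MultisetConfig | None = None,
    penalties: Sequence[PenaltyConfig] | None = None,
    graphs: Sequence[ChannelGraph | None] | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> DecompositionModel:
    """Structured-sparse multiset CCA.

    Maximizes ``sum_{i != j} |w_i' C_ij w_j|`` under unit-norm filters with
    per-dataset L1 and graph-Laplacian penalties (Lagrangian form; the
    within-set covariance constraints are identity-substituted).  Alternating
    soft-thresholded updates; the recorded objective history is monotone
    (the solver stops rather than accept a decreasing step).
    """
    cfg = cfg or MultisetConfig()
    d = len(datasets)
    if d < 2:
        raise ValueError("need at least 2 datasets")
    t = datasets[0].n_samples
    if any(ds.n_samples != t for ds in datasets):
        raise ValueError("all datasets must have equal sample counts")
    pens = list(penalties) if penalties is not None else [PenaltyConfig()] * d
    gs = list(graphs) if graphs is not None else [None] * d
    for i, (p, g) in enumerate(zip(pens, gs)):
        if p.graph_x > 0 and (g is None or g.n != datasets[i].n_channels):
            raise ValueError(f"dataset {i}: graph penalty requires matching Laplacian")

    xs = [ds.data - ds.data.mean(axis=1, keepdims=True) for ds in datasets]
    cross = {
        (i, j): xs[i] @ xs[j].T / t for i in range(d) for j in range(d) if i != j
    }
    covs = [shrink_cov(xd @ xd.T / t, DEFAULT_SHRINKAGE) for xd in xs]

    ws: list[list[np.ndarray]] = [[] for _ in range(d)]
    scores = []
    history_all = []
    converged = True
    n_iter_total = 0
    for comp in range(cfg.k):
        u, _, vt = np.linalg.svd(cross[(0, 1)])
        w = []
        for i in range(d):
            if i == 0:
                wi = u[:, min(comp, u.shape[1] - 1)].copy()
            elif i == 1:
                wi = vt[min(comp, vt.shape[0] - 1)].copy()
            else:
                wi = np.ones(datasets[i].n_channels)
            wi = _orth_project(wi, ws[i])
            w.append(wi / np.linalg.norm(wi))
        obj_prev = -np.inf
        history = []
        comp_converged = False
        for it in range(1, max_iter + 1):
            w_new = [wi.copy() for wi in w]
            for i in range(d):
                target = np.zeros(datasets[i].n_channels)
                for j in range(d):
                    if j != i:
                        sgn = np.sign(w_new[i] @ cross[(i, j)] @ w_new[j]) or 1.0
                        target += sgn * (cross[(i, j)] @ w_new[j])
                lap = gs[i].laplacian if gs[i] is not None else None
                wi = _penalized_update(
                    target, pens[i].l1_x, pens[i].l2_x, pens[i].graph_x, lap, w_new[i]
                )
                wi = _orth_project(wi, ws[i])
                nrm = np.linalg.norm(wi)
                if nrm > 1e-15:
                    w_new[i] = wi / nrm
            obj = _abs_sumcor(w_new, cross)
            if obj < obj_prev - 1e-12:
                comp_converged = True
                break
            w = w_new
            history.append(obj)
            if obj - obj_prev < tol * max(1.0, abs(obj)):
                comp_converged = True
                obj_prev = obj
                break
            obj_prev = obj
        if not comp_converged:
            converged = False
            warnings.warn(
                f"ssmCCA did not converge in {max_iter} iterations",
                RuntimeWarning,
                stacklevel=2,
            )
        n_iter_total += it
        history_all.extend(history)
        for i in range(d):
            ws[i].append(w[i])
        scores.append(history[-1] if history else 0.0)

    wmats = [np.column_stack(ws[i]) for i in range(d)]
    filters = FilterSet(wx=wmats[0], wy=wmats[1], constraint_mode="identity")
    cov01 = CovarianceSet(cx=covs[0], cy=covs[1], cxy=cross[(0, 1)])
    patterns = estimate_patterns(filters, cov01)
    return DecompositionModel(
        method="ssmcca",
        filters=filters,
        patterns=patterns,
        correlations=np.asarray(scores),
        converged=converged,
        n_iter=n_iter_total,
        objective_history=np.asarray(history_all),
        constraint_mode="identity",
        extras={"all_filters": wmats, "penalties": pens},
    )


def _abs_sumcor(w, cross) -> float:
    d = len(w)
    return float(
        sum(
            abs(w[i] @ cross[(i, j)] @ w[j])
            for i in range(d)
            for j in range(d)
            if i != j
        )
    )


def fit_tcca(
    x: ChannelTimeSeries,
    y: ChannelTimeSeries,
    k: int = 1,
    lags: EmbeddingConfig | None = None,
    penalties: PenaltyConfig | None = None,
    graphs: tuple[ChannelGraph | None, ChannelGraph | None] | None = None,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> DecompositionModel:
    """Temporally embedded CCA.

    ``x`` (the fast modality, EEG bandpower in the benchmark) is embedded
    with time-shifted copies so that delayed coupling with ``y`` becomes an
    instantaneous one; any regularized-CCA variant is then fitted on the
    embedded data.  The x-side filter is reported both flat (``P*Nx``) and
    reshaped (``Nx x P``) in ``extras``; a graph supplied for the x side is
    expanded block-diagonally across lag blocks.
    """
    cfg = lags or EmbeddingConfig(lags=[1.0, 2.0, 3.0, 4.0])
    x_emb = temporal_embed(x, cfg)
    nx, p = x.n_channels, cfg.n_lags
    gx = gy = None
    if graphs is not None:
        gx, gy = graphs
    if gx is not None and gx.n == nx:
        gx = ChannelGraph(
            adjacency=np.kron(np.eye(p), gx.adjacency), rule=gx.rule, param=gx.param
        )
    pen = penalties or PenaltyConfig()
    model = fit_regularized_cca(
        x_emb, y, k=k, penalties=pen, graphs=(gx, gy), shrinkage=shrinkage
    )
    model.method = "tcca"
    wx_flat = model.filters.wx
    model.extras["embedding"] = cfg
    model.extras["wx_flat"] = wx_flat
    model.extras["wx_lagged"] = wx_flat.reshape(p, nx, -1).transpose(1, 0, 2)
    ax_flat = model.patterns.ax
    ax_lagged = ax_flat.reshape(p, nx, -1).transpose(1, 0, 2)
    model.extras["ax_lagged"] = ax_lagged
    # dominant lag block per component (by pattern-block norm)
    block_norms = np.linalg.norm(ax_lagged, axis=0)  # p x k
    model.extras["dominant_lag"] = np.asarray(
        [cfg.lags[int(np.argmax(block_norms[:, c]))] for c in range(block_norms.shape[1])]
    )
    # spatial (per-channel) pattern: dominant lag block
    model.extras["ax_spatial"] = np.column_stack(
        [
            ax_lagged[:, int(np.argmax(block_norms[:, c])), c]
            for c in range(block_norms.shape[1])
        ]
    )
    return model
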