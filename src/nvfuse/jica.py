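"""Joint ICA on subject-by-feature matrices concatenated across modalities.

jICA assumes the group-level generative model ``D = G V'`` where
``D = [Dx, Dy]`` stacks the per-subject EEG and fNIRS feature vectors
side by side, the columns of ``V`` are statistically independent
multimodal profiles, and ``G`` holds per-subject loadings that are shared
across both modality blocks of each profile.  A standard fixed-point ICA
(tanh contrast, symmetric decorrelation, PCA whitening) extracts the
profiles, which are then split back by modality provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning


@dataclass
class SubjectFeatureMatrix:
    """Per-modality subject-by-feature matrices and their concatenation."""

    dx: np.ndarray
    dy: np.ndarray
    feature_labels_x: list[str] = field(default_factory=list)
    feature_labels_y: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dx = np.atleast_2d(np.asarray(self.dx, dtype=float))
        self.dy = np.atleast_2d(np.asarray(self.dy, dtype=float))
        if self.dx.shape[0] != self.dy.shape[0]:
            raise ValueError(
                f"subject counts differ: {self.dx.shape[0]} vs {self.dy.shape[0]}"
            )
        if not (np.all(np.isfinite(self.dx)) and np.all(np.isfinite(self.dy))):
            raise ValueError("feature matrices must be finite")
        if not self.feature_labels_x:
            self.feature_labels_x = [f"x{i}" for i in range(self.dx.shape[1])]
        if not self.feature_labels_y:
            self.feature_labels_y = [f"y{i}" for i in range(self.dy.shape[1])]

    @property
    def n_subjects(self) -> int:
        return self.dx.shape[0]

    @property
    def d(self) -> np.ndarray:
        """Column-concatenated multimodal feature matrix [Ns x (Nx+Ny)]."""
        return np.concatenate([self.dx, self.dy], axis=1)

    @property
    def modality_mask(self) -> np.ndarray:
        """Boolean mask, True where a concatenated feature belongs to x."""
        return np.concatenate(
            [np.ones(self.dx.shape[1], bool), np.zeros(self.dy.shape[1], bool)]
        )


@dataclass
class JicaModel:
    """Fitted jICA decomposition ``D ~= G V'`` with per-modality profile splits."""

    mixing: np.ndarray  # G: Ns x K
    profiles: np.ndarray  # V: (Nx+Ny) x K, unit-norm columns
    profiles_x: np.ndarray
    profiles_y: np.ndarray
    k: int
    seed: int
    n_iter: int
    converged: bool
    reconstruction_error: float  # ||D - G V'||_F / ||D||_F (centered D)
    feature_means: np.ndarray
    feature_scales: np.ndarray


def fit_jica(
    data: SubjectFeatureMatrix,
    k: int,
    seed: int = 0,
    normalize: bool = True,
    max_iter: int = 1000,
    tol: float = 1e-7,
) -> JicaModel:
    """Run joint ICA on the concatenated subject-by-feature matrix.

    Features are centered (and by default z-scored so neither modality
    dominates by scale); the independent directions are the feature profiles
    ``v_i``.  Deterministic given ``seed``.
    """
    d = data.d
    ns, nf = d.shape
    if k > min(ns, nf):
        raise ValueError(f"k={k} exceeds min(Ns, Nx+Ny) = {min(ns, nf)}")
    means = d.mean(axis=0)
    dc = d - means
    if normalize:
        scales = dc.std(axis=0)
        scales[scales == 0] = 1.0
    else:
        scales = np.ones(nf)
    dn = dc / scales
    rank = np.linalg.matrix_rank(dn)
    if k > rank:
        raise ValueError(f"k={k} exceeds data rank {rank}")

    ica = FastICA(
        n_components=k,
        fun="logcosh",
        algorithm="parallel",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        # independence is assumed across the feature axis: samples = features
        v = ica.fit_transform(dn.T)  # (Nx+Ny) x K
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            warnings.warn(
                "jICA FastICA did not converge; model flagged", RuntimeWarning,
                stacklevel=2,
            )
    g = ica.mixing_  # Ns x K
    # map profiles back to original feature units (undo the z-scoring),
    # then normalize to unit norm, absorbing scale into G
    if normalize:
        v = v * scales[:, None]
    norms = np.linalg.norm(v, axis=0)
    norms[norms == 0] = 1.0
    v = v / norms
    g = g * norms
    # FastICA centers its samples (= features) per subject; ica.mean_ is that
    # per-subject offset and belongs in the reconstruction
    if normalize:
        recon_full = g @ v.T + np.outer(ica.mean_, scales)
        err = float(
            np.linalg.norm(dc - recon_full) / max(np.linalg.norm(dc), 1e-300)
        )
    else:
        recon_full = g @ v.T + ica.mean_[:, None]
        err = float(
            np.linalg.norm(dn - recon_full) / max(np.linalg.norm(dn), 1e-300)
        )
    nx = data.dx.shape[1]
    return JicaModel(
        mixing=g,
        profiles=v,
        profiles_x=v[:nx],
        profiles_y=v[nx:],
        k=k,
        seed=seed,
        n_iter=int(getattr(ica, "n_iter_", 0)),
        converged=converged,
        reconstruction_error=err,
        feature_means=means,
        feature_scales=scales,
    )


def read_subject_feature_table(
    path: str | Path,
    modality_map: dict[str, str] | str | Path,
    subject_column: str = "subject",
) -> SubjectFeatureMatrix:
    """Read a subject-by-feature CSV/TSV with a modality column map.

    ``modality_map`` maps feature-column names to ``"x"`` (EEG) or ``"y"``
    (fNIRS); it may also be a path to a two-column CSV sidecar
    (``feature,modality``).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table = pd.read_csv(path, sep=sep)
    if isinstance(modality_map, (str, Path)):
        side = pd.read_csv(modality_map)
        modality_map = dict(zip(side.iloc[:, 0], side.iloc[:, 1]))
    if subject_column in table.columns:
        table = table.drop(columns=[subject_column])
    x_cols = [c for c in table.columns if modality_map.get(c) == "x"]
    y_cols = [c for c in table.columns if modality_map.get(c) == "y"]
    unknown = [c for c in table.columns if c not in x_cols + y_cols]
    if unknown:
        raise ValueError(f"columns without modality assignment: {unknown}")
    return SubjectFeatureMatrix(
        dx=table[x_cols].to_numpy(float),
        dy=table[y_cols].to_numpy(float),
        feature_labels_x=x_cols,
        feature_labels_y=y_cols,
    )
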