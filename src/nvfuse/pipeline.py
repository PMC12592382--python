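"""Preprocessing, epoching, splitting, evaluation and the benchmark loop.

The evaluation protocol mirrors a train/test source-recovery study: simulate
a session at a given SNR, preprocess (fNIRS: 0.01-0.6 Hz band-pass, linear
detrend, 2 Hz resampling; EEG: alpha band-pass plus per-segment variance
giving a 2 Hz bandpower series), cut trials of 8 s pre + 10 s stimulus +
8 s post, split trials 80/20 into train (concatenated in time) and test,
fit each method on the train set only, and report per-test-trial absolute
Pearson correlations between reconstructed and ground-truth sources and
between estimated and true spatial patterns.  Correlations are aggregated
with Fisher's z transform (mean and back-transformed standard error).
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .cca import (
    PenaltyConfig,
    build_channel_graph,
    fit_cca,
    fit_tcca,
)
from .core import (
    ChannelTimeSeries,
    DecompositionModel,
    EmbeddingConfig,
    bandpower_series,
    temporal_embed,
)
from .mspoc import MspocConfig, fit_mspoc
from .simulate import (
    MontageGeometry,
    SimulatedSession,
    assemble_dataset,
    make_montage,
    make_spatial_patterns,
    make_trial_schedule,
    simulate_background,
    simulate_sources,
)

logger = logging.getLogger(__name__)

METRICS = ("corr_sx", "corr_sy", "corr_ax", "corr_ay")

#: Methods available to the benchmark loop.
BENCHMARK_METHODS = (
    "cca",
    "tcca",
    "ridge-tcca",
    "sparse-tcca",
    "elasticnet-tcca",
    "ss-tcca",
    "mspoc",
)


def preprocess_fnirs(
    y: ChannelTimeSeries,
    band_hz: tuple[float, float] = (0.01, 0.6),
    out_rate: float = 2.0,
) -> ChannelTimeSeries:
    """Zero-phase 0.01-0.6 Hz band-pass, linear detrend, resample to 2 Hz."""
    if y.rate <= 2 * band_hz[1]:
        raise ValueError(f"rate {y.rate} too low for band {band_hz}")
    sos = sps.butter(2, band_hz, btype="bandpass", fs=y.rate, output="sos")
    if y.n_samples < 50:
        raise ValueError(
            f"series too short for the band-pass filter ({y.n_samples} samples)"
        )
    # maximal reflection padding: the 0.01 Hz high-pass has a ~100 s time
    # constant, so short pads leave visible edge transients
    data = sps.sosfiltfilt(sos, y.data, axis=1, padlen=y.n_samples - 1)
    data = sps.detrend(data, axis=1, type="linear")
    frac = Fraction(out_rate / y.rate).limit_denominator(10000)
    data = sps.resample_poly(data, frac.numerator, frac.denominator, axis=1)
    return ChannelTimeSeries(data, out_rate, list(y.channel_ids), y.modality, y.t0)


def preprocess_eeg(
    x: ChannelTimeSeries,
    alpha_band_hz: tuple[float, float] = (8.0, 12.0),
    bp_window_s: float = 0.5,
) -> tuple[ChannelTimeSeries, ChannelTimeSeries]:
    """Alpha band-pass plus windowed bandpower (effective 2 Hz at 0.5 s).

    Returns ``(x_alpha, x_bandpower)``: mSPoC consumes the band-passed series
    and its windows, the CCA family consumes the bandpower series.
    """
    if x.rate < 50:
        raise ValueError(f"EEG rate {x.rate} too low for alpha filtering")
    sos = sps.butter(4, alpha_band_hz, btype="bandpass", fs=x.rate, output="sos")
    data = sps.sosfiltfilt(sos, x.data, axis=1)
    x_alpha = ChannelTimeSeries(data, x.rate, list(x.channel_ids), "eeg", x.t0)
    x_bp = bandpower_series(x_alpha, bp_window_s)
    return x_alpha, x_bp


@dataclass
class TrialEpochs:
    """Aligned per-trial segments for several named series."""

    series: dict[str, list[ChannelTimeSeries]]
    trial_indices: list[int]
    pre_s: float
    stim_s: float
    post_s: float
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.trial_indices)

    def subset(self, idx: Sequence[int]) -> "TrialEpochs":
        return TrialEpochs(
            series={k: [v[i] for i in idx] for k, v in self.series.items()},
            trial_indices=[self.trial_indices[i] for i in idx],
            pre_s=self.pre_s,
            stim_s=self.stim_s,
            post_s=self.post_s,
        )


def epoch_trials(
    series: dict[str, ChannelTimeSeries],
    onsets_s: np.ndarray,
    stim_s: float = 10.0,
    pre_s: float = 8.0,
    post_s: float = 8.0,
) -> TrialEpochs:
    """Cut every series into pre + stimulus + post trials around each onset.

    Trials exceeding any series' bounds are dropped with a warning; the drop
    count is recorded.  All trials of a series have identical length.
    """
    kept: list[int] = []
    cuts: dict[str, list[ChannelTimeSeries]] = {k: [] for k in series}
    lengths = {
        k: int(round((pre_s + stim_s + post_s) * v.rate)) for k, v in series.items()
    }
    n_dropped = 0
    for ti, onset in enumerate(np.atleast_1d(onsets_s)):
        ok = True
        starts = {}
        for k, v in series.items():
            start = int(round((onset - pre_s - v.t0) * v.rate))
            if start < 0 or start + lengths[k] > v.n_samples:
                ok = False
                break
            starts[k] = start
        if not ok:
            n_dropped += 1
            continue
        kept.append(ti)
        for k, v in series.items():
            cuts[k].append(v.crop(starts[k], starts[k] + lengths[k]))
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} trial(s) exceeding recording bounds",
            RuntimeWarning,
            stacklevel=2,
        )
    return TrialEpochs(
        series=cuts,
        trial_indices=kept,
        pre_s=pre_s,
        stim_s=stim_s,
        post_s=post_s,
        n_dropped=n_dropped,
    )


def split_trials(
    epochs: TrialEpochs,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[dict[str, ChannelTimeSeries], TrialEpochs, list[int], list[int]]:
    """Random train/test split of trials; train concatenated along time.

    ``n_train = round-half-up(train_fraction * n)``, clamped so at least one
    trial lands on each side (12 trials at 0.8 give the 10/2 split).
    """
    n = epochs.n_trials
    if n < 2:
        raise ValueError("need at least 2 trials to split")
    n_train = int(np.floor(train_fraction * n + 0.5))
    n_train = max(1, min(n - 1, n_train))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = sorted(perm[:n_train].tolist())
    test_idx = sorted(perm[n_train:].tolist())
    train = {}
    for k, segs in epochs.series.items():
        data = np.concatenate([segs[i].data for i in train_idx], axis=1)
        proto = segs[0]
        train[k] = ChannelTimeSeries(
            data, proto.rate, list(proto.channel_ids), proto.modality, 0.0
        )
    return train, epochs.subset(test_idx), train_idx, test_idx


def fisher_average(values: Sequence[float]) -> tuple[float, float]:
    """Bias-corrected mean of correlations via Fisher's z transform.

    Returns ``(tanh(mean(atanh r)), tanh(sem_z))`` where ``sem_z`` is the
    standard error of the mean in z-space (0 for a single value).
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("fisher_average of an empty list")
    clip = 1.0 - 1e-12
    if np.any(np.abs(vals) >= 1.0):
        warnings.warn(
            "|r| >= 1 clipped before Fisher transform", RuntimeWarning, stacklevel=2
        )
        vals = np.clip(vals, -clip, clip)
    z = np.arctanh(vals)
    mean = float(np.tanh(z.mean()))
    if vals.size < 2:
        return mean, 0.0
    sem = float(z.std(ddof=1) / np.sqrt(vals.size))
    return mean, float(np.tanh(sem))


def _abs_corr(a: np.ndarray, b: np.ndarray) -> float | None:
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    n = min(a.size, b.size)
    a, b = a[:n], b[:n]
    if a.std() == 0 or b.std() == 0:
        return None
    return float(abs(np.corrcoef(a, b)[0, 1]))


@dataclass
class MethodSpec:
    """How the benchmark fits and applies one method."""

    name: str
    fit: Callable[[dict[str, ChannelTimeSeries]], DecompositionModel]
    x_series: str  # series name feeding the x side at test time
    gt_x: str  # ground-truth series compared against s_hat_x
    embed: EmbeddingConfig | None = None


def _tcca_penalties(name: str) -> PenaltyConfig:
    if name == "tcca":
        return PenaltyConfig()
    if name == "ridge-tcca":
        return PenaltyConfig(l2_x=0.8, l2_y=0.8)
    if name == "sparse-tcca":
        return PenaltyConfig(l1_x=0.2, l1_y=0.2)
    if name == "elasticnet-tcca":
        return PenaltyConfig(l1_x=0.2, l1_y=0.2, l2_x=0.8, l2_y=0.8)
    if name == "ss-tcca":
        return PenaltyConfig(l1_x=0.2, l1_y=0.2, graph_x=0.8, graph_y=0.8)
    raise ValueError(f"unknown tCCA variant {name!r}")


def make_method_specs(
    methods: Sequence[str],
    geom: MontageGeometry,
    lags_s: Sequence[float] = (1.0, 2.0, 3.0, 4.0),
    graph_threshold_fnirs_mm: float = 25.0,
    graph_threshold_eeg_mm: float = 60.0,
    mspoc_config: MspocConfig | None = None,
) -> list[MethodSpec]:
    """Resolve method names into fit/apply recipes (default study settings).

    Regularization defaults: L1 0.2, L2 0.8, graph 0.8 with binary
    distance-threshold adjacencies (25 mm fNIRS, 60 mm EEG); tCCA lags 1-4 s
    in 1 s steps; mSPoC with L2 0.8 on the EEG filter and PCA at 0.99
    explained variance.
    """
    unknown = [m for m in methods if m not in BENCHMARK_METHODS]
    if unknown:
        raise ValueError(
            f"unknown method(s) {unknown}; registered: {list(BENCHMARK_METHODS)}"
        )
    embed = EmbeddingConfig(lags=list(lags_s))
    graph_eeg = build_channel_graph(
        geom.eeg_positions, "distance_threshold", graph_threshold_eeg_mm
    )
    graph_fnirs = build_channel_graph(
        geom.channel_midpoints(), "distance_threshold", graph_threshold_fnirs_mm
    )
    specs: list[MethodSpec] = []
    for name in methods:
        if name == "cca":
            specs.append(
                MethodSpec(
                    name,
                    fit=lambda tr: fit_cca(tr["x_bp"], tr["y"], k=1),
                    x_series="x_bp",
                    gt_x="sx_bp",
                )
            )
        elif name == "mspoc":
            cfg = mspoc_config or MspocConfig()
            specs.append(
                MethodSpec(
                    name,
                    fit=lambda tr, c=cfg: fit_mspoc(tr["x_alpha"], tr["y"], c),
                    x_series="x_alpha",
                    gt_x="sx",
                )
            )
        else:
            pen = _tcca_penalties(name)
            graphs = (graph_eeg, graph_fnirs) if name == "ss-tcca" else None
            specs.append(
                MethodSpec(
                    name,
                    fit=lambda tr, p=pen, g=graphs, e=embed: fit_tcca(
                        tr["x_bp"], tr["y"], k=1, lags=e, penalties=p, graphs=g
                    ),
                    x_series="x_bp",
                    gt_x="sx_bp",
                    embed=embed,
                )
            )
    return specs


def evaluate_model(
    model: DecompositionModel,
    test: TrialEpochs,
    spec: MethodSpec,
    true_ax: np.ndarray,
    true_ay: np.ndarray,
) -> list[dict]:
    """Per-test-trial absolute correlations of sources and patterns.

    Pattern correlations are trial-independent but repeated per trial for a
    uniform long table.  Zero-variance reconstructions yield missing values
    with a warning.
    """
    if model.train_tag != "train":
        raise ValueError("model was not fitted on a designated train set")
    if spec.name == "mspoc" or spec.embed is None:
        ax_hat = model.ax[:, 0] if model.ax is not None else None
    else:
        ax_hat = model.extras["ax_spatial"][:, 0]
    ay_hat = model.ay[:, 0] if model.ay is not None else None
    corr_ax = _abs_corr(ax_hat, true_ax) if ax_hat is not None else None
    corr_ay = _abs_corr(ay_hat, true_ay) if ay_hat is not None else None

    records = []
    for i, trial in enumerate(test.trial_indices):
        x_seg = test.series[spec.x_series][i]
        if spec.embed is not None:
            x_seg = temporal_embed(x_seg, spec.embed)
        sx_hat = model.wx[:, 0] @ x_seg.data
        gt_x = test.series[spec.gt_x][i].data[0]
        if spec.embed is not None:
            # an embedded reconstruction estimates the source delayed by the
            # learned lag; align the ground truth before correlating so the
            # metric measures recovery, not the delay itself
            lag_s = float(model.extras["dominant_lag"][0])
            n_lag = int(round(lag_s * test.series[spec.gt_x][i].rate))
            if n_lag > 0:
                sx_hat = sx_hat[n_lag:]
                gt_x = gt_x[:-n_lag]
        sy_hat = model.wy[:, 0] @ test.series["y"][i].data
        vals = {
            "corr_sx": _abs_corr(sx_hat, gt_x),
            "corr_sy": _abs_corr(sy_hat, test.series["sy"][i].data),
            "corr_ax": corr_ax,
            "corr_ay": corr_ay,
        }
        for metric, value in vals.items():
            if value is None:
                warnings.warn(
                    f"{spec.name}: zero-variance signal for {metric} in trial "
                    f"{trial}; recorded as missing",
                    RuntimeWarning,
                    stacklevel=2,
                )
            records.append({"trial": trial, "metric": metric, "value": value})
    return records


@dataclass
class BenchmarkConfig:
    """Full benchmark sweep settings (defaults mirror the study protocol)."""

    methods: Sequence[str] = BENCHMARK_METHODS
    snr_grid_db: Sequence[float] = field(
        default_factory=lambda: np.linspace(-25.0, 10.0, 20).tolist()
    )
    n_simulations: int = 50
    seed: int = 0
    n_trials: int = 12
    train_fraction: float = 0.8
    lags_s: Sequence[float] = (1.0, 2.0, 3.0, 4.0)
    pre_s: float = 8.0
    post_s: float = 8.0
    eeg_rate: float = 250.0
    fnirs_rate: float = 12.6
    mspoc_config: MspocConfig | None = None


@dataclass
class BenchmarkResult:
    """Long-format per-trial table plus Fisher-aggregated summaries."""

    records: pd.DataFrame
    aggregates: pd.DataFrame
    config: dict
    failures: list[dict] = field(default_factory=list)

    def to_csv(self, records_path, aggregates_path=None) -> None:
        self.records.to_csv(records_path, index=False)
        if aggregates_path is not None:
            self.aggregates.to_csv(aggregates_path, index=False)


def aggregate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Fisher-average metric values per (method, snr_db, metric)."""
    rows = []
    grouped = records.dropna(subset=["value"]).groupby(
        ["method", "snr_db", "metric"], sort=True
    )
    for (method, snr, metric), grp in grouped:
        mean, err = fisher_average(grp["value"].to_numpy())
        rows.append(
            {
                "method": method,
                "snr_db": snr,
                "metric": metric,
                "fisher_mean": mean,
                "fisher_error": err,
                "n": len(grp),
            }
        )
    return pd.DataFrame(rows)


def prepare_session_inputs(
    session: SimulatedSession,
    pre_s: float = 8.0,
    post_s: float = 8.0,
) -> TrialEpochs:
    """Preprocess one session and epoch data plus aligned ground truth.

    Produces trials of the series: ``y`` (fNIRS at 2 Hz), ``x_alpha``
    (band-passed EEG), ``x_bp`` (EEG bandpower at 2 Hz), and the
    ground-truth counterparts ``sx`` (EEG-rate source), ``sx_bp`` (its
    bandpower) and ``sy`` (HbO source resampled to 2 Hz).
    """
    truth = session.truth
    y2 = preprocess_fnirs(session.y)
    x_alpha, x_bp = preprocess_eeg(session.x)
    sx_bp = bandpower_series(truth.sx, 0.5)
    frac = Fraction(2.0 / truth.sy.rate).limit_denominator(10000)
    sy2_data = sps.resample_poly(truth.sy.data, frac.numerator, frac.denominator, axis=1)
    sy2 = ChannelTimeSeries(sy2_data, 2.0, ["sy"], "fnirs-hbo", truth.sy.t0)
    onsets = truth.lead_in_s + truth.schedule.onsets
    return epoch_trials(
        {
            "y": y2,
            "x_alpha": x_alpha,
            "x_bp": x_bp,
            "sx": truth.sx,
            "sx_bp": sx_bp,
            "sy": sy2,
        },
        onsets,
        stim_s=truth.schedule.stim_s,
        pre_s=pre_s,
        post_s=post_s,
    )


def run_benchmark(
    config: BenchmarkConfig | None = None,
    progress: Callable[[str], None] | None = None,
    skip_cells: set[tuple[str, float, int]] | None = None,
    on_cell: Callable[[pd.DataFrame], None] | None = None,
) -> BenchmarkResult:
    """Run the full simulate -> preprocess -> fit -> evaluate sweep.

    The source spatial profiles and the background noise are fixed across
    simulations; each simulation draws fresh trial timing and source
    realizations, which are mixed at every SNR of the grid.  A failure in
    one (method, snr, simulation) cell is logged and isolated; it never
    aborts the sweep.  ``skip_cells`` supports resumable runs and
    ``on_cell`` streams per-cell records as they complete.
    """
    cfg = config or BenchmarkConfig()
    geom = make_montage()
    patterns = make_spatial_patterns(geom)
    specs = make_method_specs(
        cfg.methods, geom, lags_s=cfg.lags_s, mspoc_config=cfg.mspoc_config
    )

    master = np.random.SeedSequence(cfg.seed)
    bg_seed = int(master.generate_state(1)[0] & 0x7FFFFFFF)
    lead_in, tail = 12.0, 10.0
    max_duration = lead_in + cfg.n_trials * (10.0 + 16.0) + tail
    background = simulate_background(
        geom,
        duration_s=max_duration,
        seed=bg_seed,
        eeg_rate=cfg.eeg_rate,
        fnirs_rate=cfg.fnirs_rate,
    )

    all_records = []
    failures = []
    for sim in range(cfg.n_simulations):
        sim_seeds = np.random.SeedSequence([cfg.seed, 1 + sim]).generate_state(3)
        schedule = make_trial_schedule(
            n_trials=cfg.n_trials, seed=int(sim_seeds[0] & 0x7FFFFFFF)
        )
        truth = simulate_sources(
            schedule,
            eeg_rate=cfg.eeg_rate,
            fnirs_rate=cfg.fnirs_rate,
            seed=int(sim_seeds[1] & 0x7FFFFFFF),
            lead_in_s=lead_in,
            tail_s=tail,
        )
        split_seed = int(sim_seeds[2] & 0x7FFFFFFF)
        for snr in cfg.snr_grid_db:
            if not np.isfinite(snr):
                raise ValueError(f"non-finite SNR grid element: {snr}")
            session = assemble_dataset(
                truth, patterns, background, float(snr), geometry=geom
            )
            epochs = prepare_session_inputs(session, cfg.pre_s, cfg.post_s)
            train, test, _, _ = split_trials(
                epochs, cfg.train_fraction, seed=split_seed
            )
            for spec in specs:
                cell = (spec.name, float(snr), sim)
                if skip_cells and cell in skip_cells:
                    continue
                t_start = time.perf_counter()
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        model = spec.fit(train)
                        model.train_tag = "train"
                        recs = evaluate_model(
                            model,
                            test,
                            spec,
                            true_ax=patterns.ax[:, 0],
                            true_ay=patterns.ay[:, 0],
                        )
                except Exception as err:  # isolate the failing cell
                    logger.error(
                        "cell failed: method=%s snr=%.2f sim=%d: %s",
                        spec.name,
                        snr,
                        sim,
                        err,
                    )
                    failures.append(
                        {"method": spec.name, "snr_db": snr, "sim": sim,
                         "error": str(err)}
                    )
                    continue
                elapsed = time.perf_counter() - t_start
                frame = pd.DataFrame(recs)
                frame.insert(0, "method", spec.name)
                frame.insert(1, "snr_db", float(snr))
                frame.insert(2, "sim", sim)
                all_records.append(frame)
                if on_cell is not None:
                    on_cell(frame)
                logger.info(
                    "cell done: method=%s snr=%.2f sim=%d (%.2f s)",
                    spec.name, snr, sim, elapsed,
                )
                if progress is not None:
                    progress(f"{spec.name} snr={snr:+.1f} sim={sim}")
    records = (
        pd.concat(all_records, ignore_index=True)
        if all_records
        else pd.DataFrame(columns=["method", "snr_db", "sim", "trial", "metric", "value"])
    )
    aggregates = aggregate_records(records) if len(records) else pd.DataFrame()
    snapshot = {
        "methods": list(cfg.methods),
        "snr_grid_db": [float(s) for s in cfg.snr_grid_db],
        "n_simulations": cfg.n_simulations,
        "seed": cfg.seed,
        "n_trials": cfg.n_trials,
        "train_fraction": cfg.train_fraction,
        "lags_s": list(cfg.lags_s),
    }
    return BenchmarkResult(
        records=records, aggregates=aggregates, config=snapshot, failures=failures
    )
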