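"""Semi-synthetic HD-fNIRS-EEG motor-task simulator with ground truth.

The simulator emulates a single-subject finger-tapping-like session: a
shared latent source near the C3 scalp landmark produces task-locked
event-related desynchronization (ERD) of 8-12 Hz EEG activity and, coupled
to it, a canonical double-gamma hemodynamic (HbO) response whose per-trial
amplitude is proportional to the per-trial alpha-bandpower decrease.  Both
sources are projected to channel space through surrogate spatial patterns
(a signed bipolar dipole topography for EEG, a Gaussian activity mask over
fNIRS channel midpoints), normalized, and added to synthetic physiological
background noise at an exactly controlled SNR via the scaling factor gamma.

The geometry is a parametric surrogate: EEG electrode positions come from
the bundled standard 10-20 montage (32-channel actiCAP labels), and the
fNIRS probe is a bilateral triangular-lattice patch (19 mm pitch, so
nearest and next-nearest source-detector separations are 19 and ~33 mm)
whose source/detector site assignment reproduces 100 measurement channels
from 14 sources and 32 detectors.

The background model replaces a real resting-state recording: spatially
correlated 1/f noise per modality, an occipito-parietal alpha component for
EEG, and cardiac (~1.1 Hz), respiratory (~0.25 Hz) and Mayer-wave (~0.1 Hz)
systemic oscillations with a global share for fNIRS.

Every session is reconstructible bit-exactly from its manifest of seeds and
parameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import gamma as gamma_dist

from .core import ChannelTimeSeries, PatternSet

MANIFEST_SCHEMA_VERSION = 1

#: actiCAP 32-channel arrangement (standard 10-20 labels).
ACTICAP_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FT9", "FC5", "FC1", "FC2",
    "FC6", "FT10", "T7", "C3", "Cz", "C4", "T8", "TP9", "CP5", "CP1", "CP2",
    "CP6", "TP10", "P7", "P3", "Pz", "P4", "P8", "O1", "Oz", "O2",
]

# Triangular-lattice patch: row lengths and the lattice sites that carry
# light sources (remaining sites carry detectors).  This assignment yields
# exactly 50 measurement channels per hemisphere at 19 / 33 mm separations.
_PATCH_ROWS = (4, 5, 7, 7)
_PATCH_SOURCE_SITES = (10, 11, 12, 13, 14, 15, 17)
_LATTICE_PITCH_MM = 19.0


@dataclass
class MontageConfig:
    """Geometry knobs; the defaults reproduce the printed probe counts."""

    lattice_pitch_mm: float = _LATTICE_PITCH_MM
    rows: Sequence[int] = _PATCH_ROWS
    source_sites: Sequence[int] = _PATCH_SOURCE_SITES
    short_sep_band_mm: tuple[float, float] = (17.0, 21.0)
    long_sep_band_mm: tuple[float, float] = (31.0, 35.0)
    source_depth_fraction: float = 0.92  # ground-truth source: C3 scaled inward


@dataclass
class MontageGeometry:
    """EEG electrode and fNIRS optode/channel geometry (mm) with ground truth."""

    eeg_positions: np.ndarray
    eeg_labels: list[str]
    fnirs_sources: np.ndarray
    fnirs_detectors: np.ndarray
    channel_pairs: list[tuple[int, int, float]]
    source_location: np.ndarray

    @property
    def n_channels(self) -> int:
        return len(self.channel_pairs)

    def channel_midpoints(self) -> np.ndarray:
        return np.array(
            [
                0.5 * (self.fnirs_sources[s] + self.fnirs_detectors[d])
                for s, d, _ in self.channel_pairs
            ]
        )

    def channel_labels(self) -> list[str]:
        return [f"S{s + 1}-D{d + 1}" for s, d, _ in self.channel_pairs]


@dataclass
class TrialSchedule:
    """Stimulus onsets/durations and randomized recovery periods."""

    onsets: np.ndarray
    stim_s: float
    recoveries: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("trial onsets must be strictly increasing")
        gaps = np.diff(self.onsets)
        if np.any(gaps < self.stim_s):
            raise ValueError("trials overlap")

    @property
    def n_trials(self) -> int:
        return len(self.onsets)

    @property
    def total_duration(self) -> float:
        """Sum of stimulus plus recovery periods across trials."""
        return float(self.n_trials * self.stim_s + self.recoveries.sum())


@dataclass
class HRFModel:
    """Canonical double-gamma hemodynamic response kernel."""

    time_to_peak_s: float = 6.0
    undershoot_delay_s: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    onset_delay_s: float = 1.0  # hemodynamic delay relative to ERD onset
    duration_s: float = 32.0

    def kernel(self, rate: float) -> np.ndarray:
        """Finite-support kernel sampled at ``rate``, positive peak 1."""
        t = np.arange(0.0, self.duration_s, 1.0 / rate)
        # gamma pdf with scale 1 peaks at shape-1
        g1 = gamma_dist.pdf(t, a=self.time_to_peak_s + 1.0)
        g2 = gamma_dist.pdf(t, a=self.undershoot_delay_s + 1.0)
        h = g1 - self.undershoot_ratio * g2
        peak = h.max()
        if peak <= 0:
            raise ValueError("degenerate HRF parameters")
        return h / peak


@dataclass
class CouplingSpec:
    """ERD depth distribution and the ERD-to-HRF proportionality constant."""

    erd_depth_range: tuple[float, float] = (0.4, 0.8)
    amplitude_constant: float = 1.0
    alpha_band_hz: tuple[float, float] = (8.0, 12.0)

    def __post_init__(self) -> None:
        lo, hi = self.erd_depth_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("ERD depths must lie in (0, 1]")
        if not self.amplitude_constant > 0:
            raise ValueError("amplitude constant must be > 0")


@dataclass
class OscComponent:
    center_hz: float
    amplitude: float
    bandwidth_hz: float


@dataclass
class BackgroundModel:
    """Synthetic physiological background (surrogate resting-state data)."""

    eeg_exponent: float = 1.0
    eeg_oscillations: list[OscComponent] = field(
        default_factory=lambda: [OscComponent(10.0, 1.0, 2.0)]
    )
    fnirs_exponent: float = 1.0
    fnirs_oscillations: list[OscComponent] = field(
        default_factory=lambda: [
            OscComponent(1.1, 1.0, 0.15),   # cardiac
            OscComponent(0.25, 0.6, 0.05),  # respiration
            OscComponent(0.10, 0.9, 0.025),  # Mayer waves
        ]
    )
    global_share: float = 0.5
    spatial_smoothness_mm: float = 40.0

    def __post_init__(self) -> None:
        for e in (self.eeg_exponent, self.fnirs_exponent):
            if not 0.0 <= e <= 2.0:
                raise ValueError("1/f exponent must be in [0, 2]")
        for osc in list(self.eeg_oscillations) + list(self.fnirs_oscillations):
            if osc.amplitude < 0:
                raise ValueError("oscillation amplitudes must be >= 0")


@dataclass
class GroundTruth:
    """Simulated source time courses, schedule, and per-trial couplings."""

    sx: ChannelTimeSeries  # alpha-band EEG source
    sy: ChannelTimeSeries  # HbO source
    schedule: TrialSchedule
    erd_depths: np.ndarray
    bandpower_decreases: np.ndarray
    hrf_amplitudes: np.ndarray
    hrf: HRFModel
    coupling: CouplingSpec
    lead_in_s: float


@dataclass
class SimulatedSession:
    """A complete simulated recording with its ground truth and manifest."""

    x: ChannelTimeSeries
    y: ChannelTimeSeries
    truth: GroundTruth
    patterns: PatternSet
    geometry: MontageGeometry
    snr_db: float | None
    gamma_x: float
    gamma_y: float
    manifest: dict


def _patch_sites(rows: Sequence[int], pitch: float) -> np.ndarray:
    """Staggered triangular-lattice sites (2D, mm), centered on the origin."""
    h = pitch * np.sqrt(3) / 2
    pts = []
    for j, n in enumerate(rows):
        off = pitch / 2 if j % 2 else 0.0
        x0 = -(n - 1) * pitch / 2
        for i in range(n):
            pts.append((x0 + i * pitch + off, j * h))
    pts = np.asarray(pts)
    return pts - pts.mean(axis=0)


def _eeg_positions_mm() -> tuple[np.ndarray, list[str]]:
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    return np.array([pos[ch] for ch in ACTICAP_32]) * 1000.0, list(ACTICAP_32)


def _tangent_frame(p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = p / np.linalg.norm(p)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(n @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(ref, n)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v, n


def make_montage(config: MontageConfig | None = None) -> MontageGeometry:
    """Build the bilateral HD probe and EEG cap geometry.

    Two mirrored triangular-lattice patches are placed in the scalp tangent
    planes at the C3 and C4 electrodes; lattice sites are split into light
    sources and detectors by the configured assignment, and every
    source-detector pair whose separation falls in the short (19 +- 2 mm) or
    long (33 +- 2 mm) band becomes a measurement channel.  Deterministic.
    """
    cfg = config or MontageConfig()
    eeg_pos, eeg_labels = _eeg_positions_mm()
    sites2d = _patch_sites(cfg.rows, cfg.lattice_pitch_mm)
    src_sites = set(cfg.source_sites)
    if max(src_sites) >= len(sites2d):
        raise ValueError("source site index outside the lattice")

    sources, detectors = [], []
    for center_label in ("C3", "C4"):
        c = eeg_pos[eeg_labels.index(center_label)]
        u, v, _ = _tangent_frame(c)
        if center_label == "C4":  # mirror the patch for the right hemisphere
            u = -u
        for i, (a, b) in enumerate(sites2d):
            p = c + a * u + b * v
            (sources if i in src_sites else detectors).append(p)
    sources = np.asarray(sources)
    detectors = np.asarray(detectors)

    d = cdist(sources, detectors)
    lo1, hi1 = cfg.short_sep_band_mm
    lo2, hi2 = cfg.long_sep_band_mm
    pairs = [
        (s, det, float(d[s, det]))
        for s in range(len(sources))
        for det in range(len(detectors))
        if lo1 <= d[s, det] <= hi1 or lo2 <= d[s, det] <= hi2
    ]
    if not pairs:
        raise ValueError(
            "separation constraints produced no channels; montage infeasible"
        )
    c3 = eeg_pos[eeg_labels.index("C3")]
    return MontageGeometry(
        eeg_positions=eeg_pos,
        eeg_labels=eeg_labels,
        fnirs_sources=sources,
        fnirs_detectors=detectors,
        channel_pairs=pairs,
        source_location=c3 * cfg.source_depth_fraction,
    )


def make_spatial_patterns(
    geom: MontageGeometry,
    sigma_fnirs_mm: float = 15.0,
    sigma_eeg_mm: float = 40.0,
) -> PatternSet:
    """Surrogate spatial patterns centered on the common source location.

    EEG: a signed bipolar (dipole-like) topography, the tangential derivative
    of a Gaussian centered at the scalp point over the source.  fNIRS: a
    non-negative Gaussian activity mask over channel midpoints with
    ``sigma_fnirs_mm`` spread.  Both unit norm.
    """
    src = geom.source_location
    scalp = src / np.linalg.norm(src) * np.linalg.norm(
        geom.eeg_positions[geom.eeg_labels.index("C3")]
    )
    u, _, _ = _tangent_frame(scalp)
    rel = geom.eeg_positions - scalp
    r2 = (rel**2).sum(axis=1)
    ax = (rel @ u) / sigma_eeg_mm * np.exp(-r2 / (2 * sigma_eeg_mm**2))
    ax = ax / np.linalg.norm(ax)

    mids = geom.channel_midpoints()
    d2 = ((mids - src) ** 2).sum(axis=1)
    ay = np.exp(-d2 / (2 * sigma_fnirs_mm**2))
    ay = ay / np.linalg.norm(ay)
    return PatternSet(ax=ax[:, None], ay=ay[:, None])


def make_trial_schedule(
    n_trials: int = 12,
    stim_s: float = 10.0,
    recovery_range: tuple[float, float] = (8.0, 16.0),
    seed: int = 0,
) -> TrialSchedule:
    """Seeded block design: fixed stimulus, Uniform[8, 16] s recovery."""
    if n_trials < 1:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(seed)
    recoveries = rng.uniform(*recovery_range, size=n_trials)
    onsets = np.concatenate([[0.0], np.cumsum(stim_s + recoveries)[:-1]])
    return TrialSchedule(
        onsets=onsets, stim_s=stim_s, recoveries=recoveries, seed=seed
    )


def _raised_cosine_box(
    t: np.ndarray, start: float, stop: float, ramp_s: float = 1.0
) -> np.ndarray:
    """Smooth 0->1->0 box with raised-cosine ramps of ``ramp_s`` seconds."""
    box = np.zeros_like(t)
    rise = (t >= start) & (t < start + ramp_s)
    box[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - start) / ramp_s))
    box[(t >= start + ramp_s) & (t < stop - ramp_s)] = 1.0
    fall = (t >= stop - ramp_s) & (t < stop)
    box[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - (stop - ramp_s)) / ramp_s))
    return box


def simulate_sources(
    schedule: TrialSchedule,
    hrf: HRFModel | None = None,
    coupling: CouplingSpec | None = None,
    eeg_rate: float = 250.0,
    fnirs_rate: float = 12.6,
    seed: int = 0,
    lead_in_s: float = 12.0,
    tail_s: float = 10.0,
) -> GroundTruth:
    """Generate the coupled ERD / HRF source pair.

    The EEG source is unit-variance 8-12 Hz band-limited noise whose envelope
    drops by the per-trial ERD depth during the stimulus (raised-cosine 1 s
    ramps).  The HbO source is a sum of canonical HRFs time-locked to each
    ERD onset (plus the hemodynamic delay), with amplitude
    ``c * (per-trial bandpower decrease)`` so the two are proportional by
    construction.
    """
    hrf = hrf or HRFModel()
    coupling = coupling or CouplingSpec()
    rng = np.random.default_rng(seed)
    duration = lead_in_s + schedule.total_duration + tail_s

    # --- EEG source: band-limited noise with ERD envelope
    n_x = int(round(duration * eeg_rate))
    t_x = np.arange(n_x) / eeg_rate
    lo, hi = coupling.alpha_band_hz
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=eeg_rate, output="sos")
    carrier = sps.sosfiltfilt(sos, rng.standard_normal(n_x))
    carrier = carrier / carrier.std()
    depths = rng.uniform(*coupling.erd_depth_range, size=schedule.n_trials)
    envelope = np.ones(n_x)
    onsets = schedule.onsets + lead_in_s
    for onset, depth in zip(onsets, depths):
        envelope -= depth * _raised_cosine_box(
            t_x, onset, onset + schedule.stim_s
        )
    sx = carrier * envelope

    # Envelope power drops from 1 to (1 - d)^2; the per-trial bandpower
    # decrease (and hence the HRF amplitude) follows analytically.
    decreases = 1.0 - (1.0 - depths) ** 2
    amplitudes = coupling.amplitude_constant * decreases

    # --- HbO source: amplitude-scaled HRFs locked to ERD onsets
    n_y = int(round(duration * fnirs_rate))
    kernel = hrf.kernel(fnirs_rate)
    sy = np.zeros(n_y)
    for onset, amp in zip(onsets, amplitudes):
        i0 = int(round((onset + hrf.onset_delay_s) * fnirs_rate))
        i1 = min(i0 + len(kernel), n_y)
        if i0 < n_y:
            sy[i0:i1] += amp * kernel[: i1 - i0]

    return GroundTruth(
        sx=ChannelTimeSeries(sx[None, :], eeg_rate, ["sx"], "eeg"),
        sy=ChannelTimeSeries(sy[None, :], fnirs_rate, ["sy"], "fnirs-hbo"),
        schedule=schedule,
        erd_depths=depths,
        bandpower_decreases=decreases,
        hrf_amplitudes=amplitudes,
        hrf=hrf,
        coupling=coupling,
        lead_in_s=lead_in_s,
    )


def _one_over_f(rng: np.random.Generator, n: int, rate: float, exponent: float,
                size: int) -> np.ndarray:
    """FFT-shaped 1/f^exponent noise, one row per series, unit variance."""
    white = rng.standard_normal((size, n))
    if exponent == 0:
        return white
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    out = np.fft.irfft(spec * shaping, n=n, axis=1)
    std = out.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return out / std


def _narrowband(rng: np.random.Generator, n: int, rate: float,
                center: float, bw: float) -> np.ndarray:
    lo = max(center - bw, 1e-3)
    hi = min(center + bw, rate / 2 * 0.99)
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    s = x.std()
    return x / s if s > 0 else x


def _spatial_kernel(positions: np.ndarray, scale_mm: float) -> np.ndarray:
    d = squareform(pdist(positions))
    k = np.exp(-(d**2) / (2 * scale_mm**2))
    return k / np.linalg.norm(k, axis=1, keepdims=True)


def simulate_background(
    geom: MontageGeometry,
    model: BackgroundModel | None = None,
    duration_s: float = 300.0,
    seed: int = 0,
    eeg_rate: float = 250.0,
    fnirs_rate: float = 12.6,
) -> tuple[ChannelTimeSeries, ChannelTimeSeries]:
    """Synthetic physiological background for both modalities.

    EEG: spatially mixed 1/f noise plus an occipito-parietal alpha component.
    fNIRS: spatially mixed 1/f noise plus cardiac, respiratory and Mayer-wave
    oscillations, each with a global (systemic) share mixed across channels
    through a distance-kernel weighting.  Channels are normalized to unit
    variance (well within the factor-3 homogeneity requirement).
    """
    if duration_s < 60:
        raise ValueError("background duration must be >= 60 s")
    model = model or BackgroundModel()
    rng = np.random.default_rng(seed)

    # --- EEG
    n_x = int(round(duration_s * eeg_rate))
    n_eeg = geom.eeg_positions.shape[0]
    latents = _one_over_f(rng, n_x, eeg_rate, model.eeg_exponent, n_eeg)
    mix = _spatial_kernel(geom.eeg_positions, model.spatial_smoothness_mm)
    x = mix @ latents
    for osc in model.eeg_oscillations:
        if osc.amplitude == 0:
            continue
        series = _narrowband(rng, n_x, eeg_rate, osc.center_hz, osc.bandwidth_hz)
        # posterior topography centered on Pz
        pz = geom.eeg_positions[geom.eeg_labels.index("Pz")]
        d2 = ((geom.eeg_positions - pz) ** 2).sum(axis=1)
        topo = np.exp(-d2 / (2 * 60.0**2))
        x = x + osc.amplitude * np.outer(topo, series)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    x = x / std

    # --- fNIRS
    n_y = int(round(duration_s * fnirs_rate))
    mids = geom.channel_midpoints()
    n_ch = mids.shape[0]
    latents = _one_over_f(rng, n_y, fnirs_rate, model.fnirs_exponent, n_ch)
    mix = _spatial_kernel(mids, model.spatial_smoothness_mm)
    y = mix @ latents
    for osc in model.fnirs_oscillations:
        if osc.amplitude == 0:
            continue
        series = _narrowband(rng, n_y, fnirs_rate, osc.center_hz, osc.bandwidth_hz)
        local = mix @ rng.uniform(0.2, 1.0, size=n_ch)
        local = local / local.max()
        weights = model.global_share + (1 - model.global_share) * local
        y = y + osc.amplitude * np.outer(weights, series)
    std = y.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    y = y / std

    x_cts = ChannelTimeSeries(x, eeg_rate, geom.eeg_labels, "eeg")
    y_cts = ChannelTimeSeries(y, fnirs_rate, geom.channel_labels(), "fnirs-hbo")
    return x_cts, y_cts


def assemble_dataset(
    truth: GroundTruth,
    patterns: PatternSet,
    background: tuple[ChannelTimeSeries, ChannelTimeSeries],
    snr_db: float | None,
    geometry: MontageGeometry | None = None,
    manifest: dict | None = None,
) -> SimulatedSession:
    """Mix clean pattern-projected sources into the background at exact SNR.

    Each modality's clean signal ``A s(t)`` is normalized to unit total power
    and scaled by an analytically chosen gamma so that
    ``10 log10(power(gamma * signal) / power(background))`` equals ``snr_db``
    exactly.  ``snr_db=None`` (the gamma = 0 guard) returns the background
    bit-exactly.
    """
    if snr_db is not None and not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite or None")
    x0, y0 = background

    def mix(bg: ChannelTimeSeries, a: np.ndarray, s: ChannelTimeSeries):
        n = min(bg.n_samples, s.n_samples)
        sig = a @ s.data[:, :n]
        p_sig = float((sig**2).mean())
        p_bg = float((bg.data[:, :n] ** 2).mean())
        if snr_db is None or p_sig == 0:
            return bg.crop(0, n), 0.0
        sig = sig / np.sqrt(p_sig)
        gamma = float(np.sqrt(10.0 ** (snr_db / 10.0) * p_bg))
        out = bg.crop(0, n)
        out.data = out.data + gamma * sig
        return out, gamma

    x, gamma_x = mix(x0, patterns.ax, truth.sx)
    y, gamma_y = mix(y0, patterns.ay, truth.sy)
    return SimulatedSession(
        x=x,
        y=y,
        truth=truth,
        patterns=patterns,
        geometry=geometry,
        snr_db=snr_db,
        gamma_x=gamma_x,
        gamma_y=gamma_y,
        manifest=manifest or {},
    )


def default_snr_grid() -> np.ndarray:
    """The benchmark SNR grid: 20 levels spanning -25 to 10 dB."""
    return np.linspace(-25.0, 10.0, 20)


def _derive_seeds(master_seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master_seed)
    states = ss.generate_state(3)
    return {
        "schedule": int(states[0] & 0x7FFFFFFF),
        "sources": int(states[1] & 0x7FFFFFFF),
        "background": int(states[2] & 0x7FFFFFFF),
    }


def build_manifest(
    seed: int = 0,
    snr_db: float | None = 0.0,
    n_trials: int = 12,
    stim_s: float = 10.0,
    recovery_range: tuple[float, float] = (8.0, 16.0),
    eeg_rate: float = 250.0,
    fnirs_rate: float = 12.6,
    lead_in_s: float = 12.0,
    tail_s: float = 10.0,
    background_seed: int | None = None,
    erd_depth_range: tuple[float, float] = (0.4, 0.8),
) -> dict:
    """Assemble the full parameter+seed manifest for one session."""
    seeds = _derive_seeds(seed)
    if background_seed is not None:
        seeds["background"] = int(background_seed)
    return {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "master_seed": int(seed),
        "seeds": seeds,
        "snr_db": None if snr_db is None else float(snr_db),
        "n_trials": int(n_trials),
        "stim_s": float(stim_s),
        "recovery_range": [float(v) for v in recovery_range],
        "eeg_rate": float(eeg_rate),
        "fnirs_rate": float(fnirs_rate),
        "lead_in_s": float(lead_in_s),
        "tail_s": float(tail_s),
        "erd_depth_range": [float(v) for v in erd_depth_range],
        "hrf": dataclasses.asdict(HRFModel()),
        "montage": "default",
    }


def session_from_manifest(manifest: dict) -> SimulatedSession:
    """Rebuild a session bit-exactly from its manifest."""
    if manifest.get("schema_version") != MANIFEST_SCHEMA_VERSION:
        raise ValueError("unsupported manifest schema version")
    geom = make_montage()
    patterns = make_spatial_patterns(geom)
    schedule = make_trial_schedule(
        n_trials=manifest["n_trials"],
        stim_s=manifest["stim_s"],
        recovery_range=tuple(manifest["recovery_range"]),
        seed=manifest["seeds"]["schedule"],
    )
    hrf = HRFModel(**manifest["hrf"])
    coupling = CouplingSpec(erd_depth_range=tuple(manifest["erd_depth_range"]))
    truth = simulate_sources(
        schedule,
        hrf=hrf,
        coupling=coupling,
        eeg_rate=manifest["eeg_rate"],
        fnirs_rate=manifest["fnirs_rate"],
        seed=manifest["seeds"]["sources"],
        lead_in_s=manifest["lead_in_s"],
        tail_s=manifest["tail_s"],
    )
    duration = manifest["lead_in_s"] + schedule.total_duration + manifest["tail_s"]
    background = simulate_background(
        geom,
        duration_s=duration,
        seed=manifest["seeds"]["background"],
        eeg_rate=manifest["eeg_rate"],
        fnirs_rate=manifest["fnirs_rate"],
    )
    return assemble_dataset(
        truth, patterns, background, manifest["snr_db"], geometry=geom,
        manifest=manifest,
    )


def simulate_session(seed: int = 0, snr_db: float | None = 0.0, **kwargs) -> SimulatedSession:
    """Convenience wrapper: build a manifest and realize the session."""
    return session_from_manifest(build_manifest(seed=seed, snr_db=snr_db, **kwargs))
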