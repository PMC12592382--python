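# Methods

This note documents the models, numerical choices and limitations behind
`nvfuse`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Linear source model and pattern estimation

All decomposition methods assume channel data are linear mixtures of latent
sources, `x(t) = Ax sx(t) + εx(t)`, and reconstruct sources with backward
filters `ŝ = Wᵀx`. Filters are not interpretable topographies; the forward
patterns are recovered as `Â = C W (WᵀCW)⁻¹`. Covariances use the `1/T`
convention (the `1/(T−1)` difference is irrelevant at the sample sizes used
and fixing one convention keeps results reproducible). All within-modality
covariances receive trace-scaled shrinkage `C + λ·(tr C / N)·I` with
default `λ = 1e-9` — enough to guarantee invertibility without visibly
biasing small problems; it is exposed everywhere as a parameter.

Filter sign is fixed by making each component's largest-|·| pattern
coefficient positive; all evaluation metrics are additionally
sign-invariant (absolute Pearson), since the decompositions have an
inherent sign ambiguity.

## The CCA family

Standard CCA maximizes `wxᵀCxy wy` under unit source variance and is
solved as the SVD of `Cx^{-1/2} Cxy Cy^{-1/2}` (equivalent to the usual
generalized eigenproblem, but with no iterative eigensolver in the
contract). Canonical correlations are clipped to [0, 1] and sorted
descending.

**Regularization.** Pure Ridge keeps covariance constraints and acts in
closed form by whitening with `C + λ2·(tr C/N)·I`. As soon as an L1 or
graph penalty is active, constraints switch to unit norm (identity mode),
following the common practice of substituting identity matrices for the
covariances in penalized CCA; the mode is always recorded in the model.
The identity-mode solver alternates penalized power iterations initialized
from the leading SVD pair of `Cxy`:

1. `w ← (I(1+λ2) + λg L)⁻¹ (Cxy w_other)`
2. soft-threshold at `λ1 · max|w|` (scale-free threshold)
3. renormalize to unit norm

The recorded objective is `wxᵀCxy wy`. Because penalized alternating
updates cannot guarantee exact monotonicity, the solver *stops and keeps
the previous iterate* if a step would decrease the objective; the recorded
history is therefore monotone non-decreasing by construction, and stalls
count as convergence. Tolerance 1e-6 relative on the objective, at most
500 iterations; non-convergence returns `converged=False` with a warning,
never silently. Additional components come from rank-one projection
deflation of `Cxy`; multiset deflation uses plain filter-space
orthogonality instead (the two-set and multiset literatures use different
schemes; we follow each).

Constraint constants of the structured-sparse formulations are exposed as
Lagrangian weights (`λ1`, `λ2`, `λg`); the correspondence to
constraint-form constants is implementation-defined, as is usual for
penalized matrix decompositions.

**Channel graphs.** GraphNet penalties `wᵀLw` use `L = D − B` from binary
distance-threshold adjacencies (default 25 mm between fNIRS channel
midpoints, 60 mm between EEG electrodes), with kNN and Gaussian-weight
rules available. Isolated nodes are allowed and logged. For temporally
embedded data the Laplacian is expanded block-diagonally across lag blocks
(`kron(I_P, L)`): lagged copies of a channel inherit its spatial
neighbourhood, and no cross-lag edges are introduced.

**Kernel CCA** is solved in the dual with centered kernels and constraints
`αᵀ(K² + ridge·(tr K²/T)·I)α = 1`; the trace scaling makes the nominal
ridge (default 0.1) unit-free. The Gaussian bandwidth defaults to the
median pairwise distance heuristic. Dual coefficients are returned in
place of channel filters (flagged in the model); projections for new
samples go through kernels against the stored training samples. Patterns
are undefined in the dual and returned as `None`.

**Multiset CCA** maximizes SUMCOR by alternating
`wi ← Ci⁻¹ Σ_{j≠i} Cij wj` with unit-variance renormalization — each step
is the optimum given the others, so SUMCOR is non-decreasing. With two
datasets the fixed point is the top canonical pair (verified against
`fit_cca` to 1e-6). The structured-sparse multiset variant maximizes
`Σ_{i≠j} |wiᵀCij wj|` under unit-norm filters with per-dataset L1/graph
penalties, using the same soft-thresholded updates and stop-on-decrease
rule.

**tCCA** embeds the fast modality (EEG bandpower in the benchmark — the
hemodynamics are the delayed side) with lags 1–4 s in 1 s steps by
default, then runs any of the regularized fits. Lags are validated to be
integer multiples of the sample period (no silent rounding). Zero padding
on mean-centered data preserves the sample count with an O(lag/T) boundary
effect; edge padding is available. The x-side filter is reported both flat
(P·Nx) and reshaped (Nx × P), together with the dominant lag block by
pattern norm.

## mSPoC

The EEG is band-passed and cut into non-overlapping windows with one fNIRS
sample per window (0.5 s at the benchmark's 2 Hz). Source bandpower in
window e is the quadratic form `Φ(e) = wxᵀ Cx(e) wx` (windows are
mean-centered, so this equals the within-window variance of the filtered
source for any filter — asserted to 1e-10 in tests). Delays are captured
by an FIR filter `h(Φ)(e) = Σi wτi Φ(e−τi)` over lags 0…Nτ−1 windows
(bandpower precedes hemodynamics, so all lags are non-negative). The
objective `Cov(h(Φ), ŝy)` is maximized under the three unit constraints by
alternating steps, each optimal given the others:

- `wτ ∝ Φ_lagged,centered · ŝy` (unit norm),
- `wx` from the generalized eigenproblem
  `M wx = λ (C̄x + λ2·(tr C̄x/N)·I) wx` with
  `M = ⟨ŝy(e) · (h(Cx)(e) − ⟨h(Cx)⟩)⟩`,
- `wy ∝ Cy⁻¹ cov(y, h(Φ))` normalized to `wyᵀCy wy = 1`.

Defaults mirror the benchmark settings: L2 of 0.8 on the EEG step and PCA
pre-projection keeping 0.99 of the explained variance of the mean windowed
covariance (both switchable off to recover the unregularized
formulation). Ten random restarts plus one deterministic (leading
eigenvector) initialization; the best final objective wins. Convergence:
relative objective change < 1e-5 or 200 outer iterations, with the same
stop-on-decrease rule as above. The lag count is not prescribed by the
benchmark protocol; the default Nτ = 8 windows at 2 Hz covers 0–3.5 s,
which brackets the hemodynamic rise. Deflation beyond the first component
is not provided; the benchmark uses a single filter pair throughout.

## Joint ICA

Group-level matrices `Dx (Ns×Nx)` and `Dy (Ns×Ny)` are concatenated along
features and decomposed as `D = GVᵀ` with independent profiles `vi`. The
ICA core is FastICA (tanh contrast, symmetric decorrelation, PCA whitening,
tol 1e-7, ≤1000 iterations, seeded) run with features as the independence
axis, so each component keeps a single subject-loading vector shared
across both modality blocks — the structural assumption of the model.
Features are z-scored by default so neither modality dominates by scale;
profiles are mapped back to original feature units and unit-normalized.
Note that z-scoring is a per-feature transform that can rotate planted
independent directions; recovery studies on synthetic data with a common
feature scale should disable it (`normalize=False`), which is why the
planted-model tests do.

## Simulator

The simulator emulates a single-subject finger-tapping block: 12 trials of
10 s stimulation, recovery ~ Uniform[8, 16] s, 12 s lead-in and 10 s tail.

- **Geometry.** EEG positions are the 32 actiCAP-style labels of the
  bundled standard 10-20 montage (mm). The fNIRS probe is a parametric
  surrogate for a high-density hexagonal layout: a triangular lattice with
  19 mm pitch (next-nearest spacing 19·√3 ≈ 33 mm) per hemisphere, placed
  in the scalp tangent planes at C3/C4, with a fixed source/detector site
  assignment that yields exactly 100 channels within the 19±2/33±2 mm
  separation bands from 14 sources and 32 detectors. FEM head models and
  photon transport are out of scope; patterns are parametric surrogates.
- **Sources.** The EEG source is unit-variance 8–12 Hz band-limited noise
  whose envelope drops by a per-trial ERD depth ~ Uniform[0.4, 0.8]
  (raised-cosine 1 s ramps). Envelope power drops from 1 to (1−d)², so the
  per-trial bandpower decrease is 1−(1−d)² analytically, and the HbO
  amplitude is exactly proportional to it (c = 1 after normalization) —
  the neurovascular coupling is perfect by construction. The HbO source
  sums canonical double-gamma HRFs (peak 6 s, undershoot 16 s, ratio 1/6,
  32 s support) locked to each ERD onset plus a 1 s hemodynamic onset
  delay. Overlapping responses add. Consequently the HbO peak follows each
  ERD onset by onset delay + time-to-peak (≈7 s); the raw cross-correlation
  between negative bandpower and HbO peaks earlier (≈3.5 s) because the
  10 s stimulus box overlaps the HRF rise — the per-trial peak latency is
  the well-defined timing statement and is what the tests assert.
- **Patterns.** EEG: a signed bipolar (dipole-like) topography — the
  tangential derivative of a Gaussian (σ = 40 mm) at the scalp point over
  the source. fNIRS: a non-negative Gaussian mask (σ = 15 mm) over channel
  midpoints. Both unit norm; the common source sits just beneath C3.
- **Background.** A synthetic stand-in for a resting-state recording:
  spatially mixed 1/f noise (exponent 1, 40 mm Gaussian distance kernel)
  plus an occipito-parietal alpha component for EEG; for fNIRS, cardiac
  (≈1.1 Hz), respiratory (≈0.25 Hz) and Mayer-wave (≈0.1 Hz) narrowband
  components with a 50% global systemic share and smooth channel weights.
  Channels are normalized to unit variance. It reproduces the gross
  statistics (1/f slope, physiological spectral peaks, distance-dependent
  channel correlations) but not single-subject idiosyncrasies, motion
  artifacts, ocular activity, ipsilateral ERD or post-movement beta
  rebound — so passing tests demonstrate method behaviour under controlled
  physiology-like noise, not performance on real recordings.
- **SNR mixing.** Clean channel-space signals are normalized to unit total
  power over all channels (a per-channel option exists) and scaled by an
  analytic γ so the requested total-power SNR holds exactly per modality;
  both modalities get the same nominal SNR. `snr_db=None` returns the
  background bit-exactly (γ = 0). The study grid is 20 levels from −25 to
  +10 dB. Sessions are bit-exactly reproducible from their manifest of
  seeds and parameters.
- EEG is synthesized at 250 Hz (a rate knob) rather than a hardware-like
  1000 Hz; alpha-band dynamics and 0.5 s bandpower windows are fully
  resolved at either rate.

## Benchmark protocol

Per simulation: fresh trial timing and source realizations; spatial
patterns and background noise fixed across simulations (one background
seed per sweep). Per SNR: mix, then preprocess — fNIRS: zero-phase
0.01–0.6 Hz Butterworth (order 2, maximal reflection padding: the 0.01 Hz
corner has a ~100 s transient), linear detrend, polyphase resampling to
2 Hz; EEG: zero-phase 8–12 Hz (order 4), then per-window variance over
0.5 s windows → 2 Hz bandpower (window means removed per window; a global
option exists). Trials span 8 s pre + 10 s stimulus + 8 s post; trials
exceeding the recording are dropped with a warning. The 80/20 split uses
round-half-up with a ≥1-trial clamp on each side (12 trials → 10/2), train
trials concatenated along time, test trials kept separate. Models are
tagged with their training provenance and evaluation refuses untagged
models, which also makes the no-leakage property testable (deleting test
trials leaves fitted filters bit-identical).

Metrics are per-test-trial absolute Pearson correlations between
reconstructed and true sources, plus pattern correlations (trial-
independent, repeated per trial for a uniform long table). The CCA family
consumes EEG bandpower, so its EEG-side ground truth is the true source's
bandpower; mSPoC consumes band-passed EEG and is scored against the raw
source. For temporally embedded models the reconstruction estimates the
source *delayed by the learned lag* (all lags ≥ 1 s, no lag-0 block), so
the ground-truth bandpower is shifted by each fitted model's dominant lag
before correlating — without this the metric measures the delay mismatch,
which sits at the autocorrelation-inflated noise floor. The x-side pattern
of embedded models is compared via its dominant-lag block. Note the
bandpower of a linearly mixed source loads channels roughly as the squared
pattern, so bandpower-domain methods cannot fully recover the signed EEG
topography; mSPoC, which inverts the linear model before computing
bandpower, can — the benchmark reproduces this ranking.

Aggregation uses Fisher's z: means are `tanh(mean(atanh r))`; |r| ≥ 1 is
clipped to 1−1e-12 with a warning. Error bars are the z-space standard
error of the mean, back-transformed (the protocol literature leaves the
error definition open). Failures of single (method, SNR, simulation) cells
are logged and isolated, never abort the sweep; the CLI streams records to
disk and resumes by skipping completed cells.

The default full sweep is 50 simulations × 20 SNRs. The shipped reduced
configurations (3–5 simulations, 3–4 SNRs) are the package's choice for
desk-scale runs and are what the acceptance script executes; they
reproduce the qualitative ranking (temporal embedding needed on the fNIRS
side, ElasticNet tCCA strongest among the CCA family, mSPoC best on the
EEG pattern) with Fisher means stable to a few percent across seeds.

## Known limitations

- The montage is a count-and-separation-faithful reconstruction, not the
  original probe layout (which is not published); channel positions beyond
  the printed constraints are surrogate.
- Identity-mode penalized solvers optimize a surrogate of the
  covariance-constrained objective; reported "correlations" for those fits
  are recomputed as proper unit-variance correlations of the variates.
- kCCA training-set correlations are optimistic (kernel methods overfit);
  use the projection API for held-out assessment.
- The mSPoC FIR filter is reported but its resemblance to the HRF shape is
  not analysed.
- Real-data ingestion (SNIRF/EDF readers) is minimal: single data block,
  no channel-quality pruning or ocular regression (those stages are no-ops
  on the synthetic data; hooks exist at the preprocessing boundary).
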