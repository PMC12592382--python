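# nvfuse

Symmetric, unsupervised source decomposition for concurrent fNIRS–EEG
recordings — and a ground-truth simulator plus benchmark protocol to compare
the methods.

## The problem

EEG measures fast neural electrical activity; fNIRS measures the slow
hemodynamic (HbO/HbR) response that follows it through neurovascular
coupling. During a motor task, alpha-band (8–12 Hz) EEG power drops over the
contralateral motor cortex (event-related desynchronization, ERD) while HbO
rises with a delay of several seconds. Symmetric fusion methods look for
this shared latent source in both modalities at once, without labels or
stimulus timing, by assuming linear forward models

```
x(t) = Ax sx(t) + εx(t),    y(t) = Ay sy(t) + εy(t)
```

and learning backward-model filters `ŝx = Wxᵀ x`, `ŝy = Wyᵀ y` whose
spatial patterns follow from `Â = C W (Wᵀ C W)⁻¹`.

`nvfuse` implements the main family of such methods for people developing or
evaluating multimodal fusion pipelines:

- **CCA** — `max wxᵀ Cxy wy` s.t. `wxᵀCx wx = wyᵀCy wy = 1`, solved as an
  SVD of the whitened cross-covariance; reduces to PLS on whitened data.
- **Regularized CCA** — Ridge, sparse (L1), ElasticNet, and
  GraphNet-structured penalties `wᵀLw` with channel-graph Laplacians
  `L = D − B` built from montage geometry.
- **kernel CCA** — nonlinear associations through centered linear,
  polynomial or Gaussian kernels (`max wxᵀKxKywy` s.t. `wᵀK²w = 1`, ridged).
- **multiset CCA / structured-sparse multiset CCA** — SUMCOR coupling of
  D ≥ 2 datasets, with deflation for multiple components.
- **tCCA** — temporal embedding `X̃ = [X(τ1) … X(τP)]` of the fast modality
  so that delayed hemodynamic coupling becomes instantaneous.
- **mSPoC** — couples the *source* bandpower `Φ(ŝx)(e) = wxᵀ Cx(e) wx`,
  FIR-filtered over past windows, to a latent fNIRS source:
  `max Cov(h(Φ)(e), ŝy)` s.t. `wxᵀCxwx = wyᵀCywy = wτᵀwτ = 1`.
- **joint ICA** — group-level `D = G Vᵀ` on subject-by-feature matrices
  concatenated across modalities.

The **simulator** generates a semi-synthetic HD-fNIRS–EEG session: a
bilateral high-density probe (14 sources × 32 detectors → 100 channels at
19/33 mm separations), 32 EEG electrodes, 12 trials of 10 s stimulation with
8–16 s recovery, coupled ERD/HRF sources near C3, physiological background
(1/f, alpha, cardiac/respiratory/Mayer waves), and exact SNR control from
−25 to +10 dB via an analytic scaling γ. Every session is bit-exactly
reproducible from its JSON manifest.

## Worked example

```python
import nvfuse as nv
from nvfuse.pipeline import prepare_session_inputs, split_trials

session = nv.simulate_session(seed=0, snr_db=10.0)
epochs = prepare_session_inputs(session)        # 2 Hz fNIRS + EEG bandpower
train, test, tr, te = split_trials(epochs, seed=0)   # 10 train / 2 test

lags = nv.EmbeddingConfig(lags=[1.0, 2.0, 3.0, 4.0])
tcca = nv.fit_tcca(train["x_bp"], train["y"], lags=lags)
print(tcca.correlations[0], tcca.extras["dominant_lag"][0])
```

Running `python examples/02_cca_family.py` prints:

```
train/test trials: 10/2
CCA (instantaneous):      r1 = 0.582
tCCA (lags 1-4 s):        r1 = 0.851, dominant lag 2 s
ElasticNet tCCA:          r1 = 0.717, 24/128 EEG weights active
```

Standard CCA couples bandpower and HbO only instantaneously (r₁ = 0.58);
embedding lags of 1–4 s lets the model bridge the hemodynamic delay
(r₁ = 0.85, with the dominant lag near the HRF rise), and the ElasticNet
penalty concentrates the filter on a sparse set of informative channels.
`examples/03_mspoc.py` shows mSPoC recovering both spatial patterns with
|corr| = 1.000 at +10 dB; `examples/05_benchmark.py` runs a reduced method
comparison and prints the Fisher-averaged recovery table.

A thin CLI wraps the same library:

```bash
nvfuse simulate --seed 1 --snr-db 0 --out run/      # SNIRF + EDF + manifest
nvfuse fit --method tcca --session run/session.h5 --out model.npz
nvfuse benchmark --config examples/benchmark.toml --out results/
nvfuse report --results results/ --plot
```

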