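# Full default configuration for `nvfuse benchmark --config benchmark.toml`.
# Every key is optional; unknown keys are rejected.

[simulate]
seed = 0
snr_db = 0.0
n_trials = 12
stim_s = 10.0
eeg_rate = 250.0
fnirs_rate = 12.6
lead_in_s = 12.0
tail_s = 10.0

[benchmark]
methods = [
    "cca", "tcca", "ridge-tcca", "sparse-tcca",
    "elasticnet-tcca", "ss-tcca", "mspoc",
]
# 20 SNR levels from -25 to +10 dB is the full study grid; this reduced
# default keeps a desk run short.
snr_grid_db = [-25.0, -13.0, 0.0, 10.0]
n_simulations = 5
seed = 0
n_trials = 12
train_fraction = 0.8
lags_s = [1.0, 2.0, 3.0, 4.0]
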