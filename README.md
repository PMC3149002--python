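# bsafreq

Bayesian spectrum analysis for short, noisy, trended biological time
series: calcium spiking traces, circadian gene-expression courses, and
any other oscillatory signal sampled at a few dozen to a few hundred
(possibly non-uniform) time points.

Classical FFT-based period estimation struggles exactly where biological
data live: records are short (broad spectral bins), noisy, carry slow
trends that leak power across the spectrum, and are often sampled
non-uniformly. `bsafreq` instead computes the full Bayesian posterior of
the oscillation frequency, with the amplitudes and the noise scale
marginalised analytically, a Legendre-polynomial background absorbing
trends inside the model, and evidence ratios (Bayes factors) choosing
the model structure automatically. The posterior stays sharp on records
far too short for the FFT, needs no detrending preprocessing, and works
on raw non-uniform time stamps.

## What is in the box

- **`BayesianSpectrum`** — scikit-learn style estimator for a fixed
  model (r frequencies + optional Legendre background): grid scan,
  Nelder–Mead peak refinement, fine posterior sampling, and noise /
  signal-to-noise / amplitude summaries. Multi-frequency posteriors are
  located by the built-in nested sampler.
- **`AutoBayesianSpectrum`** — automated model development: Legendre
  background order and number of frequencies chosen by pairwise
  evidence ratios (Laplace evidence for unimodal posteriors, nested
  sampling otherwise), then the selected model is fitted.
- **`LocalBayesianSpectrum` / `bsal`** — sliding-window BSA yielding a
  time-resolved frequency posterior; tracks abrupt frequency switches
  with windows as short as 10 points.
- **Evidence machinery** — `laplace_log_evidence`,
  `nested_log_evidence`, `posterior_ratio`, `select_background_order`,
  `select_num_frequencies`.
- **Classical comparators** — periodogram, power-weighted FFT
  summaries, moving-average detrending, STFT, interspike intervals.
- **Seeded simulation catalog** (`bsafreq.simulate`) regenerating every
  study condition used in the validation suite.
- **CLI** — `bsafreq analyze | compare | bsal | simulate`.

## Worked example

```python
from bsafreq import BayesianSpectrum, AutoBayesianSpectrum, fixture

# a unit-amplitude sinusoid at 0.5 rad/s with 10% noise, 100 points at 3 s
_, ts = fixture("table2_row2", seed=1)

est = BayesianSpectrum().fit(ts)
print(est.omega_)         # [0.50001622]   posterior mode, rad/s
print(est.sigma_omega_)   # [0.0001387]    posterior SD
print(est.period_)        # [12.56596291]  period, s
print(est.noise_sigma_)   # 0.0866         noise scale (true: 0.1)
print(est.snr_)           # 8.25           signal-to-noise

# same signal riding on a quadratic trend: the background is selected
# automatically from the evidence-ratio trace, no detrending needed
_, trended = fixture("s1_trend", seed=1)
auto = AutoBayesianSpectrum().fit(trended)
print(auto.background_order_)   # 2
print(auto.omega_)              # [0.5000488]
print(auto.background_trace_)   # [('H_-1/H_0', 3.9e-29), ('H_0/H_1', 8.1e-119),
                                #  ('H_1/H_2', 0.0),      ('H_2/H_3', 5692.2)]
```

The ratio trace reads like a model-development table: each entry
compares the simpler background against the next order, and the first
ratio above 1 stops the search (here order 2 beats order 3 by ~5700:1,
so the quadratic background is selected). On the same trace the raw
periodogram's power-weighted mean frequency collapses to ~0.11 rad/s —
the trend swamps the oscillation.

From the command line:

```sh
bsafreq simulate --fixture table2_row2 --seed 1 --out trace.csv
bsafreq analyze trace.csv --outdir out        # summary.json, posterior.csv, run.log
bsafreq compare trace.csv --outdir out        # adds FFT columns
bsafreq bsal trace.csv --window 10 --outdir out   # time-frequency map
```

Exit codes: 0 ok, 1 user error, 2 numerical failure. All stochastic
stages are seeded; re-running a command with the same config and seed
reproduces its outputs bit-identically.

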