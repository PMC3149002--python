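# Methods

## Model

A trace d(t_i), i = 1..N (times strictly increasing, not necessarily
uniform) is modelled as a linear combination of m basis functions plus
Gaussian noise of unknown scale σ:

    d(t_i) = Σ_j a_j g_j(t_i) + ε_i,   ε_i ~ N(0, σ²)

The basis holds one sin/cos pair per angular frequency (r frequencies →
m_signal = 2r columns) and, optionally, Legendre polynomials P_0..P_n of
the affinely mapped time τ = 2(t − t_1)/(t_N − t_1) − 1 as a background
(order n → n + 1 columns; n = −1 disables it). Legendre polynomials are
used instead of monomials because they stay well conditioned at the
orders the evidence ever selects.

## Marginal posterior of frequency

The basis is orthonormalised by a Cholesky factorisation of the Gram
matrix G = XᵀX (design X = H Lᵀ with HᵀH = I). Uniform priors are
assigned to the amplitudes **of the orthonormalised model functions** —
this is the standard construction; relative to uniform priors on raw
amplitudes it differs by the Jacobian √det G(ω), and the test-suite
quadrature oracle accounts for exactly that factor. With a Jeffreys
prior 1/σ on the noise scale, the amplitudes and σ integrate out
analytically and the marginal posterior of the frequency tuple ω is

    P(ω | D) ∝ (1 − m h̄²(ω) / (N d̄²))^((m − N)/2)

where h̄² = Σ h_j²/m is the mean-square projection of the data onto the
orthonormal basis and d̄² = Σ d_i²/N. The identity
N d̄² − m h̄² = min_a ‖d − Xa‖² (the least-squares residual) is verified
property-based in the tests.

Numerics: the exponent (m−N)/2 underflows the raw form for long traces,
so everything is computed in log space via `log1p`. A numerically
perfect fit (projection exhausts the data power to machine precision)
is reported as the finite cap ((N−m)/2)·(−log ε) instead of +inf. The
hot path (grid scans, nested sampling) evaluates the explained-power
fraction through a numba-compiled normal-equations kernel
(explained SS = zᵀz with Lz = Xᵀd); a pure-numpy route with identical
semantics is the behavioural reference and the fallback. Gram matrices
with condition number above 1e12 raise `DegenerateBasisError` rather
than being silently regularised.

Single-frequency posteriors are located by a uniform grid scan over the
search window (default (0.05, 1.5) rad/time, 500 points) followed by
Nelder–Mead refinement confined to the window; the surrounding
posterior is then finely sampled on an adaptively sized window (widened
if mass is truncated at an edge, narrowed if the grid under-resolves
the peak) to produce the mode, posterior mean, posterior SD and a mode
count. Multi-frequency models go through nested sampling first.

## Noise and signal-to-noise

At the posterior mode, σ̂² = (N d̄² − m h̄²)/(N − m − 2) (the posterior
expectation of the noise power), and snr = RMS(fitted sinusoidal part)
/ σ̂. Background columns are excluded from the signal RMS so a large
trend cannot inflate the reported snr.

## Evidence and automated model development

Model evidences use Gaussian amplitude priors whose common scale δ
carries a bounded Jeffreys hyperprior, a bounded Jeffreys prior on σ,
and a uniform prior on ω over the search window. Defaults are
scale-aware: δ ∈ [0.01, 100]·RMS(d), σ ∈ [0.001, 10]·RMS(d). The σ
integral is exact (incomplete-gamma form); the δ integral is a Laplace
step around its peak δ̂² = h̄²; the ω integral is either

- **Laplace**: second-order expansion around the refined peak, Hessian
  from central finite differences (step max(1e-6, 1e-4·ω̂)). Restricted
  to r ≤ 1 and unimodal posteriors — for r ≥ 2 relabelling symmetry
  alone gives r! peaks, and a multimodal r = 1 posterior (e.g. two real
  tones fitted with one frequency) raises `MultimodalPosteriorError`;
- **Nested sampling**: no unimodality assumption; used for all r ≥ 2
  evidences and as the fallback for r = 1.

Both routes share every ω-independent term, so on unimodal problems
they agree (observed ≲ 0.01 nats; the test suite enforces ≤ 1 nat).
Terms depending only on the shared prior bounds are carried explicitly
and cancel exactly in ratios computed under the same `EvidencePriors`;
`posterior_ratio` refuses to compare evidences from different data
(sha1 fingerprint of the arrays) or different bounds. The *absolute*
size of an evidence ratio therefore depends on the chosen prior ranges;
only its side of 1 is bound-independent, which is what model
development uses.

Model development is greedy and pairwise: background orders are
compared n vs n+1 starting from "no background", frequency counts r vs
r+1 starting from r = 1; the first ratio above 1 stops the search. The
result carries status "local": the procedure is not a global search
over all model pairs. Every ratio and verdict is logged, so the
model-development table is recoverable from the run log.

## Nested sampler

A classic single-ellipsoid-free implementation: n_live points (default
400), deterministic volume shrinkage X_k = exp(−k/n_live), shell
weights accumulated with logaddexp, termination when the remaining
prior mass can change log Z by less than 1e-3, live points folded in at
the end. Constrained draws come from rejection sampling in the box
while acceptance is good (≤ 30 tries), then permanently from shrinkage
slice sampling seeded at a random live point, with initial intervals
sized to 1.2× the live-point range per coordinate (a window-plus-
shrinkage update has the correct stationary distribution even when the
window does not span the whole constrained region). Likelihood
plateaus — produced by the perfect-fit cap on noiseless data — are
handled by counting ties with the threshold as inside the constrained
region. The reported error is √(H/n_live) with H the information.
Runs are deterministic given the configuration (seed included); for
multi-frequency models the label-switching symmetry is resolved by
sorting each draw before computing moments.

## Windowed analysis (local BSA)

The single-frequency pipeline is re-run on sliding windows of fixed
point count (left-aligned, reported at the window's mean time, so the
construction is well defined on non-uniform grids). Rows of the
resulting map are proper posterior densities over a common ω grid.
Because the posterior stays sharp on very short records, a 10-point
window tracks an abrupt frequency switch within a couple of windows.
Windows whose posterior is degenerate or exactly flat (no frequency
information, e.g. constant data) are flagged, not fatal.

## Simulated study conditions

The seeded catalog (`bsafreq.simulate.FIXTURES`) defines the study
conditions; it is not a tuning dial. Conventions: e_a = additive
Gaussian noise in % of unit amplitude (e_a = 10 → SD 0.1); e_p =
per-sample phase jitter in % of 2π, shared across tones of a multi-tone
signal. Conditions include noise sweeps (1–100%), phase noise, linear/
quadratic/cubic trends, two-tone signals (well separated and a
0.007 rad/s close pair), an odd-harmonic stack, a noiseless abrupt
frequency switch, a chirp, and a 20-point short record. Everything is
bit-reproducible per seed (PCG64).

## Problem sizes and runtime choices

Defaults are sized for desk-scale hardware (one CPU): 500-point scans,
400 fine samples, 400 live points. Typical costs: a single-frequency
fit ~0.2 s; an r = 2 nested-sampling evidence on 100 points ~5 s; the
close-pair fit on 600 points ~15 s. The acceptance script (medians over
20 seeds per target) completes in ~10 minutes.

## Limitations

- Model development is greedy/pairwise ("local"), not a global model
  search.
- Laplace evidence is restricted to unimodal r ≤ 1 posteriors by
  construction; multimodal cases must use nested sampling.
- Evidence-ratio magnitudes depend on the prior bounds (only the side
  of 1 is bound-free); reported ratios should be read that way.
- The FFT comparators intentionally require uniform sampling — that
  limitation is part of the comparison.
- Fine sampling summarises r ≤ 2 posteriors on grids; higher r relies
  on nested-sampling draws alone.
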