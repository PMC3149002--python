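"""Marginal posterior of angular frequency, its maximisation and summaries.

The observed trace is modelled as a linear combination of m basis
functions (sinusoid pairs plus an optional Legendre background) with
Gaussian noise of unknown power.  Assigning uniform priors to the
amplitudes and frequencies and a Jeffreys prior 1/sigma to the noise
scale, both the amplitudes and sigma integrate out analytically and the
posterior of the frequency r-tuple omega is

    P(omega | D) propto (1 - m*h2_bar / (N*d2_bar)) ** ((m - N) / 2)

where h2_bar is the mean-square projection of the data onto the
orthonormalised model functions at omega and d2_bar the data mean square.
The exponent (m - N)/2 makes the raw form underflow for long traces, so
all arithmetic is carried out in log space via log1p.

The estimator `BayesianSpectrum` packages the full single-model pipeline:
coarse grid scan, Nelder-Mead refinement of the peak, fine sampling of
the surrounding posterior (yielding the mode, posterior mean and the
posterior standard deviation sigma_omega), and post-hoc noise, amplitude
and signal-to-noise estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .basis import (
    DegenerateBasisError,
    ModelSpec,
    design_stats,
    make_design,
    orthonormalize,
)
from .timeseries import TimeSeries

__all__ = [
    "PosteriorResult",
    "log_posterior",
    "scan",
    "refine_peak",
    "fine_sample",
    "estimate_noise_snr",
    "estimate_amplitudes",
    "BayesianSpectrum",
]

_LOG_EPS = float(np.log(np.finfo(float).eps))  # ~ -36.04
_EPS = float(np.finfo(float).eps)

try:  # compiled kernel; the numpy route below is the behavioural reference
    from ._fastmath import explained_fraction as _explained_fraction_jit
except ImportError:  # pragma: no cover
    _explained_fraction_jit = None


def _explained_fraction(ts: TimeSeries, spec: ModelSpec, omega):
    """(N, m, explained-power fraction m*h2_bar/(N*d2_bar)) at omega.

    Lean normal-equations route for the hot loops (grid scans, nested
    sampling): the explained sum of squares b^T G^{-1} b equals the sum
    of squared projections onto the orthonormalised basis, without
    forming that basis.  Cholesky failure of the Gram matrix signals a
    degenerate basis.
    """
    if _explained_fraction_jit is not None:
        w = np.atleast_1d(np.asarray(omega, float))
        if w.size != spec.n_frequencies:
            raise ValueError(
                f"expected {spec.n_frequencies} frequencies, got {w.size}"
            )
        if spec.n_frequencies:
            if w.min() <= 0:
                raise ValueError("frequencies must be positive")
            if np.unique(w).size != w.size:
                raise DegenerateBasisError(
                    "duplicate frequencies give a singular basis"
                )
        n, m = ts.n, spec.m
        if m >= n:
            raise ValueError(f"model has m={m} functions but only N={n} points")
        try:
            frac = _explained_fraction_jit(
                ts.times, ts.values, w, spec.background_order
            )
        except np.linalg.LinAlgError:
            raise DegenerateBasisError("singular Gram matrix at this omega")
        return n, m, float(frac)

    design = make_design(spec, omega, ts.times)
    d = ts.values
    gram = design.T @ design
    b = design.T @ d
    try:
        low = np.linalg.cholesky(gram)
    except np.linalg.LinAlgError:
        raise DegenerateBasisError("singular Gram matrix at this omega")
    z = solve_triangular(low, b, lower=True)
    total = float(d @ d)
    if total == 0.0:
        return d.size, design.shape[1], 0.0
    return d.size, design.shape[1], float(z @ z) / total


def log_posterior(ts: TimeSeries, spec: ModelSpec, omega) -> float:
    """Unnormalised log posterior of omega; larger means more probable.

    A numerically perfect fit (the projected power exhausts the data
    power to within machine precision) is returned as the documented
    finite cap ((N - m)/2) * (-log eps) instead of +inf.
    """
    n, m, frac = _explained_fraction(ts, spec, omega)
    cap = 0.5 * (n - m) * (-_LOG_EPS)
    if frac >= 1.0 - _EPS:
        return cap
    val = 0.5 * (m - n) * np.log1p(-frac)
    return float(min(val, cap))


def _make_loglike(ts: TimeSeries, spec: ModelSpec):
    """Closure evaluating the log posterior with minimal per-call overhead.

    For samplers that call with strictly positive, in-box omega arrays;
    degenerate bases map to -inf rather than raising.
    """
    if _explained_fraction_jit is None:
        return lambda w: _safe_log_posterior(ts, spec, w)
    times, values = ts.times, ts.values
    n, m, bg = ts.n, spec.m, spec.background_order
    cap = 0.5 * (n - m) * (-_LOG_EPS)
    half = 0.5 * (m - n)

    def loglike(w: np.ndarray) -> float:
        if w.size and w.min() <= 0:
            return -np.inf
        try:
            frac = _explained_fraction_jit(times, values, w, bg)
        except np.linalg.LinAlgError:
            return -np.inf
        if frac >= 1.0 - _EPS:
            return cap
        return min(half * np.log1p(-frac), cap)

    return loglike


def _safe_log_posterior(ts, spec, omega) -> float:
    """log_posterior that maps invalid/degenerate omega to -inf."""
    omega = np.atleast_1d(np.asarray(omega, float))
    if np.any(omega <= 0) or np.unique(omega).size != omega.size:
        return -np.inf
    try:
        return log_posterior(ts, spec, omega)
    except DegenerateBasisError:
        return -np.inf


@dataclass
class PosteriorResult:
    """Posterior curve over omega with its mode and summary statistics."""

    omega_grid: np.ndarray
    log_post: np.ndarray
    mode: np.ndarray                 # refined, shape (r,)
    sigma_omega: np.ndarray          # posterior SD per component, shape (r,)
    posterior_mean: np.ndarray       # shape (r,)
    noise_sigma: float
    snr: float
    fine_grid: np.ndarray            # (n_fine,) for r=1, (n_fine, r) axes for r=2
    fine_log_post: np.ndarray
    fine_density: np.ndarray         # normalised over the fine window
    n_modes: int = 1

    @property
    def multimodal(self) -> bool:
        return self.n_modes > 1

    @property
    def period(self) -> np.ndarray:
        return 2.0 * np.pi / self.mode


def scan(ts: TimeSeries, spec: ModelSpec, omega_min: float, omega_max: float, n_grid: int = 500):
    """Evaluate the log posterior on a uniform grid (single-frequency models).

    Returns (grid, log_post, provisional_mode); ties on the grid resolve
    to the lower frequency.  Multi-frequency posteriors go through nested
    sampling or per-axis scans instead.
    """
    if spec.n_frequencies != 1:
        raise ValueError("grid scan supports single-frequency models only")
    if not (0 < omega_min < omega_max):
        raise ValueError("need 0 < omega_min < omega_max")
    if n_grid < 10:
        raise ValueError("n_grid must be >= 10")
    grid = np.linspace(omega_min, omega_max, n_grid)
    ll = _make_loglike(ts, spec)
    logp = np.array([ll(np.array([w])) for w in grid])
    if not np.any(np.isfinite(logp)):
        raise DegenerateBasisError("posterior degenerate at every grid point")
    mode = grid[int(np.argmax(logp))]
    return grid, logp, float(mode)


def refine_peak(
    ts: TimeSeries,
    spec: ModelSpec,
    omega_start,
    step: float = 1e-3,
    bounds: tuple[float, float] | None = None,
):
    """Nelder-Mead maximisation of the log posterior from a grid mode.

    The initial simplex has edge length twice the scan grid step; when
    ``bounds`` is given the search is confined to that omega interval
    (per component).  On non-convergence a warning is emitted and the
    best point found is returned.
    """
    x0 = np.atleast_1d(np.asarray(omega_start, float))
    r = x0.size
    simplex = np.vstack([x0] + [x0 + 2.0 * step * e for e in np.eye(r)])
    ll = _make_loglike(ts, spec)
    if bounds is None:
        objective = lambda w: -ll(np.asarray(w, float))
    else:
        lo, hi = bounds

        def objective(w):
            w = np.asarray(w, float)
            if w.min() < lo or w.max() > hi:
                return np.inf
            return -ll(w)

    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": 1e-8,
            "fatol": 1e-10,
            "maxiter": 500 * r,
            "initial_simplex": simplex,
        },
    )
    if not res.success:
        warnings.warn(
            f"Nelder-Mead did not converge ({res.message}); returning best point",
            RuntimeWarning,
        )
    return np.atleast_1d(res.x)


def _count_modes(density: np.ndarray, rel_height: float = 0.01) -> int:
    """Local maxima of a sampled density exceeding rel_height * peak."""
    if density.ndim == 1:
        d = density
        interior = (d[1:-1] >= d[:-2]) & (d[1:-1] > d[2:])
        peaks = 1 + np.nonzero(interior & (d[1:-1] > rel_height * d.max()))[0]
        count = peaks.size
        if d[0] > d[1] and d[0] > rel_height * d.max():
            count += 1
        if d[-1] > d[-2] and d[-1] > rel_height * d.max():
            count += 1
        return max(count, 1)
    # 2-D: compare with the 8-neighbourhood
    d = density
    pad = np.pad(d, 1, constant_values=-np.inf)
    core = pad[1:-1, 1:-1]
    is_max = np.ones_like(core, bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == dj == 0:
                continue
            is_max &= core >= pad[1 + di : pad.shape[0] - 1 + di,
                                  1 + dj : pad.shape[1] - 1 + dj]
    return max(int(np.sum(is_max & (core > rel_height * d.max()))), 1)


def fine_sample(
    ts: TimeSeries,
    spec: ModelSpec,
    mode,
    half_width: float | None = None,
    n_fine: int = 400,
):
    """Finely sample the posterior around a refined mode and normalise it.

    The window is widened (up to three times) if it truncates visible
    mass at an edge, and narrowed if essentially all mass falls in its
    central tenth, so that the reported posterior mean and standard
    deviation are resolved by the grid.  Supports r = 1 and r = 2; higher
    dimensions are summarised from nested-sampling draws instead.
    """
    mode = np.atleast_1d(np.asarray(mode, float))
    r = mode.size
    if r > 2:
        raise ValueError("fine_sample supports r <= 2")
    if half_width is None:
        half_width = max(0.02 * float(mode.min()), 1e-4)
    hw = float(half_width)
    ll = _make_loglike(ts, spec)

    for _attempt in range(8):
        if r == 1:
            lo = max(mode[0] - hw, 1e-12)
            grid = np.linspace(lo, mode[0] + hw, n_fine)
            logp = np.array([ll(np.array([w])) for w in grid])
            dens = np.exp(logp - logp.max())
            area = np.trapezoid(dens, grid)
            dens = dens / area
            edge = max(dens[0], dens[-1])
        else:
            n_side = max(int(np.sqrt(n_fine)), 40)
            axes = [
                np.linspace(max(m_i - hw, 1e-12), m_i + hw, n_side) for m_i in mode
            ]
            logp = np.array(
                [[ll(np.array([w1, w2])) for w2 in axes[1]] for w1 in axes[0]]
            )
            dens = np.exp(logp - logp[np.isfinite(logp)].max())
            dens[~np.isfinite(logp)] = 0.0
            area = np.trapezoid(np.trapezoid(dens, axes[1], axis=1), axes[0])
            dens = dens / area
            edge = max(
                dens[0].max(), dens[-1].max(), dens[:, 0].max(), dens[:, -1].max()
            )
            grid = np.column_stack(axes)

        peak = dens.max()
        if edge > 0.01 * peak and _attempt < 3:
            hw *= 2.5
            continue
        # all mass in the central tenth -> grid too coarse for moments
        if r == 1:
            central = slice(int(0.45 * n_fine), int(0.55 * n_fine) + 1)
            frac = np.trapezoid(dens[central], grid[central])
            if frac > 0.999 and hw > 1e-8:
                hw /= 5.0
                continue
        break
    else:  # pragma: no cover
        warnings.warn("fine window did not stabilise", RuntimeWarning)

    if r == 1:
        mean = np.array([np.trapezoid(grid * dens, grid)])
        var = np.trapezoid((grid - mean[0]) ** 2 * dens, grid)
        sd = np.array([np.sqrt(max(var, 0.0))])
        n_modes = _count_modes(dens)
        peak_omega = np.array([grid[int(np.argmax(dens))]])
    else:
        w1, w2 = grid[:, 0], grid[:, 1]
        p1 = np.trapezoid(dens, w2, axis=1)
        p1 /= np.trapezoid(p1, w1)
        p2 = np.trapezoid(dens, w1, axis=0)
        p2 /= np.trapezoid(p2, w2)
        mean = np.array([np.trapezoid(w1 * p1, w1), np.trapezoid(w2 * p2, w2)])
        sd = np.sqrt(
            np.maximum(
                [
                    np.trapezoid((w1 - mean[0]) ** 2 * p1, w1),
                    np.trapezoid((w2 - mean[1]) ** 2 * p2, w2),
                ],
                0.0,
            )
        )
        n_modes = _count_modes(dens)
        i, j = np.unravel_index(int(np.argmax(dens)), dens.shape)
        peak_omega = np.array([w1[i], w2[j]])

    return {
        "grid": grid,
        "log_post": logp,
        "density": dens,
        "mean": mean,
        "sd": sd,
        "n_modes": n_modes,
        "peak": peak_omega,
        "half_width": hw,
    }


def estimate_amplitudes(ts: TimeSeries, spec: ModelSpec, mode) -> np.ndarray:
    """Posterior-mean amplitudes of all m model functions (original basis).

    Under the flat amplitude prior the posterior mean coincides with the
    least-squares coefficients; they are recovered from the orthonormal
    projections through the stored Cholesky factor.
    """
    design = make_design(spec, mode, ts.times)
    h_mat, chol = orthonormalize(design)
    h = h_mat.T @ ts.values
    # design = H L^T  =>  coefficients c solve L^T c = h
    return solve_triangular(chol.T, h, lower=False)


def estimate_noise_snr(ts: TimeSeries, spec: ModelSpec, mode) -> tuple[float, float]:
    """Posterior noise scale and signal-to-noise ratio at the mode.

    noise_sigma^2 = (N*d2_bar - m*h2_bar) / (N - m - 2) is the posterior
    expectation of the noise power given the model.  The signal-to-noise
    ratio divides the RMS of the fitted sinusoidal part only (background
    columns excluded, which would otherwise inflate it) by noise_sigma.
    """
    stats = design_stats(ts, spec, mode)
    n, m = stats.n, stats.m
    if n <= m + 2:
        raise ValueError(f"need N > m + 2 (N={n}, m={m})")
    sigma2 = max(stats.residual_ss, 0.0) / (n - m - 2)
    noise_sigma = float(np.sqrt(sigma2))
    coef = estimate_amplitudes(ts, spec, mode)
    design = make_design(spec, mode, ts.times)
    ms = spec.m_signal
    signal_fit = design[:, :ms] @ coef[:ms]
    rms = float(np.sqrt(np.mean(signal_fit**2)))
    snr = np.inf if noise_sigma == 0 else rms / noise_sigma
    return noise_sigma, float(snr)


class BayesianSpectrum(BaseEstimator):
    """Bayesian frequency estimation for a fixed model structure.

    Fits the marginal posterior of the angular-frequency r-tuple of a
    sinusoid model (with optional Legendre background) to a sampled
    trace.  For a single frequency the posterior is located by a coarse
    grid scan followed by Nelder-Mead refinement; for two or more
    frequencies the joint mode is located by nested sampling.  The
    surrounding posterior is then finely sampled to obtain the mode,
    posterior mean and standard deviation, and noise / signal-to-noise /
    amplitude summaries are derived at the mode.

    Parameters
    ----------
    n_frequencies : int, default 1
        Number of distinct angular frequencies r in the model.
    background_order : int, default -1
        Maximum Legendre order of the background; -1 disables it.
    omega_min, omega_max : float
        Angular-frequency search window, rad per time unit of the input.
    n_grid : int, default 500
        Coarse scan resolution (r = 1).
    n_fine : int, default 400
        Fine-sampling resolution around the peak.
    n_live, ns_seed : nested-sampling settings used when r >= 2.

    Attributes
    ----------
    omega_ : ndarray (r,), posterior mode (rad/time, ascending for r >= 2)
    sigma_omega_ : ndarray (r,), posterior standard deviation per component
    posterior_mean_ : ndarray (r,)
    period_ : ndarray (r,), 2*pi / omega_
    noise_sigma_ : float, posterior noise scale in signal units
    snr_ : float, RMS(fitted sinusoidal part) / noise_sigma_
    amplitudes_ : ndarray (m,), least-squares amplitudes in the original basis
    n_modes_ : int, local maxima of the fine-sampled posterior
    result_ : PosteriorResult with the full curves
    """

    def __init__(
        self,
        n_frequencies: int = 1,
        background_order: int = -1,
        omega_min: float = 0.05,
        omega_max: float = 1.5,
        n_grid: int = 500,
        n_fine: int = 400,
        n_live: int = 400,
        ns_seed: int = 0,
    ):
        self.n_frequencies = n_frequencies
        self.background_order = background_order
        self.omega_min = omega_min
        self.omega_max = omega_max
        self.n_grid = n_grid
        self.n_fine = n_fine
        self.n_live = n_live
        self.ns_seed = ns_seed

    def _to_timeseries(self, X, y) -> TimeSeries:
        if isinstance(X, TimeSeries) and y is None:
            return X
        t = np.asarray(X, float)
        if t.ndim == 2:
            if t.shape[1] != 1:
                raise ValueError("X must be the sample times: shape (n,) or (n, 1)")
            t = t[:, 0]
        return TimeSeries(t, np.asarray(y, float))

    def fit(self, X, y=None):
        """Fit the posterior. X holds the sample times, y the signal values."""
        ts = self._to_timeseries(X, y)
        spec = ModelSpec(self.n_frequencies, self.background_order)
        if spec.n_frequencies == 1:
            grid, logp, coarse_mode = scan(
                ts, spec, self.omega_min, self.omega_max, self.n_grid
            )
            step = (self.omega_max - self.omega_min) / (self.n_grid - 1)
            mode = refine_peak(
                ts, spec, coarse_mode, step=step,
                bounds=(self.omega_min, self.omega_max),
            )
        else:
            from .nested import NSConfig, nested_sample

            cfg = NSConfig(
                n_live=self.n_live,
                seed=self.ns_seed,
                prior_box=[(self.omega_min, self.omega_max)] * spec.n_frequencies,
            )
            ns = nested_sample(ts, spec, cfg)
            start = np.sort(ns.omega_map)
            mode = np.sort(refine_peak(ts, spec, start, step=1e-3))
            grid, logp = ns.samples[:, : spec.n_frequencies], ns.logl

        fine = fine_sample(ts, spec, mode, n_fine=self.n_fine)
        mode = np.sort(fine["peak"]) if spec.n_frequencies > 1 else fine["peak"]
        noise_sigma, snr = estimate_noise_snr(ts, spec, mode)

        self.spec_ = spec
        self.omega_ = mode
        self.sigma_omega_ = fine["sd"]
        self.posterior_mean_ = fine["mean"]
        self.period_ = 2.0 * np.pi / mode
        self.noise_sigma_ = noise_sigma
        self.snr_ = snr
        self.amplitudes_ = estimate_amplitudes(ts, spec, mode)
        self.n_modes_ = fine["n_modes"]
        self.result_ = PosteriorResult(
            omega_grid=grid,
            log_post=logp,
            mode=mode,
            sigma_omega=fine["sd"],
            posterior_mean=fine["mean"],
            noise_sigma=noise_sigma,
            snr=snr,
            fine_grid=fine["grid"],
            fine_log_post=fine["log_post"],
            fine_density=fine["density"],
            n_modes=fine["n_modes"],
        )
        return self

    def score(self, X, y=None) -> float:
        """Log posterior of the fitted mode on (possibly new) data."""
        ts = self._to_timeseries(X, y)
        return log_posterior(ts, self.spec_, self.omega_)
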