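"""Classical spectral baselines: periodogram, FFT summaries, moving-average
detrending, short-time Fourier transform, and interspike intervals.

These are the comparison methods, kept deliberately standard: the
periodogram is |FFT|^2 / N at the positive Fourier frequencies of a
uniformly sampled record (non-uniform input is an error - that
limitation is part of the comparison), its summary statistics are the
power-weighted mean and standard deviation of angular frequency, and the
STFT is a Hann-tapered per-segment periodogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .timeseries import TimeSeries

__all__ = [
    "Spectrum",
    "NonUniformSamplingError",
    "periodogram",
    "fft_summary",
    "detrend_moving_average",
    "stft",
    "interspike_intervals",
]


class NonUniformSamplingError(ValueError):
    """FFT-based methods require uniform sampling."""


def _uniform_dt(ts: TimeSeries, rtol: float = 1e-8) -> float:
    steps = np.diff(ts.times)
    dt = steps.mean()
    if np.any(np.abs(steps - dt) > rtol * dt + 1e-12):
        raise NonUniformSamplingError(
            "FFT requires uniform sampling; this trace is non-uniform"
        )
    return float(dt)


@dataclass(frozen=True)
class Spectrum:
    """Power at positive angular frequencies (DC excluded)."""

    omega: np.ndarray       # rad/time, strictly increasing
    power: np.ndarray       # |FFT|^2 / N per point


def periodogram(ts: TimeSeries, remove_mean: bool = True) -> Spectrum:
    """|FFT(d)|^2 / N at omega_k = 2*pi*k/(N*dt), k = 1..floor(N/2).

    The mean is removed by default so that the DC component does not
    leak into neighbouring bins.
    """
    dt = _uniform_dt(ts)
    d = ts.values - ts.values.mean() if remove_mean else ts.values
    n = d.size
    coef = np.fft.rfft(d)
    power = np.abs(coef) ** 2 / n
    omega = 2 * np.pi * np.fft.rfftfreq(n, d=dt)
    return Spectrum(omega=omega[1:], power=power[1:])


def fft_summary(spec: Spectrum) -> tuple[float, float]:
    """Power-weighted mean and standard deviation of angular frequency."""
    total = spec.power.sum()
    if spec.omega.size == 0 or total <= 0:
        raise ValueError("spectrum has no power to summarise")
    w = spec.power / total
    mean = float(w @ spec.omega)
    sd = float(np.sqrt(max(w @ (spec.omega - mean) ** 2, 0.0)))
    return mean, sd


def detrend_moving_average(ts: TimeSeries, window_points: int) -> TimeSeries:
    """Subtract a centered moving average (edges: shrinking one-sided)."""
    w = window_points
    n = ts.n
    if w % 2 == 0 or not (3 <= w < n):
        raise ValueError("window must be odd with 3 <= window < N")
    half = w // 2
    csum = np.concatenate([[0.0], np.cumsum(ts.values)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    avg = (csum[hi] - csum[lo]) / (hi - lo)
    return TimeSeries(ts.times, ts.values - avg, label=ts.label)


def stft(ts: TimeSeries, window_points: int, overlap_points: int):
    """Short-time Fourier power: Hann-tapered per-segment periodograms.

    Returns (segment_center_times, omega, power) with power of shape
    (n_omega, n_segments), matching the layout of the windowed Bayesian
    map for side-by-side plotting.
    """
    dt = _uniform_dt(ts)
    if not 0 <= overlap_points < window_points:
        raise ValueError("need 0 <= overlap < window")
    f, seg_t, z = sps.stft(
        ts.values - ts.values.mean(),
        fs=1.0 / dt,
        window="hann",
        nperseg=window_points,
        noverlap=overlap_points,
        boundary=None,
        padded=False,
        return_onesided=True,
        scaling="spectrum",
    )
    omega = 2 * np.pi * f[1:]
    power = np.abs(z[1:, :]) ** 2
    centers = ts.times[0] + seg_t
    return centers, omega, power


def interspike_intervals(
    ts: TimeSeries, min_prominence: float | None = None
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Intervals between successive prominent local maxima.

    Peaks are detected by prominence; the default threshold is half the
    spread between the maximum and the median of the trace.  Returns the
    interval list and a histogram (counts, bin_edges); fewer than two
    peaks yields an empty result with a warning.
    """
    if min_prominence is None:
        min_prominence = 0.5 * (ts.values.max() - np.median(ts.values))
    if min_prominence <= 0:
        peaks = np.empty(0, dtype=int)
    else:
        peaks, _ = sps.find_peaks(ts.values, prominence=min_prominence)
    if peaks.size < 2:
        warnings.warn("fewer than 2 peaks detected; no intervals", RuntimeWarning)
        return np.empty(0), (np.empty(0, dtype=int), np.empty(0))
    isi = np.diff(ts.times[peaks])
    counts, edges = np.histogram(isi, bins="auto")
    return isi, (counts, edges)
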