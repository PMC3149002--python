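"""Model-function bases and the sufficient statistics of the frequency posterior.

The data model is d(t_i) = f(t_i) + e(t_i), with f a linear combination of
m model functions: a sine/cosine pair for each of r angular frequencies
(m_s = 2r signal functions) plus Legendre polynomials up to a chosen order
for slow background trends (m_g functions, independent of omega).  The
Legendre polynomials are mapped onto the observed time span and the whole
basis is orthonormalised over the actual sample times by Cholesky
decomposition of its Gram matrix, so non-uniform sampling needs no special
treatment.

With an orthonormal basis H (columns H_j, sum_i H_j(t_i)^2 = 1) the
frequency posterior depends on the data only through the projections
h_j = sum_i d_i H_j(t_i), their mean square h2_bar = (1/m) sum_j h_j^2 and
the data mean square d2_bar = (1/N) sum_i d_i^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cholesky, solve_triangular

from .timeseries import TimeSeries

__all__ = [
    "ModelSpec",
    "SufficientStats",
    "DegenerateBasisError",
    "make_design",
    "orthonormalize",
    "sufficient_stats",
    "design_stats",
]

#: Gram matrices worse conditioned than this are treated as degenerate
#: rather than silently regularised (a ridge term would bias the evidence).
CONDITION_LIMIT = 1e12


class DegenerateBasisError(ValueError):
    """The model functions are (numerically) linearly dependent on these times."""


@dataclass(frozen=True)
class ModelSpec:
    """Structure of the signal model: r frequencies + Legendre background.

    Parameters
    ----------
    n_frequencies : int
        Number r of distinct angular frequencies; each contributes a sine
        and a cosine column (m_s = 2r).
    background_order : int
        Maximum Legendre order included; -1 means no background at all,
        n >= 0 means orders 0..n (m_g = n + 1 functions).
    """

    n_frequencies: int = 1
    background_order: int = -1

    def __post_init__(self) -> None:
        if self.n_frequencies < 0:
            raise ValueError("n_frequencies must be >= 0")
        if self.background_order < -1:
            raise ValueError("background_order must be >= -1")
        if self.n_frequencies == 0 and self.background_order == -1:
            raise ValueError("model has no functions at all")

    @property
    def m_signal(self) -> int:
        return 2 * self.n_frequencies

    @property
    def m_background(self) -> int:
        return self.background_order + 1

    @property
    def m(self) -> int:
        return self.m_signal + self.m_background


@dataclass(frozen=True)
class SufficientStats:
    """Orthonormal projections and mean squares entering the posterior."""

    h: np.ndarray          # m projections of the data on the orthonormal basis
    h2_bar: float          # (1/m) sum h_j^2
    d2_bar: float          # (1/N) sum d_i^2
    n: int
    m: int
    chol_factor: np.ndarray  # lower-triangular L with Gram = L L^T

    @property
    def residual_ss(self) -> float:
        """N*d2_bar - m*h2_bar: the least-squares residual sum of squares."""
        return self.n * self.d2_bar - self.m * self.h2_bar


def legendre_time_map(times: np.ndarray) -> np.ndarray:
    """Affine map of [t_1, t_N] onto [-1, 1]."""
    t0, t1 = times[0], times[-1]
    return 2.0 * (times - t0) / (t1 - t0) - 1.0


def make_design(
    spec: ModelSpec, omega: Sequence[float], times: np.ndarray
) -> np.ndarray:
    """Evaluate the m model functions at the sample times.

    Columns are ordered [sin(w_1 t), cos(w_1 t), ..., sin(w_r t),
    cos(w_r t), P_0(tau), ..., P_n(tau)] with tau the affine image of the
    time span in [-1, 1].
    """
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    if omega.size != spec.n_frequencies:
        raise ValueError(
            f"expected {spec.n_frequencies} frequencies, got {omega.size}"
        )
    if spec.n_frequencies and omega.min() <= 0:
        raise ValueError("frequencies must be positive")
    for i in range(omega.size):
        for j in range(i + 1, omega.size):
            if omega[i] == omega[j]:
                raise DegenerateBasisError(
                    "duplicate frequencies give a singular basis"
                )
    times = np.asarray(times, dtype=float)
    n = times.size
    if spec.m >= n:
        raise ValueError(
            f"model has m={spec.m} functions but only N={n} data points"
        )
    out = np.empty((n, spec.m))
    for k, w in enumerate(omega):
        wt = w * times
        np.sin(wt, out=out[:, 2 * k])
        np.cos(wt, out=out[:, 2 * k + 1])
    if spec.background_order >= 0:
        tau = legendre_time_map(times)
        base = 2 * omega.size
        # Bonnet recurrence: (k+1) P_{k+1} = (2k+1) tau P_k - k P_{k-1}
        out[:, base] = 1.0
        if spec.background_order >= 1:
            out[:, base + 1] = tau
        for k in range(1, spec.background_order):
            out[:, base + k + 1] = (
                (2 * k + 1) * tau * out[:, base + k] - k * out[:, base + k - 1]
            ) / (k + 1)
    return out


def orthonormalize(design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormalise the design over the sample times via Cholesky.

    Returns (H, L) with H^T H = I and design = H L^T; L is lower
    triangular with positive diagonal, which fixes the signs of H and
    makes the factorisation deterministic.
    """
    gram = design.T @ design
    # cond() on a symmetric PSD matrix via eigenvalues is cheap at m <= ~10
    eig = np.linalg.eigvalsh(gram)
    if eig[0] <= 0 or eig[-1] / eig[0] > CONDITION_LIMIT:
        norms = np.linalg.norm(design, axis=0)
        worst = int(np.argmin(norms)) if np.any(norms == 0) else int(np.argmin(eig))
        raise DegenerateBasisError(
            f"degenerate basis on these times (condition number "
            f"{np.inf if eig[0] <= 0 else eig[-1] / eig[0]:.3g}); "
            f"suspect column {worst}"
        )
    upper = cholesky(gram, lower=False)  # gram = U^T U, U = L^T
    h_mat = solve_triangular(upper, design.T, lower=False, trans="T").T
    return h_mat, upper.T


def sufficient_stats(ts: TimeSeries, h_mat: np.ndarray, chol_factor: np.ndarray | None = None) -> SufficientStats:
    """Project the data onto an orthonormal basis and form the mean squares."""
    d = ts.values
    h = h_mat.T @ d
    m = h.size
    n = d.size
    return SufficientStats(
        h=h,
        h2_bar=float(h @ h) / m,
        d2_bar=float(d @ d) / n,
        n=n,
        m=m,
        chol_factor=chol_factor if chol_factor is not None else np.eye(m),
    )


def design_stats(ts: TimeSeries, spec: ModelSpec, omega) -> SufficientStats:
    """Convenience: design -> orthonormalise -> sufficient statistics."""
    design = make_design(spec, omega, ts.times)
    h_mat, chol = orthonormalize(design)
    return sufficient_stats(ts, h_mat, chol)
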