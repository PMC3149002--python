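"""Model evidences and automated model development.

Competing models differ in their number of frequencies r and/or their
Legendre background order.  Each model's evidence is the likelihood
integrated over all parameters: amplitudes (Gaussian priors whose scale
delta carries a bounded Jeffreys hyperprior), the noise scale sigma
(bounded Jeffreys) and the frequencies (uniform over the search window).
The amplitude and sigma integrals are analytic; the delta hyperprior is
integrated by a Laplace step around its peak delta^2 = h2_bar; the
frequency integral is done either by a Laplace expansion around the
posterior peak (valid only for unimodal posteriors) or by nested
sampling.  Terms that depend only on the shared prior bounds are carried
explicitly so that they cancel exactly in ratios of models computed with
the same EvidencePriors.

Model development iterates pairwise evidence ratios: background orders
n vs n+1 (starting from no background at all) and frequency counts r vs
r+1, stopping the first time the simpler model wins (ratio > 1).  The
procedure is greedy, so results carry a "local" status: it is not
guaranteed to find the global optimum over all models.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .basis import DegenerateBasisError, ModelSpec
from .core import _explained_fraction, _safe_log_posterior, fine_sample, refine_peak, scan
from .nested import NSConfig, nested_sample
from .timeseries import TimeSeries

__all__ = [
    "EvidencePriors",
    "EvidenceResult",
    "MultimodalPosteriorError",
    "laplace_log_evidence",
    "nested_log_evidence",
    "posterior_ratio",
    "select_background_order",
    "select_num_frequencies",
]


class MultimodalPosteriorError(RuntimeError):
    """Laplace evidence refused: the posterior is not unimodal.

    Use nested_log_evidence, which integrates without a unimodality
    assumption.
    """


@dataclass(frozen=True)
class EvidencePriors:
    """Prior bounds entering the evidence; shared bounds cancel in ratios.

    delta_bounds : bounds of the amplitude-scale hyperprior (signal units)
    gamma_bounds : the frequency search window (rad/time)
    sigma_bounds : bounds of the noise-scale prior (signal units)
    """

    delta_bounds: tuple[float, float]
    gamma_bounds: tuple[float, float]
    sigma_bounds: tuple[float, float]

    def __post_init__(self) -> None:
        for lo, hi in (self.delta_bounds, self.gamma_bounds, self.sigma_bounds):
            if not (0 < lo < hi):
                raise ValueError("prior bounds must satisfy 0 < low < high")

    @property
    def log_r_delta(self) -> float:
        return float(np.log(self.delta_bounds[1] / self.delta_bounds[0]))

    @property
    def log_r_sigma(self) -> float:
        return float(np.log(self.sigma_bounds[1] / self.sigma_bounds[0]))

    @classmethod
    def from_data(
        cls, ts: TimeSeries, gamma_bounds: tuple[float, float] = (0.05, 1.5)
    ) -> "EvidencePriors":
        """Scale-aware defaults: bounds proportional to the data RMS."""
        rms = float(np.sqrt(np.mean(ts.values**2)))
        rms = rms if rms > 0 else 1.0
        return cls(
            delta_bounds=(0.01 * rms, 100.0 * rms),
            gamma_bounds=gamma_bounds,
            sigma_bounds=(0.001 * rms, 10.0 * rms),
        )


@dataclass(frozen=True)
class EvidenceResult:
    """Log evidence of one model on one trace."""

    log_evidence: float
    method: str                       # "laplace" | "nested"
    err: float                        # nats; 0 for laplace
    mode: np.ndarray                  # omega at the likelihood peak
    spec: ModelSpec
    priors: EvidencePriors
    data_fingerprint: str
    hessian_logdet: float = np.nan    # laplace only

    def __post_init__(self) -> None:
        if self.err < 0:
            raise ValueError("err must be >= 0")


def _fingerprint(ts: TimeSeries) -> str:
    hsh = hashlib.sha1()
    hsh.update(ts.times.tobytes())
    hsh.update(ts.values.tobytes())
    return hsh.hexdigest()


def _log_occupancy_and_fit(ts: TimeSeries, spec: ModelSpec, omega) -> float:
    """omega-dependent part of the log evidence at a given omega.

    ((m - N)/2) * log(N*d2_bar - m*h2_bar)  - (m/2) * log(h2_bar)
    i.e. the sigma-marginalised fit term plus the amplitude-occupancy
    factor from the Gaussian amplitude priors at their peak scale.
    """
    n, m, frac = _explained_fraction(ts, spec, omega)
    total = n * float(np.mean(ts.values**2))
    resid = max((1.0 - frac) * total, total * np.finfo(float).eps)
    h2 = max(frac * total / m, np.finfo(float).tiny)
    return 0.5 * (m - n) * np.log(resid) - 0.5 * m * np.log(h2)


def _log_const(n: int, m: int, priors: EvidencePriors) -> float:
    """omega-independent evidence terms shared by Laplace and NS routes."""
    k = n - m
    out = (
        -0.5 * k * np.log(2 * np.pi)
        + gammaln(0.5 * k)
        + (0.5 * k - 1.0) * np.log(2.0)
        - np.log(priors.log_r_sigma)
    )
    if m > 0:
        out += (
            -0.5 * m * np.log(2 * np.pi)
            - 0.5 * m
            + 0.5 * (np.log(np.pi) - np.log(m))
            - np.log(priors.log_r_delta)
        )
    return float(out)


def _check_unimodal(ts, spec, grid, logp) -> None:
    dens = np.exp(logp - np.max(logp[np.isfinite(logp)]))
    dens[~np.isfinite(logp)] = 0.0
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] > dens[2:])
    n_peaks = int(np.sum(interior & (dens[1:-1] > 0.01 * dens.max())))
    for end, nb in ((0, 1), (-1, -2)):
        if dens[end] > dens[nb] and dens[end] > 0.01 * dens.max():
            n_peaks += 1
    if n_peaks > 1:
        raise MultimodalPosteriorError(
            f"{n_peaks} posterior peaks above 1% of the maximum; "
            "use nested_log_evidence"
        )


def laplace_log_evidence(
    ts: TimeSeries,
    spec: ModelSpec,
    priors: EvidencePriors | None = None,
    n_grid: int = 500,
) -> EvidenceResult:
    """Laplace (saddle-point) evidence of a unimodal-posterior model.

    Supports r = 0 (background-only, no frequency integral) and r = 1.
    For r >= 2 the posterior is never unimodal (component relabelling
    alone gives r! peaks), so the caller is directed to nested sampling.
    The frequency integral is expanded to second order around the
    refined posterior peak; the Hessian comes from central finite
    differences of the log posterior.
    """
    if priors is None:
        priors = EvidencePriors.from_data(ts)
    if spec.n_frequencies >= 2:
        raise MultimodalPosteriorError(
            "Laplace evidence supports r <= 1; multi-frequency posteriors "
            "are multimodal by symmetry - use nested_log_evidence"
        )
    n, m = ts.n, spec.m
    if n <= m + 2:
        raise ValueError(f"need N > m + 2 (N={n}, m={m})")

    base = _log_const(n, m, priors)
    if spec.n_frequencies == 0:
        logz = base + _log_occupancy_and_fit(ts, spec, np.empty(0))
        return EvidenceResult(
            log_evidence=float(logz),
            method="laplace",
            err=0.0,
            mode=np.empty(0),
            spec=spec,
            priors=priors,
            data_fingerprint=_fingerprint(ts),
        )

    glo, ghi = priors.gamma_bounds
    grid, logp, coarse = scan(ts, spec, glo, ghi, n_grid)
    _check_unimodal(ts, spec, grid, logp)
    step = (ghi - glo) / (n_grid - 1)
    mode = refine_peak(ts, spec, coarse, step=step, bounds=(glo, ghi))
    fine = fine_sample(ts, spec, mode)
    if fine["n_modes"] > 1:
        raise MultimodalPosteriorError(
            "fine-sampled posterior is multimodal; use nested_log_evidence"
        )
    w_hat = float(fine["peak"][0])

    h = max(1e-6, 1e-4 * w_hat)
    g0 = _safe_log_posterior(ts, spec, w_hat)
    gp = _safe_log_posterior(ts, spec, w_hat + h)
    gm = _safe_log_posterior(ts, spec, w_hat - h)
    d2 = (gp - 2.0 * g0 + gm) / h**2
    if not np.isfinite(d2) or d2 >= 0:
        # flat or cap-dominated curvature: fall back to the sampled width
        sd = float(fine["sd"][0])
        if sd <= 0:
            raise MultimodalPosteriorError(
                "posterior curvature not negative definite at the peak"
            )
        d2 = -1.0 / sd**2
    hess_logdet = float(np.log(-d2))

    logz = (
        base
        + _log_occupancy_and_fit(ts, spec, w_hat)
        + 0.5 * np.log(2 * np.pi)
        - 0.5 * hess_logdet
        - np.log(ghi - glo)
    )
    return EvidenceResult(
        log_evidence=float(logz),
        method="laplace",
        err=0.0,
        mode=np.array([w_hat]),
        spec=spec,
        priors=priors,
        data_fingerprint=_fingerprint(ts),
        hessian_logdet=hess_logdet,
    )


def nested_log_evidence(
    ts: TimeSeries,
    spec: ModelSpec,
    priors: EvidencePriors | None = None,
    cfg: NSConfig | None = None,
    seed: int = 0,
) -> EvidenceResult:
    """Model evidence via nested sampling of the frequency posterior.

    Valid for any modality and any r >= 1; shares all omega-independent
    terms with the Laplace route so the two agree on unimodal problems.
    """
    if priors is None:
        priors = EvidencePriors.from_data(ts)
    if spec.n_frequencies < 1:
        raise ValueError("nested evidence needs r >= 1; use laplace for r = 0")
    if cfg is None:
        cfg = NSConfig(
            seed=seed, prior_box=[priors.gamma_bounds] * spec.n_frequencies
        )
    ns = nested_sample(ts, spec, cfg)
    n, m, frac = _explained_fraction(ts, spec, ns.omega_map)
    total = n * float(np.mean(ts.values**2))
    # ns integrates the log1p-normalised posterior (R / (N d2_bar))^((m-N)/2);
    # rescale to the absolute fit term and add the occupancy factor at the MAP
    conv = 0.5 * (m - n) * np.log(total)
    h2 = max(frac * total / m, np.finfo(float).tiny)
    occ = -0.5 * m * np.log(h2)
    logz = _log_const(n, m, priors) + ns.log_evidence + conv + occ
    return EvidenceResult(
        log_evidence=float(logz),
        method="nested",
        err=ns.log_evidence_err,
        mode=ns.omega_map,
        spec=spec,
        priors=priors,
        data_fingerprint=_fingerprint(ts),
    )


def posterior_ratio(ev_a: EvidenceResult, ev_b: EvidenceResult) -> tuple[float, float]:
    """Evidence (posterior) ratio of two models under equal model priors.

    Returns (ratio, log_ratio).  Requires both evidences to come from the
    same data with the same prior bounds, so that all shared bound terms
    cancel.
    """
    if ev_a.data_fingerprint != ev_b.data_fingerprint:
        raise ValueError("evidences come from different data")
    if ev_a.priors != ev_b.priors:
        raise ValueError("evidences use different prior bounds; ratio invalid")
    log_ratio = ev_a.log_evidence - ev_b.log_evidence
    return float(np.exp(log_ratio)), float(log_ratio)


def _model_evidence(ts, spec, priors, seed=0) -> EvidenceResult:
    """Laplace when the posterior allows it, nested sampling otherwise."""
    if spec.n_frequencies <= 1:
        try:
            return laplace_log_evidence(ts, spec, priors)
        except MultimodalPosteriorError:
            pass
        if spec.n_frequencies == 0:
            raise
    return nested_log_evidence(ts, spec, priors, seed=seed)


@dataclass
class SelectionResult:
    """Outcome of a greedy pairwise model-development loop."""

    selected: int
    trace: list[tuple[str, float]] = field(default_factory=list)
    converged: bool = True
    status: str = "local"             # greedy search: local, not global
    evidences: dict = field(default_factory=dict)


def select_background_order(
    ts: TimeSeries,
    base_spec: ModelSpec | None = None,
    max_order: int = 6,
    priors: EvidencePriors | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Choose the Legendre background order by pairwise evidence ratios.

    Starting from no background (-1), compares order n against n+1 and
    stops at the first ratio above 1 (the simpler model wins).  The
    trace records every ratio computed, mirroring the
    model-development tables of the methodology.
    """
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    r = base_spec.n_frequencies if base_spec is not None else 1
    if priors is None:
        priors = EvidencePriors.from_data(ts)

    evidences: dict[int, EvidenceResult] = {}

    def ev(order: int) -> EvidenceResult:
        if order not in evidences:
            evidences[order] = _model_evidence(
                ts, ModelSpec(r, order), priors, seed=seed
            )
        return evidences[order]

    trace: list[tuple[str, float]] = []
    for order in range(-1, max_order):
        ratio, _ = posterior_ratio(ev(order), ev(order + 1))
        trace.append((f"H_{order}/H_{order + 1}", ratio))
        if ratio > 1.0:
            return SelectionResult(order, trace, True, evidences=evidences)
    warnings.warn(
        f"background selection did not converge by order {max_order}",
        RuntimeWarning,
    )
    return SelectionResult(max_order, trace, False, evidences=evidences)


def select_num_frequencies(
    ts: TimeSeries,
    background_order: int = -1,
    max_r: int = 3,
    priors: EvidencePriors | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Choose the number of frequencies by pairwise evidence ratios.

    r = 1 uses the Laplace evidence when its posterior is unimodal and
    falls back to nested sampling otherwise; r >= 2 always uses nested
    sampling.  Stops at the first H_r / H_{r+1} ratio above 1.
    """
    if max_r < 1:
        raise ValueError("max_r must be >= 1")
    if priors is None:
        priors = EvidencePriors.from_data(ts)

    evidences: dict[int, EvidenceResult] = {}

    def ev(r: int) -> EvidenceResult:
        if r not in evidences:
            evidences[r] = _model_evidence(
                ts, ModelSpec(r, background_order), priors, seed=seed
            )
        return evidences[r]

    trace: list[tuple[str, float]] = []
    for r in range(1, max_r):
        ratio, _ = posterior_ratio(ev(r), ev(r + 1))
        trace.append((f"H_{r}w/H_{r + 1}w", ratio))
        if ratio > 1.0:
            return SelectionResult(r, trace, True, evidences=evidences)
    if max_r == 1:
        ev(1)
    warnings.warn(
        f"frequency-count selection did not converge by r = {max_r}",
        RuntimeWarning,
    )
    return SelectionResult(max_r, trace, False, evidences=evidences)
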