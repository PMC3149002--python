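"""Nested sampling over the frequency box.

Evidence integrals over omega are one- or two-dimensional here because
the amplitudes and the noise scale are marginalised analytically; the
nested-sampling "likelihood" is therefore the marginal log posterior of
omega itself, under a uniform prior on the configured box.  Nested
sampling replaces the worst live point with a draw from the prior
constrained to higher likelihood, shrinking the enclosed prior volume
geometrically; the evidence accumulates as the sum of shell volumes
times their likelihoods.  It needs no unimodality assumption, which is
what makes it the right tool for multi-frequency models (label-switching
symmetry, harmonic ridges) where a Laplace expansion around one peak is
ill-posed.

Constrained draws come from plain rejection sampling in the box while
that is cheap, with a shrinkage slice-sampling fallback once the
constrained region becomes too small for rejection to be practical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import ModelSpec
from .core import _make_loglike
from .timeseries import TimeSeries

__all__ = ["NSConfig", "NSResult", "nested_sample", "nested_sample_func"]


@dataclass(frozen=True)
class NSConfig:
    """Nested-sampling settings."""

    n_live: int = 400
    termination_frac: float = 1e-3
    seed: int = 0
    prior_box: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.05, 1.5)]
    )
    max_iter: int = 200_000
    slice_sweeps: int = 3

    def __post_init__(self) -> None:
        if self.n_live < 50:
            raise ValueError("n_live must be >= 50")
        if not (0 < self.termination_frac < 0.1):
            raise ValueError("termination_frac must be in (0, 0.1)")
        for lo, hi in self.prior_box:
            if not (0 < lo < hi):
                raise ValueError("prior box bounds must satisfy 0 < low < high")


@dataclass
class NSResult:
    """Evidence and weighted posterior draws from one nested-sampling run."""

    log_evidence: float
    log_evidence_err: float
    samples: np.ndarray        # (n_samples, r) omega draws
    logl: np.ndarray           # (n_samples,)
    weights: np.ndarray        # normalised posterior weights, sum to 1
    omega_mean: np.ndarray     # (r,), components sorted ascending per draw
    omega_sd: np.ndarray       # (r,)
    omega_map: np.ndarray      # highest-likelihood draw, sorted ascending
    information: float         # H in nats
    n_iter: int


class _ConstrainedSampler:
    """Draw uniformly from {omega in box : loglike(omega) > threshold}."""

    def __init__(self, loglike, box: np.ndarray, rng: np.random.Generator,
                 slice_sweeps: int):
        self.loglike = loglike
        self.lo = box[:, 0]
        self.hi = box[:, 1]
        self.rng = rng
        self.slice_sweeps = slice_sweeps
        self.use_slice = False
        self.n_calls = 0

    def _eval(self, x):
        self.n_calls += 1
        return self.loglike(x)

    def draw(self, threshold: float, live: np.ndarray, live_logl: np.ndarray):
        if not self.use_slice:
            # rejection from the full box while acceptance is decent; once a
            # draw needs more than ~30 tries the constrained region is small
            # and slice sampling is cheaper from then on
            for _ in range(30):
                x = self.rng.uniform(self.lo, self.hi)
                lx = self._eval(x)
                if lx > threshold:
                    return x, lx
            self.use_slice = True
        return self._slice_draw(threshold, live, live_logl)

    def _slice_draw(self, threshold, live, live_logl):
        ok = np.nonzero(live_logl > threshold)[0]
        strict = True
        if ok.size == 0:
            # likelihood plateau (e.g. the perfect-fit cap): every live point
            # ties with the threshold, so ties count as inside the constraint
            ok = np.nonzero(live_logl >= threshold)[0]
            strict = False
        if ok.size == 0:
            raise RuntimeError(
                "no live point above the likelihood threshold; cannot seed "
                "the constrained draw"
            )
        idx = ok[self.rng.integers(ok.size)]
        x = live[idx].copy()
        lx = live_logl[idx]
        r = x.size
        # Initial slice intervals sized from the live-point spread: the live
        # set samples the constrained region, so a window of ~1.2x its range
        # centred on the current point covers it while avoiding O(log(V))
        # shrinkage steps from the full prior box.  A window-plus-shrinkage
        # update has the correct (uniform) stationary distribution even when
        # the window does not span the whole region.
        span = 1.2 * (live[ok].max(axis=0) - live[ok].min(axis=0))
        span = np.maximum(span, 1e-3 * (self.hi - self.lo))
        for _ in range(self.slice_sweeps):
            for j in self.rng.permutation(r):
                lo = max(self.lo[j], x[j] - span[j])
                hi = min(self.hi[j], x[j] + span[j])
                for _shrink in range(200):
                    u = self.rng.uniform(lo, hi)
                    trial = x.copy()
                    trial[j] = u
                    lt = self._eval(trial)
                    if lt > threshold or (not strict and lt >= threshold):
                        x, lx = trial, lt
                        break
                    if u < x[j]:
                        lo = u
                    else:
                        hi = u
                # interval collapse keeps the current point (still valid)
        return x, lx


def nested_sample_func(loglike, cfg: NSConfig) -> NSResult:
    """Nested sampling of an arbitrary log-likelihood over cfg.prior_box."""
    rng = np.random.default_rng(cfg.seed)
    box = np.asarray(cfg.prior_box, float)
    r = box.shape[0]
    vol = float(np.prod(box[:, 1] - box[:, 0]))
    log_prior = -np.log(vol)  # uniform; Z below is mean of L over the prior

    live = rng.uniform(box[:, 0], box[:, 1], size=(cfg.n_live, r))
    live_logl = np.array([loglike(x) for x in live])
    sampler = _ConstrainedSampler(loglike, box, rng, cfg.slice_sweeps)

    dead_x, dead_logl, dead_logw = [], [], []
    log_z = -np.inf
    log_x = 0.0                      # log of the enclosed prior volume fraction
    dlog_x = -1.0 / cfg.n_live
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        worst = int(np.argmin(live_logl))
        l_star = live_logl[worst]
        log_x_new = n_iter * dlog_x
        # shell width in prior-volume terms
        log_w = np.log(np.exp(log_x) - np.exp(log_x_new))
        log_z = np.logaddexp(log_z, log_w + l_star)
        dead_x.append(live[worst].copy())
        dead_logl.append(l_star)
        dead_logw.append(log_w)
        log_x = log_x_new

        x_new, l_new = sampler.draw(l_star, live, live_logl)
        live[worst] = x_new
        live_logl[worst] = l_new

        remaining = live_logl.max() + log_x - log_z
        if remaining < np.log(cfg.termination_frac):
            break

    # fold in the surviving live points
    log_w_live = log_x - np.log(cfg.n_live)
    for i in range(cfg.n_live):
        log_z = np.logaddexp(log_z, log_w_live + live_logl[i])
        dead_x.append(live[i].copy())
        dead_logl.append(live_logl[i])
        dead_logw.append(log_w_live)

    samples = np.asarray(dead_x)
    logl = np.asarray(dead_logl)
    logw = np.asarray(dead_logw)
    log_post_w = logw + logl - log_z
    weights = np.exp(log_post_w)
    weights /= weights.sum()

    finite = weights > 0
    info = float(np.sum(weights[finite] * (logl[finite] - log_z)))
    err = float(np.sqrt(max(info, 0.0) / cfg.n_live))

    sorted_samples = np.sort(samples, axis=1)
    mean = weights @ sorted_samples
    sd = np.sqrt(np.maximum(weights @ (sorted_samples - mean) ** 2, 0.0))
    omega_map = np.sort(samples[int(np.argmax(logl))])

    return NSResult(
        log_evidence=float(log_z),
        log_evidence_err=err,
        samples=samples,
        logl=logl,
        weights=weights,
        omega_mean=mean,
        omega_sd=sd,
        omega_map=omega_map,
        information=info,
        n_iter=n_iter,
    )


def nested_sample(ts: TimeSeries, spec: ModelSpec, cfg: NSConfig) -> NSResult:
    """Nested sampling of the marginal frequency posterior of a model.

    The reported log_evidence is log of the prior-averaged posterior
    density, i.e. log (1/V) * integral of exp(log_posterior) over the
    box; the model-level constants are added by the evidence module.
    Deterministic for a fixed config (seed included).
    """
    if len(cfg.prior_box) != spec.n_frequencies:
        raise ValueError("prior_box dimension must equal n_frequencies")
    return nested_sample_func(_make_loglike(ts, spec), cfg)
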