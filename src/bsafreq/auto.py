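"""Fully automated analysis: model development followed by estimation.

The pipeline follows the model-development flowchart: first the Legendre
background order is chosen by pairwise evidence ratios, then the number
of frequencies, then the selected model's posterior is scanned, refined
and finely sampled (through nested sampling when it is multi-frequency),
and noise / signal-to-noise / amplitude summaries are attached.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator

from .core import BayesianSpectrum
from .evidence import (
    EvidencePriors,
    select_background_order,
    select_num_frequencies,
)
from .timeseries import TimeSeries

__all__ = ["AutoBayesianSpectrum"]

logger = logging.getLogger("bsafreq")


class AutoBayesianSpectrum(BaseEstimator):
    """Evidence-driven model development plus frequency estimation.

    Parameters
    ----------
    max_background_order : int, default 6
        Upper limit of the Legendre background search.
    max_frequencies : int, default 2
        Upper limit of the frequency-count search.
    omega_min, omega_max : float
        Frequency search window (also the frequency prior bounds used in
        the evidences, so ratios cancel their bound terms).
    n_grid, n_fine, n_live, seed : passed to the underlying machinery.

    Attributes (after fit)
    ----------------------
    background_order_, n_frequencies_ : the selected model
    background_trace_, frequency_trace_ : evidence-ratio traces
    estimator_ : the fitted BayesianSpectrum for the selected model
    omega_, sigma_omega_, period_, noise_sigma_, snr_ : its summaries
    status_ : "local" - greedy model development, not a global search
    """

    def __init__(
        self,
        max_background_order: int = 6,
        max_frequencies: int = 2,
        omega_min: float = 0.05,
        omega_max: float = 1.5,
        n_grid: int = 500,
        n_fine: int = 400,
        n_live: int = 400,
        seed: int = 0,
    ):
        self.max_background_order = max_background_order
        self.max_frequencies = max_frequencies
        self.omega_min = omega_min
        self.omega_max = omega_max
        self.n_grid = n_grid
        self.n_fine = n_fine
        self.n_live = n_live
        self.seed = seed

    def fit(self, X, y=None):
        if isinstance(X, TimeSeries) and y is None:
            ts = X
        else:
            t = np.asarray(X, float)
            if t.ndim == 2:
                t = t[:, 0]
            ts = TimeSeries(t, np.asarray(y, float))

        priors = EvidencePriors.from_data(
            ts, gamma_bounds=(self.omega_min, self.omega_max)
        )
        bg = select_background_order(
            ts,
            max_order=self.max_background_order,
            priors=priors,
            seed=self.seed,
        )
        for label, ratio in bg.trace:
            logger.info("background ratio %s = %.4g", label, ratio)
        logger.info("selected background order %d", bg.selected)

        freq = select_num_frequencies(
            ts,
            background_order=bg.selected,
            max_r=self.max_frequencies,
            priors=priors,
            seed=self.seed,
        )
        for label, ratio in freq.trace:
            logger.info("frequency ratio %s = %.4g", label, ratio)
        logger.info("selected %d frequencies", freq.selected)

        est = BayesianSpectrum(
            n_frequencies=freq.selected,
            background_order=bg.selected,
            omega_min=self.omega_min,
            omega_max=self.omega_max,
            n_grid=self.n_grid,
            n_fine=self.n_fine,
            n_live=self.n_live,
            ns_seed=self.seed,
        ).fit(ts)

        self.priors_ = priors
        self.background_order_ = bg.selected
        self.n_frequencies_ = freq.selected
        self.background_trace_ = bg.trace
        self.frequency_trace_ = freq.trace
        self.selection_converged_ = bg.converged and freq.converged
        self.status_ = "local"
        self.estimator_ = est
        self.omega_ = est.omega_
        self.sigma_omega_ = est.sigma_omega_
        self.period_ = est.period_
        self.noise_sigma_ = est.noise_sigma_
        self.snr_ = est.snr_
        self.n_modes_ = est.n_modes_
        return self
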