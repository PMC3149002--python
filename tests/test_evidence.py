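"""Evidence computation and evidence-ratio model development."""

import numpy as np
import pytest

from bsafreq.basis import ModelSpec
from bsafreq.evidence import (
    EvidencePriors,
    MultimodalPosteriorError,
    laplace_log_evidence,
    nested_log_evidence,
    posterior_ratio,
    select_background_order,
    select_num_frequencies,
)
from bsafreq.nested import NSConfig
from bsafreq.simulate import fixture


class TestPriors:
    def test_validation(self):
        with pytest.raises(ValueError):
            EvidencePriors((1.0, 0.1), (0.05, 1.5), (0.01, 1.0))
        with pytest.raises(ValueError):
            EvidencePriors((0.1, 1.0), (-0.1, 1.5), (0.01, 1.0))

    def test_from_data_scales_with_rms(self):
        _, ts = fixture("table2_row2", seed=0)
        p1 = EvidencePriors.from_data(ts)
        p2 = EvidencePriors.from_data(ts.scaled(10.0))
        assert p2.delta_bounds[0] == pytest.approx(10 * p1.delta_bounds[0])
        assert p2.log_r_delta == pytest.approx(p1.log_r_delta)


class TestLaplace:
    def test_rejects_multifrequency(self):
        _, ts = fixture("table2_row2", seed=0)
        with pytest.raises(MultimodalPosteriorError):
            laplace_log_evidence(ts, ModelSpec(2, -1))

    def test_background_only_model(self):
        _, ts = fixture("s1_trend", seed=1)
        ev = laplace_log_evidence(ts, ModelSpec(0, 2))
        assert np.isfinite(ev.log_evidence)
        assert ev.method == "laplace"
        assert ev.mode.size == 0


class TestLaplaceVsNested:
    def test_agreement_within_one_nat(self):
        """The mandatory cross-check: both routes integrate the same
        posterior, so on a unimodal problem they must agree."""
        _, ts = fixture("table2_row2", seed=2)
        spec = ModelSpec(1, -1)
        priors = EvidencePriors.from_data(ts)
        lap = laplace_log_evidence(ts, spec, priors)
        ns = nested_log_evidence(ts, spec, priors, seed=0)
        assert abs(lap.log_evidence - ns.log_evidence) < 1.0

    def test_agreement_with_background(self):
        _, ts = fixture("s1_trend", seed=2)
        spec = ModelSpec(1, 2)
        priors = EvidencePriors.from_data(ts)
        lap = laplace_log_evidence(ts, spec, priors)
        ns = nested_log_evidence(ts, spec, priors, seed=0)
        assert abs(lap.log_evidence - ns.log_evidence) < 1.0


class TestPosteriorRatio:
    def test_requires_same_data(self):
        _, a = fixture("table2_row2", seed=1)
        _, b = fixture("table2_row2", seed=2)
        priors = EvidencePriors.from_data(a)
        ev_a = laplace_log_evidence(a, ModelSpec(1, -1), priors)
        ev_b = laplace_log_evidence(b, ModelSpec(1, -1), priors)
        with pytest.raises(ValueError, match="different data"):
            posterior_ratio(ev_a, ev_b)

    def test_requires_same_priors(self):
        _, ts = fixture("table2_row2", seed=1)
        p1 = EvidencePriors.from_data(ts)
        p2 = EvidencePriors((0.1, 10.0), (0.05, 1.5), (0.001, 1.0))
        ev_a = laplace_log_evidence(ts, ModelSpec(1, -1), p1)
        ev_b = laplace_log_evidence(ts, ModelSpec(1, 0), p2)
        with pytest.raises(ValueError, match="prior bounds"):
            posterior_ratio(ev_a, ev_b)

    def test_ratio_value(self):
        _, ts = fixture("table2_row2", seed=1)
        priors = EvidencePriors.from_data(ts)
        ev_a = laplace_log_evidence(ts, ModelSpec(1, -1), priors)
        ev_b = laplace_log_evidence(ts, ModelSpec(1, 0), priors)
        ratio, log_ratio = posterior_ratio(ev_a, ev_b)
        assert ratio == pytest.approx(np.exp(log_ratio))


class TestOccam:
    def test_extra_background_penalised_on_clean_data(self):
        """On untrended data the model without background must win."""
        _, ts = fixture("table2_row2", seed=3)
        priors = EvidencePriors.from_data(ts)
        no_bg = laplace_log_evidence(ts, ModelSpec(1, -1), priors)
        with_bg = laplace_log_evidence(ts, ModelSpec(1, 1), priors)
        assert no_bg.log_evidence > with_bg.log_evidence


class TestSelection:
    def test_background_order_on_linear_trend(self):
        _, ts = fixture("table2_row8", seed=1)  # linear trend
        sel = select_background_order(ts, max_order=4)
        assert sel.selected == 1
        assert sel.status == "local"
        labels = [lab for lab, _ in sel.trace]
        assert labels[0] == "H_-1/H_0"
        # every ratio before the stopping one favoured the larger model
        assert all(r < 1 for _, r in sel.trace[:-1])
        assert sel.trace[-1][1] > 1

    def test_background_order_none_needed(self):
        _, ts = fixture("table2_row2", seed=1)
        sel = select_background_order(ts, max_order=4)
        assert sel.selected == -1

    def test_num_frequencies_single_tone(self):
        _, ts = fixture("case_a_single", seed=1)
        sel = select_num_frequencies(
            ts, max_r=2, seed=0,
        )
        assert sel.selected == 1
        assert sel.trace[0][0] == "H_1w/H_2w"
        assert sel.trace[0][1] > 1
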