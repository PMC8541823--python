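"""Unit and property tests for the mEPSP quantal analysis stage."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synaptoquant.exceptions import (
    DomainError,
    EmptyInputError,
    ValidationError,
)
from synaptoquant.quantal import (
    AmplitudeHistogram,
    EventSeries,
    QuantalMixtureModel,
    QuantalParams,
    build_histogram,
    mepsp_frequency,
    peak_density,
    peak_sd,
    quantal_content_pmf,
    theoretical_distribution,
)
from synaptoquant.simulate import simulate_mepsp_events


class TestHistogram:
    def test_two_events_two_bins(self):
        h = build_histogram([0.005, 0.015], bin_width=0.01)
        assert np.array_equal(h.counts, [1, 1])
        assert np.allclose(h.bin_edges, [0.0, 0.01, 0.02])

    def test_default_bin_width_is_hundredth_millivolt(self):
        h = build_histogram([0.5, 1.0])
        assert h.bin_width == pytest.approx(0.01)

    def test_every_event_counted_once(self, reference_model):
        events, _ = simulate_mepsp_events(reference_model, 1000, seed=7)
        h = build_histogram(events)
        assert h.n_events == 1000

    def test_edge_amplitude_goes_to_right_bin(self):
        h = build_histogram([0.02], bin_width=0.01)
        assert np.array_equal(h.counts, [0, 0, 1])

    def test_trailing_bin_nonempty(self):
        h = build_histogram([0.005, 0.031], bin_width=0.01)
        assert h.counts[-1] == 1 and h.counts.size == 4

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInputError):
            build_histogram([])

    def test_nonpositive_bin_width_raises(self):
        with pytest.raises(ValidationError):
            build_histogram([0.5], bin_width=0.0)


class TestQuantalContentPmf:
    def test_single_quantum_untruncated(self):
        m = QuantalParams(q=1, sigma0=0.1, n=1, p=0.5, truncated=False)
        assert quantal_content_pmf(m, 1) == pytest.approx(0.5)

    def test_four_choose_two(self):
        m = QuantalParams(q=1, sigma0=0.1, n=4, p=0.5, truncated=False)
        assert quantal_content_pmf(m, 2) == pytest.approx(0.375)

    @given(n=st.integers(1, 12), p=st.floats(0.01, 0.99))
    @settings(max_examples=40, deadline=None)
    def test_matches_bruteforce_binomial_and_normalises(self, n, p):
        """Exhaustive comparison against C(n,i) p^i (1-p)^(n-i) computed from
        scratch, in both truncation modes, plus normalisation."""
        brute = [math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
        m_u = QuantalParams(q=1, sigma0=0.1, n=n, p=p, truncated=False)
        m_t = QuantalParams(q=1, sigma0=0.1, n=n, p=p, truncated=True)
        for i in range(n + 1):
            assert quantal_content_pmf(m_u, i) == pytest.approx(brute[i], abs=1e-12)
        total_t = sum(quantal_content_pmf(m_t, i) for i in range(n + 1))
        total_u = sum(quantal_content_pmf(m_u, i) for i in range(n + 1))
        assert total_u == pytest.approx(1.0, abs=1e-9)
        assert total_t == pytest.approx(1.0, abs=1e-9)
        assert quantal_content_pmf(m_t, 0) == 0.0
        trunc_brute = brute[1] / (1 - brute[0])
        assert quantal_content_pmf(m_t, 1) == pytest.approx(trunc_brute, abs=1e-12)

    def test_out_of_range_content_raises(self):
        m = QuantalParams(q=1, sigma0=0.1, n=3, p=0.5)
        with pytest.raises(DomainError):
            quantal_content_pmf(m, 4)
        with pytest.raises(DomainError):
            quantal_content_pmf(m, -1)


class TestPeakShape:
    def test_single_quantum_sd_is_sigma0(self):
        m = QuantalParams(q=1, sigma0=0.07, n=5, p=0.5)
        assert peak_sd(m, 1) == pytest.approx(0.07)

    @pytest.mark.parametrize("exponent,expected", [(0.5, 0.10), (1.0, 0.20)])
    def test_sd_growth_law(self, exponent, expected):
        m = QuantalParams(q=1, sigma0=0.05, n=5, p=0.5, peak_sd_exponent=exponent)
        assert peak_sd(m, 4) == pytest.approx(expected)

    def test_peak_index_below_one_raises(self):
        m = QuantalParams(q=1, sigma0=0.05, n=5, p=0.5)
        with pytest.raises(DomainError):
            peak_sd(m, 0)

    def test_density_peak_value_and_symmetry(self):
        assert peak_density(0.0, 1.0, 0.0) == pytest.approx(1 / math.sqrt(2 * math.pi))
        for a in (0.3, 1.7):
            assert peak_density(2.0, 0.5, 2 + a) == pytest.approx(peak_density(2.0, 0.5, 2 - a))

    def test_density_integrates_to_one(self):
        y = np.linspace(-8, 8, 20001)
        total = np.trapezoid(peak_density(0.0, 1.0, y), y)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_sigma_raises(self):
        with pytest.raises(DomainError):
            peak_density(0.0, 0.0, 1.0)


class TestTheoreticalDistribution:
    def test_mass_conserved_when_range_covers_model(self, reference_model):
        edges = 0.01 * np.arange(0, 501)
        hist = AmplitudeHistogram(bin_edges=edges, counts=np.zeros(500))
        theo = theoretical_distribution(reference_model, 750, hist)
        assert theo.total == pytest.approx(750, rel=1e-6)
        assert theo.warning is None

    def test_zero_width_peaks_concentrate_at_multiples_of_q(self):
        m = QuantalParams(q=0.6, sigma0=0.0, n=3, p=0.4)
        edges = 0.01 * np.arange(0, 301)
        hist = AmplitudeHistogram(bin_edges=edges, counts=np.zeros(300))
        theo = theoretical_distribution(m, 1000, hist)
        nonzero = np.flatnonzero(theo.expected_counts)
        # bins containing 0.6, 1.2, 1.8
        assert nonzero.tolist() == [60, 120, 180]
        weights = theo.expected_counts[nonzero] / 1000
        expect = [quantal_content_pmf(m, i) for i in (1, 2, 3)]
        assert np.allclose(weights, expect, atol=1e-12)

    def test_narrow_range_reports_excluded_mass(self, reference_model):
        edges = 0.01 * np.arange(0, 101)  # only up to 1 mV; peaks beyond
        hist = AmplitudeHistogram(bin_edges=edges, counts=np.zeros(100))
        theo = theoretical_distribution(reference_model, 500, hist)
        assert theo.mass_outside > 0.01
        assert theo.warning is not None


class TestFit:
    def _noiseless_hist(self, params: QuantalParams, n_events=1000, n_bins=450):
        edges = 0.01 * np.arange(0, n_bins + 1)
        empty = AmplitudeHistogram(bin_edges=edges, counts=np.zeros(n_bins))
        theo = theoretical_distribution(params, n_events, empty)
        return AmplitudeHistogram(bin_edges=edges, counts=theo.expected_counts)

    def test_noiseless_self_consistency(self):
        true = QuantalParams(q=0.6, sigma0=0.08, n=5, p=0.3)
        res = QuantalMixtureModel(self._noiseless_hist(true)).fit(seed=0)
        assert res.params.q == pytest.approx(0.6, abs=1e-3)
        assert res.params.n == 5
        assert res.params.sigma0 == pytest.approx(0.08, rel=0.05)
        assert res.params.p == pytest.approx(0.3, rel=0.05)
        assert res.quantal_size == res.params.q

    def test_single_sharp_peak_recovers_q_within_one_bin(self):
        true = QuantalParams(q=0.55, sigma0=0.55 * 0.02, n=1, p=0.5)
        res = QuantalMixtureModel(self._noiseless_hist(true, n_bins=120)).fit(seed=0)
        assert res.params.q == pytest.approx(0.55, abs=0.01)

    def test_fitted_q_monotone_in_true_q_on_noiseless_inputs(self):
        fitted = []
        for q in (0.45, 0.6, 0.75):
            true = QuantalParams(q=q, sigma0=0.08, n=4, p=0.35)
            res = QuantalMixtureModel(self._noiseless_hist(true)).fit(seed=1)
            fitted.append(res.params.q)
        assert fitted[0] <= fitted[1] <= fitted[2]

    def test_fit_invariant_to_trailing_empty_bins(self):
        true = QuantalParams(q=0.6, sigma0=0.08, n=5, p=0.3)
        base = self._noiseless_hist(true)
        padded = AmplitudeHistogram(
            bin_edges=0.01 * np.arange(0, 551),
            counts=np.concatenate([base.counts, np.zeros(100)]),
        )
        r1 = QuantalMixtureModel(base).fit(seed=0)
        r2 = QuantalMixtureModel(padded).fit(seed=0)
        assert r2.params.q == pytest.approx(r1.params.q, abs=1e-6)
        assert r2.objective == pytest.approx(r1.objective, abs=1e-6)

    def test_expected_counts_conserve_events(self, reference_model):
        events, _ = simulate_mepsp_events(reference_model, 400, seed=3)
        res = QuantalMixtureModel.from_events(events).fit(seed=3)
        assert res.expected_counts.sum() + res.mass_outside * res.n_events == pytest.approx(
            res.n_events, rel=1e-6
        )

    def test_too_few_events_rejected(self):
        with pytest.raises(ValidationError):
            QuantalMixtureModel(build_histogram([0.5] * 10))

    def test_summary_reports_configuration(self, reference_model):
        events, _ = simulate_mepsp_events(reference_model, 300, seed=5)
        res = QuantalMixtureModel.from_events(events).fit(seed=5)
        text = res.summary()
        assert "quantal size q" in text and "peak SD exponent" in text


class TestFrequency:
    def test_two_hertz(self):
        ev = EventSeries(amplitudes=np.full(120, 0.5), duration=60.0)
        assert mepsp_frequency(ev) == pytest.approx(2.0)

    def test_zero_events(self):
        ev = EventSeries(amplitudes=np.array([]), duration=60.0)
        assert mepsp_frequency(ev) == 0.0

    def test_concatenating_identical_recordings_preserves_frequency(self):
        a = EventSeries(amplitudes=np.full(30, 0.4), duration=15.0)
        both = EventSeries(amplitudes=np.full(60, 0.4), duration=30.0)
        assert mepsp_frequency(both) == pytest.approx(mepsp_frequency(a))

    def test_missing_duration_raises(self):
        ev = EventSeries(amplitudes=np.array([0.5]))
        with pytest.raises(ValidationError):
            mepsp_frequency(ev)
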