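"""Spike detection, sorting, PSTH construction and unit metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mearetina import (PSTH, StimulusProtocol, UnitParams, ValidationError,
                       build_psth, compute_unit_metrics, dark_box_fraction,
                       detect_spikes, make_spike_template,
                       simulate_unit_spikes, sort_units, spikes_to_absolute)
from mearetina.simulate import unit_rate

FS = 20_000.0


def _trace_with_templates(times, amp, noise_sd, duration, seed=0):
    rng = np.random.default_rng(seed)
    trace = rng.normal(0, noise_sd, int(duration * FS))
    template = make_spike_template(FS, amp)
    trough = int(np.argmin(template))
    for t in times:
        a = int(round(t * FS)) - trough
        trace[a:a + template.size] += template
    return trace


class TestDetectSpikes:
    def test_zero_trace_yields_no_spikes(self):
        det = detect_spikes(np.zeros(int(FS)), FS)[0]
        assert det.spike_times_s.size == 0

    def test_strong_templates_all_recovered(self):
        times = np.arange(0.05, 1.95, 0.01)
        trace = _trace_with_templates(times, 50.0, 5.0, 2.0)
        det = detect_spikes(trace, FS)[0]
        for t in times:
            assert np.abs(det.spike_times_s - t).min() <= 0.5e-3

    def test_threshold_uses_robust_noise_estimate(self):
        rng = np.random.default_rng(1)
        det = detect_spikes(rng.normal(0, 7.0, int(10 * FS)), FS)[0]
        assert det.noise_sd_uv == pytest.approx(7.0, rel=0.05)
        assert det.threshold_uv == pytest.approx(-28.0, rel=0.05)


class TestSortUnits:
    def test_single_template_forms_one_unit(self):
        times = np.arange(0.05, 4.95, 0.012)
        trace = _trace_with_templates(times, 60.0, 4.0, 5.0)
        det = detect_spikes(trace, FS)[0]
        trains = sort_units(det, FS)
        assert len(trains) == 1
        assert trains[0].spike_times_s.size >= 0.99 * times.size

    def test_two_distinct_templates_separate(self):
        # interleaved, never closer than 12 ms — no collision hybrids
        t1 = np.arange(0.05, 9.95, 0.030)
        t2 = np.arange(0.062, 9.95, 0.030)
        rng = np.random.default_rng(3)
        trace = rng.normal(0, 4.0, int(10 * FS))
        for times, amp in ((t1, 40.0), (t2, 120.0)):
            tpl = make_spike_template(FS, amp)
            trough = int(np.argmin(tpl))
            for t in times:
                a = int(round(t * FS)) - trough
                trace[a:a + tpl.size] += tpl
        det = detect_spikes(trace, FS)[0]
        trains = sort_units(det, FS)
        assert len(trains) == 2
        # assign truth by nearest detection; require ≥95% label agreement
        correct = total = 0
        for times, which in ((t1, 0), (t2, 1)):
            small = min(trains, key=lambda tr: abs(tr.waveform_template.min())
                        ).unit_id
            for t in times:
                best, best_d = None, np.inf
                for tr in trains:
                    d = np.abs(tr.spike_times_s - t).min() \
                        if tr.spike_times_s.size else np.inf
                    if d < best_d:
                        best, best_d = tr, d
                if best_d <= 1e-3:
                    total += 1
                    is_small = best.unit_id == small
                    correct += (is_small == (which == 0))
        assert total >= 0.95 * (t1.size + t2.size)
        assert correct / total >= 0.95

    def test_empty_channel_returns_no_units(self):
        det = detect_spikes(np.zeros(int(FS)), FS)[0]
        assert sort_units(det, FS) == []


class TestBuildPsth:
    def test_empty_train_gives_zero_psth(self, short_protocol):
        psth = build_psth(np.array([]), short_protocol, 7.67)
        assert np.all(psth.rates == 0)
        assert psth.rates.size == 1000

    def test_two_spikes_single_trial_arithmetic(self):
        p = StimulusProtocol(intensities_log=(7.67,), n_repetitions=1)
        psth = build_psth(np.array([0.005, 0.012]), p, 7.67)
        assert psth.rates[0] == pytest.approx(100.0)
        assert psth.rates[1] == pytest.approx(100.0)
        assert np.all(psth.rates[2:] == 0)

    @given(st.integers(0, 400))
    def test_psth_mass_conservation(self, n_spikes):
        p = StimulusProtocol(intensities_log=(7.67,), n_repetitions=3)
        rng = np.random.default_rng(n_spikes)
        times = np.sort(rng.uniform(0, p.total_duration_s, n_spikes))
        psth = build_psth(times, p, 7.67)
        mass = psth.rates.sum() * psth.bin_width_s * psth.n_trials
        in_trial = sum(
            int(np.sum((times >= p.trial_onsets_s[0, r])
                       & (times < p.trial_onsets_s[0, r]
                          + p.trial_duration_s)))
            for r in range(p.n_repetitions))
        assert mass == pytest.approx(in_trial, abs=1e-9)


class TestUnitMetrics:
    def _flat_psth(self, rate, n_bins=1000):
        return PSTH(unit_id="u", intensity_log=7.67, bin_width_s=0.01,
                    rates=np.full(n_bins, float(rate)), n_trials=30)

    def test_flat_psth_is_nonresponsive(self):
        m = compute_unit_metrics(self._flat_psth(20.0), StimulusProtocol())
        assert m.r_spont == 20.0
        assert m.peak_on == 0.0
        assert m.snr_peak == 0.0
        assert m.response_class == "nonresponsive"
        assert not m.snr_flagged

    def test_single_elevated_bin_gives_peak_response(self):
        p = StimulusProtocol()
        rng = np.random.default_rng(0)
        rates = np.full(1000, 10.0)
        rates[800:] += rng.normal(0, 0.5, 200)    # spont jitter: sd > 0
        rates[50] = 60.0
        m = compute_unit_metrics(
            PSTH("u", 7.67, 0.01, rates, 30), p)
        assert m.peak_on == pytest.approx(60.0 - m.r_spont, abs=0.5)
        assert m.latency_on_s == pytest.approx(0.505, abs=0.01)
        assert m.response_class == "ON"

    def test_zero_sd_with_response_flags_snr(self):
        rates = np.full(1000, 10.0)
        rates[10] = 80.0
        m = compute_unit_metrics(PSTH("u", 7.67, 0.01, rates, 30),
                                 StimulusProtocol())
        assert np.isinf(m.snr_peak)
        assert m.snr_flagged

    def test_simulated_unit_metrics_recover_truth(self):
        p = StimulusProtocol(intensities_log=(7.67,))
        unit = UnitParams(r_spont=18.0, a_max=40.0, sigma_true=5.0)
        t_abs = spikes_to_absolute(simulate_unit_spikes(unit, p, 21), p)
        m = compute_unit_metrics(build_psth(t_abs, p, 7.67), p)
        assert m.r_spont == pytest.approx(18.0, rel=0.10)
        # average ON response against the closed-form rate integral (the
        # mean has no max-over-bins bias, unlike the peak); the generator's
        # 2 ms dead time thins the rate to r/(1 + r·τ_ref)
        tt = np.linspace(0, 2, 40_001)
        r = unit_rate(unit, 7.67, tt, p)
        r_thin = r / (1 + r * 0.002)
        spont_thin = 18.0 / (1 + 18.0 * 0.002)
        avg_expected = np.trapezoid(r_thin, tt) / 2.0 - spont_thin
        assert m.avg_on == pytest.approx(avg_expected, rel=0.15)
        # the peak estimate sits above the analytic peak-bin increment
        # (max-over-bins selection bias) but within 4 bin-SDs of it
        bins = r[:40_000].reshape(200, 200).mean(axis=1)
        peak_analytic = bins.max() - 18.0
        bin_sd = np.sqrt(bins.max() / (0.01 * 30))
        assert peak_analytic - bin_sd <= m.peak_on <= peak_analytic + 4 * bin_sd
        # max-bin latency jitters across the transient's plateau: require
        # the reported peak time to sit where the kernel is near-maximal
        from mearetina import alpha_kernel
        k_at_latency = alpha_kernel(np.array([m.latency_on_s]),
                                    unit.latency_s, unit.tau_decay_s)[0]
        assert k_at_latency >= 0.75

    def test_off_unit_classified_off(self):
        p = StimulusProtocol(intensities_log=(7.67,))
        unit = UnitParams(r_spont=10.0, a_max=50.0, sigma_true=5.0,
                          polarity="OFF")
        t_abs = spikes_to_absolute(simulate_unit_spikes(unit, p, 22), p)
        # k = 4: at 30 trials the max over 200 Poisson bins regularly
        # exceeds 3 SD by chance, so the default gate is permissive here
        m = compute_unit_metrics(build_psth(t_abs, p, 7.67), p, class_k=4.0)
        assert m.response_class == "OFF"
        assert m.peak_off > m.peak_on


class TestDarkBoxFraction:
    def test_all_black_is_100(self):
        t = np.arange(0, 300, 0.5)
        assert dark_box_fraction(t, np.full(t.size, "black")) == 100.0

    def test_alternating_halves_is_50(self):
        t = np.arange(0, 300, 0.5)
        labels = np.where((t // 30) % 2 == 0, "black", "white")
        assert dark_box_fraction(t, labels) == pytest.approx(50.0)

    def test_three_of_five_minutes_is_60(self):
        t = np.arange(0, 300, 0.5)
        labels = np.where(t < 180, "black", "white")
        assert dark_box_fraction(t, labels) == pytest.approx(60.0)

    def test_sampling_gap_raises(self):
        t = np.concatenate([np.arange(0, 100, 0.5),
                            np.arange(150, 300, 0.5)])
        with pytest.raises(ValidationError, match="gap"):
            dark_box_fraction(t, np.full(t.size, "black"))
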