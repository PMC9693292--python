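"""Generator statistics: Poisson counts, rate convergence, determinism."""

import numpy as np
import pytest

from mearetina import (ComponentKernel, StimulusProtocol, UnitParams,
                       ValidationError, assemble_recording,
                       default_microerg_kernels, hill_drive,
                       make_group_scenario, simulate_microerg,
                       simulate_unit_spikes, spikes_to_absolute)
from mearetina.simulate import alpha_kernel, unit_rate


def _total_count(per_trial):
    return sum(t.size for t in per_trial.values())


class TestUnitSpikes:
    def test_pure_spontaneous_count_matches_poisson_mean(self):
        # 18 spikes/s × 10 s × 30 trials; no refractory → plain Poisson
        unit = UnitParams(r_spont=18.0, a_max=0.0)
        p = StimulusProtocol(intensities_log=(7.67,))
        per_trial = simulate_unit_spikes(unit, p, 7, refractory_s=0.0)
        mean = 18.0 * 10.0 * 30
        assert abs(_total_count(per_trial) - mean) < 4 * np.sqrt(mean)

    def test_refractory_thinning_matches_renewal_rate(self):
        # dead-time-thinned Poisson has rate r/(1 + r·τ_ref)
        unit = UnitParams(r_spont=30.0, a_max=0.0)
        p = StimulusProtocol(intensities_log=(7.67,))
        per_trial = simulate_unit_spikes(unit, p, 7)
        mean = 30.0 / (1 + 30.0 * 0.002) * 10.0 * 30
        assert abs(_total_count(per_trial) - mean) < 4 * np.sqrt(mean)
        for t in per_trial.values():
            if t.size > 1:
                assert np.diff(t).min() >= 0.002

    def test_zero_rates_give_zero_spikes(self):
        unit = UnitParams(r_spont=0.0, a_max=0.0)
        p = StimulusProtocol(intensities_log=(7.67,), n_repetitions=3)
        assert _total_count(simulate_unit_spikes(unit, p, 0)) == 0

    def test_evoked_rate_difference_matches_closed_form(self):
        # ON-window rate at saturating vs. sub-threshold intensity differs
        # by A(I_hi)·mean(k) — oracle is the numerical kernel integral
        p = StimulusProtocol(intensities_log=(4.20, 7.67), n_repetitions=200)
        unit = UnitParams(r_spont=10.0, a_max=50.0, sigma_true=6.0)
        per_trial = simulate_unit_spikes(unit, p, 3, refractory_s=0.0)
        on_s = p.on_duration_s
        rates = []
        for i in range(2):
            n = sum(np.sum(per_trial[(i, r)] < on_s)
                    for r in range(p.n_repetitions))
            rates.append(n / (on_s * p.n_repetitions))
        t = np.linspace(0, on_s, 20_001)
        mean_k = np.trapezoid(
            alpha_kernel(t, unit.latency_s, unit.tau_decay_s), t) / on_s
        a_hi = unit.a_max * hill_drive(7.67, 6.0, 1.0)
        a_lo = unit.a_max * hill_drive(4.20, 6.0, 1.0)
        expected = (a_hi - a_lo) * mean_k
        assert rates[1] - rates[0] == pytest.approx(expected, rel=0.15)

    def test_trial_averaged_rate_converges_to_analytic(self):
        # 300 trials, 100 ms bins: sup-norm error ≤ 10% of the rate peak
        p = StimulusProtocol(intensities_log=(7.67,), n_repetitions=300)
        unit = UnitParams(r_spont=18.0, a_max=40.0, sigma_true=5.0)
        per_trial = simulate_unit_spikes(unit, p, 11, refractory_s=0.0)
        bw, T = 0.1, p.trial_duration_s
        edges = np.arange(0, T + bw / 2, bw)
        counts = np.zeros(edges.size - 1)
        for t in per_trial.values():
            counts += np.histogram(t, bins=edges)[0]
        emp = counts / (bw * p.n_repetitions)
        tt = np.linspace(0, T, 200_001)
        r = unit_rate(unit, 7.67, tt, p)
        analytic = np.array([
            r[(tt >= a) & (tt < b)].mean()
            for a, b in zip(edges[:-1], edges[1:])])
        assert np.abs(emp - analytic).max() <= 0.10 * analytic.max()


class TestMicroErg:
    def test_single_p1_kernel_peaks_at_latency(self):
        p = StimulusProtocol(intensities_log=(7.67,), n_repetitions=1)
        kernels = {"P1": ComponentKernel(120.0, 0.080, 0.018,
                                         saturation=-10.0)}
        trace, amps, overlap = simulate_microerg(kernels, p, 20_000)
        assert not overlap
        assert trace.max() == pytest.approx(120.0, rel=1e-6)
        assert np.argmax(trace) / 20_000 == pytest.approx(0.080, abs=1e-3)
        assert amps[0, 1] == pytest.approx(120.0, rel=1e-6)

    def test_zero_amplitudes_give_flat_trace(self):
        p = StimulusProtocol(intensities_log=(7.67,), n_repetitions=1)
        kernels = {c: ComponentKernel(0.0 if c[0] == "P" else -0.0,
                                      k.latency_s, k.width_s)
                   for c, k in default_microerg_kernels().items()}
        trace, _, _ = simulate_microerg(kernels, p, 20_000)
        assert np.all(trace == 0)

    def test_default_kernels_have_six_extrema(self):
        # 4 in the ON epoch, 2 after offset — count derivative sign changes
        p = StimulusProtocol(intensities_log=(7.67,), n_repetitions=1)
        trace, _, overlap = simulate_microerg(default_microerg_kernels(),
                                              p, 2_000)
        assert not overlap
        d = np.diff(trace)
        sign = np.sign(d[np.abs(d) > 1e-6])
        flips = np.flatnonzero(np.diff(sign) != 0)
        t_flip = flips[np.abs(trace[flips]) > 1.0] / 2_000
        on_extrema = np.sum(t_flip < p.on_duration_s)
        off_extrema = np.sum(t_flip >= p.on_duration_s)
        assert on_extrema == 4
        assert off_extrema == 2

    def test_truth_amplitudes_equal_clean_extrema(self):
        p = StimulusProtocol(intensities_log=(5.96, 7.67), n_repetitions=2)
        trace, amps, overlap = simulate_microerg(default_microerg_kernels(),
                                                 p, 20_000)
        assert not overlap
        fs = 20_000
        for i in (0, 1):
            t0 = p.trial_onsets_s[i, 0]
            seg = trace[int(t0 * fs):int((t0 + 0.12) * fs)]
            assert seg.max() == pytest.approx(amps[i, 1], rel=0.02)  # P1

    def test_intensity_scaling_is_saturating(self):
        p = StimulusProtocol()
        _, amps, _ = simulate_microerg(default_microerg_kernels(), p, 1_000)
        p1 = amps[:, 1]
        assert np.all(np.diff(p1) > 0) and p1[-1] < 120.0


class TestAssemble:
    def test_same_seed_is_byte_identical(self):
        p = StimulusProtocol(trial_duration_s=1.0, on_duration_s=0.2,
                             n_repetitions=2, intensities_log=(7.67,))
        units = [UnitParams(channel=0), UnitParams(channel=1, polarity="OFF")]
        rec1, _ = assemble_recording(units, p, noise_sd_uv=5.0,
                                     n_channels=2, seed=42)
        rec2, _ = assemble_recording(units, p, noise_sd_uv=5.0,
                                     n_channels=2, seed=42)
        assert rec1.traces.tobytes() == rec2.traces.tobytes()

    def test_no_noise_no_units_equals_clean_microerg(self):
        p = StimulusProtocol(trial_duration_s=1.0, on_duration_s=0.2,
                             n_repetitions=1, intensities_log=(7.67,))
        kernels = {"P1": ComponentKernel(100.0, 0.05, 0.01)}
        rec, truth = assemble_recording(
            [], p, channel_kernels={0: kernels}, noise_sd_uv=0.0,
            n_channels=2, seed=0)
        clean, _, _ = simulate_microerg(kernels, p, 20_000)
        np.testing.assert_allclose(rec.traces[0], clean, atol=1e-3)
        assert np.all(rec.traces[1] == 0)

    def test_noise_sd_matches_request(self):
        p = StimulusProtocol(trial_duration_s=10.0, on_duration_s=2.0,
                             n_repetitions=6, intensities_log=(7.67,))
        rec, _ = assemble_recording([], p, noise_sd_uv=5.0, n_channels=1,
                                    seed=3)
        assert rec.n_samples >= 1_000_000
        assert rec.traces[0].std() == pytest.approx(5.0, rel=0.02)

    def test_unit_on_missing_channel_raises(self):
        p = StimulusProtocol(trial_duration_s=1.0, on_duration_s=0.2,
                             n_repetitions=1, intensities_log=(7.67,))
        with pytest.raises(ValidationError, match="channel"):
            assemble_recording([UnitParams(channel=9)], p, n_channels=2)

    def test_spike_times_recorded_in_truth(self):
        p = StimulusProtocol(trial_duration_s=1.0, on_duration_s=0.2,
                             n_repetitions=3, intensities_log=(7.67,))
        units = [UnitParams(r_spont=20.0, channel=0)]
        _, truth = assemble_recording(units, p, noise_sd_uv=0.0,
                                      n_channels=1, seed=5)
        t = truth.unit_spike_times[0]
        assert t.size > 0 and np.all(np.diff(t) >= 0)
        assert t.max() < p.total_duration_s


class TestScenarios:
    def test_scenario_means_follow_treatment_pattern(self):
        draws = {name: make_group_scenario(name, 64, seed=0)
                 for name in ("sham", "treated_50", "treated_100")}
        mean_r = {k: np.mean([u.r_spont for u in v])
                  for k, v in draws.items()}
        # spontaneous firing: sham highest, 100 μA lowest
        assert mean_r["sham"] == pytest.approx(18.0, abs=2.0)
        assert mean_r["treated_100"] == pytest.approx(11.4, abs=2.0)
        assert mean_r["sham"] > mean_r["treated_50"] > mean_r["treated_100"]
        # sensitivity: 50 μA raises σ, 100 μA lowers it
        mean_s = {k: np.mean([u.sigma_true for u in v])
                  for k, v in draws.items()}
        assert mean_s["treated_50"] > mean_s["sham"] > mean_s["treated_100"]

    def test_unknown_scenario_raises(self):
        with pytest.raises(ValidationError, match="unknown scenario"):
            make_group_scenario("treated_999", 10, seed=0)

    def test_scenario_is_reproducible_from_seed(self):
        a = make_group_scenario("sham", 12, seed=9)
        b = make_group_scenario("sham", 12, seed=9)
        assert a == b
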