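"""Trial averaging, component peak measurement, channel summaries."""

import numpy as np
import pandas as pd
import pytest

from mearetina import (ComponentKernel, StimulusProtocol, ValidationError,
                       average_trials, detect_peaks, simulate_microerg,
                       summarize_channels)

FS = 20_000.0


@pytest.fixture
def protocol():
    return StimulusProtocol(intensities_log=(7.67,), n_repetitions=4)


def _peak(df, comp):
    return df[df["component"] == comp].iloc[0]


class TestAverageTrials:
    def test_identical_repetitions_average_to_one(self, protocol):
        one = np.sin(np.arange(int(10 * FS)) / FS)
        trace = np.tile(one, protocol.n_repetitions)[None, :]
        mean, sd, n = average_trials(trace, protocol, FS, 7.67)
        np.testing.assert_allclose(mean[0], one, atol=1e-12)
        assert np.all(sd == 0) and n == 4

    def test_antisymmetric_pair_averages_to_zero(self):
        p = StimulusProtocol(intensities_log=(7.67,), n_repetitions=2)
        one = np.sin(np.arange(int(10 * FS)) / FS)
        trace = np.concatenate([one, -one])[None, :]
        mean, _, _ = average_trials(trace, p, FS, 7.67)
        np.testing.assert_allclose(mean[0], 0.0, atol=1e-12)

    def test_residual_noise_follows_standard_error(self):
        p = StimulusProtocol(intensities_log=(7.67,), n_repetitions=30)
        rng = np.random.default_rng(0)
        kernel = 100 * np.exp(
            -0.5 * ((np.arange(int(10 * FS)) / FS - 0.5) / 0.05) ** 2)
        trace = (np.tile(kernel, 30) + rng.normal(0, 5.0, int(300 * FS)))[None]
        mean, _, _ = average_trials(trace, p, FS, 7.67)
        rms = np.sqrt(((mean[0] - kernel) ** 2).mean())
        assert rms == pytest.approx(5.0 / np.sqrt(30), rel=0.25)

    def test_unknown_intensity_raises(self, protocol):
        with pytest.raises(ValidationError, match="intensity"):
            average_trials(np.zeros((1, int(40 * FS))), protocol, FS, 5.0)


class TestDetectPeaks:
    def test_flat_waveform_flags_all_absent(self, protocol):
        df = detect_peaks(np.zeros(int(10 * FS)), protocol, FS)
        assert df["absent"].all()
        assert (df["amplitude_uv"] == 0).all()

    def test_single_p1_recovered_others_absent(self, protocol):
        kernels = {"P1": ComponentKernel(120.0, 0.080, 0.015,
                                         saturation=-10.0)}
        p1 = StimulusProtocol(intensities_log=(7.67,), n_repetitions=1)
        trace, _, _ = simulate_microerg(kernels, p1, FS)
        df = detect_peaks(trace[:int(10 * FS)], p1, FS)
        row = _peak(df, "P1")
        assert not row["absent"]
        assert row["amplitude_uv"] == pytest.approx(120.0, rel=0.01)
        assert row["latency_s"] == pytest.approx(0.080, abs=0.002)
        assert df[df["component"] != "P1"]["absent"].all()

    def test_amplitude_invariant_to_constant_offset(self, protocol):
        rng = np.random.default_rng(4)
        p1 = StimulusProtocol(intensities_log=(7.67,), n_repetitions=1)
        trace, _, _ = simulate_microerg(
            {"P1": ComponentKernel(80.0, 0.09, 0.02),
             "N2": ComponentKernel(-40.0, 0.30, 0.05)}, p1, FS)
        w = trace[:int(10 * FS)] + rng.normal(0, 0.5, int(10 * FS))
        a = detect_peaks(w, p1, FS)
        b = detect_peaks(w + 200.0, p1, FS)
        np.testing.assert_allclose(a["amplitude_uv"], b["amplitude_uv"],
                                   atol=1e-9)

    def test_amplitudes_scale_linearly_noise_free(self, protocol):
        p1 = StimulusProtocol(intensities_log=(7.67,), n_repetitions=1)
        trace, _, _ = simulate_microerg(
            {"P1": ComponentKernel(80.0, 0.09, 0.02),
             "N3": ComponentKernel(-30.0, 0.06, 0.015)}, p1, FS)
        w = trace[:int(10 * FS)]
        a = detect_peaks(w, p1, FS)
        b = detect_peaks(3.0 * w, p1, FS)
        detected = ~a["absent"].values
        np.testing.assert_allclose(
            b["amplitude_uv"].values[detected],
            3.0 * a["amplitude_uv"].values[detected], rtol=1e-9)

    def test_window_outside_trial_raises(self, protocol):
        from mearetina import PeakDetectionConfig
        cfg = PeakDetectionConfig(windows={**dict(
            __import__("mearetina").DEFAULT_WINDOWS), "P3": (0.1, 9.0)})
        with pytest.raises(ValidationError, match="window"):
            detect_peaks(np.zeros(int(10 * FS)), protocol, FS, config=cfg)


class TestSummarizeChannels:
    def _peaks_frame(self, amplitudes, component="P1"):
        return pd.DataFrame([
            {"channel": i, "component": component, "amplitude_uv": a,
             "latency_s": 0.08, "baseline_uv": 0.0, "absent": False,
             "n_trials_averaged": 30}
            for i, a in enumerate(amplitudes)])

    def test_identical_channels_have_zero_sem(self):
        out = summarize_channels(self._peaks_frame([120.0] * 5))
        assert out.iloc[0]["sem_uv"] == 0.0
        assert out.iloc[0]["n_channels"] == 5

    def test_single_channel_flags_degenerate_sem(self):
        out = summarize_channels(self._peaks_frame([120.0]))
        assert out.iloc[0]["sem_degenerate"]
        assert out.iloc[0]["sem_uv"] == 0.0

    def test_sem_matches_sampling_distribution(self):
        rng = np.random.default_rng(8)
        out = summarize_channels(
            self._peaks_frame(rng.normal(120.0, 10.0, 100)))
        assert out.iloc[0]["sem_uv"] == pytest.approx(1.0, rel=0.30)

    def test_groups_reported_separately(self):
        df = self._peaks_frame([100.0, 110.0, 120.0, 130.0])
        out = summarize_channels(df, group_labels={0: "sham", 1: "sham",
                                                   2: "t100", 3: "t100"})
        assert set(out["group"]) == {"sham", "t100"}
        assert (out["n_channels"] == 2).all()
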