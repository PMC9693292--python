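"""microERG component analysis: trial averaging and peak measurement.

Per channel, the low band is averaged across repetitions of one flash
intensity, the six named components (N1, P1, N2, P2 after light onset;
N3, P3 after offset) are located as signed extrema inside per-component
search windows, and amplitudes are measured baseline-to-peak. The baseline
is the mean of the spontaneous window — reproducible and invariant to a
constant offset, unlike a visually placed baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (COMPONENTS, StimulusProtocol, ValidationError, trial_slices)

#: Default per-component search windows (s). N1..P2 relative to light
#: onset, N3/P3 relative to offset. Consistent with the canonical ordering:
#: sharp N1 and P1 early, slower N2, slow P2; sharp N3 then slow P3.
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "N1": (0.0, 0.060),
    "P1": (0.020, 0.150),
    "N2": (0.100, 0.600),
    "P2": (0.300, 2.0),
    "N3": (0.0, 0.200),
    "P3": (0.100, 2.0),
}

_OFFSET_LOCKED = ("N3", "P3")


def average_trials(low_band: np.ndarray, protocol: StimulusProtocol,
                   sample_rate_hz: float, intensity_log: float,
                   ) -> tuple[np.ndarray, np.ndarray, int]:
    """Pointwise mean (and SD) across repetitions of one intensity.

    Returns ``(mean, sd, n_trials)`` with mean/sd shaped
    (channels, trial_samples).
    """
    x = np.atleast_2d(np.asarray(low_band))
    i = (protocol.intensity_index(intensity_log))
    slices = trial_slices(protocol, sample_rate_hz)
    reps = []
    for r in range(protocol.n_repetitions):
        a, b = slices[(i, r)].trial
        if b > x.shape[1]:
            raise ValidationError("trial window extends past the trace")
        reps.append(x[:, a:b])
    stack = np.stack(reps)                      # reps × channels × samples
    return (stack.mean(axis=0), stack.std(axis=0, ddof=0), len(reps))


@dataclass
class PeakDetectionConfig:
    """Tunables of the component peak search."""

    windows: dict[str, tuple[float, float]] | None = None
    absence_k: float = 2.0      # absent if |extremum − baseline| < k·SD(baseline)
    absence_min_uv: float = 1e-6  # floor for numerically flat baselines
    spont_window_s: float = 2.0


def detect_peaks(mean_waveform: np.ndarray, protocol: StimulusProtocol,
                 sample_rate_hz: float,
                 config: PeakDetectionConfig | None = None,
                 n_trials_averaged: int | None = None) -> pd.DataFrame:
    """Measure the six microERG components on trial-averaged waveforms.

    ``mean_waveform`` is (channels, trial_samples) or 1-D for a single
    channel. For each component the signed extremum of the correct polarity
    is located inside its search window (ties broken by the earliest
    sample); amplitude is the unsigned distance from the baseline, latency
    is relative to light onset (N1..P2) or offset (N3/P3). A component is
    flagged absent when its deflection stays within ``absence_k`` baseline
    SDs.

    Returns a tidy frame with one row per (channel, component).
    """
    cfg = config or PeakDetectionConfig()
    windows = cfg.windows or DEFAULT_WINDOWS
    x = np.atleast_2d(np.asarray(mean_waveform, dtype=float))
    fs = sample_rate_hz
    n = x.shape[1]
    T = protocol.trial_duration_s
    if abs(n / fs - T) > 1.0 / fs:
        raise ValidationError("mean_waveform length must equal one trial")

    spont_a = int(round((T - cfg.spont_window_s) * fs))
    rows = []
    for ch in range(x.shape[0]):
        w = x[ch]
        baseline = float(w[spont_a:].mean())
        base_sd = float(w[spont_a:].std(ddof=0))
        for comp in COMPONENTS:
            lo, hi = windows[comp]
            ref = protocol.on_duration_s if comp in _OFFSET_LOCKED else 0.0
            a = int(round((ref + lo) * fs))
            b = int(round((ref + hi) * fs))
            if a < 0 or b > n or a >= b:
                raise ValidationError(
                    f"search window for {comp} lies outside the trial")
            seg = w[a:b]
            if comp.startswith("N"):
                idx = int(np.argmin(seg))
            else:
                idx = int(np.argmax(seg))
            extremum = float(seg[idx])
            amp = abs(extremum - baseline)
            absent = amp < max(cfg.absence_k * base_sd, cfg.absence_min_uv)
            rows.append({
                "channel": ch,
                "component": comp,
                "amplitude_uv": 0.0 if absent else amp,
                "latency_s": (a + idx) / fs - ref,
                "baseline_uv": baseline,
                "absent": bool(absent),
                "n_trials_averaged": n_trials_averaged,
            })
    return pd.DataFrame(rows)


def summarize_channels(peaks: pd.DataFrame,
                       group_labels: dict[int, str] | pd.Series | None = None,
                       ) -> pd.DataFrame:
    """Per-group component means ± SEM with n = channels.

    ``group_labels`` maps channel → group; omit it to summarize all
    channels as one group. Absent components are excluded. With a single
    channel the SEM is undefined and reported as 0 with
    ``sem_degenerate=True``.
    """
    df = peaks[~peaks["absent"]].copy()
    if group_labels is not None:
        df["group"] = df["channel"].map(dict(group_labels)
                                        if not isinstance(group_labels, dict)
                                        else group_labels)
    else:
        df["group"] = "all"
    if df.empty:
        raise ValidationError("no channels with detected components")
    out = []
    for (grp, comp), sub in df.groupby(["group", "component"], sort=True):
        n = len(sub)
        if n == 0:
            raise ValidationError(f"empty group {grp} for component {comp}")
        mean = float(sub["amplitude_uv"].mean())
        sem = float(sub["amplitude_uv"].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out.append({"group": grp, "component": comp, "mean_amplitude_uv": mean,
                    "sem_uv": sem, "n_channels": n, "sem_degenerate": n == 1})
    return pd.DataFrame(out)
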