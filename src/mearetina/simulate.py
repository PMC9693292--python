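"""Synthetic MEA recordings with known ground truth.

Emulates the statistical structure of degenerating (rd10-like) retina
recordings: slow field-potential (microERG) components locked to light
onset/offset, spiking units with inhomogeneous-Poisson statistics and
elevated spontaneous rates, intensity-dependent evoked responses following
a Hill law, and broadband noise. Every parameter is carried in the
returned :class:`~mearetina.io.GroundTruth`, so each analysis stage can be
validated by parameter recovery.

Model summary
-------------
A unit fires as an inhomogeneous Poisson process with rate

    r(t) = r_spont + A(I) · k(t),          A(I) = A_max · Iⁿ / (Iⁿ + σⁿ)

on linear intensity I = 10^I_log, where k(t) is a unit-peak alpha-shaped
transient placed at light onset (ON cells), offset (OFF cells) or both
(ON-OFF). An absolute 2 ms refractory period is imposed by thinning.
microERG components are Gaussian bumps of fixed latency and width whose
amplitudes scale with a saturating function of intensity.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

from .io import (COMPONENTS, GroundTruth, Recording, StimulusProtocol,
                 ValidationError, default_channel_layout)

REFRACTORY_S = 0.002


@dataclass
class UnitParams:
    """Generative parameters of one simulated retinal ganglion cell."""

    r_spont: float = 18.0          # spontaneous rate, spikes/s
    a_max: float = 40.0            # maximal evoked rate increment, spikes/s
    sigma_true: float = 6.2        # half-max intensity, log10 photons/μm²/s
    hill_n: float = 1.0            # Hill coefficient
    polarity: str = "ON"           # ON | OFF | ON-OFF
    latency_s: float = 0.12        # time-to-peak of evoked transient, s
    tau_decay_s: float = 0.30      # decay constant of evoked transient, s
    waveform_amp_uv: float = 60.0  # spike template trough depth, μV
    channel: int = 0               # home electrode index
    burst_mean: float = 1.0        # mean spontaneous burst size (1 = Poisson)

    def __post_init__(self) -> None:
        if self.r_spont < 0 or self.a_max < 0:
            raise ValidationError("rates must be non-negative")
        if self.burst_mean < 1.0:
            raise ValidationError("burst_mean must be >= 1")
        if self.hill_n <= 0:
            raise ValidationError("hill_n must be positive")
        if self.tau_decay_s <= 0 or self.latency_s <= 0:
            raise ValidationError("latency_s and tau_decay_s must be positive")
        if self.polarity not in ("ON", "OFF", "ON-OFF"):
            raise ValidationError("polarity must be ON, OFF or ON-OFF")


@dataclass(frozen=True)
class ComponentKernel:
    """One microERG component: a Gaussian bump of fixed latency and width.

    ``latency_s`` is relative to light onset for N1/P1/N2/P2 and to light
    offset for N3/P3. ``saturation`` is the half-max of the intensity
    scaling (log10 photons/μm²/s): amplitude(I) = amplitude_uv · I/(I+10^sat).
    """

    amplitude_uv: float
    latency_s: float
    width_s: float
    saturation: float = 5.0


def default_microerg_kernels() -> dict[str, ComponentKernel]:
    """Default six-component kernel set.

    Latencies and widths reproduce the canonical shape: a tiny sharp
    negative N1, a large sharp positive P1, a slower negative N2 and a slow
    positive P2 after onset; a sharp negative N3 and slow positive P3 after
    offset. Amplitudes are in the range observed on healthy electrodes.
    """
    return {
        "N1": ComponentKernel(-15.0, 0.030, 0.008),
        "P1": ComponentKernel(120.0, 0.080, 0.015),
        "N2": ComponentKernel(-60.0, 0.250, 0.050),
        "P2": ComponentKernel(80.0, 0.800, 0.200),
        "N3": ComponentKernel(-50.0, 0.060, 0.015),
        "P3": ComponentKernel(70.0, 0.500, 0.150),
    }


def validate_kernels(kernels: Mapping[str, ComponentKernel]) -> None:
    """Check component signs and latency ordering."""
    for name, k in kernels.items():
        if name not in COMPONENTS:
            raise ValidationError(f"unknown microERG component '{name}'")
        if name.startswith("N") and k.amplitude_uv > 0:
            raise ValidationError(f"{name} amplitude must be negative")
        if name.startswith("P") and k.amplitude_uv < 0:
            raise ValidationError(f"{name} amplitude must be positive")
        if k.width_s <= 0:
            raise ValidationError(f"{name} width_s must be positive")
    for seq in (("N1", "P1", "N2", "P2"), ("N3", "P3")):
        present = [kernels[c].latency_s for c in seq if c in kernels
                   and kernels[c].amplitude_uv != 0]
        if np.any(np.diff(present) <= 0):
            raise ValidationError(f"component latencies must be ordered "
                                  f"{' < '.join(seq)}")


# ---------------------------------------------------------------------------
# Rate model
# ---------------------------------------------------------------------------

def hill_drive(intensity_log: float, sigma_log: float, n: float) -> float:
    """Iⁿ/(Iⁿ+σⁿ) on linear intensity, computed stably in the log domain."""
    return 1.0 / (1.0 + 10.0 ** (n * (sigma_log - np.asarray(intensity_log))))


def alpha_kernel(t: np.ndarray, t_peak: float, tau_decay: float) -> np.ndarray:
    """Unit-peak alpha-shaped transient, peaking at ``t_peak``.

    Generalized alpha (t/t_peak)^a · exp(a·(1 − t/t_peak)) with
    a = t_peak/tau_decay, so the tail decays with constant ``tau_decay``.
    """
    t = np.asarray(t, dtype=float)
    a = t_peak / tau_decay
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / t_peak
    out[pos] = np.exp(a * (np.log(x) + 1.0 - x))
    return out


def unit_rate(unit: UnitParams, intensity_log: float,
              t: np.ndarray, protocol: StimulusProtocol) -> np.ndarray:
    """Analytic firing rate r(t) over one trial (t relative to onset)."""
    amp = unit.a_max * hill_drive(intensity_log, unit.sigma_true, unit.hill_n)
    rate = np.full_like(np.asarray(t, dtype=float), unit.r_spont)
    if unit.polarity in ("ON", "ON-OFF"):
        rate += amp * alpha_kernel(t, unit.latency_s, unit.tau_decay_s)
    if unit.polarity in ("OFF", "ON-OFF"):
        rate += amp * alpha_kernel(t - protocol.on_duration_s,
                                   unit.latency_s, unit.tau_decay_s)
    return np.maximum(rate, 0.0)


def _thin_refractory(times: np.ndarray, refractory_s: float) -> np.ndarray:
    if times.size < 2:
        return times
    keep = [times[0]]
    for t in times[1:]:
        if t - keep[-1] >= refractory_s:
            keep.append(t)
    return np.asarray(keep)


def _spontaneous_times(unit: UnitParams, T: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Spontaneous spikes: Poisson for burst_mean = 1, else a Poisson
    cluster (Neyman–Scott) process with the same mean rate.

    Burst onsets arrive at rate r_spont/burst_mean; each burst holds
    1 + Poisson(burst_mean − 1) spikes fired sequentially at 2.5–8 ms
    intervals, as in the oscillatory hyperactivity of degenerating
    retinas. Clustering leaves the mean rate untouched (intervals exceed
    the refractory period) but overdisperses PSTH bin counts.
    """
    b = unit.burst_mean
    if b <= 1.0:
        n = rng.poisson(unit.r_spont * T)
        return rng.uniform(0.0, T, n)
    n_bursts = rng.poisson(unit.r_spont / b * T)
    onsets = rng.uniform(0.0, T, n_bursts)
    sizes = 1 + rng.poisson(b - 1.0, n_bursts)
    # segmented cumsum: within-burst offsets reset at each burst onset
    total = int(sizes.sum())
    if total == 0:
        return np.empty(0)
    intervals = rng.uniform(0.0025, 0.008, total)
    starts = np.repeat(np.cumsum(sizes) - sizes, sizes)
    csum = np.cumsum(intervals)
    offsets = csum - csum[starts]
    times = np.repeat(onsets, sizes) + offsets
    return times[times < T]


def simulate_unit_spikes(unit: UnitParams, protocol: StimulusProtocol,
                         rng: np.random.Generator | int,
                         refractory_s: float = REFRACTORY_S,
                         ) -> dict[tuple[int, int], np.ndarray]:
    """Spike times for every (intensity, repetition), trial-relative (s).

    The spontaneous process (homogeneous Poisson, or a burst-clustered
    variant when ``burst_mean > 1``) is superposed with the evoked
    inhomogeneous Poisson process of rate A(I)·k(t), drawn by thinning a
    homogeneous candidate stream at the rate bound; the merged train is
    pruned to the absolute refractory period.
    """
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    T = protocol.trial_duration_s
    out: dict[tuple[int, int], np.ndarray] = {}
    for i, intensity in enumerate(protocol.intensities_log):
        amp = unit.a_max * hill_drive(intensity, unit.sigma_true, unit.hill_n)
        bound = amp * (2.0 if unit.polarity == "ON-OFF" else 1.0)
        for r in range(protocol.n_repetitions):
            spont = _spontaneous_times(unit, T, rng)
            if bound > 0:
                n = rng.poisson(bound * T)
                cand = rng.uniform(0.0, T, n)
                evoked_rate = (unit_rate(unit, intensity, cand, protocol)
                               - unit.r_spont)
                evoked = cand[rng.uniform(0.0, 1.0, n)
                              < evoked_rate / bound]
            else:
                evoked = np.empty(0)
            merged = np.sort(np.concatenate([spont, evoked]))
            out[(i, r)] = _thin_refractory(merged, refractory_s)
    return out


def spikes_to_absolute(per_trial: Mapping[tuple[int, int], np.ndarray],
                       protocol: StimulusProtocol) -> np.ndarray:
    """Concatenate trial-relative spike times into absolute, sorted times."""
    parts = [protocol.trial_onsets_s[i, r] + t
             for (i, r), t in per_trial.items()]
    return (np.sort(np.concatenate(parts))
            if parts else np.empty(0))


# ---------------------------------------------------------------------------
# microERG
# ---------------------------------------------------------------------------

def simulate_microerg(kernels: Mapping[str, ComponentKernel],
                      protocol: StimulusProtocol, sample_rate_hz: float,
                      ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Clean slow-wave trace for one channel.

    Deterministic superposition over trials and components of Gaussian
    bumps ``amplitude · exp(−(t−t_peak)²/(2·width²))``, each amplitude
    scaled by a saturating function of flash intensity.

    Returns ``(trace, amplitudes, overlap_flag)`` where ``amplitudes`` has
    shape (n_intensities, 6) holding the realized per-component amplitudes
    (μV, signed, :data:`~mearetina.io.COMPONENTS` order; 0 for absent
    components) and ``overlap_flag`` is True when any two neighbouring
    bumps are closer than twice the larger width (superposition may then
    shift the true extrema).
    """
    validate_kernels(kernels)
    n_samples = int(round(protocol.total_duration_s * sample_rate_hz))
    trace = np.zeros(n_samples)
    amps = np.zeros((protocol.n_intensities, len(COMPONENTS)))

    peaks = []
    for c, kern in kernels.items():
        if kern.amplitude_uv == 0:
            continue
        rel = kern.latency_s + (protocol.on_duration_s
                                if c in ("N3", "P3") else 0.0)
        peaks.append((rel, kern.width_s))
    peaks.sort()
    overlap = any(b[0] - a[0] < 2 * max(a[1], b[1])
                  for a, b in zip(peaks, peaks[1:]))

    for i, intensity in enumerate(protocol.intensities_log):
        i_lin = 10.0 ** intensity
        for ci, c in enumerate(COMPONENTS):
            kern = kernels.get(c)
            if kern is None or kern.amplitude_uv == 0:
                continue
            scale = i_lin / (i_lin + 10.0 ** kern.saturation)
            amps[i, ci] = kern.amplitude_uv * scale
            rel = kern.latency_s + (protocol.on_duration_s
                                    if c in ("N3", "P3") else 0.0)
            half = 5.0 * kern.width_s
            for r in range(protocol.n_repetitions):
                t_peak = protocol.trial_onsets_s[i, r] + rel
                a = max(0, int((t_peak - half) * sample_rate_hz))
                b = min(n_samples, int((t_peak + half) * sample_rate_hz) + 1)
                t = np.arange(a, b) / sample_rate_hz
                trace[a:b] += amps[i, ci] * np.exp(
                    -0.5 * ((t - t_peak) / kern.width_s) ** 2)
    return trace, amps, overlap


def make_spike_template(sample_rate_hz: float, amplitude_uv: float,
                        ) -> np.ndarray:
    """Biphasic extracellular spike template, ~1.2 ms, trough-normalized."""
    t = np.arange(int(round(1.2e-3 * sample_rate_hz))) / sample_rate_hz
    w = (-np.exp(-0.5 * ((t - 0.30e-3) / 0.10e-3) ** 2)
         + 0.40 * np.exp(-0.5 * ((t - 0.70e-3) / 0.22e-3) ** 2))
    return amplitude_uv * w / np.abs(w.min())


def assemble_recording(units: Sequence[UnitParams],
                       protocol: StimulusProtocol,
                       channel_kernels: Mapping[int, Mapping[str, ComponentKernel]] | None = None,
                       noise_sd_uv: float = 5.0,
                       sample_rate_hz: float = 20_000.0,
                       n_channels: int = 64,
                       seed: int | np.random.Generator = 0,
                       ) -> tuple[Recording, GroundTruth]:
    """Full synthetic recording: microERG + spike templates + white noise.

    ``channel_kernels`` maps channel index → component kernel set (channels
    absent from the map carry no slow wave). Identical seed ⇒ identical
    traces.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    for u in units:
        if not 0 <= u.channel < n_channels:
            raise ValidationError(
                f"unit channel {u.channel} outside 0..{n_channels - 1}")
    n_samples = int(round(protocol.total_duration_s * sample_rate_hz))
    traces = np.zeros((n_channels, n_samples))

    erg_amps = None
    if channel_kernels:
        erg_amps = np.zeros((n_channels, protocol.n_intensities,
                             len(COMPONENTS)))
        for ch, kernels in channel_kernels.items():
            clean, amps, _ = simulate_microerg(kernels, protocol,
                                               sample_rate_hz)
            traces[ch] += clean
            erg_amps[ch] = amps

    spike_times: list[np.ndarray] = []
    for u in units:
        per_trial = simulate_unit_spikes(u, protocol, rng)
        t_abs = spikes_to_absolute(per_trial, protocol)
        spike_times.append(t_abs)
        template = make_spike_template(sample_rate_hz, u.waveform_amp_uv)
        trough = int(np.argmin(template))
        for t in t_abs:
            a = int(round(t * sample_rate_hz)) - trough
            b = a + template.size
            if a >= 0 and b <= n_samples:
                traces[u.channel, a:b] += template

    if noise_sd_uv > 0:
        traces += rng.normal(0.0, noise_sd_uv, traces.shape)

    rec = Recording(traces=traces.astype(np.float32),
                    sample_rate_hz=sample_rate_hz,
                    protocol=protocol,
                    channel_layout=default_channel_layout(n_channels),
                    metadata={"band_high_hz": 5000.0,
                              "noise_sd_uv": noise_sd_uv,
                              "synthetic": True})
    truth = GroundTruth(unit_spike_times=spike_times,
                        unit_params=list(units),
                        microerg_amplitudes=erg_amps)
    return rec, truth


# ---------------------------------------------------------------------------
# Group scenarios
# ---------------------------------------------------------------------------

def _load_scenarios() -> dict:
    text = (importlib.resources.files("mearetina") / "scenarios.yaml"
            ).read_text()
    return yaml.safe_load(text)


def make_group_scenario(name: str, n_units: int,
                        seed: int | np.random.Generator = 0,
                        n_channels: int = 64) -> list[UnitParams]:
    """Unit populations for a treatment-group scenario.

    Scenarios (``sham``, ``treated_50``, ``treated_100``) follow the
    qualitative treatment pattern the pipeline is designed to resolve:
    electrical stimulation lowers the pathologically high spontaneous rate
    in both treated groups; 50 μA also lowers the evoked response and
    light sensitivity (higher σ), while 100 μA keeps a sham-level response
    with improved sensitivity (lower σ). Mean parameters are tabulated in
    ``scenarios.yaml``; spreads across units are package choices, not
    measured biology.
    """
    tables = _load_scenarios()
    if name not in tables:
        raise ValidationError(
            f"unknown scenario '{name}'; available: {sorted(tables)}")
    if n_units > n_channels:
        raise ValidationError("one unit per home channel: n_units must "
                              "not exceed n_channels")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    tab = tables[name]
    pol_names = list(tab["polarity"])
    pol_probs = np.array([tab["polarity"][p] for p in pol_names], dtype=float)
    pol_probs /= pol_probs.sum()

    def draw(key: str, lo: float) -> float:
        spec = tab[key]
        return float(max(lo, rng.normal(spec["mean"], spec["sd"])))

    units = []
    for i in range(n_units):
        units.append(UnitParams(
            r_spont=draw("r_spont", 0.5),
            a_max=draw("a_max", 1.0),
            sigma_true=draw("sigma_true", 3.0),
            hill_n=draw("hill_n", 0.3),
            polarity=str(rng.choice(pol_names, p=pol_probs)),
            latency_s=draw("latency_s", 0.03),
            tau_decay_s=draw("tau_decay_s", 0.05),
            waveform_amp_uv=draw("waveform_amp_uv", 10.0),
            channel=i,
            burst_mean=draw("burst_mean", 1.0) if "burst_mean" in tab
            else 1.0,
        ))
    return units
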