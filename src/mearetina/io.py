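"""Recording container, stimulus bookkeeping and the HDF5 round-trip.

The in-memory objects here are what every analysis stage consumes: a
:class:`Recording` (channels × samples voltage matrix plus a
:class:`StimulusProtocol`), and optionally a :class:`GroundTruth` carrying
the generative parameters of a synthetic recording so downstream stages can
be checked by parameter recovery.

All index ranges are 0-based half-open sample ranges; times are seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any, Mapping, Sequence

import h5py
import numpy as np

SCHEMA_VERSION = 1

#: microERG component names, onset-locked first (N1..P2) then offset-locked.
COMPONENTS = ("N1", "P1", "N2", "P2", "N3", "P3")

#: Flash-intensity ladder, log10 photons/μm²/s.
DEFAULT_INTENSITIES = (4.20, 5.46, 5.96, 6.68, 7.09, 7.67)


class ValidationError(ValueError):
    """A container field violates its invariant; the message names the field."""


class SchemaError(IOError):
    """A recording file is missing a required dataset or attribute."""


def _sequential_onsets(trial_duration_s: float, n_intensities: int,
                       n_repetitions: int) -> np.ndarray:
    """Back-to-back trials, grouped in blocks of one intensity each."""
    n = n_intensities * n_repetitions
    return (np.arange(n, dtype=float) * trial_duration_s).reshape(
        n_intensities, n_repetitions)


@dataclass(eq=False)
class StimulusProtocol:
    """Full-field flash protocol: repeated trials with light ON at trial start.

    Defaults follow the recording protocol the pipeline targets: 30
    repetitions of 10 s trials with light ON for the first 2 s, at six
    flash intensities.
    """

    trial_duration_s: float = 10.0
    on_duration_s: float = 2.0
    n_repetitions: int = 30
    intensities_log: tuple[float, ...] = DEFAULT_INTENSITIES
    trial_onsets_s: np.ndarray | None = None  # (n_intensities, n_repetitions)

    def __post_init__(self) -> None:
        self.intensities_log = tuple(float(i) for i in self.intensities_log)
        if not self.on_duration_s < self.trial_duration_s:
            raise ValidationError("on_duration_s must be < trial_duration_s")
        if self.n_repetitions < 1:
            raise ValidationError("n_repetitions must be >= 1")
        if len(self.intensities_log) == 0:
            raise ValidationError("intensities_log must be non-empty")
        if np.any(np.diff(self.intensities_log) <= 0):
            raise ValidationError("intensities_log must be strictly increasing")
        if self.trial_onsets_s is None:
            self.trial_onsets_s = _sequential_onsets(
                self.trial_duration_s, self.n_intensities, self.n_repetitions)
        else:
            self.trial_onsets_s = np.asarray(self.trial_onsets_s, dtype=float)
            if self.trial_onsets_s.shape != (self.n_intensities,
                                             self.n_repetitions):
                raise ValidationError(
                    "trial_onsets_s must have shape "
                    "(n_intensities, n_repetitions)")

    @property
    def n_intensities(self) -> int:
        return len(self.intensities_log)

    @property
    def n_trials(self) -> int:
        return self.n_intensities * self.n_repetitions

    @property
    def total_duration_s(self) -> float:
        return float(self.trial_onsets_s.max() + self.trial_duration_s)

    def intensity_index(self, intensity_log: float) -> int:
        """Index of a ladder intensity, matched with a small tolerance."""
        d = np.abs(np.asarray(self.intensities_log) - intensity_log)
        i = int(np.argmin(d))
        if d[i] > 1e-6:
            raise ValidationError(
                f"intensity {intensity_log} not in protocol ladder "
                f"{self.intensities_log}")
        return i

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StimulusProtocol):
            return NotImplemented
        return (self.trial_duration_s == other.trial_duration_s
                and self.on_duration_s == other.on_duration_s
                and self.n_repetitions == other.n_repetitions
                and self.intensities_log == other.intensities_log
                and np.array_equal(self.trial_onsets_s, other.trial_onsets_s))


@dataclass(frozen=True)
class TrialWindows:
    """Half-open sample ranges for one trial."""

    trial: tuple[int, int]
    on: tuple[int, int]
    off: tuple[int, int]
    spont: tuple[int, int]


def trial_slices(protocol: StimulusProtocol, sample_rate_hz: float,
                 spont_window_s: float = 2.0,
                 ) -> dict[tuple[int, int], TrialWindows]:
    """Sample-index windows for every (intensity, repetition) trial.

    ON is the lit epoch, OFF the equally long epoch after light offset, and
    the spontaneous window the last ``spont_window_s`` of the trial — the
    epoch maximally distant from both light transients, serving as the
    pre-onset baseline of the following trial.
    """
    if sample_rate_hz <= 0:
        raise ValidationError("sample_rate_hz must be positive")
    on_d, T = protocol.on_duration_s, protocol.trial_duration_s
    if spont_window_s <= 0 or spont_window_s > T - 2 * on_d:
        raise ValidationError(
            "spont_window_s must lie in (0, trial_duration - 2*on_duration]")
    out: dict[tuple[int, int], TrialWindows] = {}
    for i in range(protocol.n_intensities):
        for r in range(protocol.n_repetitions):
            t0 = protocol.trial_onsets_s[i, r]

            def s(t: float) -> int:
                return int(round(t * sample_rate_hz))

            out[(i, r)] = TrialWindows(
                trial=(s(t0), s(t0 + T)),
                on=(s(t0), s(t0 + on_d)),
                off=(s(t0 + on_d), s(t0 + 2 * on_d)),
                spont=(s(t0 + T - spont_window_s), s(t0 + T)),
            )
    return out


def default_channel_layout(n_channels: int, n_cols: int = 8) -> np.ndarray:
    """(row, col) grid indices for ``n_channels`` electrodes, row-major."""
    idx = np.arange(n_channels)
    return np.stack([idx // n_cols, idx % n_cols], axis=1)


@dataclass(eq=False)
class Recording:
    """A multi-channel extracellular recording with its stimulus protocol.

    ``traces`` is channels × samples in μV (float32, matching the on-disk
    schema); ``channel_layout`` holds (row, col) grid indices on a grid of
    ``pitch_um`` spacing — analysis never depends on physical position.
    """

    traces: np.ndarray
    sample_rate_hz: float
    protocol: StimulusProtocol
    channel_layout: np.ndarray | None = None
    pitch_um: float = 100.0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=np.float32)
        if self.traces.ndim != 2:
            raise ValidationError("traces must be 2-D (channels × samples)")
        if self.channel_layout is None:
            self.channel_layout = default_channel_layout(self.n_channels)
        self.channel_layout = np.asarray(self.channel_layout, dtype=np.int64)
        if self.channel_layout.shape != (self.n_channels, 2):
            raise ValidationError(
                "channel_layout length must equal the number of trace "
                "channels")
        band_high = float(self.metadata.get("band_high_hz", 0.0))
        if band_high and self.sample_rate_hz <= 2 * band_high:
            raise ValidationError(
                "sample_rate_hz must exceed twice the acquisition band edge")
        dur = self.n_samples / self.sample_rate_hz
        last_end = (self.protocol.trial_onsets_s.max()
                    + self.protocol.trial_duration_s)
        if last_end > dur + 0.5 / self.sample_rate_hz:
            raise ValidationError(
                "protocol trial windows extend past the trace extent")

    @property
    def n_channels(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass(eq=False)
class GroundTruth:
    """Generative parameters of a synthetic recording.

    ``unit_spike_times`` are absolute seconds, sorted per unit;
    ``unit_params`` the per-unit generator parameters;
    ``microerg_amplitudes`` the realized per-channel slow-wave component
    amplitudes, shaped (channels, intensities, 6) in the order of
    :data:`COMPONENTS`.
    """

    unit_spike_times: list[np.ndarray] = field(default_factory=list)
    unit_params: list[Any] = field(default_factory=list)
    microerg_amplitudes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.unit_spike_times = [np.asarray(t, dtype=float)
                                 for t in self.unit_spike_times]
        for u, t in enumerate(self.unit_spike_times):
            if t.size and (np.any(np.diff(t) < 0) or t[0] < 0):
                raise ValidationError(
                    f"unit_spike_times[{u}] must be sorted and non-negative")
        if self.microerg_amplitudes is not None:
            self.microerg_amplitudes = np.asarray(
                self.microerg_amplitudes, dtype=float)


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def write_recording(recording: Recording, path,
                    truth: GroundTruth | None = None) -> None:
    """Write a recording (and optional ground truth) to an HDF5 container.

    The file round-trips bit-exactly through :func:`read_recording`.
    Schema: ``/traces`` (float32), ``/channel_layout``, ``/protocol``
    (attrs + onset dataset), ``/metadata`` (JSON-encoded attrs), optional
    ``/ground_truth``.
    """
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        d = f.create_dataset("traces", data=recording.traces, dtype="float32")
        d.attrs["sample_rate_hz"] = recording.sample_rate_hz
        d.attrs["pitch_um"] = recording.pitch_um
        f.create_dataset("channel_layout", data=recording.channel_layout)
        p = f.create_group("protocol")
        p.attrs["trial_duration_s"] = recording.protocol.trial_duration_s
        p.attrs["on_duration_s"] = recording.protocol.on_duration_s
        p.attrs["n_repetitions"] = recording.protocol.n_repetitions
        p.create_dataset("intensities_log",
                         data=np.asarray(recording.protocol.intensities_log))
        p.create_dataset("trial_onsets_s",
                         data=recording.protocol.trial_onsets_s)
        m = f.create_group("metadata")
        for k, v in recording.metadata.items():
            m.attrs[k] = json.dumps(v)
        if truth is not None:
            g = f.create_group("ground_truth")
            st = g.create_group("spike_times")
            for u, times in enumerate(truth.unit_spike_times):
                ds = st.create_dataset(f"unit_{u:04d}", data=times)
                if u < len(truth.unit_params):
                    params = truth.unit_params[u]
                    d_params = (asdict(params) if hasattr(params, "__dataclass_fields__")
                                else dict(params))
                    for k, v in d_params.items():
                        ds.attrs[k] = v
            if truth.microerg_amplitudes is not None:
                g.create_dataset("microerg_amplitudes",
                                 data=truth.microerg_amplitudes)


def read_recording(path) -> tuple[Recording, GroundTruth | None]:
    """Read an HDF5 container written by :func:`write_recording`."""
    with h5py.File(path, "r") as f:
        for required in ("traces", "protocol", "channel_layout"):
            if required not in f:
                raise SchemaError(f"missing required dataset/group "
                                  f"'{required}' in {path}")
        p = f["protocol"]
        for required in ("intensities_log", "trial_onsets_s"):
            if required not in p:
                raise SchemaError(f"missing required dataset "
                                  f"'protocol/{required}' in {path}")
        protocol = StimulusProtocol(
            trial_duration_s=float(p.attrs["trial_duration_s"]),
            on_duration_s=float(p.attrs["on_duration_s"]),
            n_repetitions=int(p.attrs["n_repetitions"]),
            intensities_log=tuple(p["intensities_log"][()]),
            trial_onsets_s=p["trial_onsets_s"][()],
        )
        metadata = {k: json.loads(v) for k, v in f["metadata"].attrs.items()
                    } if "metadata" in f else {}
        rec = Recording(
            traces=f["traces"][()],
            sample_rate_hz=float(f["traces"].attrs["sample_rate_hz"]),
            pitch_um=float(f["traces"].attrs.get("pitch_um", 100.0)),
            protocol=protocol,
            channel_layout=f["channel_layout"][()],
            metadata=metadata,
        )
        truth = None
        if "ground_truth" in f:
            from .simulate import UnitParams  # deferred: avoids import cycle
            g = f["ground_truth"]
            times, params = [], []
            if "spike_times" in g:
                for name in sorted(g["spike_times"]):
                    ds = g["spike_times"][name]
                    times.append(ds[()])
                    if ds.attrs:
                        kw = {k: (v.item() if hasattr(v, "item") else v)
                              for k, v in ds.attrs.items()}
                        if "polarity" in kw and isinstance(kw["polarity"], bytes):
                            kw["polarity"] = kw["polarity"].decode()
                        params.append(UnitParams(**kw))
            amps = (g["microerg_amplitudes"][()]
                    if "microerg_amplitudes" in g else None)
            truth = GroundTruth(unit_spike_times=times, unit_params=params,
                                microerg_amplitudes=amps)
    return rec, truth
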