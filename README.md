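# mearetina

Analysis pipeline for ex-vivo multi-electrode-array (MEA) recordings of
retina under full-field flashes, built for quantifying treatment effects
in photoreceptor-degeneration models (rd10 mice and similar). It covers
the full chain from raw voltage traces to group statistics:

* **Band separation** — zero-phase 100 Hz Butterworth split of each
  channel into the slow microERG field potential and the spike band;
* **microERG components** — trial-averaged measurement of the six named
  peaks (N1, P1, N2, P2 after light onset; N3, P3 after offset),
  baseline-to-peak, per channel;
* **RGC spike metrics** — threshold detection, simple two-feature
  sorting, 10 ms-bin PSTHs, and per-unit spontaneous rate, peak/average
  light response, latency, SNR and ON/OFF class;
* **Light sensitivity** — per-unit Hill fits
  R(I) = R_max·Iⁿ/(Iⁿ+σⁿ) on linear intensity, reporting σ (the flash
  intensity evoking the half-maximum response; lower σ = higher
  sensitivity) as log10 photons/μm²/s;
* **Group statistics** — the classic normality-gated tree: Shapiro–Wilk,
  then Student's t / one-way ANOVA + Tukey for parametric data or
  Mann–Whitney / Kruskal–Wallis + Dunn (Bonferroni) otherwise;
* **Synthetic recordings** — an inhomogeneous-Poisson spike and
  Gaussian-bump microERG generator with full ground truth, so every stage
  above is validated by parameter recovery (no proprietary vendor data is
  needed anywhere).

The default stimulus protocol is 30 repetitions of 10 s trials with
light ON for the first 2 s, at six intensities
{4.20, 5.46, 5.96, 6.68, 7.09, 7.67} log10 photons/μm²/s, sampled at
20 kHz on an 8×8 grid.

## Worked example

```python
import numpy as np
from mearetina import (StimulusProtocol, make_group_scenario,
                       simulate_unit_spikes, spikes_to_absolute,
                       build_psth, compute_unit_metrics)

protocol = StimulusProtocol()            # 6 intensities × 30 trials
unit = make_group_scenario("sham", 1, seed=1)[0]
spikes = spikes_to_absolute(
    simulate_unit_spikes(unit, protocol, np.random.default_rng(1)),
    protocol)
m = compute_unit_metrics(build_psth(spikes, protocol, 7.67), protocol)
print(f"spont {m.r_spont:.1f} Hz (true {unit.r_spont:.1f}), "
      f"peak ON {m.peak_on:.1f} Hz, SNR {m.snr_peak:.1f}, "
      f"class {m.response_class}")
```

prints

```
spont 18.3 Hz (true 19.3), peak ON 58.3 Hz, SNR 7.0, class ON
```

i.e. the spontaneous rate of this simulated sham-like cell is recovered
within ~5%, the light flash adds a ~58 Hz transient at onset, and the
response is 7 spontaneous-SDs above the cell's own noise.

The full analysis is organized as numbered drivers:

| script | does | writes |
|---|---|---|
| `analysis/01_simulate_recordings.py` | 8-channel demo recording (traces + ground truth) | `scratch/demo_sham.h5` |
| `analysis/02_band_separation.py` | microERG/spike band split + fidelity report | `results/band_separation.json` |
| `analysis/03_microerg_components.py` | six-component amplitudes vs. truth | `results/microerg_peaks.csv` |
| `analysis/04_spike_metrics.py` | detection → sorting → PSTH metrics | `results/unit_metrics.csv` |
| `analysis/05_light_sensitivity.py` | 3 scenario groups × 30 units, Hill fits | `results/scenario_metrics.csv` |
| `analysis/06_group_statistics.py` | decision-tree comparisons of the groups | `results/report.{json,md}` |

Running 05→06 compares the three built-in treatment scenarios (sham,
50 μA, 100 μA) and reports, per metric, group means ± SEM, the selected
branch, omnibus p and post-hoc pairs — e.g. spontaneous firing
17.5 → 12.8 → 11.9 spikes/s with the 100 μA group significantly below
sham, higher SNR, and a significantly lower σ.

## Recording container

HDF5, versioned with a `schema_version` attribute:

| path | content |
|---|---|
| `/traces` | float32, channels × samples (μV); attrs `sample_rate_hz`, `pitch_um` |
| `/channel_layout` | (row, col) grid index per channel |
| `/protocol` | attrs `trial_duration_s`, `on_duration_s`, `n_repetitions`; datasets `intensities_log`, `trial_onsets_s` |
| `/metadata` | free-form JSON-encoded attributes |
| `/ground_truth` | optional: per-unit spike times + generator params, realized microERG amplitudes |

Round-trips through `write_recording`/`read_recording` are bit-exact.

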