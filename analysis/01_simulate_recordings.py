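#!/usr/bin/env python
"""Simulate a demonstration MEA recording with known ground truth.

Builds a small sham-like recording — 8 electrodes carrying microERG
kernels, one spiking unit per electrode, white noise — at the saturating
flash intensity with 10 repetitions, and writes it (with ground truth) to
scratch/demo_sham.h5 for the downstream trace-level analyses. The full
6-intensity × 30-repetition protocol at 20 kHz would be ~GBs of waveform;
the spike-train-level analyses (05/06) use the full protocol instead.
"""

from pathlib import Path

import numpy as np

from mearetina import (StimulusProtocol, assemble_recording,
                       default_microerg_kernels, make_group_scenario,
                       write_recording)

OUT = Path(__file__).resolve().parents[1] / "scratch" / "demo_sham.h5"
SEED = 7
N_CHANNELS = 8


def main() -> None:
    protocol = StimulusProtocol(intensities_log=(7.67,), n_repetitions=10)
    rng = np.random.default_rng(SEED)
    units = make_group_scenario("sham", N_CHANNELS, rng,
                                n_channels=N_CHANNELS)
    kernels = {ch: default_microerg_kernels() for ch in range(N_CHANNELS)}
    rec, truth = assemble_recording(units, protocol,
                                    channel_kernels=kernels,
                                    noise_sd_uv=5.0,
                                    n_channels=N_CHANNELS, seed=rng)
    OUT.parent.mkdir(exist_ok=True)
    write_recording(rec, OUT, truth=truth)
    n_spikes = sum(t.size for t in truth.unit_spike_times)
    print(f"wrote {OUT}")
    print(f"  {rec.n_channels} channels × {rec.duration_s:.0f} s at "
          f"{rec.sample_rate_hz:.0f} Hz")
    print(f"  {len(units)} units, {n_spikes} true spikes, "
          f"mean spontaneous rate parameter "
          f"{np.mean([u.r_spont for u in units]):.1f} spikes/s")


if __name__ == "__main__":
    main()
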