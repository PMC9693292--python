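#!/usr/bin/env python
"""Detect, sort and characterize spiking units on the demo recording.

High-passes the traces, thresholds at 4 robust SDs, clusters clips into
units, and computes PSTH-based metrics (spontaneous rate, peak/average
light response, latency, SNR, response class). Sorted-unit spontaneous
rates are compared against the generator's per-unit truth. Writes
results/unit_metrics.csv.
"""

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from mearetina import (build_psth, compute_unit_metrics, detect_spikes,
                       read_recording, sort_units, split_bands)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    rec, truth = read_recording(ROOT / "scratch" / "demo_sham.h5")
    intensity = rec.protocol.intensities_log[-1]
    high = split_bands(rec).high_band
    detections = detect_spikes(high, rec.sample_rate_hz)

    rows, recovered = [], []
    for det in detections:
        for train in sort_units(det, rec.sample_rate_hz):
            psth = build_psth(train, rec.protocol, intensity)
            m = compute_unit_metrics(psth, rec.protocol)
            row = asdict(m)
            row["channel"] = train.channel
            row["n_spikes"] = train.spike_times_s.size
            rows.append(row)
            true_unit = truth.unit_params[train.channel]  # one unit/channel
            recovered.append((m.r_spont, true_unit.r_spont))
    df = pd.DataFrame(rows)
    out = ROOT / "results" / "unit_metrics.csv"
    out.parent.mkdir(exist_ok=True)
    df.to_csv(out, index=False)

    rec_err = [abs(a - b) / b for a, b in recovered]
    print(df[["unit_id", "r_spont", "peak_on", "avg_on", "snr_peak",
              "response_class"]].to_string(index=False))
    print(f"\n{len(df)} units sorted from {rec.n_channels} channels; "
          f"median |spontaneous-rate error| vs truth "
          f"{100 * np.median(rec_err):.1f}% at 10 trials — wrote {out}")


if __name__ == "__main__":
    main()
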