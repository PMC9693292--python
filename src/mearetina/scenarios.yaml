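# Treatment-group scenario tables for the synthetic-recording generator.
#
# Means of r_spont follow the printed group means of the study the pipeline
# emulates (18 / 13.6 / 11.4 spikes/s for sham / 50 uA / 100 uA). The
# remaining means encode the qualitative pattern: 50 uA lowers the evoked
# response and raises sigma (less sensitive); 100 uA keeps a sham-level
# response and lowers sigma. Across-unit SDs are package choices: the
# r_spont SD (3.8) reproduces an SEM of ~0.7 spikes/s at n = 30 cells;
# other SDs are set to plausible across-cell variability. burst_mean
# controls spontaneous burstiness (1 = Poisson): degenerating retinas show
# bursty/oscillatory hyperactivity, which inflates the SD of spontaneous
# firing beyond the Poisson sqrt-rate and which treatment suppresses —
# this is what lets the treated group gain SNR beyond the pure rate drop.
sham:
  r_spont:         {mean: 18.0, sd: 3.8}
  a_max:           {mean: 40.0, sd: 10.0}
  sigma_true:      {mean: 6.2,  sd: 0.2}
  hill_n:          {mean: 1.0,  sd: 0.15}
  latency_s:       {mean: 0.12, sd: 0.02}
  tau_decay_s:     {mean: 0.30, sd: 0.05}
  waveform_amp_uv: {mean: 60.0, sd: 15.0}
  burst_mean:      {mean: 2.0,  sd: 0.3}
  polarity:        {"ON": 0.70, "OFF": 0.15, "ON-OFF": 0.15}

treated_50:
  r_spont:         {mean: 13.6, sd: 3.8}
  a_max:           {mean: 28.0, sd: 8.0}
  sigma_true:      {mean: 6.55, sd: 0.2}
  hill_n:          {mean: 1.0,  sd: 0.15}
  latency_s:       {mean: 0.12, sd: 0.02}
  tau_decay_s:     {mean: 0.30, sd: 0.05}
  waveform_amp_uv: {mean: 60.0, sd: 15.0}
  burst_mean:      {mean: 1.6,  sd: 0.3}
  polarity:        {"ON": 0.70, "OFF": 0.15, "ON-OFF": 0.15}

treated_100:
  r_spont:         {mean: 11.4, sd: 3.8}
  a_max:           {mean: 40.0, sd: 10.0}
  sigma_true:      {mean: 5.9,  sd: 0.2}
  hill_n:          {mean: 1.0,  sd: 0.15}
  latency_s:       {mean: 0.12, sd: 0.02}
  tau_decay_s:     {mean: 0.30, sd: 0.05}
  waveform_amp_uv: {mean: 60.0, sd: 15.0}
  burst_mean:      {mean: 1.0,  sd: 0.0}
  polarity:        {"ON": 0.70, "OFF": 0.15, "ON-OFF": 0.15}
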