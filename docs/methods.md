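# Methods

## Scope and model

`mearetina` analyses ex-vivo multi-electrode-array (MEA) recordings of
retina under repeated full-field flashes, as used to quantify treatment
effects in photoreceptor-degeneration models (rd10). A recording is a
channels × samples voltage matrix at 20 kHz from an 8×8 grid (100 μm
pitch) together with a stimulus protocol: by default 30 repetitions of
10 s trials with light ON for the first 2 s, at six flash intensities
{4.20, 5.46, 5.96, 6.68, 7.09, 7.67} log10 photons/μm²/s.

The pipeline has five analysis stages, each behind its own module:

1. **Band separation** (`filtering`). The slow local field potential
   (microERG) and the spike band are obtained by a 4th-order Butterworth
   low-/high-pass at 100 Hz, applied forward–backward (zero phase). The
   filter family and order are not dictated by the protocol itself; the
   Butterworth/zero-phase choice is standard in extracellular
   electrophysiology because it has a maximally flat passband and does not
   displace peak latencies. Both bands are filtered from the raw trace
   independently. A side effect of the same-order forward–backward pair is
   that the effective transfer functions sum to one, so the two bands
   reconstruct the input almost exactly.

2. **microERG components** (`microerg`). Per channel, trials of one
   intensity are averaged pointwise; six components are measured on the
   average: N1, P1, N2, P2 after light onset and N3, P3 after offset. Each
   is the signed extremum of the expected polarity inside a per-component
   search window (defaults: N1 [0, 60] ms, P1 [20, 150] ms, N2 [100, 600]
   ms, P2 [0.3, 2] s after onset; N3 [0, 200] ms, P3 [0.1, 2] s after
   offset; all configurable). Amplitude is measured baseline-to-peak,
   where the baseline is the mean of the spontaneous window — reproducible
   and invariant to constant offsets, unlike a visually placed baseline. A
   component is "absent" when its deflection stays within 2 baseline SDs
   (configurable; an absolute floor of 1e-6 μV handles noise-free
   baselines whose SD is exactly zero). Ties between equal extrema go to
   the earliest sample.

3. **Spikes** (`spikes`). Detection thresholds each channel at 4 robust
   noise SDs (median(|x|)/0.6745), takes negative-going crossings with a
   1 ms dead time, and aligns 2.5 ms clips on the trough. Sorting is
   deliberately simple: k-means on two clip features (trough amplitude,
   trough-to-peak width), k ∈ {1..4} chosen by silhouette with a 0.5 floor
   for accepting k ≥ 2. Features are interpolated to sub-sample precision
   (the 50 μs grid would otherwise quantize widths into spurious clusters)
   and scaled physically — amplitude in noise-SD units, width in 0.25 ms
   units — because z-scoring inflates whichever feature carries no
   structure on a given channel. Units violating a 2 ms refractory
   contract in >1% of intervals are flagged. All downstream metrics also
   accept ground-truth spike trains, so metric correctness is testable
   independently of sorter quality.

4. **Unit metrics** (`spikes`). PSTHs use 10 ms bins tiling one trial.
   Spontaneous rate and its SD come from the spontaneous-window bins; the
   ON (OFF) response is the peak or mean rate in the 2 s after onset
   (offset) minus the spontaneous rate, kept signed; SNR divides the
   response by the SD of spontaneous firing; latency is the time from the
   transient to the PSTH peak (earliest maximal bin, bin centre).
   Response class (ON/OFF/ON-OFF/nonresponsive) is assigned by which
   window's peak exceeds k·SD (k = 3 by default). Two caveats are
   inherent to these definitions and documented rather than patched: the
   peak-of-PSTH estimator carries a max-over-bins selection bias (at 30
   trials and ~58 Hz peak rate, roughly +1.5 bin-SDs), and with ~200 bins
   per window the k = 3 gate misfires by chance at high spontaneous SD,
   inflating ON-OFF calls; k is configurable where that matters.

5. **Sensitivity and statistics** (`sensitivity`, `stats`). Each unit's
   response vs. intensity is fit by the Hill equation
   R(I) = R_max·Iⁿ/(Iⁿ+σⁿ) on linear intensity (the stimulus ladder is
   log-spaced, but "half-maximum" is defined on intensity), by unweighted
   least squares from a 3×3 multi-start grid over (σ, n); σ is reported as
   log10. The Hill coefficient is bounded to [0.3, 6] — with six points an
   unbounded n makes σ unidentifiable. Fits with σ outside the ladder ±1
   log unit are flagged extrapolated and excluded from group summaries
   (exclusions counted). Group comparisons run the classic decision tree:
   Shapiro–Wilk per group at α = 0.05; all pass → Student's t (two
   groups) or one-way ANOVA with Tukey post-hoc; otherwise Mann–Whitney U
   or Kruskal–Wallis with Dunn's post-hoc, Bonferroni-adjusted (Dunn's
   z-test is implemented in-package; no post-hoc library is a dependency).
   Constant groups route nonparametric with a warning. Channels/cells are
   treated as independent observations — nesting within retinas is
   deliberately not modelled, and reported n is per group.

## The synthetic generator

`simulate` produces recordings with known ground truth so that every
stage is validated by parameter recovery rather than by eye.

* **Spiking units.** An inhomogeneous Poisson process with rate
  r(t) = r_spont + A(I)·k(t), A(I) = A_max·Iⁿ/(Iⁿ+σⁿ) on linear
  intensity, and k(t) a unit-peak generalized alpha transient
  (t/t_peak)^a·exp(a(1−t/t_peak)), a = t_peak/τ_decay, placed at onset,
  offset or both. Spikes are drawn by thinning and pruned to a 2 ms
  absolute refractory period; the thinning makes the realized mean rate
  r/(1+r·τ_ref), a ~3–6% downward bias that the analysis does not correct
  (the estimators stay honest; recovery tests account for it in their
  oracles).
* **Spontaneous burstiness.** Spontaneous firing is Poisson by default
  (`burst_mean` = 1) or a Neyman–Scott cluster process: burst onsets at
  rate r_spont/burst_mean, each with 1 + Poisson(burst_mean−1) spikes at
  2.5–8 ms intervals. This leaves the mean rate unchanged but
  overdisperses PSTH bin counts, emulating the bursty/oscillatory
  hyperactivity of degenerating retinas. It matters for treatment
  contrasts: reducing bursty spontaneous activity lowers the SD of
  spontaneous firing faster than √rate, which is what lets a treated
  group gain SNR well beyond the pure rate drop.
* **microERG.** Deterministic Gaussian bumps per component and trial,
  with amplitudes scaled by a saturating function of intensity
  (I/(I+10^sat)); realized amplitudes are recorded as ground truth, and
  kernel sets whose neighbouring peaks are closer than twice the larger
  width are flagged as overlapping.
* **Traces.** microERG + biphasic ~1.2 ms spike templates on each unit's
  home electrode + white Gaussian noise (default 5 μV SD). One unit per
  home channel by default. Identical seed ⇒ byte-identical traces.
* **Scenarios.** `scenarios.yaml` tabulates three unit populations. Mean
  spontaneous rates follow the printed group means of the study being
  emulated (sham 18, 50 μA 13.6, 100 μA 11.4 spikes/s); the 50 μA group
  has a lower evoked amplitude and higher σ (less sensitive), the 100 μA
  group a sham-level response, lower σ, and no burstiness
  (burst_mean 2.0 / 1.6 / 1.0 for sham / 50 / 100 μA). Across-unit SDs
  are package choices of plausible variability, not measured biology; the
  r_spont SD (3.8) reproduces an SEM of ~0.7 spikes/s at n = 30 cells.

What the generator does **not** emulate: electrode drift, correlated
(pink) noise by default, spike-waveform nonstationarity, cross-channel
crosstalk, stimulus artifacts, or any biophysical (conductance-based)
dynamics. Passing recovery tests therefore demonstrate the correctness of
the measurement code under the stated statistical model, not robustness
to every pathology of real recordings.

## Validation benchmarks (`benchmarks`)

Problem sizes are chosen to finish in about a minute total while leaving
comfortable statistical margins.

* Band split: a 5 Hz (100 μV) + 500 Hz (20 μV) composite at 20 kHz; each
  band is compared to its true tone (relative RMS, interior samples), and
  the zero-phase property is checked as a 0-sample peak shift of a pulse.
* PSTH: `build_psth` against a brute-force per-bin counting loop on 100
  random spike sets — exact agreement.
* Spontaneous rate: 50 units, r_spont uniform in [5, 30] spikes/s, full
  ladder; estimate = mean spontaneous-window rate across intensities.
* SNR monotonicity: 20 units with A_max graded 5→60 spikes/s at fixed
  r_spont = 18. Units share one realization of the spontaneous process
  and one evoked candidate stream (monotone coupling): the benchmark asks
  whether the measurement path is monotone in the true amplitude at fixed
  noise, so rank inversions must reflect the estimator, not independent
  sampling noise.
* microERG recovery: 50 random kernel sets (30 noisy trials each, noise
  SD at 10% of the smallest amplitude). Draws preserve the canonical
  component proportions under a global scale, and slow-component widths
  are capped (P2 ≤ 130 ms, P3 ≤ 100 ms) so that each peak is localizable
  to the 5 ms latency tolerance at this noise level — the peak of an
  arbitrarily broad, small hump is not localizable to 5 ms by any
  extremum search, and noise-free errors (<1 ms) confirm the bound is
  sampling jitter, not bias.
* Hill σ: noise-free fits on the ladder (max |Δσ_log| ≤ 0.02), Poisson
  spiking at 30 trials (median |Δσ_log|), and agreement of the optimizer
  RSS with an independent two-stage lattice search.
* Detection: false-crossing rate on pure Gaussian noise against the
  analytic tail rate Φ(−k)·fs, and 100% recovery of inserted 10×SD
  templates within 0.5 ms.
* Statistics: omnibus type-I rate at α = 0.05 over 2000 null datasets per
  branch (normal data → parametric path, lognormal → nonparametric), and
  exact agreement of Mann–Whitney p-values with exhaustive permutation
  enumeration at n ≤ 8.
* End-to-end: sham vs. treated-100 scenarios (30 units each, full
  protocol, spike-train level) through metrics, Hill fits and the
  statistical tree. Group SNR uses the average-response variant (the peak
  variant inherits the max-over-bins noise) with the response window
  matched to each unit's true polarity, since classification flips are
  not the quantity under study. Trace-level analysis (filtering,
  detection, sorting) is exercised at demonstration scale in `analysis/`
  — the full scenario at 20 kHz would be tens of gigabytes of waveform
  without changing what the contrast tests.

## Numerical choices and degenerate inputs

* Hill curves are evaluated in the log domain,
  R = R_max/(1+10^{n(σ_log−I_log)}), to avoid overflow at linear
  intensities of 10^7+.
* sd_spont = 0 with a nonzero response reports SNR as +∞ with a flag;
  flat PSTHs are nonresponsive with SNR 0.
* All randomness flows through one `numpy` Generator per call; every
  simulation is reproducible from (parameters, seed).
* HDF5 containers are versioned (`schema_version`), traces stored
  float32; round-trips are bit-exact.

## Known limitations

* The sorter is a two-feature k-means — adequate for well-separated
  templates, not for overlapping spikes or drift; ground-truth trains
  bypass it for metric validation.
* Sharp microERG transients leak a little energy above 100 Hz, producing
  occasional stimulus-locked threshold crossings that appear as tiny
  spurious "units" at trace level; they are low-rate and visible in the
  demo output.
* The peak-response estimator is upward-biased by max-over-bins
  selection; comparisons across groups remain valid (the bias is shared)
  but absolute peak values overestimate the underlying rate increment.
* Treating cells/channels as independent n reproduces the conventional
  analysis but understates uncertainty when many cells come from one
  retina.
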