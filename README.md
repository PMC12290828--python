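# pingdecode

Time-resolved EEG decoding of retrieved long-term-memory content under
visual "ping" perturbation — a tested, reusable re-implementation of the
full statistical pipeline of a cued-recall ping experiment, driven by a
synthetic-data generator so that every claim-generating procedure can be
exercised and validated without any recordings.

## The problem

During cued recall, stimulus-specific neural patterns re-emerge
("reinstatement"), but their onset latency drifts across trials and
participants, which caps the performance of multivariate pattern analysis
(MVPA). A brief high-contrast visual impulse — a *ping* — presented during
retrieval might regularize those dynamics and so sharpen the decodability
of the retrieved content. Testing that hypothesis requires a specific
chain of machinery, all of which this package provides:

- **Design generator** (`pingdecode.design`): blocks of verb–image pairs
  drawn from a 2×2×4×12 nested category hierarchy (96 objects / 96 scenes);
  each pair is recalled once per condition {early, middle, late, no ping},
  with ping onsets uniform in 500–833.33 / 833.34–1116.67 / 1116.68–1500 ms
  after the cue (75% pinged overall), categories balanced within condition,
  and no pair tested twice in a row.
- **EEG simulator** (`pingdecode.simulate`): 1/f + oscillatory background,
  a posterior biphasic ping-evoked response, and class-specific channel
  patterns whose onset jitters trial-to-trial; a regularization parameter
  ρ ∈ [0, 1] shrinks that jitter on pinged trials (the hypothesized
  mechanism; ρ = 0 is the null).
- **Features** (`pingdecode.features`): baseline correction, Gaussian-
  weighted moving-average downsampling to 50 Hz (140 ms windows, 20 ms
  steps, edge weight 0.15), per-window z-scoring across channels, and
  Hilbert band power in θ (3–7), α (8–12), β (13–30) and γ (35–80 Hz).
- **Decoding** (`pingdecode.decoding`): per-window shrinkage LDA under
  repeated stratified k-fold CV (5 folds × 25 repetitions), rank-based AUC
  for binary problems, shuffled-label first-level permutations,
  encoding→retrieval cross-decoding, and category-level selection.
- **Statistics** (`pingdecode.stats`): the two-level Monte-Carlo
  permutation test (second-level draws average one first-level shuffle per
  participant), Wilcoxon signed-rank contrasts, Benjamini–Yekutieli FDR
  across windows, and the supplementary trial-count and intertrial-variance
  simulations.
- **Peak-order distance** (`pingdecode.pod`): for each participant, one
  decoding peak per SOA condition; with ranks compared against the true
  presentation order,

  ```
  POD_raw  = Σᵢ |rank(peakᵢ) − i|,          i = 1, 2, 3
  POD      = POD_raw / 4                     (max over all 6 orderings)
  ```

  so POD = 0 means peaks follow ping order exactly. The group mean POD is
  tested left-sided against 10⁶ second-level draws from the shuffled
  decoder pool. A detector benchmark compares the cumulative-sum-derivative
  peak detector against raw/smoothed argmax and centroid alternatives.
- **ERP** (`pingdecode.erp`): posterior evoked traces and the per-channel
  ping vs pseudo-ping amplitude contrast (200–400 ms, Monte-Carlo
  sign-flip, Bonferroni).
- **IO / CLI** (`pingdecode.io`, `pingdecode.cli`): HDF5 persistence for
  epochs/features/decoding, JSON/YAML configs, and a `pingdecode` command
  with `simulate / features / decode / stats / pod / erp / run`
  subcommands.

## Worked example

```python
import numpy as np
from pingdecode import (generate_design, SimulationConfig, simulate_epochs,
                        baseline_correct, gaussian_moving_average,
                        zscore_across_channels, DecoderConfig,
                        decode_timecourse)

design = generate_design(seed=0)            # 8 blocks x 10 pairs x 4 reps
sim = SimulationConfig(n_channels=32, seed=0, effect_amplitude_uv=12.0,
                       onset_jitter_sd_ms=60.0)
epochs = simulate_epochs(design, sim, lock="cue")
print(f"simulated {epochs.n_trials} recall trials, {epochs.n_channels} "
      f"channels, {epochs.n_times} samples at {epochs.sfreq:g} Hz")

ping = epochs.select_trials((epochs.metadata["condition"] != "none").to_numpy())
feats = zscore_across_channels(gaussian_moving_average(baseline_correct(ping)))
print(f"features: {feats.n_windows} windows at "
      f"{1000 / np.diff(feats.window_times)[0]:g} Hz")

cfg = DecoderConfig(n_repetitions=5, seed=0)
tc = decode_timecourse(feats, ping.metadata["label_top"].to_numpy(), cfg)
print(f"peak AUC {tc.empirical.max():.3f} at "
      f"{tc.window_times[tc.empirical.argmax()]:g} ms after the retrieval cue")
```

Output:

```
simulated 320 recall trials, 32 channels, 1000 samples at 250 Hz
features: 194 windows at 50 Hz
peak AUC 0.982 at 1088 ms after the retrieval cue
```

The 320 recall trials (160 objects / 160 scenes, 75% pinged) and the
4-second epochs at 250 Hz reproduce the experiment's design arithmetic; the
object-vs-scene AUC peaks near 1100 ms because the simulated reinstatement
onset (900 ± 60 ms) plus the half-sine response envelope place the most
class information there. With `effect_amplitude_uv=0` the same pipeline
stays at AUC ≈ 0.5 across all windows.

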