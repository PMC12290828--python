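# Methods

This note documents the models, parameter choices and numerical decisions
behind `pingdecode`, and what the synthetic-data tests do and do not show
about real EEG.

## Experimental design model

One participant's session is eight blocks. Each block encodes
`n_pairs_per_block = 10` verb–image pairs (one encoding row each) and tests
every pair `n_reps = 4` times during recall, for 320 recall trials and 80
encoded pairs in total. Pair images are drawn without replacement from a
nested stimulus hierarchy of 2 top-level × 2 middle-level × 4 bottom-level
categories × 12 instances = 192 leaves, with an exact 50/50 object–scene
split per block and fully random middle/bottom levels.

Each pair's four repetitions are assigned one-each to the four ping
conditions {early, middle, late, none}. The experiment's stated constraints
are only the aggregate 75/25 ping/no-ping split and top-level balance
within each condition; the per-pair allocation is the simplest rule that
forces both simultaneously, and we adopt it as the design's canonical
randomization (the alternative — balancing only within block — satisfies
the same aggregates and is not distinguishable from any downstream
statistic computed here). Ping onsets are uniform within their SOA bin
(500–833.33, 833.34–1116.67, 1116.68–1500 ms after cue onset). Within a
block, recall order is a uniformly random permutation rejected until no
pair occurs twice in a row, with a constructive most-frequent-first
fallback for adversarial inputs; infeasible inputs (odd pair counts, a
single pair with repeats) raise errors naming the violated constraint.

Pseudo-pings give every no-ping trial a time-lock matched to the real ping
distribution: sampled per trial, with replacement, from the participant's
own pool of realized ping times. Replacement is a deliberate choice — the
pool (typically 240 values) is much larger than the 80 no-ping trials, so
the with/without-replacement distinction is immaterial, and with
replacement keeps every draw identically distributed.

## Signal model

Epochs span −1000 to +3000 ms around the lock event at 250 Hz (1000
samples), in microvolt. Each trial is a sum of:

- **1/f noise**, independent per trial and channel: white Gaussian noise
  shaped in the frequency domain by f^(−exponent/2) (exponent default 1)
  and rescaled to `noise_sd_uv = 5` µV. The per-trace rescaling makes the
  noise floor exactly reproducible but means the amplitude spectrum is
  1/f only in expectation.
- **Oscillatory background**: a 10 Hz alpha sinusoid of 2 µV with a random
  phase per trial, shared across channels. Because it is spatially
  uniform, the cross-channel z-scoring step removes it from the classifier
  features — it exists to stress the feature path, not the decoder.
- **Category signal**: one fixed unit-norm random channel-weight vector
  per top-level class (redrawn if |cos| ≥ 0.9 with an existing class),
  scaled by `effect_amplitude_uv` (default 1 µV) and a half-sine envelope
  of `response_duration_ms = 400`. The onset is Normal(900 ms, 150 ms)
  after cue during recall — inside the 500–2000 ms range where memory
  reinstatement is maximal — and Normal(150 ms, 30 ms) after image onset
  during encoding, where perception is stimulus-locked.
- **Ping-evoked response** on pinged trials: a biphasic kernel (a 60 ms-σ
  positive Gaussian peaking 250 ms after ping onset, preceded by a half-
  amplitude 40 ms-σ negative lobe), weighted 1.0 on the posterior channel
  set and `ping_nonposterior_weight = 0.15` elsewhere, amplitude 5 µV.
- **Latency regularization** ρ ∈ [0, 1]: on pinged trials the onset jitter
  SD is multiplied by (1 − ρ). ρ = 0 — no regularization, the study's
  empirical conclusion — is the default; ρ = 1 aligns every pinged onset
  exactly and is the positive-control condition used in the effect-
  recovery tests.

All randomness derives from one seed through four fixed-index
`SeedSequence` substreams (patterns / noise / latencies / phases), so
changing, say, the latency structure never redraws the noise.

## Features

Baseline correction subtracts the per-trial, per-channel mean over the
half-open window [−200, 0) ms. Downsampling to 50 Hz uses a 140 ms window
stepping 20 ms; samples are combined with a Gaussian-weighted mean whose σ
is solved from the operational edge condition exp(−e²/2σ²) = 0.15 with e
the half-window extent in ms (at 250 Hz: 35 samples, e = 68 ms,
σ = 34.9 ms, realized FWHM ≈ 82 ms, logged at debug level). Only fully
covered windows are emitted — the window count is
floor((n_samples − window)/step) + 1 — and window-centre times are
reported. Per (trial, window), feature vectors are z-scored across
channels with the population denominator; a zero-variance vector maps to
zeros with a warning rather than NaN so degenerate inputs cannot poison a
permutation run.

Band power uses a zero-phase two-pass Butterworth band-pass of order 4 per
band (the filter family is configurable; nothing in the pipeline depends
on this choice beyond passband fidelity, which the sinusoid tests check),
the squared magnitude of the analytic signal, and then the identical
windowing and z-scoring path, giving n_channels × 4 features.

## Decoding

Per window, a linear discriminant with Ledoit–Wolf-shrunk within-class
covariance (shrinkage estimated on per-class standardized features and
rescaled, making the intensity scale-invariant) is trained and scored
under stratified k-fold CV, 5 folds × 25 repetitions, fold assignment
reseeded per repetition from the decoder seed. The solver is the closed
form — shrunk covariance solved against the class means — vectorized
across windows; it reproduces scikit-learn's
`LinearDiscriminantAnalysis(solver='lsqr', shrinkage='auto')` decision
values to ~1e-12 (tested), and exists because a permutation-heavy run
needs on the order of 10⁵–10⁶ fits. Binary performance is the rank-based
AUC (midranks for ties); multiclass uses accuracy with chance = 1/K
recorded, and accuracy-above-chance is the cross-level comparison scale.
Folds are combined by unweighted fold average by default; pooling
predictions across folds (equivalently, weighting folds by size) is
exposed as `fold_aggregation='pooled'` — the two differ only when fold
sizes are uneven.
First-level nulls decode 100 random label permutations × 3 CV repetitions.

Cross-phase decoding trains one LDA on all encoding windows with centres
in [100, 1000] ms — pooled as independent instances by default, preserving
temporal variance; per-trial averaging is available — and applies it to
every retrieval window without CV, the phases being disjoint.

Level selection decodes all three hierarchy levels on no-ping trials,
contrasts empirical against shuffle-mean per window with the Wilcoxon test
(FDR-corrected), and selects the level with the most significant windows;
ties — including the expected all-zero tie under null data — resolve to
the fewest classes, i.e. the most trials per class, the conservative
choice.

## Group statistics

The two-level Monte-Carlo permutation test builds, window by window, a
null of `n_second_level` (default 10⁵) group means, each averaging one
first-level value sampled with replacement per participant; the p-value is
(1 + #{null ≥ observed}) / (n + 1). The add-one convention guarantees
p > 0 and validity at any permutation count; sampling with replacement
across the per-participant pool is the natural reading of "grab one random
value", and the scheme's calibration at pools as small as 12 values per
participant is verified by simulation. Statistical windows are restricted
before FDR correction — 0–500 ms for ping-locked, 500–2000 ms for
cue-locked analyses — so the correction spans only tested windows.
Wilcoxon signed-rank contrasts are exact for n ≤ 25 without ties and use
the continuity-corrected normal approximation otherwise; all-zero
differences give p = 1 with a warning. FDR uses Benjamini–Yekutieli
(harmonic-sum correction c(m) = Σ 1/i), valid under the dependence between
neighbouring windows.

One calibration subtlety the null tests exposed: when decoding windows
overlap condition-locked evoked activity, true labels (balanced within
condition by design) and shuffled labels (balanced only in aggregate) are
not exchangeable, and the shuffle null becomes slightly optimistic. The
null-calibration suite therefore decodes pre-ping windows; analyses of
real ping-locked data inherit the same caveat.

The trial-count simulation decodes feature-level Gaussian data (16
channels, 6 windows, class separation 0.4 SD in the last 3 windows when an
effect is present) across a trial grid, reporting the median two-level p
at signal windows and the SD of the first-level shuffle distribution; it
reproduces the direction that more trials shrink the shuffle null and
reduce p-values only when an effect exists. The intertrial-variance
contrast averages across-trial variance per channel over a window and
compares conditions by paired Wilcoxon across participants.

## Peak-order distance

Per participant and SOA condition, one peak index is extracted from the
decoding time series. The default detector takes the argmax of the
central-difference derivative of the cumulative sum: under forward
differences that operator is the identity, so the central-difference
reading — a 2-point local smoother — is the only interpretation that
differs from the raw argmax, and it is what the detector benchmark shows
to be more robust at low SNR. Raw argmax, 3-point-smoothed argmax and a
centroid detector are provided as alternatives; ties resolve to the
earliest index, an all-equal series warns and returns index 0.

Peak latencies are ranked ascending with ties broken by the true condition
order; pod_raw = Σ|rank − true| with normalizer max_pod(3) = 4 (verified
by brute force over all 6 orderings; the general-n normalizer
2·⌊n²/4⌋ is exercised only at n = 3). The group statistic is the
across-participant mean of normalized POD, and the test is left-sided —
ordered peaks give small POD — against second-level draws (default 10⁶,
chunked; peak indices for every shuffled series are precomputed so a draw
costs only a gather and a rank). Under structureless nulls the mean
normalized POD is 2/3 (= (0+2+2+4+4+4)/6/4), with a ≈0.01 downward bias
when discrete latencies tie and resolve toward the true order.

The group POD is a lattice statistic (multiples of 1/(4·n_participants)),
so null draws tie with the observed value routinely — on the order of 10%
of draws at 20 participants. Counting every tie as extreme makes the null
p-value distribution visibly conservative; the test therefore uses the
add-one mid-p convention, p = (1 + #{null < obs} + ½#{null = obs})/(n+1),
computed on the integer lattice so ties are exact. The decodability tests
keep the plain non-strict convention, their statistics being effectively
continuous.

## ERP analysis

Traces are band-passed 0.2–40 Hz (zero-phase, order 4), baseline-corrected
and averaged across trials and then across the 23-channel posterior set.
The ping vs pseudo-ping contrast averages each channel 200–400 ms
post-lock per participant and condition, takes the participant-level paired
difference, and builds the null by random sign-flips of those differences
(10⁵ by default) — the participant is the exchangeability unit, the
defensible choice for a group-level claim when the trial-level unit is not
specified — with two-sided add-one p-values Bonferroni-corrected across
channels.

## Problem sizes in the validation suite

The long-running tests run at sizes chosen to make each statistical claim
decidable with comfortable margins: null calibration at 20 participants ×
80 trials × 16 channels × 200 replicate datasets, 12 label shuffles and
2000 second-level draws; POD power at 20 participants × 25 replicates ×
2000 draws; the trial-count grid at 40/120/240 trials × 10 participants ×
3 replicates. Defaults in the package itself (10⁵ second-level draws, 10⁶
for POD, 100 × 3 first-level shuffles) are the full-scale settings.

## What the synthetic tests do and do not show

The generator emulates the design's combinatorics exactly, so counting and
balance claims transfer to the real experiment as stated. The signal model
is deliberately minimal: stationary Gaussian 1/f noise, one spatially
uniform oscillation, a single fixed pattern per class with a smooth
envelope. Real EEG adds non-stationary artefacts, volume-conducted
correlated noise, per-participant pattern idiosyncrasy, and
representational dynamics richer than a fixed pattern with jittered onset.
Passing tests therefore certify the *machinery* — calibration of the
permutation schemes, correctness of the formulas and transforms, power
under the hypothesized mechanism — not the effect sizes or p-values to be
expected on recordings. Preprocessing of raw recordings (filtering,
artefact rejection, ICA, re-referencing) is out of scope: the simulator
emits clean epoched data directly.

## Known limitations

- The POD machinery is tested for exactly 3 conditions; other condition
  counts are supported generically but unvalidated.
- The Hilbert band-power path applies no edge-padding beyond the epoch
  itself; band power within half a filter ringing-length of the epoch
  edges is attenuated (the tests probe mid-epoch windows).
- `simulate_epochs` draws class patterns per call, so cross-phase
  (encoding→retrieval) decoding of simulated data must reuse one config
  seed for both locks to share patterns.
- The no-immediate-repeat randomization is rejection sampling; for
  pathological inputs (one pair holding close to half the trials) it falls
  back to a greedy construction whose order statistics are not uniform.
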