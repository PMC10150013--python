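# Methods

This note documents the models, parameter choices and numerical decisions
behind `corticograph`, and what the synthetic benchmark does and does not
establish.

## Pipeline overview

A trial is a synchronized pair of multichannel recordings: EEG
(32 channels, 500 Hz, 10-10 montage) and EMG (8 channels, 1000 Hz; FDS,
FCU, FCR, ECU, ECRL, BBS, TBL, LD), 3 s long, labeled push or pull.
Processing steps, in order:

1. **EMG resampling** to 500 Hz by polyphase decimation
   (`scipy.signal.resample_poly`, `padtype="line"` to avoid edge ringing),
   aligning the two modalities on one time base.
2. **Zero-phase FIR band-pass**: EEG 2–40 Hz, EMG 2–100 Hz. Filters are
   `firwin` designs applied forward–backward (`filtfilt`); the length is
   capped at 401 taps (and at a third of the signal length so the edge
   padding fits), which at 500 Hz gives a ≈4 Hz transition band and
   comfortably more than 20 dB stop-band attenuation after the
   forward–backward double pass.
3. **Segmentation** into six contiguous 0.5 s windows per trial, stacked
   as 40×250 matrices (EEG rows 0–31, EMG rows 32–39). The window
   partition is exact: concatenating the six windows reproduces the
   epoch. Segment length is configurable; 0.5 s is the default because
   the sub-action label space is built on six positions per trial.
4. **Train/test split** at the whole-trial level (default 4:1),
   stratified by movement, so no trial's segments leak across the
   boundary.

ICA-based artifact removal is exposed only as an optional pass-through
hook (disabled by default): a callable `TrialRecording -> TrialRecording`
that an external implementation can fill. The package does not
re-implement ICA.

## SPMI connectivity

Each channel is symbolized into ordinal patterns: the embedded vector
`[x(i), x(i+τ), …, x(i+(n−1)τ)]` is ranked by value, ties broken by order
of occurrence (stable sort), and the permutation encoded by its Lehmer
code. Defaults n = 5, τ = 1 on the 250-sample window, giving 246 patterns
out of 120 possibilities per channel. Permutation entropy (PE) uses
natural logs; SPMI = (PE_X + PE_Y − PE_XY)/PE_XY is base-invariant, so
this choice is observationally irrelevant.

Numerical details worth knowing:

- Entropies are summed over **sorted** count vectors, so the float result
  depends only on the multiset of counts. This makes SPMI symmetry and
  SPMI(X, X) = 1 exact at the bit level, not merely within rounding.
- A fully ordered pair (both series monotone) has zero joint entropy and
  SPMI is 0/0. The default raises `DegenerateSignalError`; the pipeline
  sets `degenerate_as_zero=True` and maps it to 0, since a flat filtered
  channel carries no coupling evidence.
- Edge selection keeps the k = ⌊q·P⌋ strongest of the P = N(N−1)/2 pairs
  (q = 0.25, N = 40 → exactly 195 edges), with lexicographic tie-breaks
  on channel indices. This top-fraction rule is used rather than a
  percentile cut because it fixes the edge count of every graph, which is
  what the 195-edge design point implies.
- Note the short-series bias: with 246 samples the joint distribution
  over 120² pattern pairs is severely undersampled, so independent white
  noise shows SPMI ≈ 0.6–0.7 rather than ≈ 0. The bound SPMI ≤ 1 is
  unaffected (it holds for any empirical distribution), and thresholding
  by rank is unaffected because the bias is common to all pairs of equal
  length. Tests of near-zero independence use long series.

## Node features

Per channel, a multitaper PSD: DPSS tapers with time–bandwidth NW = 2
(3 tapers), one-sided density scaling. At 0.5 s this is a ±4 Hz
half-bandwidth — coarse for the 2–4 Hz delta band; this resolution limit
is accepted in exchange for variance reduction on short windows. Band
powers integrate the PSD over half-open intervals [low, high) with
rectangle rule, keeping adjacent bands exactly disjoint on the discrete
grid. Fractions are referenced to the modality's filter band (EEG
2–40 Hz, EMG 2–100 Hz), so EMG fractions of the five sub-40 Hz bands need
not sum near 1. The feature vector is
`[δ, θ, α, β, low-γ fractions, total power, electrode index]`; the
electrode index is a raw scalar location code (0–31 EEG in montage order,
32–39 EMG), left unscaled because the classifier z-scores every feature
against training-set statistics before use.

## GIN classifier

Implemented directly in NumPy with manual backpropagation (verified
against central finite differences in the test suite) and Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8). Architecture:

- K = 3 GIN iterations (configurable). The update is
  `x' = MLP((1+ε)x + Σ_neighbors x)` with one learnable ε per layer,
  initialized at 0. Undirected edges aggregate in both directions via a
  block-diagonal sparse adjacency over the mini-batch.
- MLP per layer: Linear → BatchNorm → ReLU → Linear, 64 hidden channels.
  BatchNorm uses batch statistics during training and running averages
  (momentum 0.1) in evaluation, which is why evaluation-mode predictions
  are bit-deterministic.
- Readout: sum-pool node embeddings per depth k = 0…K (pool first, then a
  per-depth linear map — with sum pooling the other order is an
  equivalent parametrization), concatenate, then a linear classifier to
  12 logits. Sum pooling keeps the embedding permutation-invariant
  exactly.
- Loss: 12-way sub-action cross-entropy plus (weight 1.0) the 2-way
  movement cross-entropy, with movement probabilities obtained by summing
  the 12-way softmax within each movement's 6-class block. Marginalizing
  one softmax, rather than adding a second head, keeps the two objectives
  consistent by construction.
- Features are standardized (z-score per feature over the training set);
  without this the raw electrode index (0–39) dominates the band
  fractions (0–1) in scale.
- Optimization defaults: Adam lr 0.005, 300 epochs, batch 128, seeded
  shuffling; training is reproducible on one device given the seed.

## Time-based ensemble

The per-trial sequence of predicted sub-action labels is scored against a
reference sequence by mean per-segment similarity
(`1 − |Δposition|/n_seg` within the same movement, 0 across movements,
n_seg = 6 — the segment count, not the ordinal embedding dimension). The
trial is classified as the movement whose canonical in-order sequence
scores highest; ties break by the fixed movement order (push first) and
are logged. Scores are reported as round(100·value). Per-segment
categories: *wrong* (movement differs), *close* (|Δposition| ≤ 3 segments),
*far* (> 3). Group comparison uses a Student pooled-variance two-sample
t-test by default (Welch via flag).

## Synthetic generator

The generator produces the statistical structure the pipeline consumes,
and nothing more:

- Each channel is a sum of five band-limited Gaussian carriers (one per
  band, synthesized in the frequency domain, unit variance, scaled by a
  per-(class, segment, band) weight) plus white noise, scaled to a 5 µV
  unit. Carriers are independent across channels and segments.
- Default ("healthy") weights: all bands at 1.0 except θ = 2.0 for push
  vs 0.6 for pull (movement marker), and opposed α/β amplitude ramps
  across segments — push α = 0.4 + 0.8·s and β = 4.4 − 0.8·s, pull the
  mirror — a cartoon of event-related (de)synchronization. The ramp step
  (0.8 in amplitude, i.e. roughly 2–4× in adjacent-segment band power)
  makes each of the 12 (movement, segment) signatures distinct and
  recoverable from a single 0.5 s window at noise_sd = 1; this is the
  intended "easy" regime for validating the machinery.
- Coupling: one shared β-band latent series per trial is injected with
  gain `coupling` (default 1.5) into C3/Cz/C4/CP1 and into FDS/FCU/ECU/
  ECRL. On band-passed signals the SPMI of coupled pairs rises
  monotonically with the gain; on raw unfiltered signals broadband noise
  dominates sample-scale ordinal patterns and masks the effect, which is
  why coupling should always be assessed after filtering.
- The "patient" profile keeps the same planted signatures but raises the
  white-noise floor (noise_sd 10 vs 1 — in-band noise power then rivals
  the planted carriers) and attenuates coupling (×0.25), emulating the
  noisier EEG and weaker corticomuscular drive of stroke recordings. Under
  a model trained on healthy subjects this yields markedly lower movement
  scores and more far/wrong segments, reproducing the direction of the
  clinical group difference.

What the generator does **not** model: volume conduction and realistic
scalp topographies, 1/f background spectra, eye-blink/line-noise
artifacts, EMG rectification nonlinearity, or inter-subject variability
beyond independent noise draws. Passing tests therefore demonstrate that
the pipeline recovers the kinds of structure it is designed for — band
power signatures and cross-channel coupling — not that it attains any
particular accuracy on real recordings.

## Problem sizes used in tests

The end-to-end checks train on 60-trial datasets (15 per class × 2
subjects; 288 training graphs after the 4:1 split) for 100 epochs and 3
seeds, and the group-direction check uses 4 subjects (2 train-healthy, 1
eval-healthy, 1 eval-patient; 30 evaluation trials per group). These sizes
were chosen so that Monte-Carlo noise on the reported accuracies is small
relative to the acceptance margins while a full suite run remains a
desk-scale job.

## Known limitations

- The 12-class position decoding relies on spectral ramps; with flat
  profiles position information disappears by construction.
- Sub-action SPMI graphs inherit the short-window entropy bias described
  above; absolute SPMI values should not be compared across window
  lengths.
- The EDF importer requires a uniform sampling rate across channels and
  treats the first 32 channels as EEG.
- BatchNorm running statistics make evaluation depend (slightly) on the
  training batch composition; this is the standard train/eval semantics.
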