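# Methods

## Detection model

A query EEG segment x is represented by its band-limited power
spectrum, compared against M normal-template spectra {Q_j} under a
similarity metric s, aggregated to a single score
S(x) = max_j s(P̂, Q̂_j) (nearest-template matching; a worst-case
`min` aggregation is available as a configuration switch), min–max
normalized over the evaluation batch, and thresholded:

    H0 (normal):   S(x) > λ
    HA (abnormal): S(x) ≤ λ

The boundary S = λ is assigned to the abnormal class, so λ = 0 never
rejects a segment with positive normalized similarity and λ = 1 rejects
everything.  The model assumes (i) normal background EEG is
approximately stationary over the template collection period, so a
fixed template set remains representative; (ii) anomalies express
themselves in the distribution of power over frequency, not only in
total amplitude — metrics are applied to unit-sum spectra, so pure gain
changes are invisible by design.

## Feature extraction

* **Band restriction [0.1, 70] Hz.**  Covers the δ–γ rhythms.
  Implemented as the squared magnitude response of a 6th-order
  Butterworth high-pass (0.1 Hz) and low-pass (70 Hz) applied in the
  frequency domain.  The squared magnitude is exactly the gain of a
  forward–backward (zero-phase) pass.  The spectral-domain form was
  chosen because a recursive high-pass at 0.1 Hz (normalized cutoff
  4·10⁻⁴) has an impulse response longer than a 20 s segment; its
  filtfilt edge transients dominated the output no matter how the
  signal was padded, while the spectral form is exactly zero-phase,
  length-preserving and transient-free at any cutoff.  A 100 Hz tone
  retains about 0.02 % of its power; a 10 Hz tone passes within 0.1 %.

* **Welch PSD.**  Hamming taper, subsegment length M = 1024 samples,
  50 % overlap, no detrending, one-sided, density scaling.  At
  fs = 512 Hz this gives Δf = 0.5 Hz — fine enough to resolve all five
  rhythm bands — and ≥ 18 averaged subsegments per 10,000-sample
  segment, keeping per-bin variance moderate.  The estimate equals the
  mean of the individually windowed subsegment periodograms (asserted
  against a brute-force oracle in the tests to 1e-9).

* **Unit-sum normalization.**  Spectra are cropped to the analysis band
  and divided by their sum, with bins floored at ε = 1e-12 first.  The
  floor keeps divergence-based metrics (SKLD) finite without measurably
  perturbing the distribution (the smallest genuine bin mass is ~1e-6).
  The operation is idempotent.  ED and PCCD also consume unit-sum
  spectra by default so every metric sees the same input.

* **Scalar features.**  Segment mean and RMS are exposed through the
  same registry (`"mean"`, `"rms"`) as single-bin features for
  vector-space metrics; the registry is the extension point for other
  extractors.

## Similarity metrics and conversions

All six distances are implemented directly (a few numpy lines each) and
verified against pure-Python loop oracles; SKLD and BD are non-metric
distances (no triangle inequality), which the tests document by
asserting the inequality only for ED, HD, KD.  Numerical choices:

* HD is computed as ‖√p − √q‖₂/√2 rather than √(1 − BC): the two are
  algebraically identical for probability vectors, but the latter
  amplifies the O(ε) rounding of BC at p ≈ q into O(√ε) distances.
* BD returns +∞ for disjoint supports (BC = 0); the batch normalizer
  maps non-finite scores to the batch maximum similarity — BD's
  similarity conversion is BC itself, so in practice the sentinel only
  arises for the distance, not the score.
* Reciprocal similarity conversions (ED, SKLD, HD, KD) guard d = 0
  with a 1e-12 floor; after batch normalization an identical-template
  query maps to similarity 1 regardless.
* BD's similarity is the Bhattacharyya coefficient (equivalently
  exp(−d_BD)): bounded in [0, 1], maximal at identity, and
  rank-equivalent to any decreasing transform of d_BD, so decisions are
  unaffected by the choice.  PCCD's correlation is used as-is in
  [−1, 1]; batch normalization maps it into [0, 1].
* An all-equal score batch normalizes to 0.5 everywhere, keeping the
  threshold rule total.

## Threshold fitting

λ is swept over {0, 0.01, …, 1}.  Among grid points that maximize
calibration accuracy, the midpoint of the longest contiguous maximal
run is returned (first run on ties).  With separated classes the
maximal plateau spans the gap between the highest abnormal and lowest
normal score; the midpoint is the maximal-margin choice and transfers
to held-out data noticeably better than either plateau edge, which sits
directly on a calibration score.  Single-class calibration batches are
rejected.

At deployment a single query has no batch to normalize against, so the
detector stores the calibration batch's raw-score min/max and clamps
the query's normalized score into [0, 1] before thresholding.

## Evaluation protocol

* **AOPO.**  Sort the n normal test scores ascending (a_i) and the n
  abnormal scores descending (b_i); AOPO = i* − 0.5 for the first index
  with a_i ≥ b_i, or n + 0.5 if the curves never cross.  The midpoint
  convention makes every attainable value a half-integer in
  {0.5, …, n + 0.5}.  AOPO depends only on score ranks, hence is
  invariant under any common strictly increasing transform.

* **Cross-validation.**  A fixed template set of 30 normal segments;
  the test pool of 30 normal + 30 abnormal segments is reshuffled each
  repetition into two groups of 15 + 15; per metric, λ is fitted on
  group 1 and accuracy measured on group 2, then the roles swap and the
  two accuracies are averaged; AOPO is computed on each group and
  averaged; 20 repetitions (repetition r reshuffles with seed
  `base_seed + r`), and per-metric means are reported.  Features, raw
  similarities and the joint batch normalization are computed once per
  dataset — they do not depend on the split — so repetitions are cheap.

* **Template selection.**  Real template sets are curated by experts
  ("most stable" normal segments).  As a reproducible proxy, normal
  segments are ranked by the Euclidean distance of their unit-sum
  spectrum to the normal-pool centroid spectrum and the closest are
  taken, with ids breaking ties; the next-closest segments form the
  normal test pool.  Repetitions reshuffle group membership only; the
  template set stays fixed per dataset.

* **Ranking.**  Metrics are ordered by mean accuracy (descending), ties
  within 1e-9 broken by lower mean AOPO, residual ties reported as
  equal.

## Synthetic EEG generator

Each normal segment is Σ_b A_b · n_b(t) + σ · w(t), where n_b is
unit-RMS Gaussian noise band-limited to rhythm band b by a 4th-order
Butterworth (forward–backward, synthesized with guard padding so the
recursive filter's start-up transient — seconds long at the 0.5 Hz
delta edge — never reaches the returned window) and w is white.
Band-limited noise rather than sinusoids gives continuous spectra
spread over many bins, which is what distribution metrics operate on.

Defaults: fs = 512 Hz, 10,000 samples (~19.5 s), RMS amplitudes
δ 10, θ 9, α 11, β 8, γ 5 (alpha-dominant resting-style rhythm mix, in
arbitrary microvolt-like units) and σ = 15 — a deliberately prominent
broadband noise floor, emulating the heavily noise-polluted clinical
recordings this design targets.

Abnormal segments multiply each band amplitude by an independent
uniform draw from (0.2, 2.5) and the noise sigma by 2.5.  Both
mechanisms can be disabled independently (jitter (1, 1), factor 1) for
ablations.  Because unit-sum spectra are scale-invariant, a jitter that
happens to scale all bands equally is invisible; the raised noise-floor
mass fraction is the cue that remains for every abnormal segment, which
is why the default σ is large relative to the band amplitudes.  The
amplitude/noise defaults were calibrated once so that the
Bhattacharyya-family metrics (HD, BD) reach mean cross-validated
accuracy ≥ 0.9 and separate no later than Euclidean matching under the
default protocol — the qualitative behaviour the detector is designed
around — and were verified stable across several seeds.

Every segment draws from an independent random stream keyed by
(seed, class, index), so datasets are bit-reproducible and individual
segments do not change when counts do.

**What the generator does not emulate:** physiological nonstationarity
(sleep-stage drift, eye blinks, EMG artifacts), multichannel
correlation, 1/f background shape, or any specific pathology's
signature.  Passing tests therefore demonstrate that the pipeline
recovers the separability structure the generator encodes — spectral
shape disorder and noise-ratio change — not clinical performance on
real recordings.

## Problem sizes in the tests

Unit tests run the protocol at reduced scale (4096-sample segments,
512-sample Welch windows, 8 templates, groups of 8, 2–3 repetitions);
the end-to-end acceptance checks and `scripts/acceptance.py` use the
full default conditions (10,000-sample segments, 30 templates, two
15 + 15 groups, 20 repetitions), which complete in a few seconds.

## Known limitations

* Eq-style batch normalization means a query's normalized score depends
  on the batch it was evaluated with; the stored-bounds deployment path
  is an approximation whose bounds go stale if the signal's overall
  scale drifts.
* The threshold grid (0.01) bounds how finely λ can sit inside a
  narrow class gap.
* PCCD requires non-constant feature vectors and is undefined on
  single-bin (scalar) features; SKLD requires strictly positive
  probability vectors (guaranteed by the ε floor in the default
  pipeline, not for user-supplied features).
* AOPO as defined requires equally sized normal/abnormal test groups.
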