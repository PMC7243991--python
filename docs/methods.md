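# Methods

This note documents the statistical model, the numerical choices behind
each stage, the synthetic data the tests rely on, and what those tests
do and do not show about real recordings.

## Binarization

Calcium transients are long relative to the spikes that cause them; most
spikes fall in the rising phase.  The primary method therefore marks
*rise periods*: the trace is low-pass filtered with a zero-phase
(forward–backward) order-4 Butterworth filter, z-scored over the whole
recording, and frame t is active iff z(t) > 2 and z(t) − z(t−1) > 0.

Choices and their reasons:

- **Cutoff 2 Hz** (configurable): removes frame-to-frame sensor noise
  that would otherwise create spurious positive derivatives, while a
  GCaMP6f rise (~0.1 s time constant) passes mostly intact.  Zero-phase
  filtering avoids delaying the rise.
- **Whole-recording z-score** (no sliding baseline): the simplest
  normalization; slow drift (e.g. photobleaching) is assumed removed
  upstream by the trace extraction.
- **Derivative = first difference** of the filtered trace, aligned so
  frame t uses x(t) − x(t−1); frame 0 is inactive.
- **Zero-variance traces** (dead ROIs) warn and come back all-inactive
  instead of raising, so batch runs survive them.

Two comparison methods share the interface: a plain z > 2 threshold on
the unfiltered z-scored trace, and thresholding at zero of an externally
deconvolved matrix.  Deconvolution itself is out of scope; only its
output is consumed.

A consequence worth knowing: detection concentrates in the later part of
the rise (the z > 2 crossing happens a few frames after the first
spike), so binarized activity trails the causal spikes by roughly
0.2 s at 30 Hz with the default kinetics.  Tuning curves estimated from
the same raster absorb this lag symmetrically on a bidirectional track,
but it matters for temporal filtering (below).

## Behavioral states

Positions are binned at 3 cm (configurable) into half-open intervals
[k·w, (k+1)·w); the far wall clamps into the last bin.  By default a
track length not divisible by the bin width leaves a narrower last bin
(100 cm → 34 bins, the last 1 cm); an `equal` mode divides the track
into M equal bins instead.  2D arenas use a row-major grid with x
varying fastest.  Speed is the smoothed (0.5 s boxcar) frame-to-frame
displacement over time; frames below 5 cm/s are excluded everywhere,
because activity during immobility can reflect internal states (replay)
rather than position.  Direction augmentation doubles the 1D state
space into rightward/leftward copies using the sign of the smoothed
velocity; frames slower than 2 cm/s along the track are excluded rather
than assigned a guessed direction.

## Tuning estimates

All probabilities are frame counts over included frames.  States never
visited carry NaN in the likelihood — an explicit "no data" marker — and
are excluded from MI, smoothing, and decoding; storing 0 instead would
assert certain silence.  MI uses the 2×M joint table with the
0·log 0 := 0 convention; it equals H(S) + H(A) − H(S,A) exactly, which
the tests exploit as an independent oracle.

Tuning perturbations used in robustness sweeps: `inject_noise` replaces
round(fraction · M_defined) uniformly chosen *defined* likelihood
entries with Uniform(0,1) draws (prior and marginal untouched);
`smooth_tuning` convolves the curve (or the map, on its 2D grid) with a
±4σ-truncated Gaussian kernel renormalized over defined bins at
boundaries — tracks are not circular, so there is no wraparound.

## Significance and confidence

The null for tuning is built from circular permutations: the full-length
binary vector is rotated by a shift drawn uniformly from [1, T−1]
(identity excluded), then the inclusion mask is applied and the
statistic recomputed.  Rotating before masking preserves transient
structure, which is the point of this null: complete frame permutation
produces non-physiological surrogates and overstates significance.
Empirical p-values count surrogates strictly above the actual value
(so p can be exactly 0); an inclusive mode counts ties for situations
where surrogates frequently equal the actual value (empty bins).  No
multiple-testing correction is applied across bins by default; each
bin is thresholded at α = 0.05.

Bootstrap confidence intervals resample round(fraction · T_included)
included frames with replacement and report percentile bands.  The
default fraction of 0.5 follows common practice for these data but is
deliberately conservative: half-size resamples inflate the surrogate
spread by about √2, so the nominal "95%" band covers the true per-state
rate ~98–99% of the time.  At `sample_fraction=1.0` (the textbook
bootstrap) measured coverage is ~94%, which is what the coverage test
asserts.  Use 0.5 when a cautious band is wanted, 1.0 when calibrated
coverage is.

## Decoding

Scoring is log-domain.  The default `log_product` variant sums
log P(Aₖ|S) + log P(S) − log P(Aₖ) over the neurons *active* at the
frame; zero likelihood contributes −∞, i.e. training said this neuron
never fires there, so the state is impossible.  Its argmax equals the
linear product's argmax on every zero-free instance (tested against a
brute-force oracle).  The `log1p` variant sums
log(1 + P(Aₖ|S)·P(S)/P(Aₖ)); it never produces −∞ but is *not*
order-equivalent to the product — the log(1+x) transform does not
commute with multiplication — so the two variants are kept separate
rather than treated as interchangeable.  Inactive-neuron evidence
(1 − P(Aₖ|S) factors) is available but off by default.

Prior modes: `uniform` (flat over retained states), `observed`
(empirical occupancy), and `unbiased` (flat prior with P(Aₖ) replaced
by 1).  Under normalized log-product scoring the marginal is a
state-independent constant, so `unbiased` cannot change the MAP; under
`log1p` the constant enters nonlinearly and does.  Both facts are
asserted as tests.

Temporal filtering sums per-frame log scores over the past L =
round(window·rate) frames, inclusive of the current frame (partial
windows at the session start).  Frames with no active neuron in the
window are *undecodable*: their posterior falls back to the prior and
they are, by default, excluded from metrics (but counted).  An
`undecodable="count"` mode scores them from that fallback instead,
penalizing decoders that leave frames without evidence — this is the
right accounting when comparing cell counts, where sparse-evidence
frames are the dominant cost, and it is what the sweep tests use for
that axis.

Other conventions: MAP ties break to the lowest state index for
cross-platform determinism; states with zero training occupancy are
removed from the decode space and results are reported in the training
geometry; train/test splits cut the session into contiguous 5 s blocks
(long enough to keep transients intact within a block) and assign blocks
randomly until the training fraction of included frames is reached.

### Temporal filtering and lag

A past-only window of length L estimates, in effect, the position
averaged over the last L frames.  On the synthetic sessions — constant
20 cm/s running, 60 cells, already-accurate per-frame decoding — a 0.5 s
window introduces a trailing bias of about v·L/2 ≈ 5 cm, on top of the
~0.2 s detection lag of rise binarization.  The decoded trajectory at
the 0.5 s window matches the position half a second in the past to
within ~4 cm (median) while the error against the *current* position
rises to ~9 cm, and exact-bin agreement drops well below its unfiltered
value.  Temporal filtering does what it promises — it suppresses >20 cm
frame-to-frame jumps by roughly sixfold — but in a lag-dominated regime
it trades accuracy against the current position for smoothness.  On
noisier regimes (few active cells per frame relative to state count,
slow movement) the variance reduction wins instead.  Choose the window
per dataset; 0 and 0.5 s are both worth measuring.

## Encoding

The tuning curve doubles as a prediction: given the state at frame t,
each neuron's expected activity probability is its likelihood there.  On
the session used for fitting, the per-state mean of the predicted
probability equals the empirical activity rate exactly (a counting
identity), which the tests assert.  The 0.5 display threshold on
predicted probabilities is presentation only.  Refining states by
running direction raises the likelihood peak of direction-selective
cells (up to 2× when occupancy is direction-balanced) and raises their
MI under the preferred-direction states; bootstrap MI distributions
compare state definitions on equal footing.

## Synthetic sessions

The generator emulates the recording conditions the framework targets:
15 min sessions at 30 Hz; a 100 cm track traversed in ballistic runs at
20 cm/s (Gaussian speed jitter, SD 20% of the mean) with
exponential-duration pauses (mean 2 s, probability 0.5) at the reward
ends, producing reward-end immobility; or a 45 × 45 cm open field
explored by a persistent random walk (heading diffusion SD 0.35
rad/frame, reflecting walls).  Cells have Gaussian place fields
(σ = 5 cm) tiling the arena with ±3 cm center jitter; per-frame event
probability is baseline + (p_max − baseline)·exp(−d²/2σ²) with
baseline 0.01 and p_max 0.3, Bernoulli per frame.  Direction-selective
cells apply the field rate only in their preferred direction.  Calcium
traces convolve events with a·(e^{−t/τ_d} − e^{−t/τ_r}) (τ_r = 0.1 s,
τ_d = 1.0 s, conventional GCaMP6f values — the kinetics are not fitted
to any particular dataset) plus Gaussian noise with SD = amplitude/10.

What the generator does *not* model: bursting and within-field rate
modulation, indicator saturation and buffering, photobleaching drift,
crosstalk between ROIs, theta-timescale structure, and realistic
acceleration profiles (runs are constant-speed).  Tests passing on this
substrate show the estimators and decoder are correct and calibrated
under their own assumptions; they do not certify performance on any
particular real recording.

## Problem sizes and determinism

The test suite and the acceptance script run on one CPU in a few
minutes: the standard session is 27 000 frames × 60 cells; null
calibration uses 100 synthetic null cells × 1000 circular shuffles;
bootstrap coverage uses 500 replicates of a 10-state, 2000-frame
Bernoulli world at 200 resamples; decoding sweeps use 8–10 random epoch
splits per grid value.  Every stochastic stage accepts a seed or a
`numpy.random.Generator`; pipelines spawn per-stage seeds from one
master `SeedSequence`, so identical configurations give bit-identical
outputs.
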