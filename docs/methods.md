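# Methods

This note documents the models and procedures implemented in `msfingerprint`,
the parameters that matter, the synthetic data the tests rely on, and the
numerical and design choices made where more than one reading was defensible.

## 1. Gridding raw runs

A centroided MS1 acquisition is a list of scans (RT, {m/z, intensity}).
Axis unification proceeds in two independent steps.

**Mass binning.** Bin *n* of the integer mass axis collects every raw m/z
*x* with residual mass x − (mz_first + n) in **[−0.35, +0.65)**. The window
is half-open so the bins tile the axis exactly once: every in-range signal
lands in exactly one bin and total intensity is conserved (this is asserted
as a property test). Off-axis signals are dropped and counted in a debug log.
The defaults (`mz_first=100`, `n_bins=1200`) cover the instrument scan range
m/z 100–1200 plus the high-mass tail up to 1299 that the square crop later
discards.

**Time resampling.** Each mass bin's chromatogram is linearly interpolated
onto a uniform grid, by default 750 points at 0.03 min covering
**[1.5, 24.0)** (half-open: an inclusive grid would have 751 points). Grid
times outside the acquired RT range are filled with zero rather than
extrapolated — outside the run there is no signal. Scans before 1.5 min or
after 24 min still inform interpolation at the boundary grid points.

Both steps together are verified against a brute-force nested-loop oracle to
1e−9 relative tolerance on small random runs.

**Unfolding** is RT-major and documented: flat feature
f = rt_index · K + mz_index, inverted exactly by the `FeatureIndexMap`.
**Cropping** keeps integer m/z in [200, 950) — 750 bins, forced by the
750-wide square the image classifiers expect.

## 2. Augmentation

Five deterministic procedures, each a plausible experimental deviation. The
default plan produces 6 (stretch) + 1 (gradient stretch) + 1 (gradient
shrink) + 4 (mass shift) + 2 (intensity) = 14 variants per sample.

Choices the procedure descriptions left open:

- **Canonical length restoration.** Stretching a 750-point chromatogram to
  750 + k points must return to 750: the tail is truncated (k > 0) or
  zero-padded (k < 0). The end of a run is column re-equilibration and
  carries the least signal, so the tail is the safe place to cut.
- **Gradient schedule.** The per-segment inserted/removed point count ramps
  linearly from 1 to 7 over the 15 segments:
  p(s) = floor(1 + 6·(s−1)/14 + 0.5) (an explicit floor, not banker's
  rounding, for cross-platform determinism).
- **Mass-shift anchors.** Δ(x) interpolates linearly between delta_low at
  m/z 100 and delta_high at m/z 1200 — the instrument scan range — regardless
  of the current grid. Shifts move intensity between bins but never scale it;
  per-scan totals are conserved after re-gridding as long as peaks stay on
  the axis.
- Shrinkage reuses the stretching resampler with points removed; intensity
  alteration "±5% in 5% steps" is exactly the two factors 0.95 and 1.05.

Augmentation is deterministic; the plan's `seed` field exists only for
provenance of optional randomized extensions.

## 3. Grouped splitting and the linear SVM

Samples are split 70/30 **by specimen**: all replicates of one plant-part
extract, and every augmented descendant (which inherits its parent's
specimen id), land on the same side. Splits are deterministic in
(seed, repeat).

`SplitPlan(stratify=True)` draws the 70/30 partition within each class
instead of from the pooled specimen list. At realistic study sizes the two
are nearly identical; at desk scale (2–3 specimens per class) the pooled
split regularly strands a class entirely in train or test, which makes
macro-F1 degenerate for structural rather than methodological reasons. The
pooled split remains the default; the benchmark checks use the stratified
variant.

The classifier is a one-vs-rest linear SVM (squared hinge, C = 1.0, balanced
class weights, raw intensities — no scaling or centering). The primal
liblinear solver is the default: it optimizes the same objective as the dual
one but conditions far better on raw ion-count scales (~1e5) and needs an
order of magnitude less memory on wide unfolded matrices. With a class
missing from a training repeat, evaluation still scores the full class
vocabulary (the missing class simply gets recall 0 on the test side);
zero-support test classes are reported as NaN with a warning and excluded
from the macro average.

## 4. Marker mining

Per class: rank features by **signed** weight descending (markers are
class-positive evidence; ties break by ascending flat index; absolute-value
ranking is a config option), keep the top 2000, then apply the absence rule:

> a signal is *absent* from a sample if its intensity does not exceed
> `absence_factor` (default 5) times the mean intensity of that sample's
> mass spectrum at the same time point, zeros included.

A candidate survives if it is absent from **every** out-of-class sample
(a fractional threshold is configurable, since real data tolerates trace
appearances), and — by default — if it is *present* (above the same
threshold) in at least half of the in-class samples. The presence condition
is this package's addition: top-ranked weights of a well-fitted model imply
in-class signal, but on degenerate inputs (identical samples in all classes)
near-zero-weight noise cells would otherwise pass the out-of-class test
vacuously and be reported as markers.

Consolidation is single-linkage: two candidates link if they share the RT
index within |Δm/z| ≤ 2 (isotope partners) or share the m/z bin within
|Δrt| ≤ 1 point. Each group is represented by its maximum-weight member.
Consolidation never merges across classes and never increases the count.
Raising `absence_factor` can only grow the unique set (monotonicity, tested).

## 5. Neural networks

Both classifiers consume square heatmaps rescaled per sample to [0, 1],
replicated to three channels, and standardized with the ImageNet channel
means and standard deviations. Downscaling to the network input size uses
**block averaging**, not point sampling — a chromatographic peak a few cells
wide would simply vanish between sample points of an interpolating resize.

The networks are implemented in numpy with manual backpropagation (3×3/1×1
convolutions, batch normalization, ReLU, average pooling, residual blocks,
Adam); gradients are verified against finite differences. The default
"reduced" architecture — stem convolution, two residual blocks, global
average pooling — operates on 50 × 50 block-averaged heatmaps and trains in
seconds on one CPU; a "full" 18-convolution residual layout is available in
the config. No pretrained weights are bundled; networks train from scratch,
which is why the `pretrained` flag is rejected rather than silently ignored.

Details that matter at small sample sizes:

- **Weighted sampling**: training examples are drawn with probability
  inversely proportional to their class frequency (with replacement), so
  expected batch composition is uniform over classes.
- **BatchNorm re-estimation**: after training, running statistics are
  recomputed in one full pass over the training set. Momentum-averaged
  statistics from small class-balanced batches are a noisy estimate of the
  training-set statistics, and with tens of samples that noise measurably
  shifts eval-mode activations.
- **SNN**: the embedder ends in a 32-dimensional linear layer and trains
  with a batch-hard triplet loss (hardest positive and hardest negative per
  anchor, Euclidean distances). Prediction is a k-nearest-neighbor vote
  (k = 3, ties resolved by the nearest tied neighbor); nearest-centroid is
  available. The margin (default 0.5) can be tuned by a sequential
  model-based search — Gaussian-process expected improvement over a
  log-uniform range, scored by macro F1 on a grouped validation split carved
  from the training set.

## 6. Synthetic data

The generator emulates the statistical structure the pipeline assumes:

- scans every 0.02 min over RT 0–26 min, m/z 100–1200;
- compounds as Gaussian elution profiles (σ 0.04–0.08 min) with a fixed
  isotope envelope (+1.0034 Da spacing, abundances 1 / 0.45 / 0.12);
- ≥ 10 background compounds shared by all classes (amplitudes log-uniform
  3e4–3e5 counts), and two unique marker compounds per class;
- specimen-level biology: per-compound log-normal amplitude factors
  (CV 0.25) shared by a specimen's replicates;
- replicate-level technique: RT jitter (SD 0.01 min, below the 0.03-min grid
  step — the pipeline performs no alignment, so the emulated chromatography
  must be stable at the grid scale) and log-normal amplitude jitter (CV 0.1);
- a noise floor of one ion near every integer m/z per scan,
  |N(30, 8)| counts. The floor is deliberately homogeneous in m/z: the
  absence rule compares single cells against the spectrum mean, so sparse
  random-position noise spikes (whose per-cell distribution is heavy-tailed)
  would make "absent in every out-of-class sample" a coin flip rather than a
  property of the planted chemistry. The peak-list representation is kept;
  only the noise positions are regular.

Default marker amplitude is 6e4 counts with an out-of-class leak factor of
5e-4, which puts in-class apexes at S/N ≈ 400 (well above 10) and
out-of-class traces at S/N ≈ 2 (below 3) under the 5×-mean proxy — both
asserted on generated data. Compound coordinates are drawn with rejection so
that every pair is separated by more than the consolidation windows.

`make_separable_benchmark()` is the configuration used wherever a check is
*defined* on separable data (classifier sanity, augmentation neutrality):
marker amplitude 1.5e5 (comparable to the strongest background compounds),
leak 2e-4, specimen CV 0.1. With the default profiles, a marker (6e4) is
smaller than the spurious specimen-level amplitude fluctuations of the
largest shared compounds (0.25 × 3e5), so with only 1–2 training specimens
per class a raw-intensity SVM cannot reliably generalize across specimens —
that is a property of tiny designs, not of the pipeline, and it disappears
at realistic specimen counts.

What the generator does **not** emulate: peak tailing, ion suppression and
matrix effects, correlated (chemical) noise, adduct/in-source fragment
families beyond the configurable list, centroiding artifacts, and
between-batch RT drift larger than the grid step. Passing tests therefore
demonstrate the correctness of the processing chain and its statistical
behavior under the stated assumptions, not instrument-grade robustness.

## 7. Problem sizes and determinism

The test suite and the acceptance script run on one CPU in a few minutes:
marker recovery uses 3 specimens/class × 3 replicates (36 runs) per seed
over 10 (tests) or 5 (script) seeds; augmentation neutrality uses
2 specimens/class on a narrowed mass window (m/z 200–450, 250 bins) so the
15×-augmented unfolded matrix and the solver's internal copies stay within
desk memory; the neural-network benchmark uses 36 full-window runs at
50 × 50 input resolution. Gridded matrices are float32 in the large
pipelines and float64 where oracle agreement at 1e−9 is asserted. All
randomness flows through explicit integer seeds (numpy `default_rng`);
every stage is reproducible bit-for-bit on the same platform, and
augmentation contains no randomness at all.

## 8. Known limitations

- The mzML reader covers the centroided-MS1 subset of the format (32/64-bit
  float arrays, zlib or no compression, minute/second RT units); profile
  spectra, ion mobility and MSn are out of scope.
- Consolidation is single-linkage within a class: long chains of adjacent
  features can merge into one marker; the per-group member list is retained
  so finer post-processing is possible.
- The linear SVM uses raw intensities by design; data with strong global
  intensity drift between batches would need the intensity-alteration
  augmentation or external normalization to remain comparable.
- The full residual-18 configuration is provided for completeness but is not
  exercised by the test suite at desk scale.
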