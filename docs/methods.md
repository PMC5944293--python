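# Methods

## Acquisition model

A session shows nine fixation targets one at a time on a 3×3 grid at
`{0.1, 0.5, 0.9} × {0.1, 0.5, 0.9}` in normalized screen coordinates
(origin upper-left, x right, y down). A binocular tracker samples both
eyes at `sampling_rate` (default 60 Hz). A gaze pair is **effective** when
at least one eye lands strictly within `effectiveness_threshold` (default
0.05 normalized units) of the target — one accurate eye is enough, since
the fellow eye of a strabismic subject may deviate arbitrarily. Each
target advances after `pairs_per_target` (default 100) effective pairs
have been retained or after `max_display_time` (default 10 s); a compliant
subject therefore needs 100/60 ≈ 1.67 s per target. Retained pairs only
are stored in a `GazeSession`; the simulator can optionally emit the raw
stream (`keep_ineffective=True`) for calibration-style analyses.

Off-screen gaze samples (coordinates outside (0,1)) are retained
unchanged: large deviations are the diagnostic signal, and they are only
clipped at rasterization time.

## Synthetic subjects

The simulator generates each eye's gaze as target + isotropic Gaussian
fixation noise (per-subject SD drawn from 0.005–0.02 units, a plausible
range for a consumer research tracker plus normal fixational jitter). The
deviating eye of a strabismic subject additionally carries a constant
deviation vector whenever the deviation is *expressed*:

| kind         | expression                                   | default magnitude |
|--------------|----------------------------------------------|-------------------|
| recessive    | always                                       | U(0.02, 0.06)     |
| intermittent | per 0.5 s dwell segment, prob. U(0.3, 0.7)   | U(0.1, 0.3)       |
| manifest     | always                                       | U(0.1, 0.3)       |
| incomitant   | only at 2–4 randomly chosen targets          | U(0.1, 0.3)       |

Deviation axes are predominantly horizontal (±30° jitter, random side),
reflecting the predominance of eso-/exodeviations. Intermittency is a
two-state process switching at 0.5 s segment boundaries rather than
per-sample coin flips: phorias break and regain fusion on the timescale
of fixations, and per-sample switching would blur the bimodal deviation
signature out of the GaDe image. Attention lapses (probability 0.01 per
sample by default) displace *both* eyes by a common isotropic offset of
magnitude U(0.1, 0.3), giving even normal subjects an occasional
far-from-target sample. Recessive magnitudes deliberately overlap the
lapse/noise regime, which is what makes that class hard.

The default cohort is 25 normal / 17 strabismic with kind weights
0.25/0.25/0.35/0.15 (recessive/intermittent/manifest/incomitant). The
`CohortSpec.separable()` preset restricts the strabismic group to
manifest/intermittent tropias of magnitude ≥ 0.15 against noise ≤ 0.02 —
a regime separable by construction, used for end-to-end verification.
Per-subject RNG streams are spawned from the master seed, so cohorts are
reproducible and insensitive to subject count changes.

What the generator does **not** model: saccade dynamics and microsaccades,
vergence, tracker noise spectra and dropouts, calibration error, head
movement, and pupil-size effects. Passing tests on synthetic cohorts
therefore demonstrates the pipeline's correctness and its behaviour under
the stated geometric model of strabismus — not clinical performance on
real recordings, where phoria dynamics and tracker artifacts are richer.

## GaDe images

Per retained pair, three deviations are computed (left eye, right eye,
binocular midpoint — the midpoint deviation is *not* bounded by the
per-eye ones: opposite errors cancel, common errors survive). Each channel
is normalized by its session-wide maximum deviation and painted at
`floor(coordinate · S)` with coordinates clipped into [0, 1); collisions
keep the maximum intensity, making rasterization order-independent and
preserving the worst deviation per pixel. Rounding is half-away-from-zero,
so `d = d_max/2` maps to 128. A channel whose deviations are all zero
stays all-zero (the degenerate `d_max = 0` branch). Images are generated
directly at S×S (224 default, 227 supported, any S ≥ 32) rather than at
screen resolution followed by resampling, which would introduce an
unspecified interpolation step. Display brightening (+50 on nonzero
pixels, saturating) exists for visualization only and never enters the
classification path.

## Builtin features

Per channel: a 32-bin intensity histogram over nonzero pixels normalized
by the nonzero count, the nonzero-pixel count, mean and max nonzero
intensity, and the mean distance (in units of S) of nonzero pixels to the
nearest of the nine target pixels — 3 × 36 = 108 dimensions. These capture
the two axes that separate the classes in GaDe space: how much intensity
mass sits high (deviation magnitude) and how far lit pixels sit from the
target constellation (deviation geometry). All-zero channels contribute
zeros. The CNN extractor is an optional plugin behind the same interface;
it requires torch/torchvision with locally cached ImageNet weights and
raises `ExtractorUnavailableError` otherwise — it is never substituted
silently, and the test and acceptance suites run entirely on the builtin
extractor.

## Classifier and evaluation

Linear-kernel SVM with per-dimension z-scoring fit inside the training
pipeline (leakage-free), C selected from {1e−3 … 1e3} by stratified,
seeded two-fold cross-validation; stratification protects against
single-class halves at the cohort sizes involved (16–17 positives). No
class weighting — plain accuracy is the training criterion. Leave-one-out
evaluation refits everything (scaler, hyperparameter search, SVM) per
fold. Reported metrics: accuracy, specificity (correct-rejection rate
among normals), sensitivity (detection rate among strabismics), in
percent.

## Gaussian baseline

Per target, the 4-D deviation vectors of normal training subjects give a
sample mean and covariance (ddof = 1). When the covariance is singular or
has condition number > 1e8 (zero-noise synthetic data), a ridge of
`1e−8 · trace(Σ)/4` (absolute 1e−12 if the trace is zero) restores
positive-definiteness. Densities are evaluated through a Cholesky
factorization in log space; thresholds are stored on the density scale.

Thresholds: α<sub>j</sub> is searched over the {0.5, 1, 2, …, 20}-th
percentiles of the normal training pairs' densities at target j (a
percentile grid adapts to the density scale, which varies across targets),
β<sub>j</sub> over 0.05 … 0.95 in steps of 0.05. The nine (α, β) pairs are
optimized against *subject-level* training accuracy by one coordinate-
ascent pass in target order, starting from the most lenient grid corner;
ties prefer the smallest α, then the largest β. The search is fully
deterministic. All pair/target comparisons are strict (`>`), so a
proportion exactly at β<sub>j</sub> is abnormal. A target with zero
retained pairs is classified strabismic: inability to produce effective
fixations in a direction is the severe presentation of the same signal.

## Numerical and design choices

- Effectiveness comparison is strict (`<`), matching "must be smaller
  than a threshold".
- Session files are flat CSV (header `subject_id, label, target_index,
  sample_index, timestamp, lx, ly, rx, ry`), coordinates written with full
  `repr` precision so round trips are lossless.
- Timestamps are `sample_index / sampling_rate` with no jitter; timing is
  not used downstream.
- The baseline's subject rule is any-target-abnormal; raising any
  α<sub>j</sub> is monotone toward strabismic calls.
- All randomness (simulation, CV folds, permutation control) flows from
  explicit seeds; `gazedev run` embeds the seed and a config hash in its
  report.

## Problem sizes

Tests and the acceptance script use 42-subject cohorts (25/17, matching
the intended study design) with 100 pairs per target, ≤ 900 pairs per
subject; leave-one-out over 42 subjects refits 42 SVM searches and 42
baseline grid searches, which completes in seconds to tens of seconds on
one CPU. Parameter-recovery checks use n = 5000 simulated vectors; the
density-normalization check uses 2×10⁵ importance samples.

## Known limitations

- The simulator's geometric subject models are stylized; no claim is made
  about sensitivity/specificity on clinical data.
- The builtin features discard temporal structure (fixation stability over
  time, latencies); the GaDe representation itself is deliberately
  atemporal.
- MatConvNet-era CNN variants (VGG-F/M/S) have no torchvision weights and
  are not available in the optional CNN extractor.
- With 17 positives, two-fold CV inside each LOO fold yields coarse
  hyperparameter estimates; the C grid is intentionally short.
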