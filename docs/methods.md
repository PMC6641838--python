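# Methods

This note describes the models, algorithms, parameter choices and numerical
conventions used by `mbplast`. All defaults below are the library defaults;
every analysis is deterministic given its seed.

## 1. Behavioral model and scoring

### Walk model

A fly in a linear two-odor chamber of length `chamber_len = 50` mm is modeled
as a continuous-time biased telegraph walk: at exponential event times with
rate `step_rate = 0.5` s⁻¹ the fly draws a new side according to a bias, then
moves toward a uniform random position in that half. The bias is expressed as
the odds of choosing the "safe" side (the side opposite the trained odor):
bias *b* means the fly sits on the safe side with probability *b*/(1+*b*).
The walk is initialized from its stationary distribution, so the expected
side occupancy equals *b*/(1+*b*) exactly at any epoch length — there is no
burn-in transient. A test session lasts `test_s = 180` s.

### Preference and learning index

Position traces are piecewise-constant trajectories sampled at irregular
times; preferences are time-weighted:

- `preference(odor)` = percent of epoch time spent on the named odor's side,
  integrated over the piecewise-constant trace (midline time is split by the
  interval midpoint rule).
- `avoidance_index` = 100 − 2·preference, so 0 is indifference and 100 is
  complete avoidance.
- `learning_index` = preference(trained odor, pretest) − preference(trained
  odor, posttest), in percentage points. With pretest odds 1 (indifferent)
  and posttest odds 3, the expected learning index is
  100·(1/(1+1) − 1/(1+3)) = **25 points**.

### Conditioning protocol

`training_schedule()` lays out a session with 12 equally spaced shocks of
1.25 s at 50 V paired with the trained odor, then a side-swapped test epoch;
the generator consumes only the epoch structure (odor sides and time
windows), not the shock waveform.

### Exclusion rule

A fly is excluded when its number of choice-zone entries (crossings into a
central zone of half-width `zone_halfwidth = 2.5` mm, counted over the odor
epochs of both sessions) is below `min_entries = 4`. Entries are counted
per crossing; a trajectory that starts inside the zone counts its initial
residence as one entry. Because synthetic trajectories jump instantaneously
between positions, a jump across the zone with no sample inside it does not
count as an entry.

## 2. Imaging model

### Movie generator

`simulate_movie` builds frames as

F(t) = shift(baseline · (1 + Σ_odor map_odor · k_odor(t))) + ε,  ε ~ N(0, σ²) clipped at 0

- `baseline` is a smooth strictly positive random image (Gaussian-filtered
  blobs around mean level 100 counts).
- `map_odor` is a sparse nonnegative peak-ΔF/F field (default 10 % of pixels
  active, lognormal amplitudes).
- `k(t)` is a difference-of-exponentials response kernel
  (`tau_rise = 0.2` s, `tau_decay = 2` s) normalized to peak 1 inside the
  stimulus window.
- XY motion is modeled as integer **circular** shifts of the whole frame; Z
  drift as integer circular rolls of the plane axis of a volume. Circular
  shifts make exact recovery a well-defined ground truth (no content is
  created or destroyed at the borders).
- Corrupt frames are replaced by a spatial permutation of the baseline —
  fully decorrelated content emulating a large axial jump or occlusion.
- An optional knockdown applies a multiplicative gain to the response maps
  inside a designated (γ-lobe) mask.

### Motion correction

XY shifts are estimated per frame by maximizing the circular
cross-correlation with a reference (mean frame or first frame), computed via
FFT; under the circular-shift model this is exactly Pearson-correlation
maximization over all integer shifts. Frames are pre-smoothed with a
Gaussian (`smooth_sd = 4` px) using **periodic ("wrap") boundary handling**:
periodic smoothing commutes exactly with circular shifts, whereas
reflect-padding biases small (±1 px) estimates at the frame borders.
Estimated shifts are clamped to `max_shift` (default 10 px, required to be
less than a quarter of the frame); clamping sets a flag rather than failing.
Z offsets are estimated per volume by the best circular plane roll against
the reference volume, with ties resolved toward 0.

### Frame quality control

Each frame is scored by its Pearson correlation with a baseline image. With
`threshold="auto"`, the cutoff is `median − 5·MAD`, where MAD is scaled by
1.4826 to be consistent with the standard deviation under normality. The
auto rule is designed for corruption detection where most frames are intact;
on nearly noiseless movies the correlation distribution is so tight that
genuine stimulus frames can fall outside the band, so pipeline analyses use
an explicit manual threshold (`qc_threshold = 0.5`) as the stand-in for the
experimenter-chosen cutoff — corrupt (decorrelated) frames score near 0 and
are always removed by it.

### ΔF/F and activity maps

After correction and QC, movies are smoothed with a separable truncated
Gaussian (`sigma = 2`, `radius = 2`, 5×5 footprint, symmetric boundary).
Per-pixel ΔF/F = (F_stim − F₀)/F₀ with F₀ the mean over the pre-stimulus
window and F_stim the mean over the stimulus window, using kept frames only.
A pixel is "responsive" when its ΔF/F exceeds `sd_factor = 2` times its
pre-stimulus temporal SD (noiseless movies make every active pixel exceed
it). ΔF/F is invariant to global intensity scaling by construction. ROI
traces average raw fluorescence over a mask before the same ΔF/F
normalization; `peak_response` is the trace maximum inside the stimulus
window. For a noiseless movie with a square-pulse kernel, per-pixel ΔF/F
equals the amplitude map exactly and the ROI peak equals the amplitude.

## 3. Population statistics

- **Population sparseness** SP = (1 − (Σr/N)²·N/Σr²) / (1 − 1/N) over
  nonnegative responses r (negative values are clipped to 0, non-responsive
  pixels are zeroed); SP = 0 for a uniform population, 1 for a single active
  unit, and (by the identity) 2/3 for 2 equal units among 4. SP is invariant
  to scaling r by any positive constant. All-zero populations and N < 2
  return SP = 0 with a flag.
- **Inter-odor correlation** is the Pearson correlation between two odor
  activity maps restricted to pixels responsive to either odor, after
  aligning the maps by the best circular shift (same estimator as motion
  correction). It is invariant to positive affine transforms of either map.
- **MBON ratios** are within-fly trained:untrained peak ratios; flies with a
  nonpositive denominator are flagged and excluded from tests.

## 4. MBON response generator

Per-fly peak responses are lognormal with designed mean amplitudes
(`base_amp = 1` per odor; the trained group's trained odor is multiplied by
`depression = 0.5`). The total coefficient of variation `cv = 0.2` is split
so that `shared_frac = 0.5` of the log-variance is a per-fly gain shared
across odors — modeling GCaMP expression level and optical access, the very
variability that within-fly ratios are designed to cancel. This makes the
ratio comparison substantially more powerful than the raw amplitudes: the
exact Mann-Whitney test on MCH:OCT ratios reaches ≈ 0.99 power at n = 5 per
group, while the OCT:IAA (no effect) arm rejects at the test's attainable
size.

## 5. Statistical tests

- **Mann-Whitney U**: exact two-sided p by full enumeration of all
  C(n₁+n₂, n₁) group assignments whenever both groups have ≤ 8 observations
  and there are no ties; normal approximation with tie correction otherwise.
  The exact null is discrete: at n = 5 per group the smallest attainable
  two-sided p is 2/252 ≈ 0.0079 and the attainable size closest to 0.05 is
  8/252 ≈ 0.0317; at n = 3 no rejection at α = 0.05 is possible at all
  (min p = 0.1). Calibration claims about type-I error therefore refer to
  the attainable size, not nominal α.
- **Kruskal-Wallis + Dunn**: H with tie correction; Dunn's z-tests on mean
  ranks with Bonferroni adjustment over the comparison family.
- **One-sample t with Bonferroni** across regions.
- **Two-way repeated-measures (mixed) ANOVA** (between = group, within =
  session) via `pingouin.mixed_anova`, validated against a balanced
  partitioned-sums-of-squares oracle to 1e-9; post-hoc paired/unpaired
  comparisons are Holm-Šídák adjusted (step-down `1 − (1−p)^(m−i+1)` with
  monotonicity enforcement).
- **Power** is estimated by Monte-Carlo simulation with a Wilson score
  confidence interval on the rejection rate.
- **ΔΔCt**: fold = 2^(−ΔΔCt) with ΔCt = target Ct − reference Ct, relative
  to a calibrator sample (whose fold is identically 1). Noiseless Ct tables
  generated from designed folds invert exactly; samples missing the
  reference gene are dropped and reported.

## 6. Numerical conventions

- All randomness flows from `numpy.random.default_rng(seed)`; derived seeds
  are drawn as integers below 2³¹. Identical seeds give byte-identical
  outputs (verified for the end-to-end pipeline and the acceptance script).
- Epoch windows and frame-time windows are half-open `[t0, t1)` on frame
  start times.
- Movies are stored internally as float64 and written to disk as float32
  TIFF with a YAML sidecar for timing metadata (round-trip tolerance 1e-4).
- Correlation-based estimators guard degenerate inputs (constant frames or
  maps) with warnings and defined fallbacks rather than NaN propagation.

## 7. Generator realism and limitations

The generators are designed for *verifiability*, not photorealism:

- Circular-shift motion is exactly invertible; real brain motion is
  non-rigid and loses border content. The estimators are standard
  (FFT cross-correlation), but the exact-recovery guarantees hold only
  under the circular model.
- Noise is additive Gaussian (clipped at zero), not Poisson photon noise;
  bleaching, slow drift, and neuropil contamination are not modeled.
- The telegraph walk reproduces occupancy statistics and closed-form
  expected preferences but not fly locomotor kinematics; instantaneous
  jumps mean choice-zone entries require a sample inside the zone.
- The knockdown acts as a pure multiplicative response gain in a fixed
  mask, leaving sparseness and inter-odor correlation unchanged by
  construction — this isolates the amplitude-vs-coding question but is a
  simplification of receptor-level effects.
- Welch's ANOVA and Dunnett's T3 post-hoc tests are not implemented; group
  comparisons use Kruskal-Wallis/Dunn throughout.
- The auto QC threshold assumes corruption is rare and severe; it is not a
  general artifact detector (see §2, frame quality control).
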