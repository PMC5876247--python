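# Methods

`erpsource` implements a complete analysis chain for event-related potential
(ERP) studies with a 2x2 within-subject design: a spherical forward model, a
synthetic multi-subject study generator with planted cortical sources,
mass-univariate sensor statistics, Bayesian-model-averaged (BMA) LORETA
source reconstruction, and second-level group conjunction analysis.  This
note records the models, their assumptions, the defaults that matter, and
the numerical choices.

## Forward model

The head is three concentric spheres — brain, skull, scalp — of piecewise
homogeneous conductivity.  Default outer radii are 0.08 / 0.085 / 0.092 m
(standard adult values).  The default conductivity triple is
(brain, scalp, skull) = (0.33, 0.022, 0.013) S/m, the values the emulated
recording setup reports; because that assignment gives the scalp a lower
conductivity than is conventional, `build_head_model(assignment=
"conventional")` instead reads the triple in the usual inner-to-outer order.
Neither choice affects any structural property the tests assert (linearity,
referencing, attenuation, scaling).

Scalp potentials of a current dipole are computed from the spherical-
harmonic series: per harmonic order `n` the radial transfer through the
layered conductor is obtained by solving the 5x5 boundary-condition system
(continuity of potential and radial current at both internal interfaces,
vanishing radial current at the scalp).  The series is truncated at
`n_terms = 60`; for sources at <= 0.9 of the brain radius the geometric tail
ratio `(b/R)^n` is below 1e-6, and a warning is raised when it is not.  In
the equal-conductivity limit the solution is checked against an independent
closed-form homogeneous-sphere formula (the resummed series expressed
through the infinite-medium potential and two generating-function sums);
agreement is ~1e-9 relative, asserted at 1e-3.

Potentials are nose-referenced: the series is also evaluated at the
reference position and subtracted, so the predicted potential at the nose is
identically zero.  Lead fields are stored in µV per nA·m; generators carry
free 3-component moments.

The 60-channel montage ships as a plain-text table of spherical angles of
the extended 10/20 layout (best-fit-sphere angles of the published
10/05 electrode set), with the nose reference placed at azimuth 0°,
elevation −30° — a modeling choice, since only "tip of the nose" is
specified for the emulated recording.

The source space is a quasi-uniform (golden-angle spiral) shell at 90% of
the brain radius, partitioned into contiguous compartments by spherical
Voronoi cells of seeded random directions (redrawn until no cell is empty).
The default 500 generators / 12 compartments scale down the 5656 generators
/ 76 anatomical compartments of a full cortical atlas while keeping every
algorithmic property intact.  The neighbor graph is the symmetrized
6-nearest-neighbor graph, approximating a triangulated surface topology.

## Synthetic studies

`generate_study("paper_like", seed)` emulates a 28-subject, 60-channel,
2x2 (TASK x MATCH) study with 40 trials per condition, 256 samples at
250 Hz spanning −200…+820 ms.  Each planted component is a radial dipole at
a compartment centroid with a Gaussian time course:

| component | latency (ms) | width (ms) | amplitude (nA·m) | conditions |
|---|---|---|---|---|
| N170 (intra) | 170 | 18 | 3.0 | both intra |
| N170 (cross) | 170 | 18 | 2.5 | both cross |
| P200 | 200 | 22 | 3.0 | both intra |
| N250 | 270 | 25 | 2.5 | both intra |
| N400 (intra) | 385 | 45 | 4.0 | intra mismatch only |
| N400 (cross) | 385 | 45 | 4.0 | cross mismatch only |

Compartments are assigned deterministically by matching canonical scalp
directions (right/left occipito-temporal for the two N170 sources, right
middle-occipital for P200, right fusiform-like for N250, and two distinct
task-specific N400 compartments).  Amplitudes were chosen once so that
components reach the few-µV scalp magnitudes typical of real ERP components
given this geometry (the maximal lead of a superficial radial source is
~1.7 µV per nA·m); the 4 nA·m N400 strength makes the mismatch effect
clearly detectable at the group level, as in the experimental situation the
generator emulates, where the match/mismatch difference is widely
significant between 300 and 450 ms.

Per-subject amplitudes are multiplied by a log-normal factor (log-sd 0.3).
Sensor noise is Gaussian, 10 µV per sample per channel, spatially
correlated with an exponential decay over inter-electrode great-circle
angle (e-folding 30°), white in time.  With probability 0.1 a trial carries
a ±150 µV, ~100 ms square pulse on a random frontal channel, exercising the
±100 µV rejection rule.  Preprocessing drops such trials, equalizes
kept-trial counts across conditions by seeded subsampling, averages,
linearly detrends each channel and subtracts the pre-stimulus mean.

What the generator does **not** emulate: ocular artifacts and their
regression-based correction, filtering chains, 12-bit quantization,
background EEG rhythms (the noise is white in time), and any realistic
cortical geometry.  Passing tests therefore demonstrate correctness of the
analysis chain under a controlled, identifiable ground truth — not
performance on real EEG.

The `"null"` preset plants no components and is used for calibration.

## Sensor statistics

The mass-univariate analysis fits a two-way repeated-measures ANOVA at
every electrode and time point.  In a 2x2 within-subject design each effect
is a single-df paired contrast, so `F = n * mean(c'y)^2 / var(c'y)` with
df (1, n−1) — identically the square of the paired t statistic — and no
sphericity correction exists to make.  Points with zero contrast variance
report p = 1 (conservative) rather than NaN.  Multiplicity over the
electrode x time grid is controlled by Benjamini–Hochberg FDR at q = 0.05
(via statsmodels); post hoc within-factor paired t maps are evaluated only
at points significant for the corresponding main effect, with BH applied
jointly across the two within-factor comparisons and all retained points.

p-to-Z display transforms support two conventions: the default maps a
two-sided p to the unsigned quantile `Z = Phi^-1(1 - p/2)` (sign optionally
copied from a t map); `mode="one_sided"` maps `Z = Phi^-1(1 - p)`.

The behavioral discrimination index implements
`d' = 0.6 log[(pH(1−pF))/(pF(1−pH))]` with a configurable logarithm base
(default 10).  Boundary probabilities raise an error; the caller owns the
correction rule.

## BMA-LORETA inversion

Features are either window averages (default 330–440 ms, the mismatch-ERP
window) or subject-specific peak amplitudes (extremum of a posterior
channel-group mean inside a component window; subjects without an interior
extremum of the required polarity are excluded with a warning).  Peak
windows (N170: 130–200 ms negative; P200: 180–250 ms positive; N250:
230–310 ms negative) are configuration defaults, not facts about any
dataset.

For a compartment subset M the inverse model is Gaussian:
`v = K_M j + e`, `e ~ N(0, beta^-1 I)`, prior
`j ~ N(0, (alpha (L'L + eps I))^-1)` with L the graph Laplacian of the
neighbor graph restricted to M, applied identically to the three moment
components.  `eps` is a trace-normalized ridge (1e-8) making the singular
Laplacian invertible.  Hyperparameters (alpha, beta) are optimized by
evidence maximization: a 25x25 log10 grid over [1e-6, 1e6] per parameter,
a 17x17 fine grid over the winning cell, then Nelder–Mead on
(log alpha, log beta) — all closed-form through the SVD of the
prior-whitened lead field, which depends only on the model and is
precomputed once and reused across subjects and features.  The posterior
mean is followed by two steps of iterative refinement on the normal
equations, which removes the rounding-error amplification of the
ill-conditioned prior and makes the solution agree with dense brute-force
algebra to ~1e-12.

The model space is the exhaustive enumeration of nonempty compartment
subsets up to `max_size = 2` (capped at 1000 models) — exact and
oracle-verifiable at this scale, in place of the stochastic model-space
samplers used at atlas scale.  Posterior model probabilities are
`w ∝ exp(log evidence)` under a uniform model prior; models whose posterior
odds against the best fall below Occam's window (default 1/20) are pruned
and the weights renormalized.  The averaged moment field (zero outside each
model's support) yields per-voxel magnitudes.  Scale covariance holds to
~1e-7: multiplying the data by c multiplies the map by c, because the
evidence landscape shifts exactly and the optimizer tracks it.

## Group conjunction

Per subject and condition, the source map is binarized through a local
false discovery rate: exact-zero voxels (outside the averaged model
support) are inactive by definition; the remaining log magnitudes are
standardized and fitted with a two-component Gaussian mixture by EM
(deterministic quantile-based initialization: means at the median and 90th
percentile, mixing 0.9/0.1 — a null-dominant assumption).  The lower-mean
component is the null; a voxel is active when the posterior null
probability at its value is below 0.2 (Efron's conventional reporting
level).  This two-Gaussian EM is a deliberate, documented simplification of
spline-based empirical-null fitting: deterministic, few parameters,
adequate for a unimodal null.  EM non-convergence (or a degenerate
all-equal map) falls back to an all-inactive map with a warning.
Standardization plus the zero-voxel rule makes binarization exactly
invariant to positive rescaling of the map — the property that motivates
binarizing at all, since individual inverse solutions differ in scale.

Conjunction maps are per-voxel proportions of active subjects.  Between
conditions, per-subject binary maps are subtracted (−1/0/1) and averaged
with sign.  Significance uses a paired sign-flip permutation test (the
exchangeability group of "equal conditions" for paired designs): per voxel,
two-sided `p = (1 + #{|perm| >= |obs|}) / (n_iter + 1)` with BH-FDR across
voxels (default 10 000 iterations, q = 0.05).  Because the signed
conjunction of ~28 subjects is a heavily discrete statistic, this
deliberately conservative estimator cannot be distribution-uniform under
the null; the package therefore also reports tie-randomized p-values
(`(#strict + U·(1 + #ties)) / (n_iter + 1)`), the standard exactly-uniform
construction for discrete permutation statistics, which the calibration
checks use.  Inference (the FDR mask) always uses the conservative
estimator.

Cluster tables summarize suprathreshold voxels per compartment (size, mean
|conjunction|, SD, sorted by size; signed maps tabulated per sign).  Plain
within-condition conjunction maps are reported unthresholded with a 0.5
cluster floor; only difference maps are permutation-thresholded.

## Pipeline

`run_pipeline` chains simulate → sensor stats → feature extraction + BMA
inversion → conjunction, writing delimited-text outputs and a manifest with
the resolved configuration, the seed and SHA-256 hashes of every file.  The
global seed expands into per-stage substreams via
`SeedSequence([seed, stage_counter])`, so stages reproduce identically when
run standalone from each other's files (ERP and source-map interchange uses
17-significant-digit text, which round-trips doubles exactly).  The same
stages back the `erpsource` CLI (`simulate`, `sensor-stats`, `invert`,
`conjoin`, `run-all`).

## Validation problem sizes

The acceptance script and the heavier tests run at sizes chosen to keep a
complete validation pass fast while leaving every statistical property
intact: 500 generators / 12 compartments; 20 independent studies for the
recovery and localization rates; 200 replicates for FDR calibration using
the null preset with 8 trials per condition and no artifact trials (trial
count only scales ERP noise variance and artifacts are irrelevant under the
null, so BH calibration is unaffected); 1000 permutation iterations for
calibration checks (10 000 remains the analysis default).  The
source-recovery check inverts the grand-average mismatch window feature;
the localization check inverts per-subject features for both tasks and
requires at least half of the FDR-significant difference voxels to lie in
the two planted task-specific N400 compartments.

## Known limitations

- The spherical three-shell conductor and spherical atlas are deliberate
  idealizations; no claim transfers to realistic BEM/FEM geometry.
- Exhaustive model enumeration is exponential in compartment count; at
  atlas scale (76 compartments) a stochastic model search would be needed
  (out of scope here).
- The two-Gaussian lfdr binarization assumes a unimodal null on the log
  scale; heavy-tailed or multimodal null distributions would need the full
  empirical-null machinery.
- The temporal noise model is white; autocorrelated EEG background would
  widen sensor-level confidence bands relative to this idealization.
- With ~28 subjects the signed-conjunction permutation p-values are
  discrete; the conservative estimator over-covers, which costs a little
  power at fixed FDR.
- The cross-domain N400 source is planted toward the left inferior
  occipito-temporal direction, at the edge of what an upward-facing
  10/20 montage can see.  On seeds where its Voronoi compartment falls well
  below the electrode rim, per-subject reconstructions smear across
  neighboring compartments and the significant task-difference voxels are
  correspondingly diffuse: the fraction of significant voxels inside the
  nominally planted compartments then drops below one half even though the
  difference signal itself is real.  Across independent seed batches this
  concentration rate varies between roughly 75% and 95% of seeds, while the
  superior intra-domain source is recovered in 19–20 of 20 seeds per batch.
  This is electrode-coverage physics, not a property of the statistics.
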