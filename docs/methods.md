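# Methods

This note records the scientific and numerical choices behind `scenesim`:
what each stage models, the parameters that matter, where the design was
genuinely open, and what the synthetic data can and cannot show.

## Generative model of neural activity

Activity evoked by one exemplar of scene category *c* in a V-voxel region is
a draw from an isotropic multivariate Gaussian N(**μ**_c, σ²**I**). The six
category means **μ**_c are the "prototypes"; in the original experiments such
means would be estimated from a subject's parahippocampal-place-area data,
which is not available, so `generate_prototypes` synthesizes them as
independent Gaussian vectors scaled by a `separation` parameter (expected
pairwise distance `separation * sqrt(2V)`). Exemplar-to-exemplar variability
uses two settings, σ_good and σ_bad with σ²_bad = 2 σ²_good, the doubled-
variance condition that defines the bad-exemplar regime. Voxels are
independent everywhere — no spatial noise correlations are modeled.

Time courses are built on a fine grid (dt = 0.1 s, which divides both the
1.6 s image slot and the 2 s TR): zero activity during fixation, a fresh
exemplar draw held constant over each 1.6 s slot. The grid activity is
convolved with the gamma-variate HRF h(t) = (t/pq)^p e^(p−t/q) (p = 8.6,
q = 0.547; unit peak at t = pq = 4.7042 s), implemented as FIR convolution
scaled by dt and truncated at 32 s (tail mass beyond truncation < 1e-6 of
peak). The result is sampled every TR = 2 s and white Gaussian measurement
noise of SD `sigma_noise` is added.

**Blocked design.** 12 s initial fixation, then six 16 s blocks (one per
category, caller-supplied order) each followed by 12 s fixation. The literal
sum is 180 s; the package defaults to an extra 12 s of final fixation for a
192 s / 96-volume run, keeping the run length consistent with the 264 s
event-related run below; `extra_final_fixation=0` gives the 180 s reading.

**Event-related design.** 12 s fixation, 60 trials (1.6 s stimulus + 2.4 s
gap, 10 trials per category randomly interleaved), 12 s final fixation:
264 s / 132 volumes.

## Decoding

The block decoder follows the standard volume-wise MVPA recipe: extract the
eight volumes per block starting 4 s (2 TRs) after block onset — non-integer
shifts are rejected rather than interpolated — and treat every volume as an
independent sample labeled with its block's category (pooled across within-
block positions, rather than one classifier per position; the majority-vote
aggregation presupposes pooling). The classifier is a linear-kernel SVM at
C = 0.02, realized as scikit-learn's `LinearSVC` (liblinear, one-vs-rest,
squared-hinge loss). One-vs-rest makes a per-category decision value well
defined, which the tie rule needs: a held-out block takes the label most
frequent among its eight per-volume predictions; ties go to the tied
category with the largest decision value summed over the eight volumes; an
exactly tied sum (measure-zero, but must be deterministic) falls back to the
classifier's fixed class order and is logged. Leave-one-run-out
cross-validation trains on five runs and tests on the sixth, aggregating a
6×6 confusion matrix (rows = truth) whose trace/total is the reported
accuracy.

Event-related runs are first reduced to per-run category beta patterns by an
OLS regression on six HRF-convolved category regressors plus intercept; the
six beta patterns per run then enter the same LORO scheme, predicted
directly (no voting — each pattern is a single sample).

`normalize_run` (divide each voxel by its within-run temporal mean, the
preprocessing applied to scanner data) exists for real-data-shaped inputs;
the experiment drivers do not apply it to simulated runs, whose baseline is
zero by construction — a temporal-mean division would be ill-conditioned and
the simulation's activation units are already baseline-free. Zero-mean
voxels encountered in real data are set to a constant 1.0 and logged.

Condition comparisons use a two-tailed paired t-test across subjects plus
one-tailed one-sample t-tests of each condition against the 1/6 chance
level. Zero-variance differences are flagged degenerate: identical samples
report t = 0, p = 1; a constant nonzero difference reports t = ±inf, p = 0.

## Univariate GLM

Design matrices are HRF-convolved boxcars per condition sampled at the TR,
scaled to unit peak, plus an intercept. Percent signal change is
100·β/β₀ per voxel, averaged over voxels — unit-peak regressors make β the
peak-equivalent amplitude, and the ratio is invariant to global rescaling of
the data. The pooled residual SD is sqrt(RSS/(V·(T−k))), which recovers the
injected measurement-noise SD when the model spans the signal; this is the
calibration loop that, with real data, would set the simulator's
`sigma_noise` from regression residuals. The halves variant splits each 16 s
block into two 8 s sub-events (the first/second four of the eight shifted
volumes) and feeds per-subject 2×2 tables (condition × half) to a classical
two-within-factor repeated-measures ANOVA with subject as the blocking
factor. The ANOVA is implemented directly (each effect tested against its
subject-by-effect interaction, n−1 denominator df) so that all-zero effects
report F = 0 rather than the 0/0 indeterminate form; it is cross-checked
against `statsmodels` AnovaRM in the test suite. Spatial smoothing has no
meaning for synthetic voxels without geometry and is deliberately not
modeled.

## Image statistics

The form space convolves the grayscale image (fixed luminance weights
0.299/0.587/0.114, resized to 600×450) with 64 Gabor kernels — 8
orientations at kπ/8 × 8 wavelengths geometrically spaced from 2 to 8 px so
every cycle fits the 8×8 kernel. Only the bank's shape (8×8 kernels, 8
orientations × 8 frequencies) is externally fixed; the remaining conventions
are this package's: even-symmetric (cosine-phase) Gaussian-windowed kernels
(σ = 2 px), mean-subtracted to be DC-free, L2-normalized; the per-pixel
response is the absolute value of the linear response (contrast-selective,
and exactly zero on constant images), averaged over all 600×450 positions
with edge-replicated borders. The color space is the 8×8 joint hue ×
saturation histogram (hexcone transform; achromatic pixels land in hue bin
0), normalized to proportions.

Set variance in either space is the sum of the eigenvalues of the 1/n
(population) covariance matrix of the feature vectors — identically the mean
squared Euclidean distance of the vectors from their mean, which is the
brute-force oracle the tests compare against at 1e-10 relative tolerance.
The statistic is translation-invariant and scales quadratically.

## Synthetic data

*Scene images* are oriented sinusoidal textures in a fixed hue/saturation
palette, one template per category; each generated image perturbs
orientation (SD 0.2·j rad), log-frequency (SD 0.15·j), phase (SD 1.5·j),
hue (SD 0.05·j), saturation (SD 0.1·j) and adds pixel luminance noise (SD
0.08·j), with j the `jitter_scale`. Jitter 0 reproduces the template
exactly; form-space variance grows monotonically with j. Low-jitter (0.3)
vs high-jitter (1.0) sets emulate the good-vs-bad variance ordering — good
sets less variable in form space in every category — but nothing about the
appearance of real photographs, so passing image tests shows the variance
*machinery* is right, not that real good exemplars behave this way.

*Rating tables* place one check trial after every ten regular trials
(session positions 11, 22, 33, …), each repeating an image from the
rater's preceding ten trials. Consistent raters answer deterministically per
(rater, image), so their discount is exactly 0. Planted inconsistent raters
flip the category on every check (5 points each), so with ≥ 3 checks
(≥ 33 trials/rater) they exceed the exclusion threshold of 10; the generator
rejects plant requests that could not exceed the threshold. Trial counts per
rater are fixed — the real distribution of crowdworker workloads is unknown
and irrelevant to the rules being tested.

*Rating QC rules*: a check contributes 5 for a category flip, otherwise
|Δrating|; raters are discarded when the total *exceeds* 10 (11 is out, 10
stays); images are discarded when non-member responses *exceed* a quarter of
their ratings (exactly 25% stays). Exemplar selection ranks 240 candidates
(80 good / 80 medium / 80 bad) by descending mean rating, ties broken by
image id: good = top 60 of the good candidates, bad = bottom 60 of the bad
candidates, medium = ranks 91–150 of the full list ("the central 60", made
precise as ⌈(240−60)/2⌉+1 onward). Overlapping selections raise an error
rather than being silently repaired. Check-trial responses are excluded from
image mean ratings.

## Calibration and problem sizes

The simulation's absolute accuracy level is not externally pinned, so the
defaults are set by procedure (`scripts/calibrate.py`): block-design
good-exemplar accuracy should land between chance and ceiling (window
0.30–0.60), exemplar variance should remain the dominant noise source (so
the doubled bad-exemplar variance produces a clear effect), and the blocked
design should decode better than the event-related design. The adopted
defaults are V = 100 voxels (a PPA-sized region), separation 0.18,
σ_good = 1.25, σ_bad = 1.25·√2, σ_noise = 3.5. The problem is kept at unit
scale (small separation rather than large noise SDs) because liblinear at
C = 0.02 converges much faster there; the two parameterizations are
statistically equivalent under global rescaling. With these defaults, 8
subjects × 100 repetitions give good > bad with paired t(7) ≈ 25 (block) and
≈ 12 (event), both p < 0.001, and block accuracy above event accuracy.

Experiments derive one independent RNG stream per (subject, repetition) from
the master seed via `numpy.random.SeedSequence`, so reports are byte-
reproducible and independent of execution order.

Test-suite problem sizes are chosen for turnaround: the full-scale
good-vs-bad test runs 8 × 100 repetitions; the chance-level test 8 subjects
× 50 repetitions; image-space checks use 6–12 images per set (the study's
60-image sets are the `run_imagestat_experiment` default). Monte-Carlo
assertions state tolerances derived from their own standard errors.

## Known limitations

- White measurement noise only: no drift, motion, physiological or
  autocorrelated noise, and no voxel-voxel correlations.
- Synthetic scenes share none of the semantic structure of photographs; the
  image pipeline validates the variance statistic, not scene perception.
- The event-related pathway estimates betas per run with a fixed HRF; HRF
  mis-specification or trial-order optimization is out of scope.
- The per-volume (pooled) reading of "train and test on each time point
  separately" is one of two defensible readings; one-classifier-per-position
  is the alternative and is not implemented.
- Percent signal change is computed per condition across the run, not per
  block.
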