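# scenesim

Simulation and decoding toolkit for studying why *good* exemplars of natural
scene categories (beaches, city streets, forests, highways, mountains,
offices) yield more decodable multi-voxel fMRI patterns than *bad* exemplars.

Human raters agree that some photographs are highly representative of their
scene category while others are marginal. Behaviorally, good exemplars are
categorized faster and more accurately; neurally, linear classifiers decode
scene category from visual-cortex activity patterns more accurately when the
viewed images are good exemplars. `scenesim` packages the computational
machinery needed to study the leading explanation for this effect: good
exemplars cluster more tightly around a category prototype, in image-feature
space and — by hypothesis — in voxel-pattern space, and lower within-category
variance alone is enough to produce higher decoding accuracy.

## The model

Neural activity for an exemplar of category *c* is a draw from an isotropic
multivariate Gaussian

&nbsp;&nbsp;&nbsp;&nbsp;**x** ~ N(**μ**_c, σ² **I**)

with σ²_bad = 2 σ²_good. Activity time courses (zero during fixation, a fresh
exemplar draw per 1.6 s image slot) are convolved with a gamma-variate
hemodynamic response function

&nbsp;&nbsp;&nbsp;&nbsp;h(t) = (t / pq)^p · e^(p − t/q),&nbsp;&nbsp; p = 8.6, q = 0.547

(unit peak at t = pq ≈ 4.70 s), sampled at TR = 2 s, and corrupted by white
measurement noise. Two designs are simulated: a **blocked** design (12 s
fixation, six 16 s category blocks of ten 1.6 s images separated by 12 s
fixation; 192 s per run) and a **fast event-related** design (60 interleaved
1.6 s trials with 2.4 s gaps; 264 s per run). Decoding uses the standard
block MVPA pipeline: the eight volumes of each block, shifted 4 s for the
hemodynamic delay, feed a linear-kernel SVM (C = 0.02, one-vs-rest); each
held-out block is labeled by majority vote over its eight per-volume
predictions (ties broken by summed SVM decision values) under leave-one-run-
out cross-validation. Event-related runs are decoded from per-run category
beta patterns estimated by an HRF-regressor GLM.

The package also implements the surrounding analyses: the 64-dimensional
Gabor "form" space (8 orientations × 8 frequencies, 8×8 kernels at 600×450
resolution) and 8×8 hue–saturation "color" space with the eigenvalue-sum
(total-variance) statistic; univariate GLM / percent-signal-change analyses
including the first-half/second-half 2×2 repeated-measures ANOVA used to
probe repetition suppression; and the crowdsourced-rating quality control
(check trials, discount scores, rater and image exclusion, 60/60/60
good/medium/bad exemplar-set selection). Synthetic generators for voxel
prototypes, scene-like images with controllable within-category variance,
and rating tables make every stage testable without any external data.

## Worked example

```python
import scenesim as ss

config = ss.SimulationConfig(n_subjects=4, n_repetitions=10, rng_seed=0)
report = ss.run_goodbad_experiment(config, design="block")
c = report.comparison
print(f"good exemplars : mean accuracy {c.mean_good:.3f}")
print(f"bad exemplars  : mean accuracy {c.mean_bad:.3f}")
print(f"paired t({c.df}) = {c.t_statistic:.2f}, two-tailed p = {c.p_value:.4f}")
```

prints

```
good exemplars : mean accuracy 0.488
bad exemplars  : mean accuracy 0.361
paired t(3) = 10.97, two-tailed p = 0.0016
```

Good-exemplar runs (low exemplar variance) decode at ~49% — far above the
1/6 ≈ 16.7% chance level for six categories — while doubling the exemplar
variance ("bad" runs) drops accuracy by ~13 points; the paired t-test shows
the drop is consistent across the four synthetic subjects. At the full study
scale (8 subjects × 100 repetitions, `ss.SimulationConfig()` defaults) the
same ordering holds in both the blocked and the event-related design with
p < 0.001, and the blocked design decodes better overall.

The same drivers are available from the shell:

```bash
scenesim experiment goodbad --design block --subjects 8 --reps 100 --out out/
scenesim simulate --design event --runs 6 --out runs/ && scenesim decode --runs runs/ --out out/
scenesim experiment imagestats --n-images 60 --out out/
```

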