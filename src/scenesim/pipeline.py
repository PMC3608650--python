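"""Experiment drivers tying the generators, simulator and decoder together.

The central experiment simulates, for each synthetic subject, six runs of
good-exemplar activity (low exemplar variance) and six runs of bad-exemplar
activity (variance doubled), decodes each condition with leave-one-run-out
cross-validation — per-volume SVM with majority voting for the block design,
per-run category beta patterns for the event-related design — averages
accuracy over repetitions, and compares conditions with a paired t-test
across subjects.

Seeding: a master seed is split with ``numpy.random.SeedSequence`` into one
independent stream per (subject, repetition), so reports are reproducible and
independent of execution order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import decoding, image_stats
from .neural_sim import (
    BlockDesign,
    EventDesign,
    SimulationConfig,
    event_glm_betas,
    simulate_block_run,
    simulate_event_run,
)
from .synthetic_data import (
    CATEGORY_NAMES,
    SceneImageSpec,
    default_scene_specs,
    generate_prototypes,
    generate_scene_image_set,
)

CHANCE = 1.0 / 6.0


@dataclass
class ExperimentReport:
    """Per-subject mean accuracies and the paired comparison, plus provenance."""

    design: str
    n_subjects: int
    n_repetitions: int
    acc_good: np.ndarray  # (n_subjects,) mean over repetitions
    acc_bad: np.ndarray
    comparison: decoding.ConditionComparison
    config_snapshot: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "n_subjects": self.n_subjects,
            "n_repetitions": self.n_repetitions,
            "acc_good": self.acc_good.tolist(),
            "acc_bad": self.acc_bad.tolist(),
            "comparison": self.comparison.to_dict(),
            "config": self.config_snapshot,
            "seed": self.seed,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _config_snapshot(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    protos = d.pop("prototypes", None)
    d["prototypes"] = None if protos is None else "explicit"
    return d


def _subject_prototypes(config: SimulationConfig, seed: int):
    if config.prototypes is not None:
        return config.prototypes
    return generate_prototypes(config.n_voxels, config.separation, rng_seed=seed)


def _decode_condition(design, config, condition: str, rng: np.random.Generator) -> float:
    """Simulate six runs of one condition and return the LORO accuracy."""
    if isinstance(design, BlockDesign):
        runs = []
        for r in range(6):
            order = list(rng.permutation(CATEGORY_NAMES))
            runs.append(simulate_block_run(design, config, order, rng, condition, run_id=r))
        return decoding.loro_cross_validate(runs).accuracy
    if isinstance(design, EventDesign):
        patterns, labels = [], []
        for r in range(6):
            order = list(rng.permutation(np.repeat(CATEGORY_NAMES, design.trials_per_category)))
            run = simulate_event_run(design, config, order, rng, condition, run_id=r)
            betas, cats = event_glm_betas(run, config.hrf)
            patterns.append(betas)
            labels.append(cats)
        return decoding.loro_cross_validate_patterns(patterns, labels).accuracy
    raise TypeError(f"unsupported design {type(design).__name__}")


def run_goodbad_experiment(
    config: SimulationConfig,
    design: str = "block",
    rng_seed: int | None = None,
    block_design: BlockDesign | None = None,
    event_design: EventDesign | None = None,
) -> ExperimentReport:
    """The good-vs-bad decoding experiment over subjects and repetitions.

    For each subject a prototype set is drawn (unless the config fixes one);
    for each repetition six runs per condition are simulated and decoded; the
    per-subject repetition-mean accuracies feed a two-tailed paired t-test.
    """
    seed = config.rng_seed if rng_seed is None else rng_seed
    design_obj = (block_design or BlockDesign()) if design == "block" else (event_design or EventDesign())
    if design not in ("block", "event"):
        raise ValueError("design must be 'block' or 'event'")
    master = np.random.SeedSequence(seed)
    acc = np.zeros((config.n_subjects, config.n_repetitions, 2))
    for s, subj_seq in enumerate(master.spawn(config.n_subjects)):
        proto_seq, rep_root = subj_seq.spawn(2)
        protos = _subject_prototypes(config, proto_seq.generate_state(1)[0] % (2**31))
        subj_config = dataclasses.replace(config, prototypes=protos)
        for r, rep_seq in enumerate(rep_root.spawn(config.n_repetitions)):
            rng = np.random.default_rng(rep_seq)
            for c, condition in enumerate(("good", "bad")):
                acc[s, r, c] = _decode_condition(design_obj, subj_config, condition, rng)
    acc_good = acc[:, :, 0].mean(axis=1)
    acc_bad = acc[:, :, 1].mean(axis=1)
    comparison = decoding.compare_conditions(acc_good, acc_bad, chance=CHANCE)
    return ExperimentReport(
        design=design,
        n_subjects=config.n_subjects,
        n_repetitions=config.n_repetitions,
        acc_good=acc_good,
        acc_bad=acc_bad,
        comparison=comparison,
        config_snapshot=_config_snapshot(config),
        seed=seed,
    )


def run_null_experiment(
    config: SimulationConfig,
    n_reps: int,
    design: str = "block",
    rng_seed: int | None = None,
) -> dict:
    """Decoding with no category signal: identical (zero-separation) prototypes.

    Simulates the good condition of the chosen design for each subject and
    repetition with all six category distributions sharing one mean, and
    returns the mean LORO accuracy with its Monte-Carlo 95% CI, which should
    cover chance (1/6).
    """
    seed = config.rng_seed if rng_seed is None else rng_seed
    null_config = dataclasses.replace(config, separation=0.0, prototypes=None,
                                      n_repetitions=n_reps)
    design_obj = BlockDesign() if design == "block" else EventDesign()
    master = np.random.SeedSequence(seed)
    accs = []
    for s, subj_seq in enumerate(master.spawn(null_config.n_subjects)):
        proto_seq, rep_root = subj_seq.spawn(2)
        protos = _subject_prototypes(null_config, proto_seq.generate_state(1)[0] % (2**31))
        subj_config = dataclasses.replace(null_config, prototypes=protos)
        for rep_seq in rep_root.spawn(n_reps):
            rng = np.random.default_rng(rep_seq)
            accs.append(_decode_condition(design_obj, subj_config, "good", rng))
    accs = np.asarray(accs)
    # a single replication has no spread estimate; report a point value
    sem = 0.0 if len(accs) < 2 else accs.std(ddof=1) / np.sqrt(len(accs))
    mean = float(accs.mean())
    return {
        "mean_accuracy": mean,
        "ci_low": mean - 1.96 * float(sem),
        "ci_high": mean + 1.96 * float(sem),
        "n": len(accs),
        "accuracies": accs,
        "chance": CHANCE,
        "seed": seed,
    }


def run_imagestat_experiment(
    jitter_good: float = 0.3,
    jitter_bad: float = 1.0,
    n_images: int = 60,
    rng_seed: int = 0,
    image_size: tuple[int, int] = (450, 600),
) -> pd.DataFrame:
    """Form- and color-space variance of synthetic good vs bad image sets.

    For each of the six categories, generates a low-jitter ("good") and a
    high-jitter ("bad") image set around the same template and computes the
    total variance of each set in the Gabor form space and the hue-saturation
    color space.  Returns one row per category with both variances and the
    per-space ordering flags.
    """
    if jitter_bad <= jitter_good:
        raise ValueError("jitter_bad must exceed jitter_good")
    if n_images < 2:
        raise ValueError("n_images must be >= 2")
    rows = []
    for k, (spec_g, spec_b) in enumerate(
        zip(default_scene_specs(jitter_good, image_size), default_scene_specs(jitter_bad, image_size))
    ):
        seq_g, seq_b = np.random.SeedSequence((rng_seed, k)).spawn(2)
        seed_g = int(seq_g.generate_state(1)[0] % (2**31))
        seed_b = int(seq_b.generate_state(1)[0] % (2**31))
        imgs_g = generate_scene_image_set(spec_g, n_images, seed_g)
        imgs_b = generate_scene_image_set(spec_b, n_images, seed_b)
        row = {"category": CATEGORY_NAMES[k]}
        for space in ("form", "color"):
            var_g = image_stats.feature_variance(image_stats.feature_matrix(imgs_g, space))
            var_b = image_stats.feature_variance(image_stats.feature_matrix(imgs_b, space))
            row[f"{space}_var_good"] = var_g
            row[f"{space}_var_bad"] = var_b
            row[f"{space}_good_lt_bad"] = bool(var_g < var_b)
        rows.append(row)
    return pd.DataFrame(rows)
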