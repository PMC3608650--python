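"""Generators for every input the pipeline consumes.

Three families of synthetic data stand in for the study materials that are not
publicly deposited:

* **Voxel-pattern prototypes** — six category means of the multivariate Gaussian
  generative model of neural activity.  In the original experiment these came
  from subjects' parahippocampal-place-area data; here they are synthesized
  Gaussian vectors whose pairwise separation is a free parameter.
* **Scene-image sets** — oriented band-limited textures with a category palette,
  perturbed per image by a jitter parameter.  Only the *variance structure*
  of the study's photo sets (good exemplars cluster tightly in feature space,
  bad exemplars spread widely) is emulated, not their appearance.
* **Rating tables** — crowdsourced category/goodness ratings with periodic
  self-consistency check trials and optional planted inconsistent raters, for
  exercising the rating quality-control rules.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.color import hsv2rgb

CATEGORY_NAMES: tuple[str, ...] = (
    "beach",
    "city_street",
    "forest",
    "highway",
    "mountain",
    "office",
)
N_CATEGORIES = len(CATEGORY_NAMES)

RATING_COLUMNS = ("rater_id", "trial", "image_id", "response", "rating", "is_check", "refers_to")


@dataclass(frozen=True)
class CategoryPrototypeSet:
    """Per-category mean voxel patterns anchoring the generative model."""

    category_names: tuple[str, ...]
    prototypes: np.ndarray  # (6, n_voxels)

    def __post_init__(self) -> None:
        protos = np.asarray(self.prototypes, dtype=float)
        object.__setattr__(self, "prototypes", protos)
        if len(self.category_names) != N_CATEGORIES:
            raise ValueError(f"expected {N_CATEGORIES} categories, got {len(self.category_names)}")
        if protos.ndim != 2 or protos.shape[0] != N_CATEGORIES:
            raise ValueError(f"prototypes must be ({N_CATEGORIES}, V), got {protos.shape}")
        if not np.all(np.isfinite(protos)):
            raise ValueError("prototypes must be finite")

    @property
    def n_voxels(self) -> int:
        return self.prototypes.shape[1]

    def index_of(self, category: str) -> int:
        try:
            return self.category_names.index(category)
        except ValueError:
            raise ValueError(f"unknown category {category!r}") from None

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.prototypes, index=list(self.category_names))
        df.to_csv(path, index_label="category")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CategoryPrototypeSet":
        df = pd.read_csv(path, index_col="category")
        return cls(tuple(df.index), df.to_numpy(dtype=float))


@dataclass(frozen=True)
class ExemplarVarianceSpec:
    """Standard deviations of the exemplar draws for good and bad conditions.

    The default honors the study condition sigma_bad**2 = 2 * sigma_good**2:
    bad exemplars are modeled as twice as variable (in variance) as good ones.
    """

    sigma_good: float = 1.0
    sigma_bad: float = field(default=float(np.sqrt(2.0)))

    def __post_init__(self) -> None:
        if self.sigma_good <= 0 or self.sigma_bad <= 0:
            raise ValueError("exemplar standard deviations must be positive")

    @classmethod
    def with_double_variance(cls, sigma_good: float) -> "ExemplarVarianceSpec":
        return cls(sigma_good=sigma_good, sigma_bad=float(np.sqrt(2.0) * sigma_good))

    def sigma_for(self, condition: str) -> float:
        if condition == "good":
            return self.sigma_good
        if condition == "bad":
            return self.sigma_bad
        raise ValueError(f"condition must be 'good' or 'bad', got {condition!r}")


@dataclass(frozen=True)
class SceneImageSpec:
    """Parameters of one synthetic scene-category template.

    The template is an oriented sinusoidal luminance texture rendered in a
    fixed hue/saturation palette; ``jitter_scale`` controls how strongly each
    generated image perturbs the template (orientation, frequency, phase,
    palette and pixel noise all scale with it).
    """

    category_id: int
    dominant_orientation: float  # radians
    dominant_frequency: float  # cycles / pixel
    hue: float  # [0, 1)
    saturation: float  # [0, 1]
    jitter_scale: float = 0.3
    image_size: tuple[int, int] = (450, 600)  # (rows, cols)

    def __post_init__(self) -> None:
        if self.jitter_scale < 0:
            raise ValueError("jitter_scale must be >= 0")
        if self.image_size[0] <= 0 or self.image_size[1] <= 0:
            raise ValueError("image dimensions must be positive")


def default_scene_specs(jitter_scale: float, image_size: tuple[int, int] = (450, 600)) -> list[SceneImageSpec]:
    """One template per category, with distinct orientation/frequency/palette."""
    specs = []
    for k, _name in enumerate(CATEGORY_NAMES):
        specs.append(
            SceneImageSpec(
                category_id=k,
                dominant_orientation=k * np.pi / N_CATEGORIES,
                dominant_frequency=0.02 + 0.015 * k,
                hue=(0.05 + k / N_CATEGORIES) % 1.0,
                saturation=0.45 + 0.08 * (k % 3),
                jitter_scale=jitter_scale,
                image_size=image_size,
            )
        )
    return specs


def _render_scene(spec: SceneImageSpec, orientation: float, frequency: float, phase: float,
                  hue: float, saturation: float, value_noise: np.ndarray | float) -> np.ndarray:
    rows, cols = spec.image_size
    y, x = np.mgrid[0:rows, 0:cols].astype(float)
    u = x * np.cos(orientation) + y * np.sin(orientation)
    grating = np.cos(2.0 * np.pi * frequency * u + phase)
    value = np.clip(0.55 + 0.35 * grating + value_noise, 0.0, 1.0)
    hsv = np.empty((rows, cols, 3))
    hsv[..., 0] = hue % 1.0
    hsv[..., 1] = np.clip(saturation, 0.0, 1.0)
    hsv[..., 2] = value
    rgb = hsv2rgb(hsv)
    return (np.clip(rgb, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def scene_template(spec: SceneImageSpec) -> np.ndarray:
    """The unperturbed category template (what every image collapses to at jitter 0)."""
    return _render_scene(spec, spec.dominant_orientation, spec.dominant_frequency, 0.0,
                         spec.hue, spec.saturation, 0.0)


def generate_scene_image_set(spec: SceneImageSpec, n_images: int, rng_seed: int) -> np.ndarray:
    """Generate ``n_images`` RGB images around the category template.

    Returns a uint8 array of shape ``(n_images, rows, cols, 3)``.  Each image
    perturbs the template's orientation, frequency, phase, palette and adds
    pixel luminance noise, all with magnitude proportional to
    ``spec.jitter_scale``; at jitter 0 the images are pixel-identical.
    """
    if n_images < 2:
        raise ValueError("n_images must be >= 2 (set variance is undefined otherwise)")
    rng = np.random.default_rng(rng_seed)
    j = spec.jitter_scale
    rows, cols = spec.image_size
    out = np.empty((n_images, rows, cols, 3), dtype=np.uint8)
    for i in range(n_images):
        d_theta = 0.20 * j * rng.standard_normal()
        f_mult = float(np.exp(0.15 * j * rng.standard_normal()))
        phase = 1.5 * j * rng.standard_normal()
        d_hue = 0.05 * j * rng.standard_normal()
        d_sat = 0.10 * j * rng.standard_normal()
        noise = 0.08 * j * rng.standard_normal((rows, cols))
        out[i] = _render_scene(
            spec,
            spec.dominant_orientation + d_theta,
            spec.dominant_frequency * f_mult,
            phase,
            spec.hue + d_hue,
            spec.saturation + d_sat,
            noise,
        )
    return out


def save_image_set(images: np.ndarray, out_dir: str | Path, prefix: str = "img") -> list[Path]:
    """Write an image set as 8-bit RGB PNGs; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, img in enumerate(images):
        p = out_dir / f"{prefix}_{i:04d}.png"
        Image.fromarray(np.asarray(img, dtype=np.uint8)).save(p)
        paths.append(p)
    return paths


def generate_prototypes(n_voxels: int, separation: float = 1.0, rng_seed: int = 0) -> CategoryPrototypeSet:
    """Synthesize six category-mean voxel patterns.

    Each prototype is an independent Gaussian draw scaled by ``separation``;
    expected pairwise Euclidean distance is separation * sqrt(2 * n_voxels),
    so it grows monotonically with the separation parameter and collapses to
    zero (identical prototypes) at separation 0.
    """
    if n_voxels < 2:
        raise ValueError("n_voxels must be >= 2")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(rng_seed)
    protos = separation * rng.standard_normal((N_CATEGORIES, n_voxels))
    return CategoryPrototypeSet(CATEGORY_NAMES, protos)


# --------------------------------------------------------------------------
# Rating tables


def generate_rating_table(
    n_raters: int,
    n_trials_per_rater: int,
    planted_bad_raters: int = 0,
    rng_seed: int = 0,
    n_images: int = 240,
) -> pd.DataFrame:
    """Simulate a crowdsourced rating session with periodic check trials.

    Trials are 1-based per rater; every 11th trial (11, 22, 33, ...) is a check
    trial repeating an image chosen uniformly from that rater's preceding 10
    trials, so one check follows each group of 10 regular trials.  Consistent
    raters answer deterministically per (rater, image) and therefore incur a
    discount of zero.  The first ``planted_bad_raters`` raters instead flip the
    category label on every check trial (discount 5 per check), so with at
    least three checks per rater their total discount exceeds the exclusion
    threshold of 10.

    Returns a DataFrame with columns
    ``rater_id, trial, image_id, response, rating, is_check, refers_to``.
    """
    if n_trials_per_rater < 11:
        raise ValueError("n_trials_per_rater must be >= 11 (need at least one check trial)")
    if planted_bad_raters > n_raters:
        raise ValueError("planted_bad_raters cannot exceed n_raters")
    if planted_bad_raters < 0:
        raise ValueError("planted_bad_raters must be >= 0")
    n_checks = n_trials_per_rater // 11
    if planted_bad_raters > 0 and 5 * n_checks <= 10:
        raise ValueError(
            "planted raters can only exceed the discount threshold with >= 3 check "
            "trials; use n_trials_per_rater >= 33"
        )
    rng = np.random.default_rng(rng_seed)
    image_category = rng.integers(0, N_CATEGORIES, size=n_images)
    image_rating = rng.integers(1, 6, size=n_images)  # latent 1..5 goodness

    records: list[tuple] = []
    for r in range(n_raters):
        rater_id = f"rater_{r:03d}"
        is_bad = r < planted_bad_raters
        # deterministic per-(rater, image) response for self-consistency
        bias = int(rng.integers(-1, 2))
        history: list[int] = []  # image ids of preceding trials (1-based order)
        trial = 0
        while trial < n_trials_per_rater:
            trial += 1
            if trial % 11 == 0:
                lo = max(0, len(history) - 10)
                ref_pos = int(rng.integers(lo, len(history)))
                img = history[ref_pos]
                cat = int(image_category[img])
                rating = int(np.clip(image_rating[img] + bias, 1, 5))
                if is_bad:
                    response = CATEGORY_NAMES[(cat + 1 + int(rng.integers(0, N_CATEGORIES - 1))) % N_CATEGORIES]
                else:
                    response = CATEGORY_NAMES[cat]
                records.append(
                    (rater_id, trial, int(img), response, rating, True, _regular_position_to_trial(ref_pos))
                )
            else:
                img = int(rng.integers(0, n_images))
                cat = int(image_category[img])
                rating = int(np.clip(image_rating[img] + bias, 1, 5))
                records.append((rater_id, trial, img, CATEGORY_NAMES[cat], rating, False, pd.NA))
                history.append(img)
    df = pd.DataFrame.from_records(records, columns=RATING_COLUMNS)
    df["refers_to"] = df["refers_to"].astype("Int64")
    return df


def _regular_position_to_trial(pos: int) -> int:
    """Map a 0-based index into the regular-trial history to its 1-based session trial."""
    k = pos + 1  # 1-based regular-trial count
    return k + (k - 1) // 10


def write_rating_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_rating_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["refers_to"] = df["refers_to"].astype("Int64")
    df["is_check"] = df["is_check"].astype(bool)
    return df
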