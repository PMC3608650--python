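"""BOLD time-course simulation for block and event-related scene experiments.

The generative model: neural activity for an exemplar of category *c* is a
draw from an isotropic multivariate Gaussian centered on the category
prototype (mean pattern) with per-voxel standard deviation sigma.  Activity is
laid out on a fine time grid (zero during fixation, a fresh exemplar draw per
1.6 s image slot), convolved with a gamma-variate hemodynamic response
function, sampled at the scanner TR of 2 s, and corrupted by i.i.d. Gaussian
measurement noise.  Voxels are independent throughout (no spatial noise
correlations are modeled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .synthetic_data import CategoryPrototypeSet, ExemplarVarianceSpec, N_CATEGORIES

TR_DEFAULT = 2.0
HRF_SUPPORT = 32.0  # seconds; gamma-variate tail mass beyond this < 1e-6 of peak


@dataclass(frozen=True)
class HRFParams:
    """Gamma-variate HRF, h(t) = (t / (p q))**p * exp(p - t / q), unit peak at t = p q."""

    p: float = 8.6  # shape exponent (dimensionless)
    q: float = 0.547  # time constant (seconds)

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("HRF parameters p and q must be positive")

    @property
    def peak_time(self) -> float:
        return self.p * self.q


def hrf_kernel(params: HRFParams = HRFParams(), dt: float = 0.1, duration: float = HRF_SUPPORT) -> np.ndarray:
    """Sample the gamma-variate HRF on a grid of step ``dt`` over ``[0, duration]``.

    The sampled kernel is normalized to unit peak; h(0) = 0 exactly.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = np.arange(0.0, duration + dt / 2, dt)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(t > 0, (t / (params.p * params.q)) ** params.p * np.exp(params.p - t / params.q), 0.0)
    return h / h.max()


@dataclass(frozen=True)
class BlockDesign:
    """Timing of one blocked run: fixation / 16 s category blocks / fixation.

    The literal sum 12 + 6 x (16 + 12) is 180 s; the default appends an extra
    12 s of final fixation for a 192 s run (96 volumes at TR 2 s), the
    convention this package adopts; set ``extra_final_fixation = 0`` for the
    180 s reading.
    """

    initial_fixation: float = 12.0
    block_duration: float = 16.0
    images_per_block: int = 10
    image_duration: float = 1.6
    interblock_fixation: float = 12.0
    blocks_per_run: int = 6
    extra_final_fixation: float = 12.0

    def __post_init__(self) -> None:
        if abs(self.block_duration - self.images_per_block * self.image_duration) > 1e-9:
            raise ValueError("block_duration must equal images_per_block * image_duration")

    @property
    def block_onsets(self) -> np.ndarray:
        step = self.block_duration + self.interblock_fixation
        return self.initial_fixation + step * np.arange(self.blocks_per_run)

    @property
    def run_duration(self) -> float:
        return (
            self.initial_fixation
            + self.blocks_per_run * (self.block_duration + self.interblock_fixation)
            + self.extra_final_fixation
        )


@dataclass(frozen=True)
class EventDesign:
    """Timing of one fast event-related run: 60 interleaved 1.6 s trials."""

    initial_fixation: float = 12.0
    trial_stimulus: float = 1.6
    trial_fixation: float = 2.4
    trials_per_run: int = 60
    trials_per_category: int = 10
    final_fixation: float = 12.0

    def __post_init__(self) -> None:
        if self.trials_per_run != self.trials_per_category * N_CATEGORIES:
            raise ValueError("trials_per_run must be trials_per_category * 6")

    @property
    def trial_onsets(self) -> np.ndarray:
        step = self.trial_stimulus + self.trial_fixation
        return self.initial_fixation + step * np.arange(self.trials_per_run)

    @property
    def run_duration(self) -> float:
        return (
            self.initial_fixation
            + self.trials_per_run * (self.trial_stimulus + self.trial_fixation)
            + self.final_fixation
        )


@dataclass
class ScanRun:
    """A TR-sampled voxel x time matrix plus its event table.

    ``data`` has shape (T, V); ``onsets``/``durations``/``labels`` describe the
    blocks or trials; ``condition`` tags the run as good or bad.
    """

    data: np.ndarray
    tr: float
    onsets: np.ndarray
    durations: np.ndarray
    labels: list[str]
    condition: str = "good"
    run_id: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a (T, V) matrix")
        if not (len(self.onsets) == len(self.durations) == len(self.labels)):
            raise ValueError("onsets, durations and labels must have equal length")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    # -- serialization ----------------------------------------------------

    def to_npz(self, path: str | Path) -> None:
        np.savez(
            path,
            data=self.data,
            tr=self.tr,
            onsets=self.onsets,
            durations=self.durations,
            labels=np.asarray(self.labels, dtype=object),
            condition=self.condition,
            run_id=self.run_id,
        )

    @classmethod
    def from_npz(cls, path: str | Path) -> "ScanRun":
        with np.load(path, allow_pickle=True) as z:
            return cls(
                data=z["data"],
                tr=float(z["tr"]),
                onsets=z["onsets"],
                durations=z["durations"],
                labels=[str(x) for x in z["labels"]],
                condition=str(z["condition"]),
                run_id=int(z["run_id"]),
            )

    def to_nifti(self, nifti_path: str | Path, events_path: str | Path) -> None:
        """Write a 4-D NIfTI (V voxels laid out on the first axis) + BIDS-style events TSV."""
        import nibabel as nib

        vol = self.data.T.reshape(self.n_voxels, 1, 1, self.n_volumes)
        img = nib.Nifti1Image(vol, affine=np.eye(4))
        img.header["pixdim"][4] = self.tr
        nib.save(img, str(nifti_path))
        events = pd.DataFrame(
            {"onset": self.onsets, "duration": self.durations, "trial_type": self.labels}
        )
        events.to_csv(events_path, sep="\t", index=False)

    @classmethod
    def from_nifti(cls, nifti_path: str | Path, events_path: str | Path,
                   condition: str = "good", run_id: int = 0) -> "ScanRun":
        import nibabel as nib

        img = nib.load(str(nifti_path))
        arr = np.asarray(img.dataobj)
        data = arr.reshape(-1, arr.shape[-1]).T
        tr = float(img.header["pixdim"][4])
        events = pd.read_csv(events_path, sep="\t")
        return cls(
            data=data,
            tr=tr,
            onsets=events["onset"].to_numpy(float),
            durations=events["duration"].to_numpy(float),
            labels=[str(x) for x in events["trial_type"]],
            condition=condition,
            run_id=run_id,
        )


@dataclass
class SimulationConfig:
    """Everything the simulator needs besides the per-run stimulus order.

    ``sigma_noise`` is the SD of the white measurement noise added to the
    TR-sampled BOLD signal, in the same activation units as the prototypes.
    When ``prototypes`` is None, experiment drivers synthesize a fresh
    prototype set per subject from ``n_voxels`` and ``separation``.
    """

    prototypes: CategoryPrototypeSet | None = None
    variance_spec: ExemplarVarianceSpec = field(
        default_factory=lambda: ExemplarVarianceSpec.with_double_variance(1.25)
    )
    sigma_noise: float = 3.5
    n_voxels: int = 100
    separation: float = 0.18
    n_subjects: int = 8
    n_repetitions: int = 100
    fine_dt: float = 0.1
    tr: float = TR_DEFAULT
    hrf: HRFParams = field(default_factory=HRFParams)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")
        for period in (1.6, self.tr):
            ratio = period / self.fine_dt
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(f"fine_dt must evenly divide {period}")


# --------------------------------------------------------------------------
# Generative steps


def sample_exemplar_pattern(
    prototypes: CategoryPrototypeSet, category: str, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """One exemplar's activity: prototype + isotropic Gaussian noise of SD sigma."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    idx = prototypes.index_of(category)
    mu = prototypes.prototypes[idx]
    if sigma == 0:
        return mu.copy()
    return mu + sigma * rng.standard_normal(mu.shape)


def _fine_grid(run_duration: float, dt: float) -> int:
    n = run_duration / dt
    if abs(n - round(n)) > 1e-9:
        raise ValueError("fine_dt must evenly divide the run duration")
    return int(round(n))


def block_neural_time_course(
    design: BlockDesign,
    prototypes: CategoryPrototypeSet,
    category_order: Sequence[str],
    sigma: float,
    rng: np.random.Generator,
    dt: float = 0.1,
) -> np.ndarray:
    """Fine-grid neural activity (n_fine, V): zero at fixation, a fresh exemplar per slot."""
    if sorted(category_order) != sorted(prototypes.category_names):
        raise ValueError("category_order must be a permutation of the six categories")
    n_fine = _fine_grid(design.run_duration, dt)
    neural = np.zeros((n_fine, prototypes.n_voxels))
    slot_len = int(round(design.image_duration / dt))
    for onset, cat in zip(design.block_onsets, category_order):
        for s in range(design.images_per_block):
            i0 = int(round((onset + s * design.image_duration) / dt))
            neural[i0 : i0 + slot_len] = sample_exemplar_pattern(prototypes, cat, sigma, rng)
    return neural


def event_neural_time_course(
    design: EventDesign,
    prototypes: CategoryPrototypeSet,
    trial_order: Sequence[str],
    sigma: float,
    rng: np.random.Generator,
    dt: float = 0.1,
) -> np.ndarray:
    from collections import Counter

    counts = Counter(trial_order)
    expected = {c: design.trials_per_category for c in prototypes.category_names}
    if dict(counts) != expected:
        raise ValueError("trial_order must contain each category exactly "
                         f"{design.trials_per_category} times")
    n_fine = _fine_grid(design.run_duration, dt)
    neural = np.zeros((n_fine, prototypes.n_voxels))
    slot_len = int(round(design.trial_stimulus / dt))
    for onset, cat in zip(design.trial_onsets, trial_order):
        i0 = int(round(onset / dt))
        neural[i0 : i0 + slot_len] = sample_exemplar_pattern(prototypes, cat, sigma, rng)
    return neural


def convolve_and_sample(
    neural: np.ndarray, dt: float, tr: float, hrf: HRFParams = HRFParams()
) -> np.ndarray:
    """Convolve fine-grid activity with the HRF and sample at the TR.

    Discrete FIR convolution scaled by dt (so amplitudes approximate the
    continuous convolution and are independent of the grid step); the kernel
    is truncated at 32 s.
    """
    h = hrf_kernel(hrf, dt=dt) * dt
    bold = fftconvolve(neural, h[:, None], axes=0)[: neural.shape[0]]
    stride = int(round(tr / dt))
    return bold[::stride]


def _make_run(
    neural: np.ndarray,
    design_duration: float,
    onsets: np.ndarray,
    durations: np.ndarray,
    labels: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator,
    condition: str,
    run_id: int,
) -> ScanRun:
    data = convolve_and_sample(neural, config.fine_dt, config.tr, config.hrf)
    if config.sigma_noise > 0:
        data = data + config.sigma_noise * rng.standard_normal(data.shape)
    return ScanRun(
        data=data,
        tr=config.tr,
        onsets=onsets,
        durations=durations,
        labels=list(labels),
        condition=condition,
        run_id=run_id,
    )


def simulate_block_run(
    design: BlockDesign,
    config: SimulationConfig,
    category_order: Sequence[str],
    rng: np.random.Generator,
    condition: str = "good",
    run_id: int = 0,
) -> ScanRun:
    """Simulate one blocked run for the given condition ('good' or 'bad')."""
    prototypes = config.prototypes
    if prototypes is None:
        raise ValueError("config.prototypes must be set to simulate a run")
    sigma = config.variance_spec.sigma_for(condition)
    neural = block_neural_time_course(design, prototypes, category_order, sigma, rng, config.fine_dt)
    return _make_run(
        neural,
        design.run_duration,
        design.block_onsets,
        np.full(design.blocks_per_run, design.block_duration),
        category_order,
        config,
        rng,
        condition,
        run_id,
    )


def simulate_event_run(
    design: EventDesign,
    config: SimulationConfig,
    trial_order: Sequence[str],
    rng: np.random.Generator,
    condition: str = "good",
    run_id: int = 0,
) -> ScanRun:
    """Simulate one fast event-related run (60 trials, 10 per category)."""
    prototypes = config.prototypes
    if prototypes is None:
        raise ValueError("config.prototypes must be set to simulate a run")
    sigma = config.variance_spec.sigma_for(condition)
    neural = event_neural_time_course(design, prototypes, trial_order, sigma, rng, config.fine_dt)
    return _make_run(
        neural,
        design.run_duration,
        design.trial_onsets,
        np.full(design.trials_per_run, design.trial_stimulus),
        trial_order,
        config,
        rng,
        condition,
        run_id,
    )


def convolved_regressor(
    onsets: Sequence[float],
    event_duration: float,
    n_volumes: int,
    tr: float,
    hrf: HRFParams = HRFParams(),
    dt: float = 0.1,
) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at the TR (length n_volumes)."""
    n_fine = int(round(n_volumes * tr / dt))
    box = np.zeros(n_fine)
    slot = max(1, int(round(event_duration / dt)))
    for onset in onsets:
        i0 = int(round(onset / dt))
        box[i0 : i0 + slot] = 1.0
    h = hrf_kernel(hrf, dt=dt) * dt
    conv = fftconvolve(box, h)[:n_fine]
    stride = int(round(tr / dt))
    return conv[::stride]


def event_glm_betas(run: ScanRun, hrf: HRFParams = HRFParams()) -> tuple[np.ndarray, list[str]]:
    """Per-category response patterns from a single event-related run.

    Fits, per voxel, an ordinary least-squares regression of the TR-sampled
    series on six HRF-convolved category regressors plus an intercept, and
    returns the (6, V) matrix of category beta patterns together with the
    category list (sorted label order).
    """
    categories = sorted(set(run.labels))
    if len(categories) != N_CATEGORIES:
        raise ValueError(f"expected {N_CATEGORIES} categories in the run, got {len(categories)}")
    cols = []
    for cat in categories:
        onsets = [o for o, lab in zip(run.onsets, run.labels) if lab == cat]
        dur = float(run.durations[0])
        cols.append(convolved_regressor(onsets, dur, run.n_volumes, run.tr, hrf))
    X = np.column_stack(cols + [np.ones(run.n_volumes)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("event design matrix is rank deficient")
    betas, *_ = np.linalg.lstsq(X, run.data, rcond=None)
    return betas[: len(categories)], categories
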