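"""Univariate general-linear-model analyses of (simulated) BOLD runs.

Condition boxcars are convolved with the gamma-variate HRF, scaled to unit
peak, and fit per voxel by ordinary least squares.  The module reports percent
signal change (100 * beta / intercept, averaged over voxels), a pooled
residual-based estimate of the measurement-noise SD (the quantity that
calibrates the simulator), and the first-half/second-half block variant that
feeds a 2x2 repeated-measures ANOVA (condition x block half) for detecting
repetition suppression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .neural_sim import HRFParams, ScanRun, convolved_regressor


@dataclass
class DesignMatrix:
    """T x k design with named columns; the last column is the intercept."""

    X: np.ndarray
    columns: list[str]
    tr: float

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("X and column names are inconsistent")

    @property
    def task_columns(self) -> list[str]:
        return [c for c in self.columns if c != "intercept"]


def build_design_matrix(
    onsets: Sequence[float],
    durations: Sequence[float],
    labels: Sequence[str],
    n_volumes: int,
    tr: float,
    hrf: HRFParams = HRFParams(),
    halves: bool = False,
    conditions: Sequence[str] | None = None,
    dt: float = 0.1,
) -> DesignMatrix:
    """HRF-convolved boxcar design sampled at the TR, one column per condition.

    With ``halves=True`` every event is split into two sub-events of half its
    duration ("<label>:first" and "<label>:second"), the decomposition used to
    probe repetition suppression across a block.  Task columns are scaled to
    unit peak; an intercept column is appended.  Overlapping events within a
    column and declared conditions with no events are rejected.
    """
    onsets = list(map(float, onsets))
    durations = list(map(float, durations))
    labels = list(labels)
    if not (len(onsets) == len(durations) == len(labels)):
        raise ValueError("onsets, durations and labels must have equal length")
    events: list[tuple[float, float, str]] = []
    if halves:
        for o, d, lab in zip(onsets, durations, labels):
            events.append((o, d / 2.0, f"{lab}:first"))
            events.append((o + d / 2.0, d / 2.0, f"{lab}:second"))
    else:
        events = list(zip(onsets, durations, labels))

    seen_order = list(dict.fromkeys(lab for _, _, lab in events))
    if conditions is not None:
        if halves:
            wanted = [f"{c}:{h}" for c in conditions for h in ("first", "second")]
        else:
            wanted = list(conditions)
        missing = [c for c in wanted if c not in seen_order]
        if missing:
            raise ValueError(f"declared condition(s) with no events: {missing}")
        seen_order = wanted

    cols = []
    for cond in seen_order:
        ev = sorted((o, d) for o, d, lab in events if lab == cond)
        for (o1, d1), (o2, _) in zip(ev, ev[1:]):
            if o1 + d1 > o2 + 1e-9:
                raise ValueError(f"overlapping events in column {cond!r} at onsets {o1} and {o2}")
        reg = np.zeros(n_volumes)
        for o, d in ev:
            reg += convolved_regressor([o], d, n_volumes, tr, hrf, dt)
        peak = reg.max()
        if peak <= 0:
            raise ValueError(f"column {cond!r} is all zero over the run")
        cols.append(reg / peak)
    X = np.column_stack(cols + [np.ones(n_volumes)])
    return DesignMatrix(X, seen_order + ["intercept"], tr)


@dataclass
class GlmFit:
    """Per-voxel OLS betas, residual diagnostics, and percent signal change."""

    design: DesignMatrix
    betas: np.ndarray  # (k, V)
    residuals: np.ndarray  # (T, V)
    residual_sd: float  # pooled, df-corrected
    percent_signal_change: dict[str, float]  # per task column, averaged over voxels

    def beta(self, column: str) -> np.ndarray:
        return self.betas[self.design.columns.index(column)]


def fit_glm(run_or_data: ScanRun | np.ndarray, design: DesignMatrix) -> GlmFit:
    """Ordinary least squares per voxel.

    Percent signal change for a task column is 100 * beta / intercept per
    voxel (task regressors are unit-peak), averaged over voxels.  The pooled
    residual SD is sqrt(RSS_total / (V * (T - k))), an unbiased estimate of
    the white measurement-noise SD when the model captures the signal.
    """
    Y = run_or_data.data if isinstance(run_or_data, ScanRun) else np.asarray(run_or_data, dtype=float)
    X = design.X
    T, k = X.shape
    if Y.shape[0] != T:
        raise ValueError(f"data has {Y.shape[0]} volumes but the design expects {T}")
    if np.linalg.matrix_rank(X) < k:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    betas, *_ = np.linalg.lstsq(X, Y, rcond=None)
    residuals = Y - X @ betas
    V = Y.shape[1]
    residual_sd = float(np.sqrt((residuals**2).sum() / (V * (T - k))))
    intercept = betas[design.columns.index("intercept")]
    psc = {}
    for col in design.task_columns:
        b = betas[design.columns.index(col)]
        psc[col] = float(np.mean(100.0 * b / intercept))
    return GlmFit(design, betas, residuals, residual_sd, psc)


# --------------------------------------------------------------------------
# 2 x 2 repeated-measures ANOVA on the halves decomposition


def halves_table(fit: GlmFit, conditions: Sequence[str] = ("good", "bad")) -> np.ndarray:
    """One subject's 2x2 percent-signal-change table (condition x half)."""
    table = np.empty((len(conditions), 2))
    for i, cond in enumerate(conditions):
        for j, half in enumerate(("first", "second")):
            key = f"{cond}:{half}"
            if key not in fit.percent_signal_change:
                raise ValueError(f"fit lacks halves column {key!r}; fit with halves=True")
            table[i, j] = fit.percent_signal_change[key]
    return table


def _rm_anova_effect(cell_means: np.ndarray, effect: np.ndarray, n_subjects: int,
                     subject_effect: np.ndarray) -> tuple[float, float, float]:
    """F, p, MSE for one within-subject effect of a 2x2 design (1 numerator df)."""
    ss_effect = float((effect**2).sum())
    ss_error = float((subject_effect**2).sum())
    df_error = n_subjects - 1
    mse = ss_error / df_error
    if ss_effect < 1e-12 * max(1.0, float((cell_means**2).sum())):
        return 0.0, 1.0, mse
    if mse < 1e-300:
        return float(np.inf), 0.0, mse
    F = ss_effect / mse
    p = float(stats.f.sf(F, 1, df_error))
    return float(F), p, mse


def halves_contrast(tables: np.ndarray | Sequence[np.ndarray]) -> dict:
    """Two-way repeated-measures ANOVA over per-subject 2x2 PSC tables.

    ``tables`` has shape (n_subjects, 2, 2): axis 1 is condition (good, bad),
    axis 2 is block half (first, second).  Both main effects and the
    interaction are computed by the classical two-within-factor decomposition
    with subject as the blocking factor; each effect is tested against its own
    subject-by-effect interaction with (n-1) denominator df.  All-zero effects
    report F = 0 (rather than the 0/0 indeterminate form).
    """
    Y = np.asarray(tables, dtype=float)
    if Y.ndim != 3 or Y.shape[1:] != (2, 2):
        raise ValueError("tables must have shape (n_subjects, 2, 2)")
    n = Y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    grand = Y.mean()
    subj = Y.mean(axis=(1, 2))  # (n,)
    a = Y.mean(axis=(0, 2))  # condition means (2,)
    b = Y.mean(axis=(0, 1))  # half means (2,)
    ab = Y.mean(axis=0)  # (2, 2)
    # effect estimates (per-cell deviations)
    eff_a = a - grand
    eff_b = b - grand
    eff_ab = ab - a[:, None] - b[None, :] + grand
    sa = Y.mean(axis=2) - subj[:, None] - a[None, :] + grand  # subject x A
    sb = Y.mean(axis=1) - subj[:, None] - b[None, :] + grand  # subject x B
    sab = (Y - Y.mean(axis=2, keepdims=True) - Y.mean(axis=1, keepdims=True)
           - ab[None] + Y.mean(axis=(1, 2), keepdims=True).reshape(n, 1, 1)
           + a[None, :, None] + b[None, None, :] - grand)

    F_a, p_a, mse_a = _rm_anova_effect(ab, np.sqrt(2.0 * n) * eff_a, n, np.sqrt(2.0) * sa)
    F_b, p_b, mse_b = _rm_anova_effect(ab, np.sqrt(2.0 * n) * eff_b, n, np.sqrt(2.0) * sb)
    F_ab, p_ab, mse_ab = _rm_anova_effect(ab, np.sqrt(float(n)) * eff_ab, n, sab)
    return {
        "cell_means": ab,
        "condition": {"F": F_a, "p": p_a, "df": (1, n - 1), "MSE": mse_a},
        "half": {"F": F_b, "p": p_b, "df": (1, n - 1), "MSE": mse_b},
        "interaction": {"F": F_ab, "p": p_ab, "df": (1, n - 1), "MSE": mse_ab},
    }
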