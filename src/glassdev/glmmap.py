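"""Two-predictor GLM mapping, multiple-comparison thresholding, and the
onset-age regression over percent-significant-voxel summaries.

The design has m = 2 columns: the stimulus boxcar convolved with the
hemodynamic response sampled at TR, and a baseline (intercept) column
standing in for the blank predictor. Significance uses a two-sided t-test
on the stimulus contrast; maps are thresholded by Benjamini-Hochberg FDR,
per-VOI percentages by Bonferroni within the VOI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .stimgen import BLANK, PINWHEEL_OFF, StimulusSchedule
from .synthbold import BoldRun, boxcar_predictor

__all__ = [
    "DesignMatrix",
    "GlmResult",
    "OnsetRegression",
    "build_design",
    "fit_glm",
    "fdr_threshold",
    "bonferroni_threshold",
    "threshold",
    "percent_significant",
    "onset_regression",
]


@dataclass(frozen=True)
class DesignMatrix:
    """n_volumes x 2 design: convolved stimulus predictor plus baseline."""

    matrix: np.ndarray
    tr: float
    column_names: tuple[str, ...] = ("stimulus", "baseline")

    def __post_init__(self) -> None:
        if np.any(np.all(self.matrix == 0.0, axis=0)):
            raise ValueError("design contains an all-zero predictor")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.matrix.shape[1]


@dataclass
class GlmResult:
    """Per-voxel OLS estimates and the stimulus-contrast test."""

    betas: np.ndarray  # n_voxels x m
    t: np.ndarray
    p: np.ndarray
    df: int
    contrast: np.ndarray

    def __post_init__(self) -> None:
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p-values outside [0, 1]")

    @property
    def n_voxels(self) -> int:
        return self.t.size


def build_design(
    schedule: StimulusSchedule,
    tr: float,
    hrf_fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> DesignMatrix:
    """Convolve the schedule's stimulus epochs with the HRF, sample at TR."""
    if schedule.total_duration < 2 * tr:
        raise ValueError("schedule must span at least two volumes")
    stim_events = [
        ev for ev in schedule.events if ev.trial_type not in (BLANK, PINWHEEL_OFF)
    ]
    if not stim_events:
        raise ValueError("schedule has no stimulus events")
    pred = boxcar_predictor(
        stim_events, schedule.total_duration, tr, hrf_fn=hrf_fn
    )
    X = np.column_stack([pred, np.ones_like(pred)])
    return DesignMatrix(matrix=X, tr=tr)


def build_contrast_design(
    schedule: StimulusSchedule,
    tr: float,
    contrast_def,
    hrf_fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> DesignMatrix:
    """Design with a signed class-A-minus-class-B predictor plus baseline.

    For the stimulus-vs-blank contrast this reduces to the plain stimulus
    predictor (blank epochs carry no evoked response).
    """
    signed = [
        (ev.onset, ev.duration, float(cls))
        for ev in schedule.events
        for cls in [contrast_def.class_of(ev.trial_type)]
        if cls is not None and ev.trial_type != BLANK
    ]
    if not signed:
        raise ValueError(f"schedule has no events for contrast {contrast_def.name!r}")
    pred = boxcar_predictor(signed, schedule.total_duration, tr, hrf_fn=hrf_fn)
    X = np.column_stack([pred, np.ones_like(pred)])
    return DesignMatrix(matrix=X, tr=tr, column_names=(contrast_def.name, "baseline"))


def fit_glm(
    run: BoldRun | np.ndarray,
    design: DesignMatrix,
    contrast: Sequence[float] = (1.0, 0.0),
) -> GlmResult:
    """Ordinary least squares per voxel with a t-test on ``contrast``.

    t = (c @ beta) / sqrt(sigma^2 * c (X'X)^-1 c'), two-sided p from
    Student's t with n - m degrees of freedom.
    """
    Y = run.data if isinstance(run, BoldRun) else np.asarray(run, dtype=float)
    X = design.matrix
    n, m = X.shape
    if Y.shape[1] != n:
        raise ValueError(f"run has {Y.shape[1]} volumes, design expects {n}")
    if np.linalg.matrix_rank(X) < m:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    c = np.asarray(contrast, dtype=float)
    xtx_inv = np.linalg.inv(X.T @ X)
    betas = Y @ X @ xtx_inv  # n_voxels x m
    resid = Y - betas @ X.T
    df = n - m
    sigma2 = np.sum(resid**2, axis=1) / df
    se = np.sqrt(np.maximum(sigma2 * (c @ xtx_inv @ c), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, betas @ c / np.where(se > 0, se, 1.0), np.inf * np.sign(betas @ c))
    t = np.where((se == 0) & (betas @ c == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return GlmResult(betas=betas, t=t, p=p, df=df, contrast=c)


def fdr_threshold(p: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= q * (np.arange(1, n + 1) / n)
    mask = np.zeros(n, dtype=bool)
    if below.any():
        k = np.max(np.flatnonzero(below))
        mask[order[: k + 1]] = True
    return mask


def bonferroni_threshold(
    p: np.ndarray, alpha: float = 0.05, n_comparisons: int | None = None
) -> np.ndarray:
    """Reject where p < alpha / n, with n the within-VOI voxel count."""
    p = np.asarray(p, dtype=float)
    n = p.size if n_comparisons is None else n_comparisons
    return p < alpha / n


def threshold(
    result: GlmResult,
    method: str = "fdr",
    level: float = 0.05,
    voi_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Significance mask over all voxels of ``result``.

    ``fdr`` applies step-up control at q = level over the supplied voxels;
    ``bonferroni_within_voi`` divides alpha by the VOI voxel count. When
    ``voi_indices`` is given, only those voxels can enter the mask.
    """
    idx = (
        np.arange(result.n_voxels)
        if voi_indices is None
        else np.asarray(voi_indices, dtype=int)
    )
    p = result.p[idx]
    if method == "fdr":
        sub = fdr_threshold(p, q=level)
    elif method == "bonferroni_within_voi":
        sub = bonferroni_threshold(p, alpha=level, n_comparisons=idx.size)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = np.zeros(result.n_voxels, dtype=bool)
    mask[idx[sub]] = True
    return mask


def percent_significant(mask: np.ndarray, voi_indices: np.ndarray) -> float:
    """100 * |mask AND voi| / |voi|."""
    voi_indices = np.asarray(voi_indices, dtype=int)
    if voi_indices.size == 0:
        raise ValueError("VOI is empty")
    return 100.0 * float(np.count_nonzero(mask[voi_indices])) / voi_indices.size


@dataclass
class OnsetRegression:
    """Line fit to percent-significant-voxels vs age, with its x-intercept.

    ``qualified`` is False when fewer than the required number of
    consecutive significant sessions exist or the fitted slope is not
    positive; the onset age is then undefined.
    """

    qualified: bool
    slope: float = float("nan")
    intercept: float = float("nan")
    r_squared: float = float("nan")
    onset_age: float = float("nan")
    window_start_index: int | None = None
    reason: str = ""


def onset_regression(
    sessions: Sequence[tuple[float, float, bool]],
    min_consecutive: int = 4,
) -> OnsetRegression:
    """Fit percent-significant vs age once a developmental onset is reliable.

    ``sessions`` are (age, percent_significant, significant?) sorted by
    age. The fit qualifies only when ``min_consecutive`` consecutive
    sessions are significant; it then uses the first session of that
    window and all subsequent significant sessions. The onset age is the
    abscissa intercept -intercept/slope (requires slope > 0).
    """
    ages = [s[0] for s in sessions]
    if any(a2 < a1 for a1, a2 in zip(ages, ages[1:])):
        raise ValueError("sessions must be sorted by age")
    flags = [bool(s[2]) for s in sessions]
    start = None
    run_len = 0
    for i, flag in enumerate(flags):
        run_len = run_len + 1 if flag else 0
        if run_len == min_consecutive:
            start = i - min_consecutive + 1
            break
    if start is None:
        return OnsetRegression(
            qualified=False,
            reason=f"fewer than {min_consecutive} consecutive significant sessions",
        )
    pts = [(a, pct) for (a, pct, sig) in sessions[start:] if sig]
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    if not (slope > 0) or not math.isfinite(slope):
        return OnsetRegression(
            qualified=False,
            slope=float(slope),
            intercept=float(intercept),
            r_squared=r2,
            window_start_index=start,
            reason="non-positive or degenerate slope",
        )
    return OnsetRegression(
        qualified=True,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        onset_age=float(-intercept / slope),
        window_start_index=start,
    )
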