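"""Synthetic longitudinal BOLD sessions with known developmental ground truth.

Every downstream stage (detrending, GLM, spectral SNR, MVPA, trajectory
fitting) is exercised against data generated here, since the original
recordings are not deposited. The generator writes sessions in the same
shapes the analysis consumes: voxel-by-volume runs at TR = 6 s, one binary
mask per volume of interest, and a block/blank event schedule.

The developmental structure is a saturating function of age per
(VOI, contrast); its value scales (i) the mean stimulus-evoked amplitude
and (ii) the norm of a class-difference weight vector across voxels, so
multivoxel decodability grows with age under explicit control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .contrasts import ContrastDef, STANDARD_CONTRASTS
from .stimgen import (
    BLANK,
    PINWHEEL_OFF,
    PINWHEEL_ON,
    StimulusSchedule,
    build_palindromic_schedule,
    build_pinwheel_schedule,
    glass_condition_labels,
)

__all__ = [
    "hrf",
    "boxcar_predictor",
    "SaturatingTrajectory",
    "GroundTruthDevelopment",
    "SessionConfig",
    "BoldRun",
    "SyntheticSession",
    "simulate_run",
    "simulate_session",
    "make_longitudinal_study",
    "default_ground_truth",
]

DEFAULT_VOIS = ("V1", "V4", "MT-V5")

#: canonical double-gamma parameters (response delay 6 s, undershoot delay
#: 16 s, dispersions 1, undershoot ratio 1/6)
_HRF_SHAPE1 = 6.0
_HRF_SHAPE2 = 16.0
_HRF_RATIO = 1.0 / 6.0


def hrf(t: np.ndarray | float) -> np.ndarray:
    """Double-gamma hemodynamic impulse response, peak-normalized to 1.

    Difference of two gamma densities peaking near 5 s with a late
    undershoot; zero for t <= 0.
    """
    t = np.asarray(t, dtype=float)
    h = _gamma_dist.pdf(t, _HRF_SHAPE1) - _HRF_RATIO * _gamma_dist.pdf(t, _HRF_SHAPE2)
    peak_grid = np.arange(0.0, 32.0, 0.01)
    peak = np.max(
        _gamma_dist.pdf(peak_grid, _HRF_SHAPE1)
        - _HRF_RATIO * _gamma_dist.pdf(peak_grid, _HRF_SHAPE2)
    )
    return h / peak


def boxcar_predictor(
    events: Sequence,
    total_duration: float,
    tr: float,
    dt: float = 0.1,
    hrf_fn=None,
) -> np.ndarray:
    """Convolve a set of (onset, duration) epochs with the HRF, sampled at TR.

    ``events`` may carry signed weights as ``(onset, duration, weight)``
    triples; plain schedule events get weight +1. The fine-grid convolution
    is sampled at volume acquisition times k * tr.
    """
    n_fine = int(round(total_duration / dt))
    box = np.zeros(n_fine)
    tgrid = np.arange(n_fine) * dt
    for ev in events:
        if isinstance(ev, tuple):
            onset, duration, weight = (*ev, 1.0)[:3]
        else:
            onset, duration, weight = ev.onset, ev.duration, 1.0
        box[(tgrid >= onset) & (tgrid < onset + duration)] += weight
    kernel = (hrf_fn or hrf)(np.arange(0.0, 32.0, dt))
    conv = np.convolve(box, kernel)[:n_fine] * dt
    n_vol = int(math.floor(total_duration / tr + 1e-9))
    idx = np.minimum((np.arange(n_vol) * tr / dt).astype(int), n_fine - 1)
    return conv[idx]


def hrf_plateau() -> float:
    """Steady-state level a unit sustained boxcar reaches after HRF convolution."""
    dt = 0.01
    return float(np.sum(hrf(np.arange(0.0, 32.0, dt))) * dt)


@dataclass(frozen=True)
class SaturatingTrajectory:
    """Hyperbolic-ratio growth of target discriminability with age (months).

    value(A) = d0 + dmax * A**n / (a_half**n + A**n)
    """

    dmax: float
    a_half: float
    shape: float = 2.0
    d0: float = 0.0

    def __post_init__(self) -> None:
        if self.dmax < 0:
            raise ValueError("dmax must be >= 0")
        if not (0.0 < self.shape <= 4.0):
            raise ValueError("shape must be in (0, 4]")

    def __call__(self, age: np.ndarray | float) -> np.ndarray | float:
        a = np.asarray(age, dtype=float)
        out = self.d0 + self.dmax * a**self.shape / (
            self.a_half**self.shape + a**self.shape
        )
        return float(out) if np.isscalar(age) else out


@dataclass(frozen=True)
class GroundTruthDevelopment:
    """Per-(VOI, contrast) developmental targets plus BOLD mapping constants.

    ``amp_scale`` converts the stimulus-vs-blank target into the mean
    stimulus-evoked amplitude (intensity units); ``weight_scale`` converts
    a contrast's target into the norm of its class-difference weight
    vector. Both mappings are modelling conveniences, not measured
    physiology.
    """

    trajectories: Mapping[tuple[str, str], SaturatingTrajectory]
    amp_scale: float = 0.5
    weight_scale: float = 0.25

    def target(self, voi: str, contrast: str, age: float) -> float:
        traj = self.trajectories.get((voi, contrast))
        return 0.0 if traj is None else float(traj(age))

    def vois(self) -> list[str]:
        return sorted({voi for voi, _ in self.trajectories})


def default_ground_truth(
    a_half: Mapping[str, float] | None = None,
    dmax: float = 6.0,
    shape: float = 2.0,
    amp_scale: float = 0.5,
    weight_scale: float = 0.25,
) -> GroundTruthDevelopment:
    """Ground truth with an early V1 and delayed extrastriate trajectory.

    The structured-vs-random contrast is generated with zero class signal,
    modelling the absence of reliable form selectivity.
    """
    if a_half is None:
        a_half = {"V1": 12.0, "V4": 28.0, "MT-V5": 28.0}
    traj: dict[tuple[str, str], SaturatingTrajectory] = {}
    for voi, ah in a_half.items():
        traj[(voi, "stimulus_vs_blank")] = SaturatingTrajectory(dmax, ah, shape)
        traj[(voi, "dynamic_vs_static")] = SaturatingTrajectory(dmax, ah, shape)
        traj[(voi, "structured_vs_random")] = SaturatingTrajectory(0.0, ah, shape)
    return GroundTruthDevelopment(traj, amp_scale=amp_scale, weight_scale=weight_scale)


@dataclass(frozen=True)
class SessionConfig:
    """Everything needed to simulate one scanning session."""

    age: float
    tr: float = 6.0
    n_voxels: Mapping[str, int] = field(
        default_factory=lambda: {v: 80 for v in DEFAULT_VOIS}
    )
    baseline: float = 1000.0
    noise_sd: float = 8.0
    drift_slope_range: tuple[float, float] = (-0.02, 0.02)
    ar1_coef: float = 0.0
    n_runs: int = 1
    schedule: StimulusSchedule | None = None
    pinwheel_duration: float = 576.0
    pinwheel_amp: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for voi, n in self.n_voxels.items():
            if n < 1:
                raise ValueError(f"n_voxels[{voi!r}] must be >= 1")

    @property
    def voi_labels(self) -> list[str]:
        return list(self.n_voxels)

    @property
    def total_voxels(self) -> int:
        return sum(self.n_voxels.values())


@dataclass
class BoldRun:
    """One run: voxel x volume intensities plus schedule and VOI membership."""

    data: np.ndarray
    tr: float
    schedule: StimulusSchedule
    voi_of_voxel: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("run contains non-finite intensities")
        expected = self.schedule.n_volumes(self.tr)
        if self.data.shape[1] != expected:
            raise ValueError(
                f"volume count {self.data.shape[1]} != floor(duration/tr) = {expected}"
            )

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def voi_indices(self, voi: str) -> np.ndarray:
        return np.flatnonzero(self.voi_of_voxel == voi)

    def voi_mean_series(self, voi: str) -> np.ndarray:
        idx = self.voi_indices(voi)
        if idx.size == 0:
            raise ValueError(f"no voxels labeled {voi!r}")
        return self.data[idx].mean(axis=0)


@dataclass
class SyntheticSession:
    config: SessionConfig
    pinwheel_run: BoldRun
    glass_runs: list[BoldRun]

    @property
    def age(self) -> float:
        return self.config.age

    @property
    def n_patterns(self) -> int:
        """Glass-pattern stimulus blocks across all runs."""
        return sum(
            len([ev for ev in run.schedule.events if ev.trial_type != BLANK])
            for run in self.glass_runs
        )


def _noise(rng: np.random.Generator, shape: tuple[int, int], sd: float, ar1: float):
    eps = rng.standard_normal(shape) * sd
    if ar1 == 0.0 or sd == 0.0:
        return eps
    out = np.empty_like(eps)
    out[:, 0] = eps[:, 0] / math.sqrt(1.0 - ar1**2)
    for t in range(1, shape[1]):
        out[:, t] = ar1 * out[:, t - 1] + eps[:, t]
    return out


def _voi_array(config: SessionConfig) -> np.ndarray:
    return np.concatenate(
        [np.full(n, voi, dtype=object) for voi, n in config.n_voxels.items()]
    )


def simulate_run(
    config: SessionConfig,
    truth: GroundTruthDevelopment,
    schedule: StimulusSchedule,
    rng: np.random.Generator,
    *,
    stim_gain: np.ndarray,
    weights: Mapping[str, np.ndarray],
    contrast_defs: Mapping[str, ContrastDef] | None = None,
) -> BoldRun:
    """Simulate one voxel-by-volume run from explicit session-level factors.

    ``stim_gain`` is the per-voxel stimulus amplitude (already scaled by
    age and VOI); ``weights`` maps contrast name to a per-voxel
    class-difference vector (already norm-scaled). The series is
    baseline + drift + stimulus response + class responses + noise.
    """
    for voi in truth.vois():
        if voi not in config.n_voxels:
            raise ValueError(f"ground truth references VOI {voi!r} absent from config")
    contrast_defs = contrast_defs or STANDARD_CONTRASTS
    duration = schedule.total_duration
    n_vol = schedule.n_volumes(config.tr)
    n_vox = config.total_voxels
    t = np.arange(n_vol) * config.tr

    slopes = rng.uniform(*config.drift_slope_range, size=n_vox)
    data = np.full((n_vox, n_vol), config.baseline, dtype=float)
    data += np.outer(slopes, t - t.mean())

    plateau = hrf_plateau()
    stim_events = [ev for ev in schedule.events if ev.trial_type not in (BLANK, PINWHEEL_OFF)]
    if stim_events:
        # unit-plateau predictor: gains are evoked amplitudes in intensity units
        pred = boxcar_predictor(stim_events, duration, config.tr) / plateau
        data += np.outer(stim_gain, pred)

    for name, w in weights.items():
        cdef = contrast_defs[name]
        signed = [
            (ev.onset, ev.duration, float(cls))
            for ev in schedule.events
            if ev.trial_type != BLANK
            for cls in [cdef.class_of(ev.trial_type)]
            if cls is not None
        ]
        if signed and np.any(w != 0.0):
            pred = boxcar_predictor(signed, duration, config.tr) / plateau
            data += np.outer(w, pred)

    data += _noise(rng, (n_vox, n_vol), config.noise_sd, config.ar1_coef)
    return BoldRun(data=data, tr=config.tr, schedule=schedule, voi_of_voxel=_voi_array(config))


def _session_factors(
    config: SessionConfig, truth: GroundTruthDevelopment, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Draw per-voxel pinwheel gains, stimulus gains, and contrast weights."""
    n_vox = config.total_voxels
    voi_of_voxel = _voi_array(config)
    pinwheel_gain = config.pinwheel_amp * rng.uniform(0.3, 1.0, size=n_vox)

    stim_gain = np.zeros(n_vox)
    weights: dict[str, np.ndarray] = {}
    for voi in config.voi_labels:
        idx = np.flatnonzero(voi_of_voxel == voi)
        target = truth.target(voi, "stimulus_vs_blank", config.age)
        stim_gain[idx] = truth.amp_scale * target * rng.uniform(0.5, 1.5, size=idx.size)
        for cname in ("dynamic_vs_static", "structured_vs_random"):
            target_c = truth.target(voi, cname, config.age)
            w = weights.setdefault(cname, np.zeros(n_vox))
            if target_c > 0:
                raw = rng.standard_normal(idx.size)
                raw /= np.linalg.norm(raw)
                # norm over the VOI grows with the developmental target;
                # sqrt(n) keeps per-voxel amplitude independent of VOI size
                w[idx] = raw * truth.weight_scale * target_c * math.sqrt(idx.size)
    return pinwheel_gain, stim_gain, weights


def simulate_session(
    config: SessionConfig, truth: GroundTruthDevelopment
) -> SyntheticSession:
    """Simulate one session: a pinwheel localizer run plus Glass-pattern runs."""
    rng = np.random.default_rng(config.seed)
    if config.schedule is None:
        config = replace(
            config,
            schedule=build_palindromic_schedule(
                glass_condition_labels(), block_duration=42.0, blank_duration=30.0, n_cycles=5
            ),
        )
    pinwheel_gain, stim_gain, weights = _session_factors(config, truth, rng)

    pin_schedule = build_pinwheel_schedule(config.pinwheel_duration)
    pinwheel_run = simulate_run(
        config, truth, pin_schedule, rng, stim_gain=pinwheel_gain, weights={}
    )
    glass_runs = [
        simulate_run(
            config, truth, config.schedule, rng, stim_gain=stim_gain, weights=weights
        )
        for _ in range(config.n_runs)
    ]
    return SyntheticSession(config=config, pinwheel_run=pinwheel_run, glass_runs=glass_runs)


def make_longitudinal_study(
    ages: Sequence[float],
    template: SessionConfig,
    truth: GroundTruthDevelopment,
    seed: int = 0,
    pattern_count_bounds: tuple[int, int] = (32, 189),
) -> list[SyntheticSession]:
    """One seeded session per age, with per-session pattern counts in bounds.

    Pattern counts (Glass blocks per session) are drawn uniformly over the
    cycle counts compatible with ``pattern_count_bounds`` for the standard
    six-condition palindromic layout.
    """
    if len(ages) == 0:
        raise ValueError("ages must be non-empty")
    lo, hi = pattern_count_bounds
    labels = glass_condition_labels()
    per_cycle = 2 * len(labels)
    cyc_lo = max(1, math.ceil(lo / per_cycle))
    cyc_hi = max(cyc_lo, math.floor(hi / per_cycle))
    master = np.random.SeedSequence(seed)
    sessions = []
    for age, ss in zip(ages, master.spawn(len(ages))):
        rng = np.random.default_rng(ss)
        n_cycles = int(rng.integers(cyc_lo, cyc_hi + 1))
        schedule = build_palindromic_schedule(
            labels, block_duration=42.0, blank_duration=30.0, n_cycles=n_cycles
        )
        cfg = replace(
            template,
            age=float(age),
            schedule=schedule,
            seed=int(rng.integers(0, 2**63 - 1)),
        )
        sessions.append(simulate_session(cfg, truth))
    return sessions
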