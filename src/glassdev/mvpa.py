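"""Multivoxel pattern classification with a binomial chance model.

Voxels are rank-ordered by responsiveness to an independent localizer
(pinwheel) GLM, truncated at 70, and restricted to positive responses.
Patterns are per-epoch voxel means with the boxcar delayed by one volume.
Classification is 8-fold cross-validated linear SVM over held-out
condition pairs; chance is the 95% binomial quantile proportion for the
number of patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .contrasts import ContrastDef
from .glmmap import GlmResult
from .stimgen import StimulusSchedule
from .synthbold import BoldRun

__all__ = [
    "DEFAULT_TRUNCATION",
    "ContrastNotApplicableError",
    "VoxelRanking",
    "PatternMatrix",
    "ChanceLevel",
    "ClassificationResult",
    "rank_voxels",
    "assemble_patterns",
    "chance_level",
    "crossvalidate",
]

DEFAULT_TRUNCATION = 70
N_FOLDS = 8


class ContrastNotApplicableError(ValueError):
    """Session lacks the pattern types a contrast requires; drop it."""


@dataclass
class VoxelRanking:
    """Voxel ids in descending localizer-t order, positives only."""

    voi: str
    voxel_ids: np.ndarray
    t_values: np.ndarray
    truncation: int = DEFAULT_TRUNCATION

    def __len__(self) -> int:
        return self.voxel_ids.size

    @property
    def empty(self) -> bool:
        return self.voxel_ids.size == 0


def rank_voxels(
    pinwheel_glm: GlmResult,
    voi_indices: np.ndarray,
    voi: str = "",
    truncation: int = DEFAULT_TRUNCATION,
) -> VoxelRanking:
    """Rank a VOI's voxels by pinwheel t-value, keep positives, truncate.

    Ties break by ascending voxel index. If fewer than ``truncation``
    voxels respond positively, all of them are retained with a warning; an
    all-nonpositive VOI yields an empty ranking (session flagged upstream).
    """
    voi_indices = np.asarray(voi_indices, dtype=int)
    if voi_indices.size == 0:
        raise ValueError(f"VOI {voi!r} is empty")
    t = pinwheel_glm.t[voi_indices]
    positive = t > 0
    ids = voi_indices[positive]
    tv = t[positive]
    # stable sort on (-t, index): descending t, ascending index on ties
    order = np.lexsort((ids, -tv))
    ids, tv = ids[order], tv[order]
    if ids.size == 0:
        warnings.warn(f"VOI {voi!r}: no positively responsive voxels", stacklevel=2)
    elif ids.size < truncation:
        warnings.warn(
            f"VOI {voi!r}: only {ids.size} positive voxels (< {truncation})",
            stacklevel=2,
        )
    return VoxelRanking(
        voi=voi,
        voxel_ids=ids[:truncation],
        t_values=tv[:truncation],
        truncation=truncation,
    )


@dataclass
class PatternMatrix:
    """Epoch-collapsed multivoxel responses with +/-1 class labels.

    Columns follow the voxel ranking order, so column prefixes are the
    growing voxel pools.
    """

    data: np.ndarray
    labels: np.ndarray
    voxel_ids: np.ndarray
    contrast: str

    @property
    def n_patterns(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


def _epoch_volume_indices(
    onset: float, duration: float, tr: float, n_volumes: int, delay_volumes: int = 1
) -> np.ndarray:
    """Volumes whose boxcar (delayed by ``delay_volumes``) covers them."""
    first = int(np.ceil(onset / tr - 1e-9)) + delay_volumes
    last = int(np.ceil((onset + duration) / tr - 1e-9)) + delay_volumes
    return np.arange(max(first, 0), min(last, n_volumes))


def assemble_patterns(
    runs: list[BoldRun] | BoldRun,
    contrast: ContrastDef,
    ranking: VoxelRanking,
    delay_volumes: int = 1,
) -> PatternMatrix:
    """Per-epoch voxel means (one-volume delayed) for one contrast.

    Runs sharing a schedule are averaged voxelwise before epoch
    extraction; runs with distinct schedules contribute their epochs
    separately. Raises :class:`ContrastNotApplicableError` when the
    session lacks a pattern type on either side of the contrast.
    """
    if isinstance(runs, BoldRun):
        runs = [runs]
    if not runs:
        raise ValueError("no runs supplied")
    if ranking.empty:
        raise ValueError("voxel ranking is empty")

    conditions = {c for run in runs for c in run.schedule.conditions}
    if not contrast.applicable(conditions):
        raise ContrastNotApplicableError(
            f"contrast {contrast.name!r} not applicable: session presents {sorted(conditions)}"
        )

    # group runs by schedule identity and average repeats
    groups: dict[int, list[BoldRun]] = {}
    keys: dict[int, StimulusSchedule] = {}
    for run in runs:
        key = hash(tuple((ev.onset, ev.duration, ev.trial_type) for ev in run.schedule.events))
        groups.setdefault(key, []).append(run)
        keys[key] = run.schedule

    rows, labels = [], []
    for key, grp in groups.items():
        data = np.mean([r.data for r in grp], axis=0)
        schedule = keys[key]
        tr = grp[0].tr
        n_vol = data.shape[1]
        for ev in schedule.events:
            cls = contrast.class_of(ev.trial_type)
            if cls is None:
                continue
            vols = _epoch_volume_indices(ev.onset, ev.duration, tr, n_vol, delay_volumes)
            if vols.size == 0:
                continue
            rows.append(data[np.ix_(ranking.voxel_ids, vols)].mean(axis=1))
            labels.append(cls)
    if not rows:
        raise ContrastNotApplicableError(
            f"contrast {contrast.name!r}: no usable epochs in session"
        )
    return PatternMatrix(
        data=np.array(rows),
        labels=np.array(labels, dtype=int),
        voxel_ids=ranking.voxel_ids.copy(),
        contrast=contrast.name,
    )


@dataclass(frozen=True)
class ChanceLevel:
    """Binomial 95% chance boundaries for accuracy over n patterns."""

    n: int
    upper: float
    lower: float


def chance_level(n: int) -> ChanceLevel:
    """Smallest k with Binom(n, 0.5) CDF >= 0.95, as proportions.

    Returns the upper boundary k/n and the symmetric lower boundary
    (n - k)/n used for below-chance detection.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    k = int(stats.binom.ppf(0.95, n, 0.5))
    # guard against floating-point edge: ppf should satisfy cdf(k) >= 0.95
    while stats.binom.cdf(k, n, 0.5) < 0.95:
        k += 1
    while k > 0 and stats.binom.cdf(k - 1, n, 0.5) >= 0.95:
        k -= 1
    return ChanceLevel(n=n, upper=k / n, lower=(n - k) / n)


@dataclass
class ClassificationResult:
    """Cross-validated accuracies with their binomial chance context."""

    fold_accuracies: np.ndarray
    n_patterns: int
    pool_size: int
    chance: ChanceLevel
    trace: np.ndarray | None = None
    trace_pool_sizes: np.ndarray | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))

    @property
    def below_chance(self) -> bool:
        """Mean accuracy plus one SD stays under the lower chance bound."""
        return self.mean_accuracy + self.sd_accuracy < self.chance.lower

    @property
    def significant(self) -> bool:
        """Above the upper chance bound and not a below-chance session."""
        return self.mean_accuracy > self.chance.upper and not self.below_chance


def _paired_folds(
    labels: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Assign matched class-A/class-B pattern pairs to disjoint folds.

    Pairing keeps every fold balanced so per-fold chance stays at 0.5;
    surplus patterns of the larger class are left out.
    """
    idx_a = np.flatnonzero(labels == 1)
    idx_b = np.flatnonzero(labels == -1)
    m = min(idx_a.size, idx_b.size)
    if m < n_folds:
        raise ValueError(
            f"need >= {n_folds} condition pairs, got {m} "
            f"({idx_a.size} class A, {idx_b.size} class B)"
        )
    rng.shuffle(idx_a)
    rng.shuffle(idx_b)
    pairs = np.column_stack([idx_a[:m], idx_b[:m]])
    rng.shuffle(pairs)
    return [pairs[f::n_folds].ravel() for f in range(n_folds)]


def _fold_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    C: float,
    zscore: bool,
) -> float:
    Xtr, Xte = X[train], X[test]
    if zscore:
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
    clf = SVC(kernel="linear", C=C)
    clf.fit(Xtr, y[train])
    return float(np.mean(clf.predict(Xte) == y[test]))


def crossvalidate(
    patterns: PatternMatrix,
    pool_size: int = DEFAULT_TRUNCATION,
    n_folds: int = N_FOLDS,
    C: float = 1.0,
    zscore: bool = True,
    seed: int = 0,
    compute_trace: bool = False,
) -> ClassificationResult:
    """8-fold cross-validated linear SVM over held-out condition pairs.

    Any per-voxel standardization is fit on training folds only. The
    optional trace grows the voxel pool in ranking order from 1 to
    ``pool_size``; the session metric is the accuracy at the full pool.
    """
    if pool_size > patterns.n_voxels:
        warnings.warn(
            f"pool_size {pool_size} exceeds available {patterns.n_voxels} voxels; truncating",
            stacklevel=2,
        )
        pool_size = patterns.n_voxels
    rng = np.random.default_rng(seed)
    folds = _paired_folds(patterns.labels, n_folds, rng)
    used = np.sort(np.concatenate(folds))
    n_used = used.size
    X_full = patterns.data
    y = patterns.labels

    def accuracies(pool: int) -> np.ndarray:
        X = X_full[:, :pool]
        return np.array(
            [
                _fold_accuracy(
                    X, y, np.setdiff1d(used, fold), fold, C, zscore
                )
                for fold in folds
            ]
        )

    fold_acc = accuracies(pool_size)
    trace = trace_sizes = None
    if compute_trace:
        trace_sizes = np.arange(1, pool_size + 1)
        trace = np.array([accuracies(p).mean() for p in trace_sizes])
    return ClassificationResult(
        fold_accuracies=fold_acc,
        n_patterns=n_used,
        pool_size=pool_size,
        chance=chance_level(n_used),
        trace=trace,
        trace_pool_sizes=trace_sizes,
    )
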