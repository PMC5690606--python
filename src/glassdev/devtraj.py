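"""Sensitivity index, bootstrap resampling, and the constrained
saturation fit of d-prime against age with its criterion-crossing age.

d' standardizes the distance between mean cross-validated accuracy and
the 0.5 chance mean by the pooled spread of the accuracy folds and the
binomial chance boundary:

    d' = (mu_acc - 0.5) / sqrt(0.5 * (sigma_acc^2 + (p95_n - 0.5)^2))

The developmental trajectory d'(A) is a hyperbolic-ratio saturation with
offset fixed at 0, asymptote bounded by the training-set ceiling (~12)
and shape bounded in (0, 4]; the criterion age is where the fitted curve
crosses d' = 2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .mvpa import chance_level

__all__ = [
    "SensitivityIndex",
    "BootstrapDistribution",
    "NakaRushtonFit",
    "dprime",
    "bootstrap_dprime",
    "fit_naka_rushton",
    "criterion_age",
    "bootstrap_criterion_ages",
    "compare_crossing_ages",
]

DPRIME_CRITERION = 2.0
DMAX_CEILING = 12.0
SHAPE_MAX = 4.0


@dataclass(frozen=True)
class SensitivityIndex:
    """d' with its accuracy, spread, and binomial-chance components."""

    dprime: float
    mu_acc: float
    sigma_acc: float
    n: int
    chance_upper: float
    below_chance: bool = False

    @property
    def chance_spread(self) -> float:
        return self.chance_upper - 0.5

    @property
    def significant(self) -> bool:
        return self.dprime > DPRIME_CRITERION and not self.below_chance


def dprime(
    mu_acc: float, sigma_acc: float, n: int, below_chance: bool = False
) -> SensitivityIndex:
    """Evaluate the sensitivity index for one session.

    Raises when both the fold spread and the chance spread vanish (the
    denominator would be zero).
    """
    if not (0.0 <= mu_acc <= 1.0):
        raise ValueError(f"mu_acc must be in [0, 1], got {mu_acc}")
    if sigma_acc < 0:
        raise ValueError(f"sigma_acc must be >= 0, got {sigma_acc}")
    upper = chance_level(n).upper
    spread = upper - 0.5
    denom = math.sqrt(0.5 * (sigma_acc**2 + spread**2))
    if denom == 0.0:
        raise ZeroDivisionError(
            "d' undefined: zero fold spread and zero chance spread"
        )
    return SensitivityIndex(
        dprime=(mu_acc - 0.5) / denom,
        mu_acc=mu_acc,
        sigma_acc=sigma_acc,
        n=n,
        chance_upper=upper,
        below_chance=below_chance,
    )


@dataclass
class BootstrapDistribution:
    """Resampled d' values with their percentile interval."""

    values: np.ndarray
    seed: int
    ci_level: float = 0.95

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def ci(self) -> tuple[float, float]:
        lo = 100 * (1 - self.ci_level) / 2
        return (
            float(np.percentile(self.values, lo)),
            float(np.percentile(self.values, 100 - lo)),
        )


def _dprime_value(accs: np.ndarray, n: int, spread: float) -> float:
    mu = accs.mean()
    sigma = accs.std(ddof=1)
    return (mu - 0.5) / math.sqrt(0.5 * (sigma**2 + spread**2))


def bootstrap_dprime(
    fold_accuracies: Sequence[float], n: int, B: int = 1000, seed: int = 0
) -> BootstrapDistribution:
    """Resample the 8 fold accuracies with replacement, B times.

    Each replicate recomputes mu, sigma and d'; the replicate mean stays
    close to the plug-in d'.
    """
    accs = np.asarray(fold_accuracies, dtype=float)
    if B < 1:
        raise ValueError("B must be >= 1")
    if np.unique(accs).size < 2:
        warnings.warn("fold accuracies are constant; bootstrap is degenerate", stacklevel=2)
    spread = chance_level(n).upper - 0.5
    rng = np.random.default_rng(seed)
    draws = rng.choice(accs, size=(B, accs.size), replace=True)
    mu = draws.mean(axis=1)
    sigma = draws.std(axis=1, ddof=1)
    values = (mu - 0.5) / np.sqrt(0.5 * (sigma**2 + spread**2))
    return BootstrapDistribution(values=values, seed=seed)


@dataclass
class NakaRushtonFit:
    """Constrained saturation fit of d' against age (months)."""

    dmax: float
    a_half: float
    shape: float
    rss: float
    d0: float = 0.0
    dmax_ceiling: float = DMAX_CEILING

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.dmax <= self.dmax_ceiling + 1e-9):
            raise ValueError(f"dmax {self.dmax} outside [0, {self.dmax_ceiling}]")
        if not (-1e-9 <= self.shape <= SHAPE_MAX + 1e-9):
            raise ValueError(f"shape {self.shape} outside [0, {SHAPE_MAX}]")

    def __call__(self, age: np.ndarray | float) -> np.ndarray | float:
        a = np.asarray(age, dtype=float)
        out = self.d0 + self.dmax * a**self.shape / (self.a_half**self.shape + a**self.shape)
        return float(out) if np.isscalar(age) else out


def _nr_model(params: np.ndarray, ages: np.ndarray) -> np.ndarray:
    dmax, a_half, shape = params
    return dmax * ages**shape / (a_half**shape + ages**shape)


def fit_naka_rushton(
    ages: Sequence[float],
    dprimes: Sequence[float],
    dmax_ceiling: float = DMAX_CEILING,
    starts: Sequence[tuple[float, float, float]] | None = None,
) -> NakaRushtonFit:
    """Constrained trust-region least squares with multi-start.

    Offset fixed at 0; asymptote in [0, ceiling]; shape in [~0, 4];
    half-saturation age unrestricted (positive). Eight default starts span
    a log-spaced a_half grid crossed with shapes {0.5, 1, 2, 4}.
    """
    ages = np.asarray(ages, dtype=float)
    d = np.asarray(dprimes, dtype=float)
    if ages.size < 4:
        raise ValueError(f"need >= 4 (age, d') points, got {ages.size}")
    if ages.size != d.size:
        raise ValueError("ages and dprimes must have equal length")

    lo = np.array([0.0, 1e-3, 1e-3])
    hi = np.array([dmax_ceiling, 1e4, SHAPE_MAX])
    if starts is None:
        a_grid = np.exp(
            np.linspace(math.log(max(ages.min(), 1e-2)), math.log(ages.max() * 2), 2)
        )
        d0_start = float(np.clip(d.max() if d.max() > 0 else 0.1, 0.05, dmax_ceiling))
        starts = [(d0_start, a, s) for a in a_grid for s in (0.5, 1.0, 2.0, 4.0)]

    best = None
    for start in starts:
        x0 = np.clip(np.asarray(start, dtype=float), lo, hi)
        try:
            res = least_squares(
                lambda p: _nr_model(p, ages) - d, x0, bounds=(lo, hi), method="trf"
            )
        except Exception:  # pragma: no cover - defensive against optimizer failures
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0] - 1e-12:
            best = (rss, res.x)
    if best is None:  # pragma: no cover
        raise RuntimeError("all optimization starts failed")
    rss, (dmax, a_half, shape) = best
    return NakaRushtonFit(
        dmax=float(dmax),
        a_half=float(a_half),
        shape=float(shape),
        rss=rss,
        dmax_ceiling=dmax_ceiling,
    )


def criterion_age(
    fit: NakaRushtonFit, criterion: float = DPRIME_CRITERION
) -> float | None:
    """Age at which the fitted curve crosses ``criterion``, or None.

    Analytic inversion A = a_half * (c / (dmax - c))**(1/shape) with
    c = criterion - d0; not reached when the asymptote never exceeds the
    criterion or the curve is flat.
    """
    c = criterion - fit.d0
    if fit.dmax <= c or fit.shape <= 0:
        return None
    return float(fit.a_half * (c / (fit.dmax - c)) ** (1.0 / fit.shape))


def bootstrap_criterion_ages(
    sessions: Sequence[tuple[float, Sequence[float], int]],
    B: int = 1000,
    seed: int = 0,
    criterion: float = DPRIME_CRITERION,
    dmax_ceiling: float = DMAX_CEILING,
) -> np.ndarray:
    """Criterion-age distribution from resampling fold accuracies.

    ``sessions`` are (age, fold_accuracies, n_patterns) triples. Each
    replicate resamples every session's fold accuracies with replacement
    (paired across sessions by replicate index), recomputes d', refits the
    saturation curve warm-started at the plug-in fit, and records the
    criterion age. Not-reached replicates are recorded as +inf.
    """
    ages = np.array([s[0] for s in sessions], dtype=float)
    accs = [np.asarray(s[1], dtype=float) for s in sessions]
    spreads = np.array([chance_level(int(s[2])).upper - 0.5 for s in sessions])

    plug_d = np.array(
        [_dprime_value(a, int(s[2]), sp) for a, s, sp in zip(accs, sessions, spreads)]
    )
    plug_fit = fit_naka_rushton(ages, plug_d, dmax_ceiling=dmax_ceiling)
    warm = (plug_fit.dmax if plug_fit.dmax > 0 else 0.1, plug_fit.a_half, max(plug_fit.shape, 0.1))

    rng = np.random.default_rng(seed)
    out = np.empty(B)
    for b in range(B):
        d_rep = np.empty(ages.size)
        for i, a in enumerate(accs):
            draw = rng.choice(a, size=a.size, replace=True)
            mu = draw.mean()
            sigma = draw.std(ddof=1)
            d_rep[i] = (mu - 0.5) / math.sqrt(0.5 * (sigma**2 + spreads[i] ** 2))
        fit = fit_naka_rushton(
            ages, d_rep, dmax_ceiling=dmax_ceiling, starts=[warm, (1.0, float(np.median(ages)), 2.0)]
        )
        age = criterion_age(fit, criterion)
        out[b] = math.inf if age is None else age
    return out


def compare_crossing_ages(dist_a: np.ndarray, dist_b: np.ndarray) -> float:
    """One-sided bootstrap p for the hypothesis that A crosses later than B.

    p is the fraction of paired replicates with age_A <= age_B;
    not-reached replicates enter as +inf.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("bootstrap distributions must be non-empty")
    if a.size != b.size:
        raise ValueError("paired comparison requires equal-size distributions")
    return float(np.mean(a <= b))
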