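"""Glass-pattern dipole fields and block/blank stimulus schedules.

A Glass pattern is a field of paired dots (dipoles). Each dipole has a
midpoint and an orientation; when the orientations follow a shared rule
(tangential for concentric patterns, aligned with the radius for radial
ones) a global percept emerges. Orientations are measured in degrees
counterclockwise from the positive x-axis; the concentric rule is the
midpoint polar angle + 90 degrees, the radial rule the polar angle itself.

Schedules are flat lists of (onset, duration, trial_type) events in
seconds, written and read as BIDS-style tab-separated events files.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BLANK",
    "PINWHEEL_ON",
    "PINWHEEL_OFF",
    "PATTERN_CLASSES",
    "GlassPatternSpec",
    "DipoleField",
    "ScheduleEvent",
    "StimulusSchedule",
    "generate_glass_pattern",
    "render_sequence",
    "build_palindromic_schedule",
    "build_pinwheel_schedule",
]

BLANK = "blank"
PINWHEEL_ON = "pinwheel_on"
PINWHEEL_OFF = "pinwheel_off"
PATTERN_CLASSES = ("concentric", "radial", "random")

#: refresh interval for static presentation (a new field every second)
STATIC_REFRESH_S = 1.0
#: refresh interval for dynamic presentation
DYNAMIC_REFRESH_S = 0.033


class InvalidSpecError(ValueError):
    """Raised when a stimulus specification violates its invariants."""


@dataclass(frozen=True)
class GlassPatternSpec:
    """Parameters of one Glass-pattern field.

    Defaults follow the experimental stimulus: a 30 x 23 degree field,
    10 dots/deg^2, 0.12 deg dots and a within-dipole separation of
    0.414 deg.
    """

    field_width: float = 30.0
    field_height: float = 23.0
    dot_density: float = 10.0
    dot_diameter: float = 0.12
    dipole_separation: float = 0.414
    pattern_class: str = "concentric"
    coherence: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dot_density <= 0:
            raise InvalidSpecError(f"dot_density must be > 0, got {self.dot_density}")
        if self.dipole_separation <= 0:
            raise InvalidSpecError(
                f"dipole_separation must be > 0, got {self.dipole_separation}"
            )
        if not (0.0 <= self.coherence <= 1.0):
            raise InvalidSpecError(f"coherence must be in [0, 1], got {self.coherence}")
        if self.pattern_class not in PATTERN_CLASSES:
            raise InvalidSpecError(
                f"pattern_class must be one of {PATTERN_CLASSES}, got {self.pattern_class!r}"
            )
        if self.field_width <= 0 or self.field_height <= 0:
            raise InvalidSpecError("field dimensions must be positive")

    @property
    def field_area(self) -> float:
        return self.field_width * self.field_height

    @property
    def n_dipoles(self) -> int:
        return int(round(self.dot_density * self.field_area / 2.0))


@dataclass(frozen=True)
class DipoleField:
    """A realized Glass pattern: dipole endpoints plus per-dipole geometry.

    ``dots`` has shape (n_dipoles, 2, 2): two (x, y) centers per dipole in
    field-centered degrees. Geometry invariants are evaluated on these
    pre-clip coordinates; dots falling outside the field are clipped only
    at render time.
    """

    dots: np.ndarray
    orientations: np.ndarray
    spec: GlassPatternSpec

    @property
    def midpoints(self) -> np.ndarray:
        return self.dots.mean(axis=1)

    @property
    def separations(self) -> np.ndarray:
        d = self.dots[:, 0, :] - self.dots[:, 1, :]
        return np.hypot(d[:, 0], d[:, 1])

    @property
    def n_dipoles(self) -> int:
        return self.dots.shape[0]

    @property
    def n_dots(self) -> int:
        return 2 * self.n_dipoles

    def rule_orientations(self) -> np.ndarray:
        """Orientation each dipole would have under the spec's class rule."""
        mid = self.midpoints
        theta = np.degrees(np.arctan2(mid[:, 1], mid[:, 0]))
        if self.spec.pattern_class == "concentric":
            return (theta + 90.0) % 180.0
        return theta % 180.0


def generate_glass_pattern(spec: GlassPatternSpec) -> DipoleField:
    """Draw one Glass-pattern dipole field from ``spec``.

    Dipole midpoints are uniform over the field; a ``coherence`` fraction
    of dipoles follows the class orientation rule and the remainder (and
    all dipoles of the ``random`` class) get independent uniform
    orientations. Deterministic for a given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_dipoles
    mid = np.column_stack(
        [
            rng.uniform(-spec.field_width / 2.0, spec.field_width / 2.0, size=n),
            rng.uniform(-spec.field_height / 2.0, spec.field_height / 2.0, size=n),
        ]
    )
    random_ori = rng.uniform(0.0, 180.0, size=n)
    if spec.pattern_class == "random":
        ori = random_ori
    else:
        theta = np.degrees(np.arctan2(mid[:, 1], mid[:, 0]))
        rule = (theta + 90.0) % 180.0 if spec.pattern_class == "concentric" else theta % 180.0
        coherent = rng.random(n) < spec.coherence
        ori = np.where(coherent, rule, random_ori)

    half = spec.dipole_separation / 2.0
    offset = half * np.column_stack([np.cos(np.radians(ori)), np.sin(np.radians(ori))])
    dots = np.stack([mid + offset, mid - offset], axis=1)
    return DipoleField(dots=dots, orientations=ori % 180.0, spec=spec)


def render_sequence(
    spec: GlassPatternSpec, mode: str, duration: float
) -> tuple[list[DipoleField], np.ndarray]:
    """Generate the sequence of fields shown during one presentation.

    Static presentation refreshes the field every second; dynamic every
    33 ms. Returns the fields and their onset timestamps (seconds).
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if mode == "static":
        refresh = STATIC_REFRESH_S
    elif mode == "dynamic":
        refresh = DYNAMIC_REFRESH_S
    else:
        raise ValueError(f"mode must be 'static' or 'dynamic', got {mode!r}")
    n_frames = max(1, math.ceil(duration / refresh - 1e-9))
    seeds = np.random.SeedSequence(spec.seed).spawn(n_frames)
    fields = [
        generate_glass_pattern(replace(spec, seed=int(s.generate_state(1)[0])))
        for s in seeds
    ]
    timestamps = np.arange(n_frames) * refresh
    return fields, timestamps


def render_frame(field: DipoleField, pixels_per_degree: float = 10.0) -> np.ndarray:
    """Rasterize a dipole field to a binary uint8 image (dots clipped to field)."""
    spec = field.spec
    w = int(round(spec.field_width * pixels_per_degree))
    h = int(round(spec.field_height * pixels_per_degree))
    img = np.zeros((h, w), dtype=np.uint8)
    r = max(1, int(round(spec.dot_diameter / 2.0 * pixels_per_degree)))
    centers = field.dots.reshape(-1, 2)
    cols = ((centers[:, 0] + spec.field_width / 2.0) * pixels_per_degree).astype(int)
    rows = ((centers[:, 1] + spec.field_height / 2.0) * pixels_per_degree).astype(int)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (xx**2 + yy**2) <= r**2
    for row, col in zip(rows, cols):
        r0, r1 = max(row - r, 0), min(row + r + 1, h)
        c0, c1 = max(col - r, 0), min(col + r + 1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        img[r0:r1, c0:c1] |= disk[
            r0 - (row - r) : disk.shape[0] - ((row + r + 1) - r1),
            c0 - (col - r) : disk.shape[1] - ((col + r + 1) - c1),
        ].astype(np.uint8)
    return img * 255


@dataclass(frozen=True)
class ScheduleEvent:
    onset: float
    duration: float
    trial_type: str

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class StimulusSchedule:
    """An ordered, contiguous list of timed condition events starting at 0."""

    events: list[ScheduleEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.events:
            return
        if abs(self.events[0].onset) > 1e-9:
            raise ValueError("schedule must start at time 0")
        for prev, nxt in zip(self.events, self.events[1:]):
            if abs(prev.offset - nxt.onset) > 1e-9:
                raise ValueError(
                    f"events must be contiguous: {prev} ends at {prev.offset}, "
                    f"next starts at {nxt.onset}"
                )

    @property
    def total_duration(self) -> float:
        return self.events[-1].offset if self.events else 0.0

    @property
    def conditions(self) -> list[str]:
        """Distinct non-blank trial types in order of first appearance."""
        seen: dict[str, None] = {}
        for ev in self.events:
            if ev.trial_type != BLANK:
                seen.setdefault(ev.trial_type)
        return list(seen)

    def events_of(self, *trial_types: str) -> list[ScheduleEvent]:
        wanted = set(trial_types)
        return [ev for ev in self.events if ev.trial_type in wanted]

    def n_volumes(self, tr: float) -> int:
        return int(math.floor(self.total_duration / tr + 1e-9))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": [ev.onset for ev in self.events],
                "duration": [ev.duration for ev in self.events],
                "trial_type": [ev.trial_type for ev in self.events],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StimulusSchedule":
        events = [
            ScheduleEvent(float(row.onset), float(row.duration), str(row.trial_type))
            for row in frame.itertuples()
        ]
        return cls(events=events)

    @classmethod
    def from_tsv(cls, path) -> "StimulusSchedule":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def build_palindromic_schedule(
    conditions: Sequence[str],
    block_duration: float = 48.0,
    blank_duration: float = 24.0,
    n_cycles: int = 1,
) -> StimulusSchedule:
    """Interleave palindromic condition blocks with blanks.

    One cycle presents ``conditions`` followed by their reverse
    (A-B-C-C-B-A), with a blank before every block and a terminal blank;
    consecutive cycles share the boundary blank. Block durations outside
    [36, 48] s or blank durations outside [24, 36] s raise a warning but
    are honored.
    """
    if not conditions:
        raise ValueError("condition list must be non-empty")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if not (36.0 <= block_duration <= 48.0):
        warnings.warn(
            f"block_duration {block_duration} s outside the usual 36-48 s range",
            stacklevel=2,
        )
    if not (24.0 <= blank_duration <= 36.0):
        warnings.warn(
            f"blank_duration {blank_duration} s outside the usual 24-36 s range",
            stacklevel=2,
        )
    order_one_cycle = list(conditions) + list(reversed(conditions))
    events: list[ScheduleEvent] = []
    t = 0.0
    events.append(ScheduleEvent(t, blank_duration, BLANK))
    t += blank_duration
    for _ in range(n_cycles):
        for label in order_one_cycle:
            events.append(ScheduleEvent(t, block_duration, label))
            t += block_duration
            events.append(ScheduleEvent(t, blank_duration, BLANK))
            t += blank_duration
    return StimulusSchedule(events=events)


def build_pinwheel_schedule(total_duration: float = 960.0) -> StimulusSchedule:
    """Pinwheel on/off alternation, 48 s per epoch (96 s period).

    The fundamental alternation frequency is 1/1.6 min^-1 = 0.625 min^-1.
    """
    period = 96.0
    epoch = 48.0
    if total_duration < period:
        raise ValueError(
            f"total_duration must cover at least one on/off cycle ({period} s), "
            f"got {total_duration}"
        )
    n_epochs = int(math.floor(total_duration / epoch + 1e-9))
    events = [
        ScheduleEvent(i * epoch, epoch, PINWHEEL_ON if i % 2 == 0 else PINWHEEL_OFF)
        for i in range(n_epochs)
    ]
    return StimulusSchedule(events=events)


def pinwheel_fundamental_frequency() -> float:
    """Alternation frequency of the pinwheel schedule in cycles/min."""
    return 60.0 / 96.0


def glass_condition_labels(
    pattern_classes: Iterable[str] = PATTERN_CLASSES,
    modes: Iterable[str] = ("static", "dynamic"),
) -> list[str]:
    """Condition labels of the form '<class>_<mode>' for schedule building."""
    return [f"{cls}_{mode}" for cls in pattern_classes for mode in modes]
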