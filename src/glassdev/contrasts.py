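"""Two-class contrast definitions mapping schedule conditions to classes."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .stimgen import BLANK

__all__ = [
    "ContrastDef",
    "STIMULUS_VS_BLANK",
    "DYNAMIC_VS_STATIC",
    "STRUCTURED_VS_RANDOM",
    "STANDARD_CONTRASTS",
    "get_contrast",
]


@dataclass(frozen=True)
class ContrastDef:
    """A named two-class contrast over schedule condition labels.

    ``class_a`` and ``class_b`` are disjoint sets of trial-type labels; a
    session can run the contrast only when it presented at least one label
    from each class.
    """

    name: str
    class_a: frozenset[str]
    class_b: frozenset[str]

    def __post_init__(self) -> None:
        if not self.class_a or not self.class_b:
            raise ValueError(f"contrast {self.name!r}: classes must be non-empty")
        if self.class_a & self.class_b:
            raise ValueError(f"contrast {self.name!r}: classes must be disjoint")

    def applicable(self, available_conditions: Iterable[str]) -> bool:
        avail = set(available_conditions) | {BLANK}
        return bool(self.class_a & avail) and bool(self.class_b & avail)

    def class_of(self, trial_type: str) -> int | None:
        """+1 for class A, -1 for class B, None when the label is in neither."""
        if trial_type in self.class_a:
            return 1
        if trial_type in self.class_b:
            return -1
        return None


def _labels(classes: Iterable[str], modes: Iterable[str]) -> frozenset[str]:
    return frozenset(f"{c}_{m}" for c in classes for m in modes)


# All Glass-pattern presentations against blank epochs.
STIMULUS_VS_BLANK = ContrastDef(
    "stimulus_vs_blank",
    _labels(("concentric", "radial", "random"), ("static", "dynamic")),
    frozenset({BLANK}),
)

# Dynamic presentations (structured and random) against static ones.
DYNAMIC_VS_STATIC = ContrastDef(
    "dynamic_vs_static",
    _labels(("concentric", "radial", "random"), ("dynamic",)),
    _labels(("concentric", "radial", "random"), ("static",)),
)

# Static structured forms against static random dipoles.
STRUCTURED_VS_RANDOM = ContrastDef(
    "structured_vs_random",
    _labels(("concentric", "radial"), ("static",)),
    frozenset({"random_static"}),
)

STANDARD_CONTRASTS = {
    c.name: c for c in (STIMULUS_VS_BLANK, DYNAMIC_VS_STATIC, STRUCTURED_VS_RANDOM)
}


def get_contrast(name: str) -> ContrastDef:
    try:
        return STANDARD_CONTRASTS[name]
    except KeyError:
        raise KeyError(
            f"unknown contrast {name!r}; known: {sorted(STANDARD_CONTRASTS)}"
        ) from None
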