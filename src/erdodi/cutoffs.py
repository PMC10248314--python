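"""Component cutoff specifications and ordinal recoding.

Each embedded validity indicator (EVI) is described by a
:class:`ComponentSpec`: a failure direction (whether low or high scores
signal non-credible performance) and three cut values ordered from the
most liberal to the most conservative cutoff published for that
indicator.  A raw score is recoded onto a 4-point ordinal *level of
failure* scale:

* 0 — passed the most liberal cutoff (unequivocal pass),
* 1 — failed the liberal cutoff (specificity >= .84),
* 2 — failed a more conservative cutoff (base rate of failure near 10%),
* 3 — failed an ultra-conservative cutoff (base rate near 5%).

Failure comparisons are inclusive of the printed threshold: a low-fails
component fails level *j* when ``raw <= c_j``, a high-fails component
when ``raw >= c_j``.  Levels are induced purely by the three cut values
with half-open bands, so every score in the valid range maps to exactly
one level even when published tables print band endpoints on a coarse
grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Direction",
    "ComponentSpec",
    "BatteryConfig",
    "CutoffSpecError",
    "CutOrderingError",
    "CutRangeError",
    "GranularityError",
    "MissingComponentError",
    "validate_component_spec",
    "recode_score",
    "recode_profile",
]


class Direction(str, Enum):
    """Which tail of the score distribution signals failure."""

    LOW_FAILS = "low_fails"
    HIGH_FAILS = "high_fails"


class CutoffSpecError(ValueError):
    """Base class for invalid component specifications."""


class CutOrderingError(CutoffSpecError):
    """Cut values are not strictly ordered in increasing severity."""


class CutRangeError(CutoffSpecError):
    """A cut value lies outside the component's valid score range."""


class GranularityError(CutoffSpecError):
    """Granularity is not a positive step size."""


class MissingComponentError(KeyError):
    """A battery component has no score in the supplied profile."""


@dataclass(frozen=True)
class ComponentSpec:
    """One embedded validity indicator's cutoff ladder.

    Parameters
    ----------
    name:
        Identifier, unique within a battery (e.g. ``"CD"``).
    direction:
        :class:`Direction` — whether low or high scores fail.
    cuts:
        Three thresholds ``(c1, c2, c3)`` ordered liberal to
        ultra-conservative.  Strictly decreasing for ``low_fails``,
        strictly increasing for ``high_fails``.
    units:
        Free-text score metric (e.g. ``"age-corrected scaled score"``).
    valid_range:
        Closed interval of admissible raw scores.
    granularity:
        Optional positive step of the instrument's score grid
        (e.g. 0.5 for figure-copy raw scores).  Informational for
        recoding; used by grid-scan utilities and the simulator.
    """

    name: str
    direction: Direction
    cuts: tuple[float, float, float]
    units: str = ""
    valid_range: tuple[float, float] = (-math.inf, math.inf)
    granularity: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction(self.direction))
        object.__setattr__(self, "cuts", tuple(float(c) for c in self.cuts))
        object.__setattr__(
            self, "valid_range", tuple(float(v) for v in self.valid_range)
        )
        validate_component_spec(self)

    def score_grid(self) -> np.ndarray:
        """All attainable scores on the component's granularity grid."""
        lo, hi = self.valid_range
        if self.granularity is None or not np.isfinite([lo, hi]).all():
            raise ValueError(
                f"component {self.name!r} has no finite granularity grid"
            )
        n = int(round((hi - lo) / self.granularity))
        return lo + self.granularity * np.arange(n + 1)


def validate_component_spec(spec: ComponentSpec) -> ComponentSpec:
    """Check a :class:`ComponentSpec`'s invariants; return it unchanged.

    Raises
    ------
    CutOrderingError
        Cuts not strictly ordered in the direction of severity.
    CutRangeError
        A cut outside ``valid_range``.
    GranularityError
        Non-positive granularity.
    """
    if len(spec.cuts) != 3:
        raise CutoffSpecError(
            f"component {spec.name!r}: expected 3 cuts, got {len(spec.cuts)}"
        )
    c1, c2, c3 = spec.cuts
    if spec.direction is Direction.LOW_FAILS:
        if not (c1 > c2 > c3):
            raise CutOrderingError(
                f"component {spec.name!r}: low_fails cuts must be strictly "
                f"decreasing, got {spec.cuts}"
            )
    else:
        if not (c1 < c2 < c3):
            raise CutOrderingError(
                f"component {spec.name!r}: high_fails cuts must be strictly "
                f"increasing, got {spec.cuts}"
            )
    lo, hi = spec.valid_range
    if lo > hi:
        raise CutRangeError(
            f"component {spec.name!r}: empty valid_range {spec.valid_range}"
        )
    for c in spec.cuts:
        if not (lo <= c <= hi):
            raise CutRangeError(
                f"component {spec.name!r}: cut {c} outside valid_range "
                f"[{lo}, {hi}]"
            )
    if spec.granularity is not None and not spec.granularity > 0:
        raise GranularityError(
            f"component {spec.name!r}: granularity must be positive, "
            f"got {spec.granularity}"
        )
    return spec


def recode_score(raw: float, spec: ComponentSpec) -> int:
    """Recode a raw score onto the 0-3 ordinal level-of-failure scale.

    The failing comparison is inclusive of the printed threshold:
    ``low_fails`` levels are 0 if ``raw > c1``, 1 if ``c2 < raw <= c1``,
    2 if ``c3 < raw <= c2``, 3 if ``raw <= c3``; mirrored with ``>=``
    for ``high_fails``.
    """
    raw = float(raw)
    if not math.isfinite(raw):
        raise ValueError(f"component {spec.name!r}: non-finite score {raw}")
    lo, hi = spec.valid_range
    if not (lo <= raw <= hi):
        raise ValueError(
            f"component {spec.name!r}: score {raw} outside valid_range "
            f"[{lo}, {hi}]"
        )
    c1, c2, c3 = spec.cuts
    if spec.direction is Direction.LOW_FAILS:
        if raw > c1:
            return 0
        if raw > c2:
            return 1
        if raw > c3:
            return 2
        return 3
    if raw < c1:
        return 0
    if raw < c2:
        return 1
    if raw < c3:
        return 2
    return 3


@dataclass(frozen=True)
class BatteryConfig:
    """An ordered battery of components plus classification bands.

    ``pass_max`` and ``borderline_max`` trichotomize the summed index:
    totals ``<= pass_max`` are *Pass*, totals in
    ``(pass_max, borderline_max]`` are *Borderline*, and totals
    ``>= borderline_max + 1`` are *Fail*.  The standard five-component
    index (EI-5) uses bands (1, 3): Pass <=1, Borderline 2-3, Fail >=4.
    """

    name: str
    components: tuple[ComponentSpec, ...]
    pass_max: int = 1
    borderline_max: int = 3
    missing_policy: str = "error"  # or "complete_case"

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if not self.components:
            raise CutoffSpecError("battery needs at least one component")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise CutoffSpecError(f"duplicate component names in {names}")
        if self.pass_max < 0:
            raise CutoffSpecError("pass_max must be non-negative")
        if self.borderline_max < self.pass_max:
            raise CutoffSpecError("borderline_max must be >= pass_max")
        if self.borderline_max + 1 > 3 * self.k:
            raise CutoffSpecError(
                f"Fail unattainable: borderline_max+1 = "
                f"{self.borderline_max + 1} exceeds max total {3 * self.k}"
            )
        if self.missing_policy not in ("error", "complete_case"):
            raise CutoffSpecError(
                f"unknown missing_policy {self.missing_policy!r}"
            )

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def fail_min(self) -> int:
        """Smallest total classified as Fail."""
        return self.borderline_max + 1

    @property
    def component_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    def component(self, name: str) -> ComponentSpec:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(f"no component named {name!r}")

    def with_policy(self, missing_policy: str) -> "BatteryConfig":
        return replace(self, missing_policy=missing_policy)


def recode_profile(
    raw_scores: Mapping[str, float],
    battery: BatteryConfig,
    *,
    strict: bool = True,
) -> np.ndarray:
    """Recode one examinee's raw scores, in battery component order.

    Raises :class:`MissingComponentError` when a component is absent or
    its score is NaN (handling of missing data is the caller's concern,
    governed by the battery's ``missing_policy``), and ``KeyError`` on
    score names the battery does not know unless ``strict=False``.
    """
    if strict:
        unknown = set(raw_scores) - set(battery.component_names)
        if unknown:
            raise KeyError(
                f"unknown component name(s): {sorted(unknown)}"
            )
    levels = np.empty(battery.k, dtype=np.int64)
    for i, spec in enumerate(battery.components):
        if spec.name not in raw_scores:
            raise MissingComponentError(spec.name)
        raw = raw_scores[spec.name]
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            raise MissingComponentError(spec.name)
        levels[i] = recode_score(raw, spec)
    return levels
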