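"""Numerosity categorization experiment design.

The experiment briefly (500 ms) presents a field of dots and asks the child
to categorize it as containing "many" or "few" dots.  The tested numerosities
span one octave below and above a central value (default 8..32 dots around a
geometric mean of 16), log-uniformly spaced.  Four unscored *anchor* trials
showing the two range extremes precede testing so the participant can
calibrate the "few"/"many" categories; each test level is then shown a fixed
number of times in random order.

This module encodes the level ladder, the anchored trial schedule, and the
dot-field geometry (non-overlapping dots, luminance-balanced black/white
polarity) in degrees of visual angle.  No rendering is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .exceptions import DegenerateDesignError, PlacementError

__all__ = [
    "StimulusRange",
    "DotFieldSpec",
    "TrialSchedule",
    "DotArray",
    "make_levels",
    "make_schedule",
    "place_dots",
    "schedule_to_frame",
    "dots_to_frame",
]

#: 75% quantile of the standard normal; converts a Gaussian sigma into a
#: 50%->75% just-noticeable-difference.
Z75 = 0.6744897501960817


def _round_half_away(x: float) -> int:
    """Round half away from zero (8.5 -> 9), unlike banker's rounding."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class StimulusRange:
    """A log-uniform ladder of integer numerosities."""

    n_min: int
    n_max: int
    n_levels: int
    levels: tuple[int, ...]

    def __post_init__(self):
        lv = self.levels
        if len(lv) != self.n_levels:
            raise DegenerateDesignError("levels length differs from n_levels")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise DegenerateDesignError("levels must be strictly increasing")
        if lv[0] != self.n_min or lv[-1] != self.n_max:
            raise DegenerateDesignError("levels must span [n_min, n_max]")


@dataclass(frozen=True)
class DotFieldSpec:
    """Geometry and timing of the dot field, in degrees of visual angle."""

    dot_diameter_deg: float = 0.25
    field_diameter_deg: float = 12.0
    fraction_white: float = 0.5
    duration_ms: float = 500.0

    def __post_init__(self):
        if not 0 < self.dot_diameter_deg < self.field_diameter_deg:
            raise ValueError("need 0 < dot diameter < field diameter")
        if not 0 <= self.fraction_white <= 1:
            raise ValueError("fraction_white must be in [0, 1]")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")


@dataclass(frozen=True)
class TrialSchedule:
    """Anchored, randomized presentation order.

    ``anchor_trials`` are unscored calibration presentations of the range
    extremes; ``test_trials`` are the scored presentations.
    """

    anchor_trials: tuple[int, ...]
    test_trials: tuple[int, ...]
    seed: int

    @property
    def trials(self) -> tuple[tuple[int, bool], ...]:
        """(numerosity, is_anchor) pairs, anchors first."""
        return tuple((n, True) for n in self.anchor_trials) + tuple(
            (n, False) for n in self.test_trials
        )


@dataclass(frozen=True)
class DotArray:
    """Dot positions (deg, origin at field center) and polarities."""

    numerosity: int
    positions: np.ndarray  # (n, 2)
    polarity: tuple[str, ...]  # "white" / "black"

    def __post_init__(self):
        if len(self.positions) != self.numerosity:
            raise ValueError("positions length must equal numerosity")
        if len(self.polarity) != self.numerosity:
            raise ValueError("polarity length must equal numerosity")


def make_levels(n_min: int, n_max: int, n_levels: int) -> StimulusRange:
    """Log-uniformly spaced integer numerosities from ``n_min`` to ``n_max``.

    Levels are geometrically spaced then rounded half-away-from-zero to the
    nearest integer.  With the defaults (8, 32, 11) this reproduces the
    ladder 8, 9, 11, 12, 14, 16, 18, 21, 24, 28, 32, whose extremes have
    geometric mean 16.

    Raises
    ------
    ValueError
        Non-integer, non-positive or non-increasing bounds.
    DegenerateDesignError
        Two adjacent levels round to the same integer.
    """
    for name, v in (("n_min", n_min), ("n_max", n_max), ("n_levels", n_levels)):
        if not float(v).is_integer() or isinstance(v, bool):
            raise ValueError(f"{name} must be an integer, got {v!r}")
    n_min, n_max, n_levels = int(n_min), int(n_max), int(n_levels)
    if n_min < 1 or n_max <= n_min:
        raise ValueError("need 1 <= n_min < n_max")
    if n_levels < 2:
        raise ValueError("need n_levels >= 2")
    raw = np.exp(np.linspace(math.log(n_min), math.log(n_max), n_levels))
    levels = tuple(_round_half_away(x) for x in raw)
    if len(set(levels)) != n_levels:
        raise DegenerateDesignError(
            f"rounding collision in levels {levels}; use fewer levels or a wider range"
        )
    return StimulusRange(n_min=n_min, n_max=n_max, n_levels=n_levels, levels=levels)


def make_schedule(rng_levels: StimulusRange, reps: int, seed: int) -> TrialSchedule:
    """Anchored trial schedule: 4 anchor trials, then a seeded permutation.

    Anchors are presented in the fixed order [max, min, max, min]; each test
    level then appears exactly ``reps`` times, uniformly shuffled by a
    generator seeded with ``seed`` (deterministic).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    anchors = (rng_levels.n_max, rng_levels.n_min, rng_levels.n_max, rng_levels.n_min)
    pool = np.repeat(np.asarray(rng_levels.levels, dtype=int), reps)
    rng = np.random.default_rng(seed)
    rng.shuffle(pool)
    return TrialSchedule(anchor_trials=anchors, test_trials=tuple(int(n) for n in pool), seed=seed)


def place_dots(
    numerosity: int,
    spec: DotFieldSpec = DotFieldSpec(),
    seed: int = 0,
    max_tries: int = 10_000,
) -> DotArray:
    """Rejection-sample non-overlapping dot positions in the circular field.

    Dot centers stay inside the field radius minus one dot radius; no two
    centers come closer than one dot diameter.  Polarities alternate
    white/black then are shuffled, so the white/black split never differs by
    more than one dot.

    Raises
    ------
    PlacementError
        A dot could not be placed within ``max_tries`` attempts.
    """
    if numerosity < 1:
        raise ValueError("numerosity must be >= 1")
    rng = np.random.default_rng(seed)
    r_field = spec.field_diameter_deg / 2.0
    r_dot = spec.dot_diameter_deg / 2.0
    r_eff = r_field - r_dot
    min_d2 = spec.dot_diameter_deg**2
    placed = np.empty((numerosity, 2))
    for i in range(numerosity):
        for _ in range(max_tries):
            # uniform in the disc of radius r_eff
            rad = r_eff * math.sqrt(rng.random())
            theta = 2 * math.pi * rng.random()
            p = (rad * math.cos(theta), rad * math.sin(theta))
            if i == 0 or np.min(np.sum((placed[:i] - p) ** 2, axis=1)) >= min_d2:
                placed[i] = p
                break
        else:
            raise PlacementError(
                f"could not place dot {i + 1}/{numerosity} within {max_tries} tries"
            )
    n_white = numerosity // 2 + (1 if numerosity % 2 and rng.random() < spec.fraction_white else 0)
    if spec.fraction_white != 0.5:
        n_white = _round_half_away(numerosity * spec.fraction_white)
        n_white = min(max(n_white, 0), numerosity)
    pol = np.array(["white"] * n_white + ["black"] * (numerosity - n_white))
    rng.shuffle(pol)
    return DotArray(numerosity=numerosity, positions=placed, polarity=tuple(pol))


def schedule_to_frame(schedule: TrialSchedule) -> pd.DataFrame:
    """Schedule as a DataFrame with columns trial_index, numerosity, is_anchor."""
    rows = schedule.trials
    return pd.DataFrame(
        {
            "trial_index": np.arange(len(rows)),
            "numerosity": [n for n, _ in rows],
            "is_anchor": [a for _, a in rows],
        }
    )


def dots_to_frame(array: DotArray) -> pd.DataFrame:
    """Dot array as a DataFrame with columns dot_index, x_deg, y_deg, polarity."""
    return pd.DataFrame(
        {
            "dot_index": np.arange(array.numerosity),
            "x_deg": array.positions[:, 0],
            "y_deg": array.positions[:, 1],
            "polarity": list(array.polarity),
        }
    )
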