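"""Age-normative scoring of the symbolic math battery.

Six paper-and-pencil tasks probe distinct symbolic skills: counting aloud
(forward/backward), Arabic number reading, number writing (transcoding),
mental multiplications (fact retrieval), mental additions/subtractions, and
"choose the largest" (digit magnitude comparison).  Raw scores are converted
to z-scores against an age-banded normative table, and an aggregate index is
the mean of the available per-task z-scores.

Missing scores are first-class: a participant's aggregate is defined only
when at least ``min_tasks`` tasks are available (default 4, so a child who
completed 4/6 tasks still gets an aggregate), and per-task analyses use each
task's own available cases.  Group-mean imputation is provided for
robustness checks but is off by default.

The shipped normative table is synthetic (real battery norms are
proprietary): means rise linearly with age over one-year bands so that
generated raw scores invert exactly to the configured z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, NoNormError

__all__ = [
    "MATH_TASKS",
    "NormativeTable",
    "MathScores",
    "default_norms",
    "zscore",
    "raw_from_z",
    "aggregate_index",
    "impute_group_mean",
]

MATH_TASKS = (
    "counting",
    "reading",
    "writing",
    "multiplications",
    "addition_subtraction",
    "choose_largest",
)


@dataclass(frozen=True)
class NormativeTable:
    """Mapping (task, age band) -> (norm mean, norm sd) in raw-score units.

    ``bands`` is an ordered tuple of (lo, hi) year intervals tiling the
    covered age range; the last band is closed at its upper edge.
    """

    bands: tuple[tuple[float, float], ...]
    entries: Mapping[tuple[str, tuple[float, float]], tuple[float, float]]

    def __post_init__(self):
        for (lo, hi), (nxt_lo, _) in zip(self.bands, self.bands[1:]):
            if not np.isclose(hi, nxt_lo):
                raise ValueError("age bands must tile the range with no gaps")
        for key, (_, sd) in self.entries.items():
            if sd <= 0:
                raise ValueError(f"norm sd must be positive for {key}")

    def band_for(self, age_yr: float) -> tuple[float, float]:
        for i, (lo, hi) in enumerate(self.bands):
            last = i == len(self.bands) - 1
            if lo <= age_yr < hi or (last and np.isclose(age_yr, hi)):
                return (lo, hi)
        raise NoNormError(f"no normative band covers age {age_yr}")

    def lookup(self, task: str, age_yr: float) -> tuple[float, float]:
        band = self.band_for(age_yr)
        try:
            return self.entries[(task, band)]
        except KeyError:
            raise ValueError(f"unknown task {task!r}") from None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"task": task, "age_lo": lo, "age_hi": hi, "mean": m, "sd": s}
            for (task, (lo, hi)), (m, s) in self.entries.items()
        ]
        return pd.DataFrame(rows).sort_values(["task", "age_lo"]).reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NormativeTable":
        bands = sorted({(float(r.age_lo), float(r.age_hi)) for r in df.itertuples()})
        entries = {
            (str(r.task), (float(r.age_lo), float(r.age_hi))): (float(r.mean), float(r.sd))
            for r in df.itertuples()
        }
        return cls(bands=tuple(bands), entries=entries)


# synthetic per-task raw-score scales: (mean at age 8, yearly slope, sd)
_SYNTH_SCALES = {
    "counting": (40.0, 4.0, 8.0),
    "reading": (24.0, 3.0, 6.0),
    "writing": (30.0, 2.5, 5.0),
    "multiplications": (6.0, 1.5, 3.0),
    "addition_subtraction": (8.0, 1.2, 3.0),
    "choose_largest": (10.0, 1.0, 2.5),
}


def default_norms(age_lo: float = 8.0, age_hi: float = 16.0) -> NormativeTable:
    """Synthetic normative table: one-year bands, linearly age-progressing
    means, constant sd per task."""
    bands = tuple((float(a), float(a + 1)) for a in np.arange(age_lo, age_hi))
    entries = {}
    for task, (base, slope, sd) in _SYNTH_SCALES.items():
        for lo, hi in bands:
            mid = (lo + hi) / 2.0
            entries[(task, (lo, hi))] = (base + slope * (mid - age_lo), sd)
    return NormativeTable(bands=bands, entries=entries)


def zscore(raw: float, task: str, age_yr: float, table: NormativeTable) -> float:
    """z = (raw - norm_mean) / norm_sd for the band containing ``age_yr``."""
    m, s = table.lookup(task, age_yr)
    return (raw - m) / s


def raw_from_z(z: float, task: str, age_yr: float, table: NormativeTable) -> float:
    """Inverse of :func:`zscore`; used by the synthetic cohort generator."""
    m, s = table.lookup(task, age_yr)
    return m + z * s


@dataclass(frozen=True)
class MathScores:
    """Per-task z-scores (None = missing) and their aggregate index."""

    z: Mapping[str, float | None]
    aggregate: float | None
    n_available: int


def aggregate_index(z: Mapping[str, float | None], min_tasks: int = 4) -> MathScores:
    """Mean of the available z-scores; undefined below ``min_tasks``.

    Absence is a value, not an error: tasks map to None when the raw score
    was missing, and the aggregate is None when fewer than ``min_tasks``
    tasks are available.
    """
    if len(z) > len(MATH_TASKS):
        raise ValueError(f"at most {len(MATH_TASKS)} tasks expected")
    present = [v for v in z.values() if v is not None and v == v]
    n_avail = len(present)
    agg = float(np.mean(present)) if n_avail >= min_tasks else None
    return MathScores(z=dict(z), aggregate=agg, n_available=n_avail)


def impute_group_mean(scores: pd.DataFrame, task: str, group_col: str = "group") -> pd.DataFrame:
    """Replace a task's missing values by the within-group task mean.

    Returns a copy with the task column completed and a boolean
    ``{task}_imputed`` column flagging the filled cells.  Group means are
    unchanged by construction.
    """
    if task not in scores.columns:
        raise ValueError(f"unknown task column {task!r}")
    out = scores.copy()
    flag = out[task].isna()
    means = out.groupby(group_col)[task].transform("mean")
    if out.groupby(group_col)[task].count().eq(0).any():
        raise InsufficientDataError(f"a group has no observed values for {task!r}")
    out[task] = out[task].fillna(means)
    out[f"{task}_imputed"] = flag
    return out
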