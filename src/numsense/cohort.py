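"""Synthetic observers and two-group study cohorts.

The generator produces a clinical-style case/control cohort (ADHD vs
neurotypical controls, default n = 20 per group, ages 8-16) with the
statistical structure the downstream analysis assumes:

* each observer holds a true Weber fraction and PSE drawn from group-level
  normal distributions (Wf truncated at 0.01, which also induces the mild
  positive skew typical of threshold samples);
* categorization responses follow the cumulative-Gaussian observer model on
  log numerosity, so psychometric fitting can recover the truth;
* per-task math z-scores are drawn around group task means with a shared
  within-battery factor, and that factor is tied to -Wf through a Gaussian
  copula so the Weber-fraction/math-skill rank correlation has a known
  generative target;
* raw scores are produced by inverting the normative table, missingness is
  applied per a configured per-task pattern (one ADHD participant misses the
  whole battery), and clinical scale scores (CPRS, CGI-S, CGAS severity
  category) are attached to the ADHD group only.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from . import battery
from .design import Z75, TrialSchedule, make_levels, make_schedule
from .exceptions import CohortParseError, ConfigError

__all__ = [
    "GROUPS",
    "ObserverParams",
    "TrialRecord",
    "ParticipantRecord",
    "CohortConfig",
    "response_probability",
    "simulate_responses",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "participants_frame",
    "trials_frame",
]

GROUPS = ("ADHD", "control")
CLINICAL_SCALES = ("CGI-S", "CGAS", "CPRS")


@dataclass(frozen=True)
class ObserverParams:
    """Generative observer: true Weber fraction, PSE, and lapse rate."""

    wf_true: float
    pse_true: float
    lapse: float = 0.0

    def __post_init__(self):
        if self.wf_true < 0:
            raise ValueError("wf_true must be >= 0")
        if self.pse_true <= 0:
            raise ValueError("pse_true must be positive")
        if not 0 <= self.lapse <= 0.5:
            raise ValueError("lapse must be in [0, 0.5]")


@dataclass(frozen=True)
class TrialRecord:
    """One categorization trial; anchor trials carry no response."""

    numerosity: int
    response_many: bool | None
    is_anchor: bool = False

    def __post_init__(self):
        if self.is_anchor and self.response_many is not None:
            raise ValueError("anchor trials carry no response")


@dataclass
class ParticipantRecord:
    """One participant: demographics, trials, raw math scores, clinical scores.

    ``wf``/``pse`` hold *observed* values — precomputed when a cohort file
    ships them, otherwise filled in by the pipeline's psychometric fits.
    ``wf_true``/``pse_true`` are generator ground truth (None for real data).
    """

    id: str
    group: str
    age_yr: float
    sex: str
    trials: list[TrialRecord] = field(default_factory=list)
    math_raw: dict[str, float | None] = field(default_factory=dict)
    clinical: dict[str, float] | None = None
    nonverbal_z: float | None = None
    wf_true: float | None = None
    pse_true: float | None = None
    wf: float | None = None
    pse: float | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


def _default_math_means():
    # per-task (mean, sd) of normative z-scores, per group
    return {
        "ADHD": {
            "counting": (-0.33, 1.18),
            "reading": (-0.85, 1.23),
            "writing": (-0.28, 0.98),
            "multiplications": (-0.94, 1.07),
            "addition_subtraction": (-0.19, 1.06),
            "choose_largest": (-0.58, 1.62),
        },
        "control": {
            "counting": (0.78, 0.84),
            "reading": (-0.13, 1.28),
            "writing": (0.82, 0.90),
            "multiplications": (0.12, 0.76),
            "addition_subtraction": (0.42, 1.17),
            "choose_largest": (0.34, 0.47),
        },
    }


def _default_missing():
    # per-task count of absent raw scores, per group
    return {
        "ADHD": {
            "counting": 2,
            "reading": 2,
            "writing": 2,
            "multiplications": 1,
            "addition_subtraction": 1,
            "choose_largest": 2,
        },
        "control": {
            "counting": 0,
            "reading": 0,
            "writing": 0,
            "multiplications": 1,
            "addition_subtraction": 1,
            "choose_largest": 2,
        },
    }


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of the synthetic two-group study.

    Defaults are the study conditions: 20 per group, ages 8-16, group
    Weber-fraction moments 0.177/0.09 (ADHD) vs 0.143/0.07 (controls), PSE
    moments 15.63/2.38 vs 14.76/1.97, per-task math z moments and per-task
    missingness counts as observed, sex splits 14M/6F vs 9M/11F, and a
    Kendall-scale copula link of 0.3 between -Wf and the shared math factor.
    """

    n_per_group: int = 20
    age_range_yr: tuple[float, float] = (8.0, 16.0)
    wf_moments: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"ADHD": (0.177, 0.09), "control": (0.143, 0.07)}
    )
    pse_moments: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"ADHD": (15.63, 2.38), "control": (14.76, 1.97)}
    )
    math_z_moments: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=_default_math_means
    )
    missing_pattern: Mapping[str, Mapping[str, int]] = field(default_factory=_default_missing)
    sex_counts: Mapping[str, tuple[int, int]] | None = None  # (male, female); None = study split
    rho_wf_math: float = 0.3
    task_loading: float = 0.25
    wf_floor: float = 0.01
    # anchoring keeps subjective midpoints inside the presented range, so
    # PSE draws are truncated well within the default 8..32 ladder
    pse_range: tuple[float, float] = (10.0, 26.0)
    lapse: float = 0.0
    reps: int = 4
    stimulus_range: tuple[int, int, int] = (8, 32, 11)
    adhd_all_tasks_missing: bool = True
    n_missing_irp: int = 4
    nonverbal_moments: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"ADHD": (-0.15, 0.9), "control": (0.42, 0.95)}
    )
    simulate_trials: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 0:
            raise ConfigError("n_per_group must be >= 0")
        if not abs(self.rho_wf_math) < 1:
            raise ConfigError("|rho_wf_math| must be < 1")
        if not 0 <= self.task_loading <= 1:
            raise ConfigError("task_loading must be in [0, 1]")
        for g in GROUPS:
            for d in (self.wf_moments, self.pse_moments):
                if d[g][1] <= 0:
                    raise ConfigError("all SDs must be positive")
            for task, cnt in self.missing_pattern[g].items():
                if cnt < 0 or cnt > self.n_per_group:
                    if self.n_per_group > 0:
                        raise ConfigError(
                            f"missing count {cnt} for {g}/{task} exceeds group size"
                        )

    def resolved_sex_counts(self) -> dict[str, tuple[int, int]]:
        if self.sex_counts is not None:
            out = {g: tuple(self.sex_counts[g]) for g in GROUPS}
        else:
            study = {"ADHD": (14, 6), "control": (9, 11)}
            out = {}
            for g, (m, f) in study.items():
                nm = int(round(self.n_per_group * m / 20.0))
                out[g] = (nm, self.n_per_group - nm)
        for g, (m, f) in out.items():
            if m + f != self.n_per_group or m < 0 or f < 0:
                raise ConfigError(f"sex counts for {g} must sum to n_per_group")
        return out


def response_probability(observer: ObserverParams, numerosity: float) -> float:
    """p("many") at a numerosity under the Gaussian observer model:

        p = lapse/2 + (1 - lapse) * Phi((log10 N - log10 pse) / sigma),

    with sigma = log10(1 + wf) / z75, so that at N = pse*(1+wf) the
    lapse-free response probability is exactly 75%.  A zero Weber fraction
    is the noiseless step-function limit (0 below the PSE, 1 above, 1/2 at
    it)."""
    x = math.log10(numerosity) - math.log10(observer.pse_true)
    sigma = math.log10(1.0 + observer.wf_true) / Z75
    if sigma == 0.0:
        base = 0.5 if x == 0 else (1.0 if x > 0 else 0.0)
    else:
        base = float(norm.cdf(x / sigma))
    return observer.lapse / 2.0 + (1.0 - observer.lapse) * base


def simulate_responses(
    observer: ObserverParams, schedule: TrialSchedule, seed: int
) -> list[TrialRecord]:
    """Simulate categorization responses under the Gaussian observer model
    (see :func:`response_probability`).  Anchor trials are emitted without a
    response.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    out: list[TrialRecord] = []
    for n, is_anchor in schedule.trials:
        if is_anchor:
            out.append(TrialRecord(numerosity=n, response_many=None, is_anchor=True))
            continue
        p = response_probability(observer, n)
        out.append(
            TrialRecord(numerosity=n, response_many=bool(rng.random() < p), is_anchor=False)
        )
    return out


def _assign_missing(rng, members: list[str], quotas: dict[str, int], cap: int) -> dict[str, set]:
    """Greedy concentration of missing-task slots onto few participants.

    Task slots (largest quota first) go to the participant who already has
    the most missing tasks (without exceeding ``cap`` per participant or
    repeating a task), so the pattern mirrors a few time-constrained
    children rather than diffuse missingness.
    """
    order = list(members)
    rng.shuffle(order)
    missing: dict[str, set] = {m: set() for m in order}
    for task in sorted(quotas, key=lambda t: -quotas[t]):
        for _ in range(quotas[task]):
            cands = [m for m in order if task not in missing[m] and len(missing[m]) < cap]
            if not cands:
                raise ConfigError(f"infeasible missing pattern for task {task!r}")
            pick = max(cands, key=lambda m: (len(missing[m]), -order.index(m)))
            missing[pick].add(task)
    return missing


def generate_cohort(config: CohortConfig = CohortConfig()) -> list[ParticipantRecord]:
    """Generate the full two-group cohort; deterministic given ``config.seed``."""
    if config.n_per_group == 0:
        return []
    rng = np.random.default_rng(config.seed)
    norms = battery.default_norms(*config.age_range_yr)
    levels = make_levels(*config.stimulus_range)
    sex_counts = config.resolved_sex_counts()
    r_copula = math.sin(math.pi * config.rho_wf_math / 2.0)
    w = config.task_loading
    participants: list[ParticipantRecord] = []
    for group in GROUPS:
        n = config.n_per_group
        wf_m, wf_s = config.wf_moments[group]
        pse_m, pse_s = config.pse_moments[group]
        a = (config.wf_floor - wf_m) / wf_s
        ages = rng.uniform(*config.age_range_yr, size=n)
        # Gaussian copula: z_wf vs shared math factor f, corr(-z_wf, f) = r
        z_wf = rng.standard_normal(n)
        f = -r_copula * z_wf + math.sqrt(1 - r_copula**2) * rng.standard_normal(n)
        wf = truncnorm.ppf(norm.cdf(z_wf), a, np.inf, loc=wf_m, scale=wf_s)
        p_lo, p_hi = config.pse_range
        pse = truncnorm.ppf(
            rng.random(n),
            (p_lo - pse_m) / pse_s,
            (p_hi - pse_m) / pse_s,
            loc=pse_m,
            scale=pse_s,
        )
        nm, nf = sex_counts[group]
        sexes = ["M"] * nm + ["F"] * nf
        rng.shuffle(sexes)
        task_eps = rng.standard_normal((n, len(battery.MATH_TASKS)))
        nv_m, nv_s = config.nonverbal_moments[group]
        nonverbal = rng.normal(nv_m, nv_s, size=n)
        # missingness bookkeeping
        members = [f"{group}-{i + 1:02d}" for i in range(n)]
        quotas = dict(config.missing_pattern[group])
        all_missing_id = None
        if group == "ADHD" and config.adhd_all_tasks_missing:
            if any(quotas.get(t, 0) < 1 for t in battery.MATH_TASKS):
                raise ConfigError(
                    "adhd_all_tasks_missing needs >= 1 missing slot on every task"
                )
            all_missing_id = members[int(rng.integers(n))]
            quotas = {t: c - 1 for t, c in quotas.items()}
        pool = [m for m in members if m != all_missing_id]
        missing = _assign_missing(rng, pool, quotas, cap=2)
        if all_missing_id is not None:
            missing[all_missing_id] = set(battery.MATH_TASKS)
        irp_missing: set[str] = set()
        if group == "ADHD" and config.n_missing_irp:
            idx = rng.choice(n, size=min(config.n_missing_irp, n), replace=False)
            irp_missing = {members[i] for i in idx}
        for i, pid in enumerate(members):
            observer = ObserverParams(
                wf_true=float(wf[i]), pse_true=float(pse[i]), lapse=config.lapse
            )
            trials: list[TrialRecord] = []
            if config.simulate_trials:
                sched_seed = int(rng.integers(0, 2**31 - 1))
                resp_seed = int(rng.integers(0, 2**31 - 1))
                schedule = make_schedule(levels, reps=config.reps, seed=sched_seed)
                trials = simulate_responses(observer, schedule, seed=resp_seed)
            math_raw: dict[str, float | None] = {}
            for j, task in enumerate(battery.MATH_TASKS):
                if task in missing.get(pid, ()):
                    math_raw[task] = None
                    continue
                tm, ts = config.math_z_moments[group][task]
                z = tm + ts * (math.sqrt(w) * f[i] + math.sqrt(1 - w) * task_eps[i, j])
                math_raw[task] = battery.raw_from_z(z, task, float(ages[i]), norms)
            clinical = None
            if group == "ADHD":
                clinical = {
                    "CGI-S": float(np.clip(round(rng.normal(4.5, 1.0)), 1, 7)),
                    "CGAS": float(np.clip(round(rng.normal(5.0, 1.5)), 1, 10)),
                    "CPRS": float(rng.normal(60.0, 10.0)),
                }
            participants.append(
                ParticipantRecord(
                    id=pid,
                    group=group,
                    age_yr=float(ages[i]),
                    sex=sexes[i],
                    trials=trials,
                    math_raw=math_raw,
                    clinical=clinical,
                    nonverbal_z=None if pid in irp_missing else float(nonverbal[i]),
                    wf_true=observer.wf_true,
                    pse_true=observer.pse_true,
                )
            )
    return participants


# ---------------------------------------------------------------------------
# serialization


def participants_frame(cohort: Sequence[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for p in cohort:
        row = {
            "id": p.id,
            "group": p.group,
            "age_yr": p.age_yr,
            "sex": p.sex,
            "wf_true": p.wf_true,
            "pse_true": p.pse_true,
            "wf": p.wf,
            "pse": p.pse,
            "nonverbal_z": p.nonverbal_z,
        }
        for task in battery.MATH_TASKS:
            row[task] = p.math_raw.get(task)
        for scale in CLINICAL_SCALES:
            row[scale] = None if p.clinical is None else p.clinical.get(scale)
        rows.append(row)
    return pd.DataFrame(rows)


def trials_frame(cohort: Sequence[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for p in cohort:
        for i, t in enumerate(p.trials):
            rows.append(
                {
                    "id": p.id,
                    "trial_index": i,
                    "numerosity": t.numerosity,
                    "is_anchor": int(t.is_anchor),
                    "response_many": None if t.response_many is None else int(t.response_many),
                }
            )
    return pd.DataFrame(
        rows, columns=["id", "trial_index", "numerosity", "is_anchor", "response_many"]
    )


def write_cohort(cohort: Sequence[ParticipantRecord], path: str | Path) -> None:
    """Write ``participants.csv`` and ``trials.csv`` under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    participants_frame(cohort).to_csv(path / "participants.csv", index=False)
    trials_frame(cohort).to_csv(path / "trials.csv", index=False)


def _opt_float(v):
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def read_cohort(path: str | Path) -> list[ParticipantRecord]:
    """Read a cohort written by :func:`write_cohort` (exact round-trip).

    Raises :class:`CohortParseError` (with the offending row) on unknown
    group labels, duplicate ids, or a response recorded on an anchor trial.
    Missing scores stay missing — an empty cell is None, never zero.
    """
    path = Path(path)
    pdf = pd.read_csv(path / "participants.csv")
    tfile = path / "trials.csv"
    tdf = pd.read_csv(tfile) if tfile.exists() else pd.DataFrame(
        columns=["id", "trial_index", "numerosity", "is_anchor", "response_many"]
    )
    seen = set()
    trials_by_id: dict[str, list[TrialRecord]] = {}
    for i, r in tdf.iterrows():
        resp = _opt_float(r.get("response_many"))
        anchor = bool(int(r["is_anchor"]))
        if anchor and resp is not None:
            raise CohortParseError("response recorded on an anchor trial", row=int(i) + 2)
        trials_by_id.setdefault(str(r["id"]), []).append(
            TrialRecord(
                numerosity=int(r["numerosity"]),
                response_many=None if resp is None else bool(resp),
                is_anchor=anchor,
            )
        )
    cohort = []
    for i, r in pdf.iterrows():
        pid = str(r["id"])
        if pid in seen:
            raise CohortParseError(f"duplicate participant id {pid!r}", row=int(i) + 2)
        seen.add(pid)
        if r["group"] not in GROUPS:
            raise CohortParseError(f"unknown group label {r['group']!r}", row=int(i) + 2)
        clinical_vals = {s: _opt_float(r.get(s)) for s in CLINICAL_SCALES}
        clinical = (
            {k: v for k, v in clinical_vals.items() if v is not None}
            if any(v is not None for v in clinical_vals.values())
            else None
        )
        cohort.append(
            ParticipantRecord(
                id=pid,
                group=str(r["group"]),
                age_yr=float(r["age_yr"]),
                sex=str(r["sex"]),
                trials=trials_by_id.get(pid, []),
                math_raw={t: _opt_float(r.get(t)) for t in battery.MATH_TASKS},
                clinical=clinical,
                nonverbal_z=_opt_float(r.get("nonverbal_z")),
                wf_true=_opt_float(r.get("wf_true")),
                pse_true=_opt_float(r.get("pse_true")),
                wf=_opt_float(r.get("wf")),
                pse=_opt_float(r.get("pse")),
            )
        )
    return cohort
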