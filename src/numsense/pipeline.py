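"""End-to-end study analysis: from trials and raw scores to a report.

``run_study`` executes the full analysis chain of the case/control design:

1. load a cohort from CSV or simulate one;
2. fit the psychometric function per participant (participants shipping
   precomputed Weber fraction / PSE values skip fitting);
3. convert raw math scores to age-normative z-scores and build the
   aggregate index with the missing-data policy;
4. demographic checks: age (Bayesian t-test) and sex ratio (contingency BF);
5. per-measure group comparisons with a Shapiro-Wilk-gated choice between
   the parametric JZS t-test and the rank-based test;
6. Weber-fraction vs math-aggregate Kendall correlation within each group;
7. ANCOVA inclusion BFs for the impaired measures (group-comparison
   LBF > 1, plus the aggregate) with covariate sets {Wf} and
   {Wf, nonverbal reasoning, age, sex};
8. clinical-scale Kendall correlations within the clinical group;
9. a machine-readable report (JSON) plus CSV tables.

Every stage is deterministic given the config seed, and every Bayes factor
in the report carries its prior and the test-selection trace.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import battery, bayes, cohort as cohort_mod
from .cohort import CohortConfig, read_cohort
from .exceptions import ConfigError, DegenerateFitError, NumsenseError
from .psychometric import fit_psychometric

__all__ = ["AnalysisConfig", "StudyReport", "run_study", "recode_cgas"]

log = logging.getLogger("numsense")

MEASURES = ("wf", "pse", "aggregate") + battery.MATH_TASKS
CLINICAL_MEASURES = ("wf", "pse", "aggregate")


def recode_cgas(score: float) -> float:
    """Recode a raw 1-100 global-functioning score into the 1-10 severity
    category (1 = no symptoms ... 10 = very severe).  Scores already on the
    1-10 scale pass through unchanged."""
    if score <= 10:
        return float(score)
    return float(10 - min(int(score - 1) // 10, 9))


@dataclass(frozen=True)
class PriorScales:
    t_cauchy: float = 0.707
    corr_width: float = 1.0
    r_fixed: float = 0.5
    r_cov: float = 0.354
    dirichlet_a: float = 1.0


@dataclass(frozen=True)
class AnalysisConfig:
    """Inputs, priors and policies of one full analysis run.

    Exactly one of ``cohort_path`` (directory with participants.csv and
    trials.csv) or ``simulate`` (a :class:`CohortConfig`) must be given.
    """

    cohort_path: str | None = None
    simulate: CohortConfig | None = None
    norms_path: str | None = None
    priors: PriorScales = field(default_factory=PriorScales)
    min_tasks: int = 4
    alpha_norm: float = 0.05
    mw_draws: int = 3000
    impaired_lbf_threshold: float = 1.0
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if (self.cohort_path is None) == (self.simulate is None):
            raise ConfigError("give exactly one of cohort_path or a simulate block")

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        sim = d.pop("simulate", None)
        if sim is not None:
            sim = CohortConfig(**sim)
        priors = PriorScales(**d.pop("priors", {}))
        return cls(simulate=sim, priors=priors, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class StudyReport:
    """Full analysis output; ``to_json`` is byte-stable given the seed."""

    meta: dict
    descriptives: dict
    demographics: dict
    comparisons: dict
    correlations: dict
    ancova: dict
    clinical: dict
    fits: list[dict]
    math_z: list[dict]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True, allow_nan=True)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json() + "\n")
        pd.DataFrame(self.fits).to_csv(out / "fits.csv", index=False)
        pd.DataFrame(self.math_z).to_csv(out / "math_z.csv", index=False)
        bf_rows = []
        for section in ("demographics", "comparisons", "correlations", "ancova", "clinical"):
            sec = getattr(self, section)
            for name, entry in sec.items():
                if isinstance(entry, dict) and "lbf" in entry:
                    bf_rows.append({"analysis": f"{section}:{name}", **_flatten_bf(entry)})
        (out / "bf_report.json").write_text(
            json.dumps(bf_rows, indent=2, sort_keys=True) + "\n"
        )

    def summary(self) -> str:
        lines = ["Study report", "=" * 64]
        lines.append(f"groups: {self.meta['n_per_group']}")
        lines.append("")
        lines.append("Group comparisons (log10 Bayes factors)")
        lines.append("-" * 64)
        for m, c in self.comparisons.items():
            test = {"ttest_jzs": "t-test (JZS)", "mannwhitney_latent_normal": "rank (MW)"}.get(
                c["test"], c["test"]
            )
            lines.append(
                f"{m:<24}{test:<16}LBF {c['lbf']:>7.2f}  {c['label']:<16}"
                f"n={c['n']}"
            )
        lines.append("")
        lines.append("Within-group Wf vs math aggregate (Kendall)")
        lines.append("-" * 64)
        for g, c in self.correlations.items():
            lines.append(f"{g:<24}tau {c['statistic']:>6.3f}   LBF {c['lbf']:>7.2f}")
        if self.ancova:
            lines.append("")
            lines.append("ANCOVA inclusion LBF for group, by covariate set")
            lines.append("-" * 64)
            for m, sets in self.ancova.items():
                for setname, terms in sets.items():
                    lines.append(f"{m:<24}{setname:<20}group LBF {terms['group']['lbf']:>7.2f}")
        return "\n".join(lines)


def _flatten_bf(entry: dict) -> dict:
    keep = {k: entry.get(k) for k in ("method", "statistic", "n", "prior", "lbf", "label", "mc_se")}
    return {k: v for k, v in keep.items() if v is not None}


def _bf_entry(res: bayes.BFResult, **extra) -> dict:
    d = res.to_dict()
    d.update(extra)
    return d


def _measure_values(df: pd.DataFrame, measure: str, group: str) -> np.ndarray:
    v = df.loc[df["group"] == group, measure].to_numpy(float)
    return v[~np.isnan(v)]


def run_study(config: AnalysisConfig) -> StudyReport:
    """Execute the full analysis; see the module docstring for the stages.

    Raises a stage-tagged :class:`NumsenseError` on failure; artifacts
    written before the failure are preserved.
    """
    rng = np.random.default_rng(config.seed)
    stage = "load"
    try:
        if config.simulate is not None:
            sim_cfg = config.simulate
            if sim_cfg.seed != config.seed:
                sim_cfg = dataclasses.replace(sim_cfg, seed=config.seed)
            cohort = cohort_mod.generate_cohort(sim_cfg)
            log.info("simulated cohort: %d participants", len(cohort))
        else:
            cohort = read_cohort(config.cohort_path)
            log.info("loaded cohort from %s: %d participants", config.cohort_path, len(cohort))
        if not cohort:
            raise ConfigError("empty cohort")
        norms = (
            battery.NormativeTable.from_frame(pd.read_csv(config.norms_path))
            if config.norms_path
            else battery.default_norms()
        )

        stage = "psychometric_fit"
        fits = []
        for p in cohort:
            if p.trials:
                try:
                    res = fit_psychometric(p.trials)
                except (DegenerateFitError, NumsenseError) as e:
                    raise DegenerateFitError(f"participant {p.id}: {e}") from e
                p.wf, p.pse = res.wf, res.pse
                fits.append({"id": p.id, "group": p.group, **res.to_dict()})
            elif p.wf is not None and p.pse is not None:
                fits.append(
                    {"id": p.id, "group": p.group, "wf": p.wf, "pse": p.pse, "precomputed": True}
                )
            else:
                raise ConfigError(f"participant {p.id} has neither trials nor wf/pse")

        stage = "math_scores"
        math_rows = []
        for p in cohort:
            z = {
                t: (None if v is None else battery.zscore(v, t, p.age_yr, norms))
                for t, v in p.math_raw.items()
            }
            ms = battery.aggregate_index(z, min_tasks=config.min_tasks)
            row = {"id": p.id, "group": p.group}
            row.update({t: ms.z.get(t) for t in battery.MATH_TASKS})
            row["aggregate"] = ms.aggregate
            row["n_available"] = ms.n_available
            math_rows.append(row)
        mz = pd.DataFrame(math_rows)

        df = pd.DataFrame(
            {
                "id": [p.id for p in cohort],
                "group": [p.group for p in cohort],
                "age_yr": [p.age_yr for p in cohort],
                "sex": [p.sex for p in cohort],
                "nonverbal_z": [p.nonverbal_z for p in cohort],
                "wf": [p.wf for p in cohort],
                "pse": [p.pse for p in cohort],
            }
        ).merge(mz.drop(columns=["n_available"]), on=["id", "group"])

        pri = config.priors
        stage = "demographics"
        age_bf = bayes.lbf_ttest_two_sample(
            _measure_values(df, "age_yr", "ADHD"),
            _measure_values(df, "age_yr", "control"),
            r=pri.t_cauchy,
        )
        sex_tab = [
            [
                int(((df["group"] == g) & (df["sex"] == s)).sum())
                for s in ("M", "F")
            ]
            for g in ("ADHD", "control")
        ]
        sex_bf = bayes.lbf_contingency_2x2(sex_tab, a=pri.dirichlet_a)
        demographics = {
            "age": _bf_entry(age_bf),
            "sex_ratio": _bf_entry(sex_bf, table=sex_tab),
        }

        stage = "descriptives"
        descriptives = {}
        for measure in MEASURES:
            descriptives[measure] = {}
            for g in ("ADHD", "control"):
                v = _measure_values(df, measure, g)
                if len(v) >= 2:
                    descriptives[measure][g] = bayes.describe(v).to_dict()

        stage = "group_comparisons"
        comparisons = {}
        for measure in MEASURES:
            x = _measure_values(df, measure, "ADHD")
            y = _measure_values(df, measure, "control")
            if len(x) < 3 or len(y) < 3:
                continue
            gate = bayes.check_normality_and_select(x, y, alpha_norm=config.alpha_norm)
            if gate["selected"] == "parametric":
                res = bayes.lbf_ttest_two_sample(x, y, r=pri.t_cauchy)
            else:
                res = bayes.lbf_mannwhitney(
                    x,
                    y,
                    r=pri.t_cauchy,
                    draws=config.mw_draws,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            comparisons[measure] = _bf_entry(
                res,
                test=res.method,
                n=[len(x), len(y)],
                selection=gate,
                reason=(
                    "normality rejected in at least one group"
                    if gate["selected"] == "nonparametric"
                    else "no normality violation detected"
                ),
            )

        stage = "wf_math_correlation"
        correlations = {}
        for g in ("ADHD", "control"):
            sub = df[df["group"] == g][["wf", "aggregate"]].dropna()
            if len(sub) >= 3:
                correlations[g] = _bf_entry(
                    bayes.lbf_kendall(sub["wf"], sub["aggregate"], width=pri.corr_width),
                    n=[len(sub)],
                )

        stage = "ancova"
        impaired = [
            m
            for m in battery.MATH_TASKS
            if m in comparisons and comparisons[m]["lbf"] > config.impaired_lbf_threshold
        ]
        if "aggregate" in comparisons and "aggregate" not in impaired:
            impaired.append("aggregate")
        df_anc = df.copy()
        df_anc["sex_num"] = (df_anc["sex"] == "M").astype(float)
        cov_sets = {
            "wf_only": ["wf"],
            "all_covariates": ["wf", "nonverbal_z", "age_yr", "sex_num"],
        }
        ancova = {}
        for measure in impaired:
            ancova[measure] = {}
            for setname, covs in cov_sets.items():
                try:
                    inc = bayes.lbf_ancova_inclusion(
                        df_anc,
                        dv=measure,
                        group_col="group",
                        covariates=covs,
                        r_fixed=pri.r_fixed,
                        r_cov=pri.r_cov,
                    )
                except NumsenseError as e:
                    ancova[measure][setname] = {"error": str(e)}
                    continue
                ancova[measure][setname] = {t: _bf_entry(r) for t, r in inc.items()}

        stage = "clinical_correlations"
        clinical = {}
        adhd = [p for p in cohort if p.group == "ADHD" and p.clinical]
        if adhd:
            cdf = pd.DataFrame(
                [
                    {
                        "id": p.id,
                        "CGI-S": p.clinical.get("CGI-S"),
                        "CGAS": (
                            None
                            if p.clinical.get("CGAS") is None
                            else recode_cgas(p.clinical["CGAS"])
                        ),
                        "CPRS": p.clinical.get("CPRS"),
                    }
                    for p in adhd
                ]
            ).merge(df[df["group"] == "ADHD"][["id", "wf", "pse", "aggregate"]], on="id")
            for measure in CLINICAL_MEASURES:
                for scale in ("CGI-S", "CGAS", "CPRS"):
                    sub = cdf[[measure, scale]].dropna()
                    if len(sub) < 3:
                        continue
                    try:
                        res = bayes.lbf_kendall(
                            sub[measure], sub[scale], width=pri.corr_width
                        )
                    except ValueError as e:
                        clinical[f"{measure}~{scale}"] = {"error": str(e)}
                        continue
                    clinical[f"{measure}~{scale}"] = _bf_entry(res, n=[len(sub)])

        stage = "report"
        n_adhd = int((df["group"] == "ADHD").sum())
        n_ctrl = int((df["group"] == "control").sum())
        report = StudyReport(
            meta={
                "seed": config.seed,
                "n_per_group": {"ADHD": n_adhd, "control": n_ctrl},
                "priors": dataclasses.asdict(config.priors),
                "min_tasks": config.min_tasks,
                "impaired_measures": impaired,
                "source": "simulated" if config.simulate is not None else str(config.cohort_path),
            },
            descriptives=descriptives,
            demographics=demographics,
            comparisons=comparisons,
            correlations=correlations,
            ancova=ancova,
            clinical=clinical,
            fits=fits,
            math_z=math_rows,
        )
        if config.out_dir:
            report.save(config.out_dir)
            if config.simulate is not None:
                cohort_mod.write_cohort(cohort, Path(config.out_dir) / "cohort")
        return report
    except NumsenseError as e:
        e.args = (f"[stage {stage}] {e}",)
        raise
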