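"""End-to-end study-level analyses with config, logging and JSON reports.

Three analyses mirror the structure of a full cohort study:

* **descriptive** — per-measure KDE, Gaussian best fit, bootstrap moment
  panel and subsample stability curves;
* **asymmetry** — grand mean turn bias with bootstrap CI, the
  all-metadata linear model (intercept = covariate-adjusted bias), and
  genotype p-value enrichment;
* **variability** — genotype CVs, Levene-transform sex models, and
  paired treatment/control and temperature effect sizes.

Reports are JSON with a versioned schema and embed the fully resolved
configuration and seed, so any report can be regenerated from its own
header.  Every filtering step logs record counts in and out.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import distributions as dist
from . import variability as vara
from .io import CohortTable, read_cohort, TABLE_COLUMNS
from .synthetic import PopulationSpec, generate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "REPORT_SCHEMA_VERSION",
    "run_descriptive",
    "run_asymmetry",
    "run_variability",
    "run",
]

REPORT_SCHEMA_VERSION = 1

MEASURE_COLUMNS = ("handedness", "numTurns", "switchiness")

#: Metadata predictors for the full linear model: everything but date,
#: which is jointly determined by the other covariates and would make
#: the design rank deficient; eyeColor is a recode of genotype.
MODEL_PREDICTORS = (
    "genotype", "expCond", "expTemp", "age", "experimenterID", "trayID",
    "boxID", "arrayFormat", "mazeNum", "acquisition", "analysis", "sex",
)

EXIT_SCHEMA_ERROR = 2
EXIT_STAT_PRECONDITION = 3


@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run.

    ``input`` is either a path to a cohort table or a
    :class:`PopulationSpec` (a dict under the ``synthetic`` key in
    YAML).  Seeds are always explicit — there is no silent clock
    seeding.
    """

    input: str | PopulationSpec
    analyses: tuple[str, ...] = ("descriptive", "asymmetry", "variability")
    seed: int = 0
    B: int = 1000
    max_order: int = 20
    alpha: float = 0.05
    fractions: tuple[float, ...] = (1.0, 0.1)
    condition_pairs: tuple[tuple[str, str], ...] = ()
    temperature_pair: tuple[float, float] | None = None
    min_group_n: int = 2
    output_dir: str | None = None

    _VALID = frozenset({"descriptive", "asymmetry", "variability"})

    def __post_init__(self):
        self.analyses = tuple(self.analyses)
        if not self.analyses:
            raise ValueError("analysis selection must be non-empty")
        unknown = set(self.analyses) - self._VALID
        if unknown:
            raise ValueError(f"unknown analysis selection(s): {sorted(unknown)}")
        self.condition_pairs = tuple((str(c), str(t)) for c, t in self.condition_pairs)
        self.fractions = tuple(float(f) for f in self.fractions)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw:
            raw["input"] = PopulationSpec(**raw.pop("synthetic"))
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(self.input, PopulationSpec):
            d["input"] = {"synthetic": self.input.to_dict()}
        return d


def _load_cohort(config: RunConfig) -> CohortTable:
    if isinstance(config.input, PopulationSpec):
        logger.info("generating synthetic cohort: %d flies", config.input.n_flies)
        return generate_cohort(config.input, seed=config.seed).cohort
    return read_cohort(config.input)


def _measure_values(df: pd.DataFrame, column: str) -> np.ndarray:
    if column not in df.columns:
        raise KeyError(f"missing measure column: {column!r}")
    v = pd.to_numeric(df[column], errors="coerce").to_numpy()
    finite = np.isfinite(v)
    dropped = int((~finite).sum())
    if dropped:
        logger.info("%s: %d/%d record(s) missing, excluded", column, dropped, v.size)
    return v[finite]


def run_descriptive(cohort: CohortTable, config: RunConfig) -> dict:
    """KDE + Gaussian fit + moment panel + stability per measure."""
    out = {}
    for i, col in enumerate(MEASURE_COLUMNS):
        v = _measure_values(cohort.df, col)
        seed = np.random.SeedSequence([config.seed, 10 + i])
        rng = np.random.default_rng(seed)
        density = dist.kde(v)
        mu, sd = dist.gaussian_fit(v)
        panel = dist.moment_panel(v, max_order=config.max_order, B=config.B, rng=rng)
        stab = dist.stability_curve(
            v, max_order=config.max_order, fractions=config.fractions,
            B=config.B, seed=np.random.default_rng(seed.spawn(1)[0]).integers(2**31),
        )
        out[col] = {
            "n_used": int(v.size),
            "kde": {
                "grid": density.grid.tolist(),
                "density": density.density.tolist(),
                "bandwidth": density.bandwidth,
            },
            "gaussian_fit": {"mean": mu, "sd": sd},
            "moments": [r.to_dict() for r in panel],
            "stability": {
                str(f): [r.to_dict() for r in stab.panels[f]] for f in stab.fractions
            },
        }
    return out


def run_asymmetry(cohort: CohortTable, config: RunConfig) -> dict:
    """Grand-mean bias, metadata model intercept, genotype enrichment."""
    df = cohort.df
    if "genotype" not in df.columns:
        raise KeyError("cohort has no genotype column")
    bias = _measure_values(df, "handedness")
    boot = dist.bootstrap_statistic(
        bias, np.mean, B=config.B,
        seed=np.random.default_rng(np.random.SeedSequence([config.seed, 20])).integers(2**31),
    )
    predictors = [
        p for p in MODEL_PREDICTORS
        if p in df.columns and df[p].nunique(dropna=True) > 1
    ]
    model = None
    if predictors:
        try:
            model = vara.fit_metadata_model(df, "handedness", predictors).to_dict()
        except vara.RankDeficiencyError as exc:
            logger.warning("metadata model rank deficient: %s", exc.aliased)
            model = {"error": "rank_deficient", "aliased": exc.aliased}
    if df["genotype"].nunique() < 2:
        raise ValueError("need at least 2 genotypes for enrichment")
    pvals = vara.genotype_pvalues(df["handedness"], df["genotype"])
    enr = vara.genotype_enrichment(pvals, alpha=config.alpha)
    return {
        "grand_mean": {
            "estimate": boot.point_estimate,
            "ci_low": boot.ci_low,
            "ci_high": boot.ci_high,
            "boot_sd": boot.boot_sd,
            "excludes_0.5": not (boot.ci_low <= 0.5 <= boot.ci_high),
        },
        "metadata_model": model,
        "genotype_enrichment": {
            "n_significant": enr.n_below,
            "n_genotypes": enr.n_total,
            "expected": enr.expected,
            "p_value": enr.p_value,
        },
    }


def run_variability(cohort: CohortTable, config: RunConfig) -> dict:
    """Genotype CVs, sex Levene models, paired condition/temperature effects."""
    df = cohort.df
    out: dict = {"group_cv": {}, "sex_effects": {}, "paired_effects": [], "temperature_effects": []}
    for col in MEASURE_COLUMNS:
        cv = vara.group_cv(df[col], df["genotype"], min_n=config.min_group_n)
        out["group_cv"][col] = {
            "n_groups": int(len(cv)),
            "cv_mean": float(cv["cv"].mean()),
            "cv_min": float(cv["cv"].min()),
            "cv_max": float(cv["cv"].max()),
        }
        if "sex" in df.columns and df["sex"].isin(["male", "female"]).sum() > 0 \
                and df.loc[df["sex"].isin(["male", "female"]), "sex"].nunique() == 2:
            out["sex_effects"][col] = vara.sex_variability_effect(df, col).to_dict()
    for control, treatment in config.condition_pairs:
        for col in MEASURE_COLUMNS:
            try:
                res = vara.paired_effect(
                    df, col, control, treatment, min_n=config.min_group_n
                )
            except vara.PairingError as exc:
                raise vara.PairingError(f"{col}: {exc}") from exc
            out["paired_effects"].append(res.to_dict())
    if config.temperature_pair is not None and "expTemp" in df.columns:
        low, high = config.temperature_pair
        temp = vara.merge_temperature_labels(df["expTemp"])
        sub = df.assign(_temp=temp)
        sub = sub[np.isclose(temp, low) | np.isclose(temp, high)]
        sub = sub.assign(_temp=sub["_temp"].astype(str))
        for col in MEASURE_COLUMNS:
            res = vara.paired_effect(
                sub, col, str(float(low)), str(float(high)),
                cond_col="_temp", min_n=config.min_group_n,
            )
            out["temperature_effects"].append(res.to_dict())
    return out


_RUNNERS = {
    "descriptive": run_descriptive,
    "asymmetry": run_asymmetry,
    "variability": run_variability,
}


def run(config: RunConfig) -> dict:
    """Execute the selected analyses and return the versioned report."""
    cohort = _load_cohort(config)
    logger.info("cohort loaded: %d record(s)", len(cohort))
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": config.to_dict(),
        "n_records": len(cohort),
        "results": {},
    }
    for name in config.analyses:
        logger.info("running %s analysis", name)
        report["results"][name] = _RUNNERS[name](cohort, config)
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / "report.json"
        path.write_text(json.dumps(report, indent=2, default=_json_default))
        logger.info("report written to %s", path)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
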