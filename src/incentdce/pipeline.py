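"""End-to-end pipeline: design -> simulate -> clean -> encode -> fit -> postfit.

Every stage writes a plain-text artifact (CSV/JSON) and the consolidated run
report reconciles the counts across stages.  A single master seed expands
deterministically into per-stage seeds, so identical configs reproduce
identical numeric outputs.
"""

from __future__ import annotations

import functools
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as design_mod
from . import postfit
from .catalog import AttributeCatalog, default_catalog, load_catalog
from .mixlogit import MixedLogit, ModelSpec
from .preprocess import clean_study, describe_enrollment, to_long_format
from .synth import (
    CohortConfig,
    StudyDataset,
    simulate_cohort,
    table_preferences,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "make_fixture", "FIXTURES"]


def expand_seed(master: int, n: int = 6) -> list:
    """Deterministic per-stage seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


@dataclass
class RunConfig:
    catalog_path: str | None = None
    n_sets: int = 30
    n_blocks: int = 3
    design_restarts: int = 8
    n_per_income: dict = field(
        default_factory=lambda: {"low": 150, "middle": 155, "high": 155}
    )
    planted: dict = field(
        default_factory=lambda: {
            "nontrader": 3,
            "dominance_failer": 15,
            "never_enroller": 12,
        }
    )
    n_draws: int = 200
    seed: int = 0
    design_seed: int | None = None
    cohort_seed: int | None = None
    fit_seed: int | None = None
    postfit_seed: int | None = None
    sds_zero: bool = False
    wta_draws: int = 10_000
    uptake_amounts: tuple = (50, 100, 200, 350, 500, 750, 1000)
    out_dir: str | None = None

    def stage_seeds(self):
        auto = expand_seed(self.seed)
        return {
            "design": self.design_seed if self.design_seed is not None else auto[0],
            "cohort": self.cohort_seed if self.cohort_seed is not None else auto[1],
            "fit": self.fit_seed if self.fit_seed is not None else auto[2],
            "postfit": (
                self.postfit_seed if self.postfit_seed is not None else auto[3]
            ),
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        if "uptake_amounts" in d:
            cfg.uptake_amounts = tuple(d["uptake_amounts"])
        return cfg


@dataclass
class RunReport:
    cleaning: dict
    descriptives: str
    fit_summary: dict
    wta: pd.DataFrame
    uptake: pd.DataFrame
    diagnostics: dict
    config_echo: dict
    stage_log: list

    def to_dict(self) -> dict:
        return {
            "cleaning": self.cleaning,
            "descriptives": self.descriptives,
            "fit": self.fit_summary,
            "wta": self.wta.to_dict(orient="records"),
            "uptake": self.uptake.to_dict(orient="records"),
            "diagnostics": self.diagnostics,
            "config": self.config_echo,
            "stages": self.stage_log,
        }


def _log(stages, name, t0, **counts):
    stages.append(
        {"stage": name, "seconds": round(time.perf_counter() - t0, 3), **counts}
    )


def run_pipeline(config: RunConfig, catalog: AttributeCatalog | None = None) -> RunReport:
    """Execute all stages; identical config and seeds give identical numbers."""
    if catalog is None:
        catalog = (
            load_catalog(config.catalog_path)
            if config.catalog_path
            else default_catalog()
        )
    seeds = config.stage_seeds()
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    stages = []

    t0 = time.perf_counter()
    design = design_mod.generate_design(
        catalog, config.n_sets, config.n_blocks, seeds["design"],
        n_restarts=config.design_restarts,
    )
    diag = design.diagnostics
    _log(stages, "design", t0, n_sets=len(design.sets))
    if out:
        design_mod.design_to_frame(design, catalog).to_csv(
            out / "design.csv", index=False
        )

    t0 = time.perf_counter()
    prefs = table_preferences(sds_zero=config.sds_zero)
    cohort_cfg = CohortConfig(
        n_per_income=config.n_per_income,
        design=design,
        prefs=prefs,
        planted=config.planted,
        seed=seeds["cohort"],
    )
    cohort = simulate_cohort(cohort_cfg, catalog)
    _log(stages, "simulate", t0, n_respondents=cohort.n_respondents)
    if out:
        cohort.to_frame().to_csv(out / "cohort.csv", index=False)

    t0 = time.perf_counter()
    cleaned, report = clean_study(cohort)
    keep_after_dom = set(cleaned.respondents.respondent_id) | set(
        report.removed_ids["never_enrollers"]
    )
    descriptives = describe_enrollment(cohort.subset(keep_after_dom))
    _log(stages, "clean", t0, n_final=report.n_final)
    if out:
        with open(out / "cleaning_report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)

    t0 = time.perf_counter()
    encoded = to_long_format(cleaned, design, catalog)
    _log(stages, "encode", t0, n_obs=encoded.n_obs, n_rows=len(encoded.table))
    if out:
        encoded.table.to_csv(out / "encoded.csv", index=False)

    t0 = time.perf_counter()
    spec = ModelSpec(
        random_terms=list(encoded.attribute_columns),
        fixed_terms=list(encoded.fixed_columns),
        n_draws=config.n_draws,
        seed=seeds["fit"],
    )
    fit = MixedLogit(encoded, spec).fit()
    _log(stages, "fit", t0, loglik=round(fit.loglik, 2), converged=fit.converged)
    if out:
        fit.to_json(out / "fit.json")
        with open(out / "effects_table.txt", "w") as fh:
            fh.write(fit.summary(catalog))
        fit.effects_table(catalog).to_frame().to_csv(
            out / "effects_table.csv", index=False
        )

    t0 = time.perf_counter()
    wta_rows = []
    for term in encoded.attribute_columns:
        r = fit.wta_interval(
            term, n_draws=config.wta_draws, seed=seeds["postfit"]
        )
        near, far = r.display_interval()
        wta_rows.append(
            {
                "term": term,
                "wta": r.point,
                "ci_near": near,
                "ci_far": far,
                "level": r.level,
            }
        )
    wta_df = pd.DataFrame(wta_rows)

    best = postfit.ProgramConfig(
        amount=500,
        levels={
            "incentive_type": "cash",
            "schedule": "consistent",
            "sessions": "1/week",
            "location": "healthcare",
        },
    )
    uptake_rows = []
    for income in ("low", "middle", "high"):
        prog = postfit.ProgramConfig(
            amount=500, levels=best.levels, income_group=income
        )
        for pred in fit.uptake_curve(
            prog, catalog, config.uptake_amounts, seed=seeds["postfit"]
        ):
            uptake_rows.append(
                {
                    "income_group": income,
                    "amount": pred.program.amount,
                    "probability": pred.probability,
                }
            )
    uptake_df = pd.DataFrame(uptake_rows)
    indiff = fit.indifference_amount(
        postfit.ProgramConfig(
            amount=0,
            levels={a.name: a.omitted_level for a in catalog if not a.is_continuous},
        ),
        catalog,
    ) if fit.estimates["amount_rescaled"] > 0 else float("nan")
    _log(stages, "postfit", t0, n_wta=len(wta_df), n_uptake=len(uptake_df))
    if out:
        wta_df.to_csv(out / "wta.csv", index=False)
        uptake_df.to_csv(out / "uptake.csv", index=False)

    run = RunReport(
        cleaning=report.to_dict(),
        descriptives=descriptives.summary(),
        fit_summary={
            "loglik": fit.loglik,
            "converged": fit.converged,
            "n_obs": fit.n_obs,
            "estimates": {k: float(v) for k, v in fit.estimates.items()},
            "sds": {k: float(v) for k, v in fit.sds.items()},
            "indifference_amount_mean_program": indiff,
        },
        wta=wta_df,
        uptake=uptake_df,
        diagnostics={
            "design_d_error": diag.d_error,
            "design_flagged": design.flagged,
            "max_abs_column_correlation": diag.max_abs_column_correlation,
            "overlap_rate": diag.overlap_rate,
        },
        config_echo={
            **{
                k: getattr(config, k)
                for k in (
                    "n_sets", "n_blocks", "n_per_income", "planted",
                    "n_draws", "seed", "sds_zero",
                )
            },
            "stage_seeds": seeds,
            "uptake_amounts": list(config.uptake_amounts),
        },
        stage_log=stages,
    )
    if out:
        with open(out / "report.json", "w") as fh:
            json.dump(run.to_dict(), fh, indent=1, default=str)
    return run


# ---------------------------------------------------------------------------
# Canonical fixtures


FIXTURES = ("study-cohort", "tiny", "no-heterogeneity")


@functools.lru_cache(maxsize=8)
def _fixture_design(seed: int, n_sets: int = 30, n_blocks: int = 3, restarts: int = 4):
    return design_mod.generate_design(
        default_catalog(), n_sets, n_blocks, seed, n_restarts=restarts
    )


def make_fixture(name: str, seed: int = 20_2008):
    """Canonical test cohorts; returns (StudyDataset, manifest dict).

    ``study-cohort``: 460 completers across three income strata with 3
    planted nontraders, 15 dominance failers and 12 universal opt-outs, on a
    30-set / 3-block design.  ``tiny``: 12 respondents on one block.
    ``no-heterogeneity``: 500 respondents with all preference SDs zero.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    seeds = expand_seed(seed)
    if name == "study-cohort":
        design = _fixture_design(seeds[0])
        cfg = CohortConfig(
            n_per_income={"low": 150, "middle": 155, "high": 155},
            design=design,
            prefs=table_preferences(),
            planted={"nontrader": 3, "dominance_failer": 15, "never_enroller": 12},
            seed=seeds[1],
        )
    elif name == "tiny":
        design = _fixture_design(seeds[0], n_sets=10, n_blocks=1)
        cfg = CohortConfig(
            n_per_income={"low": 4, "middle": 4, "high": 4},
            design=design,
            prefs=table_preferences(),
            planted={},
            seed=seeds[1],
        )
    else:  # no-heterogeneity
        design = _fixture_design(seeds[0])
        cfg = CohortConfig(
            n_per_income={"low": 167, "middle": 167, "high": 166},
            design=design,
            prefs=table_preferences(sds_zero=True),
            planted={},
            seed=seeds[1],
        )
    data = simulate_cohort(cfg, default_catalog())
    manifest = {
        "name": name,
        "n_respondents": data.n_respondents,
        "planted": dict(cfg.planted),
        "n_tasks": cfg.n_tasks,
        "sds_zero": all(v == 0 for v in cfg.prefs.sds.values()),
        "seed": seed,
        "design": {"n_sets": len(design.sets), "n_blocks": design.n_blocks},
    }
    return data, manifest
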