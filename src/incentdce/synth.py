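"""Synthetic cohort generation under the random utility model.

Respondents carry individual coefficient vectors: effects-coded attribute
coefficients are drawn independently from normal distributions
beta_ik ~ N(b_k, w_k^2), while the money coefficient and the opt-out
alternative-specific constant (ASC) are fixed at their population values plus
income-group interactions (low income is the reference group).  Each task is
a three-alternative logit draw over (program A, program B, opt-out): when the
opt-out is drawn the respondent still reports the higher-utility program as
preferred but declines to enroll, mirroring a two-stage survey response with
a forced preference question.

Aberrant respondents can be planted for testing the downstream cleaning
rules: nontraders (always the same position), dominance-check failers, and
universal opt-outs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .catalog import (
    DEFAULT_RESCALE_UNIT,
    AttributeCatalog,
    BlockedDesign,
    ChoiceSet,
    default_catalog,
)

__all__ = [
    "TruePreferences",
    "IndividualCoefficients",
    "CohortConfig",
    "StudyDataset",
    "draw_respondent",
    "task_utilities",
    "simulate_task",
    "simulate_cohort",
    "table_preferences",
]

INCOME_GROUPS = ("low", "middle", "high")


@dataclass(frozen=True)
class TruePreferences:
    """Population preference parameters of the generating model.

    ``means``/``sds`` cover the effects-coded attribute columns (random
    coefficients); ``amount_coef`` is the fixed money coefficient per
    rescaled-£ unit; ``asc_optout`` the fixed opt-out constant; the two
    interaction maps shift amount and ASC for middle/high income relative to
    the low-income reference.
    """

    means: dict
    sds: dict
    amount_coef: float
    asc_optout: float
    amount_by_income: dict = field(default_factory=dict)
    asc_by_income: dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.sds) != set(self.means):
            raise ValueError("means and sds must cover the same coded columns")
        for k, v in self.sds.items():
            if v < 0:
                raise ValueError(f"negative sd for {k!r}")
        for d in (self.amount_by_income, self.asc_by_income):
            bad = set(d) - {"middle", "high"}
            if bad:
                raise ValueError(f"interactions only for middle/high, got {bad}")

    def amount_for(self, income: str) -> float:
        return self.amount_coef + self.amount_by_income.get(income, 0.0)

    def asc_for(self, income: str) -> float:
        return self.asc_optout + self.asc_by_income.get(income, 0.0)


def table_preferences(sds_zero: bool = False) -> TruePreferences:
    """Default generating preferences for the incentive-program experiment.

    Means and standard deviations per effects-coded column, a money
    coefficient of 0.046 per £10, an opt-out ASC of 1.102, and income
    interactions (amount: +0.065 middle / +0.007 high; ASC: +0.067 middle /
    +0.363 high).  ``sds_zero`` collapses the preference heterogeneity for
    degenerate-model tests.
    """
    means = {
        "incentive_type:cash": 0.331,
        "location:healthcare": 0.124,
        "schedule:consistent": 0.067,
        "sessions:1/fortnight": 0.221,
        "sessions:1/week": 0.273,
        "sessions:2/week": 0.114,
    }
    sds = {
        "incentive_type:cash": 0.416,
        "location:healthcare": 0.549,
        "schedule:consistent": 0.120,
        "sessions:1/fortnight": 0.393,
        "sessions:1/week": 0.290,
        "sessions:2/week": 0.022,
    }
    if sds_zero:
        sds = {k: 0.0 for k in sds}
    return TruePreferences(
        means=means,
        sds=sds,
        amount_coef=0.046,
        asc_optout=1.102,
        amount_by_income={"middle": 0.065, "high": 0.007},
        asc_by_income={"middle": 0.067, "high": 0.363},
    )


@dataclass(frozen=True)
class IndividualCoefficients:
    respondent_id: int
    beta: dict  # coded column -> individual coefficient
    income_group: str
    amount_coef: float = 0.0
    asc_optout: float = 0.0


def draw_respondent(
    prefs: TruePreferences, income: str, rng: np.random.Generator, respondent_id: int = 0
) -> IndividualCoefficients:
    """Draw one respondent's coefficient vector.

    Random columns are independent normals; the money coefficient and the
    ASC are deterministic given income group.
    """
    if income not in INCOME_GROUPS:
        raise ValueError(f"unknown income group {income!r}")
    beta = {
        k: float(rng.normal(prefs.means[k], prefs.sds[k])) for k in prefs.means
    }
    return IndividualCoefficients(
        respondent_id=respondent_id,
        beta=beta,
        income_group=income,
        amount_coef=prefs.amount_for(income),
        asc_optout=prefs.asc_for(income),
    )


def task_utilities(
    coefs: IndividualCoefficients,
    choice_set: ChoiceSet,
    catalog: AttributeCatalog,
    rescale_unit: float = DEFAULT_RESCALE_UNIT,
):
    """Deterministic utilities (V_A, V_B, V_optout) for one choice set."""
    cont = catalog.continuous_attribute
    cols = catalog.coded_columns
    vs = []
    for prof in choice_set.alternatives:
        x = catalog.code_profile(prof, rescale_unit=rescale_unit, center_amount=False)
        v = 0.0
        for name, xi in zip(cols, x):
            if cont is not None and name == cont.name:
                v += coefs.amount_coef * xi
            else:
                v += coefs.beta[name] * xi
        vs.append(v)
    return vs[0], vs[1], coefs.asc_optout


def simulate_task(
    coefs: IndividualCoefficients,
    choice_set: ChoiceSet,
    catalog: AttributeCatalog,
    rng: np.random.Generator,
    *,
    rescale_unit: float = DEFAULT_RESCALE_UNIT,
    sampler: str = "softmax",
):
    """Simulate one two-stage response from a three-alternative logit.

    ``sampler="softmax"`` draws the alternative directly from the logit
    probabilities; ``sampler="gumbel"`` adds independent standard Gumbel
    noise to the utilities and takes the argmax.  The two are distributionally
    identical (the classic extreme-value construction of the logit).
    """
    va, vb, vo = task_utilities(coefs, choice_set, catalog, rescale_unit)
    v = np.array([va, vb, vo])
    if sampler == "softmax":
        ev = np.exp(v - v.max())
        p = ev / ev.sum()
        k = int(rng.choice(3, p=p))
    elif sampler == "gumbel":
        k = int(np.argmax(v + rng.gumbel(size=3)))
    else:
        raise ValueError(f"unknown sampler {sampler!r}")
    if k == 2:  # opt-out: forced preference goes to the better program
        preferred = "A" if va >= vb else "B"
        return preferred, "no"
    return ("A", "B")[k], "yes"


@dataclass
class CohortConfig:
    """Study-condition configuration for one simulated cohort."""

    n_per_income: dict
    design: BlockedDesign
    prefs: TruePreferences
    planted: dict = field(default_factory=dict)  # behavior type -> count
    seed: int = 0
    rescale_unit: float = DEFAULT_RESCALE_UNIT
    sampler: str = "softmax"
    exclude_chance_aberrant: bool = True

    def __post_init__(self):
        total = sum(self.n_per_income.values())
        planted = sum(self.planted.values())
        if planted > total:
            raise ValueError("planted counts exceed cohort size")
        bad = set(self.planted) - {"nontrader", "dominance_failer", "never_enroller"}
        if bad:
            raise ValueError(f"unknown behavior types {bad}")

    @property
    def n_tasks(self) -> int:
        return min(self.design.block_sizes())


@dataclass
class StudyDataset:
    """Raw two-stage responses: one preferred/enroll pair per task.

    ``respondents`` has one row per respondent (respondent_id, income_group,
    block, behavior_type, dominance_response); ``responses`` one row per
    respondent x set (respondent_id, set_id, preferred, enroll).
    """

    respondents: pd.DataFrame
    responses: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Flat CSV form: one row per respondent x set with respondent columns."""
        return self.responses.merge(self.respondents, on="respondent_id")[
            [
                "respondent_id",
                "income_group",
                "block",
                "behavior_type",
                "set_id",
                "preferred",
                "enroll",
                "dominance_response",
            ]
        ]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StudyDataset":
        df = df.copy()
        if "behavior_type" not in df.columns:
            df["behavior_type"] = "model"
        resp_cols = ["respondent_id", "income_group", "block", "behavior_type"]
        if "dominance_response" in df.columns:
            resp_cols.append("dominance_response")
        respondents = df[resp_cols].drop_duplicates("respondent_id").reset_index(
            drop=True
        )
        if "dominance_response" not in respondents.columns:
            raise ValueError("dominance_response column is required")
        responses = df[["respondent_id", "set_id", "preferred", "enroll"]].reset_index(
            drop=True
        )
        return cls(respondents=respondents, responses=responses)

    @property
    def n_respondents(self) -> int:
        return len(self.respondents)

    def subset(self, keep_ids) -> "StudyDataset":
        keep = set(keep_ids)
        return StudyDataset(
            respondents=self.respondents[
                self.respondents.respondent_id.isin(keep)
            ].reset_index(drop=True),
            responses=self.responses[
                self.responses.respondent_id.isin(keep)
            ].reset_index(drop=True),
        )


def _assign_blocks(n_per_income: dict, n_blocks: int) -> list:
    """Round-robin block assignment within each income stratum.

    Guarantees per income x block counts differ by at most one.
    """
    out = []
    for income in INCOME_GROUPS:
        n = n_per_income.get(income, 0)
        out.extend((income, i % n_blocks) for i in range(n))
    return out


def _simulate_tasks(coefs, sets, catalog, rng, rescale_unit, sampler):
    return [
        simulate_task(
            coefs, s, catalog, rng, rescale_unit=rescale_unit, sampler=sampler
        )
        for s in sets
    ]


def simulate_cohort(
    config: CohortConfig, catalog: AttributeCatalog | None = None
) -> StudyDataset:
    """Simulate a full income-stratified cohort, fully reproducible from seed.

    Behavior types: ``nontrader`` reports the same position on every set,
    ``dominance_failer`` answers the dominance check wrongly, and
    ``never_enroller`` declines enrollment on every set; everyone else is
    model-driven.  With ``exclude_chance_aberrant`` (default), model-driven
    respondents whose simulated answers would by chance trip a cleaning rule
    are redrawn, so planted counts are exactly the counts the cleaning rules
    recover.
    """
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(config.seed)
    strata = _assign_blocks(config.n_per_income, config.design.n_blocks)

    # Interleave planted behaviors across income strata deterministically.
    behaviors = ["model"] * len(strata)
    slots = list(rng.permutation(len(strata)))
    i = 0
    for btype in ("nontrader", "dominance_failer", "never_enroller"):
        for _ in range(config.planted.get(btype, 0)):
            behaviors[slots[i]] = btype
            i += 1

    resp_rows, resp_answers = [], []
    for rid, ((income, block), btype) in enumerate(zip(strata, behaviors), start=1):
        coefs = draw_respondent(config.prefs, income, rng, respondent_id=rid)
        sets = config.design.sets_in_block(block)
        for _attempt in range(1000):
            answers = _simulate_tasks(
                coefs, sets, catalog, rng, config.rescale_unit, config.sampler
            )
            if btype == "nontrader":
                answers = [("A", e) for (_p, e) in answers]
            elif btype == "never_enroller":
                answers = [(p, "no") for (p, _e) in answers]
            if config.exclude_chance_aberrant and btype != "nontrader":
                # Redraw patterns that would be attributed to an earlier
                # cleaning rule than the planted one (or to any rule, for
                # model-driven respondents).
                chance_nontrader = len({p for p, _ in answers}) == 1
                chance_never = btype != "never_enroller" and all(
                    e == "no" for _, e in answers
                )
                if chance_nontrader or chance_never:
                    continue
            break
        else:  # pragma: no cover - would need pathological preferences
            raise RuntimeError("could not draw a non-aberrant respondent")
        dom = "fail" if btype == "dominance_failer" else "pass"
        resp_rows.append(
            {
                "respondent_id": rid,
                "income_group": income,
                "block": block,
                "behavior_type": btype,
                "dominance_response": dom,
            }
        )
        resp_answers.extend(
            {
                "respondent_id": rid,
                "set_id": s.set_id,
                "preferred": p,
                "enroll": e,
            }
            for s, (p, e) in zip(sets, answers)
        )

    return StudyDataset(
        respondents=pd.DataFrame(resp_rows),
        responses=pd.DataFrame(resp_answers),
    )


def cohort_config_from_yaml(path, design: BlockedDesign, prefs=None) -> CohortConfig:
    """Load cohort settings (sample sizes, planted counts, seed) from YAML."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "seed" not in d:
        raise ValueError("cohort config must state an explicit seed")
    return CohortConfig(
        n_per_income=dict(d["n_per_income"]),
        design=design,
        prefs=prefs or table_preferences(),
        planted=dict(d.get("planted", {})),
        seed=int(d["seed"]),
        rescale_unit=float(d.get("rescale_unit", DEFAULT_RESCALE_UNIT)),
        sampler=d.get("sampler", "softmax"),
    )
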