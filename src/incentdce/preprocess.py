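"""Exclusion cascade, descriptive enrollment statistics, and encoding.

Cleaning applies three rules sequentially, each to the survivors of the
previous: nontraders (same preferred position on every set), dominance-check
failers, and never-enrollers (enroll = no on every set).  Each removed
respondent is attributed to the first rule that catches them, so the report
counts reconcile exactly with the final sample size.

Encoding expands each respondent-task into three alternative rows (program A,
program B, opt-out) in the long format the estimator consumes: effects-coded
attribute columns and a rescaled money column on program rows; an
alternative-specific constant (ASC) plus income interactions on the opt-out
row; a single chosen indicator per task.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .catalog import (
    DEFAULT_RESCALE_UNIT,
    AttributeCatalog,
    BlockedDesign,
    CatalogError,
)
from .synth import StudyDataset

__all__ = [
    "CleaningReport",
    "DescriptiveStats",
    "EncodedDataset",
    "detect_nontraders",
    "apply_dominance_filter",
    "detect_never_enrollers",
    "clean_study",
    "describe_enrollment",
    "effects_code",
    "rescale_amount",
    "to_long_format",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding for display (3.145 -> 3.15 at 2 digits)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CleaningReport:
    n_input: int
    n_nontraders_removed: int
    n_dominance_removed: int
    n_never_enrollers_removed: int
    n_final: int
    removed_ids: dict = field(default_factory=dict)

    def __post_init__(self):
        removed = (
            self.n_nontraders_removed
            + self.n_dominance_removed
            + self.n_never_enrollers_removed
        )
        assert self.n_final == self.n_input - removed

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_nontraders_removed": self.n_nontraders_removed,
            "n_dominance_removed": self.n_dominance_removed,
            "n_never_enrollers_removed": self.n_never_enrollers_removed,
            "n_final": self.n_final,
            "removed_ids": {k: sorted(v) for k, v in self.removed_ids.items()},
        }


@dataclass
class DescriptiveStats:
    """Enrollment descriptives on the sample retained after the dominance rule."""

    n_always_enroll: int
    n_never_enroll: int
    n_enroll_responses: int
    n_responses: int
    denominator_n: int

    @property
    def pct_always_enroll(self) -> float:
        return round_half_up(100.0 * self.n_always_enroll / self.denominator_n)

    @property
    def pct_never_enroll(self) -> float:
        return round_half_up(100.0 * self.n_never_enroll / self.denominator_n)

    @property
    def pct_enroll_responses(self) -> float:
        return round_half_up(100.0 * self.n_enroll_responses / self.n_responses)

    def summary(self) -> str:
        return (
            f"{self.pct_always_enroll:.2f}% (n = {self.n_always_enroll}) of "
            f"{self.denominator_n} participants would enroll in all programs; "
            f"{self.pct_never_enroll:.2f}% (n = {self.n_never_enroll}) in none; "
            f"{self.pct_enroll_responses:.2f}% of all responses were "
            "'would enroll'."
        )


def detect_nontraders(data: StudyDataset) -> list:
    """Respondents whose preferred position never varies (always A or always B)."""
    flagged = []
    for rid, grp in data.responses.groupby("respondent_id"):
        if grp["preferred"].nunique() == 1:
            flagged.append(rid)
    return sorted(flagged)


def apply_dominance_filter(data: StudyDataset) -> list:
    """Respondents who did not pick the dominant option of the attention check."""
    dom = data.respondents["dominance_response"]
    if dom.isna().any():
        raise CatalogError("dominance_response missing for some respondents")
    return sorted(
        data.respondents.loc[dom == "fail", "respondent_id"].tolist()
    )


def detect_never_enrollers(data: StudyDataset) -> list:
    """Respondents answering enroll = no on every task."""
    flagged = []
    for rid, grp in data.responses.groupby("respondent_id"):
        if (grp["enroll"] == "no").all():
            flagged.append(rid)
    return sorted(flagged)


def clean_study(data: StudyDataset):
    """Sequential exclusion cascade; returns (cleaned data, report).

    Order: nontraders, then dominance failures, then never-enrollers, each
    rule applied to the survivors of the previous one, so a respondent is
    attributed to exactly one rule.
    """
    tasks_per = data.responses.groupby("respondent_id").size()
    if tasks_per.nunique() > 1:
        raise ValueError(
            "partial respondents are not supported: every respondent must "
            "answer the same number of tasks"
        )
    n_input = data.n_respondents
    nontraders = detect_nontraders(data)
    data1 = data.subset(set(data.respondents.respondent_id) - set(nontraders))
    dom = apply_dominance_filter(data1)
    data2 = data1.subset(set(data1.respondents.respondent_id) - set(dom))
    never = detect_never_enrollers(data2)
    data3 = data2.subset(set(data2.respondents.respondent_id) - set(never))
    report = CleaningReport(
        n_input=n_input,
        n_nontraders_removed=len(nontraders),
        n_dominance_removed=len(dom),
        n_never_enrollers_removed=len(never),
        n_final=data3.n_respondents,
        removed_ids={
            "nontraders": nontraders,
            "dominance": dom,
            "never_enrollers": never,
        },
    )
    return data3, report


def describe_enrollment(data_after_dominance: StudyDataset) -> DescriptiveStats:
    """Enrollment descriptives.

    The input must be the sample after nontrader and dominance exclusions but
    *before* never-enroller exclusion: the all-enroll and never-enroll
    percentages share that denominator.
    """
    resp = data_after_dominance.responses
    per = resp.groupby("respondent_id")["enroll"].agg(
        always=lambda s: (s == "yes").all(), never=lambda s: (s == "no").all()
    )
    return DescriptiveStats(
        n_always_enroll=int(per["always"].sum()),
        n_never_enroll=int(per["never"].sum()),
        n_enroll_responses=int((resp["enroll"] == "yes").sum()),
        n_responses=len(resp),
        denominator_n=data_after_dominance.n_respondents,
    )


def effects_code(catalog: AttributeCatalog, attribute: str, level) -> np.ndarray:
    """Effects-coded vector of one level of a categorical attribute.

    L levels give L−1 columns; a non-omitted level is +1 in its own column
    and 0 elsewhere; the omitted level is −1 everywhere, so the implied
    effect of the omitted level is the negative sum of the others.
    """
    spec = catalog[attribute]
    if spec.is_continuous:
        raise CatalogError(f"{attribute!r} is continuous, not effects-coded")
    if level not in spec.levels:
        raise CatalogError(f"unknown level {level!r} for {attribute!r}")
    if level == spec.omitted_level:
        return -np.ones(len(spec.coded_levels))
    return np.array([1.0 if level == l else 0.0 for l in spec.coded_levels])


def rescale_amount(amount_gbp: float, unit: float = DEFAULT_RESCALE_UNIT) -> float:
    """Continuous money attribute in coded units (default £10 per unit)."""
    if unit <= 0:
        raise ValueError("rescale unit must be positive")
    if amount_gbp < 0:
        raise ValueError("negative amount")
    return float(amount_gbp) / float(unit)


@dataclass
class EncodedDataset:
    """Three-alternative long format ready for estimation."""

    table: pd.DataFrame
    attribute_columns: list
    fixed_columns: list
    rescale_unit: float

    @property
    def n_obs(self) -> int:
        """Respondent-task count (one chosen alternative per task)."""
        return self.table.groupby(["respondent_id", "task_id"]).ngroups

    @property
    def n_respondents(self) -> int:
        return self.table["respondent_id"].nunique()


AMOUNT_COL = "amount_rescaled"
ASC_COL = "asc_no_program"


def interaction_columns():
    return [
        f"{AMOUNT_COL}:middle",
        f"{AMOUNT_COL}:high",
        f"{ASC_COL}:middle",
        f"{ASC_COL}:high",
    ]


def to_long_format(
    clean: StudyDataset,
    design: BlockedDesign,
    catalog: AttributeCatalog,
    unit: float = DEFAULT_RESCALE_UNIT,
    *,
    income_interactions: bool = True,
) -> EncodedDataset:
    """Expand cleaned two-stage responses into the estimation table.

    Each respondent-task becomes three rows (A, B, opt-out).  Program rows
    carry the rescaled amount, effects-coded attribute columns, and
    amount-by-income interactions; the opt-out row carries the ASC and its
    income interactions, zeros elsewhere.  The chosen row is the opt-out when
    enroll = no, otherwise the preferred program.
    """
    cont = catalog.continuous_attribute
    eff_cols = catalog.effects_columns
    income_of = dict(
        zip(clean.respondents.respondent_id, clean.respondents.income_group)
    )
    known_sets = {s.set_id: s for s in design.sets}

    # Precompute coded rows per (set, position)
    coded = {}
    for sid, s in known_sets.items():
        for pos, prof in zip(("A", "B"), s.alternatives):
            x = catalog.code_profile(prof, rescale_unit=unit, center_amount=False)
            coded[(sid, pos)] = dict(zip(catalog.coded_columns, x))

    rows = []
    for rec in clean.responses.itertuples(index=False):
        if rec.set_id not in known_sets:
            raise CatalogError(f"respondent references unknown set {rec.set_id}")
        income = income_of[rec.respondent_id]
        chosen_alt = "optout" if rec.enroll == "no" else rec.preferred
        for alt in ("A", "B", "optout"):
            row = {
                "respondent_id": rec.respondent_id,
                "task_id": rec.set_id,
                "alt_id": alt,
                "chosen": int(alt == chosen_alt),
                AMOUNT_COL: 0.0,
                ASC_COL: 0.0,
            }
            row.update({c: 0.0 for c in eff_cols})
            row.update({c: 0.0 for c in interaction_columns()})
            if alt == "optout":
                row[ASC_COL] = 1.0
                if income_interactions and income in ("middle", "high"):
                    row[f"{ASC_COL}:{income}"] = 1.0
            else:
                x = coded[(rec.set_id, alt)]
                for c in eff_cols:
                    row[c] = x[c]
                if cont is not None:
                    row[AMOUNT_COL] = x[cont.name]
                    if income_interactions and income in ("middle", "high"):
                        row[f"{AMOUNT_COL}:{income}"] = x[cont.name]
            rows.append(row)

    table = pd.DataFrame(rows)
    fixed = [AMOUNT_COL, ASC_COL]
    if income_interactions:
        fixed += interaction_columns()
    return EncodedDataset(
        table=table,
        attribute_columns=eff_cols,
        fixed_columns=fixed,
        rescale_unit=unit,
    )
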