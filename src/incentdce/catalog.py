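"""Attribute catalogs, profiles, choice sets, and coding.

A discrete choice experiment (DCE) describes hypothetical alternatives by a
small set of attributes, each taking one of a few levels.  This module holds
the experimental-design vocabulary: the attribute catalog (one continuous
money attribute plus categorical attributes), single program profiles, paired
choice sets, and blocked designs.  It also owns the coded representation used
everywhere downstream — effects coding for categorical attributes (omitted
level coded −1 in every column, so level effects sum to zero) and a linearly
rescaled continuous amount.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "AttributeSpec",
    "AttributeCatalog",
    "Profile",
    "ChoiceSet",
    "BlockedDesign",
    "default_catalog",
    "DEFAULT_RESCALE_UNIT",
]

#: Default rescale unit for the continuous incentive amount, in £ per coded unit.
DEFAULT_RESCALE_UNIT = 10.0


class CatalogError(ValueError):
    """Raised for invalid catalogs, unknown levels, or unusable configurations."""


@dataclass(frozen=True)
class AttributeSpec:
    """One attribute of the choice alternatives.

    Parameters
    ----------
    name : str
        Unique attribute name.
    levels : sequence
        Ordered level labels (categorical) or strictly increasing numeric
        values in £ (continuous).
    coding : {"effects", "continuous"}
        How the attribute enters the coded design matrix.
    omitted_level : str, optional
        Reference level for effects coding; coded −1 in every column of the
        attribute.  Required when ``coding == "effects"``.
    preference_direction : sequence, optional
        Levels ordered from worst to best.  Used only to build and reject
        dominated choice sets; the analysis itself never consults it.
    """

    name: str
    levels: tuple
    coding: str = "effects"
    omitted_level: object | None = None
    preference_direction: tuple | None = None

    def __post_init__(self):
        levels = tuple(self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) < 2:
            raise CatalogError(f"attribute {self.name!r} needs >= 2 levels")
        if len(set(levels)) != len(levels):
            raise CatalogError(f"attribute {self.name!r} has duplicate levels")
        if self.coding not in ("effects", "continuous"):
            raise CatalogError(f"unknown coding {self.coding!r}")
        if self.coding == "continuous":
            vals = [float(v) for v in levels]
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise CatalogError(
                    f"continuous attribute {self.name!r} levels must be strictly increasing"
                )
        else:
            if self.omitted_level is None:
                raise CatalogError(
                    f"effects-coded attribute {self.name!r} needs an omitted_level"
                )
            if self.omitted_level not in levels:
                raise CatalogError(
                    f"omitted_level {self.omitted_level!r} not a level of {self.name!r}"
                )
        if self.preference_direction is not None:
            pd_ = tuple(self.preference_direction)
            object.__setattr__(self, "preference_direction", pd_)
            if sorted(map(str, pd_)) != sorted(map(str, levels)):
                raise CatalogError(
                    f"preference_direction of {self.name!r} must order exactly its levels"
                )

    @property
    def is_continuous(self) -> bool:
        return self.coding == "continuous"

    @property
    def coded_levels(self) -> tuple:
        """Non-omitted levels, i.e. the levels that get their own column."""
        if self.is_continuous:
            return ()
        return tuple(l for l in self.levels if l != self.omitted_level)

    def best_level(self):
        if self.preference_direction is None:
            raise CatalogError(f"no preference_direction for {self.name!r}")
        return self.preference_direction[-1]

    def worst_level(self):
        if self.preference_direction is None:
            raise CatalogError(f"no preference_direction for {self.name!r}")
        return self.preference_direction[0]


@dataclass(frozen=True)
class AttributeCatalog:
    """Ordered collection of attributes defining the design space."""

    attributes: tuple

    def __post_init__(self):
        attrs = tuple(self.attributes)
        object.__setattr__(self, "attributes", attrs)
        if not attrs:
            raise CatalogError("empty catalog is unusable")
        names = [a.name for a in attrs]
        if len(set(names)) != len(names):
            raise CatalogError("attribute names must be unique")
        n_cont = sum(a.is_continuous for a in attrs)
        if n_cont > 1:
            raise CatalogError("at most one continuous attribute is supported")

    def __iter__(self):
        return iter(self.attributes)

    def __getitem__(self, name: str) -> AttributeSpec:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def names(self) -> list:
        return [a.name for a in self.attributes]

    @property
    def continuous_attribute(self) -> AttributeSpec | None:
        for a in self.attributes:
            if a.is_continuous:
                return a
        return None

    @property
    def coded_columns(self) -> list:
        """Names of coded design columns, continuous first then effects columns."""
        cols = []
        for a in self.attributes:
            if a.is_continuous:
                cols.append(a.name)
            else:
                cols.extend(f"{a.name}:{lvl}" for lvl in a.coded_levels)
        return cols

    @property
    def effects_columns(self) -> list:
        """Coded columns excluding the continuous amount."""
        cont = self.continuous_attribute
        skip = cont.name if cont is not None else None
        return [c for c in self.coded_columns if c != skip]

    def code_profile(
        self,
        profile: "Profile",
        *,
        rescale_unit: float = DEFAULT_RESCALE_UNIT,
        center_amount: bool = False,
    ) -> np.ndarray:
        """Coded row vector for one profile, ordered as ``coded_columns``.

        The continuous amount is divided by ``rescale_unit``; with
        ``center_amount`` it is first centered at the mean of its catalog
        levels (used for the null-prior information matrix, where a centered
        column keeps the money coefficient on a comparable footing).
        """
        out = []
        for a in self.attributes:
            level = profile.assignment.get(a.name)
            if level is None:
                raise CatalogError(f"profile missing attribute {a.name!r}")
            if a.is_continuous:
                x = float(level)
                if center_amount:
                    x -= float(np.mean([float(v) for v in a.levels]))
                out.append(x / float(rescale_unit))
            else:
                if level not in a.levels:
                    raise CatalogError(f"unknown level {level!r} for {a.name!r}")
                for lvl in a.coded_levels:
                    if level == a.omitted_level:
                        out.append(-1.0)
                    else:
                        out.append(1.0 if level == lvl else 0.0)
        return np.asarray(out, dtype=float)


@dataclass(frozen=True)
class Profile:
    """A single hypothetical program: one level per catalog attribute."""

    assignment: Mapping

    def __post_init__(self):
        object.__setattr__(self, "assignment", dict(self.assignment))

    def validate(self, catalog: AttributeCatalog) -> None:
        for a in catalog:
            if a.name not in self.assignment:
                raise CatalogError(f"profile missing attribute {a.name!r}")
            if self.assignment[a.name] not in a.levels:
                raise CatalogError(
                    f"unknown level {self.assignment[a.name]!r} for {a.name!r}"
                )
        extra = set(self.assignment) - set(catalog.names)
        if extra:
            raise CatalogError(f"profile has unknown attributes {sorted(extra)}")

    def __eq__(self, other):
        return isinstance(other, Profile) and self.assignment == other.assignment

    def __hash__(self):
        return hash(tuple(sorted((k, str(v)) for k, v in self.assignment.items())))


@dataclass(frozen=True)
class ChoiceSet:
    """A paired choice set: positions A and B."""

    set_id: int
    alternatives: tuple  # (Profile A, Profile B)

    def __post_init__(self):
        alts = tuple(self.alternatives)
        object.__setattr__(self, "alternatives", alts)
        if len(alts) != 2:
            raise CatalogError("a choice set holds exactly two alternatives")
        if alts[0] == alts[1]:
            raise CatalogError("alternatives of a choice set must differ")

    @property
    def a(self) -> Profile:
        return self.alternatives[0]

    @property
    def b(self) -> Profile:
        return self.alternatives[1]


@dataclass
class BlockedDesign:
    """A list of choice sets partitioned into near-equal blocks."""

    sets: list
    block_of: dict = field(default_factory=dict)
    n_blocks: int = 1
    flagged: bool = False
    diagnostics: object | None = None

    def __post_init__(self):
        ids = [s.set_id for s in self.sets]
        if len(set(ids)) != len(ids):
            raise CatalogError("duplicate set_id in design")
        if self.block_of:
            if set(self.block_of) != set(ids):
                raise CatalogError("block_of must cover exactly the design's set_ids")
            sizes = self.block_sizes()
            if max(sizes) - min(sizes) > 1:
                raise CatalogError("block sizes must differ by at most 1")
        else:
            self.block_of = {i: 0 for i in ids}
            self.n_blocks = 1

    def block_sizes(self) -> list:
        counts = [0] * self.n_blocks
        for b in self.block_of.values():
            counts[b] += 1
        return counts

    def sets_in_block(self, block: int) -> list:
        return [s for s in self.sets if self.block_of[s.set_id] == block]

    def set_by_id(self, set_id: int) -> ChoiceSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)


def default_catalog() -> AttributeCatalog:
    """The five-attribute incentive-program catalog.

    Seven total incentive amounts (£50–£1,000 over the 10-week program),
    incentive type (voucher/cash), reward schedule (escalating with reset /
    consistent weekly amount), session frequency (fortnightly up to three per
    week), and program location (healthcare center / workplace).  Preference
    directions follow the aggregate preferences the attributes are expected to
    show (higher amounts, cash, consistent schedule, one session per week
    best and three per week worst, healthcare setting); they matter only for
    dominance-set construction.
    """
    return AttributeCatalog(
        attributes=(
            AttributeSpec(
                name="amount",
                levels=(50, 100, 200, 350, 500, 750, 1000),
                coding="continuous",
                preference_direction=(50, 100, 200, 350, 500, 750, 1000),
            ),
            AttributeSpec(
                name="incentive_type",
                levels=("voucher", "cash"),
                coding="effects",
                omitted_level="voucher",
                preference_direction=("voucher", "cash"),
            ),
            AttributeSpec(
                name="schedule",
                levels=("escalating", "consistent"),
                coding="effects",
                omitted_level="escalating",
                preference_direction=("escalating", "consistent"),
            ),
            AttributeSpec(
                name="sessions",
                levels=("1/fortnight", "1/week", "2/week", "3/week"),
                coding="effects",
                omitted_level="3/week",
                preference_direction=("3/week", "2/week", "1/fortnight", "1/week"),
            ),
            AttributeSpec(
                name="location",
                levels=("workplace", "healthcare"),
                coding="effects",
                omitted_level="workplace",
                preference_direction=("workplace", "healthcare"),
            ),
        )
    )


# ---------------------------------------------------------------------------
# YAML catalog I/O


def catalog_to_dict(catalog: AttributeCatalog) -> dict:
    out = []
    for a in catalog:
        d = {"name": a.name, "levels": list(a.levels), "coding": a.coding}
        if a.omitted_level is not None:
            d["omitted_level"] = a.omitted_level
        if a.preference_direction is not None:
            d["preference_direction"] = list(a.preference_direction)
        out.append(d)
    return {"attributes": out}


def catalog_from_dict(d: Mapping) -> AttributeCatalog:
    attrs = []
    for spec in d["attributes"]:
        attrs.append(
            AttributeSpec(
                name=spec["name"],
                levels=tuple(spec["levels"]),
                coding=spec.get("coding", "effects"),
                omitted_level=spec.get("omitted_level"),
                preference_direction=(
                    tuple(spec["preference_direction"])
                    if spec.get("preference_direction")
                    else None
                ),
            )
        )
    return AttributeCatalog(attributes=tuple(attrs))


def save_catalog(catalog: AttributeCatalog, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(catalog_to_dict(catalog), fh, sort_keys=False)


def load_catalog(path) -> AttributeCatalog:
    with open(path) as fh:
        return catalog_from_dict(yaml.safe_load(fh))
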