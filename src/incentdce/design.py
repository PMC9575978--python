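"""Utility-neutral (null-prior) paired choice design construction.

The information matrix of the paired conditional logit evaluated at zero
coefficients reduces to M = (1/4) * sum_s z_s z_s', where z_s is the coded
difference between the two alternatives of set s.  The D-error is
det(M^-1)^(1/p) with p coded columns; lower is better.  Designs are built by
coordinate exchange from random starts with multiple restarts, rejecting
degenerate (identical) and dominated pairs, then blocked by a greedy
level-balance heuristic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import (
    DEFAULT_RESCALE_UNIT,
    AttributeCatalog,
    BlockedDesign,
    CatalogError,
    ChoiceSet,
    Profile,
)

__all__ = [
    "enumerate_profiles",
    "d_error_null",
    "generate_design",
    "diagnose",
    "build_dominance_set",
    "DesignDiagnostics",
    "design_to_frame",
    "design_from_frame",
]


@dataclass
class DesignDiagnostics:
    """Level balance, overlap, near-orthogonality, and efficiency summaries."""

    level_counts: dict  # attribute -> {level: count over all alternatives}
    overlap_rate: dict  # attribute -> fraction of sets with equal levels
    max_abs_column_correlation: float
    d_error: float

    def level_spread(self, attribute: str) -> int:
        counts = self.level_counts[attribute]
        return max(counts.values()) - min(counts.values())


def enumerate_profiles(catalog: AttributeCatalog) -> list:
    """Full factorial candidate set, lexicographic in catalog order."""
    names = catalog.names
    level_lists = [list(a.levels) for a in catalog]
    return [
        Profile(dict(zip(names, combo)))
        for combo in itertools.product(*level_lists)
    ]


def _design_code(
    catalog: AttributeCatalog,
    profile: Profile,
    rescale_unit: float,
    amount_coding: str,
) -> np.ndarray:
    """Coded row for the information matrix.

    ``amount_coding="continuous"`` codes the money attribute as a centered
    linear column (matching how it enters the analysis);
    ``"factor"`` effects-codes it over its levels (omitting the first), the
    factorial treatment that enforces level balance during the search.
    """
    if amount_coding == "continuous":
        return catalog.code_profile(
            profile, rescale_unit=rescale_unit, center_amount=True
        )
    if amount_coding != "factor":
        raise CatalogError(f"unknown amount_coding {amount_coding!r}")
    out = []
    for a in catalog:
        level = profile.assignment[a.name]
        if a.is_continuous:
            coded_levels = a.levels[1:]
            if level == a.levels[0]:
                out.extend([-1.0] * len(coded_levels))
            else:
                out.extend(1.0 if level == lvl else 0.0 for lvl in coded_levels)
        else:
            if level not in a.levels:
                raise CatalogError(f"unknown level {level!r} for {a.name!r}")
            for lvl in a.coded_levels:
                if level == a.omitted_level:
                    out.append(-1.0)
                else:
                    out.append(1.0 if level == lvl else 0.0)
    return np.asarray(out, dtype=float)


def _diff_matrix(
    sets, catalog: AttributeCatalog, rescale_unit: float, amount_coding: str = "continuous"
) -> np.ndarray:
    rows = [
        _design_code(catalog, s.a, rescale_unit, amount_coding)
        - _design_code(catalog, s.b, rescale_unit, amount_coding)
        for s in sets
    ]
    return np.asarray(rows, dtype=float)


def _d_error_from_Z(Z: np.ndarray) -> float:
    p = Z.shape[1]
    M = (Z.T @ Z) / 4.0
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0 or not np.isfinite(logdet):
        return np.inf
    # det(M^-1)^(1/p) = exp(-logdet(M)/p)
    return float(np.exp(-logdet / p))


def d_error_null(
    sets,
    catalog: AttributeCatalog,
    *,
    rescale_unit: float = DEFAULT_RESCALE_UNIT,
    amount_coding: str = "continuous",
) -> float:
    """Null-prior D-error of a list of paired choice sets.

    Returns ``+inf`` when the information matrix is singular (e.g. every set
    pairs identical profiles, or too few sets for the number of columns).
    ``amount_coding="factor"`` evaluates the factorial parameterization used
    by the design search (see :func:`generate_design`).
    """
    if not sets:
        raise CatalogError("no choice sets supplied")
    return _d_error_from_Z(_diff_matrix(sets, catalog, rescale_unit, amount_coding))


def _dominates(p: Profile, q: Profile, catalog: AttributeCatalog, *, strict=True) -> bool:
    """True when p beats q on every attribute per preference_direction."""
    all_equal = True
    for a in catalog:
        if a.preference_direction is None:
            return False
        rank = {lvl: i for i, lvl in enumerate(a.preference_direction)}
        rp, rq = rank[p.assignment[a.name]], rank[q.assignment[a.name]]
        if rp < rq:
            return False
        if rp > rq:
            all_equal = False
    if strict:
        # strict dominance on every attribute
        for a in catalog:
            rank = {lvl: i for i, lvl in enumerate(a.preference_direction)}
            if rank[p.assignment[a.name]] <= rank[q.assignment[a.name]]:
                return False
        return True
    return not all_equal


def _pair_ok(p: Profile, q: Profile, catalog: AttributeCatalog, check_dominance: bool) -> bool:
    if p == q:
        return False
    if check_dominance and (
        _dominates(p, q, catalog) or _dominates(q, p, catalog)
    ):
        return False
    return True


def is_dominated_pair(choice_set: ChoiceSet, catalog: AttributeCatalog) -> bool:
    """Whether one alternative strictly dominates the other (needs directions)."""
    return _dominates(choice_set.a, choice_set.b, catalog) or _dominates(
        choice_set.b, choice_set.a, catalog
    )


def _random_pairs(catalog, n_sets, rng, check_dominance):
    pairs = []
    names = catalog.names
    level_lists = [list(a.levels) for a in catalog]
    while len(pairs) < n_sets:
        a = Profile({n: lv[rng.integers(len(lv))] for n, lv in zip(names, level_lists)})
        b = Profile({n: lv[rng.integers(len(lv))] for n, lv in zip(names, level_lists)})
        if _pair_ok(a, b, catalog, check_dominance):
            pairs.append((a, b))
    return pairs


def _coordinate_exchange(
    pairs, catalog, rng, rescale_unit, check_dominance, amount_coding, max_passes=25
):
    """Greedy per-coordinate improvement of the null-prior D-error."""
    sets = [ChoiceSet(i, (a, b)) for i, (a, b) in enumerate(pairs)]
    Z = _diff_matrix(sets, catalog, rescale_unit, amount_coding)
    best = _d_error_from_Z(Z)
    pairs = [list(pr) for pr in pairs]
    for _ in range(max_passes):
        improved = False
        for s_idx in range(len(pairs)):
            for pos in (0, 1):
                for attr in catalog:
                    current = pairs[s_idx][pos].assignment[attr.name]
                    for level in attr.levels:
                        if level == current:
                            continue
                        cand = dict(pairs[s_idx][pos].assignment)
                        cand[attr.name] = level
                        cand_prof = Profile(cand)
                        other = pairs[s_idx][1 - pos]
                        if not _pair_ok(cand_prof, other, catalog, check_dominance):
                            continue
                        new_pair = (
                            (cand_prof, other) if pos == 0 else (other, cand_prof)
                        )
                        z_new = _design_code(
                            catalog, new_pair[0], rescale_unit, amount_coding
                        ) - _design_code(
                            catalog, new_pair[1], rescale_unit, amount_coding
                        )
                        Z_try = Z.copy()
                        Z_try[s_idx] = z_new
                        d = _d_error_from_Z(Z_try)
                        if d < best - 1e-12:
                            best = d
                            Z = Z_try
                            pairs[s_idx][pos] = cand_prof
                            improved = True
        if not improved:
            break
    return [tuple(pr) for pr in pairs], best


def _block_greedy(sets, n_blocks, catalog):
    """Greedy blocking minimizing squared level-count imbalance, ties by set_id."""
    size = len(sets) // n_blocks
    counts = [
        {a.name: {lvl: 0 for lvl in a.levels} for a in catalog}
        for _ in range(n_blocks)
    ]
    fill = [0] * n_blocks
    block_of = {}
    for s in sorted(sets, key=lambda s: s.set_id):
        best_block, best_score = None, None
        for b in range(n_blocks):
            if fill[b] >= size:
                continue
            score = 0.0
            for prof in s.alternatives:
                for a in catalog:
                    c = counts[b][a.name][prof.assignment[a.name]] + 1
                    score += c * c
            if best_score is None or score < best_score:
                best_block, best_score = b, score
        block_of[s.set_id] = best_block
        fill[best_block] += 1
        for prof in s.alternatives:
            for a in catalog:
                counts[best_block][a.name][prof.assignment[a.name]] += 1
    return block_of


def generate_design(
    catalog: AttributeCatalog,
    n_sets: int,
    n_blocks: int,
    seed: int,
    *,
    n_restarts: int = 20,
    rescale_unit: float = DEFAULT_RESCALE_UNIT,
    reject_dominated: bool | None = None,
    amount_coding: str = "factor",
    max_overlap_rate: float = 0.5,
    max_level_spread: int | None = None,
) -> BlockedDesign:
    """Search a utility-neutral paired design and block it.

    Coordinate exchange from ``n_restarts`` random starts minimizes the
    null-prior D-error; candidate pairs that are identical or (when every
    attribute carries a preference direction) strictly dominated are rejected.
    By default the search codes the money attribute as a factor over its
    levels (``amount_coding="factor"``), the fractional-factorial treatment
    that drives the search toward level balance across the full amount range;
    a purely linear money column would concentrate on the two extreme
    amounts.  The best design found is blocked greedily and returned; if it
    misses the diagnostic thresholds it is still returned, with
    ``flagged=True`` and a warning.
    """
    if n_sets % n_blocks != 0:
        raise CatalogError("n_sets must be divisible by n_blocks (equal blocks)")
    p = len(catalog.coded_columns)
    if n_sets < p:
        raise CatalogError(f"need at least {p} sets for {p} coded columns")
    if reject_dominated is None:
        reject_dominated = all(a.preference_direction is not None for a in catalog)

    rng = np.random.default_rng(seed)
    best_pairs, best_d = None, np.inf
    for _ in range(n_restarts):
        start = _random_pairs(catalog, n_sets, rng, reject_dominated)
        pairs, d = _coordinate_exchange(
            start, catalog, rng, rescale_unit, reject_dominated, amount_coding
        )
        if d < best_d:
            best_pairs, best_d = pairs, d

    sets = [ChoiceSet(i + 1, pr) for i, pr in enumerate(best_pairs)]
    block_of = _block_greedy(sets, n_blocks, catalog)
    design = BlockedDesign(sets=sets, block_of=block_of, n_blocks=n_blocks)
    diag = diagnose(design, catalog, rescale_unit=rescale_unit)
    design.diagnostics = diag

    ok = all(r <= max_overlap_rate for r in diag.overlap_rate.values())
    if max_level_spread is not None:
        ok = ok and all(
            diag.level_spread(a.name) <= max_level_spread
            for a in catalog
            if not a.is_continuous
        )
    if not ok:
        design.flagged = True
        warnings.warn(
            "generated design misses diagnostic thresholds; best-found returned",
            stacklevel=2,
        )
    return design


def diagnose(
    design: BlockedDesign,
    catalog: AttributeCatalog,
    *,
    rescale_unit: float = DEFAULT_RESCALE_UNIT,
) -> DesignDiagnostics:
    """Level counts, per-attribute overlap rates, max |correlation|, D-error."""
    level_counts = {
        a.name: {lvl: 0 for lvl in a.levels} for a in catalog
    }
    overlap = {a.name: 0 for a in catalog}
    coded_rows = []
    for s in design.sets:
        for prof in s.alternatives:
            prof.validate(catalog)
            for a in catalog:
                level_counts[a.name][prof.assignment[a.name]] += 1
            coded_rows.append(
                catalog.code_profile(
                    prof, rescale_unit=rescale_unit, center_amount=True
                )
            )
        for a in catalog:
            if s.a.assignment[a.name] == s.b.assignment[a.name]:
                overlap[a.name] += 1
    n_sets = len(design.sets)
    X = np.asarray(coded_rows)
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.atleast_2d(np.nan_to_num(C))
    np.fill_diagonal(C, 0.0)
    return DesignDiagnostics(
        level_counts=level_counts,
        overlap_rate={k: v / n_sets for k, v in overlap.items()},
        max_abs_column_correlation=float(np.max(np.abs(C))) if C.size else 0.0,
        d_error=d_error_null(design.sets, catalog, rescale_unit=rescale_unit),
    )


def build_dominance_set(
    catalog: AttributeCatalog, *, set_id: int = 0, dominant_position: str = "A"
) -> ChoiceSet:
    """Attention-check set: one alternative better on every attribute.

    Requires a ``preference_direction`` on every attribute — the survey
    designer must assert which level is better; the analysis never infers it.
    """
    missing = [a.name for a in catalog if a.preference_direction is None]
    if missing:
        raise CatalogError(
            f"preference_direction missing for attributes {missing}; "
            "directions must be asserted to build a dominance set"
        )
    best = Profile({a.name: a.best_level() for a in catalog})
    worst = Profile({a.name: a.worst_level() for a in catalog})
    if dominant_position.upper() == "A":
        return ChoiceSet(set_id, (best, worst))
    return ChoiceSet(set_id, (worst, best))


# ---------------------------------------------------------------------------
# CSV interchange: one row per alternative.


def design_to_frame(design: BlockedDesign, catalog: AttributeCatalog) -> pd.DataFrame:
    rows = []
    for s in design.sets:
        for pos, prof in zip(("A", "B"), s.alternatives):
            row = {
                "set_id": s.set_id,
                "block": design.block_of[s.set_id],
                "position": pos,
            }
            row.update({a.name: prof.assignment[a.name] for a in catalog})
            rows.append(row)
    return pd.DataFrame(rows)


def design_from_frame(df: pd.DataFrame, catalog: AttributeCatalog) -> BlockedDesign:
    sets, block_of = [], {}
    for set_id, grp in df.groupby("set_id", sort=True):
        grp = grp.set_index("position")
        profs = []
        for pos in ("A", "B"):
            rec = grp.loc[pos]
            assignment = {}
            for a in catalog:
                val = rec[a.name]
                if a.is_continuous:
                    val = type(a.levels[0])(val)
                assignment[a.name] = val
            profs.append(Profile(assignment))
        sets.append(ChoiceSet(int(set_id), tuple(profs)))
        block_of[int(set_id)] = int(grp["block"].iloc[0])
    n_blocks = len(set(block_of.values()))
    return BlockedDesign(sets=sets, block_of=block_of, n_blocks=n_blocks)
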