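"""Post-estimation: willingness to accept, Krinsky–Robb intervals, uptake.

Marginal willingness to accept (WTA) converts an attribute coefficient to
the total £ over the program by dividing it by the negative of the money
coefficient and restoring the rescale unit.  Interval estimates use the
Krinsky–Robb parametric bootstrap: draw parameter vectors from the estimated
multivariate normal and take percentiles of the derived quantity.  Predicted
uptake is the binary logit probability of a configured program against the
opt-out, optionally integrated over the random-coefficient distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, ndtri

from .catalog import DEFAULT_RESCALE_UNIT, AttributeCatalog, CatalogError, Profile
from .mixlogit import halton_sequence

__all__ = [
    "ProgramConfig",
    "WTAResult",
    "UptakePrediction",
    "wta_point",
    "wta_result",
    "krinsky_robb",
    "predict_uptake",
    "uptake_curve",
    "indifference_amount",
]

AMOUNT_COL = "amount_rescaled"
ASC_COL = "asc_no_program"


@dataclass(frozen=True)
class ProgramConfig:
    """One fully specified program plus the respondent's income group."""

    amount: float
    levels: dict  # categorical attribute -> level
    income_group: str = "low"

    def validate(self, catalog: AttributeCatalog) -> None:
        for a in catalog:
            if a.is_continuous:
                continue
            if a.name not in self.levels:
                raise CatalogError(f"program missing level for {a.name!r}")
            if self.levels[a.name] not in a.levels:
                raise CatalogError(
                    f"unknown level {self.levels[a.name]!r} for {a.name!r}"
                )

    def profile(self, catalog: AttributeCatalog) -> Profile:
        cont = catalog.continuous_attribute
        assignment = dict(self.levels)
        if cont is not None:
            assignment[cont.name] = self.amount
        return Profile(assignment)


@dataclass
class WTAResult:
    term: str
    point: float
    ci_low: float
    ci_high: float
    level: float
    n_draws: int
    seed: int
    flagged: bool = False

    def display_interval(self):
        """Endpoints ordered (closer to zero, farther from zero)."""
        lo, hi = self.ci_low, self.ci_high
        return (lo, hi) if abs(lo) <= abs(hi) else (hi, lo)


@dataclass
class UptakePrediction:
    program: ProgramConfig
    probability: float
    n_draws: int
    seed: int


def _amount_coef(fit, income: str) -> float:
    a = fit.estimates[AMOUNT_COL]
    if income in ("middle", "high"):
        a += fit.estimates.get(f"{AMOUNT_COL}:{income}", 0.0)
    return a


def _asc(fit, income: str) -> float:
    d = fit.estimates[ASC_COL]
    if income in ("middle", "high"):
        d += fit.estimates.get(f"{ASC_COL}:{income}", 0.0)
    return d


def wta_point(fit, term: str, unit: float = DEFAULT_RESCALE_UNIT) -> float:
    """WTA in £ over the program: unit * beta_term / (−alpha).

    ``alpha`` is the fitted money coefficient per rescaled unit for the
    low-income reference group.  Positive attribute coefficients give
    negative WTA: a desirable level *reduces* the amount required.
    """
    alpha = fit.estimates[AMOUNT_COL]
    if alpha == 0:
        raise ZeroDivisionError("amount coefficient is zero; WTA undefined")
    return float(unit) * fit.estimates[term] / (-alpha)


def krinsky_robb(fit, quantity, *, n_draws=10_000, seed=0, level=0.95):
    """Percentile interval of ``quantity(theta)`` under the estimated MVN.

    ``quantity`` maps a parameter dict (name -> value, including ``sd:`` terms)
    to a scalar; vectorized evaluation is done by looping draws.
    Returns ``(low, high)``.
    """
    cov = np.asarray(fit.covariance, float)
    if cov is None or not np.all(np.isfinite(cov)):
        raise ValueError("covariance unavailable; cannot simulate parameters")
    cov = (cov + cov.T) / 2
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(fit.theta, cov, size=n_draws, method="svd")
    names = fit.param_names
    vals = np.array(
        [quantity(dict(zip(names, row))) for row in draws], dtype=float
    )
    a = (1 - level) / 2
    lo, hi = np.quantile(vals, [a, 1 - a])
    return float(lo), float(hi)


def wta_result(
    fit, term: str, unit: float = DEFAULT_RESCALE_UNIT,
    *, n_draws=10_000, seed=0, level=0.95,
) -> WTAResult:
    point = wta_point(fit, term, unit)

    def q(params):
        return unit * params[term] / (-params[AMOUNT_COL])

    lo, hi = krinsky_robb(fit, q, n_draws=n_draws, seed=seed, level=level)
    flagged = not (lo <= point <= hi)
    return WTAResult(
        term=term, point=point, ci_low=lo, ci_high=hi,
        level=level, n_draws=n_draws, seed=seed, flagged=flagged,
    )


def _program_utility_parts(fit, program: ProgramConfig, catalog: AttributeCatalog):
    """(random-term x-vector, fixed utility excl. amount, amount coef, asc)."""
    program.validate(catalog)
    spec = fit.model.spec
    xr = np.zeros(len(spec.random_terms))
    v_fixed = 0.0
    for a in catalog:
        if a.is_continuous:
            continue
        from .preprocess import effects_code

        code = effects_code(catalog, a.name, program.levels[a.name])
        for lvl, x in zip(a.coded_levels, code):
            term = f"{a.name}:{lvl}"
            if term in spec.random_terms:
                xr[spec.random_terms.index(term)] += x
            elif term in spec.fixed_terms:
                v_fixed += fit.estimates[term] * x
            else:
                raise CatalogError(f"term {term!r} not in the fitted model")
    return xr, v_fixed


def predict_uptake(
    fit,
    program: ProgramConfig,
    catalog: AttributeCatalog,
    *,
    unit: float | None = None,
    n_draws: int = 2_000,
    seed: int = 0,
    means_only: bool = False,
) -> UptakePrediction:
    """Probability of enrolling in ``program`` rather than opting out.

    P(enroll) = E_beta[ logistic(V(program) − V_optout) ], integrating over
    the fitted normal random coefficients with seeded Halton draws;
    ``means_only`` evaluates at the coefficient means (closed form, no
    integration).
    """
    unit = unit if unit is not None else fit.model.data.rescale_unit
    xr, v_fixed = _program_utility_parts(fit, program, catalog)
    income = program.income_group
    v_amount = _amount_coef(fit, income) * (program.amount / unit)
    v_asc = _asc(fit, income)
    spec = fit.model.spec
    b = np.array([fit.estimates[t] for t in spec.random_terms])
    if means_only:
        p = float(expit(b @ xr + v_amount + v_fixed - v_asc))
        return UptakePrediction(program, p, 0, seed)
    w = np.array([fit.sds[t] for t in spec.random_terms])
    u = halton_sequence(n_draws, len(b), skip=100 + seed)
    eta = ndtri(u)
    v = (b + w * eta) @ xr + v_amount + v_fixed - v_asc
    return UptakePrediction(program, float(expit(v).mean()), n_draws, seed)


def uptake_curve(
    fit,
    base_program: ProgramConfig,
    catalog: AttributeCatalog,
    amounts,
    **kw,
):
    """``predict_uptake`` over a grid of amounts with a shared seed."""
    amounts = list(amounts)
    if not amounts or any(a < 0 for a in amounts):
        raise ValueError("amounts must be non-empty and non-negative")
    out = []
    for amt in amounts:
        prog = ProgramConfig(
            amount=amt,
            levels=dict(base_program.levels),
            income_group=base_program.income_group,
        )
        out.append(predict_uptake(fit, prog, catalog, **kw))
    return out


def indifference_amount(
    fit,
    base_program: ProgramConfig,
    catalog: AttributeCatalog,
    *,
    unit: float | None = None,
) -> float:
    """£ amount at which enrolling and opting out are equally attractive.

    Solves V(program, amount) = V_optout at the coefficient means:
    amount = unit * (asc − non-amount utility) / alpha, for the program's
    income group.  Requires a positive fitted money coefficient.
    """
    unit = unit if unit is not None else fit.model.data.rescale_unit
    income = base_program.income_group
    alpha = _amount_coef(fit, income)
    if alpha <= 0:
        raise ValueError("non-positive amount coefficient: no finite solution")
    xr, v_fixed = _program_utility_parts(fit, base_program, catalog)
    spec = fit.model.spec
    b = np.array([fit.estimates[t] for t in spec.random_terms])
    return float(unit) * (_asc(fit, income) - (b @ xr + v_fixed)) / alpha
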