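"""Panel mixed logit by maximum simulated likelihood (MSL).

The model: respondent i's utility for alternative j in task t is
V_ijt = sum_k beta_ik x_ijtk + sum_f alpha_f x_ijtf with i.i.d. extreme-value
errors, where the beta_ik are normal random coefficients
beta_ik = b_k + w_k * eta_irk shared across the respondent's tasks (panel
structure) and the alpha_f are fixed coefficients (money slope, opt-out ASC,
income interactions).  The simulated log likelihood averages the product of
task-level logit probabilities over R quasi-random draws per respondent:

    SLL(theta) = sum_i log (1/R) sum_r prod_t P_it(beta_ir)

with eta_irk = Phi^-1(u_irk) and u the Halton sequence in prime bases.
Estimation maximizes SLL with analytic gradients; standard errors come from
the finite-difference Hessian of that gradient.  Standard deviations are
identified only up to sign and reported as absolute values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtri
from scipy.stats import norm

from .preprocess import EncodedDataset, round_half_up

__all__ = [
    "halton_sequence",
    "mnl_loglik",
    "simulated_loglik",
    "ModelSpec",
    "MixedLogit",
    "MixedLogitResults",
    "EffectsTable",
]

_PRIMES = (
    2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47,
    53, 59, 61, 67, 71, 73, 79, 83, 89, 97, 101, 103, 107, 109, 113,
)


def halton_sequence(n: int, dim: int, skip: int = 0) -> np.ndarray:
    """Halton quasi-random points in (0, 1), shape ``(n, dim)``.

    Dimension d uses the radical-inverse sequence in the d-th prime base,
    starting at index 1 (so the first base-2 points are 1/2, 1/4, 3/4);
    the first ``skip`` points of every dimension are discarded.
    """
    if dim > len(_PRIMES):
        raise ValueError(f"dim={dim} exceeds the prime table ({len(_PRIMES)})")
    if n < 1:
        raise ValueError("n must be >= 1")
    out = np.empty((n, dim))
    idx = np.arange(skip + 1, skip + n + 1, dtype=np.int64)
    for d in range(dim):
        base = _PRIMES[d]
        i = idx.copy()
        x = np.zeros(n)
        f = 1.0
        while i.any():
            f /= base
            x += f * (i % base)
            i //= base
        out[:, d] = x
    return out


# ---------------------------------------------------------------------------
# Array extraction from the long-format table


@dataclass
class _Arrays:
    Xr: np.ndarray  # (T, J, Kr) random-term design
    Xf: np.ndarray  # (T, J, Kf) fixed-term design
    chosen: np.ndarray  # (T,) chosen alternative index
    resp_starts: np.ndarray  # first task index of each respondent (sorted)
    resp_ids: np.ndarray  # respondent labels in array order
    n_tasks: int
    n_alts: int


def _extract_arrays(enc: EncodedDataset, random_terms, fixed_terms) -> _Arrays:
    df = enc.table.sort_values(
        ["respondent_id", "task_id", "alt_id"], kind="stable"
    ).reset_index(drop=True)
    n_alts = df.groupby(["respondent_id", "task_id"]).size()
    if n_alts.nunique() != 1:
        raise ValueError("all tasks must present the same number of alternatives")
    J = int(n_alts.iloc[0])
    T = len(df) // J
    Xr = df[list(random_terms)].to_numpy(float).reshape(T, J, len(random_terms))
    Xf = df[list(fixed_terms)].to_numpy(float).reshape(T, J, len(fixed_terms))
    ch_mat = df["chosen"].to_numpy(int).reshape(T, J)
    if not np.all(ch_mat.sum(axis=1) == 1):
        raise ValueError("exactly one alternative must be chosen per task")
    chosen = np.argmax(ch_mat, axis=1)
    task_resp = df["respondent_id"].to_numpy()[::J]
    starts = np.flatnonzero(
        np.r_[True, task_resp[1:] != task_resp[:-1]]
    )
    return _Arrays(
        Xr=Xr,
        Xf=Xf,
        chosen=chosen,
        resp_starts=starts,
        resp_ids=task_resp[starts],
        n_tasks=T,
        n_alts=J,
    )


def _logit_logprobs(V: np.ndarray) -> np.ndarray:
    """Log softmax over axis 1 with max-subtraction for stability."""
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite utilities")
    m = V.max(axis=1, keepdims=True)
    z = V - m
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def mnl_loglik(params, data: EncodedDataset, *, grad: bool = False):
    """Conditional (multinomial) logit log likelihood on the encoded table.

    ``params`` is a mapping column -> coefficient, or an array ordered as
    ``data.attribute_columns + data.fixed_columns``.  This is the exact
    zero-heterogeneity special case of the mixed logit and serves as its
    degenerate-mixture oracle and warm start.
    """
    cols = list(data.attribute_columns) + list(data.fixed_columns)
    if isinstance(params, dict):
        theta = np.array([params[c] for c in cols], float)
    else:
        theta = np.asarray(params, float)
    arr = _extract_arrays(data, data.attribute_columns, data.fixed_columns)
    X = np.concatenate([arr.Xr, arr.Xf], axis=2)  # (T, J, K)
    V = X @ theta
    lp = _logit_logprobs(V)
    tidx = np.arange(arr.n_tasks)
    ll = float(lp[tidx, arr.chosen].sum())
    if not grad:
        return ll
    P = np.exp(lp)
    resid = X[tidx, arr.chosen, :] - np.einsum("tj,tjk->tk", P, X)
    return ll, resid.sum(axis=0)


# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Which terms are fixed vs random-normal, and how to simulate/optimize."""

    random_terms: list
    fixed_terms: list
    n_draws: int = 500
    draw_type: str = "halton"
    halton_skip: int = 100
    panel: bool = True
    seed: int = 0
    maxiter: int = 500
    gtol: float = 1e-6

    def __post_init__(self):
        if set(self.random_terms) & set(self.fixed_terms):
            raise ValueError("fixed and random term sets must be disjoint")
        if self.n_draws < 1:
            raise ValueError("need at least one draw")
        if self.draw_type not in ("halton", "random"):
            raise ValueError(f"unknown draw_type {self.draw_type!r}")


def make_draws(
    n_respondents: int,
    n_random: int,
    n_draws: int,
    *,
    draw_type: str = "halton",
    skip: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Uniform draws (respondents, R, n_random) for the MSL integral."""
    if draw_type == "halton":
        u = halton_sequence(n_respondents * n_draws, n_random, skip=skip)
        return u.reshape(n_respondents, n_draws, n_random)
    rng = np.random.default_rng(seed)
    return rng.random((n_respondents, n_draws, n_random))


class MixedLogit:
    """Panel mixed logit model over an encoded three-alternative dataset.

    Parameters
    ----------
    data : EncodedDataset
        Long-format estimation table (one row per alternative).
    spec : ModelSpec, optional
        Defaults to normal random coefficients on the effects-coded attribute
        columns and fixed coefficients on the money, ASC and interaction
        columns, with 500 Halton draws shared across each respondent's tasks.
    """

    def __init__(self, data: EncodedDataset, spec: ModelSpec | None = None):
        if spec is None:
            spec = ModelSpec(
                random_terms=list(data.attribute_columns),
                fixed_terms=list(data.fixed_columns),
            )
        self.data = data
        self.spec = spec
        self.arrays = _extract_arrays(data, spec.random_terms, spec.fixed_terms)
        self.n_respondents = len(self.arrays.resp_starts)
        self.Kr = len(spec.random_terms)
        self.Kf = len(spec.fixed_terms)
        u = make_draws(
            self.n_respondents,
            self.Kr,
            spec.n_draws,
            draw_type=spec.draw_type,
            skip=spec.halton_skip,
            seed=spec.seed,
        )
        self._eta = ndtri(u)  # (N, R, Kr), standard-normal transformed
        self.param_names = (
            list(spec.random_terms)
            + list(spec.fixed_terms)
            + [f"sd:{t}" for t in spec.random_terms]
        )

    # -- simulated likelihood -------------------------------------------------

    def _split(self, theta):
        theta = np.asarray(theta, float)
        b = theta[: self.Kr]
        a = theta[self.Kr : self.Kr + self.Kf]
        w = theta[self.Kr + self.Kf :]
        return b, a, w

    def loglik(self, theta, *, grad: bool = False):
        """Simulated panel log likelihood (and gradient) at ``theta``.

        ``theta`` is ordered [random means, fixed coefficients, random SDs].
        Respondents are processed in chunks to bound memory.
        """
        b, a, w = self._split(theta)
        arr, eta = self.arrays, self._eta
        R = eta.shape[1]
        starts = arr.resp_starts
        ends = np.r_[starts[1:], arr.n_tasks]

        ll = 0.0
        gb = np.zeros(self.Kr)
        ga = np.zeros(self.Kf)
        gw = np.zeros(self.Kr)
        Vf_all = arr.Xf @ a  # (T, J)

        # chunk respondents so T_chunk * J * R stays modest
        max_cells = 4_000_000
        per_task = arr.n_alts * R
        tasks_per_chunk = max(1, max_cells // max(per_task, 1))
        i0 = 0
        N = self.n_respondents
        while i0 < N:
            i1 = i0
            while i1 < N and ends[i1] - starts[i0] <= tasks_per_chunk:
                i1 += 1
            i1 = max(i1, i0 + 1)
            t0, t1 = starts[i0], ends[i1 - 1]
            sl = slice(t0, t1)
            # respondent index per task within chunk
            reps = ends[i0:i1] - starts[i0:i1]
            ridx = np.repeat(np.arange(i1 - i0), reps)

            beta = b + w * eta[i0:i1]  # (n, R, Kr)
            V = Vf_all[sl][:, :, None] + np.einsum(
                "tjk,trk->tjr", arr.Xr[sl], beta[ridx], optimize=True
            )  # (t, J, R)
            m = V.max(axis=1, keepdims=True)
            z = np.exp(V - m)
            denom = z.sum(axis=1, keepdims=True)
            lp = (V - m) - np.log(denom)  # (t, J, R)
            tloc = np.arange(t1 - t0)
            lpc = lp[tloc, arr.chosen[sl], :]  # (t, R)
            # per-respondent panel products in log space
            logS = np.add.reduceat(lpc, starts[i0:i1] - t0, axis=0)  # (n, R)
            ms = logS.max(axis=1, keepdims=True)
            Su = np.exp(logS - ms)
            Ssum = Su.sum(axis=1)
            ll += float((ms[:, 0] + np.log(Ssum / R)).sum())
            if grad:
                W = Su / Ssum[:, None]  # (n, R) mixture weights
                P = np.exp(lp)
                Er = (
                    arr.Xr[sl][tloc, arr.chosen[sl], None, :]
                    - np.einsum("tjr,tjk->trk", P, arr.Xr[sl], optimize=True)
                )  # (t, R, Kr)
                Gr = np.add.reduceat(Er, starts[i0:i1] - t0, axis=0)  # (n, R, Kr)
                gb += np.einsum("nr,nrk->k", W, Gr, optimize=True)
                gw += np.einsum("nr,nrk,nrk->k", W, Gr, eta[i0:i1], optimize=True)
                Ef = (
                    arr.Xf[sl][tloc, arr.chosen[sl], None, :]
                    - np.einsum("tjr,tjf->trf", P, arr.Xf[sl], optimize=True)
                )
                Gf = np.add.reduceat(Ef, starts[i0:i1] - t0, axis=0)
                ga += np.einsum("nr,nrf->f", W, Gf, optimize=True)
            i0 = i1

        if not grad:
            return ll
        return ll, np.concatenate([gb, ga, gw])

    # -- fitting --------------------------------------------------------------

    def _warm_start(self) -> np.ndarray:
        cols = list(self.spec.random_terms) + list(self.spec.fixed_terms)
        k = len(cols)

        def nll(th):
            ll, g = mnl_loglik(_reorder(th), self.data, grad=True)
            return -ll, -_reorder_back(g)

        # mnl_loglik orders columns attribute_columns + fixed_columns;
        # map between that order and this model's term order.
        mnl_cols = list(self.data.attribute_columns) + list(self.data.fixed_columns)
        pos = [mnl_cols.index(c) for c in cols]

        def _reorder(th):
            out = np.zeros(len(mnl_cols))
            out[pos] = th
            return out

        def _reorder_back(g):
            return g[pos]

        res = optimize.minimize(
            nll, np.zeros(k), jac=True, method="BFGS",
            options={"gtol": 1e-8, "maxiter": 500},
        )
        return res.x

    def fit(
        self,
        start_params: np.ndarray | None = None,
        *,
        sd_init: float = 0.1,
        robust: bool = False,
    ) -> "MixedLogitResults":
        """Maximize the simulated log likelihood.

        Starts from conditional-logit estimates for the means and fixed
        terms with all SDs at ``sd_init``, then runs BFGS with the analytic
        gradient.  Standard errors come from the inverse negative Hessian
        (finite differences of the analytic gradient); ``robust`` requests
        the sandwich estimator instead.
        """
        if start_params is None:
            warm = self._warm_start()
            start_params = np.concatenate([warm, np.full(self.Kr, sd_init)])
        history: list = []

        def nll(th):
            ll, g = self.loglik(th, grad=True)
            return -ll, -g

        def cb(th):
            history.append(-self.loglik(th))

        res = optimize.minimize(
            nll,
            np.asarray(start_params, float),
            jac=True,
            method="BFGS",
            callback=cb,
            options={"gtol": self.spec.gtol, "maxiter": self.spec.maxiter},
        )
        theta = res.x
        H = self._hessian(theta)
        cov, cov_ok = _invert_neg_hessian(H)
        if robust and cov_ok:
            B = self._opg(theta)
            cov = cov @ B @ cov
        converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-3
        return MixedLogitResults(
            model=self,
            theta=theta,
            covariance=cov,
            loglik=-float(res.fun),
            converged=converged,
            gradient_norm=float(np.max(np.abs(res.jac))),
            objective_history=[-h for h in history],
            se_available=cov_ok,
        )

    def _hessian(self, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
        k = len(theta)
        H = np.empty((k, k))
        for j in range(k):
            h = rel_step * max(1.0, abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            _, gp = self.loglik(tp, grad=True)
            _, gm = self.loglik(tm, grad=True)
            H[:, j] = (gp - gm) / (2 * h)
        return (H + H.T) / 2.0

    def _opg(self, theta: np.ndarray) -> np.ndarray:
        """Outer product of per-respondent gradients (for sandwich SEs)."""
        # finite-difference per-respondent scores via single-respondent models
        # would be slow; use numerical scores of the summed likelihood split
        # by respondent through chunked evaluation.
        eps = 1e-6
        k = len(theta)
        scores = np.zeros((self.n_respondents, k))
        base = self._per_respondent_loglik(theta)
        for j in range(k):
            tp = theta.copy()
            tp[j] += eps
            scores[:, j] = (self._per_respondent_loglik(tp) - base) / eps
        return scores.T @ scores

    def _per_respondent_loglik(self, theta) -> np.ndarray:
        b, a, w = self._split(theta)
        arr, eta = self.arrays, self._eta
        starts = arr.resp_starts
        ends = np.r_[starts[1:], arr.n_tasks]
        out = np.empty(self.n_respondents)
        Vf = arr.Xf @ a
        for i, (t0, t1) in enumerate(zip(starts, ends)):
            beta = b + w * eta[i]  # (R, Kr)
            V = Vf[t0:t1][:, :, None] + np.einsum(
                "tjk,rk->tjr", arr.Xr[t0:t1], beta
            )
            lp = V - V.max(axis=1, keepdims=True)
            lp -= np.log(np.exp(lp).sum(axis=1, keepdims=True))
            lpc = lp[np.arange(t1 - t0), arr.chosen[t0:t1], :].sum(axis=0)
            m = lpc.max()
            out[i] = m + np.log(np.exp(lpc - m).mean())
        return out


def simulated_loglik(theta, data: EncodedDataset, draws: np.ndarray) -> float:
    """Simulated panel log likelihood with caller-supplied uniform draws.

    ``draws`` has shape (respondents, R, n_random) with entries in (0, 1);
    coefficients are beta = b + w * Phi^-1(u).  Term order follows
    ``data.attribute_columns`` (random) then ``data.fixed_columns`` (fixed).
    """
    if draws.ndim != 3 or draws.shape[2] == 0:
        raise ValueError("draws must be (respondents, R, n_random)")
    if draws.shape[1] < 1:
        raise ValueError("R must be >= 1")
    spec = ModelSpec(
        random_terms=list(data.attribute_columns),
        fixed_terms=list(data.fixed_columns),
        n_draws=draws.shape[1],
    )
    model = MixedLogit(data, spec)
    if draws.shape[0] != model.n_respondents:
        raise ValueError("draws respondent dimension mismatch")
    model._eta = ndtri(draws)
    return model.loglik(theta)


def _invert_neg_hessian(H: np.ndarray):
    try:
        cov = np.linalg.inv(-H)
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError
        return cov, True
    except np.linalg.LinAlgError:
        return np.linalg.pinv(-H), False


# ---------------------------------------------------------------------------
# Results


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class EffectsTable:
    """Per-level effects with the omitted level reconstructed.

    The omitted level's estimate is the negative sum of its attribute's
    estimated levels (effects coding); its SE follows from the covariance of
    that sum.  A willingness-to-accept column can be joined by the caller.
    """

    rows: pd.DataFrame  # attribute, level/term, estimate, se, p, stars, omitted

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()

    def render(self) -> str:
        lines = [f"{'Predictor':<28}{'Estimate (SE)':<22}{'SD (SE)':<20}"]
        for _, r in self.rows.iterrows():
            est = f"{round_half_up(r.estimate, 3):.3f}"
            if np.isfinite(r.se):
                est += f" ({round_half_up(r.se, 3):.3f}){r.stars}"
            sd = ""
            if isinstance(r.get("sd"), float) and np.isfinite(r.get("sd", np.nan)):
                sd = f"{round_half_up(r.sd, 3):.3f}"
                if np.isfinite(r.get("sd_se", np.nan)):
                    sd += f" ({round_half_up(r.sd_se, 3):.3f}){r.sd_stars}"
            lines.append(f"{r.label:<28}{est:<22}{sd:<20}")
        return "\n".join(lines)


class MixedLogitResults:
    """Estimates, uncertainty, and post-estimation for a fitted mixed logit."""

    def __init__(
        self,
        model: MixedLogit,
        theta: np.ndarray,
        covariance: np.ndarray,
        loglik: float,
        converged: bool,
        gradient_norm: float,
        objective_history=None,
        se_available: bool = True,
    ):
        self.model = model
        self.theta = np.asarray(theta, float)
        self.covariance = np.asarray(covariance, float)
        self.loglik = loglik
        self.converged = converged
        self.gradient_norm = gradient_norm
        self.objective_history = objective_history or []
        self.se_available = se_available
        self.param_names = list(model.param_names)
        spec = model.spec
        b, a, w = model._split(self.theta)
        self.estimates = dict(zip(spec.random_terms, b)) | dict(
            zip(spec.fixed_terms, a)
        )
        self.sds = {t: abs(x) for t, x in zip(spec.random_terms, w)}
        self.n_obs = model.arrays.n_tasks
        self.draws_used = (spec.draw_type, spec.n_draws, spec.seed)

    # -- uncertainty ----------------------------------------------------------

    def se(self, name: str) -> float:
        i = self.param_names.index(name)
        return float(np.sqrt(self.covariance[i, i]))

    def zvalue(self, name: str) -> float:
        i = self.param_names.index(name)
        return float(self.theta[i] / np.sqrt(self.covariance[i, i]))

    def pvalue(self, name: str) -> float:
        return float(2 * norm.sf(abs(self.zvalue(name))))

    # -- reporting ------------------------------------------------------------

    def effects_table(self, catalog, wta: dict | None = None) -> EffectsTable:
        return report_effects_table(self, catalog, wta=wta)

    def summary(self, catalog=None) -> str:
        head = [
            "Panel mixed logit (maximum simulated likelihood)",
            f"Respondents: {self.model.n_respondents}   "
            f"Observations (N*tasks): {self.n_obs:,}",
            f"Draws: {self.draws_used[1]} ({self.draws_used[0]})   "
            f"Log-likelihood: {self.loglik:,.1f}   "
            f"Converged: {self.converged}",
            "",
        ]
        if catalog is not None:
            body = self.effects_table(catalog).render()
        else:
            rows = []
            for name in self.param_names:
                i = self.param_names.index(name)
                se = np.sqrt(self.covariance[i, i]) if self.se_available else np.nan
                rows.append(f"{name:<28}{self.theta[i]: .4f}  ({se:.4f})")
            body = "\n".join(rows)
        return "\n".join(head) + body + (
            "\n\n*p < .05; **p < .01; ***p < .001."
        )

    def to_json(self, path=None) -> dict:
        out = {
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "sds": {k: float(v) for k, v in self.sds.items()},
            "param_names": self.param_names,
            "theta": self.theta.tolist(),
            "covariance": self.covariance.tolist(),
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "gradient_norm": self.gradient_norm,
            "draws_used": list(self.draws_used),
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(out, fh, indent=1)
        return out

    # -- post-estimation (delegates to the postfit module) --------------------

    def wta(self, term: str, unit: float | None = None) -> float:
        from . import postfit

        return postfit.wta_point(self, term, unit or self.model.data.rescale_unit)

    def wta_interval(self, term, *, n_draws=10_000, seed=0, level=0.95, unit=None):
        from . import postfit

        return postfit.wta_result(
            self, term, unit or self.model.data.rescale_unit,
            n_draws=n_draws, seed=seed, level=level,
        )

    def krinsky_robb(self, quantity, *, n_draws=10_000, seed=0, level=0.95):
        from . import postfit

        return postfit.krinsky_robb(
            self, quantity, n_draws=n_draws, seed=seed, level=level
        )

    def predict_uptake(self, program, catalog, **kw):
        from . import postfit

        return postfit.predict_uptake(self, program, catalog, **kw)

    def uptake_curve(self, program, catalog, amounts, **kw):
        from . import postfit

        return postfit.uptake_curve(self, program, catalog, amounts, **kw)

    def indifference_amount(self, program, catalog, **kw):
        from . import postfit

        return postfit.indifference_amount(self, program, catalog, **kw)


class FitView:
    """Read-only view over a saved fit (estimates, SDs, covariance).

    Provides the surface the post-estimation functions consume, so WTA and
    uptake can be computed from a ``fit.json`` without re-estimating.
    """

    def __init__(self, payload: dict, rescale_unit: float = 10.0):
        from types import SimpleNamespace

        self.param_names = list(payload["param_names"])
        self.theta = np.asarray(payload["theta"], float)
        self.covariance = np.asarray(payload["covariance"], float)
        self.estimates = {k: float(v) for k, v in payload["estimates"].items()}
        self.sds = {k: float(v) for k, v in payload["sds"].items()}
        self.loglik = payload.get("loglik")
        random_terms = list(payload["sds"].keys())
        fixed_terms = [
            n for n in self.param_names
            if not n.startswith("sd:") and n not in random_terms
        ]
        self.model = SimpleNamespace(
            spec=SimpleNamespace(
                random_terms=random_terms, fixed_terms=fixed_terms
            ),
            data=SimpleNamespace(rescale_unit=rescale_unit),
        )

    def se(self, name: str) -> float:
        i = self.param_names.index(name)
        return float(np.sqrt(self.covariance[i, i]))


def load_fit_json(path, rescale_unit: float = 10.0) -> FitView:
    with open(path) as fh:
        return FitView(json.load(fh), rescale_unit)


def report_effects_table(
    fit: MixedLogitResults, catalog, wta: dict | None = None
) -> EffectsTable:
    """Level-by-level effects table with reconstructed omitted levels."""
    spec = fit.model.spec
    names = fit.param_names
    V = fit.covariance
    rows = []

    def _row(label, attribute, level, est, se, sd=np.nan, sd_se=np.nan):
        p = 2 * norm.sf(abs(est / se)) if se and np.isfinite(se) and se > 0 else np.nan
        sd_p = (
            2 * norm.sf(abs(sd / sd_se))
            if np.isfinite(sd_se) and sd_se > 0
            else np.nan
        )
        rows.append(
            {
                "attribute": attribute,
                "level": level,
                "label": label,
                "estimate": est,
                "se": se,
                "p": p,
                "stars": _stars(p) if np.isfinite(p) else "",
                "sd": sd,
                "sd_se": sd_se,
                "sd_stars": _stars(sd_p) if np.isfinite(sd_p) else "",
            }
        )

    # fixed terms first (amount, ASC, interactions)
    for term in spec.fixed_terms:
        i = names.index(term)
        se = np.sqrt(V[i, i]) if fit.se_available else np.nan
        _row(term, None, None, fit.theta[i], se)

    for a in catalog:
        if a.is_continuous:
            continue
        terms = [f"{a.name}:{lvl}" for lvl in a.coded_levels]
        if not all(t in spec.random_terms or t in spec.fixed_terms for t in terms):
            continue
        idx = [names.index(t) for t in terms]
        for lvl, t, i in zip(a.coded_levels, terms, idx):
            se = np.sqrt(V[i, i]) if fit.se_available else np.nan
            sd = fit.sds.get(t, np.nan)
            sd_se = np.nan
            if t in fit.sds and fit.se_available:
                j = names.index(f"sd:{t}")
                sd_se = np.sqrt(V[j, j])
            _row(f"{a.name}: {lvl}", a.name, lvl, fit.theta[i], se, sd, sd_se)
        # omitted level: negative sum of the estimated levels (estimate only)
        contrast = np.zeros(len(names))
        contrast[idx] = -1.0
        est = float(contrast @ fit.theta)
        _row(f"{a.name}: {a.omitted_level} (omitted)", a.name, a.omitted_level,
             est, np.nan)

    df = pd.DataFrame(rows)
    if wta:
        df["wta"] = df["label"].map(wta)
    return EffectsTable(rows=df)
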