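"""Estimator: Halton draws, likelihood oracles, MSL fitting, effects table."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, qmc

import incentdce as dce
from incentdce.mixlogit import MixedLogitResults, make_draws
from incentdce.preprocess import EncodedDataset


def tiny_encoded(rows, attr_cols, fixed_cols):
    """Build an EncodedDataset from explicit row dicts."""
    return EncodedDataset(
        table=pd.DataFrame(rows),
        attribute_columns=attr_cols,
        fixed_columns=fixed_cols,
        rescale_unit=10.0,
    )


def one_task(x_by_alt, chosen, rid=1, tid=1, attr_cols=("x",), fixed_cols=()):
    rows = []
    for alt, x in x_by_alt.items():
        row = {"respondent_id": rid, "task_id": tid, "alt_id": alt,
               "chosen": int(alt == chosen)}
        for c, v in zip(list(attr_cols) + list(fixed_cols), x):
            row[c] = v
        rows.append(row)
    return rows


class TestHalton:
    def test_base2_radical_inverse(self):
        np.testing.assert_allclose(
            dce.halton_sequence(3, 1)[:, 0], [0.5, 0.25, 0.75]
        )

    def test_base3_radical_inverse(self):
        np.testing.assert_allclose(
            dce.halton_sequence(3, 2)[:, 1], [1 / 3, 2 / 3, 1 / 9]
        )

    def test_skip_discards_prefix(self):
        full = dce.halton_sequence(10, 2)
        skipped = dce.halton_sequence(5, 2, skip=5)
        np.testing.assert_allclose(skipped, full[5:])

    def test_strictly_inside_unit_interval(self):
        u = dce.halton_sequence(5000, 6, skip=100)
        assert np.all(u > 0) and np.all(u < 1)

    def test_dimension_beyond_prime_table_rejected(self):
        with pytest.raises(ValueError):
            dce.halton_sequence(10, 1000)

    def test_matches_scipy_qmc_ordering(self):
        # scipy's unscrambled Halton starts at index 0 (the origin); ours at 1
        ours = dce.halton_sequence(7, 3)
        scipys = qmc.Halton(d=3, scramble=False).random(8)[1:]
        np.testing.assert_allclose(ours, scipys, atol=1e-12)


class TestMnlLoglik:
    def test_equal_utilities_three_alternatives(self):
        enc = tiny_encoded(
            one_task({"A": [1.0], "B": [1.0], "optout": [1.0]}, "A"), ["x"], []
        )
        assert dce.mnl_loglik({"x": 0.7}, enc) == pytest.approx(np.log(1 / 3))

    def test_binary_logit_closed_form(self):
        # V_chosen − V_other = ln 3 → P = 3/4
        enc = tiny_encoded(
            one_task({"A": [np.log(3)], "B": [0.0]}, "A"), ["x"], []
        )
        assert dce.mnl_loglik({"x": 1.0}, enc) == pytest.approx(np.log(0.75))

    def test_zero_params_scale_with_tasks(self, study_encoded):
        zeros = {c: 0.0 for c in study_encoded.attribute_columns
                 + study_encoded.fixed_columns}
        assert dce.mnl_loglik(zeros, study_encoded) == pytest.approx(
            4300 * np.log(1 / 3)
        )

    def test_brute_force_enumeration_oracle(self):
        # 4 alternatives, 2 tasks, hand-set utilities; compare against a
        # direct probability enumeration
        rng = np.random.default_rng(2)
        X = rng.normal(size=(2, 4, 3))
        theta = np.array([0.3, -0.8, 1.1])
        rows = []
        chosen = [2, 0]
        for t in range(2):
            for j in range(4):
                rows.append(
                    {"respondent_id": 1, "task_id": t, "alt_id": f"a{j}",
                     "chosen": int(j == chosen[t]),
                     "x0": X[t, j, 0], "x1": X[t, j, 1], "x2": X[t, j, 2]}
                )
        enc = tiny_encoded(rows, ["x0", "x1", "x2"], [])
        expected = 0.0
        for t in range(2):
            v = X[t] @ theta
            expected += np.log(np.exp(v[chosen[t]]) / np.exp(v).sum())
        assert dce.mnl_loglik(theta, enc) == pytest.approx(expected, abs=1e-12)


class TestSimulatedLoglik:
    def test_degenerate_mixture_equals_mnl(self, study_encoded):
        cols = study_encoded.attribute_columns + study_encoded.fixed_columns
        rng = np.random.default_rng(0)
        means = rng.normal(scale=0.3, size=len(cols))
        mnl = dce.mnl_loglik(dict(zip(cols, means)), study_encoded)
        n = study_encoded.n_respondents
        kr = len(study_encoded.attribute_columns)
        for R in (1, 10):
            draws = make_draws(n, kr, R)
            theta = np.concatenate([means, np.zeros(kr)])
            sll = dce.simulated_loglik(theta, study_encoded, draws)
            assert sll == pytest.approx(mnl, abs=1e-10)

    def test_gauss_hermite_quadrature_oracle(self):
        # one respondent, one task, one random coefficient:
        # L = ∫ φ(η) P(A | b + wη) dη, P = σ(2(b+wη)) for coded x = ±1
        b, w = 0.4, 0.7
        enc = tiny_encoded(one_task({"A": [1.0], "B": [-1.0]}, "A"), ["x"], [])
        nodes, weights = np.polynomial.hermite.hermgauss(80)
        eta = np.sqrt(2) * nodes
        probs = 1 / (1 + np.exp(-2 * (b + w * eta)))
        exact = np.log((weights / np.sqrt(np.pi)) @ probs)
        draws = make_draws(1, 1, 5000)
        sll = dce.simulated_loglik(np.array([b, w]), enc, draws)
        assert sll == pytest.approx(exact, abs=1e-3)

    def test_invariant_to_respondent_order(self, study_encoded):
        kr = len(study_encoded.attribute_columns)
        kf = len(study_encoded.fixed_columns)
        theta = np.concatenate(
            [np.full(kr, 0.2), np.full(kf, 0.1), np.full(kr, 0.3)]
        )
        draws = make_draws(study_encoded.n_respondents, kr, 5)
        base = dce.simulated_loglik(theta, study_encoded, draws)
        # relabel respondents in reverse; panels and their draws permute with them
        table = study_encoded.table.copy()
        ids = sorted(table.respondent_id.unique())
        relabel = dict(zip(ids, reversed(ids)))
        table["respondent_id"] = table["respondent_id"].map(relabel)
        enc2 = EncodedDataset(
            table=table,
            attribute_columns=study_encoded.attribute_columns,
            fixed_columns=study_encoded.fixed_columns,
            rescale_unit=10.0,
        )
        permuted = dce.simulated_loglik(theta, enc2, draws[::-1].copy())
        assert permuted == pytest.approx(base, rel=1e-12)

    def test_sd_sign_invariance(self, study_encoded):
        kr = len(study_encoded.attribute_columns)
        kf = len(study_encoded.fixed_columns)
        theta = np.concatenate(
            [np.full(kr, 0.2), np.full(kf, 0.1), np.full(kr, 0.3)]
        )
        spec = dce.ModelSpec(
            random_terms=list(study_encoded.attribute_columns),
            fixed_terms=list(study_encoded.fixed_columns),
            n_draws=20,
        )
        m = dce.MixedLogit(study_encoded, spec)
        flipped = theta.copy()
        flipped[kr + kf :] *= -1
        # antithetic symmetry of the normal makes ±w indistinguishable in the
        # population; with finite draws the likelihood is invariant only up to
        # the draw symmetry, so compare against a sign-symmetrized draw set
        m._eta = np.concatenate([m._eta, -m._eta], axis=1)
        assert m.loglik(theta) == pytest.approx(m.loglik(flipped), rel=1e-12)


class TestFit:
    def test_monotone_objective_and_determinism(self, study_encoded, study_fit):
        hist = study_fit.objective_history
        assert len(hist) > 1
        assert all(b >= a - 1e-9 for a, b in zip(hist, hist[1:]))
        assert study_fit.converged
        # reported SDs are non-negative representatives
        assert all(v >= 0 for v in study_fit.sds.values())

    def test_refit_same_seed_identical(self, study_encoded):
        spec = dce.ModelSpec(
            random_terms=list(study_encoded.attribute_columns),
            fixed_terms=list(study_encoded.fixed_columns),
            n_draws=25,
            seed=7,
        )
        r1 = dce.MixedLogit(study_encoded, spec).fit()
        r2 = dce.MixedLogit(study_encoded, spec).fit()
        np.testing.assert_array_equal(r1.theta, r2.theta)
        assert r1.loglik == r2.loglik

    def test_recovery_with_zero_heterogeneity(self, catalog):
        """Data generated with all SDs = 0: means recovered, SDs shrink."""
        data, manifest = dce.make_fixture("no-heterogeneity")
        assert manifest["sds_zero"]
        from incentdce.pipeline import _fixture_design, expand_seed

        design = _fixture_design(expand_seed(202008)[0])
        cleaned, _ = dce.clean_study(data)
        enc = dce.to_long_format(cleaned, design, catalog)
        spec = dce.ModelSpec(
            random_terms=list(enc.attribute_columns),
            fixed_terms=list(enc.fixed_columns),
            n_draws=100,
            seed=3,
        )
        res = dce.MixedLogit(enc, spec).fit()
        prefs = dce.table_preferences()
        for term, truth in prefs.means.items():
            assert abs(res.estimates[term] - truth) < 3 * res.se(term)
        assert all(abs(w) < 0.15 for w in res.sds.values())


class TestEffectsTable:
    @staticmethod
    def _results_with(study_encoded, estimates):
        spec = dce.ModelSpec(
            random_terms=list(study_encoded.attribute_columns),
            fixed_terms=list(study_encoded.fixed_columns),
            n_draws=2,
        )
        model = dce.MixedLogit(study_encoded, spec)
        kr, kf = model.Kr, model.Kf
        theta = np.zeros(kr + kf + kr)
        for i, t in enumerate(spec.random_terms):
            theta[i] = estimates.get(t, 0.0)
        for i, t in enumerate(spec.fixed_terms):
            theta[kr + i] = estimates.get(t, 0.0)
        cov = np.eye(len(theta)) * 0.01
        return MixedLogitResults(
            model=model, theta=theta, covariance=cov, loglik=0.0,
            converged=True, gradient_norm=0.0,
        )

    def test_omitted_session_level_is_negative_sum(self, study_encoded, catalog):
        res = self._results_with(
            study_encoded,
            {"sessions:1/fortnight": 0.221, "sessions:1/week": 0.273,
             "sessions:2/week": 0.114},
        )
        table = res.effects_table(catalog).to_frame()
        omitted = table[(table.attribute == "sessions") & (table.level == "3/week")]
        assert omitted.estimate.iloc[0] == pytest.approx(-0.608)

    def test_binary_omitted_is_exact_negation(self, study_encoded, catalog):
        res = self._results_with(study_encoded, {"incentive_type:cash": 0.331})
        table = res.effects_table(catalog).to_frame()
        omitted = table[
            (table.attribute == "incentive_type") & (table.level == "voucher")
        ]
        assert omitted.estimate.iloc[0] == pytest.approx(-0.331)

    def test_level_estimates_sum_to_zero_per_attribute(self, study_fit, catalog):
        table = study_fit.effects_table(catalog).to_frame()
        for attr, grp in table[table.attribute.notna()].groupby("attribute"):
            assert grp.estimate.sum() == pytest.approx(0.0, abs=1e-9)

    def test_summary_renders(self, study_fit, catalog):
        text = study_fit.summary(catalog)
        assert "Observations (N*tasks): 4,300" in text
        assert "sessions: 3/week (omitted)" in text
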