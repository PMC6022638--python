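"""Unit tests for the REML mixed-model core.

The implementation evaluates participant blocks grouped by missingness
pattern; the oracles here take entirely different routes — a dense full-matrix
evaluation, the balanced-ANOVA closed form, and statsmodels MixedLM.
"""

import numpy as np
import pandas as pd
import pytest

import compensatrack as ct
from compensatrack.mlmm import _Stacked, _neg2_reml_and_grad, _theta_size

from conftest import dense_reml, make_scenario_data, theta_from


def _small_instance(seed, n=6, outcomes=("X", "Y"), degrees=(1, 2), missing=False):
    rng = np.random.default_rng(seed)
    data = make_scenario_data("compensation_quadratic", n_participants=n, seed=seed)
    if missing:
        for v in outcomes:
            idx = rng.choice(len(data), size=max(1, len(data) // 6), replace=False)
            data.loc[data.index[idx], v] = np.nan
    spec = ct.ModelSpec(outcomes, degrees, covariates=("sex",))
    return data, spec


class TestRemlValue:
    def test_matches_dense_oracle_at_random_parameters(self):
        """Blockwise restricted likelihood equals the full-matrix evaluation."""
        rng = np.random.default_rng(0)
        for seed in range(6):
            data, spec = _small_instance(seed, missing=(seed % 2 == 1))
            V = len(spec.outcomes)
            for _ in range(3):
                A = rng.normal(size=(V, V)) * 0.5
                D = A @ A.T + 0.1 * np.eye(V)
                sigma2 = rng.uniform(0.2, 1.5, V)
                expected, _, _ = dense_reml(data, spec, D, sigma2)
                got = ct.reml_neg2loglik(theta_from(D, sigma2), data, spec)
                assert got == pytest.approx(expected, abs=1e-6)

    def test_row_permutation_invariance(self):
        data, spec = _small_instance(3)
        theta = np.zeros(_theta_size(2))
        v1 = ct.reml_neg2loglik(theta, data, spec)
        shuffled = data.sample(frac=1.0, random_state=1).reset_index(drop=True)
        v2 = ct.reml_neg2loglik(theta, shuffled, spec)
        assert v1 == pytest.approx(v2, abs=1e-9)

    def test_zero_random_variance_collapses_to_ols_reml(self):
        """With the intercept variance at ~0 the criterion equals the
        closed-form REML of an ordinary linear regression."""
        data, _ = _small_instance(4, n=12)
        spec = ct.ModelSpec(("X",), (1,), covariates=())
        X = np.column_stack([np.ones(len(data)), data["cap_star"]])
        y = data["X"].to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        r = y - X @ beta
        n, p = X.shape
        for s2 in (0.5, 1.3):
            theta = np.array([np.log(1e-8) / 2, np.log(s2)])
            expected = (
                n * np.log(s2)
                + np.linalg.slogdet(X.T @ X / s2)[1]
                + r @ r / s2
                + (n - p) * np.log(2 * np.pi)
            )
            assert ct.reml_neg2loglik(theta, data, spec) == pytest.approx(
                expected, abs=1e-4
            )

    def test_wrong_theta_length_rejected(self):
        data, spec = _small_instance(5)
        with pytest.raises(ValueError):
            ct.reml_neg2loglik(np.zeros(2), data, spec)


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self):
        from scipy.optimize import approx_fprime

        for seed in (0, 1):
            data, spec = _small_instance(seed, missing=True)
            st = _Stacked(data, spec)
            theta = np.random.default_rng(seed).normal(0, 0.3, _theta_size(2))
            _, g = _neg2_reml_and_grad(theta, st)
            gn = approx_fprime(
                theta, lambda t: _neg2_reml_and_grad(t, st, want_grad=False)[0], 1e-6
            )
            assert np.allclose(g, gn, rtol=1e-4, atol=1e-3)


class TestFit:
    def test_noise_free_recovery(self, default_cohort):
        """Near-zero noise: fixed effects interpolate the truth to 1e-6."""
        truth = ct.scenario_preset(
            "compensation_quadratic", residual_sd=1e-6, intercept_var=1e-12
        )
        data = ct.simulate_outcomes(default_cohort, truth, seed=0)
        spec = ct.ModelSpec(("X", "Y"), (1, 2))
        fit = ct.fit_mlmm(data, spec)
        assert fit.coef("X", "cap_star^1")[0] == pytest.approx(-1.0, abs=1e-6)
        assert fit.coef("Y", "cap_star^1")[0] == pytest.approx(-0.5, abs=1e-6)
        assert fit.coef("Y", "cap_star^2")[0] == pytest.approx(-0.3, abs=1e-6)
        # covariate effects too
        assert fit.coef("X", "sex[male]")[0] == pytest.approx(0.15, abs=1e-6)

    def test_balanced_closed_form(self):
        """Univariate balanced random-intercept REML equals the ANOVA
        moment estimators (grand-mean model)."""
        rng = np.random.default_rng(7)
        N, nvis = 40, 3
        rows = []
        for i in range(N):
            a = rng.normal(0, 0.8)
            for j in range(nvis):
                rows.append(
                    {
                        "participant_id": f"P{i}",
                        "cap_star": 0.0,
                        "y": 1.5 + a + rng.normal(0, 0.6),
                    }
                )
        data = pd.DataFrame(rows)
        fit = ct.fit_mlmm(data, ct.ModelSpec(("y",), (0,), covariates=()))
        ybar_i = data.groupby("participant_id")["y"].mean()
        ybar = data["y"].mean()
        msw = (
            data.groupby("participant_id")["y"].apply(lambda g: ((g - g.mean()) ** 2).sum()).sum()
            / (N * (nvis - 1))
        )
        msb = nvis * ((ybar_i - ybar) ** 2).sum() / (N - 1)
        assert fit.residual_var["y"] == pytest.approx(msw, abs=1e-6)
        assert fit.random_intercept_cov[0, 0] == pytest.approx(
            (msb - msw) / nvis, abs=1e-6
        )
        assert fit.coef("y", "intercept")[0] == pytest.approx(ybar, abs=1e-8)

    def test_univariate_matches_statsmodels(self, quad_data):
        import statsmodels.formula.api as smf

        fit = ct.fit_mlmm(quad_data, ct.ModelSpec(("X",), (1,)))
        m = smf.mixedlm(
            "X ~ cap_star + sex + education + site",
            quad_data,
            groups=quad_data["participant_id"],
        ).fit(reml=True)
        assert fit.coef("X", "cap_star^1")[0] == pytest.approx(
            m.params["cap_star"], abs=1e-5
        )
        assert fit.coef("X", "cap_star^1")[1] == pytest.approx(
            m.bse["cap_star"], abs=1e-4
        )
        assert fit.random_intercept_cov[0, 0] == pytest.approx(
            float(m.cov_re.iloc[0, 0]), rel=1e-4
        )
        assert fit.residual_var["X"] == pytest.approx(m.scale, rel=1e-4)
        assert fit.reml_loglik == pytest.approx(m.llf, abs=1e-5)

    def test_site_relabelling_leaves_cap_terms_invariant(self, quad_data):
        spec = ct.ModelSpec(("Y",), (2,))
        fit1 = ct.fit_mlmm(quad_data, spec)
        relabelled = quad_data.copy()
        # swap reference ordering: rename sites so the sorted order changes
        relabelled["site"] = relabelled["site"].map(
            {"London": "Z_London", "Leiden": "A_Leiden", "Paris": "Paris", "Vancouver": "B_Vanc"}
        )
        fit2 = ct.fit_mlmm(relabelled, spec)
        for term in ("cap_star^1", "cap_star^2"):
            assert fit1.coef("Y", term)[0] == pytest.approx(fit2.coef("Y", term)[0], abs=1e-6)
            assert fit1.coef("Y", term)[1] == pytest.approx(fit2.coef("Y", term)[1], abs=1e-6)
        assert fit1.reml_loglik == pytest.approx(fit2.reml_loglik, abs=1e-6)

    def test_too_few_participants_rejected(self):
        data = pd.DataFrame(
            {"participant_id": ["P1"] * 3, "cap_star": [0.0, 0.1, 0.2], "y": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError):
            ct.fit_mlmm(data, ct.ModelSpec(("y",), (1,), covariates=()))


class TestWald:
    def test_headline_structural_slope_significant(self):
        # a linear-decline estimate of -1.0271 with SE 0.0509 is decisive
        t = ct.wald_test(-1.0271, 0.0509)
        assert t.p < 0.0001
        assert t.z == pytest.approx(-20.179, abs=1e-2)

    def test_zero_estimate(self):
        t = ct.wald_test(0.0, 1.0)
        assert t.z == 0.0 and t.p == pytest.approx(1.0)

    def test_normal_quantile_identity(self):
        assert ct.wald_test(1.959964, 1.0).p == pytest.approx(0.05, abs=1e-6)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            ct.wald_test(1.0, 0.0)
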