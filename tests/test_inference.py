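"""Unit tests for grouped FDR, the three-step strategy and classification."""

import numpy as np
import pandas as pd
import pytest

import compensatrack as ct
from compensatrack.inference import (
    HierarchyResult,
    Step1Result,
    classify_compensation,
    fdr_adjust,
)
from compensatrack.mlmm import FitResult, ModelSpec, TestResult, wald_test

from conftest import make_scenario_data


class TestFdrAdjust:
    def test_single_test_q_equals_p(self):
        assert fdr_adjust([0.031]) == pytest.approx([0.031])

    def test_bh_closed_form(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_groups_adjusted_independently(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.01]
        q = fdr_adjust(p, group_labels=["a", "a", "a", "a", "b"])
        assert np.allclose(q[:4], 0.04)
        assert q[4] == pytest.approx(0.01)  # singleton group untouched

    def test_invariants_q_ge_p_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        q = fdr_adjust(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=28)  # e.g. the compensator group of one Y
        q = fdr_adjust(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


# --- fabricated hierarchies for classification-rule tests -------------------


def _fake_hierarchy(outcome, p_by_term, beta_by_term, q_by_term=None):
    """HierarchyResult with prescribed tests/coefficients, no real fits."""
    tests, fits = {}, {}
    for term, deg in zip(("linear", "quadratic", "cubic"), (1, 2, 3)):
        est = beta_by_term[term][deg - 1]
        t = TestResult(outcome, term, est, 1.0, est, p_by_term[term],
                       q=(q_by_term or p_by_term)[term], group="g")
        tests[term] = t
        fe = {outcome: {"intercept": (0.0, 1.0)}}
        for k in range(1, deg + 1):
            fe[outcome][f"cap_star^{k}"] = (beta_by_term[term][k - 1], 1.0)
        fits[term] = FitResult(
            spec=ModelSpec((outcome,), (deg,), covariates=()),
            fixed_effects=fe,
            random_intercept_cov=np.eye(1),
            residual_var={outcome: 1.0},
            reml_loglik=0.0,
            n_participants=10,
            n_obs=30,
            converged=True,
            grad_norm=0.0,
            n_restarts=0,
        )
    return HierarchyResult(outcome, tests, fits, True)


def _passing_step1():
    h = _fake_hierarchy(
        "X",
        {"linear": 1e-6, "quadratic": 0.5, "cubic": 0.5},
        {"linear": (-1.0, 0, 0), "quadratic": (-1.0, 0.0, 0), "cubic": (-1.0, 0, 0.0)},
    )
    return Step1Result(h, True, "linear decline confirmed")


def _good_y():
    return _fake_hierarchy(
        "Y",
        {"linear": 1e-4, "quadratic": 1e-4, "cubic": 0.6},
        {"linear": (-0.5, 0, 0), "quadratic": (-0.5, -0.3, 0), "cubic": (-0.5, -0.3, 0.0)},
    )


class TestClassification:
    def test_quadratic_compensator_full_compensation(self):
        c = _fake_hierarchy(
            "C",
            {"linear": 0.8, "quadratic": 0.001, "cubic": 0.4},
            {"linear": (0.1, 0, 0), "quadratic": (0.0, -0.18, 0), "cubic": (0.0, -0.18, 0.0)},
        )
        v = classify_compensation(_passing_step1(), _good_y(), c, late_cap=420.0)
        assert v.cond3_C_class == "quadratic_concave_down"
        assert v.overall == "compensation"
        assert v.late_slope_Y < 0

    def test_delayed_cubic_partial_compensation(self):
        c = _fake_hierarchy(
            "C",
            {"linear": 0.9, "quadratic": 0.2, "cubic": 0.004},
            {"linear": (0.0, 0, 0), "quadratic": (0.0, -0.08, 0), "cubic": (0.0, -0.08, -0.12)},
        )
        v = classify_compensation(_passing_step1(), _good_y(), c, late_cap=420.0)
        assert v.cond3_C_class == "cubic_with_negative_late_slope"
        assert v.overall == "partial_compensation"
        assert v.late_slope_C < 0

    def test_positive_cubic_positive_slope_inconsistent(self):
        # mirrors the one published cubic trend with a positive late slope
        c = _fake_hierarchy(
            "C",
            {"linear": 0.5, "quadratic": 0.4, "cubic": 0.01},
            {"linear": (0.05, 0, 0), "quadratic": (0.05, -0.05, 0), "cubic": (0.05, -0.05, 0.13)},
        )
        v = classify_compensation(_passing_step1(), _good_y(), c, late_cap=420.0)
        assert v.cond3_C_class == "inconsistent"
        assert v.overall == "no_compensation"

    def test_no_significant_c_terms(self):
        c = _fake_hierarchy(
            "C",
            {"linear": 0.4, "quadratic": 0.4, "cubic": 0.4},
            {"linear": (0.0, 0, 0), "quadratic": (0.0, 0.0, 0), "cubic": (0.0, 0.0, 0.0)},
        )
        v = classify_compensation(_passing_step1(), _good_y(), c, late_cap=420.0)
        assert v.cond3_C_class == "none"
        assert v.overall == "no_compensation"
        assert v.late_slope_C is None

    def test_cubic_takes_precedence_over_quadratic(self):
        # both terms significant: the delayed (cubic) reading wins
        c = _fake_hierarchy(
            "C",
            {"linear": 0.9, "quadratic": 0.001, "cubic": 0.001},
            {"linear": (0.0, 0, 0), "quadratic": (0.0, -0.2, 0), "cubic": (0.0, -0.2, -0.1)},
        )
        v = classify_compensation(_passing_step1(), _good_y(), c, late_cap=420.0)
        assert v.cond3_C_class == "cubic_with_negative_late_slope"

    def test_failed_step1_blocks_compensation(self):
        s1 = _passing_step1()
        s1 = Step1Result(s1.hierarchy, False, "higher-order trend significant")
        c = _fake_hierarchy(
            "C",
            {"linear": 0.8, "quadratic": 0.001, "cubic": 0.4},
            {"linear": (0.1, 0, 0), "quadratic": (0.0, -0.18, 0), "cubic": (0.0, -0.18, 0.0)},
        )
        v = classify_compensation(s1, _good_y(), c, late_cap=420.0)
        assert not v.cond1_linear_X
        assert v.overall == "no_compensation"

    def test_missing_q_rejected(self):
        c = _fake_hierarchy(
            "C",
            {"linear": 0.5, "quadratic": 0.5, "cubic": 0.5},
            {"linear": (0, 0, 0), "quadratic": (0, 0, 0), "cubic": (0, 0, 0)},
        )
        c.tests["cubic"] = TestResult("C", "cubic", 0.0, 1.0, 0.0, 0.5, q=None)
        with pytest.raises(ValueError):
            classify_compensation(_passing_step1(), _good_y(), c, late_cap=420.0)


class TestSteps:
    def test_duplicate_companion_rejected(self, quad_data):
        with pytest.raises(ValueError):
            ct.test_polynomial_hierarchy(quad_data, "X", companions=(("X", 1),))

    def test_step1_on_quadratic_scenario(self, quad_data):
        s1 = ct.run_step1(quad_data, "X", covariates=())
        assert s1.passed
        assert s1.hierarchy.tests["linear"].estimate < 0

    def test_step1_rejects_strong_quadratic_x(self):
        data = make_scenario_data("compensation_quadratic", n_participants=80, seed=3)
        # use Y (true quadratic) in the structural role: condition 1 must fail
        s1 = ct.run_step1(data, "Y", covariates=())
        assert not s1.passed

    def test_step1_rejects_positive_linear_trend(self):
        data = make_scenario_data("compensation_quadratic", n_participants=80, seed=4)
        data["Xpos"] = -data["X"]
        s1 = ct.run_step1(data, "Xpos", covariates=())
        assert not s1.passed
        assert s1.reason == "linear trend not negative"

    def test_step2_survivor_and_filtering(self, quad_data):
        # Y has a true negative quadratic; C (as a second candidate here)
        # is also concave-down, X linear is held fixed
        s2 = ct.run_step2(quad_data, "X", ["Y", "C"], covariates=())
        assert "Y" in s2.survivors
        for t in s2.tests:
            assert t.q is not None and t.q >= t.p - 1e-12

    def test_step2_drops_linear_only_y(self):
        data = make_scenario_data("no_compensation_linear", n_participants=100, seed=5)
        s2 = ct.run_step2(data, "X", ["Y"], covariates=())
        assert s2.survivors == []

    def test_step3_quadratic_compensator(self, quad_data):
        s3 = ct.run_step3(quad_data, "X", "Y", ["C"], covariates=())
        t = s3.hierarchies["C"].tests["quadratic"]
        assert t.estimate < 0 and t.q < 0.05

    def test_zero_variance_c_surfaces_error(self, quad_data):
        data = quad_data.copy()
        data["flat"] = 1.0
        # standardization (the pipeline entry point) rejects the degenerate C
        with pytest.raises(ValueError):
            ct.standardize(data["flat"].to_numpy(), ct.VariableSpec("flat", "C"))
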