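"""Three-step trajectory testing and compensation classification.

The operational definition of compensation requires, over the CAP* axis:

  Condition 1 — structural load X declines linearly (significant negative
      linear trend; quadratic and cubic trends non-significant).
  Condition 2 — performance Y is concave-down (significant negative
      quadratic trend).
  Condition 3 — the compensator C is concave-down, either as a significant
      negative quadratic, or (the revised "delayed" pattern) as a
      significant cubic whose instantaneous slope at a late CAP point is
      negative.

Testing proceeds in three steps mirroring the growing model: a univariate
LMM for X alone (raw P at 0.05; X is the only structural variable), then
bivariate MLMMs of each candidate Y with X held linear (BH-adjusted within
the group of Y variables, per polynomial term), then trivariate MLMMs of
each candidate C with X linear and the surviving Y quadratic (BH-adjusted
within the group of C variables sharing that Y). For every variable the
linear, quadratic and cubic trends are tested in three separately fitted
models: each model's highest-order coefficient carries the test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .mlmm import DEFAULT_COVARIATES, FitResult, ModelSpec, TestResult, fit_mlmm, wald_test
from .preprocessing import CapParams
from .trajectory import instantaneous_slope

__all__ = [
    "TestResult",
    "ConditionVerdict",
    "HierarchyResult",
    "test_polynomial_hierarchy",
    "fdr_adjust",
    "run_step1",
    "run_step2",
    "run_step3",
    "classify_compensation",
]

_TERMS = ("linear", "quadratic", "cubic")


@dataclass
class HierarchyResult:
    """Linear/quadratic/cubic tests for one outcome, from three fits."""

    outcome: str
    tests: dict[str, TestResult]  # term -> test of that model's top coefficient
    fits: dict[str, FitResult]  # term -> the model it came from
    all_converged: bool

    def coefficients(self, term: str) -> tuple[float, float, float]:
        """(beta1, beta2, beta3) of the fit selected by `term` (absent
        higher-order terms are zero)."""
        fit = self.fits[term]
        fe = fit.fixed_effects[self.outcome]
        return tuple(
            fe.get(f"cap_star^{k}", (0.0, 0.0))[0] for k in (1, 2, 3)
        )


@dataclass
class ConditionVerdict:
    """Per-(X, Y, C) classification against the compensation conditions."""

    triple: tuple[str, str, str]
    cond1_linear_X: bool
    cond2_quadratic_Y: bool
    cond3_C_class: str  # quadratic_concave_down | cubic_with_negative_late_slope | inconsistent | none
    late_slope_Y: float
    late_slope_C: float | None
    overall: str  # compensation | partial_compensation | no_compensation

    def __post_init__(self) -> None:
        expected = "no_compensation"
        if self.cond1_linear_X and self.cond2_quadratic_Y:
            if self.cond3_C_class == "quadratic_concave_down":
                expected = "compensation"
            elif self.cond3_C_class == "cubic_with_negative_late_slope":
                expected = "partial_compensation"
        if self.overall != expected:
            raise ValueError(
                f"overall verdict {self.overall!r} inconsistent with conditions"
            )


def test_polynomial_hierarchy(
    data: pd.DataFrame,
    outcome: str,
    companions: tuple[tuple[str, int], ...] = (),
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    **fit_kwargs,
) -> HierarchyResult:
    """Fit the linear, quadratic and cubic models for one outcome and test
    each model's highest-order CAP* coefficient.

    `companions` are outcomes already selected at earlier steps, with their
    degrees fixed (e.g. X linear, Y quadratic); they are re-estimated jointly
    in each model but their degree never varies.
    """
    comp_names = tuple(n for n, _ in companions)
    if outcome in comp_names:
        raise ValueError(f"{outcome!r} duplicated as its own companion")
    tests: dict[str, TestResult] = {}
    fits: dict[str, FitResult] = {}
    all_ok = True
    start = None  # warm-start each degree from the previous fit's variances
    for deg, term in zip((1, 2, 3), _TERMS):
        spec = ModelSpec(
            outcomes=comp_names + (outcome,),
            degrees=tuple(d for _, d in companions) + (deg,),
            covariates=covariates,
        )
        fit = fit_mlmm(data, spec, start_theta=start, **fit_kwargs)
        start = fit.theta if fit.converged else None
        all_ok &= fit.converged
        est, se = fit.coef(outcome, f"cap_star^{deg}")
        tests[term] = wald_test(est, se, variable=outcome, term=term)
        fits[term] = fit
    return HierarchyResult(outcome, tests, fits, all_ok)


def fdr_adjust(pvalues, group_labels=None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, applied within each group.

    With m p-values in a group sorted ascending, q_(i) = min over j >= i of
    p_(j) * m / j, capped at 1. Groups partition the tests; a test in a
    singleton group keeps q = p.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if group_labels is None:
        group_labels = np.zeros(p.size)
    groups = np.asarray(group_labels)
    if groups.size != p.size:
        raise ValueError("group_labels must match pvalues in length")
    q = np.empty_like(p)
    for g in np.unique(groups):
        idx = np.where(groups == g)[0]
        pg = p[idx]
        m = pg.size
        order = np.argsort(pg, kind="stable")
        ranked = pg[order] * m / np.arange(1, m + 1)
        qg = np.minimum.accumulate(ranked[::-1])[::-1]
        qg = np.clip(qg, 0.0, 1.0)
        out = np.empty(m)
        out[order] = qg
        q[idx] = out
    return q


@dataclass
class Step1Result:
    hierarchy: HierarchyResult
    passed: bool
    reason: str


def run_step1(
    data: pd.DataFrame,
    x_name: str,
    alpha: float = 0.05,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    **fit_kwargs,
) -> Step1Result:
    """Univariate hierarchy on the structural variable X.

    Condition 1 holds iff the linear trend is negative and significant at
    raw P < alpha while the quadratic and cubic trends are non-significant
    (raw P; no FDR since X is the single structural candidate). On success
    X's degree is fixed to 1 for all later steps.
    """
    h = test_polynomial_hierarchy(data, x_name, covariates=covariates, **fit_kwargs)
    lin, quad, cub = (h.tests[t] for t in _TERMS)
    if not h.all_converged:
        return Step1Result(h, False, "non-converged fit in hierarchy")
    if lin.p >= alpha:
        return Step1Result(h, False, "linear trend not significant")
    if lin.estimate >= 0:
        return Step1Result(h, False, "linear trend not negative")
    if quad.p < alpha or cub.p < alpha:
        return Step1Result(h, False, "higher-order trend significant")
    return Step1Result(h, True, "linear decline confirmed")


@dataclass
class Step2Result:
    hierarchies: dict[str, HierarchyResult]
    tests: list[TestResult]  # all terms, q filled in
    survivors: list[str]


def run_step2(
    data: pd.DataFrame,
    x_name: str,
    y_names: list[str],
    q_threshold: float = 0.05,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    fdr_group: str = "Y",
    **fit_kwargs,
) -> Step2Result:
    """Bivariate hierarchies of each candidate Y with X held linear.

    BH adjustment is applied within the group of Y variables, separately per
    polynomial term. A Y survives iff its quadratic coefficient is negative
    with q < q_threshold; survivors carry degree 2 into step 3.
    """
    hierarchies = {
        y: test_polynomial_hierarchy(
            data, y, companions=((x_name, 1),), covariates=covariates, **fit_kwargs
        )
        for y in y_names
    }
    tests = _adjust_group(hierarchies, fdr_group)
    survivors = [
        y
        for y in y_names
        if hierarchies[y].all_converged
        and hierarchies[y].tests["quadratic"].q < q_threshold
        and hierarchies[y].tests["quadratic"].estimate < 0
    ]
    return Step2Result(hierarchies, tests, survivors)


@dataclass
class Step3Result:
    y_name: str
    hierarchies: dict[str, HierarchyResult]
    tests: list[TestResult]


def run_step3(
    data: pd.DataFrame,
    x_name: str,
    y_name: str,
    c_names: list[str],
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    **fit_kwargs,
) -> Step3Result:
    """Trivariate hierarchies of each candidate compensator C with X linear
    and Y quadratic; BH within the group of C variables sharing this Y,
    separately per polynomial term."""
    hierarchies = {
        c: test_polynomial_hierarchy(
            data,
            c,
            companions=((x_name, 1), (y_name, 2)),
            covariates=covariates,
            **fit_kwargs,
        )
        for c in c_names
    }
    tests = _adjust_group(hierarchies, f"C|{y_name}")
    return Step3Result(y_name, hierarchies, tests)


def _adjust_group(hierarchies: dict[str, HierarchyResult], group: str) -> list[TestResult]:
    """BH-adjust each polynomial term's p-values across the variables of one
    group; writes q back into the HierarchyResult tests."""
    out: list[TestResult] = []
    names = list(hierarchies)
    for term in _TERMS:
        ps = [hierarchies[n].tests[term].p for n in names]
        qs = fdr_adjust(ps)
        for n, qv in zip(names, qs):
            t = replace(hierarchies[n].tests[term], q=float(qv), group=f"{group}:{term}")
            hierarchies[n].tests[term] = t
            out.append(t)
    return out


def classify_compensation(
    step1: Step1Result,
    y_hierarchy: HierarchyResult,
    c_hierarchy: HierarchyResult,
    late_cap: float,
    q_threshold: float = 0.05,
    cap_params: CapParams = CapParams(),
) -> ConditionVerdict:
    """Assemble the per-triple verdict from the three steps.

    C is classified by its cubic model when the cubic term is significant
    (the delayed pattern takes precedence): a negative cubic with negative
    instantaneous slope at the late CAP point is
    'cubic_with_negative_late_slope'; a significant cubic failing either
    sign check is 'inconsistent'. Otherwise a significant negative quadratic
    gives 'quadratic_concave_down'; otherwise 'none'. Late-phase slopes of
    Y and C are recorded for description, never tested.
    """
    if y_hierarchy.tests["quadratic"].q is None or c_hierarchy.tests["cubic"].q is None:
        raise ValueError("q-values missing; run the step functions first")

    cond1 = step1.passed
    yq = y_hierarchy.tests["quadratic"]
    cond2 = yq.q < q_threshold and yq.estimate < 0

    cq, cc = c_hierarchy.tests["quadratic"], c_hierarchy.tests["cubic"]
    slope_y = instantaneous_slope(
        y_hierarchy.coefficients("quadratic"), late_cap, cap_params
    )
    if cc.q < q_threshold:
        slope_c = instantaneous_slope(
            c_hierarchy.coefficients("cubic"), late_cap, cap_params
        )
        if cc.estimate < 0 and slope_c < 0:
            c_class = "cubic_with_negative_late_slope"
        else:
            c_class = "inconsistent"
    elif cq.q < q_threshold and cq.estimate < 0:
        slope_c = instantaneous_slope(
            c_hierarchy.coefficients("quadratic"), late_cap, cap_params
        )
        c_class = "quadratic_concave_down"
    else:
        slope_c = None
        c_class = "none"

    if cond1 and cond2 and c_class == "quadratic_concave_down":
        overall = "compensation"
    elif cond1 and cond2 and c_class == "cubic_with_negative_late_slope":
        overall = "partial_compensation"
    else:
        overall = "no_compensation"
    return ConditionVerdict(
        triple=(step1.hierarchy.outcome, y_hierarchy.outcome, c_hierarchy.outcome),
        cond1_linear_X=cond1,
        cond2_quadratic_Y=cond2,
        cond3_C_class=c_class,
        late_slope_Y=float(slope_y),
        late_slope_C=None if slope_c is None else float(slope_c),
        overall=overall,
    )
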