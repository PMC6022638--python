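"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pandas as pd
import pytest

import compensatrack as ct


def make_scenario_data(
    scenario: str,
    n_participants: int = 60,
    seed: int = 0,
    residual_sd: float = 0.5,
    design_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Small synthetic cohort with outcomes from a named scenario."""
    n3 = n_participants - 6
    design = ct.CohortDesign(
        n_participants=n_participants,
        visit_counts={3: n3, 2: 4, 1: 2},
        seed=seed,
        **(design_kwargs or {}),
    )
    cohort = ct.add_cap_columns(ct.generate_cohort(design))
    truth = ct.scenario_preset(scenario, residual_sd=residual_sd)
    return ct.simulate_outcomes(cohort, truth, seed=seed + 1)


@pytest.fixture(scope="session")
def quad_data():
    """Cohort simulated under the full-compensation (quadratic) scenario."""
    return make_scenario_data("compensation_quadratic", n_participants=80, seed=42)


@pytest.fixture(scope="session")
def default_cohort():
    """Demographics-only cohort at the canonical design (110, 89/15/6)."""
    return ct.add_cap_columns(ct.generate_cohort(ct.CohortDesign(seed=7)))


# --- dense REML oracle ------------------------------------------------------
#
# Independent route: build the FULL joint covariance matrix over all
# observations explicitly (never blockwise) and evaluate the restricted
# likelihood and GLS fixed effects with plain dense linear algebra.


def dense_design(data: pd.DataFrame, spec: ct.ModelSpec):
    """Stacked y, X, participant index and outcome index, loop-built."""
    rows = []
    for k, (v, deg) in enumerate(zip(spec.outcomes, spec.degrees)):
        for _, r in data.iterrows():
            if np.isnan(r[v]):
                continue
            rows.append((r["participant_id"], k, deg, r["cap_star"], r, v))
    # fixed-effect layout: per outcome [intercept, cap powers, dummies]
    dummy_levels = []
    for cov in spec.covariates:
        levels = sorted(data[cov].astype(str).unique())
        dummy_levels += [(cov, lev) for lev in levels[1:]]
    widths = [1 + d + len(dummy_levels) for d in spec.degrees]
    offsets = np.cumsum([0] + widths)
    p = offsets[-1]
    y = np.array([r[4][r[5]] for r in rows], dtype=float)
    X = np.zeros((len(rows), p))
    pid = np.array([r[0] for r in rows])
    out = np.array([r[1] for r in rows])
    for i, (pi, k, deg, c, r, v) in enumerate(rows):
        o = offsets[k]
        X[i, o] = 1.0
        for d in range(1, deg + 1):
            X[i, o + d] = c**d
        for j, (cov, lev) in enumerate(dummy_levels):
            X[i, o + 1 + deg + j] = float(str(r[cov]) == lev)
    return y, X, pid, out


def dense_reml(data: pd.DataFrame, spec: ct.ModelSpec, D: np.ndarray, sigma2: np.ndarray):
    """-2 restricted log-likelihood and GLS beta via the full N x N matrix."""
    y, X, pid, out = dense_design(data, spec)
    n = y.size
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if pid[i] == pid[j]:
                V[i, j] = D[out[i], out[j]]
            if i == j:
                V[i, j] += sigma2[out[i]]
    sign, logdetV = np.linalg.slogdet(V)
    Vinv = np.linalg.inv(V)
    A = X.T @ Vinv @ X
    signA, logdetA = np.linalg.slogdet(A)
    beta = np.linalg.solve(A, X.T @ Vinv @ y)
    r = y - X @ beta
    n2ll = logdetV + logdetA + r @ Vinv @ r + (n - X.shape[1]) * np.log(2 * np.pi)
    return float(n2ll), beta, A


def theta_from(D: np.ndarray, sigma2: np.ndarray) -> np.ndarray:
    """Pack (D, sigma2) into the log-Cholesky parameter vector."""
    L = np.linalg.cholesky(D + 1e-12 * np.eye(D.shape[0]))
    vals = []
    for i in range(D.shape[0]):
        for j in range(i + 1):
            vals.append(np.log(L[i, j]) if i == j else L[i, j])
    return np.array(vals + list(np.log(sigma2)))
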