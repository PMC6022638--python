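"""Multivariate linear mixed models with correlated random intercepts, by REML.

The model for standardized score Z_ij(v) of outcome v, participant i, visit j:

    Z_ij(v) = alpha(v) + a_i(v) + sum_k beta_k(v) (CAP*)^k + gamma(v)' x_i
              + e_ij(v),    k = 1..degree(v)

The participant-level intercepts a_i = (a_i(1), ..., a_i(V)) are jointly
normal with unstructured covariance D (so outcomes are allowed to correlate
through their random intercepts); residuals e_ij(v) are independent with
per-outcome variance sigma2(v). Cross-outcome residual correlation is fixed
to zero: the between-outcome dependence is carried entirely by D.

Estimation profiles the fixed effects out by generalized least squares and
minimizes -2 x restricted log-likelihood over the variance parameters,
parameterized as the log-Cholesky factor of D plus log residual variances
(unconstrained, with D positive semi-definite by construction). An analytic
gradient is used. Each participant contributes a block with covariance
Z_i D Z_i' + R_i; blocks are grouped by missingness pattern so the
per-pattern covariance is factorized once, which keeps hundreds of fits in
a simulation affordable.

Missing visits/outcomes are handled by simply omitting the corresponding
rows; REML is unbiased when the missingness mechanism is ignorable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["ModelSpec", "FitResult", "reml_neg2loglik", "fit_mlmm", "wald_test"]

_LOG2PI = float(np.log(2.0 * np.pi))

DEFAULT_COVARIATES = ("sex", "education", "site")


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one (possibly multivariate) mixed model.

    outcomes  : ordered outcome column names (1 to 3 of them), all distinct
    degrees   : per-outcome polynomial degree in CAP* (0..3; the analysis
                pipeline uses 1..3, 0 is intercept-only)
    covariates: categorical columns to treatment-code (references are the
                first level in sorted order); pass () for no covariates
    """

    outcomes: tuple[str, ...]
    degrees: tuple[int, ...]
    covariates: tuple[str, ...] = DEFAULT_COVARIATES

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcomes", tuple(self.outcomes))
        object.__setattr__(self, "degrees", tuple(self.degrees))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if len(self.outcomes) != len(set(self.outcomes)):
            raise ValueError("outcomes must be distinct")
        if not 1 <= len(self.outcomes) <= 3:
            raise ValueError("1 to 3 outcomes supported")
        if len(self.degrees) != len(self.outcomes):
            raise ValueError("one degree per outcome required")
        if any(not 0 <= d <= 3 for d in self.degrees):
            raise ValueError("degrees must be between 0 and 3")

    @property
    def n_outcomes(self) -> int:
        return len(self.outcomes)


@dataclass
class FitResult:
    """REML fit of one MLMM.

    fixed_effects maps outcome -> {coefficient name -> (estimate, SE)}.
    Coefficient names: 'intercept', 'cap_star^k', and covariate dummy labels.
    random_intercept_cov is the V x V estimated D; residual_var per outcome.
    """

    spec: ModelSpec
    fixed_effects: dict[str, dict[str, tuple[float, float]]]
    random_intercept_cov: np.ndarray
    residual_var: dict[str, float]
    reml_loglik: float
    n_participants: int
    n_obs: int
    converged: bool
    grad_norm: float
    n_restarts: int
    theta: np.ndarray = field(repr=False, default=None)

    def coef(self, outcome: str, name: str) -> tuple[float, float]:
        """(estimate, SE) of one coefficient."""
        return self.fixed_effects[outcome][name]


@dataclass(frozen=True)
class TestResult:
    """Wald test of a single coefficient."""

    variable: str
    term: str
    estimate: float
    se: float
    z: float
    p: float
    q: float | None = None
    group: str | None = None


def wald_test(estimate: float, se: float, variable: str = "", term: str = "") -> TestResult:
    """Wald z-ratio test: z = estimate / SE, two-sided normal p-value."""
    if not se > 0:
        raise ValueError("standard error must be positive")
    z = estimate / se
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(variable, term, float(estimate), float(se), float(z), float(p))


# --- design construction ----------------------------------------------------


def _dummy_columns(data: pd.DataFrame, covariates: tuple[str, ...]):
    """Treatment-coded dummies; reference = first sorted level per covariate."""
    names: list[str] = []
    cols: list[np.ndarray] = []
    for cov in covariates:
        levels = sorted(data[cov].astype(str).unique())
        for lev in levels[1:]:
            names.append(f"{cov}[{lev}]")
            cols.append((data[cov].astype(str) == lev).to_numpy(float))
    if cols:
        return names, np.column_stack(cols)
    return names, np.empty((len(data), 0))


class _Stacked:
    """Observations stacked per participant and grouped by outcome pattern.

    For each participant the rows are ordered by outcome index then visit.
    A 'pattern' is the tuple of outcome indices of a participant's stacked
    rows; participants sharing a pattern share the marginal covariance
    V = Z D Z' + R, so its Cholesky is computed once per pattern.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        if "cap_star" not in data.columns:
            raise ValueError("data must have a cap_star column")
        V = spec.n_outcomes
        dummy_names, dummies = _dummy_columns(data, spec.covariates)

        # per-outcome fixed-effect column names and slices into beta vector
        self.coef_names: list[tuple[str, str]] = []  # (outcome, name)
        per_out_names: dict[str, list[str]] = {}
        for v, deg in zip(spec.outcomes, spec.degrees):
            names = ["intercept"] + [f"cap_star^{k}" for k in range(1, deg + 1)]
            names += dummy_names
            per_out_names[v] = names
            self.coef_names += [(v, nm) for nm in names]
        self.p = len(self.coef_names)
        offs = np.cumsum([0] + [len(per_out_names[v]) for v in spec.outcomes])
        self.offsets = {v: (offs[k], offs[k + 1]) for k, v in enumerate(spec.outcomes)}

        cap = data["cap_star"].to_numpy(float)
        ymat = data[list(spec.outcomes)].to_numpy(float)

        # build per-participant stacked y, X, outcome-index vector
        pids = data["participant_id"].to_numpy()
        order = np.argsort(pids, kind="stable")
        self.patterns: dict[tuple[int, ...], dict] = {}
        n_participants = 0
        n_obs = 0
        idx_by_pid: dict = {}
        for r in order:
            idx_by_pid.setdefault(pids[r], []).append(r)
        for pid, rows in idx_by_pid.items():
            rows = np.asarray(rows)
            y_parts, x_parts, out_idx = [], [], []
            for k, v in enumerate(spec.outcomes):
                obs = rows[~np.isnan(ymat[rows, k])]
                if obs.size == 0:
                    continue
                deg = spec.degrees[k]
                poly = np.column_stack(
                    [np.ones(obs.size)] + [cap[obs] ** d for d in range(1, deg + 1)]
                )
                xk = np.hstack([poly, dummies[obs]])
                lo, hi = self.offsets[v]
                xfull = np.zeros((obs.size, self.p))
                xfull[:, lo:hi] = xk
                y_parts.append(ymat[obs, k])
                x_parts.append(xfull)
                out_idx += [k] * obs.size
            if not y_parts:
                continue
            n_participants += 1
            key = tuple(out_idx)
            n_obs += len(out_idx)
            g = self.patterns.setdefault(key, {"y": [], "X": []})
            g["y"].append(np.concatenate(y_parts))
            g["X"].append(np.vstack(x_parts))
        if n_participants < 2:
            raise ValueError("need >=2 participants with observations")
        for key, g in self.patterns.items():
            g["y"] = np.stack(g["y"])  # (n_g, m)
            g["X"] = np.stack(g["X"])  # (n_g, m, p)
            g["out_idx"] = np.asarray(key)
        self.n_participants = n_participants
        self.n_obs = n_obs
        self.n_outcomes = V
        self.spec = spec


def _unpack_theta(theta: np.ndarray, V: int):
    """theta -> (D, sigma2, L). Log-Cholesky: diagonal of L stored as logs."""
    ntri = V * (V + 1) // 2
    L = np.zeros((V, V))
    pos = 0
    for i in range(V):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(theta[pos])
            else:
                L[i, j] = theta[pos]
            pos += 1
    sigma2 = np.exp(theta[ntri : ntri + V])
    return L @ L.T, sigma2, L


def _theta_size(V: int) -> int:
    return V * (V + 1) // 2 + V


def _neg2_reml_and_grad(theta: np.ndarray, st: _Stacked, want_grad: bool = True):
    """-2 restricted log-likelihood (with constant) and its gradient."""
    V = st.n_outcomes
    D, sigma2, L = _unpack_theta(theta, V)
    p = st.p

    A = np.zeros((p, p))  # sum X' V^-1 X
    b = np.zeros(p)  # sum X' V^-1 y
    yVy = 0.0
    logdet_sum = 0.0
    per_pattern = []
    for key, g in st.patterns.items():
        oi = g["out_idx"]
        m = oi.size
        Vm = D[np.ix_(oi, oi)] + np.diag(sigma2[oi])
        try:
            c = np.linalg.cholesky(Vm)
            Vinv = np.linalg.inv(Vm)
        except np.linalg.LinAlgError:
            # infeasible/singular point during a line search: reject it
            return np.inf, (np.zeros_like(theta) if want_grad else None)
        logdet = 2.0 * float(np.log(np.diag(c)).sum())
        n_g = g["y"].shape[0]
        logdet_sum += n_g * logdet
        W = np.einsum("mk,nkp->nmp", Vinv, g["X"])  # V^-1 X_i
        A += np.einsum("nmp,nmq->pq", g["X"], W)
        b += np.einsum("nmp,nm->p", W, g["y"])
        yVy += float(np.einsum("nm,mk,nk->", g["y"], Vinv, g["y"]))
        per_pattern.append((g, Vinv, W))

    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf, (np.zeros_like(theta) if want_grad else None)
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return np.inf, (np.zeros_like(theta) if want_grad else None)
    beta = Ainv @ b
    quad = yVy - float(b @ beta)
    n2ll = logdet_sum + logdetA + quad + (st.n_obs - p) * _LOG2PI

    if not want_grad:
        return n2ll, None

    # gradient: d(-2lR)/dt = tr(P Vdot) - r' V^-1 Vdot V^-1 r, blockwise
    ntri = V * (V + 1) // 2
    grad = np.zeros_like(theta)
    # precompute dD/dtheta_k = Ldot L' + L Ldot'
    dDs = []
    pos = 0
    for i in range(V):
        for j in range(i + 1):
            Ldot = np.zeros((V, V))
            Ldot[i, j] = L[i, j] if i == j else 1.0  # chain rule for log-diag
            dD = Ldot @ L.T + L @ Ldot.T
            dDs.append(dD)
            pos += 1

    for g, Vinv, W in per_pattern:
        oi = g["out_idx"]
        n_g = g["y"].shape[0]
        resid = g["y"] - np.einsum("nmp,p->nm", g["X"], beta)
        s = np.einsum("mk,nk->nm", Vinv, resid)  # V^-1 r_i
        # M1 = sum_i (V^-1 X_i)' Vdot (V^-1 X_i) contracted with Ainv
        for k in range(ntri):
            dV = dDs[k][np.ix_(oi, oi)]
            tr1 = n_g * float(np.einsum("mk,km->", Vinv, dV))
            M = np.einsum("nmp,mk,nkq->pq", W, dV, W)
            tr2 = float(np.einsum("pq,qp->", Ainv, M))
            rterm = float(np.einsum("nm,mk,nk->", s, dV, s))
            grad[k] += tr1 - tr2 - rterm
        # residual-variance params: dV = diag(sigma2_v on rows of outcome v)
        for v in range(V):
            mask = (oi == v).astype(float) * sigma2[v]
            if not mask.any():
                continue
            tr1 = n_g * float(np.diag(Vinv) @ mask)
            M = np.einsum("nmp,m,nmq->pq", W, mask, W)
            tr2 = float(np.einsum("pq,qp->", Ainv, M))
            rterm = float(np.einsum("nm,m,nm->", s, mask, s))
            grad[ntri + v] += tr1 - tr2 - rterm
    return n2ll, grad


def reml_neg2loglik(theta: np.ndarray, data: pd.DataFrame, spec: ModelSpec) -> float:
    """-2 x restricted log-likelihood at variance parameters theta.

    theta is the log-Cholesky parameterization of the random-intercept
    covariance (row-major lower triangle, diagonal on the log scale)
    followed by the log residual variances, length V(V+1)/2 + V.
    Includes the (n - p) log 2*pi constant.
    """
    st = _Stacked(data, spec)
    theta = np.asarray(theta, dtype=float)
    if theta.size != _theta_size(st.n_outcomes):
        raise ValueError(
            f"theta must have length {_theta_size(st.n_outcomes)}, got {theta.size}"
        )
    val, _ = _neg2_reml_and_grad(theta, st, want_grad=False)
    return float(val)


def _moment_start(st: _Stacked) -> np.ndarray:
    """Moment-based starting values: split each outcome's marginal residual
    variance evenly between intercept variance and residual variance."""
    V = st.n_outcomes
    var0 = np.ones(V)
    # crude per-outcome variance of observations around the overall mean
    tot = np.zeros(V)
    cnt = np.zeros(V)
    for g in st.patterns.values():
        oi = g["out_idx"]
        for v in range(V):
            yv = g["y"][:, oi == v]
            tot[v] += float((yv**2).sum())
            cnt[v] += yv.size
    var0 = np.where(cnt > 1, tot / np.maximum(cnt - 1, 1), 1.0)
    var0 = np.clip(var0, 1e-4, None)
    theta = np.zeros(_theta_size(V))
    pos = 0
    for i in range(V):
        for j in range(i + 1):
            if i == j:
                theta[pos] = 0.5 * np.log(0.5 * var0[i])
            pos += 1
    theta[pos : pos + V] = np.log(0.5 * var0)
    return theta


def fit_mlmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    max_restarts: int = 3,
    gtol: float = 1e-6,
    seed: int = 0,
    start_theta: np.ndarray | None = None,
) -> FitResult:
    """Fit the MLMM by REML.

    Minimizes the restricted -2 log-likelihood over variance parameters with
    L-BFGS-B and the analytic gradient, starting from moment-based values
    (or `start_theta`, e.g. a previous fit's estimate when refitting related
    models); on failure, retries from up to `max_restarts` dispersed starts.
    Fixed effects and SEs come from generalized least squares at the optimum
    (SE = sqrt of the diagonal of the inverse weighted cross-product).
    """
    st = _Stacked(data, spec)
    V = st.n_outcomes

    def objective(theta):
        return _neg2_reml_and_grad(theta, st, want_grad=True)

    rng = np.random.default_rng(seed)
    best = None
    n_restarts_used = 0
    if start_theta is not None and np.asarray(start_theta).size == _theta_size(V):
        starts = [np.asarray(start_theta, dtype=float)]
    else:
        starts = [_moment_start(st)]
    strict_tol = max(1e-3, gtol * 100)
    for attempt in range(1 + max_restarts):
        if attempt > 0:
            n_restarts_used += 1
            starts.append(_moment_start(st) + rng.normal(0, 0.7, _theta_size(V)))
        res = optimize.minimize(
            objective,
            starts[-1],
            jac=True,
            method="L-BFGS-B",
            # bounds keep exp() finite; +/-20 on a log-SD / log-variance scale
            # is far beyond any standardized-data optimum
            bounds=[(-20.0, 20.0)] * _theta_size(V),
            options={"maxiter": 500, "ftol": 1e-12, "gtol": gtol},
        )
        gnorm = float(np.max(np.abs(res.jac))) if np.all(np.isfinite(res.jac)) else np.inf
        # at an active bound (variance driven to ~0) the raw gradient need
        # not vanish, so accept moderate norms there; a huge norm means the
        # line search stalled in a degenerate region and must be retried
        ok = np.isfinite(res.fun) and (
            gnorm < strict_tol or (bool(res.success) and gnorm < 1e3)
        )
        if best is None or (np.isfinite(res.fun) and res.fun < best[0].fun - 1e-9):
            best = (res, gnorm, ok)
        if np.isfinite(res.fun) and gnorm < strict_tol:
            best = (res, gnorm, ok)
            break
    res, gnorm, ok = best
    theta_hat = res.x
    D, sigma2, _ = _unpack_theta(theta_hat, V)

    # GLS at the optimum for estimates and SEs
    A = np.zeros((st.p, st.p))
    b = np.zeros(st.p)
    for g in st.patterns.values():
        oi = g["out_idx"]
        Vm = D[np.ix_(oi, oi)] + np.diag(sigma2[oi])
        Vinv = np.linalg.inv(Vm)
        W = np.einsum("mk,nkp->nmp", Vinv, g["X"])
        A += np.einsum("nmp,nmq->pq", g["X"], W)
        b += np.einsum("nmp,nm->p", W, g["y"])
    Ainv = np.linalg.inv(A)
    beta = Ainv @ b
    ses = np.sqrt(np.clip(np.diag(Ainv), 0, None))

    fixed: dict[str, dict[str, tuple[float, float]]] = {v: {} for v in spec.outcomes}
    for (v, nm), est, se in zip(st.coef_names, beta, ses):
        fixed[v][nm] = (float(est), float(se))

    n2ll, _ = _neg2_reml_and_grad(theta_hat, st, want_grad=False)
    return FitResult(
        spec=spec,
        fixed_effects=fixed,
        random_intercept_cov=D,
        residual_var={v: float(sigma2[k]) for k, v in enumerate(spec.outcomes)},
        reml_loglik=-0.5 * float(n2ll),
        n_participants=st.n_participants,
        n_obs=st.n_obs,
        converged=bool(ok),
        grad_norm=gnorm,
        n_restarts=n_restarts_used,
        theta=theta_hat,
    )
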