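"""Synthetic longitudinal cohorts with known ground truth.

Emulates the design of a multisite premanifest Huntington's disease cohort:
~110 CAG-expansion carriers (CAG >= 40, fully penetrant), up to three annual
visits with a realistic visit-count mix (89 with three visits, 15 with two,
6 with one), four sites, sex and three-level education covariates, and
outcome trajectories that follow the cubic mixed-model equation

    Z_ij(v) = alpha(v) + a_i(v) + b1(v) CAP* + b2(v) CAP*^2 + b3(v) CAP*^3
              + gamma(v)' x_i + e_ij(v)

with correlated zero-mean random intercepts a_i across outcomes and
independent residuals. Scenario presets encode the coefficient-sign
templates the compensation conditions are designed to detect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import CapParams, add_cap_columns

__all__ = [
    "CohortDesign",
    "TrajectoryTruth",
    "SCENARIO_NAMES",
    "generate_cohort",
    "simulate_outcomes",
    "apply_missingness",
    "apply_availability_mask",
    "scenario_preset",
    "write_cohort",
    "read_cohort",
]

SITES = ("London", "Leiden", "Paris", "Vancouver")
EDUCATION_LEVELS = ("ISCED3", "ISCED4", "ISCED5")


@dataclass(frozen=True)
class CohortDesign:
    """Sampling plan for a synthetic cohort.

    visit_counts maps number-of-visits (1..3) to participant count and must
    sum to n_participants. Baseline age and CAG are drawn independently and
    uniformly over their ranges; CAG draws are integers and the lower bound
    must be >= 40 (full penetrance).
    """

    n_participants: int = 110
    visit_counts: dict[int, int] = field(
        default_factory=lambda: {3: 89, 2: 15, 1: 6}
    )
    visit_interval: float = 1.0
    age_range: tuple[float, float] = (30.0, 55.0)
    cag_range: tuple[int, int] = (40, 46)
    site_levels: tuple[str, ...] = SITES
    education_levels: tuple[str, ...] = EDUCATION_LEVELS
    sex_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.visit_counts.values()) != self.n_participants:
            raise ValueError(
                f"visit_counts sum to {sum(self.visit_counts.values())}, "
                f"expected n_participants={self.n_participants}"
            )
        if any(k < 1 or k > 3 for k in self.visit_counts):
            raise ValueError("visit counts must be between 1 and 3")
        if self.cag_range[0] < 40:
            raise ValueError("CAG lower bound must be >= 40 (full penetrance)")
        if len(self.site_levels) != 4:
            raise ValueError("exactly four site levels expected")
        if len(self.education_levels) != 3:
            raise ValueError("exactly three education levels expected")

    @property
    def n_rows(self) -> int:
        return sum(k * n for k, n in self.visit_counts.items())


@dataclass(frozen=True)
class TrajectoryTruth:
    """Generative fixed and random effects for a set of outcome variables.

    Per variable: intercept alpha, polynomial coefficients (beta1, beta2,
    beta3) on CAP*, and a covariate-effect vector gamma of length 6
    (sex, education x2, site x3 treatment dummies). random_intercept_cov is
    the cross-variable covariance of the participant-level intercepts and
    must be symmetric positive-semidefinite; residual_sd is per-variable.
    """

    variables: tuple[str, ...]
    alpha: dict[str, float]
    beta: dict[str, tuple[float, float, float]]
    gamma: dict[str, tuple[float, ...]]
    random_intercept_cov: np.ndarray
    residual_sd: dict[str, float]

    def __post_init__(self) -> None:
        D = np.asarray(self.random_intercept_cov, dtype=float)
        object.__setattr__(self, "random_intercept_cov", D)
        if D.shape != (len(self.variables),) * 2:
            raise ValueError("random_intercept_cov shape mismatch")
        if not np.allclose(D, D.T):
            raise ValueError("random_intercept_cov must be symmetric")
        if np.linalg.eigvalsh(D).min() < -1e-10:
            raise ValueError("random_intercept_cov must be PSD")
        for v in self.variables:
            if self.residual_sd[v] < 0:
                raise ValueError("residual_sd must be non-negative")


def _dummy_row(sex: str, education: str, site: str) -> np.ndarray:
    """Treatment-coded covariate vector; refs: female, ISCED3, London."""
    return np.array(
        [
            1.0 if sex == "male" else 0.0,
            1.0 if education == EDUCATION_LEVELS[1] else 0.0,
            1.0 if education == EDUCATION_LEVELS[2] else 0.0,
            1.0 if site == SITES[1] else 0.0,
            1.0 if site == SITES[2] else 0.0,
            1.0 if site == SITES[3] else 0.0,
        ]
    )


def generate_cohort(design: CohortDesign) -> pd.DataFrame:
    """Draw demographics and the visit grid; deterministic given design.seed.

    Returns one row per participant x attended visit with columns
    participant_id, visit, age, cag, sex, education, site. Ages increase by
    visit_interval within participant; CAG and covariates are constant.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_participants

    # per-participant number of visits, shuffled so ids are not ordered by it
    nvisits = np.repeat(
        list(design.visit_counts.keys()), list(design.visit_counts.values())
    )
    rng.shuffle(nvisits)

    age0 = rng.uniform(*design.age_range, size=n)
    cag = rng.integers(design.cag_range[0], design.cag_range[1] + 1, size=n)
    sex = np.where(rng.random(n) < design.sex_ratio, "male", "female")
    education = rng.choice(design.education_levels, size=n, p=(0.3, 0.4, 0.3))
    site = rng.choice(design.site_levels, size=n)

    rows = []
    for i in range(n):
        pid = f"P{i + 1:04d}"
        for j in range(int(nvisits[i])):
            rows.append(
                {
                    "participant_id": pid,
                    "visit": j + 1,
                    "age": age0[i] + j * design.visit_interval,
                    "cag": int(cag[i]),
                    "sex": sex[i],
                    "education": education[i],
                    "site": site[i],
                }
            )
    return pd.DataFrame(rows)


def simulate_outcomes(
    cohort: pd.DataFrame, truth: TrajectoryTruth, seed: int = 0
) -> pd.DataFrame:
    """Add outcome columns generated from the cubic mixed-model equation.

    Requires a 'cap_star' column (add via preprocessing.add_cap_columns).
    Random intercepts are drawn once per participant from the multivariate
    normal with covariance truth.random_intercept_cov; residuals are
    independent within and across outcomes.
    """
    if "cap_star" not in cohort.columns:
        raise ValueError("cohort must have cap_star (run add_cap_columns first)")
    rng = np.random.default_rng(seed)
    out = cohort.copy()

    pids = out["participant_id"].unique()
    V = len(truth.variables)
    a = rng.multivariate_normal(
        np.zeros(V), truth.random_intercept_cov, size=len(pids), method="svd"
    )
    a_by_pid = {pid: a[k] for k, pid in enumerate(pids)}

    c = out["cap_star"].to_numpy(dtype=float)
    xmat = np.stack(
        [
            _dummy_row(s, e, st)
            for s, e, st in zip(out["sex"], out["education"], out["site"])
        ]
    )
    a_rows = np.stack([a_by_pid[p] for p in out["participant_id"]])

    for k, v in enumerate(truth.variables):
        b1, b2, b3 = truth.beta[v]
        gamma = np.asarray(truth.gamma[v], dtype=float)
        mean = (
            truth.alpha[v]
            + b1 * c
            + b2 * c**2
            + b3 * c**3
            + xmat @ gamma
        )
        e = rng.normal(0.0, truth.residual_sd[v], size=len(out))
        out[v] = mean + a_rows[:, k] + e
    return out


def apply_missingness(
    table: pd.DataFrame,
    dropout_prob: float,
    seed: int = 0,
    site_effect: float = 0.0,
    age_effect: float = 0.0,
) -> pd.DataFrame:
    """Monotone missing-at-random dropout: once a visit is missed, all later
    visits are missed; the baseline visit is always kept.

    The per-visit dropout hazard is logistic in observed covariates,
    logit(p_i) = logit(dropout_prob) + site_effect*1[non-reference site]
               + age_effect*(standardized baseline age), so the mechanism
    depends only on fully observed quantities (ignorable). With both effects
    zero (the default) the hazard is the constant dropout_prob and the
    expected retained-visit fraction has a closed geometric form.
    """
    if not 0 <= dropout_prob < 1:
        raise ValueError("dropout_prob must be in [0, 1)")
    if dropout_prob == 0 and site_effect == 0 and age_effect == 0:
        return table.copy()
    rng = np.random.default_rng(seed)

    base = table[table["visit"] == 1]
    age0 = base.set_index("participant_id")["age"]
    mu = float(age0.mean())
    sd = float(age0.std(ddof=1)) if len(age0) > 1 else 1.0
    if not np.isfinite(sd) or sd == 0.0:
        sd = 1.0

    def hazard(pid: str, site: str) -> float:
        if dropout_prob == 0:
            return 0.0
        logit0 = np.log(dropout_prob / (1 - dropout_prob))
        z_age = (age0[pid] - mu) / sd
        lg = logit0 + site_effect * (site != SITES[0]) + age_effect * z_age
        return float(1.0 / (1.0 + np.exp(-lg)))

    keep = pd.Series(True, index=table.index)
    for pid, grp in table.groupby("participant_id", sort=False):
        grp = grp.sort_values("visit")
        site = grp["site"].iloc[0]
        p = hazard(pid, site)
        dropped = False
        for idx, visit in zip(grp.index, grp["visit"]):
            if visit == 1:
                continue
            if dropped or rng.random() < p:
                dropped = True
                keep[idx] = False
    return table[keep].copy()


def apply_availability_mask(
    table: pd.DataFrame,
    variables: list[str],
    available_sites: tuple[str, ...],
    visit: int = 3,
) -> pd.DataFrame:
    """Blank per-variable values outside the sites that acquired them.

    Reproduces the design feature that some task measures were collected at
    only two sites at the third visit: rows at `visit` from sites not in
    available_sites get NaN for the listed variables (the row itself stays).
    """
    out = table.copy()
    mask = (out["visit"] == visit) & ~out["site"].isin(available_sites)
    out.loc[mask, variables] = np.nan
    return out


# --- scenario presets -------------------------------------------------------

SCENARIO_NAMES = (
    "compensation_quadratic",
    "compensation_delayed_cubic",
    "no_compensation_linear",
    "null_flat",
    "anti_pattern_positive_cubic",
)

_ZERO6 = (0.0,) * 6
# modest covariate effects so the dummy design is exercised
_GAMMA = (0.15, 0.1, -0.1, 0.1, -0.05, 0.05)

_SCENARIO_BETA: dict[str, dict[str, tuple[float, float, float]]] = {
    # X linearly declining; Y and C concave-down quadratic: full compensation
    "compensation_quadratic": {
        "X": (-1.0, 0.0, 0.0),
        "Y": (-0.5, -0.3, 0.0),
        "C": (0.0, -0.3, 0.0),
    },
    # C's concave-down phase is delayed: negative cubic, negative late slope
    "compensation_delayed_cubic": {
        "X": (-1.0, 0.0, 0.0),
        "Y": (-0.5, -0.3, 0.0),
        "C": (0.0, 0.0, -0.25),
    },
    # everything declines linearly: performance never shows the plateau
    "no_compensation_linear": {
        "X": (-1.0, 0.0, 0.0),
        "Y": (-0.5, 0.0, 0.0),
        "C": (-0.3, 0.0, 0.0),
    },
    # no trajectory at all: calibration scenario
    "null_flat": {
        "X": (0.0, 0.0, 0.0),
        "Y": (0.0, 0.0, 0.0),
        "C": (0.0, 0.0, 0.0),
    },
    # positive cubic with positive late slope: fails the slope sign check
    "anti_pattern_positive_cubic": {
        "X": (-1.0, 0.0, 0.0),
        "Y": (-0.5, -0.3, 0.0),
        "C": (0.0, 0.0, 0.25),
    },
}

# the verdict the pipeline should reach on each scenario at large n
SCENARIO_EXPECTED_VERDICT = {
    "compensation_quadratic": "compensation",
    "compensation_delayed_cubic": "partial_compensation",
    "no_compensation_linear": "no_compensation",
    "null_flat": "no_compensation",
    "anti_pattern_positive_cubic": "no_compensation",
}


def scenario_preset(
    name: str,
    residual_sd: float = 0.5,
    intercept_var: float = 0.25,
    intercept_corr: float = 0.5,
) -> TrajectoryTruth:
    """Coefficient template for a named compensation scenario.

    Variables are X (structural load), Y (performance), C (compensator).
    Random intercepts have common variance `intercept_var` and pairwise
    correlation `intercept_corr`.
    """
    if name not in _SCENARIO_BETA:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        )
    beta = _SCENARIO_BETA[name]
    varnames = ("X", "Y", "C")
    D = np.full((3, 3), intercept_corr * intercept_var)
    np.fill_diagonal(D, intercept_var)
    return TrajectoryTruth(
        variables=varnames,
        alpha={v: 0.0 for v in varnames},
        beta={v: beta[v] for v in varnames},
        gamma={v: _GAMMA for v in varnames},
        random_intercept_cov=D,
        residual_sd={v: residual_sd for v in varnames},
    )


# --- I/O --------------------------------------------------------------------

_ID_COLS = ["participant_id", "visit", "age", "cag", "sex", "education", "site"]


def write_cohort(
    table: pd.DataFrame, out_dir: str | Path, manifest: dict | None = None
) -> Path:
    """Write a long-format CSV (one row per participant x visit x variable)
    and an optional ground-truth JSON manifest; returns the CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    value_cols = [c for c in table.columns if c not in _ID_COLS + ["cap", "cap_star"]]
    long = table.melt(
        id_vars=_ID_COLS, value_vars=value_cols, var_name="variable", value_name="value"
    )
    csv_path = out_dir / "cohort.csv"
    long.to_csv(csv_path, index=False)
    if manifest is not None:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return csv_path


def read_cohort(csv_path: str | Path) -> pd.DataFrame:
    """Read a long-format cohort CSV back into the wide per-visit layout."""
    long = pd.read_csv(csv_path)
    wide = long.pivot_table(
        index=_ID_COLS, columns="variable", values="value", aggfunc="first"
    ).reset_index()
    wide.columns.name = None
    return wide
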