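"""Fitted trajectories, instantaneous slopes and cluster-bootstrap bands.

Curves are population-averaged polynomial trajectories over the CAP axis;
the instantaneous rate of change is the first derivative of the selected
polynomial model at a late progression point (CAP = 420, approximately the
0.95 CAP percentile). Confidence bands resample participants with
replacement (cluster bootstrap, preserving within-participant repeated
measures), refit the model, and take pointwise percentile intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mlmm import FitResult, ModelSpec, fit_mlmm
from .preprocessing import CapParams, center_cap

__all__ = [
    "CurveEstimate",
    "fitted_curve",
    "instantaneous_slope",
    "bootstrap_bands",
    "reference_covariate_profile",
    "plot_trajectory",
]


@dataclass
class CurveEstimate:
    """Pointwise curve and percentile band on a CAP grid (SD units)."""

    cap_grid: np.ndarray
    mean_curve: np.ndarray
    lower_band: np.ndarray
    upper_band: np.ndarray
    coverage: float = 0.95
    n_boot: int = 0
    n_redrawn: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: columns cap, estimate, lower, upper."""
        return pd.DataFrame(
            {
                "cap": self.cap_grid,
                "estimate": self.mean_curve,
                "lower": self.lower_band,
                "upper": self.upper_band,
            }
        )


def reference_covariate_profile(fit: FitResult, data: pd.DataFrame, outcome: str) -> dict[str, float]:
    """Population-averaged dummy profile: each dummy at its sample mean,
    giving the cohort-level curve rather than a reference cell's."""
    profile = {}
    for name in fit.fixed_effects[outcome]:
        if name == "intercept" or name.startswith("cap_star^"):
            continue
        cov, lev = name[:-1].split("[")
        profile[name] = float((data[cov].astype(str) == lev).mean())
    return profile


def fitted_curve(
    fit: FitResult,
    outcome: str,
    cap_grid,
    reference_covariates: dict[str, float] | None = None,
    params: CapParams = CapParams(),
    data_cap_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Evaluate alpha + sum_k beta_k CAP*^k + gamma' x_ref on a CAP grid.

    Emits an extrapolation warning when the grid exceeds data_cap_range.
    """
    if not fit.converged:
        raise ValueError("refusing to evaluate a non-converged fit")
    cap_grid = np.asarray(cap_grid, dtype=float)
    if data_cap_range is not None and (
        cap_grid.min() < data_cap_range[0] or cap_grid.max() > data_cap_range[1]
    ):
        warnings.warn("grid extends beyond observed CAP range (extrapolation)")
    c = center_cap(cap_grid, params)
    fe = fit.fixed_effects[outcome]
    curve = np.full_like(c, fe["intercept"][0])
    for k in (1, 2, 3):
        name = f"cap_star^{k}"
        if name in fe:
            curve = curve + fe[name][0] * c**k
    if reference_covariates:
        for name, x in reference_covariates.items():
            curve = curve + fe[name][0] * x
    return curve


def instantaneous_slope(
    coefficients: tuple[float, float, float],
    cap: float,
    params: CapParams = CapParams(),
) -> float:
    """First derivative b1 + 2 b2 c* + 3 b3 c*^2 at c* = (cap - M)/S.

    `coefficients` are (beta1, beta2, beta3) of the selected polynomial
    model, with absent higher-order terms passed as zero. The slope is in
    SD units per CAP* unit.
    """
    b1, b2, b3 = coefficients
    c = center_cap(cap, params)
    return float(b1 + 2.0 * b2 * c + 3.0 * b3 * c**2)


def bootstrap_bands(
    data: pd.DataFrame,
    spec: ModelSpec,
    outcome: str,
    cap_grid,
    n_boot: int = 1000,
    coverage: float = 0.95,
    seed: int = 0,
    params: CapParams = CapParams(),
    max_failure_frac: float = 0.2,
    **fit_kwargs,
) -> CurveEstimate:
    """Cluster-bootstrap percentile bands for one outcome's fitted curve.

    Participants are resampled with replacement (resampled copies get fresh
    ids so repeated draws stay distinct clusters), the model is refitted on
    each resample and the curve evaluated at the population-averaged
    covariate profile of the original data. Non-converged resamples are
    redrawn (counted); more than `max_failure_frac` failures aborts.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    cap_grid = np.asarray(cap_grid, dtype=float)
    rng = np.random.default_rng(seed)

    full_fit = fit_mlmm(data, spec, **fit_kwargs)
    if not full_fit.converged:
        raise ValueError("full-data fit did not converge")
    profile = reference_covariate_profile(full_fit, data, outcome)
    mean_curve = fitted_curve(full_fit, outcome, cap_grid, profile, params)

    # row indices per participant, so a resample is a single iloc take
    data = data.reset_index(drop=True)
    row_idx = {
        pid: g.index.to_numpy() for pid, g in data.groupby("participant_id", sort=False)
    }
    pids = np.array(list(row_idx))
    curves = np.empty((n_boot, cap_grid.size))
    n_redrawn = 0
    max_failures = int(np.ceil(max_failure_frac * n_boot))
    b = 0
    while b < n_boot:
        draw = rng.choice(pids, size=pids.size, replace=True)
        take = np.concatenate([row_idx[pid] for pid in draw])
        resample = data.iloc[take].reset_index(drop=True)
        # repeated draws of one participant must stay distinct clusters
        resample["participant_id"] = np.repeat(
            np.arange(draw.size), [row_idx[p].size for p in draw]
        )
        try:
            fit = fit_mlmm(resample, spec, start_theta=full_fit.theta, **fit_kwargs)
            ok = fit.converged
        except (ValueError, np.linalg.LinAlgError):
            ok = False
        if not ok:
            n_redrawn += 1
            if n_redrawn > max_failures:
                raise RuntimeError(
                    f"more than {max_failure_frac:.0%} of bootstrap refits failed"
                )
            continue
        prof = reference_covariate_profile(fit, resample, outcome)
        curves[b] = fitted_curve(fit, outcome, cap_grid, prof, params)
        b += 1

    lo = (1.0 - coverage) / 2.0
    lower = np.quantile(curves, lo, axis=0)
    upper = np.quantile(curves, 1.0 - lo, axis=0)
    return CurveEstimate(
        cap_grid=cap_grid,
        mean_curve=mean_curve,
        lower_band=lower,
        upper_band=upper,
        coverage=coverage,
        n_boot=n_boot,
        n_redrawn=n_redrawn,
    )


def plot_trajectory(
    data: pd.DataFrame,
    outcome: str,
    bands: CurveEstimate,
    ax=None,
    out_path: str | None = None,
):
    """Spaghetti plot of per-participant observations with the fitted curve
    and its bootstrap band (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for _, g in data.groupby("participant_id", sort=False):
        g = g.sort_values("cap")
        ax.plot(g["cap"], g[outcome], "o-", color="grey", lw=0.5, ms=2, alpha=0.4)
    ax.fill_between(
        bands.cap_grid, bands.lower_band, bands.upper_band, color="tab:red", alpha=0.25
    )
    ax.plot(bands.cap_grid, bands.mean_curve, color="tab:red", lw=2)
    ax.set_xlabel("CAP")
    ax.set_ylabel(f"{outcome} (SD units)")
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=150, bbox_inches="tight")
    return ax
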