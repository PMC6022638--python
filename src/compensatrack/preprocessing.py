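"""Transformations onto the analysis scale.

The longitudinal time metric is the CAG-Age Product, CAP = age x (CAG - 35.5),
which places carriers with different repeat lengths on a common disease-load
axis. For model fitting CAP is centred and scaled, CAP* = (CAP - M) / S with
M = 320 and S = 60 (the approximate cohort mean and SD). Analysis variables
are z-standardized over their own pooled vector of scores (participants and
repeated measures together), after an optional sign flip so that smaller
values always indicate greater deterioration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CapParams",
    "VariableSpec",
    "StandardizationRecord",
    "compute_cap",
    "center_cap",
    "add_cap_columns",
    "standardize",
    "standardize_table",
    "build_brain_composite",
    "cap_percentile",
]


@dataclass(frozen=True)
class CapParams:
    """Constants of the CAP time metric.

    cag_offset : repeats subtracted from CAG (35.5, the conventional offset)
    center_M   : centring constant in CAP units (320)
    scale_S    : scaling constant in CAP units (60); must be > 0
    """

    cag_offset: float = 35.5
    center_M: float = 320.0
    scale_S: float = 60.0

    def __post_init__(self) -> None:
        if self.scale_S <= 0:
            raise ValueError("scale_S must be positive")


@dataclass(frozen=True)
class VariableSpec:
    """Role and conventions for one analysis variable.

    role       : 'X' (structural load), 'Y' (performance) or 'C' (compensator)
    flip_sign  : multiply raw scores by -1 before standardization; used when
                 larger raw values mean worse status (e.g. a motor error score)
    fdr_group  : label of the group within which BH adjustment is applied
    network    : 'cognitive' or 'motor' (bookkeeping only)
    """

    name: str
    role: str
    flip_sign: bool = False
    fdr_group: str = ""
    network: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("X", "Y", "C"):
            raise ValueError(f"role must be X, Y or C, got {self.role!r}")


@dataclass(frozen=True)
class StandardizationRecord:
    """Mean/SD actually used to z-score one variable (post sign flip)."""

    variable: str
    mean: float
    sd: float
    n_used: int


def compute_cap(age, cag, params: CapParams = CapParams()):
    """CAP = age x (CAG - offset), evaluated per visit with age at that visit.

    Raises ValueError if any CAG is at or below the offset (metric undefined).
    Accepts scalars or arrays.
    """
    age = np.asarray(age, dtype=float)
    cag = np.asarray(cag, dtype=float)
    if np.any(age <= 0):
        raise ValueError("age must be positive")
    if np.any(cag <= params.cag_offset):
        raise ValueError(
            f"CAP undefined for CAG <= {params.cag_offset} (got min {cag.min()})"
        )
    out = age * (cag - params.cag_offset)
    return out.item() if out.ndim == 0 else out


def center_cap(cap, params: CapParams = CapParams()):
    """CAP* = (CAP - M) / S."""
    cap = np.asarray(cap, dtype=float)
    out = (cap - params.center_M) / params.scale_S
    return out.item() if out.ndim == 0 else out


def add_cap_columns(table: pd.DataFrame, params: CapParams = CapParams()) -> pd.DataFrame:
    """Return a copy of a cohort table with 'cap' and 'cap_star' columns."""
    out = table.copy()
    out["cap"] = compute_cap(out["age"].to_numpy(), out["cag"].to_numpy(), params)
    out["cap_star"] = center_cap(out["cap"].to_numpy(), params)
    return out


def standardize(values, spec: VariableSpec) -> tuple[np.ndarray, StandardizationRecord]:
    """Z-score a variable over its pooled vector of scores.

    The sign flip (if any) is applied before standardization so the returned
    z-scores satisfy "smaller = worse". Missing entries (NaN) are ignored for
    the mean/SD and propagate as NaN. Raises on fewer than two non-missing
    values or zero spread (a degenerate variable cannot be standardized).
    """
    v = np.asarray(values, dtype=float).copy()
    if spec.flip_sign:
        v = -v
    mask = ~np.isnan(v)
    n = int(mask.sum())
    if n < 2:
        raise ValueError(f"{spec.name}: need >=2 non-missing values, got {n}")
    mean = float(v[mask].mean())
    sd = float(v[mask].std(ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError(f"{spec.name}: zero spread, cannot standardize")
    z = (v - mean) / sd
    return z, StandardizationRecord(spec.name, mean, sd, n)


def standardize_table(
    table: pd.DataFrame, specs: list[VariableSpec]
) -> tuple[pd.DataFrame, dict[str, StandardizationRecord]]:
    """Standardize every listed variable column in place (on a copy)."""
    out = table.copy()
    records: dict[str, StandardizationRecord] = {}
    for spec in specs:
        z, rec = standardize(out[spec.name].to_numpy(), spec)
        out[spec.name] = z
        records[spec.name] = rec
    return out, records


def build_brain_composite(
    volume_table: pd.DataFrame, columns: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """First-principal-component disease-load composite of regional volumes.

    All visits are pooled, the volume columns (grey matter, white matter,
    caudate, putamen — already corrected for total intracranial volume) are
    z-scored, and the first PC of the correlation matrix provides the weights.
    The sign is oriented so every loading is non-negative: larger composite
    means larger volumes, i.e. less disease. Rows with any missing volume get
    a NaN score (listwise for the PCA itself).

    Returns (scores aligned to the input rows, loadings per column).
    """
    cols = list(columns) if columns is not None else list(volume_table.columns)
    mat = volume_table[cols].to_numpy(dtype=float)
    complete = ~np.isnan(mat).any(axis=1)
    x = mat[complete]
    if x.shape[0] < 2:
        raise ValueError("need >=2 complete rows for the composite")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant volume column: composite undefined")
    z = (x - x.mean(axis=0)) / sd
    corr = (z.T @ z) / (z.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals[-1] <= 1e-12:
        raise ValueError("rank-deficient volume matrix")
    w = eigvecs[:, -1]
    # orient so loadings are non-negative (volumes load together on PC1)
    if w.sum() < 0:
        w = -w
    scores = np.full(mat.shape[0], np.nan)
    scores[complete] = z @ w
    return scores, w


def cap_percentile(table: pd.DataFrame, q: float = 0.95) -> float:
    """Empirical q-quantile of all per-observation CAP values.

    Linear interpolation between order statistics (numpy default rule).
    The 0.95 quantile defines the "late" progression point for slopes.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    cap = table["cap"].to_numpy(dtype=float)
    cap = cap[~np.isnan(cap)]
    if cap.size == 0:
        raise ValueError("no CAP values in table")
    return float(np.quantile(cap, q))
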