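"""Pipeline orchestration and results-table rendering.

`run_pipeline` chains preprocessing, the three testing steps, compensation
classification and (optionally) trajectory bands, and can persist a
machine-readable bundle: a JSON file with every test and verdict, CSV
coefficient tables formatted like the published ones ("estimate (SE)" with
q-value stars), and a log of seeds and convergence retries.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import (
    ConditionVerdict,
    HierarchyResult,
    Step1Result,
    Step2Result,
    Step3Result,
    classify_compensation,
    run_step1,
    run_step2,
    run_step3,
)
from .mlmm import DEFAULT_COVARIATES
from .preprocessing import (
    CapParams,
    VariableSpec,
    add_cap_columns,
    cap_percentile,
    standardize_table,
)

__all__ = ["RunConfig", "PipelineResult", "render_results_table", "run_pipeline"]

_TERMS = ("linear", "quadratic", "cubic")


@dataclass
class RunConfig:
    """Configuration for one full compensation analysis.

    variables     : VariableSpec per analysis variable (exactly one role X)
    c_by_y        : compensators to test against each performance variable;
                    by default every C is tested against every surviving Y
    alpha         : raw significance level for step 1 (structural variable)
    q_threshold   : FDR significance level for steps 2-3
    late_cap_rule : 'percentile' (default, uses late_cap_q) or 'fixed'
                    (uses late_cap_value, e.g. the canonical 420)
    """

    variables: list[VariableSpec]
    c_by_y: dict[str, list[str]] | None = None
    cap_params: CapParams = field(default_factory=CapParams)
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    alpha: float = 0.05
    q_threshold: float = 0.05
    late_cap_rule: str = "percentile"
    late_cap_q: float = 0.95
    late_cap_value: float = 420.0
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.q_threshold < 1:
            raise ValueError("thresholds must be in (0, 1)")
        if self.late_cap_rule not in ("percentile", "fixed"):
            raise ValueError("late_cap_rule must be 'percentile' or 'fixed'")
        roles = [v.name for v in self.variables if v.role == "X"]
        if len(roles) != 1:
            raise ValueError(f"exactly one X variable required, got {roles}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        variables = [VariableSpec(**v) for v in raw.pop("variables")]
        cap = raw.pop("cap_params", None)
        cfg = cls(variables=variables, **raw)
        if cap:
            cfg.cap_params = CapParams(**cap)
        return cfg

    @property
    def x_name(self) -> str:
        return next(v.name for v in self.variables if v.role == "X")

    @property
    def y_names(self) -> list[str]:
        return [v.name for v in self.variables if v.role == "Y"]

    @property
    def c_names(self) -> list[str]:
        return [v.name for v in self.variables if v.role == "C"]


@dataclass
class PipelineResult:
    halted_at: str | None  # 'step1' when X is not linear-decreasing, else None
    step1: Step1Result
    step2: Step2Result | None
    step3: dict[str, Step3Result]
    verdicts: list[ConditionVerdict]
    late_cap: float
    tables: dict[str, pd.DataFrame]
    log: dict

    def to_json_dict(self) -> dict:
        def tests_of(h: HierarchyResult):
            return {
                term: {
                    k: getattr(t, k)
                    for k in ("variable", "term", "estimate", "se", "z", "p", "q", "group")
                }
                for term, t in h.tests.items()
            }

        return {
            "halted_at": self.halted_at,
            "late_cap": self.late_cap,
            "step1": {
                "passed": self.step1.passed,
                "reason": self.step1.reason,
                "tests": tests_of(self.step1.hierarchy),
            },
            "step2": None
            if self.step2 is None
            else {
                "survivors": self.step2.survivors,
                "tests": {y: tests_of(h) for y, h in self.step2.hierarchies.items()},
            },
            "step3": {
                y: {c: tests_of(h) for c, h in s3.hierarchies.items()}
                for y, s3 in self.step3.items()
            },
            "verdicts": [asdict(v) for v in self.verdicts],
            "log": self.log,
        }


def _stars(q: float | None) -> str:
    if q is None:
        return ""
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return ""


def render_results_table(
    hierarchies: dict[str, HierarchyResult],
    slopes: dict[str, float] | None = None,
    counts: dict[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Format hierarchy results as a published-style coefficient table.

    Cells read "estimate (SE)" at 4 decimals with star suffixes
    (* q<0.05, ** q<0.01, *** q<0.001); the slope column carries no stars
    because it is descriptive, not inferential. Negative signs are ASCII.
    Raises if a starred column is missing its q-value.
    """
    rows = []
    for name, h in hierarchies.items():
        row = {"variable": name}
        for term in _TERMS:
            t = h.tests[term]
            if t.q is None:
                raise ValueError(f"missing q-value for {name}/{term}")
            row[term] = f"{t.estimate:.4f} ({t.se:.4f}){_stars(t.q)}"
        if slopes is not None and name in slopes:
            row["slope"] = f"{slopes[name]:.4f}"
        if counts is not None and name in counts:
            row["n"], row["obs"] = counts[name]
        rows.append(row)
    return pd.DataFrame(rows)


def _counts(data: pd.DataFrame, name: str) -> tuple[int, int]:
    obs = data[~data[name].isna()]
    return obs["participant_id"].nunique(), len(obs)


def run_pipeline(data: pd.DataFrame, config: RunConfig) -> PipelineResult:
    """Execute the full analysis on a wide cohort table.

    `data` must hold raw (unstandardized) variable values plus the
    demographic columns; CAP columns are (re)computed here. A step-1 failure
    (X not linearly decreasing) halts the pipeline with an explicit verdict
    rather than raising.
    """
    if len(data) == 0:
        raise ValueError("empty input table")
    data = add_cap_columns(data, config.cap_params)
    data, records = standardize_table(data, config.variables)

    late_cap = (
        cap_percentile(data, config.late_cap_q)
        if config.late_cap_rule == "percentile"
        else config.late_cap_value
    )

    log: dict = {
        "seed": config.seed,
        "standardization": {
            k: {"mean": r.mean, "sd": r.sd, "n": r.n_used} for k, r in records.items()
        },
        "restarts": {},
    }

    step1 = run_step1(
        data, config.x_name, alpha=config.alpha, covariates=config.covariates
    )
    log["restarts"]["step1"] = sum(
        f.n_restarts for f in step1.hierarchy.fits.values()
    )
    if not step1.passed:
        result = PipelineResult(
            halted_at="step1",
            step1=step1,
            step2=None,
            step3={},
            verdicts=[],
            late_cap=late_cap,
            tables={},
            log=log,
        )
        _maybe_write(result, config)
        return result

    step2 = run_step2(
        data,
        config.x_name,
        config.y_names,
        q_threshold=config.q_threshold,
        covariates=config.covariates,
    )
    step3: dict[str, Step3Result] = {}
    verdicts: list[ConditionVerdict] = []
    c_by_y = config.c_by_y or {y: config.c_names for y in config.y_names}
    for y in step2.survivors:
        cs = c_by_y.get(y, [])
        if not cs:
            continue
        s3 = run_step3(data, config.x_name, y, cs, covariates=config.covariates)
        step3[y] = s3
        for c in cs:
            verdicts.append(
                classify_compensation(
                    step1,
                    step2.hierarchies[y],
                    s3.hierarchies[c],
                    late_cap,
                    q_threshold=config.q_threshold,
                    cap_params=config.cap_params,
                )
            )

    # published-style tables
    from .trajectory import instantaneous_slope

    y_slopes = {}
    for y, h in step2.hierarchies.items():
        term = "quadratic" if h.tests["quadratic"].q < config.q_threshold else "linear"
        y_slopes[y] = instantaneous_slope(
            h.coefficients(term), late_cap, config.cap_params
        )
    # step 1 uses raw P-values (no FDR), so only steps 2-3 get starred tables
    tables = {
        "step2": render_results_table(
            step2.hierarchies,
            slopes=y_slopes,
            counts={y: _counts(data, y) for y in step2.hierarchies},
        ),
    }
    for y, s3 in step3.items():
        c_slopes = {}
        for c, h in s3.hierarchies.items():
            if h.tests["cubic"].q < config.q_threshold:
                term = "cubic"
            elif h.tests["quadratic"].q < config.q_threshold:
                term = "quadratic"
            else:
                term = "linear"
            c_slopes[c] = instantaneous_slope(
                h.coefficients(term), late_cap, config.cap_params
            )
        tables[f"step3_{y}"] = render_results_table(
            s3.hierarchies,
            slopes=c_slopes,
            counts={c: _counts(data, c) for c in s3.hierarchies},
        )

    result = PipelineResult(
        halted_at=None,
        step1=step1,
        step2=step2,
        step3=step3,
        verdicts=verdicts,
        late_cap=late_cap,
        tables=tables,
        log=log,
    )
    _maybe_write(result, config)
    return result


def _maybe_write(result: PipelineResult, config: RunConfig) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "results.json").write_text(
        json.dumps(result.to_json_dict(), indent=2, sort_keys=True, default=float)
    )
    for name, table in result.tables.items():
        table.to_csv(out / f"table_{name}.csv", index=False)
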