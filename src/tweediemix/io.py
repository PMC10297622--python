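"""Reading long-format data, configuration files, and writing fit reports."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .estimation import FitResult
from .data import MultilevelData

__all__ = [
    "RunConfig",
    "read_long_csv",
    "read_config",
    "write_results",
    "write_blup_table",
    "CoefficientRow",
    "FitReport",
]


class RunConfig(BaseModel):
    """Fit configuration: level assignments, Tweedie index, controls."""

    levels: dict[str, str] = Field(default_factory=dict)
    p: float = 1.5
    intercept: bool = True
    cluster_col: str = "cluster"
    subcluster_col: str = "subcluster"
    response_col: str = "y"
    max_iter: int = 200
    tol_params: float = 1e-8
    tol_score: float = 1e-6
    fix_sigma2: Optional[float] = None
    fix_tau2: Optional[float] = None
    fix_rho2: Optional[float] = None

    @field_validator("p")
    @classmethod
    def _check_p(cls, v: float) -> float:
        if not 1.0 < v < 2.0:
            raise ValueError(f"p must lie in (1, 2); got {v}")
        return v

    @field_validator("levels")
    @classmethod
    def _check_levels(cls, v: dict[str, str]) -> dict[str, str]:
        bad = {k: lv for k, lv in v.items() if lv not in ("cluster", "subcluster", "observation")}
        if bad:
            raise ValueError(f"unknown level assignment(s): {bad}")
        return v


class CoefficientRow(BaseModel):
    name: str
    level: str
    estimate: float
    se: float
    p_value: float


class FitReport(BaseModel):
    """Serializable fit report: coefficients by level, dispersions, diagnostics."""

    coefficients: list[CoefficientRow]
    sigma2: float
    tau2: float
    rho2: float
    p: float
    converged: bool
    n_iter: int
    score_inf_norm: float


def read_long_csv(path: str | Path) -> pd.DataFrame:
    """Read a long-format CSV (comma separated, UTF-8, '.' decimal).

    Requires cluster, subcluster and response columns (named in the run
    config); IDs are kept as strings, numerics are parsed strictly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such data file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    return df


def read_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return RunConfig(**(raw or {}))


def build_report(result: FitResult, data: MultilevelData) -> FitReport:
    levels = (
        ["cluster"] * len(data.names1)
        + ["subcluster"] * len(data.names2)
        + ["observation"] * len(data.names3)
    )
    rows = [
        CoefficientRow(
            name=n, level=lv, estimate=float(e), se=float(s), p_value=float(pv)
        )
        for n, lv, e, s, pv in zip(
            result.coef_names, levels, result.coef, result.se, result.p_values
        )
    ]
    return FitReport(
        coefficients=rows,
        sigma2=result.params.sigma2,
        tau2=result.params.tau2,
        rho2=result.params.rho2,
        p=result.params.p,
        converged=result.converged,
        n_iter=result.n_iter,
        score_inf_norm=result.score_inf_norm,
    )


def format_report(report: FitReport) -> str:
    """Human-readable aligned table, coefficients grouped by level."""
    lines = []
    header = f"{'level':<12} {'covariate':<16} {'estimate':>10} {'se':>10} {'p-value':>8}"
    lines.append(header)
    lines.append("-" * len(header))
    for level in ("observation", "subcluster", "cluster"):
        for row in report.coefficients:
            if row.level == level:
                lines.append(
                    f"{row.level:<12} {row.name:<16} {row.estimate:>10.4f} "
                    f"{row.se:>10.4f} {row.p_value:>8.4f}"
                )
    lines.append("-" * len(header))
    for name, val in (("sigma2", report.sigma2), ("tau2", report.tau2), ("rho2", report.rho2)):
        lines.append(f"{'dispersion':<12} {name:<16} {val:>10.4f}")
    lines.append(f"p = {report.p}  converged = {report.converged}  iterations = {report.n_iter}")
    return "\n".join(lines)


def write_results(result: FitResult, data: MultilevelData, path: str | Path) -> FitReport:
    """Persist a fit as JSON (machine) plus an aligned-text table (human).

    The text table is written next to the JSON file with suffix ``.txt``.
    """
    path = Path(path)
    report = build_report(result, data)
    path.write_text(report.model_dump_json(indent=2), encoding="utf-8")
    path.with_suffix(".txt").write_text(format_report(report) + "\n", encoding="utf-8")
    return report


def write_blup_table(result: FitResult, data: MultilevelData, path: str | Path) -> None:
    """Write the predicted random effects (one row per sub-cluster) as CSV."""
    result.blup.to_frame(data).to_csv(path, index=False, float_format="%.12g")
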