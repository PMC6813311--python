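"""Reading survival tables and serializing fit reports.

Input CSV may be pre-aggregated (columns ``concentration, n_exposed,
n_surviving`` plus optional ``day, label``) or per-animal (columns
``concentration, survived`` with survived in {0, 1}).  Duplicate
concentration/day rows are summed before validation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .pipeline import ConcentrationResponseData, EcxSysFit, PipelineConfig, predict_survival
from .traditional import LogLogisticParams, loglogistic_evaluate

__all__ = ["RunConfig", "read_response_table", "write_report", "load_report"]

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """End-to-end settings of one CLI run."""

    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    fit_traditional: bool = True
    seed: int | None = None
    output: str | None = None
    curve_points: int = 200


def _aggregate(df: pd.DataFrame) -> pd.DataFrame:
    keys = [k for k in ("day", "label", "concentration") if k in df.columns]
    return df.groupby(keys, as_index=False, dropna=False)[["n_exposed", "n_surviving"]].sum()


def read_response_table(path):
    """Read and validate a concentration-response CSV.

    Returns a single :class:`ConcentrationResponseData` when the file holds
    one observation day, otherwise a dict keyed by day.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "concentration" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'concentration'")
    if "survived" in df.columns:  # per-animal rows
        bad = ~df["survived"].isin((0, 1))
        if bad.any():
            raise ValidationError(
                f"{path}: 'survived' must be 0/1; offending rows {df.index[bad].tolist()}")
        df = df.assign(n_exposed=1, n_surviving=df["survived"].astype(int))
        df = df.drop(columns=["survived"])
    missing = {"n_exposed", "n_surviving"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    for col in ("concentration", "n_exposed", "n_surviving"):
        if df[col].isna().any():
            raise ValidationError(
                f"{path}: NaN in '{col}' at rows {df.index[df[col].isna()].tolist()}")
    bad = df["n_surviving"] > df["n_exposed"]
    if bad.any():
        raise ValidationError(
            f"{path}: survival exceeds 100% at rows {df.index[bad].tolist()}")
    df = _aggregate(df)

    def build(sub: pd.DataFrame, day=None) -> ConcentrationResponseData:
        label = None
        if "label" in sub.columns and sub["label"].nunique(dropna=True) == 1:
            val = sub["label"].dropna()
            label = str(val.iloc[0]) if len(val) else None
        return ConcentrationResponseData(
            concentration=sub["concentration"].to_numpy(float),
            n_exposed=sub["n_exposed"].to_numpy(int),
            n_surviving=sub["n_surviving"].to_numpy(int),
            day=None if day is None else int(day),
            label=label,
        )

    if "day" in df.columns and df["day"].nunique(dropna=True) > 1:
        return {int(day): build(sub, day) for day, sub in df.groupby("day")}
    day = int(df["day"].iloc[0]) if "day" in df.columns and df["day"].notna().all() else None
    return build(df, day)


def _params_dict(params) -> dict:
    return {k: float(v) for k, v in asdict(params).items()}


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_report(fit: EcxSysFit, path, traditional: LogLogisticParams | None = None,
                 traditional_lc: dict | None = None, input_paths=None,
                 run_config: RunConfig | None = None, stage_failure: str | None = None,
                 curve_points: int = 200) -> dict:
    """Serialize a fit (possibly partial) to JSON plus a predicted-curve CSV.

    The companion CSV (``<stem>_curve.csv``) samples the predicted survival
    curve on a log-concentration grid.  Returns the report dict.
    """
    path = Path(path)
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "inputs": {str(p): _digest(p) for p in (input_paths or [])},
        "config": {
            "capacity": {"p": fit.capacity.p, "q": fit.capacity.q},
            "smoothing": fit.config.smoothing,
            "lc_definition": fit.config.lc_definition,
            "lc_levels": list(fit.config.lc_levels),
            "seed": run_config.seed if run_config else None,
        },
        "converged": fit.converged,
        "stage_failure": stage_failure,
        "warnings": list(fit.warnings),
        "toxicant_curve": _params_dict(fit.toxicant_curve),
        "sys_curve": _params_dict(fit.sys_curve),
        "s_env": fit.s_env,
        "hormesis_concentration": fit.hormesis_concentration,
        "smoothing_points": [list(p) for p in fit.smoothing_points],
        "sys_ec99_stress": fit.sys_ec99_stress,
        "hormetic_range": list(fit.hormetic_range) if fit.hormetic_range else None,
        "decomposition": fit.decomposition.to_dict(),
        "lc": {f"{k:g}": v for k, v in fit.lc.items()},
        "residual_sum_of_squares": fit.residual_sum_of_squares,
    }
    if traditional is not None:
        report["traditional"] = {
            "params": {"b": traditional.b, "c": 0.0, "d": traditional.d, "e": traditional.e},
            "lc": {f"{k:g}": v for k, v in (traditional_lc or {}).items()},
        }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    pos = fit.decomposition.concentration[fit.decomposition.concentration > 0]
    grid = np.logspace(np.log10(pos.min() / 100.0), np.log10(pos.max() * 10.0), curve_points)
    curve = pd.DataFrame({
        "concentration": grid,
        "predicted_survival": np.asarray(predict_survival(fit, grid)),
    })
    if traditional is not None:
        curve["traditional_survival"] = np.asarray(loglogistic_evaluate(traditional, grid))
    curve.to_csv(path.with_name(path.stem + "_curve.csv"), index=False)
    return report


def write_failure_report(path, stage_failure: str, input_paths=None,
                         run_config: RunConfig | None = None) -> dict:
    """Write a stub report for a run that failed before producing a fit."""
    path = Path(path)
    report = {
        "schema_version": SCHEMA_VERSION,
        "inputs": {str(p): _digest(p) for p in (input_paths or [])},
        "config": {"seed": run_config.seed if run_config else None},
        "converged": False,
        "stage_failure": stage_failure,
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def load_report(path) -> dict:
    """Reload a JSON fit report."""
    return json.loads(Path(path).read_text())
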