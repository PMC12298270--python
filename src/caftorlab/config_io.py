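"""Typed configuration, tabular I/O and report assembly.

The package exchanges data through two plain-text formats:

* a JSON *panel* file describing, per analyte, the quantification range
  (LLOQ/ULOQ), the calibrator and QC levels, the internal standard and the
  MRM transitions (informational), and optionally the terminal elimination
  rate constant ``beta`` used by the exposure analysis;
* a measurement CSV with the fixed header
  ``analyte,role,run_id,replicate,nominal_ug_ml,response,concentration_ug_ml,timepoint_h,dilution_factor``.

Units are fixed package-wide: µg/mL for concentrations, hours for time,
µg/mL·h for AUC.
"""

from __future__ import annotations

import json
import math
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Any, Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

__all__ = [
    "AnalyteConfig",
    "AnalytePanel",
    "Measurement",
    "ConfigurationError",
    "MeasurementParseError",
    "MEASUREMENT_COLUMNS",
    "QC_LEVEL_ROLES",
    "default_panel",
    "load_panel",
    "save_panel",
    "read_measurements",
    "write_measurements",
    "write_report",
    "round_half_up",
]

MEASUREMENT_COLUMNS = [
    "analyte",
    "role",
    "run_id",
    "replicate",
    "nominal_ug_ml",
    "response",
    "concentration_ug_ml",
    "timepoint_h",
    "dilution_factor",
]

#: Measurement roles mapped to the QC level key they refer to in the panel.
QC_LEVEL_ROLES = {"qc_low": "low", "qc_mid": "medium", "qc_high": "high"}

Role = Literal[
    "blank", "blank_is", "calibrator", "qc_low", "qc_mid", "qc_high", "lloq", "patient"
]


class ConfigurationError(ValueError):
    """A panel or measurement file violates the configuration contract."""


class MeasurementParseError(ValueError):
    """A measurement CSV row could not be parsed; the message names the row."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of printed lab tables),

    unlike Python's builtin banker's rounding.
    """
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class AnalyteConfig(BaseModel):
    """Per-analyte quantification configuration."""

    name: str
    lloq: float = Field(gt=0)
    uloq: float = Field(gt=0)
    calibrator_levels: list[float]
    qc_levels: dict[str, float]
    internal_standard: str
    mrm_quantifier: str = ""
    mrm_qualifier: str = ""
    beta: Optional[float] = Field(default=None, description="terminal elimination rate, 1/h")

    @model_validator(mode="after")
    def _check_range(self) -> "AnalyteConfig":
        if not self.lloq < self.uloq:
            raise ValueError(
                f"analyte {self.name!r}: lloq ({self.lloq}) must be < uloq ({self.uloq})"
            )
        lv = self.calibrator_levels
        if len(lv) < 2 or any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError(
                f"analyte {self.name!r}: calibrator_levels must be strictly increasing"
            )
        if lv[0] != self.lloq or lv[-1] != self.uloq:
            raise ValueError(
                f"analyte {self.name!r}: calibrator_levels must span [lloq, uloq]"
            )
        for key, c in self.qc_levels.items():
            if not (self.lloq <= c <= self.uloq):
                raise ValueError(
                    f"analyte {self.name!r}: QC level {key!r} = {c} outside "
                    f"[{self.lloq}, {self.uloq}]"
                )
        if self.beta is not None and self.beta < 0:
            raise ValueError(f"analyte {self.name!r}: beta must be >= 0")
        return self

    def qc_nominal(self, role: str) -> float:
        """Nominal concentration for a QC role (``qc_low``/``qc_mid``/``qc_high``/``lloq``)."""
        if role == "lloq":
            return self.lloq
        return self.qc_levels[QC_LEVEL_ROLES[role]]


class AnalytePanel(BaseModel):
    """The full multi-analyte assay configuration."""

    analytes: list[AnalyteConfig]

    @field_validator("analytes")
    @classmethod
    def _non_empty_unique(cls, v: list[AnalyteConfig]) -> list[AnalyteConfig]:
        if not v:
            raise ValueError("panel must contain at least one analyte")
        names = [a.name for a in v]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate analyte names: {sorted(names)}")
        return v

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.analytes]

    def get(self, name: str) -> AnalyteConfig:
        for a in self.analytes:
            if a.name == name:
                return a
        raise KeyError(f"analyte {name!r} not in panel ({self.names})")


class Measurement(BaseModel):
    """One observed response ratio or concentration with its provenance."""

    analyte: str
    role: Role
    run_id: str = "run1"
    replicate: int = 1
    nominal: Optional[float] = None
    response: Optional[float] = None
    concentration: Optional[float] = None
    timepoint_h: Optional[float] = None
    dilution_factor: float = Field(default=1.0, ge=1.0)

    @model_validator(mode="after")
    def _has_value(self) -> "Measurement":
        if self.response is None and self.concentration is None:
            raise ValueError("measurement needs at least one of response/concentration")
        return self


def default_panel() -> AnalytePanel:
    """The packaged IVA/TEZ/ELX panel (range 0.1–20 µg/mL, QCs 0.3/8/18)."""
    text = resources.files("caftorlab.data").joinpath("default_panel.json").read_text()
    return AnalytePanel.model_validate(json.loads(text))


def load_panel(path: str | Path) -> AnalytePanel:
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"panel file {path}: invalid JSON ({exc})") from exc
    try:
        return AnalytePanel.model_validate(data)
    except ValidationError as exc:
        raise ConfigurationError(f"panel file {path}: {exc}") from exc


def save_panel(panel: AnalytePanel, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(panel.model_dump(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def _opt(value: Any) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_measurements(path: str | Path, panel: AnalytePanel) -> list[Measurement]:
    """Read a measurement CSV, validating analytes and roles against the panel."""
    df = pd.read_csv(path, dtype={"analyte": str, "role": str, "run_id": str})
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise MeasurementParseError(f"{path}: missing columns {missing}")
    out: list[Measurement] = []
    known = set(panel.names)
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        if row.analyte not in known:
            raise MeasurementParseError(
                f"{path} row {i}: unknown analyte {row.analyte!r}"
            )
        try:
            out.append(
                Measurement(
                    analyte=row.analyte,
                    role=row.role,
                    run_id=str(row.run_id) if not pd.isna(row.run_id) else "run1",
                    replicate=int(row.replicate) if not pd.isna(row.replicate) else 1,
                    nominal=_opt(row.nominal_ug_ml),
                    response=_opt(row.response),
                    concentration=_opt(row.concentration_ug_ml),
                    timepoint_h=_opt(row.timepoint_h),
                    dilution_factor=(
                        float(row.dilution_factor)
                        if not pd.isna(row.dilution_factor)
                        else 1.0
                    ),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise MeasurementParseError(f"{path} row {i}: {exc}") from exc
    return out


def measurements_to_frame(measurements: list[Measurement]) -> pd.DataFrame:
    rows = [
        {
            "analyte": m.analyte,
            "role": m.role,
            "run_id": m.run_id,
            "replicate": m.replicate,
            "nominal_ug_ml": m.nominal,
            "response": m.response,
            "concentration_ug_ml": m.concentration,
            "timepoint_h": m.timepoint_h,
            "dilution_factor": m.dilution_factor,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def write_measurements(measurements: list[Measurement], path: str | Path) -> None:
    measurements_to_frame(measurements).to_csv(path, index=False)


# --------------------------------------------------------------------------
# report rendering


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, BaseModel):
        return obj.model_dump()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def _fmt_cell(v: Any) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "n.a"
    if isinstance(v, bool):
        return "pass" if v else "FAIL"
    if isinstance(v, float):
        return f"{round_half_up(v, 2):.2f}"
    return str(v)


def _markdown_table(records: list[dict]) -> str:
    if not records:
        return "_(empty)_\n"
    cols = list(records[0])
    lines = [
        "| " + " | ".join(cols) + " |",
        "| " + " | ".join("---" for _ in cols) + " |",
    ]
    for rec in records:
        lines.append("| " + " | ".join(_fmt_cell(rec.get(c)) for c in cols) + " |")
    return "\n".join(lines) + "\n"


def write_report(
    results: dict[str, Any], path: str | Path, format: Literal["json", "markdown"] = "json"
) -> None:
    """Serialize pipeline stage outputs deterministically.

    JSON keeps full numeric precision; markdown renders each section as a
    table with values rounded half-up to 2 decimals.
    """
    payload = _jsonable(results)
    if format == "json":
        text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
    elif format == "markdown":
        parts = []
        for section in sorted(payload):
            parts.append(f"## {section}\n")
            body = payload[section]
            if isinstance(body, list) and body and isinstance(body[0], dict):
                parts.append(_markdown_table(body))
            elif isinstance(body, dict):
                parts.append(_markdown_table([body]))
            else:
                parts.append(f"{_fmt_cell(body)}\n")
            parts.append("")
        text = "\n".join(parts)
    else:
        raise ValueError(f"unknown report format {format!r}")
    Path(path).write_text(text, encoding="utf-8")
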