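"""Accuracy/precision, selectivity, carry-over, matrix effect/recovery,
LLOQ qualification and stability — the core bioanalytical validation
statistics with regulatory-style acceptance verdicts.

Conventions (all configurable through :class:`Thresholds`):

* accuracy = mean %bias, precision = %CV (sample SD, n−1), both ≤15%
  (≤20% at the LLOQ);
* matrix effect acceptable in 85–115%, extraction recovery in 90–110%;
* stability acceptable in 85–115% of the time-0 measured value;
* blank/carry-over signal below 20% of the LLOQ analyte response and 5%
  of the internal-standard response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config_io import AnalyteConfig, Measurement, QC_LEVEL_ROLES

__all__ = [
    "Thresholds",
    "ValidationSummary",
    "MatrixEffectResult",
    "StabilityRecord",
    "BlankCheck",
    "LloqQualification",
    "percent_bias",
    "percent_cv",
    "accuracy_precision_tables",
    "selectivity_check",
    "carryover_check",
    "matrix_effect",
    "extraction_recovery",
    "is_normalized",
    "stability_percent",
    "stability_table",
    "lloq_qualification",
]


@dataclass(frozen=True)
class Thresholds:
    bias_cv_percent: float = 15.0
    bias_cv_percent_lloq: float = 20.0
    me_range: tuple[float, float] = (85.0, 115.0)
    er_range: tuple[float, float] = (90.0, 110.0)
    stability_range: tuple[float, float] = (85.0, 115.0)
    blank_analyte_fraction: float = 0.20
    blank_is_fraction: float = 0.05


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class ValidationSummary:
    analyte: str
    level: str
    n: int
    mean: float
    median: float
    range: tuple[float, float]
    percent_bias: float
    percent_cv: float
    scope: str  # "intra" | "inter"
    passed: bool
    run_id: Optional[str] = None


@dataclass(frozen=True)
class MatrixEffectResult:
    level: str
    per_lot: list[float]
    mean_percent: float
    cv_percent: float
    n_lots: int
    passed: bool


@dataclass(frozen=True)
class StabilityRecord:
    analyte: str
    level: str
    condition: str
    t0_value: float
    t_value: float
    elapsed_days: float
    stability_percent: float
    passed: bool


@dataclass(frozen=True)
class BlankCheck:
    analyte_fraction: float
    is_fraction: float
    analyte_pass: bool
    is_pass: bool

    @property
    def passed(self) -> bool:
        return self.analyte_pass and self.is_pass


@dataclass(frozen=True)
class LloqQualification:
    overall_bias: float
    overall_cv: float
    per_session: list[ValidationSummary]
    passed: bool
    warnings: list[str] = field(default_factory=list)


def percent_bias(values: Iterable[float], nominal: float) -> float:
    """Mean accuracy error: 100·(mean − nominal)/nominal."""
    values = list(values)
    if nominal <= 0:
        raise ValueError("nominal must be > 0")
    if not values:
        raise ValueError("no values")
    return 100.0 * (float(np.mean(values)) - nominal) / nominal


def percent_cv(values: Iterable[float]) -> float:
    """Coefficient of variation: 100·SD(n−1)/mean."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs >= 2 values")
    mean = float(arr.mean())
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * float(arr.std(ddof=1)) / mean


def _tolerance(level: str, thresholds: Thresholds) -> float:
    return (
        thresholds.bias_cv_percent_lloq
        if level == "lloq"
        else thresholds.bias_cv_percent
    )


def _summarize(
    analyte: str,
    level: str,
    values: np.ndarray,
    nominal: float,
    scope: str,
    thresholds: Thresholds,
    run_id: Optional[str] = None,
) -> ValidationSummary:
    bias = percent_bias(values, nominal)
    cv = percent_cv(values) if values.size >= 2 else 0.0
    tol = _tolerance(level, thresholds)
    return ValidationSummary(
        analyte=analyte,
        level=level,
        n=int(values.size),
        mean=float(np.mean(values)),
        median=float(np.median(values)),
        range=(float(np.min(values)), float(np.max(values))),
        percent_bias=bias,
        percent_cv=cv,
        scope=scope,
        passed=abs(bias) <= tol and cv <= tol,
        run_id=run_id,
    )


def accuracy_precision_tables(
    qc: Sequence[Measurement],
    panel: AnalyteConfig,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[ValidationSummary]:
    """Intra- and inter-run accuracy/precision per (analyte, QC level).

    Intra-run statistics are computed within each run; the reported intra row
    is the worst run (largest of |bias| and CV), which is the conservative
    reading of per-run tables. Inter-run statistics are computed on the run
    means. Measurements must carry ``concentration`` and a ``run_id``.
    """
    rows = [
        m
        for m in qc
        if m.role in ("lloq", *QC_LEVEL_ROLES) and m.concentration is not None
    ]
    if any(not m.run_id for m in rows):
        raise ValueError("QC measurements must carry run_id labels")
    out: list[ValidationSummary] = []
    df = pd.DataFrame(
        {
            "analyte": [m.analyte for m in rows],
            "level": [m.role for m in rows],
            "run": [m.run_id for m in rows],
            "value": [m.concentration for m in rows],
            "nominal": [
                m.nominal if m.nominal is not None else panel.qc_nominal(m.role)
                for m in rows
            ],
        }
    )
    for (analyte, level), grp in df.groupby(["analyte", "level"], sort=True):
        nominal = float(grp["nominal"].iloc[0])
        per_run = [
            _summarize(
                analyte, level, g["value"].to_numpy(), nominal, "intra", thresholds, r
            )
            for r, g in grp.groupby("run", sort=True)
        ]
        worst = max(per_run, key=lambda s: max(abs(s.percent_bias), s.percent_cv))
        out.append(worst)
        run_means = grp.groupby("run", sort=True)["value"].mean().to_numpy()
        out.append(_summarize(analyte, level, run_means, nominal, "inter", thresholds))
    return out


def _blank_check(
    blank_values: Sequence[float],
    lloq_response: float,
    is_response: float,
    blank_is_values: Sequence[float],
    thresholds: Thresholds,
) -> BlankCheck:
    if lloq_response <= 0 or is_response <= 0:
        raise ValueError("reference responses must be > 0")
    if not blank_values:
        raise ValueError("no blank responses")
    frac_an = float(np.median(blank_values)) / lloq_response
    frac_is = (
        float(np.median(blank_is_values)) / is_response if blank_is_values else 0.0
    )
    return BlankCheck(
        analyte_fraction=frac_an,
        is_fraction=frac_is,
        analyte_pass=frac_an < thresholds.blank_analyte_fraction,
        is_pass=frac_is < thresholds.blank_is_fraction,
    )


def selectivity_check(
    blank_responses: Sequence[float],
    lloq_response: float,
    is_response_in_lloq: float,
    blank_is_responses: Sequence[float],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> BlankCheck:
    """Endogenous interference: median blank signal below 20% of the LLOQ
    response and 5% of the internal-standard response."""
    return _blank_check(
        blank_responses, lloq_response, is_response_in_lloq, blank_is_responses, thresholds
    )


def carryover_check(
    post_uloq_blanks: Sequence[float],
    lloq_response: float,
    is_response: float,
    blank_is_responses: Sequence[float] = (),
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> BlankCheck:
    """Residual signal in blanks injected after the highest calibrator,
    judged with the same 20%/5% thresholds as selectivity."""
    return _blank_check(
        post_uloq_blanks, lloq_response, is_response, blank_is_responses, thresholds
    )


def matrix_effect(
    areas: Sequence[tuple[float, float]],
    level: str = "",
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> MatrixEffectResult:
    """Per-lot matrix effect 100·B/A (post-extraction spike over neat)."""
    per_lot = []
    for a, b in areas:
        if a <= 0:
            raise ValueError("neat area A must be > 0")
        per_lot.append(100.0 * b / a)
    mean = float(np.mean(per_lot))
    cv = percent_cv(per_lot) if len(per_lot) >= 2 else 0.0
    lo, hi = thresholds.me_range
    return MatrixEffectResult(
        level=level,
        per_lot=per_lot,
        mean_percent=mean,
        cv_percent=cv,
        n_lots=len(per_lot),
        passed=lo <= mean <= hi,
    )


def extraction_recovery(
    areas: Sequence[tuple[float, float]],
    level: str = "",
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> MatrixEffectResult:
    """Per-lot extraction recovery 100·C/B (pre- over post-extraction spike)."""
    per_lot = []
    for b, c in areas:
        if b <= 0:
            raise ValueError("post-extraction area B must be > 0")
        per_lot.append(100.0 * c / b)
    mean = float(np.mean(per_lot))
    cv = percent_cv(per_lot) if len(per_lot) >= 2 else 0.0
    lo, hi = thresholds.er_range
    return MatrixEffectResult(
        level=level,
        per_lot=per_lot,
        mean_percent=mean,
        cv_percent=cv,
        n_lots=len(per_lot),
        passed=lo <= mean <= hi,
    )


def is_normalized(me_analyte: float, me_is: float) -> float:
    """Matrix effect normalized to the deuterated internal standard."""
    if me_is <= 0:
        raise ValueError("IS matrix effect must be > 0")
    return 100.0 * me_analyte / me_is


def stability_percent(t_value: float, t0_value: float) -> float:
    """Remaining fraction at a later timepoint: 100·C(t)/C(0).

    The denominator is the *measured* time-0 concentration, not the nominal;
    that is the ratio printed in autosampler-stability tables.
    """
    if t0_value <= 0:
        raise ValueError("time-0 value must be > 0")
    return 100.0 * t_value / t0_value


def stability_table(
    series: pd.DataFrame,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[StabilityRecord]:
    """Stability records from a long table with columns
    ``analyte, level, condition, timepoint_days, value``.

    Each (analyte, level, condition) group needs a timepoint-0 row; every
    later timepoint yields one record.
    """
    required = {"analyte", "level", "condition", "timepoint_days", "value"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"stability table missing columns {sorted(missing)}")
    lo, hi = thresholds.stability_range
    records: list[StabilityRecord] = []
    for (analyte, level, cond), grp in series.groupby(
        ["analyte", "level", "condition"], sort=True
    ):
        grp = grp.sort_values("timepoint_days")
        t0_rows = grp[grp["timepoint_days"] == 0]
        if t0_rows.empty:
            raise ValueError(
                f"no time-0 entry for ({analyte}, {level}, {cond})"
            )
        t0 = float(t0_rows["value"].iloc[0])
        for _, row in grp[grp["timepoint_days"] > 0].iterrows():
            pct = stability_percent(float(row["value"]), t0)
            records.append(
                StabilityRecord(
                    analyte=analyte,
                    level=level,
                    condition=cond,
                    t0_value=t0,
                    t_value=float(row["value"]),
                    elapsed_days=float(row["timepoint_days"]),
                    stability_percent=pct,
                    passed=lo <= pct <= hi,
                )
            )
    return records


def lloq_qualification(
    replicates: Sequence[Measurement],
    nominal: float,
    tolerance: float = 20.0,
    min_sessions: int = 5,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> LloqQualification:
    """Qualify the LLOQ from replicates spread over analytical sessions.

    Passes when overall |bias| and CV are within ``tolerance`` and every
    session individually is too. Fewer sessions than ``min_sessions`` is a
    warning, not a failure.
    """
    rows = [m for m in replicates if m.concentration is not None]
    if not rows:
        raise ValueError("no LLOQ replicates with concentrations")
    values = np.array([m.concentration for m in rows])
    overall_bias = percent_bias(values, nominal)
    overall_cv = percent_cv(values) if values.size >= 2 else 0.0
    sessions: list[ValidationSummary] = []
    by_session: dict[str, list[float]] = {}
    for m in rows:
        by_session.setdefault(m.run_id, []).append(m.concentration)
    for sid in sorted(by_session):
        vals = np.array(by_session[sid])
        sessions.append(
            _summarize(rows[0].analyte, "lloq", vals, nominal, "intra", thresholds, sid)
        )
    warnings = []
    if len(by_session) < min_sessions:
        warnings.append(
            f"only {len(by_session)} sessions (expected >= {min_sessions})"
        )
    session_ok = all(
        abs(s.percent_bias) <= tolerance and s.percent_cv <= tolerance
        for s in sessions
    )
    passed = abs(overall_bias) <= tolerance and overall_cv <= tolerance and session_ok
    return LloqQualification(
        overall_bias=overall_bias,
        overall_cv=overall_cv,
        per_session=sessions,
        passed=passed,
        warnings=warnings,
    )
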