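"""Weighted linear calibration, back-calculation and sample quantification.

An LC-MS/MS calibration line relates the analyte/internal-standard peak-area
ratio *y* to the nominal concentration *x* over the quantification range.
Because the response variance of MS detectors grows with concentration,
weighted least squares with weights 1/x or 1/x² is standard practice; 1/x²
is the default here for the 200-fold 0.1–20 µg/mL range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .config_io import AnalyteConfig, Measurement

__all__ = [
    "CalibrationFit",
    "CalibratorAssessment",
    "QuantResult",
    "WeightingScheme",
    "fit_calibration",
    "back_calculate",
    "assess_calibrators",
    "max_percent_residual",
    "quantify",
]

WeightingScheme = Literal["none", "1/x", "1/x^2"]


class DegenerateDesignError(ValueError):
    """All calibrators sit at one level; the line is not identifiable."""


@dataclass(frozen=True)
class CalibrationFit:
    analyte: str
    slope: float
    intercept: float
    r_squared: float
    weighting: WeightingScheme
    n_points: int

    @property
    def usable(self) -> bool:
        return self.slope > 0


@dataclass(frozen=True)
class CalibratorAssessment:
    level: float
    back_calculated: float
    percent_bias: float
    tolerance: float
    passed: bool


@dataclass(frozen=True)
class QuantResult:
    concentration: float
    below_lloq: bool
    above_uloq: bool
    diluted: bool


def _weights(x: np.ndarray, scheme: WeightingScheme) -> np.ndarray:
    if scheme == "none":
        return np.ones_like(x)
    if scheme == "1/x":
        return 1.0 / x
    if scheme == "1/x^2":
        return 1.0 / x**2
    raise ValueError(f"unknown weighting scheme {scheme!r}")


def fit_calibration(
    standards: Sequence[Measurement], weighting: WeightingScheme = "1/x^2"
) -> CalibrationFit:
    """Fit response on nominal concentration by weighted least squares.

    ``r_squared`` is computed on the weighted fit: 1 − Σw·e²/Σw·(y−ȳ_w)²
    with the weighted mean ȳ_w.
    """
    pts = [m for m in standards if m.response is not None and m.nominal is not None]
    if len({m.analyte for m in pts}) > 1:
        raise ValueError("standards mix analytes; fit one analyte at a time")
    x = np.array([m.nominal for m in pts], dtype=float)
    y = np.array([m.response for m in pts], dtype=float)
    if len(np.unique(x)) < 2:
        raise DegenerateDesignError("need responses at >=2 distinct levels")
    w = _weights(x, weighting)
    slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
    resid = y - (slope * x + intercept)
    y_wmean = np.average(y, weights=w)
    ss_tot = float(np.sum(w * (y - y_wmean) ** 2))
    ss_res = float(np.sum(w * resid**2))
    r_squared = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return CalibrationFit(
        analyte=pts[0].analyte,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(min(r_squared, 1.0)),
        weighting=weighting,
        n_points=len(pts),
    )


def back_calculate(fit: CalibrationFit, response: float) -> float:
    """Invert the line: (response − intercept)/slope.

    May be negative for sub-blank responses; callers flag, not clip.
    """
    if fit.slope <= 0:
        raise ValueError(f"calibration slope must be > 0 (got {fit.slope})")
    return (response - fit.intercept) / fit.slope


def assess_calibrators(
    fit: CalibrationFit,
    standards: Sequence[Measurement],
    lloq: float,
    tolerance: float = 15.0,
    lloq_tolerance: float = 20.0,
    min_levels: int = 6,
    min_pass_fraction: float = 0.75,
) -> tuple[list[CalibratorAssessment], bool]:
    """Back-calculate every calibrator and judge the curve.

    Per-point tolerance is ±15% (±20% at the LLOQ).  The curve passes when at
    least ``min_pass_fraction`` of the calibrators pass and the passing points
    cover at least ``min_levels`` distinct levels (the usual regulatory rule).
    """
    assessments: list[CalibratorAssessment] = []
    for m in standards:
        if m.response is None or m.nominal is None:
            continue
        bc = back_calculate(fit, m.response)
        bias = 100.0 * (bc - m.nominal) / m.nominal
        tol = lloq_tolerance if np.isclose(m.nominal, lloq) else tolerance
        assessments.append(
            CalibratorAssessment(
                level=m.nominal,
                back_calculated=bc,
                percent_bias=bias,
                tolerance=tol,
                passed=abs(bias) <= tol,
            )
        )
    n_pass = sum(a.passed for a in assessments)
    passing_levels = {a.level for a in assessments if a.passed}
    curve_pass = (
        bool(assessments)
        and n_pass / len(assessments) >= min_pass_fraction
        and len(passing_levels) >= min_levels
    )
    return assessments, curve_pass


def max_percent_residual(
    fit: CalibrationFit, standards: Sequence[Measurement]
) -> float:
    """The back-calculation %bias of largest magnitude, sign preserved."""
    assessments, _ = assess_calibrators(fit, standards, lloq=-np.inf, min_levels=0)
    if not assessments:
        raise ValueError("no assessable standards")
    return max((a.percent_bias for a in assessments), key=abs)


def quantify(
    fit: CalibrationFit, sample: Measurement, panel: AnalyteConfig
) -> QuantResult:
    """Quantify an unknown, applying its dilution factor and range flags.

    ``above_uloq`` refers to the *pre-dilution* estimate: a sample measured
    within range after dilution still reports a valid (diluted) result.
    """
    if sample.response is None:
        raise ValueError("sample has no response to quantify")
    raw = back_calculate(fit, sample.response)
    conc = raw * sample.dilution_factor
    return QuantResult(
        concentration=conc,
        below_lloq=raw < panel.lloq,
        above_uloq=raw > panel.uloq,
        diluted=sample.dilution_factor > 1.0,
    )
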