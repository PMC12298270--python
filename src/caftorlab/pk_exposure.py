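"""Limited-sampling pharmacokinetic exposure analysis.

With steady-state samples at T0 (pre-dose, C_trough) and T4 (4 h post-dose,
taken as C_max for ivacaftor), the 12 h concentration is extrapolated from
the terminal elimination rate β,

    C12 = C4 · exp(−β · (t12 − t4)),

the AUC over one dosing interval is computed by the trapezoidal rule on the
three points (0, C0), (4, C4), (12, C12), and AUC0–24h = 2·AUC0–12h for a
q12h regimen. Cohort-level exposure is then summarized by the trough–AUC
regression (OLS line, Spearman rank correlation with a Fisher-z confidence
interval, residual %CV), which supports back-calculating a trough
concentration from an AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config_io import AnalytePanel

__all__ = [
    "ExposureRecord",
    "ExposureRegression",
    "extrapolate_c12",
    "auc_0_12",
    "exposure_from_samples",
    "fit_exposure_regression",
    "back_calc_ctrough",
    "cohort_summary",
]

AucMethod = Literal["linear", "linear_up_log_down"]


@dataclass(frozen=True)
class ExposureRecord:
    patient_id: str
    analyte: str
    c_trough: float
    c4: float
    beta: float
    c12: float
    auc_0_12: float
    auc_0_24: float
    log_down_fallback: bool = False


@dataclass(frozen=True)
class ExposureRegression:
    slope: float
    intercept: float
    slope_stderr: float
    r_squared: float
    spearman_r: float
    spearman_ci: tuple[float, float]
    residual_cv_mean: float
    residual_cv_sd: float
    n: int


def extrapolate_c12(c4: float, beta: float, t4: float = 4.0, t12: float = 12.0) -> float:
    """Mono-exponential extrapolation C4·e^(−β·(t12−t4))."""
    if beta < 0:
        raise ValueError("beta must be >= 0 (no accumulation extrapolation)")
    if t12 <= t4:
        raise ValueError("t12 must exceed t4")
    return c4 * math.exp(-beta * (t12 - t4))


def auc_0_12(
    c_trough: float,
    c4: float,
    c12: float,
    method: AucMethod = "linear",
) -> tuple[float, bool]:
    """AUC over one 12 h interval from the (0, 4, 12) h samples.

    ``linear`` applies the trapezoidal rule on both segments. The
    ``linear_up_log_down`` variant uses the logarithmic trapezoid on the
    declining 4→12 h segment when c4 > c12 > 0, falling back to linear
    (flagged in the second return value) when the log rule is undefined.
    """
    if min(c_trough, c4, c12) < 0:
        raise ValueError("concentrations must be non-negative")
    seg1 = 0.5 * (c_trough + c4) * 4.0
    fallback = False
    if method == "linear":
        seg2 = 0.5 * (c4 + c12) * 8.0
    elif method == "linear_up_log_down":
        if c4 > c12 > 0:
            seg2 = 8.0 * (c4 - c12) / math.log(c4 / c12)
        else:
            seg2 = 0.5 * (c4 + c12) * 8.0
            fallback = True
    else:
        raise ValueError(f"unknown AUC method {method!r}")
    return seg1 + seg2, fallback


def exposure_from_samples(
    samples: pd.DataFrame,
    panel: Optional[AnalytePanel] = None,
    beta: Optional[float] = None,
    method: AucMethod = "linear",
    analyte: str = "IVA",
) -> list[ExposureRecord]:
    """Build per-patient exposure records from a long table of T0/T4 samples.

    ``samples`` needs columns ``patient_id, analyte, timepoint_h,
    concentration_ug_ml``. β is taken from the ``beta`` argument when given,
    else from the panel configuration for the analyte. Patients missing
    either timepoint are skipped.
    """
    if beta is None:
        if panel is None:
            raise ValueError("provide beta or a panel carrying it")
        beta = panel.get(analyte).beta
        if beta is None:
            raise ValueError(f"panel has no beta for analyte {analyte!r}")
    sub = samples[samples["analyte"] == analyte]
    records: list[ExposureRecord] = []
    for pid, grp in sub.groupby("patient_id", sort=True):
        by_t = {float(r.timepoint_h): float(r.concentration_ug_ml) for r in grp.itertuples()}
        if 0.0 not in by_t or 4.0 not in by_t:
            continue  # missing timepoint: skip this patient
        c0, c4 = by_t[0.0], by_t[4.0]
        c12 = extrapolate_c12(c4, beta)
        auc12, fb = auc_0_12(c0, c4, c12, method=method)
        records.append(
            ExposureRecord(
                patient_id=str(pid),
                analyte=analyte,
                c_trough=c0,
                c4=c4,
                beta=beta,
                c12=c12,
                auc_0_12=auc12,
                auc_0_24=2.0 * auc12,
                log_down_fallback=fb,
            )
        )
    return records


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1.0:
        return (r, r)
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    zc = stats.norm.ppf(0.5 + level / 2.0)
    return (math.tanh(z - zc * se), math.tanh(z + zc * se))


def fit_exposure_regression(
    pairs: Sequence[tuple[float, float]],
) -> ExposureRegression:
    """Regress AUC0–24h on C_trough across the cohort.

    OLS gives the line and R²; the Spearman rank correlation (average ranks
    for ties) with a Fisher-z 95% CI quantifies monotone agreement; residual
    %CV per patient is 100·(measured − predicted)/predicted, reported as
    mean ± SD.
    """
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 pairs")
    if np.allclose(x, x[0]):
        raise ValueError("constant trough values: regression degenerate")
    res = stats.linregress(x, y)
    rho = stats.spearmanr(x, y).statistic
    pred = res.slope * x + res.intercept
    with np.errstate(divide="ignore", invalid="ignore"):
        resid_cv = 100.0 * (y - pred) / pred
    resid_cv = resid_cv[np.isfinite(resid_cv)]
    return ExposureRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_stderr=float(res.stderr),
        r_squared=float(res.rvalue**2),
        spearman_r=float(rho),
        spearman_ci=_fisher_ci(float(rho), x.size),
        residual_cv_mean=float(resid_cv.mean()) if resid_cv.size else 0.0,
        residual_cv_sd=float(resid_cv.std(ddof=1)) if resid_cv.size > 1 else 0.0,
        n=int(x.size),
    )


def back_calc_ctrough(auc_0_24: float, regression: ExposureRegression) -> float:
    """Invert the cohort regression to predict a trough from an AUC."""
    if regression.slope == 0:
        raise ValueError("regression slope is zero")
    return (auc_0_24 - regression.intercept) / regression.slope


def cohort_summary(records: Sequence[ExposureRecord]) -> pd.DataFrame:
    """Median and 25th/75th percentiles (linear interpolation) per analyte
    for C_trough, C4 and AUC0–12h; AUC columns are NaN ("n.a") for analytes
    whose records carry no usable β-based AUC."""
    if not records:
        raise ValueError("empty cohort")
    rows = []
    df = pd.DataFrame(
        {
            "analyte": [r.analyte for r in records],
            "c_trough": [r.c_trough for r in records],
            "c4": [r.c4 for r in records],
            "auc_0_12": [r.auc_0_12 for r in records],
        }
    )
    for analyte, grp in df.groupby("analyte", sort=True):
        row: dict = {"analyte": analyte, "n": len(grp)}
        for field in ("c_trough", "c4", "auc_0_12"):
            vals = grp[field].to_numpy(dtype=float)
            if np.all(np.isnan(vals)):
                q25 = med = q75 = float("nan")
            else:
                q25, med, q75 = np.percentile(vals, [25, 50, 75])
            row[f"{field}_p25"] = float(q25)
            row[f"{field}_median"] = float(med)
            row[f"{field}_p75"] = float(q75)
        rows.append(row)
    return pd.DataFrame(rows)
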