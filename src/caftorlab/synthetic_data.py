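"""Synthetic instrument and cohort data with known ground truth.

Every input the validation and exposure pipeline consumes can be generated
here, so each downstream estimator is testable against the parameters that
produced its data:

* calibration/QC response ratios: straight line through the origin-offset
  response model with multiplicative lognormal noise (heteroscedastic —
  the variance grows with level, as LC-MS/MS response ratios do);
* matrix-effect / extraction-recovery peak-area triplets (A neat, B
  post-extraction spike, C pre-extraction spike) with per-lot factors;
* first-order degradation series for stability studies;
* exponentially modified Gaussian (EMG) chromatographic traces, whose tail
  constant gives asymmetry metrics a tunable truth (τ = 0 is a pure
  Gaussian);
* a steady-state one-compartment oral-absorption PK cohort dosed q12h,
  sampled at T0/T4, carrying each patient's true parameters and true AUCτ.

All noise is mean-one lognormal: a fractional CV ``cv`` maps to
σ² = ln(1 + cv²) and the factor exp(N(−σ²/2, σ²)), so zero CV gives exactly
1 and generated quantities stay strictly positive.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import erfcx

from .config_io import AnalyteConfig, Measurement

__all__ = [
    "ResponseTruth",
    "MatrixTruth",
    "StabilityTruth",
    "PKTruth",
    "PeakTruth",
    "lognormal_factors",
    "generate_calibration_run",
    "generate_qc_runs",
    "generate_stability_series",
    "generate_me_er_experiment",
    "generate_peak_trace",
    "steady_state_concentration",
    "generate_pk_cohort",
]


def lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative noise factors with fractional CV ``cv``."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return np.ones(size)
    s2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-0.5 * s2, sigma=math.sqrt(s2), size=size)


class ResponseTruth(BaseModel):
    """True linear response of an analyte: response = slope·c + intercept."""

    slope: float = Field(gt=0)
    intercept: float = 0.0
    noise_cv: float = Field(default=0.0, ge=0)
    seed: int = 0


class MatrixTruth(BaseModel):
    """True per-lot matrix-effect (B/A) and recovery (C/B) factors."""

    me_factor: float = Field(gt=0, le=1.5)
    er_factor: float = Field(gt=0, le=1.5)
    n_lots: int = Field(default=6, ge=1)


class StabilityTruth(BaseModel):
    """First-order degradation: measured(t) = base·e^(−k·t)."""

    k_decay: float = Field(ge=0, description="per day")
    timepoints_days: list[float]

    @model_validator(mode="after")
    def _starts_at_zero(self) -> "StabilityTruth":
        if not self.timepoints_days or self.timepoints_days[0] != 0:
            raise ValueError("timepoints must start at 0")
        return self


class PKTruth(BaseModel):
    """Steady-state one-compartment oral PK regimen, dosed every ``tau`` h.

    Defaults emulate an ivacaftor-like regimen in a pediatric cohort:
    150 mg q12h, absorption ka = 0.5 /h (steady-state Tmax near 4 h),
    elimination ke = 0.0866 /h (8 h half-life), V/F = 150 L, 40%
    between-patient lognormal variability, n = 25.
    """

    dose_morning: float = Field(default=150.0, gt=0, description="mg")
    dose_evening: float = Field(default=150.0, gt=0, description="mg")
    ka: float = Field(default=0.5, gt=0, description="1/h")
    ke: float = Field(default=0.0866, gt=0, description="1/h (terminal beta)")
    v_over_f: float = Field(default=150.0, gt=0, description="L")
    tau: float = Field(default=12.0, gt=0, description="h")
    iiv_cv: float = Field(default=0.4, ge=0)
    n_patients: int = Field(default=25, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _ka_ne_ke(self) -> "PKTruth":
        if self.ka == self.ke:
            raise ValueError("ka must differ from ke (flip-flop singularity)")
        return self


class PeakTruth(BaseModel):
    """EMG peak shape: Gaussian core σ convolved with exponential tail τ."""

    retention_time: float = Field(gt=0, description="min")
    sigma: float = Field(gt=0, description="min")
    tau_emg: float = Field(default=0.0, ge=0, description="min (0 = Gaussian)")
    height: float = Field(default=1.0, gt=0)
    dead_time: float = Field(default=0.5, gt=0, description="min")
    grid_step: float = Field(default=0.001, gt=0, description="min")


# --------------------------------------------------------------------------
# calibration / QC responses


def generate_calibration_run(
    truth: ResponseTruth,
    panel: AnalyteConfig,
    replicates: int = 1,
    seed: Optional[int] = None,
) -> list[Measurement]:
    """Calibrator responses at each panel level with multiplicative noise."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    out: list[Measurement] = []
    for level in panel.calibrator_levels:
        eps = lognormal_factors(rng, truth.noise_cv, replicates)
        for rep in range(replicates):
            out.append(
                Measurement(
                    analyte=panel.name,
                    role="calibrator",
                    run_id="cal",
                    replicate=rep + 1,
                    nominal=level,
                    response=(truth.slope * level + truth.intercept) * eps[rep],
                )
            )
    return out


def generate_qc_runs(
    truth: ResponseTruth,
    panel: AnalyteConfig,
    runs: int = 10,
    replicates_per_run: int = 3,
    between_run_cv: float = 0.0,
    seed: Optional[int] = None,
) -> list[Measurement]:
    """QC responses with a shared per-run lognormal factor (inter-run
    component) on top of within-run noise, at LLOQ and L/M/H levels."""
    if runs < 1:
        raise ValueError("runs must be >= 1")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    levels = {
        "lloq": panel.lloq,
        "qc_low": panel.qc_levels["low"],
        "qc_mid": panel.qc_levels["medium"],
        "qc_high": panel.qc_levels["high"],
    }
    out: list[Measurement] = []
    for r in range(runs):
        run_factor = lognormal_factors(rng, between_run_cv, 1)[0]
        for role, level in levels.items():
            eps = lognormal_factors(rng, truth.noise_cv, replicates_per_run)
            for rep in range(replicates_per_run):
                out.append(
                    Measurement(
                        analyte=panel.name,
                        role=role,  # type: ignore[arg-type]
                        run_id=f"run{r + 1:02d}",
                        replicate=rep + 1,
                        nominal=level,
                        response=(truth.slope * level + truth.intercept)
                        * run_factor
                        * eps[rep],
                    )
                )
    return out


# --------------------------------------------------------------------------
# stability, matrix effect


def generate_stability_series(
    truth: StabilityTruth,
    base_concentrations: dict[str, float],
    noise_cv: float = 0.0,
    seed: int = 0,
    analyte: str = "IVA",
    condition: str = "autosampler_rt",
) -> pd.DataFrame:
    """Long stability table: measured(t) = base·e^(−k·t)·ε per QC level."""
    if any(c <= 0 for c in base_concentrations.values()):
        raise ValueError("base concentrations must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for level, base in base_concentrations.items():
        eps = lognormal_factors(rng, noise_cv, len(truth.timepoints_days))
        for t, e in zip(truth.timepoints_days, eps):
            rows.append(
                {
                    "analyte": analyte,
                    "level": level,
                    "condition": condition,
                    "timepoint_days": t,
                    "value": base * math.exp(-truth.k_decay * t) * e,
                }
            )
    return pd.DataFrame(rows)


def generate_me_er_experiment(
    truth: MatrixTruth,
    level: float,
    neat_area: float,
    seed: int = 0,
    noise_cv: float = 0.0,
) -> pd.DataFrame:
    """Peak-area triplets per matrix lot.

    A = neat solution, B = blank-extract spiked post-extraction
    (B/A = matrix effect), C = matrix spiked pre-extraction
    (C/B = extraction recovery). Noise applies per measured area.
    """
    if neat_area <= 0:
        raise ValueError("neat_area must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for lot in range(truth.n_lots):
        ea, eb, ec = lognormal_factors(rng, noise_cv, 3)
        a = neat_area * ea
        b = a * truth.me_factor * eb
        c = b * truth.er_factor * ec
        rows.append(
            {"lot": lot + 1, "level": level, "area_A": a, "area_B": b, "area_C": c}
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# chromatographic trace


def generate_peak_trace(truth: PeakTruth) -> tuple[np.ndarray, np.ndarray]:
    """Sampled EMG trace on a grid covering ±6σ + 6τ around the apex.

    Uses the scaled-complementary-error-function form of the EMG, which is
    numerically stable for small τ/σ; τ = 0 degenerates to a pure Gaussian.
    The trace is normalized so its maximum equals ``height``.
    """
    if truth.grid_step > truth.sigma / 10:
        raise ValueError("grid_step too coarse: must be <= sigma/10")
    half = 6.0 * truth.sigma + 6.0 * truth.tau_emg
    t = np.arange(
        truth.retention_time - half, truth.retention_time + half, truth.grid_step
    )
    z = (t - truth.retention_time) / truth.sigma
    if truth.tau_emg == 0:
        y = np.exp(-0.5 * z * z)
    else:
        r = truth.sigma / truth.tau_emg
        y = (
            r
            * math.sqrt(math.pi / 2.0)
            * np.exp(-0.5 * z * z)
            * erfcx((r - z) / math.sqrt(2.0))
        )
    y = truth.height * y / y.max()
    return t, y


# --------------------------------------------------------------------------
# PK cohort


def _one_train(t: np.ndarray, dose: float, ka: float, ke: float, v_over_f: float, tau: float) -> np.ndarray:
    """Steady-state concentration of a single repeated-dose train (dose mg,
    volume L → µg/mL via mg/L ≡ µg/mL)."""
    coef = dose * ka / (v_over_f * (ka - ke))
    return coef * (
        np.exp(-ke * t) / (1.0 - math.exp(-ke * tau))
        - np.exp(-ka * t) / (1.0 - math.exp(-ka * tau))
    )


def steady_state_concentration(
    t: np.ndarray | float,
    dose_morning: float,
    ka: float,
    ke: float,
    v_over_f: float,
    tau: float = 12.0,
    dose_evening: Optional[float] = None,
) -> np.ndarray:
    """Steady-state plasma concentration at time ``t`` (h) after the morning
    dose.

    Equal morning/evening doses use the standard τ-periodic superposition
    formula. Unequal doses are handled as two interleaved 2τ-periodic dose
    trains offset by τ.
    """
    t = np.asarray(t, dtype=float)
    if ka == ke:
        raise ValueError("ka must differ from ke")
    if dose_evening is None or dose_evening == dose_morning:
        return _one_train(t % tau, dose_morning, ka, ke, v_over_f, tau)
    period = 2.0 * tau
    tm = t % period
    te = (t - tau) % period
    return _one_train(tm, dose_morning, ka, ke, v_over_f, period) + _one_train(
        te, dose_evening, ka, ke, v_over_f, period
    )


def generate_pk_cohort(
    truth: PKTruth,
    sampling_times_h: Sequence[float] = (0.0, 4.0),
    assay_cv: float = 0.0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate a steady-state cohort sampled at the given times.

    Per-patient ka, ke and V/F are lognormal deviates around the population
    values with CV ``iiv_cv``; optional ``assay_cv`` adds measurement noise
    to the sampled concentrations. The returned wide table carries one row
    per patient with columns ``c_{t}h`` for each sampling time plus the true
    parameters (``true_ka``, ``true_ke``, ``true_v_over_f``) and the true
    steady-state exposure ``true_auc_tau`` = dose/(V/F·ke).
    """
    if any(t < 0 or t > truth.tau for t in sampling_times_h):
        raise ValueError("sampling times must lie within [0, tau]")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n = truth.n_patients
    ka = truth.ka * lognormal_factors(rng, truth.iiv_cv, n)
    ke = truth.ke * lognormal_factors(rng, truth.iiv_cv, n)
    vf = truth.v_over_f * lognormal_factors(rng, truth.iiv_cv, n)
    rows = []
    for i in range(n):
        if ka[i] == ke[i]:  # measure-zero, but keep the formula safe
            ke[i] *= 1.0 + 1e-9
        row: dict = {
            "patient_id": f"P{i + 1:03d}",
            "true_ka": ka[i],
            "true_ke": ke[i],
            "true_v_over_f": vf[i],
            "true_auc_tau": truth.dose_morning / (vf[i] * ke[i]),
        }
        for t in sampling_times_h:
            c = float(
                steady_state_concentration(
                    t, truth.dose_morning, ka[i], ke[i], vf[i], truth.tau,
                    dose_evening=truth.dose_evening,
                )
            )
            c *= float(lognormal_factors(rng, assay_cv, 1)[0])
            row[f"c_{t:g}h"] = c
        rows.append(row)
    return pd.DataFrame(rows)
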