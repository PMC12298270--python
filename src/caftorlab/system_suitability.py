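"""USP-style system-suitability metrics from chromatographic peaks.

Given a sampled trace (or pre-measured peak geometry), compute:

* capacity factor k′ = (tR − t0)/t0, retention relative to the column dead
  time t0;
* resolution Rs = 2·ΔtR/(w1 + w2) with baseline widths (4σ-equivalent,
  derived from the width at half height for Gaussian-like peaks);
* asymmetry factor As = b/a from the leading (a) and trailing (b)
  half-widths at 10% height;
* tailing factor T = W05/(2·f) at 5% height (USP <621>).

A symmetric Gaussian peak gives As = T = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PeakGeometry",
    "SuitabilityAcceptance",
    "SuitabilityMetrics",
    "GAUSSIAN_FWHM_FACTOR",
    "measure_peak",
    "capacity_factor",
    "resolution",
    "tailing_factor",
    "asymmetry_factor",
    "suitability_report",
]

#: FWHM of a unit-σ Gaussian: 2·sqrt(2 ln 2)
GAUSSIAN_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class PeakGeometry:
    """Retention time and widths/half-widths at fixed height fractions (min)."""

    retention_time: float
    width_50: float
    a_10: float
    b_10: float
    w_05: float
    f_05: float
    height: float

    def __post_init__(self) -> None:
        for name in ("width_50", "a_10", "b_10", "w_05", "f_05"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.a_10 + self.b_10 > self.w_05 * (1 + 1e-9):
            raise ValueError("width at 10% height exceeds width at 5% height")
        if self.f_05 > self.w_05:
            raise ValueError("leading half-width exceeds full width at 5%")


@dataclass(frozen=True)
class SuitabilityAcceptance:
    rs_min: float = 2.0
    as_range: tuple[float, float] = (0.8, 1.5)
    tailing_max: float = 2.0
    k_prime_range: tuple[float, float] = (1.0, 10.0)


@dataclass(frozen=True)
class SuitabilityMetrics:
    analyte: str
    k_prime: float
    rs_to_previous: Optional[float]
    as_factor: float
    tailing: float
    k_prime_pass: bool
    rs_pass: Optional[bool]
    as_pass: bool
    tailing_pass: bool


def _cross_time(t: np.ndarray, y: np.ndarray, i: int, level: float) -> float:
    """Linear interpolation of the time where y crosses `level` between i and i+1."""
    y0, y1 = y[i], y[i + 1]
    return float(t[i] + (level - y0) * (t[i + 1] - t[i]) / (y1 - y0))


def _crossings(t: np.ndarray, y: np.ndarray, apex_idx: int, level: float) -> tuple[float, float]:
    left = None
    for i in range(apex_idx, 0, -1):
        if y[i - 1] <= level <= y[i]:
            left = _cross_time(t, y, i - 1, level)
            break
    right = None
    for i in range(apex_idx, len(y) - 1):
        if y[i] >= level >= y[i + 1]:
            right = _cross_time(t, y, i, level)
            break
    if left is None or right is None:
        raise ValueError(f"trace does not cross {level:g} on both sides of the apex")
    return left, right


def measure_peak(
    time: Sequence[float], intensity: Sequence[float], baseline: float = 0.0
) -> PeakGeometry:
    """Measure a single dominant peak on a densely sampled trace.

    The apex is located by parabolic interpolation of the three samples
    around the maximum; crossing times at 50/10/5% of the apex height are
    found by linear interpolation between samples.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(intensity, dtype=float) - baseline
    if t.ndim != 1 or t.shape != y.shape or t.size < 5:
        raise ValueError("need matching 1-D time/intensity arrays (>=5 samples)")
    i = int(np.argmax(y))
    if i in (0, len(y) - 1):
        raise ValueError("peak apex at the edge of the trace")
    # parabola through (t[i-1..i+1], y[i-1..i+1])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        t_apex, h = float(t[i]), float(y1)
    else:
        delta = 0.5 * (y0 - y2) / denom
        t_apex = float(t[i] + delta * (t[i + 1] - t[i]))
        h = float(y1 - 0.25 * (y0 - y2) * delta)
    l50, r50 = _crossings(t, y, i, 0.50 * h)
    l10, r10 = _crossings(t, y, i, 0.10 * h)
    l05, r05 = _crossings(t, y, i, 0.05 * h)
    return PeakGeometry(
        retention_time=t_apex,
        width_50=r50 - l50,
        a_10=t_apex - l10,
        b_10=r10 - t_apex,
        w_05=r05 - l05,
        f_05=t_apex - l05,
        height=h,
    )


def capacity_factor(t_r: float, dead_time: float) -> float:
    if dead_time <= 0:
        raise ValueError("dead time must be > 0")
    return (t_r - dead_time) / dead_time


def resolution(
    peak1: PeakGeometry,
    peak2: PeakGeometry,
    width_basis: str = "baseline_4sigma_from_50",
) -> float:
    """Rs = 2·(tR2 − tR1)/(w1 + w2) with baseline widths.

    Default basis converts the width at half height to a 4σ baseline width
    (w = width_50 · 4 / 2.355, exact for Gaussian peaks).
    """
    if peak2.retention_time < peak1.retention_time:
        raise ValueError("peaks must be ordered by retention time")
    if width_basis == "baseline_4sigma_from_50":
        w1 = peak1.width_50 * 4.0 / GAUSSIAN_FWHM_FACTOR
        w2 = peak2.width_50 * 4.0 / GAUSSIAN_FWHM_FACTOR
    elif width_basis == "tangent":
        # tangent baseline width approximated from the 10%-height widths
        w1 = (peak1.a_10 + peak1.b_10) / 1.28
        w2 = (peak2.a_10 + peak2.b_10) / 1.28
    else:
        raise ValueError(f"unknown width basis {width_basis!r}")
    if w1 + w2 == 0:
        raise ValueError("zero peak widths")
    return 2.0 * (peak2.retention_time - peak1.retention_time) / (w1 + w2)


def tailing_factor(geom: PeakGeometry) -> float:
    """USP tailing factor T = W05/(2·f) at 5% height."""
    if geom.f_05 <= 0:
        raise ValueError("leading half-width must be > 0")
    return geom.w_05 / (2.0 * geom.f_05)


def asymmetry_factor(geom: PeakGeometry) -> float:
    """Asymmetry As = b/a at 10% height."""
    if geom.a_10 <= 0:
        raise ValueError("leading half-width must be > 0")
    return geom.b_10 / geom.a_10


def suitability_report(
    peaks: Sequence[tuple[str, PeakGeometry]],
    dead_time: float,
    acceptance: SuitabilityAcceptance = SuitabilityAcceptance(),
) -> list[SuitabilityMetrics]:
    """Metrics plus pass flags for a sequence of peaks ordered by retention."""
    times = [g.retention_time for _, g in peaks]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("peaks must be ordered by retention time")
    out: list[SuitabilityMetrics] = []
    prev: Optional[PeakGeometry] = None
    for name, geom in peaks:
        kp = capacity_factor(geom.retention_time, dead_time)
        rs = resolution(prev, geom) if prev is not None else None
        asf = asymmetry_factor(geom)
        tf = tailing_factor(geom)
        out.append(
            SuitabilityMetrics(
                analyte=name,
                k_prime=kp,
                rs_to_previous=rs,
                as_factor=asf,
                tailing=tf,
                k_prime_pass=acceptance.k_prime_range[0] <= kp <= acceptance.k_prime_range[1],
                rs_pass=None if rs is None else rs >= acceptance.rs_min,
                as_pass=acceptance.as_range[0] <= asf <= acceptance.as_range[1],
                tailing_pass=tf <= acceptance.tailing_max,
            )
        )
        prev = geom
    return out
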