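"""Kinetic quantities from peak-area traces.

Turns per-species band-area time series into the measurement-level numbers
of the film experiment: apparent initial velocities after each gas
exchange (linear fit to the first three acquired points), titration
linearity (velocity vs pCO2 — the pseudo-first-order signature),
dehydration reaction order (log-log fit), concentration calibration
against carbonate reference samples with an exponential-saturation
pCO2–HCO3- correlation, and relative activity at a fixed evaluation time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .decomposition import KineticTrace
from .spectra_core import GasProgram
from .synthetic_data import BACKGROUND_FLOOR

__all__ = [
    "RateFit",
    "TitrationResult",
    "Calibration",
    "RelativeActivity",
    "initial_velocity",
    "velocities_from_program",
    "titration_fit",
    "dehydration_order_fit",
    "calibrate",
    "apply_calibration",
    "fit_saturation",
    "relative_activity",
]


@dataclass(frozen=True)
class RateFit:
    """Apparent initial velocity from a short linear fit (area s-1)."""

    v_app: float
    stderr: float
    r2: float
    n_points: int
    window: tuple[float, float]


@dataclass(frozen=True)
class TitrationResult:
    """Velocity-vs-pCO2 regression over a titration series."""

    pco2: np.ndarray
    velocities: np.ndarray
    slope: float            # area s-1 per % pCO2
    intercept: float
    r2: float
    slope_stderr: float
    intercept_stderr: float
    intercept_consistent_with_zero: bool


@dataclass(frozen=True)
class Calibration:
    """Area-to-concentration factor plus optional saturation parameters.

    ``factor`` converts band area to mM (area per mM, least-squares slope
    through the origin over carbonate reference samples).  ``c_max`` and
    ``p0`` parameterise the saturating pCO2 correlation
    c(p) = c_max * (1 - exp(-p / p0)), which satisfies c(0) = 0.
    """

    factor: float
    c_max: float | None = None
    p0: float | None = None

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("calibration factor must be > 0")

    def saturation(self, pco2: np.ndarray | float) -> np.ndarray:
        if self.c_max is None or self.p0 is None:
            raise ValueError("saturation parameters not fitted")
        return self.c_max * (1.0 - np.exp(-np.asarray(pco2, dtype=float) / self.p0))


@dataclass(frozen=True)
class RelativeActivity:
    """Percent of reference activity plus the unspecific background level."""

    percent: float
    background_percent: float = 100.0 * BACKGROUND_FLOOR
    t_eval: float = 60.0


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """OLS of y on t: slope, intercept, slope SE, intercept SE, r2."""
    n = t.size
    tm, ym = t.mean(), y.mean()
    sxx = np.sum((t - tm) ** 2)
    if sxx == 0:
        raise ValueError("degenerate abscissa: all points at one time")
    slope = float(np.sum((t - tm) * (y - ym)) / sxx)
    intercept = float(ym - slope * tm)
    resid = y - (intercept + slope * t)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res <= 1e-30 else (1.0 - ss_res / ss_tot if ss_tot else 0.0)
    if n > 2:
        s2 = ss_res / (n - 2)
        se_slope = math.sqrt(s2 / sxx)
        se_intercept = math.sqrt(s2 * (1.0 / n + tm**2 / sxx))
    else:
        se_slope = se_intercept = 0.0
    return slope, intercept, se_slope, se_intercept, r2


def initial_velocity(trace: KineticTrace, t_switch: float, n_points: int = 3) -> RateFit:
    """Apparent initial velocity after a gas exchange.

    Ordinary least-squares slope over the first ``n_points`` samples at or
    after ``t_switch`` — the spectroscopic initial-rate rule (the first
    three acquired spectra after the switch).  The slope is signed: positive
    for hydration (bicarbonate rise), negative for dehydration; callers
    plotting dehydration velocities use the magnitude.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    sel = trace.times >= t_switch
    t = trace.times[sel][:n_points]
    y = trace.area[sel][:n_points]
    if t.size < n_points:
        raise ValueError(
            f"only {t.size} samples at t >= {t_switch:g}s; need {n_points}"
        )
    if np.any(~np.isfinite(y)):
        raise ValueError("trace contains missing points inside the fit window")
    slope, _, se, _, r2 = _ols_line(t, y)
    return RateFit(
        v_app=slope, stderr=se, r2=r2, n_points=n_points, window=(float(t[0]), float(t[-1]))
    )


def velocities_from_program(
    trace: KineticTrace, program: GasProgram, n_points: int = 3
) -> dict[str, list[tuple[float, RateFit]]]:
    """Initial velocities at every gas exchange of a program.

    Returns ``{"hydration": [(pCO2, fit), ...], "dehydration": [...]}``;
    hydration entries are keyed by the CO2 level switched to, dehydration
    entries by the CO2 level switched away from.
    """
    hyd: list[tuple[float, RateFit]] = []
    deh: list[tuple[float, RateFit]] = []
    steps = program.steps
    for i in range(1, len(steps)):
        t_sw, level, _ = steps[i]
        fit = initial_velocity(trace, t_sw, n_points=n_points)
        if level > 0:
            hyd.append((level, fit))
        else:
            deh.append((steps[i - 1][1], fit))
    return {"hydration": hyd, "dehydration": deh}


def titration_fit(
    pco2: Sequence[float],
    velocities: Sequence[float],
    stderrs: Sequence[float] | None = None,
) -> TitrationResult:
    """Weighted linear regression of velocity on pCO2.

    Linearity (high r2, intercept consistent with zero) is the signature of
    pseudo-first-order hydration kinetics: velocity proportional to the
    dissolved CO2 concentration.  Weights are 1/stderr^2 when provided.
    """
    p = np.asarray(pco2, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if p.size != v.size:
        raise ValueError("pco2 and velocities must have equal length")
    if p.size < 3:
        raise ValueError("titration needs at least 3 pCO2 levels")
    if stderrs is not None:
        se = np.asarray(stderrs, dtype=float)
        w = np.where(se > 0, 1.0 / np.maximum(se, 1e-300) ** 2, np.nan)
        if np.any(~np.isfinite(w)):  # zero/absent errors -> unweighted
            w = np.ones_like(v)
    else:
        w = np.ones_like(v)

    sw = w.sum()
    pm = np.sum(w * p) / sw
    vm = np.sum(w * v) / sw
    sxx = np.sum(w * (p - pm) ** 2)
    if sxx == 0:
        raise ValueError("all titration levels identical")
    slope = float(np.sum(w * (p - pm) * (v - vm)) / sxx)
    intercept = float(vm - slope * pm)
    resid = v - (intercept + slope * p)
    ss_res = float(np.sum(w * resid**2))
    ss_tot = float(np.sum(w * (v - vm) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res <= 1e-30 else (1.0 - ss_res / ss_tot if ss_tot else 0.0)
    dof = p.size - 2
    s2 = ss_res / dof if dof > 0 else 0.0
    se_slope = math.sqrt(s2 / sxx)
    se_intercept = math.sqrt(s2 * (1.0 / sw + pm**2 / sxx))
    consistent = abs(intercept) <= 2.0 * se_intercept if se_intercept > 0 else intercept == 0.0
    return TitrationResult(
        pco2=p,
        velocities=v,
        slope=slope,
        intercept=intercept,
        r2=r2,
        slope_stderr=se_slope,
        intercept_stderr=se_intercept,
        intercept_consistent_with_zero=bool(consistent),
    )


def dehydration_order_fit(
    v_d: Sequence[float], bicarb_conc: Sequence[float]
) -> tuple[float, float, float]:
    """Apparent reaction order of dehydration: log|v| = log k + n log c.

    Returns (order n, rate constant k, stderr of n).  All velocities and
    concentrations must be positive and at least three points are needed.
    """
    v = np.asarray(v_d, dtype=float)
    c = np.asarray(bicarb_conc, dtype=float)
    if v.size != c.size:
        raise ValueError("v_d and bicarb_conc must have equal length")
    if v.size < 3:
        raise ValueError("order fit needs at least 3 points")
    if np.any(v <= 0) or np.any(c <= 0):
        raise ValueError("velocities and concentrations must be positive")
    slope, intercept, se, _, _ = _ols_line(np.log(c), np.log(v))
    return float(slope), float(math.exp(intercept)), float(se)


def calibrate(areas: Sequence[float], known_conc: Sequence[float]) -> Calibration:
    """Area-per-mM factor from carbonate reference samples.

    Least-squares slope through the origin of area on concentration.  The
    references must span more than a two-fold concentration range.
    """
    a = np.asarray(areas, dtype=float)
    c = np.asarray(known_conc, dtype=float)
    if a.size != c.size or a.size < 2:
        raise ValueError("need >=2 matched (area, concentration) references")
    if np.any(c <= 0):
        raise ValueError("reference concentrations must be positive")
    if c.max() / c.min() < 2.0:
        raise ValueError("reference concentrations must span a >2x range")
    factor = float(np.sum(a * c) / np.sum(c * c))
    if factor <= 0:
        raise ValueError("degenerate references: non-positive calibration factor")
    return Calibration(factor=factor)


def apply_calibration(areas: np.ndarray | Sequence[float], calibration: Calibration) -> np.ndarray:
    """Convert band areas to concentrations (mM)."""
    return np.asarray(areas, dtype=float) / calibration.factor


def fit_saturation(
    pco2: Sequence[float], conc: Sequence[float], calibration: Calibration
) -> Calibration:
    """Fit the saturating pCO2-concentration correlation c_max(1-e^{-p/p0}).

    Returns a copy of ``calibration`` with c_max (mM) and p0 (%) filled in.
    """
    p = np.asarray(pco2, dtype=float)
    c = np.asarray(conc, dtype=float)
    if p.size < 3:
        raise ValueError("saturation fit needs at least 3 pCO2 levels")

    def model(x, c_max, p0):
        return c_max * (1.0 - np.exp(-x / p0))

    guess = (float(c.max()) * 1.05 + 1e-9, float(p.mean()))
    popt, _ = curve_fit(model, p, c, p0=guess, maxfev=20000)
    return Calibration(factor=calibration.factor, c_max=float(popt[0]), p0=float(popt[1]))


def relative_activity(
    condition_trace: KineticTrace,
    reference_trace: KineticTrace,
    t_eval: float = 60.0,
    background_floor: float = BACKGROUND_FLOOR,
) -> RelativeActivity:
    """Condition activity as percent of reference at ``t_eval`` seconds.

    100 x area_condition(t_eval) / area_reference(t_eval), both linearly
    interpolated.  The unspecific-background level (default 30% of wild
    type) is reported alongside for comparison against the result.
    """
    for tr in (condition_trace, reference_trace):
        if not (tr.times[0] <= t_eval <= tr.times[-1]):
            raise ValueError(f"trace {tr.species!r} does not cover t_eval={t_eval:g}s")
    a_cond = float(np.interp(t_eval, condition_trace.times, condition_trace.area))
    a_ref = float(np.interp(t_eval, reference_trace.times, reference_trace.area))
    if a_ref <= 0:
        raise ValueError("reference area must be positive at t_eval")
    return RelativeActivity(
        percent=100.0 * a_cond / a_ref,
        background_percent=100.0 * background_floor,
        t_eval=t_eval,
    )
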