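"""Carbonate solution chemistry and the colorimetric hydration assay.

Equilibrium side: Henry's-law CO2 solubility, closed-system carbonate
speciation (CO2(aq)/HCO3-; the second acidity is neglected below pH ~9) by
bisection on the charge balance, and the bicarbonate fraction of the
CO2/HCO3- couple as a function of pH.

Kinetic side: a simulator of the classic colorimetric CO2-hydration assay
(Wilbur–Anderson): injecting CO2-saturated buffer acidifies the solution as
CO2 + 2 H2O <-> HCO3- + H3O+, bleaching a pH indicator (bromothymol blue).
Hydration/dehydration are the slow steps; all acid–base equilibria (buffer,
indicator, water) are treated as instantaneous, so the pH at any instant
follows from the charge balance at the current CO2/HCO3- partition.
Catalysis enters as a single enhancement factor F multiplying both
directions, which rescales time exactly: the activity unit
U = T_blank / T_cat - 1 then equals F - 1 in the hydration-limited regime.

Default constants (standard 25 C physical-chemistry values, not fitted):
Henry coefficient 33.8 mM/atm, pKa1(CO2/HCO3-) = 6.35, pKw = 14.0,
uncatalysed hydration rate k_uncat = 0.037 s-1, bromothymol blue pKa = 7.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "CarbonateParams",
    "Buffer",
    "Indicator",
    "AssayTrace",
    "co2_solubility",
    "solve_speciation",
    "strong_ion_for_ph",
    "bicarbonate_fraction",
    "simulate_wa_assay",
    "assay_units",
]

HENRY_K_DEFAULT = 33.8   # mM/atm
PKA1_DEFAULT = 6.35
PKW_DEFAULT = 14.0
K_UNCAT_DEFAULT = 0.037  # s-1
BTB_PKA = 7.1            # bromothymol blue


@dataclass(frozen=True)
class Buffer:
    """A monoprotic buffer (HA/A- pair): pKa and total concentration."""

    pka: float
    total_mM: float

    def __post_init__(self) -> None:
        if self.total_mM < 0:
            raise ValueError("buffer total must be >= 0")


@dataclass(frozen=True)
class Indicator:
    """A pH indicator: pKa and molar absorptivities of acid/base forms."""

    pka: float = BTB_PKA
    eps_acid: float = 0.0
    eps_base: float = 1.0
    total_mM: float = 0.05

    def base_fraction(self, ph: float | np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + 10.0 ** (self.pka - np.asarray(ph, dtype=float)))

    def absorbance(self, ph: float | np.ndarray) -> np.ndarray:
        fb = self.base_fraction(ph)
        return self.total_mM * (fb * self.eps_base + (1.0 - fb) * self.eps_acid)


@dataclass(frozen=True)
class CarbonateParams:
    henry_K: float = HENRY_K_DEFAULT
    pKa1: float = PKA1_DEFAULT
    pKw: float = PKW_DEFAULT
    buffer: Buffer | None = None
    indicator: Indicator | None = None
    k_uncat: float = K_UNCAT_DEFAULT
    enhancement: float = 1.0

    def __post_init__(self) -> None:
        for name in ("henry_K", "pKa1", "pKw", "k_uncat"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.enhancement < 1.0:
            raise ValueError("enhancement must be >= 1")


@dataclass
class AssayTrace:
    """Time course of the colorimetric assay."""

    times: np.ndarray
    ph: np.ndarray
    absorbance: np.ndarray
    time_to_threshold: float  # s; +inf when the threshold is never reached
    threshold_reached: bool


def co2_solubility(pco2_atm: float, henry_K: float = HENRY_K_DEFAULT) -> float:
    """Dissolved CO2 (mM) at a given partial pressure: Henry's law."""
    if pco2_atm < 0:
        raise ValueError("partial pressure must be >= 0")
    return henry_K * pco2_atm


def bicarbonate_fraction(ph: float | np.ndarray, pKa1: float = PKA1_DEFAULT) -> np.ndarray | float:
    """Fraction of the CO2(aq)+HCO3- pool present as HCO3- at equilibrium."""
    ph_arr = np.asarray(ph, dtype=float)
    if np.any(ph_arr < 0) or np.any(ph_arr > 14):
        raise ValueError("pH must be in [0, 14]")
    out = 1.0 / (1.0 + 10.0 ** (pKa1 - ph_arr))
    return float(out) if np.isscalar(ph) else out


def _charge_imbalance(
    ph: float,
    dic_M: float,
    params: CarbonateParams,
    strong_ion_M: float,
    hco3_fixed_M: float | None = None,
) -> float:
    """Cations minus anions (M) at a trial pH.

    [H+] + Z - [OH-] - [HCO3-] - [A-]_buffer - [Ind-].  With
    ``hco3_fixed_M`` given, bicarbonate is a kinetically fixed anion;
    otherwise it equilibrates with the total carbon ``dic_M``.
    """
    h = 10.0**-ph
    oh = 10.0 ** (ph - params.pKw)
    ka1 = 10.0**-params.pKa1
    hco3 = hco3_fixed_M if hco3_fixed_M is not None else dic_M * ka1 / (h + ka1)
    bal = h + strong_ion_M - oh - hco3
    if params.buffer is not None:
        ka = 10.0**-params.buffer.pka
        bal -= (params.buffer.total_mM * 1e-3) * ka / (h + ka)
    if params.indicator is not None:
        ka = 10.0**-params.indicator.pka
        bal -= (params.indicator.total_mM * 1e-3) * ka / (h + ka)
    return bal


def _solve_ph(
    dic_M: float,
    params: CarbonateParams,
    strong_ion_M: float,
    hco3_fixed_M: float | None = None,
) -> float:
    f = lambda ph: _charge_imbalance(ph, dic_M, params, strong_ion_M, hco3_fixed_M)
    lo, hi = 0.0, 14.0
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError("charge balance has no root for pH in [0, 14]")
    # bisection; ~90 halvings drive the residual far below 1e-10 M
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if flo * fm <= 0:
            hi = mid
        else:
            lo, flo = mid, fm
        if hi - lo < 1e-15:
            break
    return 0.5 * (lo + hi)


def solve_speciation(
    dic_mM: float,
    params: CarbonateParams | None = None,
    strong_ion_mM: float = 0.0,
) -> dict[str, float]:
    """Equilibrium pH and speciation of a closed carbonate system.

    ``dic_mM`` is the total dissolved inorganic carbon (CO2(aq) + HCO3-);
    ``strong_ion_mM`` the net inert cation concentration (e.g. Na+ minus
    Cl-), which sets where the buffer sits before carbon is added.  Solved
    by bisection on pH in [0, 14]; the charge-balance residual at the
    returned pH is below 1e-10 M.  Carbonate (CO3 2-) is neglected — valid
    below pH ~9.
    """
    if params is None:
        params = CarbonateParams()
    if dic_mM < 0:
        raise ValueError("dissolved carbon must be >= 0")
    dic_M = dic_mM * 1e-3
    z = strong_ion_mM * 1e-3
    ph = _solve_ph(dic_M, params, z)
    ka1 = 10.0**-params.pKa1
    h = 10.0**-ph
    hco3 = dic_M * ka1 / (h + ka1)
    return {
        "pH": ph,
        "CO2_mM": (dic_M - hco3) * 1e3,
        "HCO3_mM": hco3 * 1e3,
        "residual_M": _charge_imbalance(ph, dic_M, params, z),
    }


def strong_ion_for_ph(
    ph_start: float, params: CarbonateParams, dic_mM: float = 0.0
) -> float:
    """Net strong-ion concentration (mM) that sets the initial pH.

    Inverts the charge balance at ``ph_start`` (before/with ``dic_mM`` of
    carbon); used to initialise buffered assays at their working pH.
    """
    z = -_charge_imbalance(ph_start, dic_mM * 1e-3, params, 0.0)
    return z * 1e3


def simulate_wa_assay(
    params: CarbonateParams,
    co2_injected_mM: float,
    ph_start: float = 8.0,
    ph_threshold: float = 6.3,
    t_max: float = 600.0,
    n_out: int = 400,
) -> AssayTrace:
    """Simulate the colorimetric CO2-hydration assay.

    A bolus of ``co2_injected_mM`` dissolved CO2 enters a buffered,
    indicator-containing solution poised at ``ph_start``.  The slow
    reversible hydration

        d[CO2]/dt = F * (-k_uncat [CO2] + (k_uncat / Ka1) [HCO3-][H+])

    (F = enhancement; the reverse constant follows from microscopic
    reversibility) converts CO2 to bicarbonate, and the instantaneously
    equilibrated charge balance yields pH(t) and the indicator absorbance.
    Reported is the time for the pH to fall to ``ph_threshold``; if the
    horizon ends first the trace is flagged and the time is +inf.
    """
    if ph_start <= ph_threshold:
        raise ValueError("ph_start must exceed ph_threshold")
    if co2_injected_mM < 0:
        raise ValueError("injected CO2 must be >= 0")
    z_M = strong_ion_for_ph(ph_start, params) * 1e-3
    total_M = co2_injected_mM * 1e-3
    ka1 = 10.0**-params.pKa1
    k1 = params.k_uncat * params.enhancement
    k_rev = k1 / ka1

    def ph_of(x_co2: float) -> float:
        hco3 = max(total_M - x_co2, 0.0)
        return _solve_ph(total_M, params, z_M, hco3_fixed_M=hco3)

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        x = min(max(y[0], 0.0), total_M)
        h = 10.0 ** -ph_of(x)
        return [-k1 * x + k_rev * (total_M - x) * h]

    def crossing(_t: float, y: np.ndarray) -> float:
        x = min(max(y[0], 0.0), total_M)
        return ph_of(x) - ph_threshold

    crossing.terminal = False
    crossing.direction = -1

    t_eval = np.linspace(0.0, t_max, n_out)
    if total_M == 0.0:
        ph0 = ph_of(0.0)
        ph = np.full_like(t_eval, ph0)
        ab = (
            params.indicator.absorbance(ph)
            if params.indicator is not None
            else np.zeros_like(ph)
        )
        return AssayTrace(t_eval, ph, ab, float("inf"), False)

    sol = solve_ivp(
        rhs,
        (0.0, t_max),
        [total_M],
        t_eval=t_eval,
        events=crossing,
        rtol=1e-8,
        atol=1e-12 * max(total_M, 1e-6),
        method="LSODA",
    )
    ph = np.array([ph_of(float(x)) for x in sol.y[0]])
    ab = (
        params.indicator.absorbance(ph)
        if params.indicator is not None
        else np.zeros_like(ph)
    )
    events = sol.t_events[0]
    reached = events.size > 0
    t_thr = float(events[0]) if reached else float("inf")
    return AssayTrace(sol.t, ph, ab, t_thr, reached)


def assay_units(
    params: CarbonateParams,
    co2_injected_mM: float,
    ph_start: float = 8.0,
    ph_threshold: float = 6.3,
    t_max: float = 600.0,
) -> float:
    """Activity units U = T_blank / T_cat - 1.

    T_blank is the threshold time at enhancement 1 (uncatalysed), T_cat
    with ``params.enhancement``.  Raises if either run never reaches the
    threshold within the horizon.
    """
    from dataclasses import replace

    blank = simulate_wa_assay(
        replace(params, enhancement=1.0), co2_injected_mM, ph_start, ph_threshold, t_max
    )
    cat = simulate_wa_assay(params, co2_injected_mM, ph_start, ph_threshold, t_max)
    if not (blank.threshold_reached and cat.threshold_reached):
        raise ValueError("threshold not reached within the time horizon")
    return blank.time_to_threshold / cat.time_to_threshold - 1.0
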