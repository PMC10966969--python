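"""Model-based decomposition of difference spectra into species traces.

Each "CO2–N2" difference spectrum is fitted as a signed linear combination
of species band templates (dissolved CO2, bicarbonate, local water, plus an
optional bulk-water component absorbing unspecific hydration changes) and a
low-order polynomial baseline.  The linear stage is an ordinary
least-squares solve; an optional refinement stage then adjusts band centers
within bounded windows by nonlinear least squares (variable projection: the
amplitudes are re-solved linearly at every center trial).

Fitting is restricted to the spectral windows that carry the analyte bands
(2450–2200 cm-1 for CO2, 1750–1150 cm-1 for bicarbonate, 3700–2100 cm-1 for
water); the amide-contaminated 1680–1620 cm-1 stretch is down-weighted.
Applied per time point across a stack this yields per-species peak-area
traces, the bicarbonate trace being the sum of its v2 + v3 + v4 band areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from numpy.polynomial import legendre
from scipy.optimize import least_squares

from .spectra_core import (
    SpeciesTemplate,
    Spectrum,
    TimeSeriesSpectra,
    band_area,
    band_profile,
    template_area,
)
from .synthetic_data import prune_to_window

logger = logging.getLogger(__name__)

__all__ = [
    "DecompositionResult",
    "KineticTrace",
    "DEFAULT_FIT_WINDOWS",
    "decompose_spectrum",
    "extract_traces",
    "estimate_hydration",
]

#: (high, low) cm-1 windows included in the fit
DEFAULT_FIT_WINDOWS: tuple[tuple[float, float], ...] = (
    (2450.0, 2200.0),
    (1750.0, 1150.0),
    (3700.0, 2100.0),
)
#: amide-band overlap region, down-weighted
_DOWNWEIGHT_WINDOW = (1680.0, 1620.0)
_DOWNWEIGHT = 0.5


class CollinearTemplatesError(ValueError):
    """Raised when two species templates are indistinguishable on the grid."""


@dataclass(frozen=True)
class DecompositionResult:
    """Per-spectrum fit result.

    ``areas`` are species peak areas (amplitude x template area, mOD cm-1);
    ``fitted_centers`` maps (species, band label) -> center when refinement
    ran.  ``refine_converged`` is False when refinement failed and the
    linear answer was retained.
    """

    amplitudes: dict[str, float]
    areas: dict[str, float]
    baseline_coeffs: np.ndarray
    residual_rms: float
    fitted_centers: dict[tuple[str, str], float] = field(default_factory=dict)
    refine_converged: bool = True


@dataclass
class KineticTrace:
    """Peak-area time series of one species."""

    times: np.ndarray
    area: np.ndarray
    species: str
    stderr: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if self.times.shape != self.area.shape:
            raise ValueError("times and area must have the same shape")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def _fit_weights(
    wavenumbers: np.ndarray,
    windows: Sequence[tuple[float, float]],
) -> np.ndarray:
    w = np.zeros_like(wavenumbers)
    for hi, lo in windows:
        w[(wavenumbers <= hi) & (wavenumbers >= lo)] = 1.0
    hi, lo = _DOWNWEIGHT_WINDOW
    w[(wavenumbers <= hi) & (wavenumbers >= lo) & (w > 0)] = _DOWNWEIGHT
    return w


def _design(
    wavenumbers: np.ndarray,
    templates: Sequence[SpeciesTemplate],
    baseline_degree: int,
) -> np.ndarray:
    x = 2.0 * (wavenumbers - wavenumbers.min()) / np.ptp(wavenumbers) - 1.0
    cols = [np.sum([band_profile(b, wavenumbers) for b in t.bands], axis=0) for t in templates]
    for d in range(baseline_degree + 1):
        cols.append(legendre.legval(x, [0.0] * d + [1.0]))
    return np.column_stack(cols)


def _check_collinear(design: np.ndarray, names: Sequence[str]) -> None:
    n_species = len(names)
    cols = design[:, :n_species]
    norms = np.linalg.norm(cols, axis=0)
    for i in range(n_species):
        if norms[i] == 0:
            raise CollinearTemplatesError(
                f"template {names[i]!r} renders to zero inside the fit windows"
            )
    for i in range(n_species):
        for j in range(i + 1, n_species):
            rho = abs(cols[:, i] @ cols[:, j]) / (norms[i] * norms[j])
            if rho > 0.999:
                raise CollinearTemplatesError(
                    f"templates {names[i]!r} and {names[j]!r} are collinear "
                    f"on this grid (|corr| = {rho:.4f})"
                )


def _linear_solve(
    y: np.ndarray, design: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    sw = np.sqrt(weights)
    coeffs, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    resid = y - design @ coeffs
    return coeffs, resid


def decompose_spectrum(
    spectrum: Spectrum,
    templates: Mapping[str, SpeciesTemplate],
    baseline_degree: int = 2,
    refine: bool = False,
    fit_windows: Sequence[tuple[float, float]] = DEFAULT_FIT_WINDOWS,
    refine_bound: float = 25.0,
) -> DecompositionResult:
    """Fit one spectrum as species templates + polynomial baseline.

    Linear mode solves OLS for the species amplitudes and baseline jointly;
    amplitudes are unconstrained in sign (the water component is negative in
    hydration difference spectra).  With ``refine=True`` band centers are
    subsequently optimised within ±``refine_bound`` cm-1 by nonlinear least
    squares; if the optimiser does not converge the linear answer is kept
    and flagged.
    """
    if not 0 <= baseline_degree <= 3:
        raise ValueError("baseline_degree must be in 0..3")
    nu = spectrum.wavenumbers
    names = list(templates)
    pruned = [prune_to_window(templates[n], nu) for n in names]
    active = [(n, t) for n, t in zip(names, pruned) if t.bands]
    if not active:
        raise ValueError("no template band lies inside the spectrum grid")
    names = [n for n, _ in active]
    pruned = [t for _, t in active]

    weights = _fit_weights(nu, fit_windows)
    if not np.any(weights > 0):
        raise ValueError("no grid point falls inside the fit windows")

    design = _design(nu, pruned, baseline_degree)
    _check_collinear(design * np.sqrt(weights)[:, None], names)
    coeffs, resid = _linear_solve(spectrum.absorbance, design, weights)

    fitted_centers: dict[tuple[str, str], float] = {}
    converged = True
    current = pruned

    if refine:
        offsets0 = np.zeros(sum(len(t.bands) for t in pruned))

        def shifted_templates(offsets: np.ndarray) -> list[SpeciesTemplate]:
            out = []
            k = 0
            for t in pruned:
                bands = []
                for b in t.bands:
                    bands.append(replace(b, center=b.center + offsets[k]))
                    k += 1
                out.append(replace(t, bands=tuple(bands)))
            return out

        sw = np.sqrt(weights)

        def residual(offsets: np.ndarray) -> np.ndarray:
            d = _design(nu, shifted_templates(offsets), baseline_degree)
            c, *_ = np.linalg.lstsq(d * sw[:, None], spectrum.absorbance * sw, rcond=None)
            return (spectrum.absorbance - d @ c) * sw

        try:
            sol = least_squares(
                residual,
                offsets0,
                bounds=(-refine_bound, refine_bound),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
            converged = bool(sol.success)
        except Exception:  # numerical failure -> keep linear answer
            converged = False
            sol = None
        if sol is not None and converged:
            current = shifted_templates(sol.x)
            design = _design(nu, current, baseline_degree)
            coeffs, resid = _linear_solve(spectrum.absorbance, design, weights)
        for t in current:
            for b in t.bands:
                fitted_centers[(t.species, b.label)] = b.center

    n_species = len(names)
    amplitudes = {n: float(coeffs[i]) for i, n in enumerate(names)}
    areas = {n: float(coeffs[i] * template_area(current[i])) for i, n in enumerate(names)}
    mask = weights > 0
    rms = float(np.sqrt(np.mean(resid[mask] ** 2)))
    return DecompositionResult(
        amplitudes=amplitudes,
        areas=areas,
        baseline_coeffs=coeffs[n_species:].copy(),
        residual_rms=rms,
        fitted_centers=fitted_centers,
        refine_converged=converged,
    )


def extract_traces(
    series: TimeSeriesSpectra,
    templates: Mapping[str, SpeciesTemplate],
    baseline_degree: int = 2,
    refine: bool = False,
    fit_windows: Sequence[tuple[float, float]] = DEFAULT_FIT_WINDOWS,
) -> dict[str, KineticTrace]:
    """Decompose every spectrum of a stack into per-species area traces.

    The bicarbonate trace is the sum of its band areas (v2 + v3 + v4) by
    construction of the template area; the water trace comes out signed
    negative.  A failed fit marks that time point NaN in every trace and is
    logged — never silently dropped.
    """
    names = list(templates)
    n_t = len(series)
    areas = {n: np.full(n_t, np.nan) for n in names}
    flags: list[str] = []
    for i, spec in enumerate(series.spectra):
        try:
            result = decompose_spectrum(
                spec, templates, baseline_degree=baseline_degree, refine=refine,
                fit_windows=fit_windows,
            )
        except Exception as exc:
            msg = f"t={series.times[i]:g}s: decomposition failed: {exc}"
            logger.warning(msg)
            flags.append(msg)
            continue
        for n in names:
            if n in result.areas:
                areas[n][i] = result.areas[n]
    return {
        n: KineticTrace(series.times, areas[n], species=n, flags=list(flags)) for n in names
    }


def estimate_hydration(
    spectrum: Spectrum,
    full_hydration_reference: Spectrum,
    window: tuple[float, float] = (3700.0, 2800.0),
) -> float:
    """Film hydration fraction from the OH-stretch area ratio.

    Integrates absorbance over the OH-stretch window (3700–2800 cm-1) in
    both spectra and returns their ratio, clipped to [0, 1.5].  Both
    spectra must share a grid and the reference must carry OH intensity.
    """
    if not np.array_equal(spectrum.wavenumbers, full_hydration_reference.wavenumbers):
        raise ValueError("spectrum and reference must share one wavenumber grid")
    hi, lo = window
    nu = spectrum.wavenumbers
    mask = (nu <= hi) & (nu >= lo)
    if mask.sum() < 2:
        raise ValueError("OH window contains fewer than two grid points")
    # grid is descending; integrate on the reversed axis for positive dx
    x = nu[mask][::-1]
    a_spec = np.trapezoid(spectrum.absorbance[mask][::-1], x)
    a_ref = np.trapezoid(full_hydration_reference.absorbance[mask][::-1], x)
    if a_ref == 0:
        raise ValueError("reference OH-stretch area is zero")
    return float(np.clip(a_spec / a_ref, 0.0, 1.5))
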