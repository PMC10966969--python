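"""Synthetic generators emulating the study's measurements.

Three generators cover the three data streams the analysis consumes:

* :func:`generate_timeseries` — stacks of time-resolved "CO2–N2" difference
  spectra driven by a step gas program, with reversible pseudo-first-order
  film kinetics, baseline drift, an unspecific bulk-water disturbance and
  white noise;
* :func:`simulate_film_kinetics` — the underlying two-compartment kinetic
  model (gas exchange into the film, reversible hydration), exposed so that
  ground-truth concentration courses are available to tests;
* :func:`generate_trajectory` — toy CO2-centroid trajectories in a periodic
  box with a Boltzmann-weighted active-site well, for the occupancy stage.

The kinetic model is

    dC/dt = (henry_K * pCO2(t) - C) / mix_tau        (film gas exchange)
    dB/dt = a * k_h * C - k_d * B                    (reversible hydration)

with C the dissolved CO2 and B the bicarbonate concentration in the film,
and a = activity_scale * hydration_level the condition multiplier.  The
local-water signal is stoichiometrically coupled to B (one water cluster
consumed per bicarbonate formed): its rendered area is -alpha times the
bicarbonate area at every time point.  Both equations are linear, so B is
exactly proportional to a at fixed k_d — which is what makes relative
activities recoverable from band areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .occupancy import RegionBox, Trajectory
from .spectra_core import (
    Band,
    GasProgram,
    SpeciesTemplate,
    Spectrum,
    TimeSeriesSpectra,
    WATER_MODES,
    default_grid,
    load_band_library,
    template_area,
    template_profile,
)

__all__ = [
    "FilmKinetics",
    "NoiseModel",
    "ConditionPreset",
    "PRESETS",
    "BACKGROUND_FLOOR",
    "TITRATION5",
    "shift_templates",
    "prune_to_window",
    "simulate_film_kinetics",
    "generate_timeseries",
    "generate_trajectory",
]

#: fraction of wild-type hydration attributable to unspecific background
BACKGROUND_FLOOR = 0.30


@dataclass(frozen=True)
class FilmKinetics:
    """Rate parameters of the hydrated-film kinetic model.

    k_h is the hydration rate constant per unit dissolved CO2 (s-1 mM-1),
    k_d the dehydration rate constant (s-1), henry_K the film solubility
    (mM per % pCO2), mix_tau the gas-exchange time constant (s),
    hydration_level the film humidity fraction and activity_scale a
    dimensionless condition multiplier on k_h.
    """

    k_h: float = 0.02
    k_d: float = 0.01
    henry_K: float = 0.338
    mix_tau: float = 5.0
    hydration_level: float = 1.0
    activity_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_h", "k_d", "henry_K", "mix_tau", "activity_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.hydration_level <= 1.0:
            raise ValueError("hydration_level must be in (0, 1]")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement disturbances: white noise, drift, unspecific band.

    baseline_drift holds polynomial coefficients (highest power first, in
    reduced wavenumber x in [-1, 1]) accrued once per time step, so the
    baseline at step i is i * polyval(coeffs, x).  unspecific_amp sets the
    final amplitude of a bulk-water-like disturbance that grows linearly
    over the series.  Identical seeds give identical output.
    """

    sigma: float = 0.02
    baseline_drift: tuple[float, ...] = ()
    unspecific_amp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        object.__setattr__(self, "baseline_drift", tuple(self.baseline_drift))


@dataclass(frozen=True)
class ConditionPreset:
    """An experimental condition: enzyme, variant or additive.

    activity_scale encodes the published relative bicarbonate-formation
    activities (transcriptions of the reported percentages, not
    predictions).  water_center_override replaces the local-water band
    center (cm-1) for variants whose water signature is up-shifted.
    """

    label: str
    activity_scale: float
    water_mode: str = "local_KsCcr"
    water_center_override: float | None = None

    def __post_init__(self) -> None:
        if self.activity_scale < 0:
            raise ValueError("activity_scale must be >= 0")
        if self.water_mode not in WATER_MODES:
            raise ValueError(f"unknown water_mode {self.water_mode!r}")


# Relative activities: EcCA ~4x wild type; E171A / H365N ~50%; the double
# mutant and BSA show only the ~30% unspecific background; crotonyl-CoA and
# butyryl-CoA suppress activity to 33% and 17%.  Water signatures: single
# mutants up-shift to 3030, the double mutant and BSA to the 3320 bulk mode.
PRESETS: Mapping[str, ConditionPreset] = {
    "KsCcr_WT": ConditionPreset("KsCcr_WT", 1.0),
    "EcCA": ConditionPreset("EcCA", 4.0, water_mode="local_EcCA"),
    "BSA": ConditionPreset("BSA", BACKGROUND_FLOOR, water_mode="bulk"),
    "E171A": ConditionPreset("E171A", 0.5, water_center_override=3030.0),
    "H365N": ConditionPreset("H365N", 0.5, water_center_override=3030.0),
    "E171A/H365N": ConditionPreset(
        "E171A/H365N", BACKGROUND_FLOOR, water_center_override=3320.0
    ),
    "KsCcr_WT+NADPH": ConditionPreset("KsCcr_WT+NADPH", 1.0),
    "KsCcr_WT+NADP+": ConditionPreset("KsCcr_WT+NADP+", 1.0),
    "KsCcr_WT+C-CoA": ConditionPreset("KsCcr_WT+C-CoA", 0.33),
    "KsCcr_WT+B-CoA": ConditionPreset("KsCcr_WT+B-CoA", 0.17),
}

#: five-step titration: 1/3/10/30/100% CO2, each followed by a 100 s N2 purge
TITRATION5 = GasProgram(
    steps=tuple(
        [(0.0, 0.0, "N2")]
        + [
            step
            for i, p in enumerate((1.0, 3.0, 10.0, 30.0, 100.0))
            for step in (
                (50.0 + 200.0 * i, p, "CO2/N2"),
                (150.0 + 200.0 * i, 0.0, "N2"),
            )
        ]
    ),
    duration=1050.0,
)


# ---------------------------------------------------------------------------
# template shifting
# ---------------------------------------------------------------------------

_ISOTOPOLOGUES = ("12C", "13C")
_SOLVENTS = ("H2O", "D2O")


def shift_templates(
    templates: Mapping[str, SpeciesTemplate],
    isotopologue: str = "12C",
    solvent: str = "H2O",
    water_mode: str = "local_KsCcr",
) -> dict[str, SpeciesTemplate]:
    """Apply isotopologue / solvent / water-mode center shifts.

    Offsets in each template's shift_map are absolute relative to the
    12C / H2O / local_KsCcr reference state, so shifting is idempotent per
    axis and invertible (re-applying 12C restores the reference centers).
    13C leaves water bands untouched; D2O moves the bicarbonate COH bend
    below the detection window (prune with :func:`prune_to_window` before
    rendering).  A combined ``"<water_mode>:<solvent>"`` key overrides the
    sum of the separate water-mode and solvent offsets for listed bands.
    """
    if isotopologue not in _ISOTOPOLOGUES:
        raise ValueError(f"unknown isotopologue {isotopologue!r}")
    if solvent not in _SOLVENTS:
        raise ValueError(f"unknown solvent {solvent!r}")
    if water_mode not in WATER_MODES:
        raise ValueError(f"unknown water_mode {water_mode!r}")

    out: dict[str, SpeciesTemplate] = {}
    for name, tpl in templates.items():
        ref = tpl.shift_map.get("_reference_centers", None)
        centers = dict(ref) if ref else {b.label: b.center for b in tpl.bands}
        combined_key = f"{water_mode}:{solvent}"
        new_bands = []
        for band in tpl.bands:
            delta = 0.0
            if isotopologue != "12C":
                delta += tpl.shift_map.get(isotopologue, {}).get(band.label, 0.0)
            if combined_key in tpl.shift_map and band.label in tpl.shift_map[combined_key]:
                delta += tpl.shift_map[combined_key][band.label]
            else:
                if solvent != "H2O":
                    delta += tpl.shift_map.get(solvent, {}).get(band.label, 0.0)
                delta += tpl.shift_map.get(water_mode, {}).get(band.label, 0.0)
            new_bands.append(replace(band, center=centers[band.label] + delta))
        shift_map = dict(tpl.shift_map)
        shift_map["_reference_centers"] = centers
        out[name] = SpeciesTemplate(species=tpl.species, bands=tuple(new_bands), shift_map=shift_map)
    return out


def prune_to_window(
    template: SpeciesTemplate, wavenumbers: np.ndarray
) -> SpeciesTemplate:
    """Drop bands whose center lies outside the grid's detection window."""
    lo, hi = float(np.min(wavenumbers)), float(np.max(wavenumbers))
    kept = tuple(b for b in template.bands if lo <= b.center <= hi)
    return replace(template, bands=kept)


# ---------------------------------------------------------------------------
# film kinetics
# ---------------------------------------------------------------------------


def _advance_segment(
    c0: float, b0: float, kappa: float, k_d: float, tau: float, c_inf: float, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact solution of the linear film model over one constant-pCO2 segment.

    C(t) = c_inf + (c0 - c_inf) e^{-t/tau}   (C == c_inf when tau == 0)
    B(t) = homogeneous decay + particular responses to the constant and
    exponential parts of C, with the k_d == 1/tau and k_d == 0 degeneracies
    handled separately.
    """
    t = np.asarray(t, dtype=float)
    if tau == 0.0:
        c = np.full_like(t, c_inf)
        delta = 0.0
        s = math.inf
    else:
        s = 1.0 / tau
        delta = c0 - c_inf
        c = c_inf + delta * np.exp(-s * t)

    e_d = np.exp(-k_d * t)
    if k_d == 0.0:
        b = b0 + kappa * c_inf * t
        if delta:
            b = b + kappa * delta * (1.0 - np.exp(-s * t)) / s
        return c, b

    b = b0 * e_d + (kappa * c_inf / k_d) * (1.0 - e_d)
    if delta:
        if abs(s - k_d) < 1e-12 * max(s, k_d):
            b = b + kappa * delta * t * e_d
        else:
            b = b + kappa * delta * (np.exp(-s * t) - e_d) / (k_d - s)
    return c, b


def simulate_film_kinetics(
    kinetics: FilmKinetics,
    gas_program: GasProgram,
    times: Sequence[float] | np.ndarray,
    alpha: float = 1.0,
) -> dict[str, np.ndarray]:
    """Integrate the film model; returns concentration courses per species.

    The returned mapping has keys ``"CO2(aq)"``, ``"HCO3-"`` (mM) and
    ``"water_loss"`` (= -alpha * HCO3-, the stoichiometrically coupled
    local-water consumption).  Integration is exact (piecewise-analytic per
    gas step), so ground truth is available to machine precision.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if times[0] < 0 or times[-1] > gas_program.duration:
        raise ValueError("times must lie within the gas program duration")

    kappa = kinetics.activity_scale * kinetics.hydration_level * kinetics.k_h
    starts = [s[0] for s in gas_program.steps] + [gas_program.duration]
    levels = [s[1] for s in gas_program.steps]

    c_out = np.empty_like(times)
    b_out = np.empty_like(times)
    c_state, b_state = 0.0, 0.0
    for i, level in enumerate(levels):
        t0, t1 = starts[i], starts[i + 1]
        c_inf = kinetics.henry_K * level
        mask = (times >= t0) & (times < t1)
        if i == len(levels) - 1:
            mask |= times == t1
        if np.any(mask):
            c_seg, b_seg = _advance_segment(
                c_state, b_state, kappa, kinetics.k_d, kinetics.mix_tau, c_inf, times[mask] - t0
            )
            c_out[mask], b_out[mask] = c_seg, b_seg
        c_end, b_end = _advance_segment(
            c_state, b_state, kappa, kinetics.k_d, kinetics.mix_tau, c_inf, np.array([t1 - t0])
        )
        c_state, b_state = float(c_end[0]), float(b_end[0])

    return {"CO2(aq)": c_out, "HCO3-": b_out, "water_loss": -alpha * b_out}


# ---------------------------------------------------------------------------
# spectrum stack generation
# ---------------------------------------------------------------------------


def generate_timeseries(
    preset: ConditionPreset | str,
    kinetics: FilmKinetics,
    noise: NoiseModel,
    gas_program: GasProgram,
    templates: Mapping[str, SpeciesTemplate] | None = None,
    isotopologue: str = "12C",
    solvent: str = "H2O",
    wavenumbers: np.ndarray | None = None,
    dt: float = 5.0,
    alpha: float = 1.0,
) -> TimeSeriesSpectra:
    """Render a time-resolved difference-spectrum stack for one condition.

    Each spectrum is C(t)*T_CO2 + B(t)*T_HCO3 + a_w(t)*T_water plus drift,
    unspecific bulk-water disturbance and white noise, where the water
    amplitude a_w is normalised so that the rendered water-loss area equals
    -alpha times the rendered bicarbonate area.  Deterministic under a
    fixed ``noise.seed``.  Default time sampling is one spectrum per 5 s.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    if templates is None:
        templates = load_band_library()
    if wavenumbers is None:
        wavenumbers = default_grid()

    shifted = shift_templates(templates, isotopologue, solvent, preset.water_mode)
    if preset.water_center_override is not None and "local_water" in shifted:
        tpl = shifted["local_water"]
        bands = tuple(
            replace(b, center=preset.water_center_override) if b.label == "vOH" else b
            for b in tpl.bands
        )
        shifted["local_water"] = replace(tpl, bands=bands)

    t_co2 = prune_to_window(shifted["CO2(aq)"], wavenumbers)
    t_hco3 = prune_to_window(shifted["HCO3-"], wavenumbers)
    t_water = prune_to_window(shifted["local_water"], wavenumbers)
    p_co2 = template_profile(t_co2, wavenumbers)
    p_hco3 = template_profile(t_hco3, wavenumbers)
    p_water = template_profile(t_water, wavenumbers)
    a_hco3 = template_area(t_hco3)
    a_water = template_area(t_water)
    if a_water == 0.0:
        raise ValueError("water template has zero area on this grid")
    # rendered water area = -alpha * rendered bicarbonate area
    water_scale = alpha * a_hco3 / abs(a_water)

    times = np.arange(0.0, gas_program.duration, dt)
    kin = replace(kinetics, activity_scale=kinetics.activity_scale * preset.activity_scale)
    conc = simulate_film_kinetics(kin, gas_program, times, alpha=alpha)

    rng = np.random.default_rng(noise.seed)
    x = (wavenumbers - wavenumbers.mean()) / (np.ptp(wavenumbers) / 2.0)
    drift_poly = np.polyval(noise.baseline_drift, x) if noise.baseline_drift else 0.0
    unspecific_profile = (
        template_profile(prune_to_window(shifted["bulk_water"], wavenumbers), wavenumbers)
        if "bulk_water" in shifted and noise.unspecific_amp
        else 0.0
    )

    n_t = times.size
    spectra = []
    for i, t in enumerate(times):
        y = (
            conc["CO2(aq)"][i] * p_co2
            + conc["HCO3-"][i] * p_hco3
            + water_scale * conc["HCO3-"][i] * p_water
        )
        if noise.baseline_drift:
            y = y + i * drift_poly
        if noise.unspecific_amp:
            y = y + noise.unspecific_amp * (i / max(n_t - 1, 1)) * unspecific_profile
        if noise.sigma > 0:
            y = y + rng.normal(0.0, noise.sigma, size=y.size)
        meta = {
            "time_s": float(t),
            "pco2_percent": float(gas_program.pco2_at(t)),
            "condition": preset.label,
            "isotopologue": isotopologue,
            "solvent": solvent,
        }
        spectra.append(Spectrum(wavenumbers, y, meta))

    return TimeSeriesSpectra(
        times,
        spectra,
        gas_program,
        meta={
            "condition": preset.label,
            "isotopologue": isotopologue,
            "solvent": solvent,
            "alpha": alpha,
            "seed": noise.seed,
        },
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def generate_trajectory(
    n_frames: int,
    n_molecules: int,
    box_edges: Sequence[float],
    site_box: RegionBox,
    well_depth_kT: float,
    seed: int = 0,
) -> Trajectory:
    """Sample CO2 centroids from a two-region Boltzmann density.

    Positions are i.i.d. per molecule per frame with density proportional
    to exp(+well_depth_kT) inside ``site_box`` and uniform elsewhere
    (analytic two-region sampling: each molecule falls in the site with
    probability V_site*e^w / (V_site*e^w + V_bulk), then uniformly within
    its region).  The imposed binding free energy is therefore exactly
    -well_depth_kT.
    """
    if well_depth_kT < 0:
        raise ValueError("well_depth_kT must be >= 0")
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    box = np.asarray(box_edges, dtype=float)
    lo, hi = site_box.min_corner, site_box.max_corner
    if np.any(lo < 0) or np.any(hi > box):
        raise ValueError("site_box must lie strictly inside the periodic box")
    v_site = site_box.volume
    v_box = float(np.prod(box))
    if v_site >= v_box:
        raise ValueError("site volume must be smaller than the box volume")
    v_bulk = v_box - v_site

    w = math.exp(well_depth_kT)
    p_site = v_site * w / (v_site * w + v_bulk)
    rng = np.random.default_rng(seed)

    frames = []
    for _ in range(n_frames):
        in_site = rng.random(n_molecules) < p_site
        coords = np.empty((n_molecules, 3))
        n_in = int(in_site.sum())
        if n_in:
            coords[in_site] = lo + rng.random((n_in, 3)) * (hi - lo)
        n_out = n_molecules - n_in
        if n_out:
            # rejection-sample the bulk (uniform in box, outside the site)
            need = np.where(~in_site)[0]
            filled = 0
            while filled < n_out:
                cand = rng.random((max(2 * (n_out - filled), 16), 3)) * box
                inside = np.all((cand >= lo) & (cand < hi), axis=1)
                cand = cand[~inside]
                take = min(cand.shape[0], n_out - filled)
                coords[need[filled : filled + take]] = cand[:take]
                filled += take
        frames.append(coords)
    return Trajectory(frames=frames, box_edges=box)
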