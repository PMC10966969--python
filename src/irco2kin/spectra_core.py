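"""Domain types and band math for ATR-FTIR difference spectra.

The package works on "CO2–N2" difference spectra: absorbance recorded under a
CO2-containing atmosphere minus absorbance under pure N2, so species formed
during CO2 hydration appear as positive bands and species consumed (the
strongly hydrogen-bonded local-water cluster) as negative bands.

Conventions used throughout:

* wavenumber grids are stored strictly descending (4000 -> 1000 cm-1), the
  way mid-IR spectra are plotted; ascending input is reversed on read;
* absorbance is on the mOD scale and signed;
* band profiles are Gaussian, Lorentzian or pseudo-Voigt (linear mix with
  mixing parameter eta in [0, 1]), parameterised by center, FWHM and peak
  amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Spectrum",
    "Band",
    "SpeciesTemplate",
    "GasProgram",
    "TimeSeriesSpectra",
    "SpectrumParseError",
    "default_grid",
    "band_profile",
    "band_area",
    "template_profile",
    "template_area",
    "read_spectrum",
    "write_spectrum",
    "read_timeseries",
    "write_timeseries",
    "load_band_library",
]

_SHAPES = ("gaussian", "lorentzian", "pseudo_voigt")

# two established species water modes plus the bulk-water signature of
# uncatalysed hydration
WATER_MODES = ("local_KsCcr", "local_EcCA", "bulk")


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed."""


def default_grid(start: float = 4000.0, stop: float = 1000.0, step: float = 2.0) -> np.ndarray:
    """Default descending wavenumber grid, 4000 -> 1000 cm-1 at 2 cm-1."""
    n = int(round((start - stop) / step)) + 1
    return np.linspace(start, stop, n)


@dataclass(frozen=True)
class Spectrum:
    """A single spectrum: descending wavenumber grid + signed absorbance.

    ``meta`` carries free-form acquisition metadata (time in s, pCO2 in %,
    isotopologue, solvent, condition label, ...).
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.ndim != 1 or ab.ndim != 1 or wn.size != ab.size:
            raise ValueError("wavenumbers and absorbance must be 1-D and equal length")
        if wn.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if not (np.all(np.isfinite(wn)) and np.all(np.isfinite(ab))):
            raise ValueError("non-finite values in spectrum")
        if not np.all(np.diff(wn) < 0):
            raise ValueError("wavenumber grid must be strictly decreasing")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)

    def __len__(self) -> int:
        return self.wavenumbers.size


@dataclass(frozen=True)
class Band:
    """One vibrational band: center/FWHM/amplitude plus a line shape."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "gaussian"
    eta: float = 0.0  # Lorentzian fraction, pseudo-Voigt only
    label: str = ""

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"band {self.label!r}: fwhm must be > 0, got {self.fwhm}")
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown band shape {self.shape!r}; expected one of {_SHAPES}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta must be in [0, 1], got {self.eta}")


@dataclass(frozen=True)
class SpeciesTemplate:
    """Band model of one chemical species plus its condition shift map.

    ``shift_map`` holds per-band center offsets (cm-1) keyed first by the
    condition axis value (isotopologue ``13C``, solvent ``D2O``, or a
    ``water_mode`` name) and then by band label.  ``12C``/``H2O`` are the
    reference state (implicit zero shift).  A band whose shifted center falls
    outside the detection window is dropped when the template is rendered.
    """

    species: str
    bands: tuple[Band, ...]
    shift_map: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))
        labels = [b.label for b in self.bands]
        if len(set(labels)) != len(labels):
            raise ValueError(f"{self.species}: band labels must be unique")


@dataclass(frozen=True)
class GasProgram:
    """Piecewise-constant CO2 partial-pressure schedule.

    ``steps`` is an ordered list of (start_time s, pCO2 %, carrier-gas label);
    the program runs from t=0 to ``duration``.
    """

    steps: tuple[tuple[float, float, str], ...]
    duration: float

    def __post_init__(self) -> None:
        steps = tuple((float(t), float(p), str(c)) for t, p, c in self.steps)
        if not steps:
            raise ValueError("gas program needs at least one step")
        if steps[0][0] != 0.0:
            raise ValueError("first step must start at t=0")
        t_prev = -1.0
        for t, p, _ in steps:
            if t <= t_prev:
                raise ValueError("step start times must be strictly increasing")
            if not 0.0 <= p <= 100.0:
                raise ValueError(f"pCO2 must be in [0, 100] %, got {p}")
            t_prev = t
        if self.duration <= steps[-1][0]:
            raise ValueError("duration must exceed the last step start time")
        object.__setattr__(self, "steps", steps)

    def pco2_at(self, t: float | np.ndarray) -> np.ndarray:
        """pCO2 (%) at time(s) t."""
        t = np.asarray(t, dtype=float)
        starts = np.array([s[0] for s in self.steps])
        levels = np.array([s[1] for s in self.steps])
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(starts) - 1)
        return levels[idx]

    def switch_times(self) -> list[float]:
        """Start times of every step after the first (the gas exchanges)."""
        return [s[0] for s in self.steps[1:]]


@dataclass
class TimeSeriesSpectra:
    """A time-stamped stack of spectra on one shared grid, plus its program."""

    times: np.ndarray
    spectra: list[Spectrum]
    gas_program: GasProgram
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size != len(self.spectra):
            raise ValueError("times must match the number of spectra")
        if self.times.size and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.spectra:
            grid = self.spectra[0].wavenumbers
            for s in self.spectra[1:]:
                if not np.array_equal(s.wavenumbers, grid):
                    raise ValueError("all spectra must share one wavenumber grid")

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.spectra[0].wavenumbers

    def __len__(self) -> int:
        return len(self.spectra)


# ---------------------------------------------------------------------------
# band math
# ---------------------------------------------------------------------------

_GAUSS_AREA = 0.5 * math.sqrt(math.pi / math.log(2.0))  # area of unit-peak, unit-FWHM Gaussian


def band_profile(band: Band, wavenumbers: np.ndarray) -> np.ndarray:
    """Evaluate a band's absorbance profile on a wavenumber grid.

    The peak value equals ``band.amplitude`` at the band center for every
    shape (pseudo-Voigt mixes unit-peak Gaussian and Lorentzian).
    """
    nu = np.asarray(wavenumbers, dtype=float)
    d = nu - band.center
    w = band.fwhm
    gauss = np.exp(-4.0 * math.log(2.0) * d * d / (w * w))
    if band.shape == "gaussian":
        prof = gauss
    else:
        hw2 = (w / 2.0) ** 2
        lor = hw2 / (d * d + hw2)
        if band.shape == "lorentzian":
            prof = lor
        else:
            prof = band.eta * lor + (1.0 - band.eta) * gauss
    return band.amplitude * prof


def band_area(band: Band) -> float:
    """Integrated band area (mOD·cm-1), signed like the amplitude.

    Closed forms: Gaussian A·w·(1/2)·sqrt(pi/ln 2), Lorentzian A·w·pi/2;
    the pseudo-Voigt is the eta-weighted mix of the two (the profile is a
    linear combination, so its integral is too).
    """
    a_gauss = band.amplitude * band.fwhm * _GAUSS_AREA
    if band.shape == "gaussian":
        return a_gauss
    a_lor = band.amplitude * band.fwhm * math.pi / 2.0
    if band.shape == "lorentzian":
        return a_lor
    return band.eta * a_lor + (1.0 - band.eta) * a_gauss


def template_profile(template: SpeciesTemplate, wavenumbers: np.ndarray) -> np.ndarray:
    """Unit-amplitude rendering of a species: the sum of its band profiles."""
    nu = np.asarray(wavenumbers, dtype=float)
    out = np.zeros_like(nu)
    for band in template.bands:
        out += band_profile(band, nu)
    return out


def template_area(template: SpeciesTemplate) -> float:
    """Signed total area of a species template (sum of band areas)."""
    return float(sum(band_area(b) for b in template.bands))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _oriented(wn: np.ndarray, ab: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip ascending grids to the descending storage convention."""
    if wn.size >= 2 and wn[1] > wn[0]:
        return wn[::-1].copy(), ab[::-1].copy()
    return wn, ab


def read_spectrum(path: str | Path, format: str | None = None) -> Spectrum:
    """Read a spectrum from a two-column CSV or a JCAMP-DX (.jdx) file.

    ``format`` is ``"csv"`` or ``"jcamp"``; when omitted it is inferred from
    the file suffix.  Ascending grids are reversed to the descending
    convention.  Metadata carried by the format (JCAMP ##TITLE, CSV header
    comments) is preserved in ``Spectrum.meta``.
    """
    path = Path(path)
    if format is None:
        format = "jcamp" if path.suffix.lower() in (".jdx", ".dx", ".jcamp") else "csv"
    if format == "csv":
        return _read_csv(path)
    if format == "jcamp":
        return _read_jcamp(path)
    raise ValueError(f"unknown format {format!r}")


def write_spectrum(spectrum: Spectrum, path: str | Path, format: str | None = None) -> None:
    """Write a spectrum; round-trips through :func:`read_spectrum` to <=1e-9."""
    path = Path(path)
    if format is None:
        format = "jcamp" if path.suffix.lower() in (".jdx", ".dx", ".jcamp") else "csv"
    if format == "csv":
        _write_csv(spectrum, path)
    elif format == "jcamp":
        _write_jcamp(spectrum, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_csv(path: Path) -> Spectrum:
    wn: list[float] = []
    ab: list[float] = []
    meta: dict[str, Any] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    k, _, v = line.lstrip("#").partition("=")
                    meta[k.strip()] = _coerce(v.strip())
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            if len(parts) != 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            try:
                x, y = float(parts[0]), float(parts[1])
            except ValueError:
                if not wn:  # header row before any data
                    continue
                raise SpectrumParseError(f"{path}:{lineno}: non-numeric row {line!r}") from None
            wn.append(x)
            ab.append(y)
    if len(wn) < 2:
        raise SpectrumParseError(f"{path}: fewer than two data rows")
    x_arr, y_arr = _oriented(np.asarray(wn), np.asarray(ab))
    try:
        return Spectrum(x_arr, y_arr, meta)
    except ValueError as exc:
        raise SpectrumParseError(f"{path}: {exc}") from exc


def _write_csv(spectrum: Spectrum, path: Path) -> None:
    with open(path, "w") as fh:
        for k, v in spectrum.meta.items():
            fh.write(f"# {k} = {v}\n")
        fh.write("wavenumber_cm-1,absorbance_mOD\n")
        for x, y in zip(spectrum.wavenumbers, spectrum.absorbance):
            fh.write(f"{x:.10g},{y:.12e}\n")


def _coerce(text: str) -> Any:
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


# Minimal JCAMP-DX: the ##XYDATA=(X++(Y..Y)) AFFN dialect only.  Compressed
# ordinate forms (SQZ/DIF/DUP/PAC) are rejected with a clear error.

_JCAMP_COMPRESSED = set("@ABCDEFGHIJKLMNOPQRSabcdefghijklmnopqrs%")


def _read_jcamp(path: Path) -> Spectrum:
    headers: dict[str, str] = {}
    ys: list[float] = []
    xs_first: list[tuple[float, int]] = []  # (line-start X, ordinate index)
    in_data = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                value = value.strip()
                if key == "XYDATA":
                    if value.replace(" ", "") != "(X++(Y..Y))":
                        raise SpectrumParseError(
                            f"{path}:{lineno}: unsupported XYDATA dialect {value!r}; "
                            "only (X++(Y..Y)) AFFN is supported"
                        )
                    in_data = True
                    continue
                if key == "END":
                    in_data = False
                headers[key] = value
                continue
            if not in_data:
                continue
            if any(c in _JCAMP_COMPRESSED for c in line.split()[0][1:]):
                raise SpectrumParseError(
                    f"{path}:{lineno}: compressed (SQZ/DIF/DUP) ordinates are not supported"
                )
            parts = line.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                raise SpectrumParseError(f"{path}:{lineno}: non-AFFN token in data line") from None
            if len(vals) < 2:
                raise SpectrumParseError(f"{path}:{lineno}: data line needs X plus >=1 Y")
            xs_first.append((vals[0], len(ys)))
            ys.extend(vals[1:])
    if not ys:
        raise SpectrumParseError(f"{path}: no XYDATA table found")

    xf = float(headers.get("XFACTOR", 1.0))
    yf = float(headers.get("YFACTOR", 1.0))
    npoints = int(float(headers.get("NPOINTS", len(ys))))
    if npoints != len(ys):
        raise SpectrumParseError(f"{path}: NPOINTS={npoints} but {len(ys)} ordinates read")
    first_x = float(headers.get("FIRSTX", xs_first[0][0] * xf))
    last_x = float(headers.get("LASTX", xs_first[-1][0] * xf))
    wn = np.linspace(first_x, last_x, npoints)
    ab = np.asarray(ys) * yf
    # cross-check per-line abscissas against the implied even grid
    if npoints >= 2:
        dx = (last_x - first_x) / (npoints - 1)
        for x0, iy in xs_first:
            implied = first_x + iy * dx
            if abs(x0 * xf - implied) > max(1e-6, 0.5 * abs(dx)):
                raise SpectrumParseError(
                    f"{path}: line-start abscissa {x0 * xf:g} disagrees with grid ({implied:g})"
                )
    meta: dict[str, Any] = {}
    if "TITLE" in headers:
        meta["title"] = headers["TITLE"]
    for key in headers:
        if key.startswith("$"):
            meta[key[1:].lower()] = _coerce(headers[key])
    x_arr, y_arr = _oriented(wn, ab)
    try:
        return Spectrum(x_arr, y_arr, meta)
    except ValueError as exc:
        raise SpectrumParseError(f"{path}: {exc}") from exc


def _write_jcamp(spectrum: Spectrum, path: Path) -> None:
    wn, ab = spectrum.wavenumbers, spectrum.absorbance
    ymax = float(np.max(np.abs(ab))) or 1.0
    yfactor = ymax / 1e9  # 9 significant digits of dynamic range
    with open(path, "w") as fh:
        fh.write(f"##TITLE={spectrum.meta.get('title', 'spectrum')}\n")
        fh.write("##JCAMP-DX=4.24\n##DATA TYPE=INFRARED SPECTRUM\n")
        fh.write("##XUNITS=1/CM\n##YUNITS=ABSORBANCE\n")
        for k, v in spectrum.meta.items():
            if k != "title":
                fh.write(f"##${k.upper()}={v}\n")
        fh.write(f"##XFACTOR=1.0\n##YFACTOR={yfactor:.12e}\n")
        fh.write(f"##FIRSTX={wn[0]:.10g}\n##LASTX={wn[-1]:.10g}\n")
        fh.write(f"##NPOINTS={len(wn)}\n")
        fh.write("##XYDATA=(X++(Y..Y))\n")
        scaled = ab / yfactor
        per_line = 6
        for i in range(0, len(wn), per_line):
            chunk = scaled[i : i + per_line]
            fh.write(f"{wn[i]:.10g} " + " ".join(f"{y:.10g}" for y in chunk) + "\n")
        fh.write("##END=\n")


# ---------------------------------------------------------------------------
# time-series (directory of CSVs + YAML manifest)
# ---------------------------------------------------------------------------


def write_timeseries(series: TimeSeriesSpectra, directory: str | Path) -> None:
    """Write a stack as one CSV per time point plus a ``manifest.yaml``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (t, spec) in enumerate(zip(series.times, series.spectra)):
        name = f"spectrum_{i:04d}.csv"
        write_spectrum(spec, directory / name, format="csv")
        entries.append(
            {
                "file": name,
                "time_s": float(t),
                "pco2_percent": float(series.gas_program.pco2_at(t)),
            }
        )
    manifest = {
        "meta": dict(series.meta),
        "gas_program": {
            "duration_s": series.gas_program.duration,
            "steps": [
                {"start_s": t, "pco2_percent": p, "carrier": c}
                for t, p, c in series.gas_program.steps
            ],
        },
        "spectra": entries,
    }
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_timeseries(directory: str | Path) -> TimeSeriesSpectra:
    """Read a stack written by :func:`write_timeseries`."""
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    prog = manifest["gas_program"]
    program = GasProgram(
        steps=tuple((s["start_s"], s["pco2_percent"], s.get("carrier", "N2")) for s in prog["steps"]),
        duration=prog["duration_s"],
    )
    times = []
    spectra = []
    for entry in manifest["spectra"]:
        times.append(entry["time_s"])
        spectra.append(read_spectrum(directory / entry["file"], format="csv"))
    return TimeSeriesSpectra(np.asarray(times), spectra, program, dict(manifest.get("meta", {})))


# ---------------------------------------------------------------------------
# band library fixture
# ---------------------------------------------------------------------------


def load_band_library(path: str | Path | None = None) -> dict[str, SpeciesTemplate]:
    """Load the species band library (centers, widths, shapes, shift maps).

    With no argument the packaged default library is used.  Returns a mapping
    species name -> :class:`SpeciesTemplate` in the 12C/H2O reference state.
    """
    if path is None:
        from importlib.resources import files

        text = (files("irco2kin") / "data" / "band_library.yaml").read_text()
        data = yaml.safe_load(text)
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    templates: dict[str, SpeciesTemplate] = {}
    for name, entry in data["species"].items():
        bands = tuple(
            Band(
                center=b["center"],
                fwhm=b["fwhm"],
                amplitude=b["amplitude"],
                shape=b.get("shape", "gaussian"),
                eta=b.get("eta", 0.0),
                label=b["label"],
            )
            for b in entry["bands"]
        )
        shift_map = {k: dict(v) for k, v in entry.get("shift_map", {}).items()}
        templates[name] = SpeciesTemplate(species=name, bands=bands, shift_map=shift_map)
    return templates
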