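"""Template fitting: amplitude recovery, baselines, center refinement."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irco2kin.decomposition import (
    CollinearTemplatesError,
    decompose_spectrum,
    estimate_hydration,
    extract_traces,
)
from irco2kin.spectra_core import (
    Band,
    SpeciesTemplate,
    Spectrum,
    default_grid,
    template_profile,
)
from irco2kin.synthetic_data import (
    FilmKinetics,
    NoiseModel,
    generate_timeseries,
    shift_templates,
    simulate_film_kinetics,
)


def _render(templates, amplitudes, grid):
    y = np.zeros_like(grid)
    for name, amp in amplitudes.items():
        y += amp * template_profile(templates[name], grid)
    return y


class TestDecomposeSpectrum:
    def test_exact_linear_recovery(self, reference_templates):
        grid = default_grid()
        truth = {"CO2(aq)": 2.0, "HCO3-": 1.0, "local_water": -0.0}
        y = _render(reference_templates, {"CO2(aq)": 2.0, "HCO3-": 1.0}, grid)
        res = decompose_spectrum(Spectrum(grid, y), reference_templates, baseline_degree=0)
        assert res.amplitudes["CO2(aq)"] == pytest.approx(2.0, abs=1e-9)
        assert res.amplitudes["HCO3-"] == pytest.approx(1.0, abs=1e-9)
        assert res.residual_rms < 1e-10

    def test_baseline_absorbed_without_biasing_amplitudes(self, reference_templates):
        grid = default_grid()
        y = _render(reference_templates, {"CO2(aq)": 2.0, "HCO3-": 1.0}, grid)
        y_drift = y + 0.01 * (grid - 2000.0) / 1000.0  # linear baseline
        res = decompose_spectrum(
            Spectrum(grid, y_drift), reference_templates, baseline_degree=1
        )
        assert res.amplitudes["CO2(aq)"] == pytest.approx(2.0, abs=1e-6)
        assert res.amplitudes["HCO3-"] == pytest.approx(1.0, abs=1e-6)

    @given(
        a_co2=st.floats(-3.0, 3.0),
        a_hco3=st.floats(-3.0, 3.0),
        a_w=st.floats(-3.0, 3.0),
    )
    @settings(deadline=None, max_examples=25)
    def test_exact_recovery_any_amplitude_draw(
        self, reference_templates, a_co2, a_hco3, a_w
    ):
        grid = default_grid()
        amps = {"CO2(aq)": a_co2, "HCO3-": a_hco3, "local_water": a_w}
        y = _render(reference_templates, amps, grid)
        res = decompose_spectrum(Spectrum(grid, y), reference_templates, baseline_degree=2)
        for name, truth in amps.items():
            assert res.amplitudes[name] == pytest.approx(truth, abs=1e-6)

    def test_matches_normal_equations_oracle_on_toy_grid(self):
        # independent oracle: explicit normal equations on a 50-point grid
        rng = np.random.default_rng(7)
        grid = np.linspace(2500.0, 2302.0, 50)
        t1 = SpeciesTemplate("A", (Band(2400.0, 30.0, 1.0, "gaussian"),))
        t2 = SpeciesTemplate("B", (Band(2430.0, 40.0, 1.0, "lorentzian"),))
        templates = {"A": t1, "B": t2}
        for _ in range(20):
            amps = rng.normal(0, 2, size=2)
            y = amps[0] * template_profile(t1, grid) + amps[1] * template_profile(t2, grid)
            y += rng.normal(0, 0.01, size=grid.size)
            res = decompose_spectrum(
                Spectrum(grid, y), templates, baseline_degree=0,
                fit_windows=((2500.0, 2302.0),),
            )
            X = np.column_stack(
                [template_profile(t1, grid), template_profile(t2, grid), np.ones(grid.size)]
            )
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert res.amplitudes["A"] == pytest.approx(beta[0], abs=1e-6)
            assert res.amplitudes["B"] == pytest.approx(beta[1], abs=1e-6)

    def test_collinear_templates_error_names_pair(self):
        grid = default_grid()
        t = SpeciesTemplate("X", (Band(2341.0, 12.0, 1.0),))
        res_templates = {"X": t, "Y": replace(t, species="Y")}
        with pytest.raises(CollinearTemplatesError, match="'X' and 'Y'"):
            decompose_spectrum(Spectrum(grid, np.zeros(grid.size)), res_templates)

    def test_amplitude_error_shrinks_with_noise(self, reference_templates):
        grid = default_grid()
        y0 = _render(reference_templates, {"HCO3-": 1.0}, grid)
        rng = np.random.default_rng(0)
        errors = []
        for sigma in (0.1, 0.01, 0.001):
            errs = []
            for _ in range(5):
                y = y0 + rng.normal(0, sigma, grid.size)
                res = decompose_spectrum(Spectrum(grid, y), reference_templates)
                errs.append(abs(res.amplitudes["HCO3-"] - 1.0))
            errors.append(np.mean(errs))
        # estimator consistency: error roughly proportional to sigma
        assert errors[2] < errors[1] < errors[0]
        assert errors[2] < 0.01 * errors[0] * 50  # within a factor of a few of /100


class TestCenterRefinement:
    def _series_spectrum(self, isotopologue="12C", solvent="H2O"):
        from irco2kin.spectra_core import GasProgram

        prog = GasProgram(steps=((0.0, 0.0, "N2"), (10.0, 10.0, "CO2")), duration=130.0)
        series = generate_timeseries(
            "KsCcr_WT", FilmKinetics(), NoiseModel(sigma=0.0), prog,
            isotopologue=isotopologue, solvent=solvent,
        )
        return series.spectra[-1]

    def _offset_templates(self, band_library, isotopologue="12C", solvent="H2O", off=6.0):
        tpl = shift_templates(band_library, isotopologue, solvent)
        tpl.pop("bulk_water")
        return {
            n: replace(t, bands=tuple(replace(b, center=b.center + off) for b in t.bands))
            for n, t in tpl.items()
        }

    def test_refinement_recovers_generated_centers(self, band_library):
        spec = self._series_spectrum()
        start = self._offset_templates(band_library, off=6.0)
        res = decompose_spectrum(spec, start, refine=True)
        assert res.refine_converged
        assert res.fitted_centers[("CO2(aq)", "v3_CO2")] == pytest.approx(2341.0, abs=0.5)
        assert res.fitted_centers[("HCO3-", "v2")] == pytest.approx(1618.0, abs=0.5)
        assert res.fitted_centers[("local_water", "vOH")] == pytest.approx(3000.0, abs=0.5)

    def test_refinement_13c(self, band_library):
        spec = self._series_spectrum(isotopologue="13C")
        start = self._offset_templates(band_library, isotopologue="13C", off=-5.0)
        res = decompose_spectrum(spec, start, refine=True)
        assert res.fitted_centers[("CO2(aq)", "v3_CO2")] == pytest.approx(2278.0, abs=0.5)
        assert res.fitted_centers[("HCO3-", "v2")] == pytest.approx(1586.0, abs=0.5)

    def test_refinement_unbiased_across_presets(self, band_library):
        # noiseless data, matched starting centers: refinement must not walk
        # away from the generated centers by more than grid spacing / 4
        from irco2kin.spectra_core import GasProgram

        prog = GasProgram(steps=((0.0, 0.0, "N2"), (10.0, 10.0, "CO2")), duration=130.0)
        for preset in ("KsCcr_WT", "EcCA", "E171A"):
            series = generate_timeseries(preset, FilmKinetics(), NoiseModel(sigma=0.0), prog)
            spec = series.spectra[-1]
            tpl = shift_templates(
                band_library, water_mode="local_EcCA" if preset == "EcCA" else "local_KsCcr"
            )
            tpl.pop("bulk_water")
            if preset == "E171A":
                w = tpl["local_water"]
                tpl["local_water"] = replace(
                    w, bands=tuple(replace(b, center=3030.0) for b in w.bands)
                )
            truth = {(t.species, b.label): b.center for t in tpl.values() for b in t.bands}
            res = decompose_spectrum(spec, tpl, refine=True)
            for key, center in res.fitted_centers.items():
                assert center == pytest.approx(truth[key], abs=0.5)


class TestExtractTraces:
    def test_recovers_generator_course(
        self, step10_program, default_kinetics, reference_templates
    ):
        noise = NoiseModel(sigma=0.02, seed=3)
        series = generate_timeseries(
            "KsCcr_WT", default_kinetics, noise, step10_program
        )
        traces = extract_traces(series, reference_templates)
        conc = simulate_film_kinetics(default_kinetics, step10_program, series.times)
        from irco2kin.decomposition import DEFAULT_FIT_WINDOWS, _design, _fit_weights
        from irco2kin.spectra_core import template_area
        from irco2kin.synthetic_data import prune_to_window

        truth = conc["HCO3-"] * template_area(reference_templates["HCO3-"])
        # propagate the white noise through the weighted LSQ to get the
        # per-point area standard error, then require every point within 3 sigma
        grid = series.wavenumbers
        names = list(reference_templates)
        pruned = [prune_to_window(reference_templates[n], grid) for n in names]
        X = _design(grid, pruned, 2)
        w = _fit_weights(grid, DEFAULT_FIT_WINDOWS)
        Xw = X * np.sqrt(w)[:, None]
        cov = np.linalg.inv(Xw.T @ Xw) * noise.sigma**2
        i = names.index("HCO3-")
        se_area = np.sqrt(cov[i, i]) * template_area(pruned[i])
        assert np.all(np.abs(traces["HCO3-"].area - truth) < 3.0 * se_area)
        assert np.corrcoef(traces["HCO3-"].area, truth)[0, 1] > 0.999

    def test_all_zero_stack(self, reference_templates, noiseless, default_kinetics):
        from irco2kin.spectra_core import GasProgram

        prog = GasProgram(steps=((0.0, 0.0, "N2"),), duration=60.0)
        series = generate_timeseries("KsCcr_WT", default_kinetics, noiseless, prog)
        traces = extract_traces(series, reference_templates)
        for tr in traces.values():
            assert np.allclose(tr.area, 0.0, atol=1e-12)

    def test_noiseless_traces_exact(
        self, step10_program, default_kinetics, noiseless, reference_templates
    ):
        series = generate_timeseries("KsCcr_WT", default_kinetics, noiseless, step10_program)
        traces = extract_traces(series, reference_templates)
        from irco2kin.spectra_core import template_area

        conc = simulate_film_kinetics(default_kinetics, step10_program, series.times)
        truth = conc["HCO3-"] * template_area(reference_templates["HCO3-"])
        nz = truth != 0
        assert np.max(np.abs(traces["HCO3-"].area[nz] / truth[nz] - 1.0)) <= 1e-6
        # water trace is signed negative once hydration starts
        assert np.all(traces["local_water"].area[nz] < 0)


class TestEstimateHydration:
    def _reference(self):
        grid = default_grid()
        band = Band(3300.0, 400.0, 1.0, "gaussian", label="vOH")
        y = template_profile(SpeciesTemplate("w", (band,)), grid)
        return Spectrum(grid, y)

    def test_identity(self):
        ref = self._reference()
        assert estimate_hydration(ref, ref) == pytest.approx(1.0)

    def test_linearity(self):
        ref = self._reference()
        scaled = Spectrum(ref.wavenumbers, 0.35 * ref.absorbance)
        assert estimate_hydration(scaled, ref) == pytest.approx(0.35, abs=1e-9)

    def test_band_outside_window_ignored(self):
        ref = self._reference()
        extra = template_profile(
            SpeciesTemplate("x", (Band(1500.0, 50.0, 5.0),)), ref.wavenumbers
        )
        spec = Spectrum(ref.wavenumbers, ref.absorbance + extra)
        assert estimate_hydration(spec, ref) == pytest.approx(1.0, abs=1e-6)

    def test_zero_reference_rejected(self):
        ref = self._reference()
        zero = Spectrum(ref.wavenumbers, np.zeros(len(ref)))
        with pytest.raises(ValueError, match="zero"):
            estimate_hydration(ref, zero)

    def test_clipped_to_band(self):
        ref = self._reference()
        over = Spectrum(ref.wavenumbers, 2.5 * ref.absorbance)
        assert estimate_hydration(over, ref) == 1.5
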