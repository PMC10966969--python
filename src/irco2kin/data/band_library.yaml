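# Species band library for "CO2-N2" difference spectra.
#
# Band centers and the 13C / D2O shifts are the published assignments for
# dissolved CO2, bicarbonate and the active-site water cluster; widths,
# shapes and relative amplitudes are library choices (typical ATR-FTIR
# values), since the source spectra are not deposited in numeric form.
#
# The COH bend (v4) of bicarbonate appears as a shoulder; the literature
# discusses both 1298 and 1258 cm-1 for this feature.  1298 is carried as
# the canonical v4 center here; the 13C effect on it is minor and is set
# to zero.  In D2O the v4 mode down-shifts by ~300 cm-1, which moves it
# below the 1000 cm-1 edge of the detection window (it is pruned from the
# rendered model there).
#
# shift_map keys: isotopologue ("13C"), solvent ("D2O"), water modes
# ("local_KsCcr", "local_EcCA", "bulk"), and combined water-mode:solvent
# overrides.  All offsets are cm-1 relative to the 12C / H2O /
# local_KsCcr reference state.

species:
  CO2(aq):
    bands:
      - {label: v3_CO2, center: 2341.0, fwhm: 12.0, amplitude: 1.0, shape: pseudo_voigt, eta: 0.3}
    shift_map:
      "13C": {v3_CO2: -63.0}          # 2341 -> 2278
      "D2O": {v3_CO2: 0.0}

  HCO3-:
    bands:
      - {label: v2, center: 1618.0, fwhm: 34.0, amplitude: 1.0, shape: pseudo_voigt, eta: 0.3}
      - {label: v3, center: 1358.0, fwhm: 30.0, amplitude: 0.7, shape: pseudo_voigt, eta: 0.3}
      - {label: v4, center: 1298.0, fwhm: 26.0, amplitude: 0.35, shape: pseudo_voigt, eta: 0.3}
    shift_map:
      "13C": {v2: -32.0, v3: -36.0, v4: 0.0}   # 1618 -> 1586, 1358 -> 1322
      "D2O": {v2: 0.0, v3: 0.0, v4: -300.0}    # v4 leaves the window

  local_water:
    # strongly hydrogen-bonded active-site water cluster, consumed during
    # hydration -> broad negative band in the difference spectrum
    bands:
      - {label: vOH, center: 3000.0, fwhm: 350.0, amplitude: -1.0, shape: gaussian}
    shift_map:
      "13C": {vOH: 0.0}
      "D2O": {vOH: -720.0}             # 3000 -> 2280
      "local_KsCcr": {vOH: 0.0}
      "local_EcCA": {vOH: 50.0}        # 3050
      "bulk": {vOH: 320.0}             # 3320, uncatalysed bulk-water signature
      "local_EcCA:D2O": {vOH: -750.0}  # 3050 -> 2300

  bulk_water:
    # unspecific bulk-water disturbance used as a correction component
    bands:
      - {label: vOH_bulk, center: 3320.0, fwhm: 350.0, amplitude: -1.0, shape: gaussian}
    shift_map:
      "13C": {vOH_bulk: 0.0}
      "D2O": {vOH_bulk: -720.0}
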