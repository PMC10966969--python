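# Methods

## Spectral model

A difference spectrum is modelled as a signed linear combination of
species templates on a descending wavenumber grid (4000 → 1000 cm⁻¹ at
2 cm⁻¹; typical ATR-FTIR resolution, ~1500 points). Each template is a
set of bands with center, FWHM, peak amplitude and shape: pseudo-Voigt
with Lorentzian fraction η = 0.3 for the sharp analyte bands (CO2 and
bicarbonate), and a pure Gaussian with FWHM 350 cm⁻¹ for the broad
water feature. The published band *positions* and isotope/solvent
*shifts* are transcribed in `src/irco2kin/data/band_library.yaml`;
widths, shapes and relative amplitudes are library choices, because the
source spectra exist only as figures. The sign convention is
"CO2 − N2": species formed are positive, the consumed water cluster is
negative.

Shift maps store per-band offsets relative to the ¹²C/H2O/local-water
reference state, so condition shifting is invertible and composable
(¹³C then ¹²C restores the reference centers exactly). A band whose
shifted center leaves the detection window — the bicarbonate COH bend
in D2O, which moves ~300 cm⁻¹ down and below the 1000 cm⁻¹ edge — is
retained in the template but pruned before rendering or fitting.

The library carries both discussed positions of the bicarbonate COH
bend (1298 cm⁻¹ shoulder vs 1258 cm⁻¹); 1298 is used as the canonical
v4 center, with a zero ¹³C shift (the reported isotope effect on this
feature is minor).

## Film kinetics

The generator's kinetic model is the two-compartment linear system

    dC/dt = (K_H · pCO2(t) − C) / τ_mix        (gas exchange into the film)
    dB/dt = a · k_h · C − k_d · B              (reversible hydration)

with C dissolved CO2 (mM), B bicarbonate (mM), pCO2(t) the
piecewise-constant gas program and a = activity_scale × hydration_level.
Local-water consumption is stoichiometrically coupled: the rendered
water-loss area equals −α times the bicarbonate area at every instant
(α = 1 by default; only ratios matter downstream). Integration is
piecewise-analytic per gas step, so generator ground truth is exact; an
independent ODE-solver cross-check is part of the test suite.

Because the system is linear, B(t) is exactly proportional to
a = activity_scale at fixed k_d — this is what makes relative activities
recoverable from band areas at any evaluation time, including the 60 s
point used for condition comparisons.

Parameter defaults (the absolute apparent velocities of the source
experiment are not published, so absolute rate values are generator
choices; only ratios are treated as transcriptions):

| parameter | default | unit | meaning |
|---|---|---|---|
| k_h | 0.02 | s⁻¹ mM⁻¹ | hydration rate per unit dissolved CO2 |
| k_d | 0.01 | s⁻¹ | dehydration rate (slower than hydration) |
| K_H | 0.338 | mM per % pCO2 | film solubility (Henry-type, 33.8 mM/atm) |
| τ_mix | 5 | s | gas-exchange time constant |
| hydration_level | 1.0 | — | film humidity multiplier on k_h |
| σ (noise) | 0.02 | mOD | white measurement noise |
| dt | 5 | s | spectrum acquisition interval |

The 5 s sampling makes the "first three data points after gas exchange"
span 10 s, matching the reported early bicarbonate build-up within
15 s. Condition presets transcribe the published relative activities
(EcCA ≈ 4× wild type; E171A and H365N ≈ 50 %; crotonyl-CoA 33 %;
butyryl-CoA 17 %; BSA and the double mutant at the 30 % unspecific
background) and the water-band signatures (3050 cm⁻¹ for EcCA,
3030 cm⁻¹ for single mutants, 3320 cm⁻¹ bulk mode for the double
mutant and BSA). Note the butyryl-CoA preset (17 %) sits *below* the
30 % background line — the reported behaviour — so the preset type
deliberately does not enforce a background floor; the floor is reported
alongside relative activities instead.

## Decomposition

The linear stage solves weighted ordinary least squares for the species
amplitudes and a Legendre-polynomial baseline (default degree 2)
jointly. Fitting is restricted to 2450–2200 cm⁻¹ (CO2),
1750–1150 cm⁻¹ (bicarbonate) and 3700–2100 cm⁻¹ (water); the
amide-contaminated 1680–1620 cm⁻¹ stretch is down-weighted to 0.5.
Unspecific hydration changes are absorbed by an extra fitted component —
a bulk-water template at 3320 cm⁻¹ — plus the baseline; this mirrors the
identification of unspecific hydration by exactly that bulk-water
signature. Template pairs whose rendered profiles correlate above 0.999
inside the windows raise a collinearity error naming the pair (e.g. a
bulk-mode local-water template together with the unspecific component);
the caller then drops one of them.

Center refinement is bounded (±25 cm⁻¹) nonlinear least squares on the
per-band center offsets via variable projection: amplitudes are
re-solved linearly at every trial, starting from the linear solution
(single start, first local optimum). If the optimiser fails, the linear
answer is kept and flagged. Band widths are held fixed at the library
values at all time points.

The per-species peak area is amplitude × template area (the bicarbonate
trace is thus the v2 + v3 + v4 sum by construction). Film hydration is
estimated as the OH-stretch (3700–2800 cm⁻¹) area ratio against a
fully hydrated reference, clipped to [0, 1.5].

## Kinetics

Apparent initial velocities are OLS slopes over the first three
acquired points at or after each gas-switch time, regardless of mixing
lag — the data-driven reading of the initial-rate rule. Dehydration
velocities are computed identically after CO2 → N2 switches and
reported as magnitudes. Consequences of this estimator under the
default conditions, quantified in the tests: the τ_mix = 5 s lag
attenuates all apparent velocities by a common factor (ratios and
linearity are unaffected), and residual bicarbonate surviving a 100 s
N2 purge biases sequential-titration velocities by a few percent.
Absolute recovery of k_h·K_H to within 5 % therefore holds in the
fast-mixing, fully-purged regime, while the standard five-step program
still yields velocity-vs-pCO2 linearity with r² > 0.999 and an
intercept consistent with zero.

The calibration converts areas to mM via a least-squares slope through
the origin over carbonate reference samples, and the pCO2–bicarbonate
correlation is fitted as the saturating form c(p) = c_max(1 − e^(−p/p0))
— an exponential-saturation choice satisfying c(0) = 0; the specific
functional form is a package decision, as only the qualitative
exponential character of the correlation is reported.

## Solution chemistry

Speciation treats the carbonate system as closed (total dissolved
inorganic carbon fixed): given DIC, a monoprotic buffer and a net
strong-ion concentration, the pH solves the charge balance
[H⁺] + Z = [OH⁻] + [HCO3⁻] + [A⁻] by bisection on pH ∈ [0, 14]
(residual < 1e-10 M). CO3²⁻ is neglected, valid below pH ≈ 9.
Constants (25 °C standard values, in `solution_chemistry.py`): Henry
coefficient 33.8 mM/atm, pKa1 = 6.35, pKw = 14.0, k_uncat = 0.037 s⁻¹,
bromothymol blue pKa = 7.1.

The colorimetric-assay simulator integrates the slow reversible
hydration (reverse constant from microscopic reversibility,
k_rev = k_uncat/Ka1) with all acid–base equilibria instantaneous:
protonation is orders of magnitude faster than hydration, so the pH at
each instant follows from the charge balance at the current CO2/HCO3⁻
partition, with bicarbonate a kinetically fixed anion. Catalysis is a
single enhancement factor F on both directions, which rescales time
exactly — hence U = T_blank/T_cat − 1 = F − 1 in the hydration-limited
regime. Default assay conditions (generic, since the source assay's
exact concentrations are not published): 20 mM pKa-8.1 buffer, 33.8 mM
injected CO2 (CO2-saturated water), pH 8.3 → 6.3. The blank reaches
threshold in ≈ 13 s with the room-temperature k_uncat; classical
ice-bath implementations run slower, but only time ratios matter.

## Occupancy

Binding free energy: ΔG = −ln(c_site/c_bulk) in k_BT, with
concentrations from time-averaged molecule counts inside / outside an
axis-aligned region after wrapping coordinates into the primary
periodic image; region bounds are half-open (min ≤ x < max) so boundary
counts are deterministic. Errors are the standard error of per-block ΔG
over 5 contiguous blocks. The generator samples positions i.i.d. per
frame from the two-region Boltzmann density (site weight e^w), so the
imposed ΔG is exactly −w; recovery within 3 block-SE over 2×10⁴ frames
is part of the acceptance suite.

Binding sites: all samples are histogrammed at 0.1 nm cells (periodic),
Gaussian-smoothed with σ = 1 cell, and peaks are local maxima of the
smoothed density above mean + 3 SD of the *raw* cell counts. Thresholding
on raw-count statistics while peak-picking on the smoothed grid is what
lets a uniform trajectory produce zero peaks (smoothing suppresses the
Poisson fluctuations far below the raw 3 SD line) while genuine wells
stand orders of magnitude above it.

## What the synthetic data does and does not show

The generators reproduce the *statistical structure* the analysis
assumes: linear band superposition, exact pseudo-first-order film
kinetics, white noise, polynomial drift, an i.i.d. two-region
Boltzmann density. Passing tests therefore demonstrate that the
pipeline recovers known ground truth under its own model assumptions —
estimator correctness, not instrument fidelity. Real measurements add
effects deliberately out of scope: atmospheric water-vapour lines,
band-shape temperature dependence, film swelling, detector drift that
is not polynomial, correlated MD frames (the i.i.d. trajectory makes
block errors optimistic relative to autocorrelated data), and protein
amide backgrounds beyond the down-weighted window.

## Numerical choices and degenerate inputs

- Piecewise-analytic kinetics integration handles the τ_mix → 0 and
  k_d → 0 limits and the k_d = 1/τ_mix degeneracy explicitly.
- Refinement tie-break: first local optimum from the linear start, no
  multistart; bounds ±25 cm⁻¹.
- All-zero stacks decompose to all-zero traces; failed per-spectrum
  fits mark the time point NaN and are logged, never dropped silently.
- Speciation bisection runs to interval width 1e-15 pH, far past the
  1e-10 M residual requirement; absence of a sign change in [0, 14]
  raises.
- Zero injected CO2 in the assay yields a flagged, infinite
  time-to-threshold rather than an error.
- JCAMP-DX support is limited to the (X++(Y..Y)) AFFN dialect;
  compressed ordinate forms are rejected with a clear message.

## Problem sizes

Default test and acceptance workloads are desk-scale: ~1500-point
grids, stacks of 26–211 spectra, 2×10⁴-frame/20-molecule trajectories,
100-draw property suites. These sizes give sampling errors comfortably
inside the asserted tolerances while keeping the full suite around half
a minute.
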