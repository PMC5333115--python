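# Methods

This note records the models, conventions and numerical choices behind
chirokit, and what its synthetic validation does and does not demonstrate.

## The dissymmetry-factor model of ee

The analysis rests on a linear detector model for a co-eluting enantiomer
pair at a single detection wavelength λ (default 250 nm):

* UV absorbance: A(t) = k·(c_R + c_S)·p(t), with p(t) the elution profile;
* ECD: ΔA(t) = k·g_pure·(c_R − c_S)·p(t), with g_pure the dissymmetry
  factor of the pure reference enantiomer.

Integrating both channels over the same bounds and forming
g = (θ/32980)/(A_mAU/1000) cancels k, the injected amount and the profile,
leaving g_mix = ee·g_pure. The two unit constants (32980 mdeg per ΔA unit,
the standard small-angle ellipticity relation, and 1000 mAU/AU) are
configurable on `compute_g_factor`; they cancel in every ee estimate, so
they matter only if g values are compared across instruments. No numeric g
is published for the reference compound, so the package never asserts an
absolute g scale — only ratios.

Assumptions worth keeping in mind: both detectors see the same eluate
(time alignment is taken as exact), the response is in each detector's
linear range, and the substrate is achiral (ECD-silent). `estimate_ee`
treats |g_mix/g_pure| up to 1.05 as measurement scatter (clipped to 1 with
a warning) and beyond that as an inconsistent reference.

The racemic floor (default 0.005, i.e. 0.5% ee) is the band inside which no
dominant-configuration call is made; it sits below realistic detector
precision, so a "racemic" verdict means "indistinguishable from racemic at
this noise level", not exactly 50:50.

## Conversion ratio

CR = 100·(P/f)/((P/f) + S) from the UV areas P (product) and S (substrate),
with an optional product-to-substrate response factor f (default 1). This
is plain area-percent at one wavelength: it assumes the two species'
absorptivities at λ are equal (or corrected by f) and that no other
UV-active species elutes in the assigned windows. Absolute quantitation
(mg/mL) is out of scope.

## Peak detection and integration

Peaks are found on the baseline-corrected UV channel with SciPy's
prominence-based finder; an optional moving-average smoothing (odd window,
default off) is applied for apex finding only — areas are always computed
on raw data. Integration bounds walk outward from the apex to the first
point below `bound_threshold_rel` (default 10⁻³) of the apex height, capped
at the prominence bases. Because the cutoff is relative, the truncated tail
fraction is scale-invariant, which is what makes the g-factor exactly
concentration-independent in the noise-free round trip.

Two baseline models: `linear-endpoints` (chord through the window's own
endpoints; exact for flat and linearly drifting baselines, and linear in
the signal, so integration is a linear functional) and `rolling-minimum`
(running-minimum filter over ~5% of the trace, for non-linear drift; not a
linear operation, so the linearity property applies only to the default
mode). The ECD channel is always integrated over the UV-determined bounds:
the ECD trace of a near-racemic sample crosses zero under a perfectly good
peak, so its own "bounds" would be meaningless. Areas are trapezoid sums on
the raw uniform grid (no resampling), time in minutes, areas in signal·min.

## ECD simulation and configuration assignment

Per conformer, each electronic transition (Eᵢ in eV, Rᵢ in 10⁻⁴⁰ cgs)
contributes a Gaussian band; the spectrum in Δε (L·mol⁻¹·cm⁻¹) is

Δε(E) = 1/(2.297·10⁻³⁹·√π·σ) · Σᵢ Eᵢ·Rᵢ·10⁻⁴⁰·exp(−((E−Eᵢ)/σ)²)

evaluated pointwise on a wavelength grid via E = 1239.842/λ. Conventions
adopted (each configurable or documented because upstream sources vary):

* σ = 0.35 eV is the Gaussian σ in the exponent — not a FWHM;
* the prefactor is the common Δε band-shape normalization, under which the
  integral of a single band over E equals Eᵢ·Rᵢ·10⁻⁴⁰/2.297·10⁻³⁹ — the
  identity the band-area oracle test checks to 0.5%;
* conformer spectra are Boltzmann-averaged from relative energies in
  kcal/mol at 298.15 K (k_B = 0.0019872 kcal·mol⁻¹·K⁻¹), with energies
  shifted by their minimum before exponentiation (underflow-safe, weight-
  preserving). Which electronic energies (SCF vs free) to feed in is the
  caller's choice; the temperature is a parameter.

The R/S call compares only the **sign** of the experimental Cotton effect
with the simulated-R spectrum at one wavelength, so it is independent of
the prefactor convention. A call is refused (indeterminate) when the
simulated amplitude there is below max(absolute floor, 1% of the spectrum
maximum) — a sign read off a near-node wavelength would be noise.
Oscillator strengths are carried through I/O but not convolved; UV spectrum
simulation is out of scope.

## Orthogonal-array range analysis

`build_L9` returns the standard L9(3⁴) array; columns A/B/C carry catalyst
loading (5/10/20 mol %), temperature (−10/0/10 °C) and time (8/16/24 h),
and the fourth column is retained internally as an error column but
excluded from reports. Level means M and ranges R are computed at full
precision; rounding (half-up, 2 decimals) is display-only, and R is always
computed from unrounded M — rounded-M arithmetic visibly corrupts the
second decimal of small ranges. Responses are aligned to the design by
their level columns (multiset match), so run order is immaterial. Ties are
resolved deterministically and flagged: tied R keeps factor declaration
order, tied M picks the lowest level. "Higher is better" is assumed for
both responses (maximize CR and OP). The packaged nine-run response table
is instrument data shipped as a fixture; the reported optical purity is
interpreted as ee% of the dominant enantiomer (the table's 86–94% values
are also consistent with a dominant-fraction reading; only the
interpretation label changes, not the arithmetic).

## Synthetic data: what it emulates, and what it does not

The generator produces the two measurement regimes: an achiral column
(substrate peak + single product peak carrying ECD ∝ c_R − c_S) and a
chiral column (resolved R/S product peaks near 24/29 min with mirror ECD
signs). Peak profiles are unit-area Gaussians, optionally exponentially
modified (tail constant τ); `uv_response` is therefore an **area** response
(mAU·min per concentration unit), which makes conversion-ratio ground truth
exact for any peak shape. Noise is multiplicative per point and channel
(relative σ, default 0); drift is a linear baseline on the UV channel. The
defaults — g_pure = 5·10⁻³ (a typical magnitude for an allowed/partially
allowed organic chromophore), 1% noise in the noise studies, total
concentration 1 in arbitrary units — define the standard validation
conditions used throughout the tests.

Not emulated: retention modeling, gradient elution, detector saturation,
wavelength-dependent response, chemical interferents, and — deliberately —
additive ECD noise. The last point matters for interpreting one validation
result: with purely multiplicative noise a racemate's ECD trace is exactly
zero, so the "racemate g at the noise floor" check demonstrates that the
*pipeline* adds no spurious dissymmetry, not that a real detector's
additive dark noise vanishes. Passing the synthetic suite shows the
estimators are exact under their own model and robust at 1% relative
noise; it cannot certify real-instrument accuracy.

## Validation problem sizes and numerical tolerances

The noise study uses 50 replicates of the 11-point composition grid
(f_R = 0, 0.1, …, 1) plus 50 racemate injections, each a 10-minute
chromatogram at 0.005-minute steps — small enough to run in seconds while
leaving the mean |ee error| estimate stable to well under its 0.02
acceptance bound (observed ≈ 8·10⁻⁴). Concentration invariance uses five
noise-free injections spanning 10× (CV observed ≈ 10⁻¹⁶ against a 10⁻⁶
bound). The band-shape oracle integrates a 180–400 nm grid at 0.1 nm
(±5σ coverage in energy). Grid-refinement stability holds exactly because
the band formula is evaluated pointwise, never discretized.

## Known limitations

* Overlapping-peak deconvolution is not attempted; quantitation assumes
  baseline-resolved peaks (bounds are capped at inter-peak valleys).
* The ee model presumes a validated linear range; `check_linearity` and
  `g_concentration_invariance` are the provided gates, but the package
  cannot know a real detector's range by itself.
* The L9 module handles exactly the 3-level, ≤4-factor design (no ANOVA,
  SN ratios or interactions).
* Configuration calls inherit whatever error the upstream quantum-chemistry
  transition tables carry; the significance floor guards against weak
  simulated bands, not against a wrong simulation.
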