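# Methods

This note records the models, conventions and design choices behind `susi`,
in the spirit of a methods appendix: what is computed, under which
assumptions, and what the simulation-based validation does and does not
demonstrate.

## Coordinate and unit conventions

RF volumes are indexed (axial sample, lateral line, elevational slice), with
sample 0 nearest the transducer.  All depths are one-way distances obtained
by halving round-trip times.  Frequencies are MHz, distances mm (µm for
scatterer radii and grid spacings), times seconds, sound speeds m/s, and the
attenuation coefficient dB/(cm·MHz); conversions (notably the cm in α)
happen inside the functions, never at call sites.  The on-disk container is
a directory with a JSON metadata file and one little-endian float32 raw
array per slice, one contiguous A-line after another (axial-fastest), so a
round trip is bit-exact at 32-bit precision.

## Bulk acoustics

**Thickness and speed of sound** use the substitution method with four
round-trip times — construct top `t_top`, bottom `t_bot`, the gel-pad
reflector under the specimen `t_gel`, and the same reflector without the
specimen `t_ref`:

    L   = c_f · [(t_ref − t_gel) + (t_bot − t_top)] / 2
    c_t = 2L / (t_bot − t_top)

with the fluid speed `c_f = 1480 m/s` (culture medium at room temperature).
These forms satisfy the identities `2L/c_t = t_bot − t_top` and
`2L/c_f = (t_ref − t_gel) + (t_bot − t_top)` exactly, and are exact to
machine precision on analytically constructed times.

Surface times come from envelope peaks: per A-line, peaks above a threshold
(default −18 dB re the line maximum, minimum separation 0.12 µs) are
classified first → top, last → gel pad, strongest interior → bottom, each
refined to sub-sample precision by parabolic interpolation of the envelope.
The peak (rather than the threshold crossing itself) is used because it is
pulse-shape independent to first order.  Lines without three distinct echoes
are flagged and excluded; aggregation is by median for robustness to
dropouts.

**Attenuation** is the insertion loss of the gel-pad echo,
`α(f) = 20·log10(|A₀(f)|/|A(f)|) / (2L)` in dB/cm with the round-trip path
`2L` in cm, fitted linearly over 20–55 MHz to give the coefficient in
dB/(cm·MHz).  The echo windows are Hamming-tapered and deliberately long
(eight pulse durations) so that taper-induced spectral smoothing does not
flatten the ratio: with short gates the Gaussian echo spectra are convolved
with the window kernel, which shrinks the fitted slope by roughly
σ²/(σ² + σ_w²) (≈5% at three pulse durations, <1% at eight).

**Construct volume** is the serial-contour estimate: per B-mode slice the
largest connected region brighter than a threshold (default 30 dB below the
slice maximum) is polygonized and the volume is the rectangular rule
Σ areaᵢ × slice spacing (a trapezoidal flag exists).  Before thresholding,
everything below the specimen (the gel-pad band) is cropped using the
detected surface times, and the mask is filled per A-line between its first
and last bright pixel, so constructs whose interior speckle is dim at low
cell density are still segmented as solid cross-sections bounded by their
surface echoes.  On synthetic cylinders the estimate converges to the
analytic volume as the slice spacing shrinks; at 200 µm spacing the error is
≈1%.

## Spectral model and inversion

Windows of 32 carrier periods (≈0.58 µs at 55 MHz), 50% overlap,
Hamming-tapered, slide between the detected surfaces with a 0.1 mm one-way
margin; periodograms are averaged over groups of 5 adjacent A-lines before
regression to stabilise the fit (window count and grouping are
configurable).  The reference spectrum is the line-averaged periodogram of
the gel-pad echo of the reference scan, and the analysis band is its −9 dB
span — taken from the reference, not the sample, so the band choice cannot
couple to the estimand.

The expected calibrated spectrum of identical spherical scatterers
(radius `a` µm, sound speed `c` m/s, concentration `C` mm⁻³, impedance
contrast `Q`) is modelled as

    S(f) = E + 10·log10(C Q² a⁶) + 10·n·log10(f) − (10/ln10)·φ(f),
    φ(f) = 0.827 · (2π f a / c)²

i.e. a frequency power law of exponent `n` (4 for small spheres — Rayleigh
geometry; configurable) times the Gaussian form factor.  Because `φ` is
quadratic in `f`, the OLS line over any symmetric band has slope
`−2κ f_c a²` exactly (κ = (10/ln10)·0.827·(2π/c)²), and the `log f` term
contributes the closed-form OLS slope of `ln f` over the band.  The radius
inversion is the exact algebraic inverse of this forward map; slopes steeper
than the zero-radius system slope give a negative radicand and are flagged
non-physical (NaN) and *excluded* from statistics rather than clipped, which
would bias means.  The MBF of the OLS line equals the band mean of the
model, giving the closed-form `CQ²` inversion (band mean of `f²` is
`f_c² + b²/12`).

`f_c` everywhere denotes the centre of the measured analysis band, which for
the nominal 20–75 MHz transducer band is ≈47.5 MHz, not the 55 MHz carrier.

**The shape/system constant E** absorbs beam geometry, gate length, taper
power and the reference reflectivity.  It is computed analytically from the
shot-noise expectation of the windowed periodogram,

    E_lin = (4π/3)² · 10⁻¹⁸ · S_beam · (c_t·dt/2) · Σw² / (A_ref² · w_peak²)

(beam-tube cross-section `S_beam` in mm², per-sample gate length in mm,
Hamming window `w`, reference echo amplitude `A_ref`); an empirical one-run
calibration against a specimen of known `CQ²` and radius
(`spectral.calibrate_shape_parameter`) is provided as an alternative and
agrees with the analytic value to within ~0.1 dB.

**Attenuation correction** is `m = m' + 2αz`, `MBF = MBF' + 2αz·f_c` with
`z` the window-centre depth below the construct top (one-way, cm).  For the
construct-level "ensemble" estimate each window's spectrum is compensated
exactly per frequency (+2αz·f dB), linear powers are averaged over all
windows, and one regression/inversion is performed.  The ensemble route
pools the full scatterer population and is the preferred estimator at low
number concentration, where single windows hold fewer than a handful of
scatterers; per-window estimates feed the parametric maps and the ROI
statistics (0.6 mm × 5.0 mm × thickness elements, ⌊600/31⌋ = 19 lines wide).

**Impedance and calcium.**  `Q = (ρᵢcᵢ − ρc)/(ρc)` with ECM density/speed
`ρ, c` and scatterer values `ρᵢ, cᵢ`.  Deposited mineral is modelled as a
density increment of the scatterer at constant sound speed and volume
`Vᵢ = (4/3)πa³`, giving

    Qᵢ − Q₀ = Δρ·cᵢ/(ρc),  Δρ = M/(Nᵢ·Vᵢ)   ⇒   M = Nᵢ·Vᵢ·ρc·(Qᵢ − Q₀)/cᵢ .

Forward (mass → impedance) and inverse are exact algebraic counterparts.  A
measured `Qᵢ < Q₀` reports zero mass with a warning; negative masses are
never emitted.  Estimating `Q` requires the number concentration (here from
the configured cell count, experimentally from DNA quantification); this is
a genuine limitation of the method, not of the implementation.

## The simulator

The forward model deliberately shares the inversion's model family so that
recovery is exact in expectation; model-mismatch studies are out of scope.
Per A-line, scatterers are Poisson-placed in an effective beam tube (default
diameter `2·√(λ·DOF/2π)` ≈ 160 µm from the Gaussian-beam relation, tied to
the 1.5 mm depth of focus), each echoing a Gaussian-envelope pulse
(spectral peak at 55 MHz, −6 dB power width equal to the 55 MHz nominal
bandwidth) scaled by `Q·(4/3)πa³` and filtered in amplitude by
`f^(n/2)·exp(−φ/2)`.  Attenuation multiplies each echo by
`10^(−α·f·d/20)` over its round-trip in-sample path `d`.  Specular top,
bottom and gel-pad echoes use the raw pulse (no form factor); interface
transmission losses are frequency-flat and omitted, which shifts only
intercepts, never fitted slopes.  Synthesis is exact in the frequency
domain (sub-sample delays), and additive white Gaussian noise is scaled to a
configurable SNR (default 30 dB) relative to the analytically expected
diffuse backscatter power.  A single integer seed expands into per-A-line
substreams keyed by (slice, line), so results are independent of generation
order.

What the simulator does *not* emulate: diffraction and depth-dependent beam
width (a single effective tube is used), laterally correlated speckle
(adjacent A-lines are independent realizations, which makes 5-line spectral
averaging more effective than it would be on real data), non-Gaussian form
factors, polydisperse scatterer populations, and electronic/system noise
colour.  Passing recovery tests therefore demonstrates the correctness and
self-consistency of the estimation chain — windowing, calibration,
regression, attenuation compensation, closed-form inversions — not
robustness to the model mismatch present in real tissue.

## Validation conditions

The recovery studies fix: bead phantoms of 6/10/16/25 µm diameter at
C = 1000 /mm³, Q = 0.6, α = 0.5 dB/(cm·MHz), 2 mm thickness; cell-scale
constructs of 14 µm at 2×10⁶ /ml (day-0 attenuation 0.1 dB/(cm·MHz), matrix
at 1520 m/s); a concentration series at 0.5/1/2/5 ×10⁶ /ml with known
Q = 0.6; and a 4-day mineralizing timecourse whose volume compacts to ≈27%
of day 1 (10.2 → 2.75 mm³ at desk scale), loses 60% of its cells over the
first week, and deposits ≈40 µg/ml of calcium by day 21
(Q: 0.6 → 0.77), with attenuation rising 0.1 → 0.5 dB/(cm·MHz) and sound
speed 1510 → 1540 m/s.  Scan sizes (120 lines × 1 slice for single-specimen
studies, 126 × 20 for the timecourse, 10 seeds per quantity) are chosen so
each pooled estimate rests on ≳200 analysis windows while a full validation
pass stays in the minutes range on one CPU.

## Known numerical behaviours

* The largest beads (25 µm) are mildly underestimated (≈6%): their Gaussian
  form factor falls >40 dB across the upper analysis band, so the noise
  floor flattens the measured slope there.  This is the expected physics of
  a fixed −9 dB band, within the 15% validation tolerance.
* Per-window `CQ²` medians sit a few percent below truth (log-domain
  averaging of speckle); the ensemble estimator is unbiased to ~1% and is
  what the headline concentration/impedance numbers use.
* Degenerate inputs are defined, not fatal: all-zero B-mode slices map to a
  uniform floor; zero concentration yields interface-echo-only traces with
  zero derived noise; empty ROIs and windowless groups are logged and
  skipped; `t_gel ≤ t_bot` and negative depths raise errors.
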