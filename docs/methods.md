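# Methods

This note records the models behind each module, the defaults and why
they were chosen, the numerical choices that matter, and what the
package's synthetic inputs do and do not establish about real hardware.

## Lens design

The Fresnel half-wavelength-band construction places boundary n at
`r_n = sqrt(n λ F + (n λ/2)^2)`, the exact solution of
`sqrt(r_n² + F²) = F + n λ/2`.  The central circle and every other
annulus transmit; the intervening zones are blocked by air cavities whose
large impedance mismatch reflects essentially all incident energy, so the
source is modelled as binary (unit normal velocity on transmitting
annuli, zero elsewhere).

Defaults: focal length 5 mm, frequency 20.7 MHz (the 9th thickness-mode
harmonic of a 1 mm piezoelectric plate), 11 boundaries (six transmitting
regions).  The design sound speed defaults to 1465 m/s — a
room-temperature water value.  The device whose dimensions ship in the
tests was evidently designed near this speed: over 1460–1470 m/s the
computed radii stay within 3 µm of its printed values, with the residual
~2 µm offset attributable to rounding in the published table.  Radii are
kept at full precision internally and rounded to µm only for display.

The quarter-wave matching layer (`c/(4f)`, 26 µm for the polymer coating
at 2153 m/s) is treated as perfectly transmitting in the field model; its
job is to remove the plate/medium mismatch, and residual transmission
ripple is far below the model's other approximations.

## Field simulation

The propagator is linear scalar diffraction in an axisymmetric geometry —
appropriate because the quantities of interest (focal position, −3 dB
widths, attenuated peak pressure) are diffraction- and
attenuation-dominated.  Nonlinear steepening, shear conversion and
thermal diffusion are out of scope.

**Angular-spectrum path (default).**  For a uniform velocity source over
annuli the zeroth-order Hankel spectrum is closed-form,
`A(kr) = Σ [r_out J1(kr r_out) − r_in J1(kr r_in)]/kr`, so no numerical
forward transform is needed.  The pressure spectrum of a velocity source
carries the obliquity factor k/kz.  The inverse transform is integrated
with a composite Gauss–Legendre rule in θ where `kr = Re(k) sin θ`
(default ~6000 nodes): the substitution cancels the 1/kz endpoint
singularity analytically.  The evanescent branch `kr > Re(k)` is included
through a second node set mapped as `κ = k x²` (256 nodes), which matters
within a few wavelengths of the source; with it the propagator matches
the exact on-axis piston solution `|p| = 2|sin((k/2)(√(a²+z²) − z))|` to
machine precision, and a 1 % agreement bound is asserted in the tests.
Near the branch point `k² − kr²` is evaluated as `(k² − k_re²) − q` with
`q = kr² − k_re²` carried in closed form, avoiding catastrophic
cancellation.

**Direct Rayleigh–Sommerfeld path.**  A separate quadrature of the first
Rayleigh integral over the source area (radial midpoint nodes at ~λ/6,
Gauss nodes in azimuth) provides an independent route; the two agree to
<1 % and the cross-check is a test.

**Layered media.**  Plane layers are handled by continuing each spectral
component with the local `kz = sqrt(k_l² − kr²)`, `k_l = 2πf/c_l + iα_l`.
Interface reflection/transmission coefficients are neglected: the
gel/skin/tumor impedances differ by ≲8 %, a ≲1 % amplitude effect at
normal incidence, far below the attenuation contrasts being modelled.
Components that turn evanescent in a slower→faster transition decay
naturally through the complex square root.  The absolute scale is set by
calibration: the source amplitude is chosen so the all-gel ("free-field")
configuration reproduces a measured focal pressure, default 4.53 MPa,
which is interpreted as a pressure amplitude.

Media presets (density kg/m³, speed m/s, attenuation Np/mm): coupling
gel/water 1000/1480/0.110, mouse skin 1060/1558/1.091, B16F10 tumor
1060/1521/0.321.  These are measured/literature values for the
subcutaneous melanoma geometry; user overrides construct new `Medium`
objects rather than mutating presets.  Skin-thickness sweeps default to
0.4–1.5 mm.

**Geometry.**  z = 0 at the transducer face, +z toward the target; the
gel gap spans the transducer-to-skin standoff D, skin spans its
thickness, tumor is semi-infinite beyond.  The aperture is bounded at the
outermost transmitting radius (~2.01 mm); the electrode area beyond it is
covered by the outermost air-cavity ring and does not radiate.

**Grids.**  Defaults Δr = 3–4 µm (≈ λ/20) and Δz = 10 µm near the focus;
radial sampling coarser than λ/4 is refused outright.  These defaults
resolve the ~96 µm focal spot with >20 samples while keeping a full
r–z map under a second of compute.

**Beam metrics.**  Focal position is refined with a three-point parabolic
fit; widths are full widths at a threshold crossing found by linear
interpolation.  The default convention is **half-power** (crossing at
peak/√2 of the amplitude, i.e. the intensity FWHM / −3 dB width), the
convention under which the simulated water-field metrics reproduce the
device's published simulated focal size (96 µm) and depth (790 µm); a
`half_amplitude` (−6 dB) option is provided, and for this aperture the
two differ by the Airy-pattern factor ≈1.37.

**Energy diagnostic.**  `axial_power_flux` integrates
`2π ∫ ½ Re(p vz*) r dr` with vz reconstructed spectrally.  It reports the
power of the beam within a declared angular aperture (default 60°,
comfortably containing the ~22° focusing cone) through a window that
grows with z, because the hard-edged source also radiates a weak
near-grazing tail that legitimately leaves any finite window.  With zero
attenuation the flux at z = 1, 3, 5 mm agrees to well under 2 %,
asserting the propagator neither gains nor loses energy.

## Dosimetry

`I_SPPA = p²/(2ρc)` converted to W/cm²; `I_SPTA = I_SPPA × duty cycle`
with the treatment pulse defaulting to 60 Hz PRF × 1.45 ms = 0.087 duty
cycle (kept at full precision); `MI = p_neg[MPa]/√(f[MHz])` with the peak
negative pressure taken equal to the simulated amplitude (linear model).
The plane-wave intensity relation applied at the focus reproduces the
device's four published intensity figures from its published pressures
and media to <0.5 %.

CEM43 uses the standard piecewise rate constants R = 0.25 (T < 43 °C)
and 0.5 (T ≥ 43 °C); time series are integrated per interval with the
interval-mean temperature, which makes the metric exactly additive for
records that are continuous at the junction.  At treatment skin
temperatures (≤35.6 °C) an 11.5 min exposure accumulates ~24 ms — five
orders of magnitude below the ≥ minutes-scale doses associated with
thermal damage.

Safety comparisons use the FDA diagnostic-ultrasound limits (I_SPPA
190 W/cm², I_SPTA 0.720 W/cm², MI 1.9) as configurable defaults, with a
strict-less pass convention (a value equal to the limit fails) and a
qualitative category: within a factor of two of the limit is "close",
otherwise "much higher"/"much lower".

The tissue-characterization estimators implement the **substitution
method**: `α_sample = α_ref + ln(A_ref/A_sample)/d` and
`1/c_sample = 1/c_ref − Δt/d`, with Δt the arrival-time advance of the
through-sample pulse, optionally estimated by cross-correlation with
parabolic sub-sample refinement.  The exact measurement geometry of the
original tissue characterization is not published; these are the standard
through-transmission forms, and the tests verify only that they exactly
invert their own forward models.

## Scan planning

A square lattice clipped to a circle is ambiguous about lattice
placement, so three conventions ship: `centered` (default), `half-offset`
and `rows-offset`.  For the 4.8 mm / 0.3 mm protocol these give 197, 208
and 196 spots per plane; the protocol's stated 204 is not reproduced by
any natural convention (the discrepancy is documented, not hidden), so
timing calculations accept the stated spot count as an explicit input
while taking travel time from the geometric serpentine route.  Under
those protocol inputs (204 dwell stops × 6 planes, 0.4 s dwell, 2 mm/s)
the computed total is ~11.3 min against the stated ~11.5 min.

Coverage statistics model each treated spot as a cylinder (default
diameter = the measured 104 µm focal diameter, height = the 0.3 mm plane
spacing).  Because all planes share one XY pattern, unions are computed
exactly as (2-D union area, rasterized at 5 µm cells) × (union of z
intervals) — equivalent to a 3-D voxelization, which the tests verify
against a brute-force voxel oracle on a small plan.  The reference
"total treatment volume" is the scan circle extruded over the nominal
plane span ((n−1)·Δz = 1.5 mm), with spot volumes counted in full even
where they poke past it; under these conventions the default plan treats
~11 % of the target cylinder and sweeps ~42 % including travel.  The
published 12.2 %/51.0 % coverage figures rest on unstated conventions and
are therefore reproduced only in order of magnitude, not asserted.

G-code export emits a minimal RS-274 subset (G21/G90/G0/G1/G4) with
3-decimal (1 µm) coordinates and dwell in integer milliseconds; the
parser inverts the export exactly (re-export is byte-identical), and
rejects unsupported words with their line numbers.

## Synthetic inputs and their limits

The waveform/profile generators emulate the *structure* of hydrophone
measurements — gated tone bursts at the carrier repeated at the PRF with
Gaussian noise, linear pressure-vs-voltage calibration data, delayed and
attenuated pulse pairs — deterministically under a fixed seed.  They do
not emulate hydrophone spatial averaging, amplifier nonlinearity,
reverberation, or tissue heterogeneity; tests passing on them establish
the correctness of the processing (spectra, fits, estimators), not the
fidelity of any physical measurement chain.  Likewise the field model's
agreement with published simulated metrics validates the diffraction
model, not the electromechanical behaviour of a physical transducer.

## Known limitations

- Linear acoustics only: at ~4.5 MPa and 20.7 MHz some nonlinear
  steepening is expected in reality; peak positive/negative asymmetry is
  not modelled, and MI uses the linear amplitude.
- Plane parallel layers: the curved tumor surface's refraction is
  ignored; published in-tissue pressures suggest layer-dominated
  behaviour, and the sweep here reproduces them within ~7 %.
- Interface reflections neglected (≲1 % amplitude for these media).
- No bioheat model: CEM43 is evaluated on *measured or supplied*
  temperature histories, never predicted ones.
- The 204-spot lattice convention and the exact coverage-volume
  conventions of the original protocol remain open; both are surfaced as
  explicit inputs/conventions rather than silently chosen.
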