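# Methods

This package reconstructs two-dimensional shear-wave phase-velocity images
from spatiotemporal particle-velocity movies `v(z, x, t)`, of the kind
produced by acoustic-radiation-force (ARF) shear-wave elastography with
ultrafast plane-wave tracking.  It implements a slant-wavenumber method
built on the generalized Stockwell transform, a local phase velocity
imaging (LPVI) baseline, 1D dispersion estimators with viscoelastic model
fitting, quantitative map metrics, and a synthetic dispersive-wavefield
simulator that provides exact ground truth for every stage.

## The imaging problem

In a viscoelastic medium a shear wave's phase velocity depends on
frequency.  Time-of-flight methods report a bandwidth-averaged group
velocity; frequency-domain methods can report `c_ph(f)` per frequency, but
classical local-wavenumber estimators lose the spectral ridge at high
frequency, where viscous attenuation leaves little signal.  The slant
method addresses this by combining three ingredients:

1. **Generalized S-transform** (module `stockwell`).  Each trace is
   decomposed with a frequency-dependent Gaussian window of temporal
   standard deviation `sqrt(beta)/f`.  The oscillatory kernel is referenced
   to the time origin, so at a voice frequency `f0` a travelling wave
   appears in `H(z, x, tau)` as a time-localised envelope (centred at the
   arrival time) carrying the spatial phase `exp(-i k x)`.  Discretely the
   transform is an exact circular convolution with the periodised sampled
   window, evaluated per voice with FFTs; a literal O(N^2) summation
   reproduces it to ~1e-15.  Two window normalisations are provided
   (`printed`, the default, with prefactor `|f|/(2 pi beta)`, and
   `unit_area` with `|f|/sqrt(2 pi beta)`); they differ by a constant and
   all estimators use peak positions only.

2. **Slant slicing over steering group velocities** (module
   `reconstruct`).  Lines `tau = xbar/u` through the push event (`xbar` is
   lateral distance from the push line) sample `H` at a constant-time
   slant.  When `u` matches the local group velocity the slice rides the
   arrival ridge across the whole spatial window, so the windowed 2D
   spatial spectrum `Lambda(kz, kx, u)` concentrates the wave's energy at
   its local wavenumber.  Taking the element-wise maximum over the steering
   series yields `K(kz, kx)`, whose annulus-restricted peak gives
   `|k|` and `c_ph = 2 pi f0/|k|`.  The steering series
   `u_m = xbar_max/(t_max - m dt)` uses the field of view's maximum
   distance-from-push and the full record length, so the slant lines pivot
   at the push event; a window-local origin would never intersect the
   arrival ridge of windows whose travel time exceeds `window/u_min`.  The
   literal series is clamped to [0.5, 15] m/s and uniformly decimated to at
   most `max_values` entries (default 64): the envelope-alignment width in
   `u` is much coarser than the raw series spacing, so decimation changes
   nothing but cost.

3. **Annulus-restricted peak picking.**  The spectral argmax is restricted
   to `2 pi f0/c_max <= |k| <= 2 pi f0/c_min` (default 0.5-10 m/s, covering
   soft tissue), with deterministic tie-breaks (smallest `|k|`, then
   smallest `kx`) and independent 3-point parabolic sub-bin refinement per
   axis.  Wavenumbers are rad/m everywhere; the FFT's cycles/m axes are
   converted once where they are created.

LPVI (module `lpvi`) shares the window geometry, peak picker and map
assembly, but replaces the time-frequency decomposition with the plain
temporal Fourier coefficient at `f0` — making the two methods directly
comparable.  Its optional k-filter is a first-order Butterworth band-pass
on `|k|` with the band derived from a velocity interval `v0 +- dv`.

## Preprocessing for strongly attenuating media

Three conditioning steps proved essential once the simulator included
realistic viscous attenuation (hundreds to >1000 Np/m at kilohertz
frequencies), and are enabled by default in both reconstructors:

- **Push-region mute** (`preprocess.push_mute`): lateral columns within
  2.5 mm of a push line are zeroed with a 1 mm cosine roll-off.  The push
  region carries no usable tracking data in practice, and, if left in, the
  half-plane directional mask smears its near-delta footprint into a
  slowly decaying `1/x` tail that dominates the attenuated far field.  The
  mute is purely spatial: a time-gated mute was evaluated and rejected
  because its moving edge slices through the strong slow low-frequency
  packets and radiates broadband artifacts with the gate's own (fast)
  apparent velocity.  Map pixels inside muted zones are NaN-masked.

- **Directional filtering with per-frequency amplitude equalisation**
  (`preprocess.directional_filter`): left-to-right and right-to-left waves
  are separated by half-plane masking of the `(kx, f)` spectrum, with the
  `kx = 0` ridge shared half/half and a 3-bin raised-cosine transition.
  Before masking, each temporal-frequency frame is divided by its own
  smoothed lateral magnitude envelope and multiplied back afterwards: the
  masked field is then (nearly) pure phase, for which the half-plane split
  is essentially exact, and the mask's `1/x` kernel tails scale with the
  local rather than the peak amplitude.

- **Lateral equalisation of the analysed field**
  (`preprocess.equalize_lateral`): the same per-frequency envelope
  division, applied (without undoing) to the field entering the
  S-transform or the LPVI temporal spectrum.  An attenuated wave
  `exp(-(alpha + i k)x)` becomes the pure ramp `exp(-i k x)`; this removes
  two low-`|k|` biases that otherwise grow with `alpha`: the asymmetric
  amplitude tilt across an analysis window, and the dominance of
  less-attenuated neighbouring frequencies within the voice bandwidth.
  Phases — hence wavenumbers — are untouched.  Where the wave has decayed
  below the noise the equalised frame is amplified noise; those windows
  return outliers or masked pixels rather than biased values.

With two pushes, the two directional intermediate maps are averaged with
weights equal to each direction's local signal power at `f0`
(depth-averaged squared magnitude of the temporal Fourier coefficient of
the direction-filtered field).  Plain averaging — the obvious
alternative — mixes in the far-side noise estimates wherever one
direction's wave has died out; signal-power weighting reduces to the plain
mean when both directions observe the wave equally.

## The simulator and what it does (not) emulate

`synthetic.Scene` renders dual-lateral-push acquisitions by frequency-domain
superposition: every temporal frequency propagates away from each push as
`A(f) exp(i(2 pi f t - k(f) d)) exp(-alpha(f) d)` with optional cylindrical
spreading `1/sqrt(d)`, a Gaussian depth envelope centred at the focal
depth, and piecewise phase/attenuation accumulation through an optional
circular inclusion (phase-continuous at the boundary; no reflection or
mode conversion).  Dispersion laws come from the complex shear modulus:
elastic (`G* = E/3`), Kelvin-Voigt (`G* = mu + i omega eta`) and standard
linear solid (`G* = mu1(mu2 + i omega eta)/(mu1 + mu2 + i omega eta)`,
moduli converted to shear scale via `E = 3 mu` for incompressible media);
`c = omega/Re k*` and `alpha = -Im k*` with `k* = omega sqrt(rho/G*)`.
Ground truth per pixel is exact by construction.

Defaults match a high-frame-rate research acquisition: 0.154 mm pitch,
4167 Hz frame rate, 20 x 40 mm field of view, focal depth 20 mm, pushes
3 mm from the lateral edges, a Gaussian-spectrum pulse centred at 700 Hz
with 1400 Hz FWHM delayed by 2 ms, density 1000 kg/m^3 (configurable; this
value makes an 80 kPa elastic medium's nominal speed 5.16 m/s).  Additive
white Gaussian noise is calibrated against the whole-field mean square.

Not emulated: speckle-tracking noise statistics, reflections and mode
conversion at interfaces, out-of-plane propagation, transducer directivity
and push-beam shape.  Passing tests therefore demonstrate estimator
correctness under ideal dispersive propagation plus white noise, not
robustness to every artifact of real acquisitions.

## An important physical regime

A Kelvin-Voigt medium with appreciable viscosity is drastically lossy at
high frequency: for `mu = 5 kPa, eta = 2 Pa s`, `alpha` is ~360 Np/m at
400 Hz and ~1100 Np/m at 1200 Hz, i.e. one-way amplitude factors of 1e-3
to 1e-9 over the 12-22 mm between edge pushes and a centred region of
interest.  No estimator can recover what noise has irreversibly buried, so
on such scenes with finite SNR the map CV in the centre degrades at high
frequency for every method (the slant method degrades most gracefully —
this is its central comparative property, tested over seeds).  Real
tissue-mimicking phantoms behave like standard linear solids, whose
attenuation saturates (e.g. ~170 Np/m at 1.2 kHz for the SLS parameters
used in the recovery suite), which is why kilohertz imaging of such
phantoms is feasible.

## 1D dispersion and model fitting

`dispersion_2dft` extracts the per-frequency ridge of the f-k magnitude of
a depth-averaged lateral line (1.69 mm depth average at the focal depth,
~27 mm lateral segment, DC removed); `dispersion_gst_sfk` is the 1D slant
analogue and keeps the ridge detectable on lossy media where plain 2D-FT
washes out.  Both mask frequencies whose peak lacks prominence (below 3x
the row median in the velocity-band annulus) and refine parabolically.
`fit_material_model` identifies Kelvin-Voigt or SLS parameters by bounded
trust-region least squares on `c(f)`, multi-started from a log-spaced grid
(moduli ~1-100 kPa, viscosity 0.1-30 Pa s).  Identifiability note: the SLS
series spring `E1` (the high-frequency plateau) is strongly determined;
`E2` and `eta` act mostly below the relaxation corner
`(mu1 + mu2)/eta` (~250 Hz for the default phantom parameters) and carry
several-fold wider Monte-Carlo spread under curve noise.

## Numerical choices

- Window sizes round to odd sample counts (centre pixel); Tukey taper
  ratio 0.25 by default; stride 1 by default, larger strides for the
  study-scale runs below.
- Spectra are zero-padded per axis (`pad_factor`, default 4; 2.75 in the
  study-scale runs — with parabolic refinement the recovered speed changes
  by well under 1% between the two paddings).
- `beta = 1` (classical S-transform) by default; on heavily dispersive
  media `beta ~ 4` sharpens the voice's frequency resolution at the cost
  of temporal localisation, but after lateral equalisation the default is
  adequate.
- Low-frequency caveat: when the wavelength exceeds the window
  (e.g. 7 mm vs 4.47 mm at 400 Hz in the soft Kelvin-Voigt medium) the
  annulus peak sits within ~2 spectral bins of DC and the recovered speed
  carries a few-percent positive bias; this mirrors the known degradation
  of short-window local-wavenumber estimators at long wavelengths.
- All FFT work is done in single-precision complex batches for the map
  reconstructions (validated against double precision); oracles and
  1D estimators use double precision.
- Degenerate inputs are rejected with explicit errors: zero/negative
  spacings, inclusions crossing the boundary, pulse spectra beyond
  Nyquist, empty search annuli, all-zero fields with finite SNR requests.

## Problem sizes used by the test suite and the acceptance study

Unit and acceptance tests synthesise reduced scenes (typically 10-14 mm
deep, 24-30 mm wide, 70-100 ms records at native sampling; the comparative
seed study uses a 64 x 96 x 300 grid) with window strides of 2-3 samples
and 32 steering values, sizes at which every pipeline stage is exercised
end-to-end in seconds per map.  The acceptance script runs the full
default grid (130 x 260 x 417) at stride 2 with 40 steering values.  These
are the package's chosen study scales; all method parameters are otherwise
the library defaults.
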