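# Methods

## Volume-conductor model

The slice MEA set-up is idealised as three infinite planar layers: a
non-conducting substrate (the chip, conductivity σ_G, default 0) below
z = 0, homogeneous brain tissue (σ_T) for 0 < z < h, and an infinitely
thick bath (σ_S) above z = h.  Media are ohmic, real-valued and
frequency-independent; the quasi-static approximation holds at LFP and
spike frequencies, so the potential obeys Poisson's equation with
transmembrane currents as sources and can be superposed source by
source.  Potentials are referenced to zero at infinity; subtracting the
value at a reference-electrode position is a trivial post-hoc shift the
caller can apply.

Each planar conductivity jump is replaced by mirror sources scaled by
the reflection coefficient W = (σ₁−σ₂)/(σ₁+σ₂).  With two interfaces
the mirrors proliferate into a doubly infinite family; the implementation
sums the resulting geometric series:

- `moi_point_general` — point source, observation anywhere in the slice,
  arbitrary σ_G (double series in W_TG·W_TS);
- `moi_point_mea_plane` — observation on the chip plane with σ_G = 0,
  where the series collapses to one index (every chip reflection has
  W_TG = 1 and pairs with its mirror);
- `moi_line_mea_plane` — the same series for a uniform line source.  For
  observation points on the chip plane each mirror pair of image
  segments is equivalent to a pure ±2nh translation of the original
  segment with its direction preserved, which is how the images are
  built;
- `moi_point_anisotropic_mea_plane` — planar-anisotropic tissue
  (σ_Tx ≠ σ_Ty = σ_Tz).  An exact image solution requires the bath to
  share the tissue's planar anisotropy ratio α_a = σ_Tx/σ_Ty; that
  assumption is imposed internally even though a physical bath is
  isotropic.  The approximation is good for sources in the lower half of
  the slice and degrades toward the bath interface, so a warning is
  emitted for z′ > 0.8 h when α_a ≠ 1.

Line-source potentials use the analytic log-form integral of the point
kernel.  The textbook expression suffers catastrophic cancellation when
the observation point approaches the segment's axis extension; the
implementation switches between three algebraically equivalent branch
forms keyed on the axial coordinate, each well-conditioned in its
region.  Observation points on the segment itself raise a singularity
error — there is no softening radius anywhere in the package, and a
zero source–observation distance is always an error rather than a
clamped value.

### Series truncation

The series converges geometrically with ratio |W_TS|.  The default
truncation is 20 image pairs, configurable per geometry; an adaptive
mode (`n_terms="adaptive"`) adds pairs until the last pair's relative
contribution falls below 1e−12.  The n-th pair is bounded by
4|W_TS|ⁿ φ_h(2nh−h); at |W_TS| = 2/3 (tissue 0.3 S/m under saline
1.5 S/m) the 20-term truncation error is of order 1e−5 relative in the
worst case and falls below 1e−6 once |W_TS| ≲ 0.6.  The unit tests
assert the analytic tail bound against a 1000-term brute-force oracle.
The general-σ_G series keeps n_terms reflections per image family so
that at σ_G = 0, z = 0 it reduces term-for-term to the MEA-plane
formula.

### Units and conventions

SI throughout the library (m, S/m, A, V); file formats and the CLI use
µm, nA, µV with unit-suffixed column names, converted once at the I/O
boundary.  z = 0 is the chip plane, z grows into the slice; x is the
anisotropy principal axis (apical-dendrite direction).  Sources must lie
strictly inside (0, h): positions on either interface are rejected.
Line sources exist only for the isotropic σ_G = 0 case — no closed form
is available for the general-substrate or anisotropic line source, and
the package does not approximate one (split the segment into point
sources instead).

## Electrode model

Ideal point electrodes read the potential at their centre.  Real
contacts (radii ~5–15 µm) read approximately the average potential over
the exposed metal, so `disc_average` samples m points (default 100)
with uniform planar density on the disc (radius·√u polar sampling) and
averages the point-electrode model over them.  Sample points are drawn
once per contact from a fixed seed, so readings are deterministic and
the Monte-Carlo error (∝ 1/√m, about 1 % at m = 100 for sources beyond
one radius) is frozen rather than resampled per call.  Lead-field maps
(`lead_field_map`) tabulate potential per unit current over source
positions, optionally normalised to an on-centre source at 1 µm height.
The point and disc models agree within ~10 % beyond about two electrode
radii; field distortion by the metal contact itself is outside the
model.

## Compartment recordings

`CompartmentRecording` carries segment endpoints, per-compartment
transmembrane current time series and cell identifiers exported from any
multicompartment simulator (HDF5 or wide CSV).  A Kirchhoff check warns
(never aborts — simulator exports carry numeric noise) when a cell's
currents sum to more than a 1e−3 relative residual at any time step,
summed with compensated (fsum) arithmetic.  `squeeze_transform`
compresses coordinates about a pivot (default: each cell's first
compartment, the soma) to fit tall morphologies into a thin slice;
currents are untouched because the transform mimics post-simulation
repositioning, not a physical change of the cell.  `forward_matrix`
factorises the linear physics into a time-independent
electrodes × compartments matrix — point sources at axis midpoints or
line sources along the axes, point or disc electrodes in any
combination; the default is line sources with point electrodes for
morphologies, points for abstract sources.

## Kernel CSD

The estimator follows the kernel-CSD construction: M isotropic planar
Gaussian basis densities b̃_i (unit amplitude, width R defaulting to the
electrode pitch) on a grid covering the electrode hull with margin
(default 2R) at spacing R.  Sources are assumed uniform across the slice
thickness, which integrates the forward model analytically in z and
yields the arsinh image kernel.  Each basis potential is radially
symmetric, so the 2D convolution reduces to a 1D integral (the angular
integral of the displaced Gaussian is an exponentially scaled Bessel
term i0e); it is evaluated by 240-node Gauss–Legendre quadrature over
the Gaussian's ±6R support and tabulated on a dense radial grid
(≤ 4000 points, cubic spline lookup).  The electrode kernel
K = BᵀB is symmetric PSD by construction; the fit solves
(K + λI)β = V with ridge λ defaulting to 1e−5·tr(K)/n (the original
construction leaves λ open; cross-validation can replace the default by
passing an explicit λ).  A singular kernel with λ = 0 raises an error
suggesting λ > 0.  CSD maps are Σ_i b̃_i(x)·(Bβ)_i in A/m³; positive
CSD means current leaving cells (a source), and the sign convention is
asserted in tests.

`n_terms = 0` reproduces the bath-neglecting estimator (semi-infinite
slice), `n_terms = 20` the bath-corrected one.  The analytic
`image_source_ratios` explain why the difference is modest: for a
mid-slice source with W_TS = −2/3 the first image is 2/9 of the
potential but 2/81 of the 2D-Laplacian CSD — curvature decays faster
than amplitude.  `laplacian_csd` implements that traditional estimator
(−σ_T times the five-point stencil) for reference; the one-cell
boundary frame is NaN because the stencil is undefined there and
inventing one-sided values would silently bias edge estimates.

## Synthetic data

The generator module produces every input the toolkit consumes, under
the reference conditions used throughout: h = 300 µm, σ_T = 0.3 S/m,
σ_S = 1.5 S/m, and a 30 × 10 electrode grid at 103/111 µm pitch
(~3 × 1 mm²).  The stimulus waveform is a switched-on sinusoid
(default 2 nA at 50 Hz).  `make_toy_neuron` builds a ball-and-stick
cell lying parallel to the chip: the soma carries the stimulus current
and distance-weighted return currents leak along the dendrite, with all
currents snapped to a common dyadic grid (relative resolution 2⁻⁴⁰) so
per-time-step sums cancel exactly in floating point.  `make_csd_scene`
draws Gaussian CSD patches (widths 90–150 µm, amplitudes ±50–100 A/m³)
inside the electrode hull and generates matched MEA potentials through
the same depth-integrated kernel the estimator uses.

What the generator does *not* emulate: biophysical membrane dynamics,
realistic morphologies, measurement noise, electrode impedance, or CSD
profiles that violate the uniform-in-z assumption.  Passing recovery
tests therefore demonstrate the estimator's self-consistency and
spatial resolution on the reference array, not robustness to model
mismatch in real recordings.

## Problem sizes and determinism

The test suite and the acceptance script run on desk-scale problems:
closed-form evaluations, 100-instance randomized oracle comparisons,
single-snapshot kCSD fits on the 300-electrode reference array
(~500 basis sources, radial-profile tabulation makes a fit a fraction
of a second).  All randomness flows through explicitly seeded
`numpy.random.default_rng` generators; regenerating any synthetic
object with the same seed is byte-identical, and every CLI run writes a
resolved config (with seed) next to its outputs.

## Known limitations

- Four-layer geometries (e.g. a saline film between chip and slice) and
  laterally inhomogeneous conductivity have no image solution here;
  they need a numerical solver.
- The general three-layer series is only evaluated for observation
  points inside the slice (0 ≤ z ≤ h); points in the bath are rejected.
- The anisotropic formula inherits the matched-anisotropy bath
  assumption (error grows near the bath interface).
- Electrode metal is not modelled as a conductor; the disc average is
  an approximation that breaks down for sources within ~half a radius.
- kCSD output quality depends on λ and R; the defaults are sensible for
  the reference array but are not auto-tuned.
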