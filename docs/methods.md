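# Methods

## Scope and model

`sheetwave` simulates image formation in light-sheet fluorescence
microscopes at the level of scalar wave optics.  The sample is a
complex refractive-index volume n(x,y,z) (real part: refraction,
non-negative imaginary part: absorption) on a regular voxel grid; light
is a scalar complex field advanced slice by slice.  Everything the
package produces — excitation volumes, detection PSF lattices, camera
frames, adaptive-optics focus metrics — is derived from one propagation
primitive plus linear post-processing.

Assumptions inherited from the beam-propagation model (BPM):

* forward scattering only — no back-reflections, no standing waves;
* scalar fields — polarization effects (relevant for NA well above
  ~0.7 in water) are ignored;
* index contrasts are small (|m − 1| up to a few percent, the regime of
  biological tissue); the thin-phase-screen factorization degrades for
  large contrast.

## The split-step scheme

Each slice of thickness `dz` applies, symmetrically (Strang splitting,
second-order in `dz`):

1. a half diffraction step through the homogeneous reference index
   `n0`, exact (non-paraxial) angular-spectrum kernel
   `exp(i (dz/2) sqrt((n0 k0)^2 − kx² − ky²))`, `k0 = 2π/λ_vacuum`;
2. the refractive phase screen `exp(i k0 (n − n0) dz)` in real space;
3. the second half diffraction step.

`n0` is either the ambient immersion index (global mode) or the
slice-mean real index (locally re-expanded mode, the default for
heterogeneous work): re-expanding around the local mean minimizes the
phase-screen residual and keeps the scheme accurate beyond the strictly
paraxial regime.  Both choices give identical accumulated on-axis
optical path; they differ in how much of the propagation is handled by
the (exact) diffraction factor.

Units: all lengths in micrometers; wavelengths are vacuum wavelengths.

### Evanescent modes and band geometry

Transverse frequencies with `kx² + ky² > (n0 k0)²` cannot propagate;
they are zeroed by default (an orthogonal projection, keeping power
bookkeeping exact) or damped with their physical `exp(−dz κz)` decay.
A subtlety that matters for conservation tests: whether any *grid* mode
is evanescent depends on the pitch.  For `dx ≥ sqrt(2)·λ/(2n)` the whole
discrete Fourier plane lies inside the propagating circle and the
propagator is exactly unitary (measured power drift ~1e-14 over 256
steps through strongly scattering tissue).  For finer pitches the grid
corners are evanescent, and strong scattering leaks a small amount of
power (~1e-4 over 256 steps at dx = λ/2) into them, where it is
(correctly) removed.  Conservation-style tests therefore run on
evanescent-free grids; the same geometry makes the scheme exactly
reciprocal, which is the foundation of the phase-conjugation module.

### Boundaries and sampling guards

The FFT imposes periodic wrap-around; an optional super-Gaussian
absorbing frame (default 16 px) suppresses it for beams that approach
the window edge.  The propagator warns (never fails) when
`dx > λ/(2 n_max)` or `dz > dx`.

A consequence of the periodic window that test writers should know: a
field must stay well inside the window for open-boundary references
(e.g. the direct Rayleigh–Sommerfeld sum) to be meaningful.  At three
or more beam radii of clearance, the angular-spectrum step matches the
direct summation to 1e-5..1e-3; a hard-edged aperture whose diffraction
reaches the window edge does not converge to the open-boundary answer
at any tolerance worth testing.

## Input fields

All focused sources are pupil-synthesized: fill a pupil support at
`kr ≤ k0·NA`, apply the defocus phase `exp(−i kz z_focus)` and the
lateral carrier, inverse transform, normalize to unit power.  Pupil
kinds: disk (point source), annulus (Bessel), 1D slit (cylindrical
light sheet; uniform fill — apodization optional and off by default),
annulus × comb (Bessel lattice, default period 2λ/NA), plane waves and
seeded incoherent plane-wave sets (consumers average intensities).

Two pupil-edge treatments are provided and matter a great deal for
multiplexing:

* `softness`: a C² smoothstep roll-off over a stated NA fraction.
  Focal tails fall ~v^(−7/2) asymptotically, but the roll-off band of
  width `s·k0·NA` sets a real-space tail scale `2π/(s·k0·NA)` (~2-3 um
  for typical parameters) that dominates at desk-scale tile pitches.
* `gaussian_sigma`: truncated-Gaussian apodization
  `exp(−kr²/2(σ·k0·NA)²)`.  With σ = 0.25 the focal spot carries
  measured tail amplitudes below 1e-5 of peak at 5 um distance — this
  is what makes tile-exact multiplexing possible (below).  The spot is
  Gaussian rather than Airy, ~25% wider at equal NA.

## Multiplexed spatially varying PSFs

The detection model: a point emitter in the focal plane radiates an
NA-capped field, traverses the tissue between the focal plane and the
detection-side boundary, and is imaged by an idealized telecentric
system — a hard (or rolled-off) NA crop in the pupil plane followed by
aberration-free homogeneous back-propagation to each refocus plane.
The refocus medium is the immersion index, not the tissue mean.

Because the wave equation is linear, many emitters can be propagated
in one run and separated on the camera if their refocused light stays
in disjoint tiles.  The per-tile discrepancy between a multiplexed run
and independent single-source runs is *exactly* the cross-talk
interference term `2 Re(u_own* · u_leak)`; linearity itself contributes
only rounding noise (~1e-15).  Three regimes, all measured:

* hard-NA pupils: Airy tails give 1e-3..1e-2 per-tile error at 16-px
  tiles — never tile-exact;
* C² rolled-off pupils: floor ~1e-4 (vacuum) at 16-px tiles;
* truncated-Gaussian pupils (σ = NA/4): 3e-5 (vacuum), 5e-5 through a
  smoothly aberrating tissue — tile-exact at the 1e-4 level.

Medium-induced cross-talk is physics, not bookkeeping: once the
detection path is long enough (or the medium turbid enough) that a
source's scattered halo spans more than its tile, neighboring tiles
receive that light in the multiplexed run and no tiling scheme can
remove it.  The shipped equivalence checks therefore use weakly
scattering, smoothly varying media (σ_n = 0.005, correlation length
8 um, detection path ≤ ~13 um) — the aberration regime in which
light-sheet imaging operates.  Cross-talk per tile is monitored
(guard-ring energy fraction, default tolerance 1%) and reported as
per-tile flags, never silently dropped.

PSF bookkeeping: each tile stores a volumetric stack over refocus
planes spaced `dz` around the focal plane, normalized to unit 3D
integral, together with the removed integral and the mean per-plane
detected power ("transmission" ≤ the unit source power) — tissue
attenuation of the detection path rides along in these raw integrals.

### Aberration maps

Per-tile Zernike maps come from single-source runs: the exit field is
transformed to the pupil plane, the ideal defocus of the traversed
depth and the source-position carrier are divided out, the remaining
phase is unwrapped (2D quality-guided) and least-squares fit with
RMS-normalized Noll modes over 0.95 of the pupil radius.  Piston is
reported but physically meaningless; unwrap failures flag the tile.

## Image formation

Emission is fully incoherent: the emitted density is
excitation × fluorophore density, and each voxel contributes its tile's
raw PSF slice at its axial offset.  "Partially coherent" detection
means exactly this: coherent propagation per point source, incoherent
summation across sources.  Tile assignment is nearest-tile or the
bilinear blend of the four surrounding tiles (default); both are exact
linear operators implemented with zero-padded FFT convolutions that
match a direct superposition sum to 1e-10 (the criterion the whole
camera model hangs on).  Nearest and bilinear converge to each other
as the lattice refines *provided* the aberration field varies on
scales longer than the coarsest tile pitch; for aberrations finer than
the pitch, adjacent-tile PSFs are already decorrelated and the
difference saturates instead of shrinking.

The stack scan moves illumination sheet and focal plane together
(standard SPIM).  Energy accounting: total camera energy is bounded by
emitted energy times the largest raw PSF plane sum; equality requires
every emitter on the brightest plane of the brightest tile.  An
optional camera noise model (Poisson at a stated photon scale plus
Gaussian read noise) is seeded and off by default.

## Phantoms

All generators are bit-reproducible under (parameters, seed) and carry
ground truth.

* Spheres / coated spheres: anti-aliased voxelization (3³ supersampling
  of boundary voxels) by default — at 100-nm pitches the staircase is
  resolved away, at desk pitches supersampling suppresses spurious
  edge scattering.  Sphere parameters are shared with the scattering
  oracle through one spec, so phantom and oracle cannot drift apart.
* Perlin tissue: octaved 3D lattice gradient noise; the base lattice
  spacing is calibrated (0.85 autocorrelation-FWHM per cell, measured
  once) so `correlation_length` is the autocorrelation FWHM in um; the
  field is explicitly normalized so mean and std are exact.  Defaults
  n = 1.36 ± 0.03.
* Embryo: parametric — ellipsoidal eggshell (n = 1.43), cytoplasm
  (1.365) with granular octave noise, dart-throwing-placed
  non-overlapping nuclei (1.39) labeled with fluorophore; indices
  clamped to [1.33, 1.43].  It is a stand-in for a real multicellular
  geometry: statistically plausible, not anatomically derived.
* Test chart: planar bar groups at stated pixel periods, embedded at a
  stated z plane.

What a green test on these phantoms does *not* establish: real tissue
has non-Gaussian, anisotropic index statistics, organelle-scale
discrete scatterers, and absorption structure none of these generators
reproduce; conclusions about specific organisms need measured index
maps.

## Adaptive optics

The guide star is an ideal NA-capped point emitter; its field is
propagated to the entry face through the flipped slice stack,
conjugated (fully, or phase-only at equal power), and sent back.  In a
lossless medium the split-step scheme is numerically reciprocal, so
full conjugation is essentially perfect (vacuum Strehl 1.000; 2 mean
free paths deep in n = 1.36 ± 0.03 tissue, Strehl ≥ 0.9 while the
uncorrected focus is several times dimmer).  Strehl is peak intensity
over the peak of an equal-power, equal-NA vacuum focus; values are
clipped at 1.05 to absorb interpolation noise.

The shift-shift memory effect: the conjugated wavefront is translated
laterally (Fourier shift), re-propagated, and the focal intensity at
the translated target recorded; C(Δx) = I(Δx)/I(0) (peak-intensity
ratio; the full-field-correlation alternative is noted but not
implemented).  The reference is the normalized intensity-fluctuation
autocorrelation of the speckle a plane wave produces on the guide-star
plane.  Seed-averaged over 20 tissue realizations, C(Δx) tracks the
speckle autocorrelation at 4 mean free paths (max gap ≤ 0.1, measured
~0.02) and departs from it at 1 mean free path (measured gap ~0.3),
where the ballistic component keeps the shifted focus alive far beyond
the speckle scale.

Mean free path: ballistic definition — propagate plane waves through
realizations of the medium, average the transverse-mean (k⊥ = 0) field
over realizations, fit `|⟨u⟩(z)|² ∝ exp(−z/ℓs)` log-linearly.  Chosen
over cross-section bookkeeping because it applies to continuous media;
for n = 1.36 ± 0.03, correlation length 1 um, λ = 0.5 um it gives
ℓs ≈ 7.4 um (R² = 1.000), consistent with the weak-fluctuation
estimate 1/ℓs ≈ k0² σn² ℓc.  Homogeneous media report ℓs = ∞ with a
no-decay flag.

## Oracles

Implementation-independent references used by the test suite and the
`validate` subcommand:

* scalar sphere scattering: partial-wave series for a penetrable
  (optionally coated) sphere — continuity of u and du/dr at each
  interface, truncation at `x + 4x^(1/3) + 2`, coated-sphere shell mix
  in cross-multiplied form (no division by core Bessel zeros).  The
  scalar series is the right reference for a scalar engine; against
  vector Mie both would differ at high NA.  BPM vs series at the
  committed scenario (r = 2.5 um, Δn = 0.05): 1.25% relative L2,
  error monotone in Δn.
* The coated-sphere far-field check compares angularly binned BPM
  scattering intensity with the series below 0.5 rad as a relative L2
  (3.5% measured); pointwise relative error is unbounded at the deep
  phase-function nulls and is not a meaningful metric there.
* Fresnel knife edge: closed form via scipy's Fresnel integrals; exact
  limits I(0) = 1/4, lit-side → 1.  The closed form is paraxial, so
  the 2% BPM comparison is made over the main fringe region
  (|x| ≲ 4 Fresnel-zone units); at 45° observation angles the paraxial
  curve itself is wrong by ~0.1 and the comparison would test the
  reference, not the propagator.
* Direct Rayleigh–Sommerfeld summation (O(N⁴), ≤ 64² grids), Gaussian
  beam closed forms, scalar lateral (0.514 λ/NA) and axial
  (1.772 nλ/NA²) focus widths, and a sequential (non-multiplexed)
  PSF path sharing no tiling code with the PSF engine.

## Numerical choices

* float64/complex128 throughout; FFTs via scipy.fft.
* Symmetric splitting; consecutive half steps are *not* merged, so a
  homogeneous volume reduces bitwise to chained half-step kernels.
* Focus metrics (FWHM) by linear interpolation of half-max crossings;
  peak positions by argmax with 3×3 centroid refinement where sub-pixel
  matters.
* Tile lattices are centered in the grid; sources sit at integer pixel
  centers so the delta-emitter identity is exact.
* Degenerate inputs fail loudly: NaN fields, non-positive indices,
  mismatched pitches, undersampled NAs, foci outside the volume.

## Known limitations

No vectorial fields, no back-reflections or iterative schemes, no GPU
path, no camera MTF/pixelation beyond the grid, no photobleaching.
The embryo is parametric, not a replica of any real organism.  Memory-
effect and conjugation results are demonstrated on isotropic Gaussian
index statistics; anisotropic (fibrous) tissue changes the speckle
statistics and hence the iso-planatic patch.
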