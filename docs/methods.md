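# Methods

## Geometry and reciprocal mapping

Detector pixels map to reciprocal space per axis by the exact Bragg
relation d = λ/(2 sin θ) with θ = ½·atan(x/SDD), λ = 12.3984/E(keV) Å.
At the small angles of a muscle experiment (q ≲ 0.05 Å⁻¹) this differs
from the flat-detector approximation by <0.01%, but the exact form makes
the mapping an exact bijection, which the round-trip tests exploit.
Conventions: row 0 is the top of the TIFF raster; the meridian (fiber
axis) is vertical through the beam center; axial coordinates are quoted
in Å⁻¹ (spacings in Å), radial in nm⁻¹ (lattice spacings in nm);
q = 1/d with no 2π.  All conversion factors live in `units.py`.

## Image-plane operations

**Quadrant fold.** Each pixel is replaced by the mean of its up to four
mirror mates about the beam center, with off-detector or masked mates
excluded.  The implementation mirrors integer indices and therefore
requires the doubled beam-center coordinates to be integral (integer or
half-integer centers); this keeps the fold exact, idempotent, and
mean-conserving to float precision, which the oracle tests assert.  A
center that does not satisfy this is rejected rather than silently
interpolated.

**Background.** A measured background exposure (beam through the empty
cell) is subtracted pixelwise.  Negative residuals are kept signed —
clipping would bias the centroids — and their fraction is flagged in the
image metadata.  The diffuse scatter of the corrected image is modelled
as the azimuthal **median** radial profile (the median is insensitive to
the sparse Bragg features riding on the smooth diffuse component); its
sum over valid pixels is the normalization standard used for all
reflection intensities, so intensity ratios are comparable across
exposures of different length or flux.

## Reflection measurements

Axial projections sum counts over the radial band 0 ≤ R ≤ 0.053 nm⁻¹
(configurable) per axial bin and average the two meridian sides.  Peak
spacings are plain discrete intensity-weighted centroids of
baseline-corrected samples inside a window; the baseline is a local
linear fit through the outer 15% of window bins on each flank.  Default
windows are centered on the canonical spacings (27.3, 59, 51, 180,
127.5 Å) with half-widths of 1.2×10⁻³ Å⁻¹ for the layer lines and
1.5×10⁻³ Å⁻¹ for the meridionals — wide enough (≥5 peak σ at the
generator's default widths) that the flank bins sample background rather
than peak tails, narrow enough that ALL6 and ALL7 stay out of each
other's windows.  Intensities are Gaussian + linear-baseline fit areas
(amp·σ·√2π); the area rather than the amplitude is used because it is
invariant to modest width changes between states.

The ALL6 radial first maximum is located on the radial projection of the
layer-line window as the smallest-r local maximum exceeding 3× the local
noise SD, refined to sub-pixel precision by a quadratic fit through the
five surrounding samples (an intensity-centroid variant is available).
The parabolic refinement was chosen because the |J₁|² first lobe is broad
and asymmetric: a centroid over a fixed window inherits the ±half-pixel
quantization of the discrete argmax, while the parabola removes it; on
noiseless defaults the residual bias is ≤0.25% of R across R ∈ [4, 6] nm.

Equatorial analysis projects a narrow band (|z| ≤ 10⁻³ Å⁻¹) onto the
radial axis and Gaussian-fits the two innermost reflections; d₁,₀ = 1/r.
A missing 1,1 reflection yields an absent d₁,₁, not an error.

## Derived structure

Helix parameters follow the one-start pitch geometry (h from the
harmonic sum of the pitches, n = 1 + d₆/d₇).  The twist change between
conditions is computed as Δn/n with n evaluated per condition from its
own pitches; this assumes a pure rotation of subunits at constant rise,
an assumption checkable through the independence of the M13 spacing.
The filament radius uses R = c/(2πr) with c = 1.85 by field convention;
the exact J₁ argmax 1.84118 (verified in-code by numerical optimization)
is available everywhere by argument, and reports record which was used.

The deficit budget is additive percentage-point bookkeeping: lattice
term 100·(1 − (s_ref/s_test)²) — filament areal density ∝ 1/spacing² in
a hexagonal lattice, and the ratio is unchanged whether d₁,₀ or the
thin-thick distance (2/3)·d₁,₀ enters — plus the myofibrillar
fractional-area difference ×100.  The multiplicative combination
100·(1 − (1−l)(1−m)) is always computed and carried alongside, never
substituted.  Per-filament force uses the unit-cell area 2·d₁,₀²/√3
with two thin filaments per thick (configurable); 1 mN/mm² = 10⁻³
pN/nm².

Electron-micrograph lengths are rescaled by 1.6 µm/measured thick-
filament length (preparation shrinkage); optical thin-filament lengths
are half the separation of the two Gaussian-fitted pointed-end epitope
peaks flanking the Z-disk, with peak *detection* on a lightly smoothed
copy so noise cannot split one epitope into two, and fitting on raw data.

## Mechanics fits

All fits are bounded nonlinear least squares (scipy trust-region), with
data-driven initialization: extremes for the force plateaus, the
interpolated half-crossing for F50/pCa50, nH = 2, and the 63%-of-rise
time for the fast k_tr rate.  Bounds keep rates and nH positive because
unbounded Hill fits are multimodal.  The k_tr model is the two-phase
association form with both exponentials decaying and both amplitudes
tied to Fss; the fitted rates are returned sorted descending so "k_tr"
is always the fast phase.  Because the tied form fixes the amplitude
split at 50:50, a two-amplitude generalization is available
(`shared_amplitude=False`) and reports the fast-phase amplitude share.
The slack-test regression puts the measured delay on the left-hand side
(that is where the noise lives): delay = t₀ + distance/v, so v is the
reciprocal slope with a delta-method SE, and the intercept t₀ (activation
delay) is returned, not discarded.  Tetanus half-times are linear
interpolations between bracketing samples: rise from stimulus onset to
half the plateau maximum, relaxation from end-of-stimulation to half the
force at that moment; the rise reference point (stimulus onset vs force
onset) is a genuine convention choice and is configurable.

The one-curve-fits-all comparison is the extra-sum-of-squares F-test:
F = ((SS_pool − SS_sep)/(df_pool − df_sep))/(SS_sep/df_sep) with p from
the F distribution; it is verified against a brute-force SS computation
and calibrated by simulation (type-I error within [0.03, 0.07] at
α = 0.05 over 1000 null replicates).

## Synthetic data: what it emulates and what it does not

The pattern generator is the testbed standing in for detector data.  It
renders each reflection as a separable product of reciprocal-space
profiles: Gaussians for equatorials/meridionals, axial Gaussian ×
max-normalized, Gaussian-broadened |J_n(2πRr)|² for the layer lines
(n = 1 for ALL6/ALL7; n = 2 default for ALL2, configurable, since no
canonical order is established for it), an isotropic exponential diffuse
background, and optional Poisson sampling from one named RNG stream per
image (seed, state).  Ground truth is constructively consistent: the
M13 position equals the helix rise derived from the pitches unless an
activation strain overrides it.  Defaults: canonical 13/6 actin helix
(d₆ = 59.15 Å, d₇ = 50.70 Å, rise 27.30 Å), R = 5.2 nm, d₁,₀ = 36 nm,
TN3 at 1/127.5 Å⁻¹ (no canonical value; configurable), ALL2 at 180 Å,
512×512 pixels at SDD 900 mm so every analysed reflection is on the
detector, axial peak σ 2×10⁻⁴ Å⁻¹, 0.3% activation strain on M13 and
0.7 intensity scaling of ALL2/TN3 for rest/active pairs.  It does *not*
model cylindrically averaged transforms of an atomic actin model, myosin-
based reflections, fiber disorder/arcing, detector gaps' real topology,
or beam polarization — so passing tests demonstrate the correctness of
the measurement chain on well-formed peaks, not robustness to every
artifact of beamline data.  Mechanics traces are drawn from exactly the
fitted model families plus Gaussian noise; recovery tests therefore
check estimator correctness and bias, not model misspecification.

Problem sizes used in the automated checks (512×512 images; 200-500
Monte-Carlo seeds for bias checks; 1000 replicates for the F-test
calibration) were chosen as the smallest at which Monte-Carlo error is
comfortably below the tolerances being asserted.

## Known limitations

* The quadrant fold requires half-integer-aligned beam centers; real
  data with arbitrary centers must be re-centered upstream.
* The twist calculation uses pitch ratios only; analytical treatments
  exist that include radius terms, and no attempt is made to reproduce
  them.
* Intensity normalization is per-exposure (summed diffuse); per-muscle
  normalization schemes are not implemented.
* The deficit budget is bookkeeping, not a mechanical model: it assumes
  force strictly proportional to filament areal density and myofibrillar
  fraction.
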